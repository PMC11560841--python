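import numpy as np
import pytest

from sc3dmulti import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def small_config(**overrides) -> sd.SimConfig:
    """5-Mb single-type cohort used by fast unit tests."""
    defaults = dict(
        genome=[sd.ChromSpec("chr1", 5_000_000)],
        cell_types=[sd.CellTypeParams("a", 4, 0.7)],
        contacts_log_mean=float(np.log(5000)),
        contacts_log_sd=0.1,
        methylome=sd.MethylomeConfig(
            global_mcg={"a": 0.8}, global_mch={"a": 0.03},
            global_mccc={"a": 0.005}),
        seed=7,
    )
    defaults.update(overrides)
    return sd.SimConfig(**defaults)


@pytest.fixture(scope="session")
def mini_loop_cohort():
    """Planted-loop cohort on a 5-Mb chromosome (session-cached; ~10 s)."""
    cfg = sd.SimConfig(
        genome=[sd.ChromSpec("chr1", 5_000_000)],
        cell_types=[sd.CellTypeParams("a", 10, 0.8)],
        contacts_log_mean=float(np.log(8000)), contacts_log_sd=0.1,
        planted_loops=[
            sd.PlantedLoop(60, 80, {"a": 1.0}),
            sd.PlantedLoop(200, 260, {"a": 1.0}),
            sd.PlantedLoop(350, 380, {"a": 0.8}),
        ],
        methylome=sd.MethylomeConfig(
            global_mcg={"a": 0.8}, global_mch={"a": 0.03},
            global_mccc={"a": 0.005}),
        loop_contact_rate=0.004, seed=11)
    return sd.simulate_cohort(cfg)
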