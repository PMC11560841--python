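"""Synthetic snm3C-like cohorts with planted, recoverable structure.

A cohort is a set of cells from one or more cell types, each with

* a cis contact list drawn from a mixture of a distance-decay background
  (short log-uniform 25 kb - 2 Mb with probability ``pi_short``, else long
  log-uniform 2 Mb - chromosome span), a planted-loop component, a
  within-domain component shaped by planted boundaries, and a checkerboard
  compartment bias applied to long-range draws;
* an allc-style methylation table whose per-10-kb-bin mCG baseline is
  depressed at planted loop anchors by a logistic ramp in pseudotime whose
  midpoint trails the loop's activation onset by a configurable lag.

Everything planted is recorded in a :class:`TruthLedger` so downstream
recovery can be scored without external data.  Identical seed + config
give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import contact_distance
from .io_formats import write_json, read_json

SHORT_MIN = 25_000
SHORT_MAX = 2_000_000
LOOP_RES = 10_000
BOUNDARY_RES = 25_000
LOOP_MIN_SEP = 5      # bins at 10 kb  (50 kb)
LOOP_MAX_SEP = 500    # bins at 10 kb  (5 Mb)


class ConfigError(ValueError):
    pass


@dataclass
class ChromSpec:
    name: str = "chr1"
    length: int = 20_000_000


@dataclass
class CellTypeParams:
    name: str
    n_cells: int
    pi_short: float
    pseudotime_center: float = 0.5
    pseudotime_sd: float = 0.05
    pseudotime_uniform: bool = False    # U(0, 1) instead of the clipped normal


@dataclass
class PlantedLoop:
    bin1: int
    bin2: int
    strength: dict[str, float]          # per cell type
    onset: dict[str, float] = field(default_factory=dict)  # pseudotime midpoint
    differential: bool = False


@dataclass
class PlantedBoundary:
    bin25: int
    presence: dict[str, float]          # per-type per-cell presence probability


@dataclass
class CompartmentBlocks:
    block_size: int = 2_000_000
    amplitude: dict[str, float] = field(default_factory=dict)  # per type, [0, 1]


@dataclass
class MethylomeConfig:
    global_mcg: dict[str, float] = field(default_factory=dict)
    global_mch: dict[str, float] = field(default_factory=dict)
    global_mccc: dict[str, float] = field(default_factory=dict)
    baseline_sd: float = 0.03
    anchor_amplitude: float = 0.3
    lag: float = 0.0                    # pseudotime units, >= 0: mCG trails loops
    onset_tau: float = 0.05             # logistic scale for loop/mCG ramps
    cg_coverage: float = 20.0
    ch_sites_per_bin: int = 4
    ch_coverage: float = 20.0
    constant_coverage: bool = False


@dataclass
class SimConfig:
    genome: list[ChromSpec] = field(default_factory=lambda: [ChromSpec()])
    resolutions: tuple[int, ...] = (10_000, 25_000, 100_000, 1_000_000)
    cell_types: list[CellTypeParams] = field(default_factory=list)
    contacts_log_mean: float = float(np.log(20_000))
    contacts_log_sd: float = 0.1
    planted_loops: list[PlantedLoop] = field(default_factory=list)
    planted_boundaries: list[PlantedBoundary] = field(default_factory=list)
    compartment_blocks: CompartmentBlocks = field(default_factory=CompartmentBlocks)
    methylome: MethylomeConfig = field(default_factory=MethylomeConfig)
    loop_contact_rate: float = 0.0      # fraction of contacts per unit strength/loop
    domain_weight: float = 0.0          # fraction of contacts drawn within domains
    seed: int = 0

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if not self.genome or any(c.length <= 0 for c in self.genome):
            raise ConfigError("genome must contain chromosomes of positive length")
        if not self.cell_types:
            raise ConfigError("at least one cell type required")
        for ct in self.cell_types:
            if not 0.0 <= ct.pi_short <= 1.0:
                raise ConfigError(f"pi_short out of [0,1] for {ct.name}")
        for loop in self.planted_loops:
            sep = loop.bin2 - loop.bin1
            if not LOOP_MIN_SEP <= sep <= LOOP_MAX_SEP:
                raise ConfigError(
                    f"loop ({loop.bin1},{loop.bin2}) separation {sep} bins "
                    f"outside [{LOOP_MIN_SEP},{LOOP_MAX_SEP}]")
            hi = self.genome[0].length // LOOP_RES
            if loop.bin1 < 0 or loop.bin2 >= hi:
                raise ConfigError("loop pixel outside the genome")
        for b in self.planted_boundaries:
            for p in b.presence.values():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError("boundary presence probability out of [0,1]")
        for a in self.compartment_blocks.amplitude.values():
            if not 0.0 <= a <= 1.0:
                raise ConfigError("compartment amplitude out of [0,1]")
        if not np.isfinite(self.methylome.lag):
            raise ConfigError("methylome lag must be finite")

    @property
    def chrom(self) -> ChromSpec:
        return self.genome[0]


@dataclass
class TruthLedger:
    """Ground truth of everything the generator planted."""

    cells: pd.DataFrame          # cell_id, cell_type, pseudotime, conformation_class
    loops: pd.DataFrame          # chrom, bin1, bin2, strength_<type>..., differential
    boundaries: pd.DataFrame     # chrom, bin25, presence_<type>...
    compartment_sign: np.ndarray  # per 1-Mb bin, +1 / -1
    lag: float

    def to_json(self, path) -> None:
        write_json({
            "cells": self.cells.to_dict(orient="list"),
            "loops": self.loops.to_dict(orient="list"),
            "boundaries": self.boundaries.to_dict(orient="list"),
            "compartment_sign": self.compartment_sign,
            "lag": self.lag,
        }, path)

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        raw = read_json(path)
        return cls(
            cells=pd.DataFrame(raw["cells"]),
            loops=pd.DataFrame(raw["loops"]),
            boundaries=pd.DataFrame(raw["boundaries"]),
            compartment_sign=np.asarray(raw["compartment_sign"]),
            lag=raw["lag"],
        )


@dataclass
class Cohort:
    contacts: dict[str, pd.DataFrame]
    allc: dict[str, pd.DataFrame]
    annotations: dict[str, pd.DataFrame]
    truth: TruthLedger
    config: SimConfig


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _log_uniform(rng, lo: float, hi: float, size: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def loop_activation(loop: PlantedLoop, cell_type: str, pseudotime: float,
                    tau: float) -> float:
    """Planted loop strength for a cell: per-type base scaled by a logistic
    ramp centred at the per-type onset pseudotime (no onset => always on)."""
    base = loop.strength.get(cell_type, 0.0)
    onset = loop.onset.get(cell_type)
    if onset is None:
        return base
    return base * float(_logistic((pseudotime - onset) / tau))


def _block_sign(pos: np.ndarray, block_size: int) -> np.ndarray:
    return np.where((pos // block_size) % 2 == 0, 1, -1)


def simulate_contacts_for_cell(config: SimConfig, cell_type: str,
                               pseudotime: float, n_contacts: int,
                               rng, active_boundaries=None) -> pd.DataFrame:
    """Draw one cell's cis contact list (1-based bp, pos1 <= pos2)."""
    if n_contacts <= 0:
        raise ConfigError("n_contacts must be positive")
    L = config.chrom.length
    ct = next(c for c in config.cell_types if c.name == cell_type)
    tau = config.methylome.onset_tau

    # --- partition contacts across mixture components ---
    acts = np.array([loop_activation(l, cell_type, pseudotime, tau)
                     for l in config.planted_loops])
    p_loop = min(0.5, config.loop_contact_rate * float(acts.sum()))
    p_dom = config.domain_weight if config.planted_boundaries else 0.0
    n_loop = rng.binomial(n_contacts, p_loop) if p_loop > 0 else 0
    n_dom = rng.binomial(n_contacts - n_loop, p_dom) if p_dom > 0 else 0
    n_bg = n_contacts - n_loop - n_dom

    pos1_parts, pos2_parts = [], []

    # --- background: pi_short mixture with compartment bias on long draws ---
    if n_bg > 0:
        short = rng.random(n_bg) < ct.pi_short
        n_short, n_long = int(short.sum()), int(n_bg - short.sum())
        if n_short:
            d = _log_uniform(rng, SHORT_MIN, min(SHORT_MAX, L - 1), n_short)
            d = np.floor(d).astype(np.int64)
            p1 = rng.integers(1, L - d + 1)
            pos1_parts.append(p1)
            pos2_parts.append(p1 + d)
        if n_long and L > SHORT_MAX + 1:
            amp = config.compartment_blocks.amplitude.get(cell_type, 0.0)
            bias = rng.random(n_long) < amp
            d = np.floor(_log_uniform(rng, SHORT_MAX, L - 1, n_long)).astype(np.int64)
            p1 = rng.integers(1, L - d + 1)
            p2 = p1 + d
            if bias.any():
                bs = config.compartment_blocks.block_size
                # rejection rounds: redraw biased pairs until signs match
                todo = np.flatnonzero(
                    bias & (_block_sign(p1, bs) != _block_sign(p2, bs)))
                for _ in range(30):
                    if len(todo) == 0:
                        break
                    d_new = np.floor(
                        _log_uniform(rng, SHORT_MAX, L - 1, len(todo))
                    ).astype(np.int64)
                    p1_new = rng.integers(1, L - d_new + 1)
                    p2_new = p1_new + d_new
                    p1[todo], p2[todo] = p1_new, p2_new
                    todo = todo[_block_sign(p1_new, bs) != _block_sign(p2_new, bs)]
            pos1_parts.append(p1)
            pos2_parts.append(p2)

    # --- planted loops: uniform within the two 10-kb anchor bins ---
    if n_loop > 0:
        probs = acts / acts.sum()
        counts = rng.multinomial(n_loop, probs)
        for loop, c in zip(config.planted_loops, counts):
            if c == 0:
                continue
            p1 = loop.bin1 * LOOP_RES + rng.integers(1, LOOP_RES + 1, size=c)
            p2 = loop.bin2 * LOOP_RES + rng.integers(1, LOOP_RES + 1, size=c)
            pos1_parts.append(p1)
            pos2_parts.append(p2)

    # --- within-domain contacts shaped by this cell's active boundaries ---
    if n_dom > 0:
        if active_boundaries is None:
            active_boundaries = sample_active_boundaries(config, cell_type, rng)
        edges = np.concatenate([[0], np.sort(active_boundaries) * BOUNDARY_RES, [L]])
        lengths = np.diff(edges).astype(float)
        ok = lengths > 2 * SHORT_MIN
        weights = np.where(ok, lengths, 0.0)
        if weights.sum() > 0:
            weights /= weights.sum()
            choice = rng.choice(len(lengths), size=n_dom, p=weights)
            dmax = np.minimum(lengths[choice] - 1, SHORT_MAX)
            d = np.floor(np.exp(rng.uniform(
                np.log(SHORT_MIN), np.log(dmax)))).astype(np.int64)
            lo = edges[choice] + 1
            hi = edges[choice + 1] - d
            p1 = (lo + rng.random(n_dom) * (hi - lo + 1)).astype(np.int64)
            pos1_parts.append(p1)
            pos2_parts.append(p1 + d)

    pos1 = np.concatenate(pos1_parts) if pos1_parts else np.empty(0, np.int64)
    pos2 = np.concatenate(pos2_parts) if pos2_parts else np.empty(0, np.int64)
    swap = pos1 > pos2
    pos1[swap], pos2[swap] = pos2[swap], pos1[swap].copy()
    return pd.DataFrame({"chrom": config.chrom.name, "pos1": pos1, "pos2": pos2})


def sample_active_boundaries(config: SimConfig, cell_type: str, rng) -> np.ndarray:
    """Per-cell Bernoulli draw of which planted boundaries are present."""
    bins, keep = [], []
    for b in config.planted_boundaries:
        p = b.presence.get(cell_type, 0.0)
        bins.append(b.bin25)
        keep.append(rng.random() < p)
    return np.asarray(bins, dtype=np.int64)[np.asarray(keep, dtype=bool)]


def anchor_depression(config: SimConfig, cell_type: str,
                      pseudotime: float) -> dict[int, float]:
    """mCG depression per 10-kb anchor bin at a given pseudotime.

    The logistic midpoint of the methylation response is the loop onset
    plus the configured lag, so methylation trails conformation by ``lag``
    pseudotime units.  Loops without an onset depress anchors statically.
    """
    meth = config.methylome
    out: dict[int, float] = {}
    for loop in config.planted_loops:
        if loop.strength.get(cell_type, 0.0) <= 0:
            continue
        onset = loop.onset.get(cell_type)
        if onset is None:
            depth = meth.anchor_amplitude
        else:
            depth = meth.anchor_amplitude * float(
                _logistic((pseudotime - (onset + meth.lag)) / meth.onset_tau))
        for b in (loop.bin1, loop.bin2):
            out[b] = max(out.get(b, 0.0), depth)
    return out


def simulate_methylome_for_cell(config: SimConfig, cell_type: str,
                                pseudotime: float, rng,
                                baseline: np.ndarray) -> pd.DataFrame:
    """One cell's allc table: per-10-kb-bin CG counts plus CH/CCC sites."""
    meth = config.methylome
    L = config.chrom.length
    n_bins = L // LOOP_RES
    chrom = config.chrom.name

    m = baseline.copy()
    for b, depth in anchor_depression(config, cell_type, pseudotime).items():
        m[b] = baseline[b] - depth
    m = np.clip(m, 0.01, 0.99)

    if meth.constant_coverage:
        cov = np.full(n_bins, int(meth.cg_coverage), dtype=np.int64)
    else:
        cov = rng.poisson(meth.cg_coverage, size=n_bins)
    mc = rng.binomial(cov, m)
    frames = [pd.DataFrame({
        "chrom": chrom, "pos": np.arange(n_bins) * LOOP_RES + 1,
        "strand": "+", "context": "CGN", "mc": mc, "cov": cov,
    })]

    mch = meth.global_mch.get(cell_type, 0.01)
    mccc = meth.global_mccc.get(cell_type, 0.005)
    step = LOOP_RES // (meth.ch_sites_per_bin + 2)
    for k in range(meth.ch_sites_per_bin):
        cov_ch = rng.poisson(meth.ch_coverage, size=n_bins)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": np.arange(n_bins) * LOOP_RES + (k + 1) * step + 1,
            "strand": "+", "context": "CHH",
            "mc": rng.binomial(cov_ch, mch), "cov": cov_ch,
        }))
    cov_ccc = rng.poisson(meth.ch_coverage, size=n_bins)
    frames.append(pd.DataFrame({
        "chrom": chrom,
        "pos": np.arange(n_bins) * LOOP_RES + (meth.ch_sites_per_bin + 1) * step + 1,
        "strand": "+", "context": "CCC",
        "mc": rng.binomial(cov_ccc, mccc), "cov": cov_ccc,
    }))
    table = pd.concat(frames, ignore_index=True)
    table = table[table["cov"] > 0].reset_index(drop=True)
    table["methylated"] = (table["mc"] > 0).astype(np.int64)
    return table


def expected_conformation_class(config: SimConfig, ct: CellTypeParams) -> str:
    """Class of the type's expected valid-bin contact mixture.

    The loop and domain components always land in the median-distance
    block; background splits pi_short / (1 - pi_short).  This is the
    generator's own calibration, recorded in the truth ledger.
    """
    tau = config.methylome.onset_tau
    acts = sum(loop_activation(l, ct.name, ct.pseudotime_center, tau)
               for l in config.planted_loops)
    p_loop = min(0.5, config.loop_contact_rate * acts)
    p_dom = config.domain_weight if config.planted_boundaries else 0.0
    p_bg = 1.0 - p_loop - p_dom
    loop_median = 1.0
    if config.planted_loops:
        seps = np.array([l.bin2 - l.bin1 for l in config.planted_loops])
        loop_median = float(np.mean(seps * LOOP_RES < SHORT_MAX))
    m = p_loop * loop_median + p_dom + p_bg * ct.pi_short
    m = min(max(m, 1e-9), 1 - 1e-9)
    return contact_distance.classify(float(np.log2(m / (1 - m))))


def _make_annotations(config: SimConfig, rng) -> dict[str, pd.DataFrame]:
    L = config.chrom.length
    chrom = config.chrom.name

    n_genes = max(10, L // 500_000)
    tss = np.sort(rng.integers(100_000, L - 600_000, size=n_genes))
    length = rng.integers(20_000, 500_000, size=n_genes)
    strand = np.where(rng.random(n_genes) < 0.5, "+", "-")
    start = np.where(strand == "+", tss, np.maximum(tss - length, 0))
    end = np.where(strand == "+", np.minimum(tss + length, L), tss)
    genes = pd.DataFrame({
        "chrom": chrom, "start": start, "end": end,
        "name": [f"gene{i}" for i in range(n_genes)],
        "score": 0.0, "strand": strand,
    })

    n_mb = L // 1_000_000
    sign = _block_sign(np.arange(n_mb) * 1_000_000,
                       config.compartment_blocks.block_size)
    gc = pd.DataFrame({
        "chrom": chrom, "start": np.arange(n_mb) * 1_000_000,
        "end": (np.arange(n_mb) + 1) * 1_000_000,
        "name": "gc", "score": 0.41 + 0.03 * sign + rng.normal(0, 0.004, n_mb),
        "strand": ".",
    })

    # DMRs: one 500-bp interval inside each planted loop anchor (labelled by
    # the types with positive strength) plus unlabelled background DMRs.
    rows = []
    for loop in config.planted_loops:
        for b in (loop.bin1, loop.bin2):
            s = b * LOOP_RES + int(rng.integers(1000, LOOP_RES - 2000))
            types = ",".join(sorted(t for t, v in loop.strength.items() if v > 0))
            rows.append((chrom, s, s + 500, types or "none"))
    for _ in range(max(20, L // 400_000)):
        s = int(rng.integers(0, L - 600))
        rows.append((chrom, s, s + 500, "background"))
    dmrs = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    dmrs["score"] = 0.0
    dmrs["strand"] = "."
    dmrs = dmrs.sort_values("start", ignore_index=True)

    # fine-mapped-like SNPs: half planted inside anchor DMRs, half background
    anchor_dmrs = dmrs[dmrs["name"] != "background"]
    snp_rows = []
    for i, (_, d) in enumerate(anchor_dmrs.iterrows()):
        snp_rows.append((chrom, int(d.start) + 250, f"locus{i % 10}",
                         float(rng.uniform(0.15, 0.9))))
    for i in range(200):
        snp_rows.append((chrom, int(rng.integers(1, L)), f"bg{i}",
                         float(rng.uniform(0.0, 0.05))))
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos", "locus", "pip"])

    # motif hits enriched in anchor DMRs
    hit_rows = []
    for _, d in anchor_dmrs.iterrows():
        if rng.random() < 0.6:
            s = int(d.start) + 100
            hit_rows.append((chrom, s, s + 12))
    for _ in range(100):
        s = int(rng.integers(0, L - 12))
        hit_rows.append((chrom, s, s + 12))
    motifs = pd.DataFrame(hit_rows, columns=["chrom", "start", "end"])
    motifs["name"] = "motif"
    motifs["score"] = 0.0
    motifs["strand"] = "."

    return {"genes": genes, "gc": gc, "dmrs": dmrs, "snps": snps,
            "motifs": motifs}


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate contacts, methylomes, annotations and truth for a cohort."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    n_total = sum(ct.n_cells for ct in config.cell_types)
    seeds = root.spawn(n_total + 2)
    cohort_rng = np.random.default_rng(seeds[-1])
    anno_rng = np.random.default_rng(seeds[-2])

    n10 = config.chrom.length // LOOP_RES
    baselines = {
        ct.name: np.clip(
            config.methylome.global_mcg.get(ct.name, 0.75)
            + cohort_rng.normal(0, config.methylome.baseline_sd, size=n10),
            0.05, 0.95)
        for ct in config.cell_types
    }

    contacts: dict[str, pd.DataFrame] = {}
    allc: dict[str, pd.DataFrame] = {}
    cell_rows = []
    i = 0
    for ct in config.cell_types:
        expected_class = expected_conformation_class(config, ct)
        for j in range(ct.n_cells):
            rng = np.random.default_rng(seeds[i])
            cell_id = f"{ct.name}_{j:04d}"
            if ct.pseudotime_uniform:
                pt = float(rng.uniform(0.0, 1.0))
            else:
                pt = float(np.clip(rng.normal(ct.pseudotime_center,
                                              ct.pseudotime_sd), 0.0, 1.0))
            n_contacts = max(1, int(rng.lognormal(config.contacts_log_mean,
                                                  config.contacts_log_sd)))
            tab = simulate_contacts_for_cell(config, ct.name, pt, n_contacts, rng)
            tab.insert(0, "cell_id", cell_id)
            contacts[cell_id] = tab
            allc[cell_id] = simulate_methylome_for_cell(
                config, ct.name, pt, rng, baselines[ct.name])
            cell_rows.append((cell_id, ct.name, pt, expected_class))
            i += 1

    cells = pd.DataFrame(cell_rows, columns=[
        "cell_id", "cell_type", "pseudotime", "conformation_class"])

    loops = pd.DataFrame([{
        "chrom": config.chrom.name, "bin1": l.bin1, "bin2": l.bin2,
        "differential": l.differential,
        **{f"strength_{t}": v for t, v in l.strength.items()},
        **{f"onset_{t}": v for t, v in l.onset.items()},
    } for l in config.planted_loops])
    boundaries = pd.DataFrame([{
        "chrom": config.chrom.name, "bin25": b.bin25,
        **{f"presence_{t}": v for t, v in b.presence.items()},
    } for b in config.planted_boundaries])
    n_mb = config.chrom.length // 1_000_000
    comp_sign = _block_sign(np.arange(n_mb) * 1_000_000,
                            config.compartment_blocks.block_size)

    truth = TruthLedger(cells=cells, loops=loops, boundaries=boundaries,
                        compartment_sign=comp_sign, lag=config.methylome.lag)
    annotations = _make_annotations(config, anno_rng)
    return Cohort(contacts=contacts, allc=allc, annotations=annotations,
                  truth=truth, config=config)


def config_to_json(config: SimConfig, path) -> None:
    write_json(asdict(config), path)


def config_from_json(path) -> SimConfig:
    raw = read_json(path)
    raw["genome"] = [ChromSpec(**c) for c in raw["genome"]]
    raw["cell_types"] = [CellTypeParams(**c) for c in raw["cell_types"]]
    raw["planted_loops"] = [PlantedLoop(**c) for c in raw["planted_loops"]]
    raw["planted_boundaries"] = [PlantedBoundary(**c)
                                 for c in raw["planted_boundaries"]]
    raw["compartment_blocks"] = CompartmentBlocks(**raw["compartment_blocks"])
    raw["methylome"] = MethylomeConfig(**raw["methylome"])
    raw["resolutions"] = tuple(raw["resolutions"])
    return SimConfig(**raw)
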