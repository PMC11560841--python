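"""End-to-end orchestration of the per-cell and pseudobulk stages.

These runners take a cohort's contact/methylome dictionaries (as produced
by :mod:`sc3dmulti.synthetic_data` or read from disk) and drive the matrix,
loop, domain, compartment, embedding and meta-cell stages.  They exist so
the CLI, the tests and the acceptance script all exercise one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import (compartment_analysis, contact_distance, domain_analysis,
               loop_analysis, matrix_core, metacell_dynamics,
               methylome_features)

LOOP_RES = 10_000
LOOP_MAX_DIST = 5_050_000
DOMAIN_RES = 25_000
DOMAIN_MAX_DIST = 10_050_000
EMBED_RES = 100_000
COMP_RES = 1_000_000


def _n_bins(chrom_length: int, resolution: int) -> int:
    return -(-chrom_length // resolution)


# ---------------------------------------------------------------------------
# loop stage
# ---------------------------------------------------------------------------

@dataclass
class LoopStageResult:
    pseudobulks: dict[str, matrix_core.PseudobulkStats]
    shuffled: dict[str, matrix_core.PseudobulkStats]
    calls: dict[str, pd.DataFrame]
    tested_loops: pd.DataFrame              # union of called pixels
    differential: pd.DataFrame | None
    tracked_q: dict[str, np.ndarray] = field(default_factory=dict)
    band: int = 0


def loop_stage(contacts: dict[str, pd.DataFrame], chrom_length: int,
               groups: dict[str, str], seed: int = 0,
               track_pixels: pd.DataFrame | None = None,
               thresholds: loop_analysis.LoopThresholds | None = None,
               chrom: str = "chr1") -> LoopStageResult:
    """Impute every cell at 10 kb, aggregate per-group pseudobulks (observed
    and diagonal-shuffled), call loops per group, and test the union of
    called pixels for differential strength across groups.

    ``track_pixels`` (columns bin1/bin2) optionally records every cell's
    imputed Q at those pixels for downstream meta-cell profiling.
    """
    n = _n_bins(chrom_length, LOOP_RES)
    band = LOOP_MAX_DIST // LOOP_RES
    obs = {g: matrix_core.PseudobulkAccumulator() for g in set(groups.values())}
    shuf = {g: matrix_core.PseudobulkAccumulator() for g in set(groups.values())}
    tracked: dict[str, np.ndarray] = {}
    tp = None
    if track_pixels is not None:
        tp = (track_pixels["bin1"].to_numpy(), track_pixels["bin2"].to_numpy())

    root = np.random.SeedSequence(seed)
    for cell_id, seq in zip(sorted(contacts), root.spawn(len(contacts))):
        g = groups[cell_id]
        tab = contacts[cell_id]
        raw = matrix_core.contacts_to_matrix(
            tab["pos1"], tab["pos2"], n, LOOP_RES)
        q, e, t = matrix_core.cell_triplet(raw, pad=2,
                                           max_distance=LOOP_MAX_DIST,
                                           resolution=LOOP_RES)
        obs[g].add(q, e, t)
        rng = np.random.default_rng(seq)
        e_s = matrix_core.shuffle_diagonals(e, band, rng)
        t_s = matrix_core.subtract_local_background(e_s, band)
        shuf[g].add(q, e_s, t_s)
        if tp is not None:
            tracked[cell_id] = q[tp].astype(np.float64)

    pseudobulks = {g: acc.finalize() for g, acc in obs.items()}
    shuffled = {g: acc.finalize() for g, acc in shuf.items()}
    calls = {g: loop_analysis.call_loops(pseudobulks[g], shuffled[g], band,
                                         thresholds, chrom=chrom)
             for g in pseudobulks}

    called = [c.loc[c["is_loop"], ["chrom", "bin1", "bin2"]] for c in calls.values()]
    tested = (pd.concat(called, ignore_index=True)
              .drop_duplicates(ignore_index=True)
              .sort_values(["bin1", "bin2"], ignore_index=True))

    differential = None
    if len(tested) >= 2 and len(pseudobulks) >= 2:
        px = (tested["bin1"].to_numpy(), tested["bin2"].to_numpy())
        names = sorted(pseudobulks)
        f_q = loop_analysis.anova_from_summaries(
            [(pseudobulks[g].n_cell, pseudobulks[g].Q[px],
              pseudobulks[g].Q2[px]) for g in names])
        f_t = loop_analysis.anova_from_summaries(
            [(pseudobulks[g].n_cell, pseudobulks[g].T[px],
              pseudobulks[g].T2[px]) for g in names])
        differential = pd.concat(
            [tested.reset_index(drop=True),
             loop_analysis.select_differential(f_q, f_t)], axis=1)
        for g in names:
            differential[f"E_{g}"] = pseudobulks[g].E[px]

    return LoopStageResult(pseudobulks=pseudobulks, shuffled=shuffled,
                           calls=calls, tested_loops=tested,
                           differential=differential, tracked_q=tracked,
                           band=band)


def track_loop_q(contacts: dict[str, pd.DataFrame], chrom_length: int,
                 pixels: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-cell imputed Q at the given 10-kb pixels (no pseudobulks)."""
    n = _n_bins(chrom_length, LOOP_RES)
    tp = (pixels["bin1"].to_numpy(), pixels["bin2"].to_numpy())
    out = {}
    for cell_id in sorted(contacts):
        tab = contacts[cell_id]
        raw = matrix_core.contacts_to_matrix(
            tab["pos1"], tab["pos2"], n, LOOP_RES)
        q = matrix_core.impute(raw, pad=2, max_distance=LOOP_MAX_DIST,
                               resolution=LOOP_RES)
        out[cell_id] = q[tp].astype(np.float64)
    return out


# ---------------------------------------------------------------------------
# domain stage
# ---------------------------------------------------------------------------

@dataclass
class DomainStageResult:
    calls_by_group: dict[str, np.ndarray]
    insulation_by_group: dict[str, np.ndarray]
    boundary_prob: pd.DataFrame
    differential: pd.DataFrame


def domain_stage(contacts: dict[str, pd.DataFrame], chrom_length: int,
                 groups: dict[str, str], window: int = 10,
                 margin: float = 0.02) -> DomainStageResult:
    """Per-cell 25-kb boundary calls, group insulation, differential bins."""
    n = _n_bins(chrom_length, DOMAIN_RES)
    cells = sorted(contacts)
    group_names = sorted(set(groups.values()))
    calls = {g: [] for g in group_names}
    acc = {g: matrix_core.PseudobulkAccumulator() for g in group_names}
    for cell_id in cells:
        tab = contacts[cell_id]
        raw = matrix_core.contacts_to_matrix(
            tab["pos1"], tab["pos2"], n, DOMAIN_RES)
        q = matrix_core.impute(raw, pad=2, max_distance=DOMAIN_MAX_DIST,
                               resolution=DOMAIN_RES)
        g = groups[cell_id]
        calls[g].append(domain_analysis.percell_boundaries(q, window, margin))
        acc[g].add(q, q, q)  # only Q is consumed downstream
    calls_by_group = {g: np.stack(v) for g, v in calls.items()}
    insulation_by_group = {
        g: domain_analysis.insulation_score(acc[g].finalize().Q, window)
        for g in group_names}
    prob = domain_analysis.boundary_probability(
        np.concatenate([calls_by_group[g] for g in group_names]),
        np.concatenate([[g] * calls_by_group[g].shape[0] for g in group_names]))
    diff = domain_analysis.differential_boundaries(
        calls_by_group, insulation_by_group)
    return DomainStageResult(calls_by_group=calls_by_group,
                             insulation_by_group=insulation_by_group,
                             boundary_prob=prob, differential=diff)


# ---------------------------------------------------------------------------
# compartment stage
# ---------------------------------------------------------------------------

@dataclass
class CompartmentStageResult:
    tracks: dict[str, np.ndarray]
    saddles: dict[str, compartment_analysis.SaddleStats]


def compartment_stage(contacts: dict[str, pd.DataFrame], chrom_length: int,
                      groups: dict[str, str],
                      gc_track: np.ndarray) -> CompartmentStageResult:
    """Raw 1-Mb pseudobulk per group -> eigenvector + saddle strength."""
    n = _n_bins(chrom_length, COMP_RES)
    group_names = sorted(set(groups.values()))
    mats = {g: np.zeros((n, n)) for g in group_names}
    counts = {g: 0.0 for g in group_names}
    for cell_id, tab in contacts.items():
        g = groups[cell_id]
        mats[g] += matrix_core.contacts_to_matrix(
            tab["pos1"], tab["pos2"], n, COMP_RES)
        counts[g] += len(tab)
    tracks, saddles = {}, {}
    for g in group_names:
        track = compartment_analysis.compartment_eigenvector(mats[g], gc_track)
        oe = compartment_analysis.oe_matrix(mats[g])
        tracks[g] = track
        saddles[g] = compartment_analysis.saddle_stats(
            oe, track, n_contacts=counts[g])
    return CompartmentStageResult(tracks=tracks, saddles=saddles)


# ---------------------------------------------------------------------------
# embedding + distance stages
# ---------------------------------------------------------------------------

def distance_stage(contacts: dict[str, pd.DataFrame],
                   k: int = 10, seed: int = 0) -> pd.DataFrame:
    """Per-cell 143-bin histograms -> SE/LE/INT metrics and k-means cluster."""
    cells = sorted(contacts)
    hists = np.stack([
        contact_distance.bin_distances(
            contacts[c]["pos2"].to_numpy() - contacts[c]["pos1"].to_numpy())
        for c in cells])
    table = contact_distance.metrics_table(hists, cells)
    if len(cells) >= k:
        table["cluster"] = contact_distance.cluster_profiles(hists, k, seed)
    return table


def embedding_stage(contacts: dict[str, pd.DataFrame], chrom_length: int,
                    dims: int = 20) -> tuple[np.ndarray, list[str]]:
    """100-kb imputation (pad=1) -> 100 kb - 1 Mb pixels -> SVD embedding."""
    n = _n_bins(chrom_length, EMBED_RES)
    cells = sorted(contacts)
    feats = []
    for cell_id in cells:
        tab = contacts[cell_id]
        raw = matrix_core.contacts_to_matrix(
            tab["pos1"], tab["pos2"], n, EMBED_RES)
        q = matrix_core.impute(raw, pad=1, max_distance=(n - 1) * EMBED_RES,
                               resolution=EMBED_RES)
        feats.append(matrix_core.embedding_features(q))
    dims = min(dims, len(cells))
    return matrix_core.embed_cells(np.stack(feats), dims), cells


# ---------------------------------------------------------------------------
# meta-cell stage
# ---------------------------------------------------------------------------

def metacell_stage(embedding: np.ndarray, cells: list[str],
                   allc: dict[str, pd.DataFrame],
                   tracked_q: dict[str, np.ndarray],
                   loops: pd.DataFrame,
                   pseudotime: dict[str, float], chrom_length: int,
                   k: int = 20, max_shift: int = 5,
                   min_overlap: int = 10) -> metacell_dynamics.CrossCorrResult:
    """Meta-cells -> pooled anchor mCG + mean loop Q -> cross-correlation."""
    n10 = _n_bins(chrom_length, LOOP_RES)
    mcg_counts = {}
    for c in cells:
        tab = allc[c]
        cg = tab[methylome_features.context_class_mask(tab["context"], "CG")]
        mc = np.zeros(n10)
        cov = np.zeros(n10)
        bins = (cg["pos"].to_numpy() - 1) // LOOP_RES
        np.add.at(mc, bins, cg["mc"].to_numpy())
        np.add.at(cov, bins, cg["cov"].to_numpy())
        mcg_counts[c] = (mc, cov)

    metas = metacell_dynamics.build_metacells(embedding, cells, k)
    metas = metacell_dynamics.deduplicate(metas)
    profiles = metacell_dynamics.metacell_profiles(
        metas, mcg_counts, tracked_q, pseudotime)
    for m in profiles:
        m.mcg = metacell_dynamics.anchor_mcg_per_loop(m.mcg, loops)
    return metacell_dynamics.loop_methylation_crosscorr(
        profiles, max_shift, min_overlap)


# ---------------------------------------------------------------------------
# whole-cohort convenience runner
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    distance: pd.DataFrame
    loops: LoopStageResult
    domains: DomainStageResult
    compartments: CompartmentStageResult
    embedding: np.ndarray
    cells: list[str]
    crosscorr: metacell_dynamics.CrossCorrResult | None
    gene_mcg: pd.DataFrame | None = None


def run_full_pipeline(cohort, group_by: str = "cell_type",
                      seed: int = 0, metacell_k: int = 20,
                      max_shift: int = 5) -> PipelineResult:
    """Every stage on a synthetic cohort, grouped by a truth column."""
    truth = cohort.truth
    chrom_length = cohort.config.chrom.length
    groups = dict(zip(truth.cells["cell_id"], truth.cells[group_by]))
    pseudotime = dict(zip(truth.cells["cell_id"], truth.cells["pseudotime"]))

    dist = distance_stage(cohort.contacts,
                          k=min(10, len(cohort.contacts)), seed=seed)
    track = truth.loops[["bin1", "bin2"]] if len(truth.loops) else None
    loops = loop_stage(cohort.contacts, chrom_length, groups, seed=seed,
                       track_pixels=track)
    domains = domain_stage(cohort.contacts, chrom_length, groups)
    gc = cohort.annotations["gc"]["score"].to_numpy()
    comps = compartment_stage(cohort.contacts, chrom_length, groups, gc)
    embedding, cells = embedding_stage(cohort.contacts, chrom_length)

    crosscorr = None
    if track is not None and len(cohort.allc) and \
            len(cells) >= 2 * max_shift + 10 and len(cells) >= metacell_k:
        try:
            crosscorr = metacell_stage(
                embedding, cells, cohort.allc, loops.tracked_q, truth.loops,
                pseudotime, chrom_length, k=metacell_k, max_shift=max_shift)
        except ValueError:
            # deduplication can leave too few meta-cells for the shift
            # window on small cohorts; the stage is then skipped
            crosscorr = None

    genes = methylome_features.expand_gene_bodies(
        cohort.annotations["genes"], chrom_length=chrom_length)
    vals, cov = methylome_features.feature_matrix(cohort.allc, genes, "CG")
    samples = [groups[c] for c in vals.index]
    gene_mcg = methylome_features.filter_impute_features(vals, cov, samples)

    return PipelineResult(distance=dist, loops=loops, domains=domains,
                          compartments=comps, embedding=embedding,
                          cells=cells, crosscorr=crosscorr, gene_mcg=gene_mcg)
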