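"""Regulatory overlap statistics: loop-connected DMRs, motif enrichment,
fine-mapped SNP overlap, SNP-gene linking, and the enrichment-difference
t-test on jackknife standard errors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom
from scipy.stats import t as t_dist

PIP_THRESHOLD = 0.1
DMR_EXTENSION = 250
TSS_ANCHOR_DIST = 5_000


def _overlaps_any(starts, ends, other_starts, other_ends) -> np.ndarray:
    """Boolean per (start, end) interval: >= 1 bp overlap with any other.

    Half-open intervals; O(n log n) sweep via cumulative max of ends.
    """
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    os = np.asarray(other_starts)
    oe = np.asarray(other_ends)
    if len(os) == 0 or len(starts) == 0:
        return np.zeros(len(starts), dtype=bool)
    order = np.argsort(os)
    os, oe = os[order], oe[order]
    run_max_end = np.maximum.accumulate(oe)
    # candidates with other.start < end
    idx = np.searchsorted(os, ends, side="left")
    out = np.zeros(len(starts), dtype=bool)
    nonzero = idx > 0
    out[nonzero] = run_max_end[idx[nonzero] - 1] > starts[nonzero]
    return out


def loop_anchor_intervals(loops: pd.DataFrame, resolution: int) -> pd.DataFrame:
    """Both anchors of each loop as 0-based half-open intervals."""
    frames = []
    for col in ("bin1", "bin2"):
        frames.append(pd.DataFrame({
            "chrom": loops["chrom"],
            "start": loops[col] * resolution,
            "end": (loops[col] + 1) * resolution,
            "loop_index": loops.index,
            "anchor": col,
        }))
    return pd.concat(frames, ignore_index=True)


def loop_connected_dmrs(dmrs: pd.DataFrame, loops: pd.DataFrame,
                        resolution: int = 10_000) -> pd.DataFrame:
    """DMRs overlapping (>= 1 bp) any loop anchor of the matching type."""
    anchors = loop_anchor_intervals(loops, resolution)
    keep = np.zeros(len(dmrs), dtype=bool)
    for chrom in dmrs["chrom"].unique():
        dm = dmrs["chrom"] == chrom
        an = anchors["chrom"] == chrom
        keep[np.flatnonzero(dm)] = _overlaps_any(
            dmrs.loc[dm, "start"], dmrs.loc[dm, "end"],
            anchors.loc[an, "start"], anchors.loc[an, "end"])
    return dmrs.loc[keep].reset_index(drop=True)


def extend_from_edges(intervals: pd.DataFrame, pad: int = DMR_EXTENSION
                      ) -> pd.DataFrame:
    out = intervals.copy()
    out["start"] = np.maximum(out["start"] - pad, 0)
    out["end"] = out["end"] + pad
    return out


def extend_from_centre(intervals: pd.DataFrame, pad: int = DMR_EXTENSION
                       ) -> pd.DataFrame:
    out = intervals.copy()
    centre = (out["start"] + out["end"]) // 2
    out["start"] = np.maximum(centre - pad, 0)
    out["end"] = centre + pad
    return out


@dataclass
class MotifEnrichment:
    x: int       # foreground DMRs overlapping a hit
    n: int       # foreground DMRs
    K: int       # background DMRs overlapping a hit
    N: int       # background DMRs
    fold: float
    pvalue: float


def motif_enrichment(fg_dmrs: pd.DataFrame, bg_dmrs: pd.DataFrame,
                     motif_hits: pd.DataFrame) -> MotifEnrichment:
    """Hypergeometric motif enrichment of foreground vs background DMRs.

    Foreground DMRs are extended +/-250 bp from their edges, background
    +/-250 bp from their centres; overlap needs >= 1 bp.  p is the
    upper-tail P(X >= x) for x successes among n draws from a population
    of N with K successes.
    """
    fg = extend_from_edges(fg_dmrs)
    bg = extend_from_centre(bg_dmrs)

    def n_hit(ivs):
        total = 0
        for chrom in ivs["chrom"].unique():
            sub = ivs[ivs["chrom"] == chrom]
            hits = motif_hits[motif_hits["chrom"] == chrom]
            total += int(_overlaps_any(sub["start"], sub["end"],
                                       hits["start"], hits["end"]).sum())
        return total

    x, n = n_hit(fg), len(fg)
    K, N = n_hit(bg), len(bg)
    p = float(hypergeom.sf(x - 1, N, K, n)) if x > 0 else 1.0
    fold = np.inf if K == 0 else (x / n) / (K / N)
    return MotifEnrichment(x=x, n=n, K=K, N=N, fold=fold, pvalue=p)


@dataclass
class FinemapOverlap:
    table: np.ndarray          # 2x2 [[a, b], [c, d]]
    odds_ratio: float
    pvalue: float
    locus_hits: pd.DataFrame   # locus, any_overlap


def filter_pip(snps: pd.DataFrame, threshold: float = PIP_THRESHOLD
               ) -> pd.DataFrame:
    return snps[snps["pip"] > threshold].reset_index(drop=True)


def _snp_in_annotation(snps: pd.DataFrame, annot: pd.DataFrame) -> np.ndarray:
    out = np.zeros(len(snps), dtype=bool)
    for chrom in snps["chrom"].unique():
        sm = (snps["chrom"] == chrom).to_numpy()
        an = annot[annot["chrom"] == chrom]
        pos0 = snps.loc[sm, "pos"].to_numpy() - 1
        out[np.flatnonzero(sm)] = _overlaps_any(
            pos0, pos0 + 1, an["start"], an["end"])
    return out


def finemap_overlap(snps: pd.DataFrame, annotation: pd.DataFrame,
                    background_snps: pd.DataFrame) -> FinemapOverlap:
    """Fisher overlap of PIP-filtered fine-mapped SNPs with an annotation.

    a/b: fine-mapped SNPs in/out of the annotation; c/d: background SNPs
    in/out.  OR = ad/bc with an inf sentinel on zero margins (no Haldane
    correction); per-locus indicator = any member SNP in the annotation.
    """
    fm = filter_pip(snps)
    in_ann = _snp_in_annotation(fm, annotation)
    bg_in = _snp_in_annotation(background_snps, annotation)
    a, b = int(in_ann.sum()), int((~in_ann).sum())
    c, d = int(bg_in.sum()), int((~bg_in).sum())
    table = np.array([[a, b], [c, d]])
    orat = np.inf if b * c == 0 else (a * d) / (b * c)
    p = float(fisher_exact(table, alternative="two-sided")[1])
    locus_hits = (pd.DataFrame({"locus": fm["locus"], "hit": in_ann})
                  .groupby("locus")["hit"].any().rename("any_overlap")
                  .reset_index())
    return FinemapOverlap(table=table, odds_ratio=orat, pvalue=p,
                          locus_hits=locus_hits)


def link_snp_to_genes(snps: pd.DataFrame, dmrs: pd.DataFrame,
                      loops: pd.DataFrame, tss_table: pd.DataFrame,
                      resolution: int = 10_000,
                      max_tss_dist: int = TSS_ANCHOR_DIST) -> pd.DataFrame:
    """(SNP, gene) pairs connected through a chromatin loop.

    A pair qualifies iff the SNP lies in a DMR overlapping one anchor and
    the gene's TSS is within ``max_tss_dist`` of the *other* anchor
    (cross-anchor only).  ``tss_table`` needs columns chrom, tss (0-based
    bp), name.  Duplicates are collapsed.
    """
    pairs = set()
    for _, loop in loops.iterrows():
        anchors = []
        for col in ("bin1", "bin2"):
            s = int(loop[col]) * resolution
            anchors.append((s, s + resolution))
        for a_idx, (a_s, a_e) in enumerate(anchors):
            dm = dmrs[(dmrs["chrom"] == loop["chrom"])
                      & (dmrs["end"] > a_s) & (dmrs["start"] < a_e)]
            if len(dm) == 0:
                continue
            pos0 = snps["pos"].to_numpy() - 1
            snp_in_dmr = np.zeros(len(snps), dtype=bool)
            same_chrom = (snps["chrom"] == loop["chrom"]).to_numpy()
            snp_in_dmr[same_chrom] = _overlaps_any(
                pos0[same_chrom], pos0[same_chrom] + 1, dm["start"], dm["end"])
            if not snp_in_dmr.any():
                continue
            o_s, o_e = anchors[1 - a_idx]
            t = tss_table[tss_table["chrom"] == loop["chrom"]]
            gap = (np.maximum(o_s - t["tss"].to_numpy(), 0)
                   + np.maximum(t["tss"].to_numpy() - (o_e - 1), 0))
            genes = t.loc[gap <= max_tss_dist, "name"]
            for si in np.flatnonzero(snp_in_dmr):
                snp_key = (snps.iloc[si]["chrom"], int(snps.iloc[si]["pos"]))
                for g in genes:
                    pairs.add((snp_key[0], snp_key[1], g))
    return pd.DataFrame(sorted(pairs), columns=["chrom", "pos", "gene"])


def mean_credible_set_size(n_snps: int, n_loci: int) -> float:
    """Average number of retained fine-mapped SNPs per independent locus."""
    if n_loci <= 0:
        raise ValueError("need at least one locus")
    return n_snps / n_loci


def enrichment_difference_test(e1: float, se1: float, e2: float, se2: float,
                               n_blocks: int = 200) -> tuple[float, float]:
    """Two-sample t-test on jackknife SEs with d.f. = 2 * n_blocks - 2."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    t = (e1 - e2) / np.sqrt(se1 ** 2 + se2 ** 2)
    df = 2 * n_blocks - 2
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return float(t), p
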