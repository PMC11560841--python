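"""Cell QC, methylation feature matrices, 3CGS, and feature correlations."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import pos_to_bin

QC_MCCC_MAX = 0.03
QC_MCG_MIN = 0.5
QC_MCH_MAX = 0.2
QC_CONTACTS_MIN = 100_000


def classify_context(context: str) -> str:
    """Collapse a 3-mer context to its class: CG, CCC, or CH.

    CCC sites proxy bisulfite non-conversion; they also count as CH when a
    CH total is requested (see :func:`context_class_mask`).
    """
    if context.startswith("CG"):
        return "CG"
    if context == "CCC":
        return "CCC"
    return "CH"


def context_class_mask(contexts: pd.Series, context: str) -> np.ndarray:
    cls = contexts.map(classify_context)
    if context == "CG":
        return (cls == "CG").to_numpy()
    if context == "CCC":
        return (cls == "CCC").to_numpy()
    if context == "CH":
        return ((cls == "CH") | (cls == "CCC")).to_numpy()
    raise ValueError(f"unknown context class {context!r}")


def global_methylation(allc: pd.DataFrame, context: str) -> float:
    mask = context_class_mask(allc["context"], context)
    cov = allc.loc[mask, "cov"].sum()
    return float(allc.loc[mask, "mc"].sum() / cov) if cov else np.nan


def cell_qc(metadata: pd.DataFrame) -> pd.DataFrame:
    """Strict four-way QC conjunction on per-cell metadata.

    Requires columns mccc_level, global_mcg, global_mch, n_contacts; all
    comparators are strict, exactly as printed.
    """
    required = ["mccc_level", "global_mcg", "global_mch", "n_contacts"]
    missing = [c for c in required if c not in metadata.columns]
    if missing:
        raise ValueError(f"missing QC metrics: {missing}")
    if metadata[required].isna().any().any():
        raise ValueError("missing QC metric values")
    out = metadata.copy()
    out["pass"] = (
        (out["mccc_level"] < QC_MCCC_MAX)
        & (out["global_mcg"] > QC_MCG_MIN)
        & (out["global_mch"] < QC_MCH_MAX)
        & (out["n_contacts"] > QC_CONTACTS_MIN)
    )
    return out


def expand_gene_bodies(genes: pd.DataFrame, flank: int = 2_000,
                       chrom_length: int | None = None) -> pd.DataFrame:
    """Gene body +/- flank, clipped at chromosome bounds."""
    out = genes.copy()
    out["start"] = np.maximum(out["start"] - flank, 0)
    out["end"] = out["end"] + flank
    if chrom_length is not None:
        out["end"] = np.minimum(out["end"], chrom_length)
    return out


def region_methylation(allc: pd.DataFrame, regions: pd.DataFrame,
                       context: str) -> pd.DataFrame:
    """Per-region methylated fraction and coverage for one cell.

    Fraction = sum(mc) / sum(cov) over records of the context class whose
    1-based position falls inside the 0-based half-open region.  Regions
    with zero coverage get NaN fraction and zero coverage.
    """
    mask = context_class_mask(allc["context"], context)
    sub = allc.loc[mask]
    pos0 = sub["pos"].to_numpy() - 1  # to 0-based
    mc = sub["mc"].to_numpy()
    cov = sub["cov"].to_numpy()
    order = np.argsort(pos0)
    pos0, mc, cov = pos0[order], mc[order], cov[order]
    cmc = np.concatenate([[0], np.cumsum(mc)])
    ccov = np.concatenate([[0], np.cumsum(cov)])
    lo = np.searchsorted(pos0, regions["start"].to_numpy(), side="left")
    hi = np.searchsorted(pos0, regions["end"].to_numpy(), side="left")
    mc_sum = cmc[hi] - cmc[lo]
    cov_sum = ccov[hi] - ccov[lo]
    frac = np.divide(mc_sum, cov_sum, out=np.full(len(regions), np.nan),
                     where=cov_sum > 0)
    return pd.DataFrame({"name": regions["name"].to_numpy(),
                         "fraction": frac, "coverage": cov_sum})


def feature_matrix(allc_by_cell: dict[str, pd.DataFrame],
                   regions: pd.DataFrame, context: str):
    """(values, coverage) cell x region DataFrames across a cohort."""
    values, covers = {}, {}
    for cell_id, allc in allc_by_cell.items():
        r = region_methylation(allc, regions, context)
        values[cell_id] = r["fraction"].to_numpy()
        covers[cell_id] = r["coverage"].to_numpy()
    names = regions["name"].to_numpy()
    return (pd.DataFrame(values, index=names).T,
            pd.DataFrame(covers, index=names).T)


def filter_impute_features(values: pd.DataFrame, coverage: pd.DataFrame,
                           sample_labels) -> pd.DataFrame:
    """Coverage-based feature filtering and low-coverage imputation.

    Features with mean coverage < 10 are dropped.  Entries with coverage
    < 5 are replaced by the sample's mean of that feature over its
    well-covered (coverage >= 5) entries; features for which some sample
    has no well-covered entry are dropped.
    """
    samples = pd.Series(np.asarray(sample_labels), index=values.index)
    keep = coverage.mean(axis=0) >= 10
    values = values.loc[:, keep].copy()
    coverage = coverage.loc[:, keep]
    low = coverage < 5
    dropped = []
    for col in values.columns:
        col_low = low[col]
        if not col_low.any():
            continue
        good = values[col].where(~col_low)
        means = good.groupby(samples).mean()
        if means.isna().any():
            dropped.append(col)
            continue
        fill = samples.map(means)
        values.loc[col_low, col] = fill[col_low]
    if dropped:
        values = values.drop(columns=dropped)
    return values


def gene_3cgs(q: np.ndarray, tss_bin: int, tes_bin: int, band: int) -> float:
    """Sum of imputed upper-triangle contacts touching the gene's bin span.

    Pixels (i, j) with i < j, j - i <= band, and i or j inside
    [min(tss,tes), max(tss,tes)] are summed; the diagonal is excluded.
    Scores of genes wider than the band are truncated at the band.
    """
    n = q.shape[0]
    b1, b2 = sorted((int(tss_bin), int(tes_bin)))
    if b1 < 0 or b2 >= n:
        raise ValueError("gene outside matrix")
    i, j = np.triu_indices(n, k=1)
    keep = (j - i) <= band
    i, j = i[keep], j[keep]
    in_span = ((i >= b1) & (i <= b2)) | ((j >= b1) & (j <= b2))
    return float(q[i[in_span], j[in_span]].sum())


def gene_3cgs_profile(q: np.ndarray, genes: pd.DataFrame, resolution: int,
                      band: int) -> pd.Series:
    """3CGS for every gene of a BED-like table against one cell's Q.

    TSS is strand-aware (start for +, end for -); the spanned bin range is
    the min/max of the TSS and TES bins, so strand does not change the
    score.
    """
    scores = {}
    for _, g in genes.iterrows():
        if g["strand"] == "-":
            tss, tes = g["end"] - 1, g["start"]
        else:
            tss, tes = g["start"], g["end"] - 1
        scores[g["name"]] = gene_3cgs(
            q, int(pos_to_bin(tss + 1, resolution)),
            int(pos_to_bin(tes + 1, resolution)), band)
    return pd.Series(scores, name="3cgs")


def feature_correlations(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame,
                         min_pairs: int = 3) -> pd.Series:
    """Per-feature Pearson r across paired rows of two matrices.

    Rows are aligned on the index (cells or meta-cells); features with
    fewer than ``min_pairs`` complete pairs or zero variance give NaN.
    """
    shared_rows = matrix_a.index.intersection(matrix_b.index)
    shared_cols = matrix_a.columns.intersection(matrix_b.columns)
    a = matrix_a.loc[shared_rows, shared_cols]
    b = matrix_b.loc[shared_rows, shared_cols]
    out = {}
    for col in shared_cols:
        x, y = a[col].to_numpy(dtype=float), b[col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_pairs or x[ok].std() == 0 or y[ok].std() == 0:
            out[col] = np.nan
        else:
            out[col] = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return pd.Series(out, name="pearson_r")
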