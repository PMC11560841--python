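"""Insulation scores, per-cell domain boundaries, and the chi-square
differential-boundary test at 25-kb resolution."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm


def boundary_z_threshold(quantile: float = 0.975) -> float:
    """Standard-normal quantile used as the differential-boundary z cutoff."""
    return float(norm.ppf(quantile))


def insulation_score(matrix: np.ndarray, window: int = 10) -> np.ndarray:
    """Raw cross-window mean of the matrix at each bin.

    score(b) is the mean of entries (i, j) with b - window <= i <= b < j
    <= b + window, the window clipped at the chromosome ends.  No log-ratio
    normalization is applied.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = matrix.shape[0]
    score = np.full(n, np.nan)
    for b in range(n - 1):
        i0 = max(b - window, 0)
        j1 = min(b + window, n - 1)
        block = matrix[i0:b + 1, b + 1:j1 + 1]
        if block.size:
            score[b] = block.mean()
    return score


def _local_minima_boundaries(score: np.ndarray, margin_frac: float) -> np.ndarray:
    """Strict local minima deeper than both flanking maxima by a margin.

    The margin is ``margin_frac`` of the score's finite range; flanking
    maxima are taken between the minimum and the adjacent local minima (or
    the profile ends).
    """
    finite = np.isfinite(score)
    if finite.sum() < 3:
        return np.zeros(len(score), dtype=bool)
    s = np.where(finite, score, np.inf)
    rng_span = np.nanmax(score[finite]) - np.nanmin(score[finite])
    if not np.isfinite(margin_frac):
        return np.zeros(len(score), dtype=bool)
    margin = margin_frac * rng_span
    n = len(s)
    minima = [b for b in range(1, n - 1)
              if s[b] < s[b - 1] and s[b] < s[b + 1] and np.isfinite(score[b])]
    calls = np.zeros(n, dtype=bool)
    fences = [0] + minima + [n - 1]
    for k, b in enumerate(minima):
        left = np.max(score[fences[k]:b + 1][np.isfinite(score[fences[k]:b + 1])])
        right_seg = score[b:fences[k + 2] + 1]
        right = np.max(right_seg[np.isfinite(right_seg)])
        if left - s[b] > margin and right - s[b] > margin:
            calls[b] = True
    return calls


def percell_boundaries(q_cell: np.ndarray, window: int = 10,
                       margin: float = 0.02) -> np.ndarray:
    """Binary boundary calls from one cell's imputed 25-kb matrix."""
    n = q_cell.shape[0]
    if n < 2 * window:
        raise ValueError("chromosome shorter than 2*window bins")
    score = insulation_score(q_cell, window)
    return _local_minima_boundaries(score, margin)


def boundary_probability(calls: np.ndarray, groups) -> pd.DataFrame:
    """Per-group, per-bin fraction of cells calling the bin a boundary.

    ``calls`` is a cells x bins boolean matrix aligned with ``groups``.
    """
    calls = np.asarray(calls, dtype=bool)
    groups = np.asarray(groups)
    if calls.shape[0] == 0 or groups.size == 0:
        raise ValueError("no cells to compute boundary probabilities from")
    out = {}
    for g in np.unique(groups):
        members = calls[groups == g]
        if members.shape[0] == 0:
            raise ValueError(f"empty group {g!r}")
        out[g] = members.mean(axis=0)
    return pd.DataFrame(out)


def pearson_chi2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) and its p-value."""
    table = np.asarray(table, dtype=float)
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    total = table.sum()
    expected = rowsum * colsum / total
    if np.any(expected == 0):
        raise ValueError("zero expected count")
    stat = float(((table - expected) ** 2 / expected).sum())
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, float(chi2_dist.sf(stat, dof))


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _merge_peaks(peaks: list[int], chi2: np.ndarray, min_gap: int = 5) -> list[int]:
    """Keep the higher-chi2 peak whenever two are within < min_gap bins.

    Iterated to a fixed point; ties broken toward the smaller bin so the
    result is independent of scan direction.
    """
    peaks = sorted(peaks)
    changed = True
    while changed:
        changed = False
        for i in range(len(peaks) - 1):
            a, b = peaks[i], peaks[i + 1]
            if b - a < min_gap:
                drop = b if (chi2[a] > chi2[b]
                             or (chi2[a] == chi2[b] and a < b)) else a
                peaks.remove(drop)
                changed = True
                break
    return peaks


def differential_boundaries(calls_by_group: dict[str, np.ndarray],
                            insulation_by_group: dict[str, np.ndarray],
                            fdr_threshold: float = 1e-3,
                            z_threshold: float = 1.960,
                            insulation_fc_threshold: float = 1.2,
                            prob_range_threshold: float = 0.05,
                            min_peak_gap: int = 5) -> pd.DataFrame:
    """Chi-square differential-boundary peaks across cell groups.

    Per 25-kb bin an n-groups x 2 table (boundary / not) feeds a Pearson
    chi-square; peaks are local maxima of the statistic passing BH FDR,
    then merged within ``min_peak_gap`` bins, and finally filtered on the
    genome-wide z-scored chi-square, the max/min insulation fold change and
    the boundary-probability range.  Bins with a zero expected count are
    excluded (``chi2`` is NaN there).
    """
    names = sorted(calls_by_group)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    calls = [np.asarray(calls_by_group[g], dtype=bool) for g in names]
    n_bins = calls[0].shape[1]
    n_cells = np.array([c.shape[0] for c in calls])

    chi2 = np.full(n_bins, np.nan)
    pval = np.full(n_bins, np.nan)
    for b in range(n_bins):
        yes = np.array([c[:, b].sum() for c in calls], dtype=float)
        table = np.stack([yes, n_cells - yes], axis=1)
        try:
            chi2[b], pval[b] = pearson_chi2(table)
        except ValueError:
            continue
    valid = np.isfinite(chi2)
    fdr = np.full(n_bins, np.nan)
    if valid.any():
        fdr[valid] = benjamini_hochberg(pval[valid])

    # local maxima of chi2 passing FDR
    peaks = [b for b in range(n_bins)
             if valid[b] and fdr[b] < fdr_threshold
             and (b == 0 or not valid[b - 1] or chi2[b] > chi2[b - 1])
             and (b == n_bins - 1 or not valid[b + 1] or chi2[b] >= chi2[b + 1])]
    peaks = _merge_peaks(peaks, chi2, min_peak_gap)

    mu, sd = chi2[valid].mean(), chi2[valid].std()
    z = (chi2 - mu) / sd if sd > 0 else np.zeros(n_bins)

    ins = np.stack([np.asarray(insulation_by_group[g], dtype=float)
                    for g in names])
    prob = np.stack([c.mean(axis=0) for c in calls])

    rows = []
    for b in peaks:
        ins_b = ins[:, b]
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = (np.nanmax(ins_b) / np.nanmin(ins_b)
                  if np.nanmin(ins_b) > 0 else np.inf)
        prange = prob[:, b].max() - prob[:, b].min()
        rows.append({
            "bin": b, "chi2": chi2[b], "fdr": fdr[b], "z_chi2": z[b],
            "insulation_fc": fc, "prob_range": prange,
            "is_peak": bool(z[b] > z_threshold
                            and fc > insulation_fc_threshold
                            and prange > prob_range_threshold),
        })
    return pd.DataFrame(rows, columns=["bin", "chi2", "fdr", "z_chi2",
                                       "insulation_fc", "prob_range", "is_peak"])
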