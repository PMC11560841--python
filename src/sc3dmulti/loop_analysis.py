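"""Loop calling with empirical FDR, summary-statistic ANOVA, and SIPs.

All statistics are computed from pseudobulk summaries (mean and mean of
squares across cells), never from per-cell stacks, so the cost is
independent of the number of cells once the pseudobulks exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm

from .matrix_core import PseudobulkStats, band_mask

EPS_VAR = 1e-12
LOG_EPS = 1e-12

# candidate band at 10 kb: 50 kb .. 5 Mb
CANDIDATE_MIN_SEP = 5
CANDIDATE_MAX_SEP = 500

DIFFERENTIAL_Z = 1.036   # 85th percentile of the standard normal
SIP_P = 0.001


@dataclass
class LoopThresholds:
    e_mean: float = 0.0
    fc_donut: float = 1.33
    fc_lowerleft: float = 1.33
    fc_horizontal: float = 1.2
    fc_vertical: float = 1.2
    fdr: float = 0.01


EDGE_MARGIN = 5   # ring/background radius: pixels closer to the matrix
                  # edge have clipped backgrounds and are not candidates


def candidate_mask(n: int, min_sep: int = CANDIDATE_MIN_SEP,
                   max_sep: int = CANDIDATE_MAX_SEP,
                   edge_margin: int = EDGE_MARGIN) -> np.ndarray:
    """Upper-triangle pixels with separation in [min_sep, max_sep] bins,
    at least ``edge_margin`` bins away from the matrix boundary."""
    idx = np.arange(n)
    sep = idx[None, :] - idx[:, None]
    ok = (sep >= min_sep) & (sep <= max_sep)
    if edge_margin > 0:
        ok[:edge_margin, :] = False
        ok[:, n - edge_margin:] = False
    return ok


def pseudobulk_tstat(stats: PseudobulkStats, which: str) -> np.ndarray:
    """t = mean / sqrt(max(meansq - mean^2, eps) / n), elementwise."""
    if stats.n_cell < 2:
        raise ValueError("need at least two cells for a t-statistic")
    mean = stats.matrix(which)
    meansq = stats.matrix(which + "2")
    var = np.maximum(meansq - mean ** 2, EPS_VAR)
    return mean / np.sqrt(var / stats.n_cell)


def empirical_fdr(t_obs: np.ndarray, t_shuffle: np.ndarray) -> np.ndarray:
    """Empirical FDR at each observed t against the shuffled-null t values.

    FDR(x) = min(1, [#{shuffle >= x} / N_shuffle] / [#{obs >= x} / N_obs]),
    evaluated at every observed value and made monotone non-increasing in t
    by a running minimum from the largest t downward.
    """
    obs = np.asarray(t_obs, dtype=float).ravel()
    shuf = np.asarray(t_shuffle, dtype=float).ravel()
    if shuf.size == 0:
        raise ValueError("empty shuffle set")
    order = np.argsort(obs, kind="stable")
    sorted_obs = obs[order]
    sorted_shuf = np.sort(shuf)
    # counts of values >= each observed t
    n_obs_ge = obs.size - np.searchsorted(sorted_obs, sorted_obs, side="left")
    n_shuf_ge = shuf.size - np.searchsorted(sorted_shuf, sorted_obs, side="left")
    raw = np.minimum(
        1.0, (n_shuf_ge / shuf.size) / (n_obs_ge / obs.size))
    # q-value style: FDR at t is the best achievable raw ratio among
    # thresholds <= t, which makes the result non-increasing in t.
    fdr_sorted = np.minimum.accumulate(raw)
    out = np.empty_like(obs)
    out[order] = fdr_sorted
    return out.reshape(np.asarray(t_obs).shape)


def _oe_normalize(q: np.ndarray, band: int) -> np.ndarray:
    n = q.shape[0]
    oe = np.zeros_like(q, dtype=np.float64)
    for d in range(min(band, n - 1) + 1):
        v = np.diagonal(q, offset=d)
        mu = v.mean()
        if mu > 0:
            idx = np.arange(n - d)
            oe[idx, idx + d] = v / mu
            if d > 0:
                oe[idx + d, idx] = v / mu
    return oe


def _offset_kernel(offsets) -> np.ndarray:
    """Convolution kernel summing values at the given (di, dj) offsets.

    ``scipy.ndimage.convolve`` flips the kernel, so offset (di, dj) maps to
    kernel position (r - di, r - dj).
    """
    r = max(max(abs(di), abs(dj)) for di, dj in offsets)
    k = np.zeros((2 * r + 1, 2 * r + 1))
    for di, dj in offsets:
        k[r - di, r - dj] = 1.0
    return k


DONUT_OFFSETS = [(di, dj) for di in range(-5, 6) for dj in range(-5, 6)
                 if 2 <= max(abs(di), abs(dj)) <= 5 and di != 0 and dj != 0]
LOWERLEFT_OFFSETS = [(di, dj) for di in range(1, 6) for dj in range(-5, 0)]
HORIZONTAL_OFFSETS = [(0, dj) for dj in range(-5, 6) if 2 <= abs(dj) <= 5]
VERTICAL_OFFSETS = [(di, 0) for di in range(-5, 6) if 2 <= abs(di) <= 5]

_BACKGROUNDS = {
    "donut": DONUT_OFFSETS,
    "lowerleft": LOWERLEFT_OFFSETS,
    "horizontal": HORIZONTAL_OFFSETS,
    "vertical": VERTICAL_OFFSETS,
}


def background_fold_changes(q_bulk: np.ndarray, band: int) -> dict[str, np.ndarray]:
    """Fold change of the O/E-normalized pseudobulk against four local
    backgrounds (donut, lower-left, horizontal, vertical).

    The background mean runs over in-band offsets only; a zero background
    under a positive pixel yields +inf.
    """
    n = q_bulk.shape[0]
    oe = _oe_normalize(q_bulk, band)
    mask = band_mask(n, band).astype(float)
    out = {}
    for name, offsets in _BACKGROUNDS.items():
        kernel = _offset_kernel(offsets)
        num = ndimage.convolve(oe * mask, kernel, mode="constant")
        den = ndimage.convolve(mask, kernel, mode="constant")
        bg = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(bg > 0, oe / np.where(bg > 0, bg, 1.0),
                          np.where(oe > 0, np.inf, 1.0))
        out[name] = fc
    return out


def call_loops(stats: PseudobulkStats, shuffle_stats: PseudobulkStats,
               band: int, thresholds: LoopThresholds | None = None,
               chrom: str = "chr1") -> pd.DataFrame:
    """Score every candidate pixel and flag loops.

    Loops require E_mean > 0, the four fold-change filters, and empirical
    FDR < threshold for both the global (t_E vs shuffled-E t) and local
    (t_T vs shuffled-T t) comparisons.
    """
    if thresholds is None:
        thresholds = LoopThresholds()
    n = stats.Q.shape[0]
    cand = candidate_mask(n) & band_mask(n, band)
    b1, b2 = np.nonzero(cand)

    t_e = pseudobulk_tstat(stats, "E")
    t_t = pseudobulk_tstat(stats, "T")
    t_e_shuf = pseudobulk_tstat(shuffle_stats, "E")
    t_t_shuf = pseudobulk_tstat(shuffle_stats, "T")
    fdr_global = empirical_fdr(t_e[cand], t_e_shuf[cand])
    fdr_local = empirical_fdr(t_t[cand], t_t_shuf[cand])
    fcs = background_fold_changes(stats.Q, band)

    table = pd.DataFrame({
        "chrom": chrom, "bin1": b1, "bin2": b2,
        "E_mean": stats.E[cand], "t_E": t_e[cand], "t_T": t_t[cand],
        "fdr_global": fdr_global, "fdr_local": fdr_local,
        "fc_donut": fcs["donut"][cand],
        "fc_lowerleft": fcs["lowerleft"][cand],
        "fc_horizontal": fcs["horizontal"][cand],
        "fc_vertical": fcs["vertical"][cand],
    })
    table["is_loop"] = (
        (table["E_mean"] > thresholds.e_mean)
        & (table["fc_donut"] > thresholds.fc_donut)
        & (table["fc_lowerleft"] > thresholds.fc_lowerleft)
        & (table["fc_horizontal"] > thresholds.fc_horizontal)
        & (table["fc_vertical"] > thresholds.fc_vertical)
        & (table["fdr_global"] < thresholds.fdr)
        & (table["fdr_local"] < thresholds.fdr)
    )
    return table


def loop_summits(calls: pd.DataFrame, n_bins: int, by: str = "t_E",
                 connectivity: int = 2) -> pd.DataFrame:
    """Collapse connected components of called pixels to their best pixel.

    Adjacent called pixels (8-connected by default) arise from the box
    smoothing around a single underlying loop; each component is reduced
    to its pixel with the largest ``by`` statistic.
    """
    called = calls[calls["is_loop"]]
    if len(called) == 0:
        return called.copy()
    grid = np.zeros((n_bins, n_bins), dtype=bool)
    grid[called["bin1"].to_numpy(), called["bin2"].to_numpy()] = True
    structure = ndimage.generate_binary_structure(2, connectivity)
    labels, n_comp = ndimage.label(grid, structure=structure)
    lab = labels[called["bin1"].to_numpy(), called["bin2"].to_numpy()]
    out = called.copy()
    out["component"] = lab
    idx = out.groupby("component")[by].idxmax()
    return out.loc[idx].sort_values(["bin1", "bin2"]).reset_index(drop=True)


def anova_from_summaries(groups: list[tuple[int, np.ndarray, np.ndarray]]
                         ) -> np.ndarray:
    """One-way ANOVA F from per-group (n, mean, mean-of-squares) summaries.

    SSB = sum n_g m_g^2 - N m_bar^2, SSW = sum n_g (q2_g - m_g^2),
    F = (SSB / (G - 1)) / (SSW / (N - G)).  Zero within-group variance with
    non-zero between-group variance yields +inf.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ns = np.array([g[0] for g in groups], dtype=float)
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    N = ns.sum()
    G = len(groups)
    means = np.stack([np.asarray(g[1], dtype=float) for g in groups])
    meansqs = np.stack([np.asarray(g[2], dtype=float) for g in groups])
    grand = (ns[:, None] * means.reshape(G, -1)).sum(axis=0) / N
    ssb = (ns[:, None] * means.reshape(G, -1) ** 2).sum(axis=0) - N * grand ** 2
    ssw = (ns[:, None] * (meansqs.reshape(G, -1)
                          - means.reshape(G, -1) ** 2)).sum(axis=0)
    msb = ssb / (G - 1)
    msw = ssw / (N - G)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(msw > 0, msb / msw, np.where(msb > 0, np.inf, 0.0))
    return f.reshape(means.shape[1:])


def select_differential(f_q: np.ndarray, f_t: np.ndarray,
                        z_threshold: float = DIFFERENTIAL_Z) -> pd.DataFrame:
    """Z-score log F across tested loops; differential iff both z exceed
    the threshold (~ top 5% under bivariate normality)."""
    f_q = np.asarray(f_q, dtype=float)
    f_t = np.asarray(f_t, dtype=float)
    if f_q.size < 2:
        raise ValueError("need at least two tested loops")

    def zscore(f):
        f = f.copy()
        finite = np.isfinite(f)
        f[~finite] = f[finite].max() if finite.any() else 1.0  # inf -> max finite
        logf = np.log(f + LOG_EPS)
        sd = logf.std()
        return np.zeros_like(logf) if sd == 0 else (logf - logf.mean()) / sd

    z_q, z_t = zscore(f_q), zscore(f_t)
    return pd.DataFrame({
        "F_Q": f_q, "F_T": f_t, "z_FQ": z_q, "z_FT": z_t,
        "is_differential": (z_q > z_threshold) & (z_t > z_threshold),
    })


def differential_z_threshold(quantile: float = 0.85) -> float:
    """Standard-normal quantile used as the differential-loop z cutoff."""
    return float(norm.ppf(quantile))


# ---------------------------------------------------------------------------
# promoter cumulative loop scores and SIPs
# ---------------------------------------------------------------------------

def _anchor_within(tss: np.ndarray, bin_idx: np.ndarray, resolution: int,
                   max_dist: int) -> np.ndarray:
    """Distance from each TSS (0-based bp) to each anchor interval <= max_dist.

    Returns a (n_tss, n_loops) boolean matrix; distance is 0 when the TSS
    falls inside the anchor's [bin*res, (bin+1)*res) interval.
    """
    start = bin_idx[None, :] * resolution
    end = start + resolution
    t = tss[:, None]
    gap = np.maximum(start - t, 0) + np.maximum(t - (end - 1), 0)
    return gap <= max_dist


def cumulative_loop_score(loops: pd.DataFrame, promoters: pd.DataFrame,
                          resolution: int = 10_000, max_tss_dist: int = 5_000,
                          strength_col: str = "E_mean",
                          mode: str = "strength") -> pd.Series:
    """Per-promoter sum of loop strengths for loops with an anchor within
    ``max_tss_dist`` bp of the TSS.

    ``promoters`` needs columns ``name`` and ``tss`` (0-based bp).
    ``mode="count"`` counts qualifying loops instead of summing strengths.
    """
    tss = promoters["tss"].to_numpy()
    if len(loops) == 0:
        return pd.Series(0.0, index=promoters["name"])
    near = (_anchor_within(tss, loops["bin1"].to_numpy(), resolution, max_tss_dist)
            | _anchor_within(tss, loops["bin2"].to_numpy(), resolution,
                             max_tss_dist))
    weights = (np.ones(len(loops)) if mode == "count"
               else loops[strength_col].to_numpy())
    scores = near @ weights
    return pd.Series(scores, index=promoters["name"], name="cumulative_score")


def call_sips(scores: pd.Series, p_threshold: float = SIP_P) -> pd.DataFrame:
    """Half-Gaussian SIP test: sigma = SD of all scores, p = 2(1 - Phi(x/sigma))."""
    x = scores.to_numpy(dtype=float)
    if x.size < 2:
        raise ValueError("need at least two promoters")
    sigma = x.std()
    if sigma == 0:
        raise ValueError("zero variance in cumulative loop scores")
    p = 2.0 * norm.sf(x / sigma)
    return pd.DataFrame({
        "cumulative_score": x, "sigma": sigma, "p_halfgauss": p,
        "is_SIP": p < p_threshold,
    }, index=scores.index)


def sip_score_threshold(sigma: float, p_threshold: float = SIP_P) -> float:
    return float(sigma * norm.ppf(1 - p_threshold / 2))


def cumulative_differential_score(differential_loops: pd.DataFrame,
                                  stage_strengths: pd.DataFrame,
                                  promoters: pd.DataFrame,
                                  resolution: int = 10_000,
                                  max_tss_dist: int = 5_000) -> pd.DataFrame:
    """Per-promoter, per-stage sum of pseudobulk strengths over the
    promoter-linked differential loops.

    ``stage_strengths`` has one row per differential loop and one column
    per stage (ordered); output rows are promoters, columns stages.
    """
    out = {}
    for stage in stage_strengths.columns:
        loops = differential_loops.copy()
        loops[stage] = stage_strengths[stage].to_numpy()
        out[stage] = cumulative_loop_score(
            loops, promoters, resolution, max_tss_dist, strength_col=stage)
    return pd.DataFrame(out)
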