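"""A/B compartments at 1 Mb: eigenvectors, saddle strength, transitions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu


def oe_matrix(matrix: np.ndarray) -> np.ndarray:
    """Observed / expected with the expectation taken per diagonal."""
    n = matrix.shape[0]
    oe = np.zeros((n, n))
    m = np.asarray(matrix, dtype=float)
    for d in range(n):
        v = np.diagonal(m, offset=d)
        mu = v.mean()
        if mu > 0:
            idx = np.arange(n - d)
            oe[idx, idx + d] = v / mu
            if d > 0:
                oe[idx + d, idx] = v / mu
    return oe


def compartment_eigenvector(matrix: np.ndarray, gc_track: np.ndarray,
                            n_candidates: int = 3,
                            min_informative: int = 10) -> np.ndarray:
    """Signed compartment eigenvector of a 1-Mb pseudobulk matrix.

    O/E is computed per diagonal, then the Pearson-correlation matrix of
    its columns is eigendecomposed; among the top ``n_candidates``
    eigenvectors (by eigenvalue), the one correlating best in magnitude
    with the GC track is chosen and its sign flipped so the correlation is
    non-negative (positive = A).  Bins with no signal are NaN.
    """
    m = np.asarray(matrix, dtype=float)
    if m.sum() == 0:
        raise ValueError("all-zero matrix")
    gc = np.asarray(gc_track, dtype=float)
    n = m.shape[0]
    informative = m.sum(axis=1) > 0
    if informative.sum() < min_informative:
        raise ValueError(f"fewer than {min_informative} informative bins")
    oe = oe_matrix(m)[np.ix_(informative, informative)]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(oe)
    corr = np.nan_to_num(corr)
    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1][:n_candidates]
    gci = gc[informative]
    best, best_r = None, -1.0
    for k in order:
        ev = v[:, k]
        if ev.std() == 0 or gci.std() == 0:
            continue
        r = float(np.corrcoef(ev, gci)[0, 1])
        if abs(r) > best_r:
            best, best_r = ev * np.sign(r) if r != 0 else ev, abs(r)
    if best is None:
        raise ValueError("no usable eigenvector")
    track = np.full(n, np.nan)
    track[informative] = best
    return track


@dataclass
class SaddleStats:
    aa: float
    bb: float
    ab: float
    ba: float
    strength: float
    aa_dominance: float
    bb_dominance: float
    low_contacts: bool


def saddle_stats(oe: np.ndarray, track: np.ndarray, top_pct: float = 20.0,
                 n_contacts: float | None = None,
                 min_contacts: float = 30e6) -> SaddleStats:
    """Saddle sums over the strongest-assigned compartment bins.

    Within each compartment, bins whose |eigenvector| is in the top
    ``top_pct`` percent are selected; O/E is then summed over ordered
    off-diagonal pairs.  strength = (AA + BB) / (AB + BA); the dominances
    are each quadrant's fraction of the four sums.  Pseudobulks under
    ``min_contacts`` are flagged, not dropped.
    """
    track = np.asarray(track, dtype=float)
    a_bins = np.flatnonzero(track > 0)
    b_bins = np.flatnonzero(track < 0)
    if len(a_bins) == 0 or len(b_bins) == 0:
        raise ValueError("strength undefined without both compartments")

    def top(bins):
        mag = np.abs(track[bins])
        cut = np.percentile(mag, 100 - top_pct)
        return bins[mag >= cut]

    a_sel, b_sel = top(a_bins), top(b_bins)

    def pair_sum(rows, cols):
        sub = oe[np.ix_(rows, cols)].astype(float).copy()
        if rows is cols or np.array_equal(rows, cols):
            np.fill_diagonal(sub, 0.0)
        return float(sub.sum())

    aa = pair_sum(a_sel, a_sel)
    bb = pair_sum(b_sel, b_sel)
    ab = pair_sum(a_sel, b_sel)
    ba = pair_sum(b_sel, a_sel)
    cross = ab + ba
    strength = np.inf if cross == 0 else (aa + bb) / cross
    total = aa + bb + cross
    return SaddleStats(
        aa=aa, bb=bb, ab=ab, ba=ba, strength=strength,
        aa_dominance=aa / total if total else np.nan,
        bb_dominance=bb / total if total else np.nan,
        low_contacts=bool(n_contacts is not None and n_contacts < min_contacts),
    )


def compartment_transitions(track_early: np.ndarray,
                            track_late: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bins switching sign between the two tracks (zeros/NaN excluded).

    Returns (AB, BA): A->B means early > 0 and late < 0.
    """
    early = np.asarray(track_early, dtype=float)
    late = np.asarray(track_late, dtype=float)
    if early.shape != late.shape:
        raise ValueError("tracks on different grids")
    ab = np.flatnonzero((early > 0) & (late < 0))
    ba = np.flatnonzero((early < 0) & (late > 0))
    return ab, ba


def transition_methylation(ab_bins: np.ndarray, ba_bins: np.ndarray,
                           mcg_by_age: dict[str, np.ndarray],
                           age_order: list[str]):
    """Per-age mCG deltas (vs the earliest age) for AB and BA bins, with a
    two-sided rank-sum comparison per age.

    Returns (deltas, pvalues): deltas maps age -> dict with "AB"/"BA"
    arrays; pvalues maps age -> Mann-Whitney two-sided p.
    """
    if len(age_order) < 2:
        raise ValueError("need at least two ages")
    if len(ab_bins) == 0 or len(ba_bins) == 0:
        raise ValueError("empty transition set")
    base = np.asarray(mcg_by_age[age_order[0]], dtype=float)
    deltas, pvalues = {}, {}
    for age in age_order:
        lvl = np.asarray(mcg_by_age[age], dtype=float)
        d_ab = lvl[ab_bins] - base[ab_bins]
        d_ba = lvl[ba_bins] - base[ba_bins]
        deltas[age] = {"AB": d_ab, "BA": d_ba}
        if np.all(d_ab == d_ab[0]) and np.all(d_ba == d_ba[0]) \
                and d_ab[0] == d_ba[0]:
            pvalues[age] = 1.0
        else:
            pvalues[age] = float(mannwhitneyu(
                d_ab, d_ba, alternative="two-sided").pvalue)
    return deltas, pvalues
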