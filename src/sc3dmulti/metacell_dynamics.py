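"""Meta-cells and the loop-strength vs anchor-mCG cross-correlation lag.

A meta-cell pools a cell with its k - 1 nearest embedding neighbours
(k = 20 by default, self included).  Overlap deduplication keeps removing
the worse member of the worst-overlapping pair until no pair shares more
than five cells.  Cross-correlation shifts are in meta-cell rank steps
along pseudotime; a negative recovered shift means the interaction change
precedes the methylation change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MetaCell:
    seed_cell: str
    members: list[str]
    origin: str = ""
    pseudotime: float = float("nan")
    mcg: np.ndarray | None = None          # per-10-kb-bin pooled fraction
    loop_strength: np.ndarray | None = None  # mean imputed Q per loop pixel
    extras: dict = field(default_factory=dict)


def build_metacells(embedding: np.ndarray, cell_ids: list[str],
                    k: int = 20) -> list[MetaCell]:
    """One meta-cell per cell: the cell plus its k-1 Euclidean nearest
    neighbours, distance ties broken by cell id order."""
    x = np.asarray(embedding, dtype=float)
    n = x.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} cells")
    ids = np.asarray(cell_ids)
    id_rank = np.argsort(np.argsort(ids, kind="stable"), kind="stable")
    out = []
    for i in range(n):
        d = np.linalg.norm(x - x[i], axis=1)
        order = np.lexsort((id_rank, d))
        members = [str(ids[j]) for j in order[:k]]
        out.append(MetaCell(seed_cell=str(ids[i]), members=members))
    return out


def pairwise_overlap(metacells: list[MetaCell]) -> np.ndarray:
    sets = [set(m.members) for m in metacells]
    n = len(sets)
    ov = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            ov[i, j] = ov[j, i] = len(sets[i] & sets[j])
    return ov


def deduplicate(metacells: list[MetaCell], max_shared: int = 5) -> list[MetaCell]:
    """Iteratively drop one meta-cell of the worst-overlapping pair.

    Within the worst pair the meta-cell with the larger total overlap
    against all remaining meta-cells is removed (ties by seed-cell id), so
    the procedure is deterministic and order-independent.
    """
    keep = list(range(len(metacells)))
    ov = pairwise_overlap(metacells)
    while True:
        if len(keep) < 2:
            break
        sub = ov[np.ix_(keep, keep)]
        worst = sub.max()
        if worst <= max_shared:
            break
        ii, jj = np.unravel_index(np.argmax(sub), sub.shape)
        a, b = keep[ii], keep[jj]
        tot_a, tot_b = sub[ii].sum(), sub[jj].sum()
        if tot_a > tot_b:
            drop = a
        elif tot_b > tot_a:
            drop = b
        else:
            drop = max(a, b, key=lambda x: metacells[x].seed_cell)
        keep.remove(drop)
    return [metacells[i] for i in keep]


def downsample_origin(metacells: list[MetaCell], origin: str,
                      fraction: float = 0.5, seed: int = 0) -> list[MetaCell]:
    """Keep ceil(fraction * n) uniformly random meta-cells of one origin."""
    rng = np.random.default_rng(seed)
    matching = [i for i, m in enumerate(metacells) if m.origin == origin]
    if not matching:
        return list(metacells)
    n_keep = int(np.ceil(fraction * len(matching)))
    kept = set(rng.choice(matching, size=n_keep, replace=False).tolist())
    return [m for i, m in enumerate(metacells)
            if m.origin != origin or i in kept]


def metacell_profiles(metacells: list[MetaCell],
                      mcg_counts: dict[str, tuple[np.ndarray, np.ndarray]],
                      loop_q: dict[str, np.ndarray],
                      pseudotime: dict[str, float],
                      origin: dict[str, str] | None = None) -> list[MetaCell]:
    """Fill per-meta-cell profiles from per-cell data.

    mcg_counts maps cell -> (mc, cov) arrays per 10-kb bin; the meta-cell
    fraction is the pooled-count ratio sum(mc)/sum(cov), not the mean of
    fractions.  loop_q maps cell -> per-loop mean imputed interaction;
    pseudotime is averaged over members.
    """
    out = []
    for m in metacells:
        missing = [c for c in m.members if c not in mcg_counts]
        if missing:
            raise ValueError(f"members without methylome: {missing}")
        mc = np.sum([mcg_counts[c][0] for c in m.members], axis=0).astype(float)
        cov = np.sum([mcg_counts[c][1] for c in m.members], axis=0).astype(float)
        frac = np.divide(mc, cov, out=np.full_like(mc, np.nan), where=cov > 0)
        strength = np.mean([loop_q[c] for c in m.members], axis=0)
        out.append(MetaCell(
            seed_cell=m.seed_cell, members=list(m.members),
            origin=origin[m.seed_cell] if origin else m.origin,
            pseudotime=float(np.mean([pseudotime[c] for c in m.members])),
            mcg=frac, loop_strength=strength))
    return out


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def crosscorr_curve(loop_series: np.ndarray, mcg_series: np.ndarray,
                    max_shift: int, min_overlap: int = 10) -> dict[int, float]:
    """Pearson r between the loop series and the mCG series displaced by s.

    r(s) correlates loop[t] with mcg[t - s] over the overlapping segment;
    with methylation trailing conformation, the most negative r occurs at a
    negative s.  Shifts whose overlap is shorter than ``min_overlap`` are
    omitted.
    """
    x = np.asarray(loop_series, dtype=float)
    y = np.asarray(mcg_series, dtype=float)
    n = len(x)
    curve = {}
    for s in range(-max_shift, max_shift + 1):
        if s >= 0:
            xs, ys = x[s:], y[:n - s] if s else y
        else:
            xs, ys = x[:n + s], y[-s:]
        if len(xs) < min_overlap:
            continue
        xs, ys = _standardize(xs), _standardize(ys)
        curve[s] = float(np.dot(xs, ys) / len(xs))
    return curve


@dataclass
class CrossCorrResult:
    shifts: pd.Series          # per-loop argmin shift (loops with r(0) < 0)
    curves: dict               # loop -> {shift: r}
    median_shift: float
    skew: float


def loop_methylation_crosscorr(profiles: list[MetaCell], max_shift: int,
                               min_overlap: int = 10) -> CrossCorrResult:
    """Cross-correlation lag between loop strength and anchor mCG.

    ``profiles`` must carry loop_strength and mcg already reduced to the
    anchor mean per loop (same length arrays); they are sorted by
    pseudotime here.  Only loops with negative zero-shift correlation
    enter the shift distribution.
    """
    ordered = sorted(profiles, key=lambda m: m.pseudotime)
    if len(ordered) < 2 * max_shift + min_overlap:
        raise ValueError("too few meta-cells for the requested shift window")
    loops = np.stack([m.loop_strength for m in ordered])   # t x loops
    mcg = np.stack([m.mcg for m in ordered])
    n_loops = loops.shape[1]
    shifts, curves = {}, {}
    for l in range(n_loops):
        curve = crosscorr_curve(loops[:, l], mcg[:, l], max_shift, min_overlap)
        if not curve or curve.get(0, 0.0) >= 0:
            continue
        argmin = min(curve, key=lambda s: (curve[s], abs(s)))
        shifts[l] = argmin
        curves[l] = curve
    s = pd.Series(shifts, dtype=float)
    if len(s):
        med = float(s.median())
        sd = s.std(ddof=0)
        skew = float(((s - s.mean()) ** 3).mean() / sd ** 3) if sd > 0 else 0.0
    else:
        med, skew = np.nan, np.nan
    return CrossCorrResult(shifts=s, curves=curves, median_shift=med, skew=skew)


def anchor_mcg_per_loop(mcg_bins: np.ndarray, loops: pd.DataFrame) -> np.ndarray:
    """Mean of the two anchor bins' mCG for each loop (vector per profile)."""
    b1 = loops["bin1"].to_numpy()
    b2 = loops["bin2"].to_numpy()
    return (np.asarray(mcg_bins)[b1] + np.asarray(mcg_bins)[b2]) / 2.0
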