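"""Per-cell contact matrices: imputation, E/T derivation, pseudobulks, SVD.

The per-cell pipeline at a given resolution is::

    raw counts -> impute (box filter + random-walk-with-restart)  = Q
    Q          -> per-diagonal z-score of log(1 + Q)              = E
    E          -> minus local ring background                     = T

Matrices are dense, symmetric, and band-limited: entries with bin
separation above ``band`` are zero and carry no meaning.  Pseudobulk
aggregation keeps the mean and the mean of squares of each of Q/E/T so
that t- and F-statistics can later be computed from summaries alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_formats import pos_to_bin


def contacts_to_matrix(pos1, pos2, n_bins: int, resolution: int) -> np.ndarray:
    """Symmetric raw count matrix from 1-based bp contact ends."""
    b1 = np.asarray(pos_to_bin(np.asarray(pos1), resolution))
    b2 = np.asarray(pos_to_bin(np.asarray(pos2), resolution))
    keep = (b1 < n_bins) & (b2 < n_bins)
    b1, b2 = b1[keep], b2[keep]
    m = np.zeros((n_bins, n_bins), dtype=np.float32)
    np.add.at(m, (b1, b2), 1.0)
    off = b1 != b2
    np.add.at(m, (b2[off], b1[off]), 1.0)
    return m


_BAND_MASK_CACHE: dict[tuple, np.ndarray] = {}


def band_mask(n: int, band: int) -> np.ndarray:
    key = (n, band)
    cached = _BAND_MASK_CACHE.get(key)
    if cached is None:
        idx = np.arange(n)
        cached = np.abs(idx[:, None] - idx[None, :]) <= band
        if len(_BAND_MASK_CACHE) > 8:
            _BAND_MASK_CACHE.clear()
        _BAND_MASK_CACHE[key] = cached
    return cached


def impute(matrix: np.ndarray, pad: int, max_distance: int, resolution: int,
           restart: float = 0.5, tol: float = 1e-2, max_iter: int = 20,
           use_rwr: bool = True) -> np.ndarray:
    """Box-filter + random-walk-with-restart imputation, band-restricted.

    Steps: (1) box-filter convolution of half-width ``pad``; (2) RWR with
    restart probability ``restart`` on the row-normalized matrix, iterated
    until the relative L1 change drops below ``tol`` or ``max_iter`` is
    reached; (3) symmetrization (M + M.T)/2; (4) zeroing of entries beyond
    ``max_distance``.  Output is non-negative.

    An all-zero input yields an all-zero output (with no warning raised
    beyond a silent early return, since downstream code treats empty cells
    uniformly).
    """
    if pad not in (0, 1, 2):
        raise ValueError("pad must be 0, 1 or 2")
    if max_distance % resolution != 0:
        raise ValueError("max_distance must be a multiple of resolution")
    n = matrix.shape[0]
    band = max_distance // resolution
    m = np.asarray(matrix, dtype=np.float32)
    if m.sum() == 0:
        return np.zeros_like(m)
    if pad > 0:
        size = 2 * pad + 1
        m = ndimage.uniform_filter(m, size=size, mode="constant") * (size * size)
    if use_rwr:
        rowsum = m.sum(axis=1, keepdims=True)
        rowsum[rowsum == 0] = 1.0
        w = m / rowsum
        p = np.eye(n, dtype=np.float32)
        for _ in range(max_iter):
            nxt = restart * np.eye(n, dtype=np.float32) \
                + (1.0 - restart) * (p @ w)
            delta = np.abs(nxt - p).sum() / max(np.abs(nxt).sum(), 1e-30)
            p = nxt
            if delta < tol:
                break
        m = p
    q = (m + m.T) * 0.5
    q[~band_mask(n, band)] = 0.0
    np.maximum(q, 0.0, out=q)
    return q


def diagonal_zscore(q: np.ndarray, band: int) -> np.ndarray:
    """E[i, j] = (log1p(Q) - mu_d) / sigma_d per diagonal d = |j - i|.

    Population (n-denominator) standard deviation; a constant diagonal
    (sigma_d = 0) maps to zeros.  Only diagonals 0..band are populated.
    """
    n = q.shape[0]
    e = np.zeros_like(q, dtype=np.float32)
    logq = np.log1p(q)
    for d in range(min(band, n - 1) + 1):
        v = np.diagonal(logq, offset=d)
        mu = v.mean()
        sd = v.std()
        z = np.zeros_like(v) if sd == 0 else (v - mu) / sd
        idx = np.arange(n - d)
        e[idx, idx + d] = z
        if d > 0:
            e[idx + d, idx] = z
    return e


def _ring_sum(x: np.ndarray, radius: int) -> np.ndarray:
    """Sum of x over the Chebyshev ring at ``radius`` (separable box trick)."""
    outer = 2 * radius + 1
    inner = 2 * radius - 1
    big = ndimage.uniform_filter(x, size=outer, mode="constant") * (outer ** 2)
    small = ndimage.uniform_filter(x, size=inner, mode="constant") * (inner ** 2)
    return big - small


_RING_DEN_CACHE: dict[tuple, np.ndarray] = {}


def subtract_local_background(e: np.ndarray, band: int,
                              radius: int = 4) -> np.ndarray:
    """T = E minus the mean of E over the Chebyshev ring at ``radius``.

    At 10-kb resolution radius 4 corresponds to offsets strictly between
    30 kb and 50 kb.  Ring offsets falling outside the matrix or outside
    the valid band are clipped (the mean runs over in-band offsets only).
    """
    n = e.shape[0]
    mask = band_mask(n, band).astype(np.float32)
    key = (n, band, radius)
    den = _RING_DEN_CACHE.get(key)
    if den is None:
        den = _ring_sum(mask, radius)
        if len(_RING_DEN_CACHE) > 8:
            _RING_DEN_CACHE.clear()
        _RING_DEN_CACHE[key] = den
    num = _ring_sum((e * mask).astype(np.float32), radius)
    bg = np.divide(num, den, out=np.zeros_like(num), where=den > 0.5)
    t = (e - bg).astype(np.float32)
    t[mask == 0] = 0.0
    return t


def shuffle_diagonals(e: np.ndarray, band: int, rng) -> np.ndarray:
    """Permute values within each (upper) diagonal; mirrored to keep symmetry."""
    n = e.shape[0]
    out = np.zeros_like(e)
    for d in range(min(band, n - 1) + 1):
        v = np.diagonal(e, offset=d).copy()
        perm = rng.permutation(len(v))
        v = v[perm]
        idx = np.arange(n - d)
        out[idx, idx + d] = v
        if d > 0:
            out[idx + d, idx] = v
    return out


@dataclass
class PseudobulkStats:
    """Means of values and of squares of Q/E/T across member cells."""

    n_cell: int
    Q: np.ndarray
    Q2: np.ndarray
    E: np.ndarray
    E2: np.ndarray
    T: np.ndarray
    T2: np.ndarray

    def matrix(self, which: str) -> np.ndarray:
        return getattr(self, which)


class PseudobulkAccumulator:
    """Streaming accumulator for :class:`PseudobulkStats`.

    Cells are added one at a time so the full per-cell matrix stack never
    has to be held in memory.
    """

    def __init__(self) -> None:
        self.n = 0
        self._sums: dict[str, np.ndarray] = {}

    def add(self, q: np.ndarray, e: np.ndarray, t: np.ndarray) -> None:
        parts = {"Q": q, "Q2": q.astype(np.float64) ** 2,
                 "E": e, "E2": e.astype(np.float64) ** 2,
                 "T": t, "T2": t.astype(np.float64) ** 2}
        if self.n == 0:
            for k, v in parts.items():
                self._sums[k] = v.astype(np.float64).copy()
        else:
            for k, v in parts.items():
                if v.shape != self._sums[k].shape:
                    raise ValueError("shape mismatch across cells")
                self._sums[k] += v
        self.n += 1

    def finalize(self) -> PseudobulkStats:
        if self.n == 0:
            raise ValueError("no cells accumulated")
        return PseudobulkStats(
            n_cell=self.n,
            **{k: v / self.n for k, v in self._sums.items()},
        )


def aggregate_pseudobulk(triplets) -> PseudobulkStats:
    """Aggregate an iterable of (Q, E, T) per-cell triplets."""
    acc = PseudobulkAccumulator()
    for q, e, t in triplets:
        acc.add(q, e, t)
    return acc.finalize()


def write_pseudobulk(stats: PseudobulkStats, directory, prefix: str = "bulk",
                     threshold: float = 0.0) -> None:
    """Dump the six pseudobulk matrices as sparse TSV triplets.

    One file per matrix (``<prefix>.<name>.tsv`` with columns i, j, value;
    upper triangle only) plus ``<prefix>.meta.tsv`` holding n_cell and the
    matrix shape.  Entries with |value| <= threshold are omitted.
    """
    import os
    os.makedirs(directory, exist_ok=True)
    n = stats.Q.shape[0]
    with open(os.path.join(directory, f"{prefix}.meta.tsv"), "w") as fh:
        fh.write(f"n_cell\t{stats.n_cell}\nn_bins\t{n}\n")
    for name in ("Q", "Q2", "E", "E2", "T", "T2"):
        m = stats.matrix(name)
        i, j = np.nonzero(np.triu(np.abs(m) > threshold))
        with open(os.path.join(directory, f"{prefix}.{name}.tsv"), "w") as fh:
            for a, b in zip(i, j):
                fh.write(f"{a}\t{b}\t{float(m[a, b])!r}\n")


def read_pseudobulk(directory, prefix: str = "bulk") -> PseudobulkStats:
    """Read a :func:`write_pseudobulk` dump back into dense matrices."""
    import os
    meta = {}
    with open(os.path.join(directory, f"{prefix}.meta.tsv")) as fh:
        for line in fh:
            key, val = line.split("\t")
            meta[key] = int(val)
    n = meta["n_bins"]
    mats = {}
    for name in ("Q", "Q2", "E", "E2", "T", "T2"):
        m = np.zeros((n, n))
        with open(os.path.join(directory, f"{prefix}.{name}.tsv")) as fh:
            for line in fh:
                a, b, v = line.split("\t")
                m[int(a), int(b)] = float(v)
                m[int(b), int(a)] = float(v)
        mats[name] = m
    return PseudobulkStats(n_cell=meta["n_cell"], **mats)


def cell_triplet(raw: np.ndarray, pad: int, max_distance: int,
                 resolution: int, **impute_kwargs):
    """Convenience: raw counts -> (Q, E, T) at one resolution."""
    band = max_distance // resolution
    q = impute(raw, pad, max_distance, resolution, **impute_kwargs)
    e = diagonal_zscore(q, band)
    t = subtract_local_background(e, band)
    return q, e, t


def embed_cells(feature_matrix: np.ndarray, dims: int = 20) -> np.ndarray:
    """SVD embedding of a cell x feature matrix.

    Components are divided by their singular values (leaving the left
    singular vectors) and every cell's vector is L2-normalized.  Sign is
    fixed per component so the feature loading of largest magnitude is
    positive, making the output deterministic.
    """
    x = np.asarray(feature_matrix, dtype=np.float64)
    n_cells = x.shape[0]
    if n_cells < dims:
        raise ValueError(f"need at least dims={dims} cells, got {n_cells}")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    dims = min(dims, rank)
    u, s, vt = u[:, :dims], s[:dims], vt[:dims]
    for c in range(dims):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            vt[c] *= -1.0
            u[:, c] *= -1.0
    coords = u  # (U S) / S
    norms = np.linalg.norm(coords, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return coords / norms


def embedding_features(q100kb: np.ndarray, min_sep_bins: int = 2,
                       max_sep_bins: int = 9) -> np.ndarray:
    """Flatten the 100-kb imputed matrix into the embedding feature vector.

    Uses pixels with bin separation in [min_sep_bins, max_sep_bins]
    (> 100 kb and < 1 Mb at 100-kb resolution).
    """
    n = q100kb.shape[0]
    feats = []
    for d in range(min_sep_bins, max_sep_bins + 1):
        feats.append(np.diagonal(q100kb, offset=d))
    return np.concatenate(feats)
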