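"""Contact-distance histograms, SE/LE/INT classes and conformation clusters.

Distances between cis-contact ends are histogrammed into 143 logarithmic
bins: bin 1 collects everything below 2**10 bp ("< 1 kb" read as the exact
base-2 edge), and each later bin spans an exponent step of 0.125 in base 2,
i.e. bin k (k >= 2) covers [2**(10 + (k-2)/8), 2**(10 + (k-1)/8)).  Bins
1-37 are treated as noise; bins 38-141 are the valid bins, split into a
"median" block (38-89) and a "long" block (90-141).  All public bin numbers
are 1-based to match that wording; array indices are of course 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

N_BINS = 143
# 1-based inclusive bin ranges
VALID_BINS = (38, 141)
MEDIAN_BINS = (38, 89)
LONG_BINS = (90, 141)

SE_THRESHOLD = 0.4
LE_THRESHOLD = -0.4

# Upper edges of bins 1..143; bin k >= 2 has lower edge 2**(10 + (k-2)/8).
BIN_UPPER_EDGES = 2.0 ** (10.0 + np.arange(N_BINS) / 8.0)


class UndefinedMetricsError(ValueError):
    """No contacts in the valid bins: the SE/LE metrics are undefined."""


@dataclass
class DistanceMetrics:
    pct_median: float
    pct_long: float
    ratio: float
    conformation_class: str


def bin_distances(distances) -> np.ndarray:
    """Histogram cis-contact distances into the 143 logarithmic bins.

    Distances at or beyond the upper edge of bin 143 are dropped; the count
    of dropped contacts is available via :func:`count_overflow`.
    """
    distances = np.asarray(distances, dtype=float)
    counts = np.zeros(N_BINS, dtype=np.int64)
    if distances.size == 0:
        return counts
    idx = np.searchsorted(BIN_UPPER_EDGES, distances, side="right")
    kept = idx < N_BINS
    np.add.at(counts, idx[kept], 1)
    return counts


def count_overflow(distances) -> int:
    """Number of distances beyond the histogram's last edge."""
    distances = np.asarray(distances, dtype=float)
    return int(np.count_nonzero(distances >= BIN_UPPER_EDGES[-1]))


def _block_slice(bins_1based: tuple[int, int]) -> slice:
    lo, hi = bins_1based
    return slice(lo - 1, hi)


def valid_profile(counts: np.ndarray) -> np.ndarray:
    """Counts restricted to the valid bins 38-141 (length 104)."""
    counts = np.asarray(counts)
    return counts[..., _block_slice(VALID_BINS)]


def classify(ratio: float) -> str:
    """SE above 0.4, LE below -0.4, INT on the closed interval between."""
    if ratio > SE_THRESHOLD:
        return "SE"
    if ratio < LE_THRESHOLD:
        return "LE"
    return "INT"


def distance_metrics(counts: np.ndarray) -> DistanceMetrics:
    counts = np.asarray(counts, dtype=float)
    total = counts[_block_slice(VALID_BINS)].sum()
    if total <= 0:
        raise UndefinedMetricsError("no contacts in valid bins 38-141")
    pct_median = counts[_block_slice(MEDIAN_BINS)].sum() / total
    pct_long = counts[_block_slice(LONG_BINS)].sum() / total
    with np.errstate(divide="ignore"):
        ratio = float(np.log2(pct_median) - np.log2(pct_long))
    return DistanceMetrics(float(pct_median), float(pct_long), ratio,
                           classify(ratio))


def metrics_table(hists: np.ndarray, cell_ids=None) -> pd.DataFrame:
    """Per-cell metrics for a stack of histograms (cells x 143)."""
    rows = []
    for counts in np.asarray(hists):
        m = distance_metrics(counts)
        rows.append((m.pct_median, m.pct_long, m.ratio, m.conformation_class))
    out = pd.DataFrame(rows, columns=["pct_median", "pct_long", "ratio", "class"])
    if cell_ids is not None:
        out.insert(0, "cell_id", list(cell_ids))
    return out


def _normalized_profiles(hists: np.ndarray) -> np.ndarray:
    prof = valid_profile(np.asarray(hists, dtype=float))
    sums = prof.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise UndefinedMetricsError("cell with no contacts in valid bins")
    return prof / sums


def cluster_profiles(hists: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """k-means over L1-normalized valid-bin profiles, labels 1..k.

    Clusters are renumbered so cluster 1 has the highest mean
    log2(pct_median / pct_long) — short-range dominated cells first.
    """
    hists = np.asarray(hists)
    if hists.shape[0] < k:
        raise ValueError(f"need at least k={k} cells, got {hists.shape[0]}")
    prof = _normalized_profiles(hists)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(prof)
    ratios = np.array([distance_metrics(h).ratio for h in hists])
    order = []
    for c in range(k):
        mask = raw == c
        order.append(np.mean(ratios[mask]) if mask.any() else -np.inf)
    rank = np.argsort(np.argsort(-np.asarray(order)))  # 0 = highest mean ratio
    return rank[raw] + 1


def cluster_enrichment(labels, cell_types) -> pd.DataFrame:
    """enrichment[t, c] = (frac of type-t cells in c) / (frac of all cells in c).

    Empty clusters yield NaN columns.
    """
    labels = np.asarray(labels)
    cell_types = np.asarray(cell_types)
    clusters = np.unique(labels)
    types = np.unique(cell_types)
    n = len(labels)
    out = pd.DataFrame(index=types, columns=clusters, dtype=float)
    for c in clusters:
        in_c = labels == c
        size_frac = in_c.sum() / n
        for t in types:
            of_t = cell_types == t
            if of_t.sum() == 0 or size_frac == 0:
                out.loc[t, c] = np.nan
            else:
                frac_t_in_c = (in_c & of_t).sum() / of_t.sum()
                out.loc[t, c] = frac_t_in_c / size_frac
    return out


def cluster_similarity_pvalues(hists, labels, n_iter: int = 1000,
                               r_threshold: float = 0.8,
                               seed: int = 0) -> pd.DataFrame:
    """For each cluster pair, count random cross-cluster cell pairs whose
    valid-bin profiles correlate above ``r_threshold`` (Pearson), out of
    ``n_iter`` draws.
    """
    labels = np.asarray(labels)
    prof = _normalized_profiles(np.asarray(hists, dtype=float))
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    rng = np.random.default_rng(seed)
    # standardize rows once; Pearson r = dot / len
    z = prof - prof.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(z, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    z = z / norm
    out = pd.DataFrame(index=clusters, columns=clusters, dtype=float)
    for i, a in enumerate(clusters):
        ia = np.flatnonzero(labels == a)
        if len(ia) == 0:
            raise ValueError(f"cluster {a} is empty")
        for b in clusters[i:]:
            ib = np.flatnonzero(labels == b)
            pa = ia[rng.integers(0, len(ia), size=n_iter)]
            pb = ib[rng.integers(0, len(ib), size=n_iter)]
            r = np.einsum("ij,ij->i", z[pa], z[pb])
            count = int(np.count_nonzero(r > r_threshold))
            out.loc[a, b] = count
            out.loc[b, a] = count
    return out
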