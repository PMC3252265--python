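"""Consensus clustering of expression profiles into molecular subtypes.

Repeated average-linkage hierarchical clustering of subsampled cohorts,
with distance 1 minus the Pearson correlation between samples.  The
consensus matrix entry (i, j) is the fraction of iterations, among those
co-sampling both i and j, in which they landed in the same cluster; a
sharp 0/1 consensus indicates stable clusters.  Final labels come from
average-linkage clustering of 1 minus the consensus matrix, and samples
are restricted to those with strictly positive silhouette widths before
subtype-stratified ordering analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples

__all__ = [
    "ConsensusResult",
    "SubtypeAssignment",
    "pearson_distance",
    "consensus_cluster",
    "consensus_cdf_scan",
    "silhouette_filter",
]


@dataclass
class ConsensusResult:
    k: int
    consensus: pd.DataFrame       # samples x samples, entries in [0, 1]
    labels: pd.Series             # sample -> cluster id (1..k)
    cdf_x: np.ndarray             # grid of consensus values
    cdf_y: np.ndarray             # empirical CDF over off-diagonal entries

    @property
    def area_under_cdf(self) -> float:
        return float(np.trapezoid(self.cdf_y, self.cdf_x))


@dataclass
class SubtypeAssignment:
    labels: pd.Series
    silhouette: pd.Series
    core: pd.Series               # strictly positive silhouette width

    @property
    def core_samples(self) -> list[str]:
        return list(self.core.index[self.core])


def pearson_distance(expr: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson correlation between sample columns of a genes x samples
    matrix.  Errors on constant-expression samples (undefined correlation)."""
    sd = expr.std(axis=0, ddof=1)
    flat = sd[sd == 0]
    if len(flat):
        raise ValueError(
            f"constant expression (undefined correlation) for sample(s): "
            f"{list(flat.index)}"
        )
    corr = np.corrcoef(expr.to_numpy().T)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return pd.DataFrame(d, index=expr.columns, columns=expr.columns)


def _hier_labels(dist: np.ndarray, k: int) -> np.ndarray:
    z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(z, t=k, criterion="maxclust")


def consensus_cluster(
    expr: pd.DataFrame,
    k: int,
    iters: int = 1000,
    subsample: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus clustering of a genes x samples expression matrix.

    Each iteration subsamples ``subsample`` of the samples without
    replacement, clusters them by average-linkage hierarchical clustering
    on the 1 - Pearson distance, cut at ``k`` clusters.  consensus(i, j) =
    (co-clustering count) / (co-sampling count); pairs never co-sampled get
    0.  Final labels cluster 1 - consensus the same way.  Deterministic
    given the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not 0 < subsample <= 1:
        raise ValueError("subsample must be in (0, 1]")
    n = expr.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    dist_full = pearson_distance(expr).to_numpy()
    rng = np.random.default_rng(seed)
    m = max(k, int(round(subsample * n)))
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for _ in range(iters):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        lab = _hier_labels(dist_full[np.ix_(idx, idx)], k)
        co = (lab[:, None] == lab[None, :]).astype(float)
        sampled[np.ix_(idx, idx)] += 1.0
        together[np.ix_(idx, idx)] += co
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    labels = _hier_labels(1.0 - consensus, k)
    tri = consensus[np.triu_indices(n, k=1)]
    cdf_x = np.linspace(0.0, 1.0, 101)
    cdf_y = np.searchsorted(np.sort(tri), cdf_x, side="right") / tri.size
    cols = list(expr.columns)
    return ConsensusResult(
        k=k,
        consensus=pd.DataFrame(consensus, index=cols, columns=cols),
        labels=pd.Series(labels, index=cols, name="cluster"),
        cdf_x=cdf_x,
        cdf_y=cdf_y,
    )


def consensus_cdf_scan(
    expr: pd.DataFrame,
    k_range: range | list[int] = range(2, 11),
    iters: int = 1000,
    subsample: float = 0.8,
    seed: int = 0,
    plateau_delta: float = 0.03,
) -> tuple[dict[int, ConsensusResult], dict[int, float], int | None]:
    """Run consensus clustering over a range of k and report CDF areas.

    Returns (per-k results, relative area-under-CDF increments, suggested
    k).  The increment for k is (A(k) - A(k-1)) / A(k-1).  The suggestion
    is the largest k before the increments plateau below
    ``plateau_delta``; when no plateau is reached the heuristic abstains
    and returns None (selection is ultimately the caller's, typically by
    graphical examination).
    """
    ks = sorted(k_range)
    if not ks:
        raise ValueError("k_range must be non-empty")
    results = {
        k: consensus_cluster(expr, k, iters=iters, subsample=subsample,
                             seed=seed + i)
        for i, k in enumerate(ks)
    }
    areas = {k: results[k].area_under_cdf for k in ks}
    deltas: dict[int, float] = {}
    for prev, k in zip(ks, ks[1:]):
        base = areas[prev]
        deltas[k] = (areas[k] - base) / base if base > 0 else float("inf")
    recommended = None
    for prev, k in zip(ks, ks[1:]):
        if deltas[k] < plateau_delta:
            recommended = prev
            break
    return results, deltas, recommended


def silhouette_filter(
    labels: pd.Series, distance: pd.DataFrame
) -> SubtypeAssignment:
    """Silhouette widths on a precomputed distance; core = width > 0.

    Uses the standard width (b - a) / max(a, b), where a is the mean
    within-cluster distance and b the mean distance to the nearest other
    cluster.  Samples in singleton clusters get width 0 and are excluded,
    like any sample with non-positive width.
    """
    if labels.nunique() < 2:
        raise ValueError("silhouette requires at least two clusters")
    distance = distance.loc[labels.index, labels.index]
    widths = silhouette_samples(
        distance.to_numpy(), labels.to_numpy(), metric="precomputed"
    )
    sil = pd.Series(widths, index=labels.index, name="silhouette")
    core = sil > 0
    core.name = "core"
    return SubtypeAssignment(labels=labels, silhouette=sil, core=core)
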