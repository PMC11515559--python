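"""Unsupervised exploration of (adjusted) RAS matrices.

Samples are embedded in 2-D with UMAP and density-clustered with HDBSCAN
on the embedding coordinates; HDBSCAN's outliers form the pseudo-cluster
0, real clusters are numbered 1..k.  Because the embedding is stochastic,
stability is assessed by repeating it under incremented seeds, recording
per-sample coordinate sums (x + y, the quantity plotted in stability
line plots) and three internal validity indices per iteration: the
C-index, the Calinski-Harabasz index, and the silhouette score, all
computed on the Euclidean geometry of the embedding with noise points
excluded.  Marker reactions per cluster come from Welch t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import HDBSCAN
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .differential import bh_adjust

__all__ = [
    "StabilityResult",
    "embed_and_cluster",
    "stability_iterations",
    "clustering_indices",
    "c_index",
    "marker_reactions",
    "minpts_scan",
]


def _sample_matrix(M: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list]:
    """Samples-as-rows array plus sample ids from a reactions x samples frame."""
    if isinstance(M, pd.DataFrame):
        return M.to_numpy(dtype=float).T, list(M.columns)
    X = np.asarray(M, dtype=float)
    return X.T, list(range(X.shape[1]))


def embed_and_cluster(
    M: pd.DataFrame | np.ndarray,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    min_pts: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """One seeded UMAP embedding + HDBSCAN clustering of the samples.

    ``M`` is reactions x samples (columns are embedded).  Returns the
    (n_samples, 2) coordinates and integer labels with 0 = outlier/noise
    and clusters numbered from 1.  A fixed seed makes the call fully
    deterministic.  ``min_pts`` larger than the sample count yields all
    zeros (every sample is noise at that density requirement).
    """
    import umap  # deferred: numba compilation is slow at import time

    X, _ = _sample_matrix(M)
    n_samples = X.shape[0]
    if n_samples < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors + 1 = {n_neighbors + 1} samples, "
            f"got {n_samples}")
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", module="sklearn.utils.deprecation")
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                            min_dist=min_dist, random_state=seed)
        coords = np.asarray(reducer.fit_transform(X), dtype=float)
    if min_pts > n_samples:
        labels = np.zeros(n_samples, dtype=int)
    else:
        raw = HDBSCAN(min_cluster_size=min_pts, copy=True).fit(coords).labels_
        labels = raw + 1  # noise -1 -> pseudo-cluster 0, clusters 1..k
    return coords, labels


@dataclass
class StabilityResult:
    """Per-iteration record of repeated embedding + clustering.

    ``records``: long table (sample, iteration, seed, x, y, coord_sum,
    label).  ``indices``: one row per iteration with the three validity
    indices (NaN when fewer than 2 non-noise clusters were found) and
    the non-noise cluster count.  ``subset``: the iteration ids sampled
    for the stability line plot.
    """

    records: pd.DataFrame
    indices: pd.DataFrame
    subset: tuple[int, ...]

    def subset_records(self) -> pd.DataFrame:
        return self.records[self.records["iteration"].isin(self.subset)]


def stability_iterations(
    M: pd.DataFrame | np.ndarray,
    n_iter: int,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    min_pts: int = 5,
    base_seed: int = 0,
    subset_size: int = 50,
) -> StabilityResult:
    """Repeat :func:`embed_and_cluster` ``n_iter`` times (seed base_seed + i).

    Records coordinates, labels and the per-sample coordinate sum for
    every iteration, plus the validity indices; ``subset`` is a seeded
    random choice of ``subset_size`` iterations for line plotting.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    _, samples = _sample_matrix(M)
    rec_frames = []
    idx_rows = []
    for i in range(n_iter):
        seed = base_seed + i
        coords, labels = embed_and_cluster(M, n_neighbors, min_dist, min_pts,
                                           seed)
        rec_frames.append(pd.DataFrame({
            "sample": samples,
            "iteration": i,
            "seed": seed,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "coord_sum": coords[:, 0] + coords[:, 1],
            "label": labels,
        }))
        ci, ch, sil = clustering_indices(coords, labels)
        idx_rows.append({
            "iteration": i, "seed": seed, "c_index": ci,
            "calinski_harabasz": ch, "silhouette": sil,
            "n_clusters": int(len(set(labels[labels > 0]))),
        })
    rng = np.random.default_rng(base_seed)
    size = min(subset_size, n_iter)
    subset = tuple(sorted(rng.choice(n_iter, size=size, replace=False).tolist()))
    return StabilityResult(
        records=pd.concat(rec_frames, ignore_index=True),
        indices=pd.DataFrame(idx_rows),
        subset=subset,
    )


def c_index(coords: np.ndarray, labels: np.ndarray) -> float:
    """Hubert & Levin C-index on Euclidean distances.

    (S_w - S_min) / (S_max - S_min), where S_w is the sum of
    within-cluster pairwise distances and S_min / S_max are the sums of
    the equally many smallest / largest pairwise distances overall.
    0 means the within-cluster pairs are exactly the globally closest
    pairs.
    """
    d = pdist(coords)
    same = squareform(labels[:, None] == labels[None, :], checks=False)
    n_w = int(same.sum())
    if n_w == 0 or n_w == d.size:
        return float("nan")
    s_w = d[same].sum()
    d_sorted = np.sort(d)
    s_min = d_sorted[:n_w].sum()
    s_max = d_sorted[-n_w:].sum()
    if s_max == s_min:
        return float("nan")
    return float((s_w - s_min) / (s_max - s_min))


def clustering_indices(
    coords: np.ndarray,
    labels: np.ndarray,
) -> tuple[float, float, float]:
    """(C-index, Calinski-Harabasz, silhouette) on the 2-D embedding.

    Noise points (label 0) are excluded; with fewer than 2 remaining
    clusters all three are NaN (undefined).
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    mask = labels != 0
    labs = labels[mask]
    pts = coords[mask]
    uniq = np.unique(labs)
    if len(uniq) < 2 or len(labs) < 3:
        return (float("nan"),) * 3
    ci = c_index(pts, labs)
    ch = float(calinski_harabasz_score(pts, labs))
    sil = float(silhouette_score(pts, labs))
    return ci, ch, sil


def minpts_scan(
    coords: np.ndarray,
    values: tuple[int, ...] = (3, 5, 8, 10, 15, 20),
) -> pd.DataFrame:
    """Cluster counts and outlier counts on fixed coordinates over minPts."""
    rows = []
    n = len(coords)
    for mp in values:
        if mp > n:
            labels = np.zeros(n, dtype=int)
        else:
            labels = HDBSCAN(min_cluster_size=mp, copy=True).fit(coords).labels_ + 1
        rows.append({
            "min_pts": mp,
            "n_clusters": int(len(set(labels[labels > 0]))),
            "n_outliers": int((labels == 0).sum()),
        })
    return pd.DataFrame(rows)


def marker_reactions(
    M: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    mode: str = "vs_rest",
) -> dict[int, pd.DataFrame]:
    """Per-cluster marker reactions by Welch t-tests.

    ``vs_rest`` (default): each reaction, cluster members against all
    other non-noise samples.  ``pairwise_max``: per reaction, the
    maximum p-value over Welch tests against every other cluster — a
    marker must separate the cluster from each of them individually.
    Noise samples (label 0) are excluded throughout; clusters smaller
    than 2 are skipped with a warning.  Each table reports the
    log-fold-change (mean difference on the already log-scaled matrix),
    p-value and BH false-discovery rate, sorted ascending by p; zero
    variance everywhere yields p = 1 with ``zero_variance`` flagged.
    """
    if mode not in ("vs_rest", "pairwise_max"):
        raise ValueError(f"unknown marker mode {mode!r}")
    labels = np.asarray(labels)
    if labels.shape[0] != M.shape[1]:
        raise ValueError("labels must align with the matrix columns")
    keep = labels != 0
    X = M.to_numpy(dtype=float)[:, keep]
    labs = labels[keep]
    clusters = sorted(int(c) for c in set(labs))
    if len(clusters) < 2:
        raise ValueError("marker detection requires >= 2 non-noise clusters")
    sizes = {c: int((labs == c).sum()) for c in clusters}
    usable = [c for c in clusters if sizes[c] >= 2]
    for c in clusters:
        if sizes[c] < 2:
            warnings.warn(f"cluster {c} has fewer than 2 samples; skipped",
                          stacklevel=2)

    def welch_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"), \
                warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        return np.asarray(p)

    out: dict[int, pd.DataFrame] = {}
    for c in usable:
        members = X[:, labs == c]
        rest = X[:, labs != c]
        lfc = members.mean(axis=1) - rest.mean(axis=1)
        if mode == "vs_rest":
            p = welch_p(members, rest)
        else:
            others = [welch_p(members, X[:, labs == d])
                      for d in usable if d != c]
            p = np.nanmax(np.stack(others), axis=0) if others else np.full(
                X.shape[0], np.nan)
        zero_var = np.isnan(p)
        p = np.where(zero_var, 1.0, p)
        table = pd.DataFrame(
            {
                "log_fc": lfc,
                "pvalue": p,
                "fdr": bh_adjust(p),
                "zero_variance": zero_var,
            },
            index=M.index,
        ).sort_values("pvalue", kind="mergesort")
        table.index.name = "reaction_id"
        out[c] = table
    return out
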