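"""Single-day behavioral space: day matrix, PCA, embedding, clustering.

Each row of the day matrix is one "behavioral day" (one bee on one calendar
day), each column one of the 12 behavioral metrics, z-scored per column
with the population standard deviation so the total variance equals the
number of metrics.  Honey and brood usage have the nest content fraction of
that date subtracted before normalization, which removes colony-level
changes in comb composition and leaves individual usage relative to what
the nest offered; the dance floor is a fixed region and is left untouched.

The within-group variance fraction W for a partition {G} is

    W = (1/||M||^2) * sum_{q in G} sum_{i in q} sum_k (M_ik - <M_jk>_{j in q})^2

i.e. the residual variance after subtracting conditional group means,
normalized by the total squared matrix norm; Ward clustering minimizes this
quantity, and "variance explained" by a grouping is 1 - W.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .core_model import CombMapSeries
from .daily_metrics import METRICS

#: A behavioral day enters the matrix only with more than this many
#: detections over the whole day (at 3 Hz this is 5.5 min observed).
MIN_DAY_DETECTIONS = 1000


class PipelineError(RuntimeError):
    pass


@dataclass
class DayMatrix:
    """Z-scored behavioral-day matrix with row metadata."""

    M: np.ndarray  # (n_rows, n_metrics)
    meta: pd.DataFrame  # bee_id, date, age, cohort, n_detections
    metrics: list[str]
    col_means: np.ndarray
    col_sds: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.M.shape[0]

    @property
    def total_variance(self) -> float:
        """Mean squared row norm; equals the number of metrics after z-scoring."""
        return float((self.M ** 2).sum() / self.M.shape[0])

    def metric_index(self, metric) -> int:
        return metric if isinstance(metric, (int, np.integer)) else self.metrics.index(metric)


def build_day_matrix(behavioral_days: pd.DataFrame, registry: pd.DataFrame,
                     maps: CombMapSeries,
                     min_detections: int = MIN_DAY_DETECTIONS) -> DayMatrix:
    """Assemble and normalize the day matrix.

    Rows are kept only if the bee was alive on that date (registry death
    date is the cutoff), had strictly more than ``min_detections``
    detections over the day, and the date is not the bee's introduction
    day (introduced bees are not observed for a full 24 h on that day).
    """
    df = behavioral_days.merge(
        registry[["bee_id", "birth_date", "death_date"]], on="bee_id", how="left")
    dates = pd.to_datetime(df["date"]).dt.date
    birth = pd.to_datetime(df["birth_date"]).dt.date
    death = pd.to_datetime(df["death_date"]).dt.date
    keep = (
        (df["n_detections"] > min_detections)
        & (dates > birth)
        & (dates < death)
    )
    keep &= np.isfinite(df[METRICS].to_numpy(dtype=float)).all(axis=1)
    df = df.loc[keep].reset_index(drop=True)
    if len(df) < 2:
        raise PipelineError("fewer than 2 behavioral days survive the filters")

    raw = df[METRICS].to_numpy(dtype=float).copy()
    # subtract the interpolated nest content fraction from honey/brood usage
    for sub, col in (("honey", "f_honey"), ("brood", "f_brood")):
        j = METRICS.index(col)
        baseline = np.array([maps.content_fraction(sub, d) for d in
                             pd.unique(df["date"])])
        lut = dict(zip(pd.unique(df["date"]), baseline))
        raw[:, j] -= np.array([lut[d] for d in df["date"]])

    means = raw.mean(axis=0)
    sds = raw.std(axis=0)  # population SD: total variance is exactly n_metrics
    M = np.zeros_like(raw)
    nz = sds > 0
    M[:, nz] = (raw[:, nz] - means[nz]) / sds[nz]
    if not nz.all():
        degenerate = [METRICS[j] for j in np.flatnonzero(~nz)]
        warnings.warn(f"metrics with zero variance left at 0: {degenerate}")
    meta = df[["bee_id", "date", "age", "cohort", "n_detections"]].reset_index(drop=True)
    return DayMatrix(M=M, meta=meta, metrics=list(METRICS), col_means=means, col_sds=sds)


@dataclass
class PCAResult:
    """Principal components of a z-scored matrix.

    ``loadings[j, c]`` is the weight of metric j on component c (columns
    orthonormal); ``projections = M @ loadings``.  Components are oriented
    so each one's largest-magnitude loading is positive.
    """

    loadings: np.ndarray  # (n_metrics, n_components)
    projections: np.ndarray  # (n_rows, n_components)
    variance_fraction: np.ndarray


def _pca(M: np.ndarray) -> PCAResult:
    if not np.isfinite(M).all():
        raise ValueError("matrix contains non-finite entries")
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    V = Vt.T
    for c in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, c])))
        if V[j, c] < 0:
            V[:, c] = -V[:, c]
            U[:, c] = -U[:, c]
    var = S ** 2
    return PCAResult(loadings=V, projections=U * S,
                     variance_fraction=var / var.sum())


def day_pca(day_matrix: DayMatrix) -> PCAResult:
    """PCA of the day matrix: dominant axes of single-day behavioral variation."""
    return _pca(day_matrix.M)


@dataclass
class EmbeddingModel:
    """A fitted 2-D t-SNE embedding of behavioral days.

    Fit with perplexity 30 for 1000 iterations, initialized from the first
    two PCA projections so the embedding's global structure aligns with
    them.  New points (vectors in day-matrix z units) are placed into the
    existing embedding by barycentric interpolation over their k nearest
    training rows in PCA space -- a transform that by construction lands
    inside the convex hull of those neighbours.
    """

    coords: np.ndarray  # (n_rows, 2)
    loadings: np.ndarray
    train_projections: np.ndarray
    perplexity: float
    n_iter: int
    seed: int
    k_neighbors: int = 30
    _nn: NearestNeighbors | None = field(default=None, repr=False)

    def __post_init__(self):
        if self._nn is None:
            self._nn = NearestNeighbors(
                n_neighbors=min(self.k_neighbors, len(self.train_projections)))
            self._nn.fit(self.train_projections)

    def transform(self, Z: np.ndarray) -> np.ndarray:
        """Map z-scored metric vectors (rows) into the fitted embedding."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        proj = Z @ self.loadings
        dist, idx = self._nn.kneighbors(proj)
        out = np.empty((len(Z), 2))
        for r in range(len(Z)):
            d = dist[r]
            if d[0] == 0.0:
                exact = idx[r][d == 0.0]
                out[r] = self.coords[exact].mean(axis=0)
            else:
                w = 1.0 / d
                w /= w.sum()
                out[r] = w @ self.coords[idx[r]]
        return out


def embed_days(pca: PCAResult, perplexity: float = 30.0, n_iter: int = 1000,
               seed: int = 0) -> EmbeddingModel:
    """2-D t-SNE embedding of behavioral days, initialized from PCA.

    Operates on the full set of PCA projections (a rotation of the z-scored
    matrix, so pairwise distances are unchanged).
    """
    X = pca.projections
    n = X.shape[0]
    if n < 3 * perplexity:
        raise ValueError(
            f"{n} rows is too few for perplexity {perplexity}; reduce perplexity "
            f"to at most {n / 3:.0f}")
    init = X[:, :2].copy()
    init = init / max(init[:, 0].std(), 1e-12) * 1e-4  # small-scale PCA init
    tsne = TSNE(n_components=2, perplexity=perplexity, max_iter=n_iter,
                init=init, random_state=seed)
    coords = tsne.fit_transform(X)
    return EmbeddingModel(coords=np.asarray(coords, dtype=float),
                          loadings=pca.loadings, train_projections=X,
                          perplexity=perplexity, n_iter=n_iter, seed=seed)


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # 1..n_clusters per row
    linkage: np.ndarray
    within_variance: float  # W_n

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


def within_group_variance(M: np.ndarray, groups: np.ndarray,
                          metric_index: int | None = None) -> float:
    """Residual variance fraction W after subtracting group conditional means.

    With ``metric_index`` set, the normalization is that single column's
    squared norm; otherwise the whole matrix norm.
    """
    M = np.asarray(M, dtype=float)
    groups = np.asarray(groups)
    if len(groups) != len(M):
        raise ValueError("grouping length must match matrix rows")
    if len(groups) == 0:
        raise ValueError("empty grouping")
    _, inv = np.unique(groups, return_inverse=True)
    n_groups = inv.max() + 1
    sums = np.zeros((n_groups, M.shape[1]))
    np.add.at(sums, inv, M)
    counts = np.bincount(inv, minlength=n_groups).astype(float)
    means = sums / counts[:, None]
    resid = M - means[inv]
    if metric_index is None:
        denom = (M ** 2).sum()
        num = (resid ** 2).sum()
    else:
        denom = (M[:, metric_index] ** 2).sum()
        num = (resid[:, metric_index] ** 2).sum()
    if denom == 0:
        return 0.0
    return float(num / denom)


def ward_cluster(day_matrix: DayMatrix | np.ndarray, n_clusters: int) -> ClusterAssignment:
    """Ward hierarchical clustering cut at ``n_clusters``, with W_n."""
    M = day_matrix.M if isinstance(day_matrix, DayMatrix) else np.asarray(day_matrix)
    n = len(M)
    if not (1 <= n_clusters <= n):
        raise ValueError(f"n_clusters must be in [1, {n}]")
    Z = linkage(M, method="ward")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    W = within_group_variance(M, labels)
    return ClusterAssignment(labels=labels, linkage=Z, within_variance=W)


def variance_by_grouping(day_matrix: DayMatrix | np.ndarray, groups,
                         metric=None) -> float:
    """Residual variance fraction W for an arbitrary grouping of the rows.

    ``groups`` can be any row-aligned label sequence (e.g. age, cohort, or
    age-and-cohort tuples).  ``metric`` restricts the computation to one
    column.  Report explained variance as ``1 - W``.
    """
    if isinstance(day_matrix, DayMatrix):
        M = day_matrix.M
        mi = None if metric is None else day_matrix.metric_index(metric)
    else:
        M = np.asarray(day_matrix)
        mi = metric
    codes, _ = pd.factorize(pd.Series(list(groups)))
    if (codes < 0).any():
        raise ValueError("every row must be assigned to a group")
    return within_group_variance(M, codes, mi)


def explained_percent(day_matrix, groups, metric=None) -> float:
    """Percentage of variance explained by a grouping: 100 * (1 - W)."""
    return 100.0 * (1.0 - variance_by_grouping(day_matrix, groups, metric))


def cluster_profiles(assignment: ClusterAssignment, day_matrix: DayMatrix,
                     detections: pd.DataFrame | None = None,
                     geometry=None) -> dict:
    """Per-cluster summaries: mean metric vector (z units), ages, occupancy.

    Spatial histograms (detection-weighted counts on the analysis grid) are
    computed only when a detection table and geometry are supplied.
    """
    labels = assignment.labels
    out = {}
    for q in np.unique(labels):
        rows = labels == q
        meta_q = day_matrix.meta.loc[rows]
        entry = {
            "n_rows": int(rows.sum()),
            "mean_metrics": pd.Series(day_matrix.M[rows].mean(axis=0),
                                      index=day_matrix.metrics),
            "median_age": float(meta_q["age"].median()),
        }
        if detections is not None and geometry is not None:
            key = set(zip(meta_q["bee_id"], meta_q["date"]))
            ts = pd.to_datetime(detections["timestamp"]).dt.date
            mask = [(b, d) in key for b, d in zip(detections["bee_id"], ts)]
            sub = detections.loc[mask]
            hist = np.zeros((geometry.n_cells_y, geometry.n_cells_x))
            if len(sub):
                ix, iy = geometry.cell_index(sub["x_cm"].to_numpy(),
                                             sub["y_cm"].to_numpy())
                np.add.at(hist, (iy, ix), 1.0)
                hist /= hist.sum()
            entry["spatial_histogram"] = hist
        out[int(q)] = entry
    return out
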