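"""Lifetime behavioral trajectories: the bee-life tensor and its analysis.

A bee-life is the ordered sequence of a bee's behavioral days.  The tensor
``B[alpha, t, j]`` holds bee alpha's value of metric j on life-day t, in the
same z units as the day matrix.  Life-day t = 0 is the first full day after
introduction (the introduction day itself is excluded upstream), and ages
at or beyond ``amax`` (default 25) are truncated.  Only bees with at least
``dmin`` (default 10) behavioral days, and birth dates inside the
observation period, are included.

PCA cannot handle missing values, so cells where a bee was dead or
unobserved are filled with the per-age mean over observed bees, h[t, j].
Filling with the age-conditional mean (rather than zero, the global mean)
avoids biasing the components: the average metric trajectory is strongly
age-structured even though each day-matrix column averages to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .day_space import (
    ClusterAssignment,
    DayMatrix,
    EmbeddingModel,
    PCAResult,
    PipelineError,
    _pca,
    within_group_variance,
)
from scipy.cluster.hierarchy import fcluster, linkage

AMAX_DEFAULT = 25
DMIN_DEFAULT = 10


@dataclass
class BeeLifeTensor:
    """Fill-completed bee-life tensor with its observation mask."""

    B: np.ndarray  # (n_bees, amax, n_metrics)
    observed: np.ndarray  # bool (n_bees, amax): True where a behavioral day exists
    h: np.ndarray  # (amax, n_metrics) per-age means of observed entries
    bee_ids: np.ndarray
    metrics: list[str]
    amax: int
    dmin: int

    @property
    def n_bees(self) -> int:
        return self.B.shape[0]

    @property
    def flat(self) -> np.ndarray:
        """Bees x (amax * n_metrics) matrix; width 300 with the defaults."""
        return self.B.reshape(self.n_bees, -1)


def build_life_tensor(day_matrix: DayMatrix, registry: pd.DataFrame,
                      amax: int = AMAX_DEFAULT, dmin: int = DMIN_DEFAULT,
                      observation_start=None) -> BeeLifeTensor:
    """Assemble the bee-life tensor from day-matrix rows.

    ``observation_start``, if given, drops bees born before it (cohorts
    already present when recording began have truncated early lives).
    """
    meta = day_matrix.meta
    counts = meta.groupby("bee_id").size()
    keep_ids = set(counts[counts >= dmin].index)
    if observation_start is not None:
        start = pd.Timestamp(observation_start).date()
        births = registry.set_index("bee_id")["birth_date"]
        keep_ids = {b for b in keep_ids
                    if b in births.index and pd.Timestamp(births[b]).date() >= start}
    bee_ids = np.array(sorted(keep_ids))
    if len(bee_ids) == 0:
        raise PipelineError("no bees satisfy the lifetime-analysis filters")
    index = {b: i for i, b in enumerate(bee_ids)}

    n_metrics = day_matrix.M.shape[1]
    B = np.full((len(bee_ids), amax, n_metrics), np.nan)
    ages = meta["age"].to_numpy()
    for r, bee in enumerate(meta["bee_id"]):
        if bee not in index:
            continue
        t = int(ages[r]) - 1  # t = 0 is the first full day after introduction
        if 0 <= t < amax:
            B[index[bee], t, :] = day_matrix.M[r]
    observed = np.isfinite(B[:, :, 0])
    cnt = observed.sum(axis=0)
    sums = np.where(observed[:, :, None], B, 0.0).sum(axis=0)
    # ages with no observed bee at all fall back to the global (zero) mean
    h = np.where(cnt[:, None] > 0, sums / np.maximum(cnt, 1)[:, None], 0.0)
    miss = ~observed
    B[miss] = np.broadcast_to(h, B.shape)[miss]
    return BeeLifeTensor(B=B, observed=observed, h=h, bee_ids=bee_ids,
                         metrics=list(day_matrix.metrics), amax=amax, dmin=dmin)


@dataclass
class LifePCAResult:
    """PCA over flattened bee-lives.

    ``loadings`` has shape (n_components, amax, n_metrics); ``projections``
    is bees x components.  Sign conventions orient component 1 so higher
    overall movement activity is positive (mean dispersion / nest-fraction
    loading > 0) and component 2 so an earlier transition to dance-floor
    use and time outside is positive.
    """

    loadings: np.ndarray
    projections: np.ndarray
    variance_fraction: np.ndarray
    mean: np.ndarray
    metrics: list[str]


def life_pca(tensor: BeeLifeTensor) -> LifePCAResult:
    X = tensor.flat
    mean = X.mean(axis=0)
    pca: PCAResult = _pca(X - mean)
    k = pca.loadings.shape[1]
    L = pca.loadings.T.reshape(k, tensor.amax, len(tensor.metrics)).copy()
    P = pca.projections.copy()
    j_disp = tensor.metrics.index("dispersion")
    j_frac = tensor.metrics.index("fraction_nest_visited")
    j_df = tensor.metrics.index("f_dancefloor")
    j_out = tensor.metrics.index("time_outside")
    if k >= 1 and (L[0, :, j_disp].mean() + L[0, :, j_frac].mean()) < 0:
        L[0] = -L[0]
        P[:, 0] = -P[:, 0]
    if k >= 2 and (L[1, :, j_df].mean() + L[1, :, j_out].mean()) < 0:
        L[1] = -L[1]
        P[:, 1] = -P[:, 1]
    return LifePCAResult(loadings=L, projections=P,
                         variance_fraction=pca.variance_fraction,
                         mean=mean, metrics=tensor.metrics)


@dataclass
class LifeClusterAssignment:
    """Ward clustering of bee-lives with per-cluster summaries."""

    labels: np.ndarray  # 1..n per bee
    linkage: np.ndarray
    within_variance: float
    bee_ids: np.ndarray
    lifespans: pd.Series  # true days lived per bee (registry), not tensor occupancy
    cluster_age_means: np.ndarray  # (n_clusters, amax, n_metrics), NaN if unobserved

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())

    def median_lifespans(self) -> pd.Series:
        return self.lifespans.groupby(self.labels).median()


def life_cluster(tensor: BeeLifeTensor, registry: pd.DataFrame,
                 n_clusters: int = 5) -> LifeClusterAssignment:
    """Ward clustering on the flattened (fill-completed) bee-life tensor."""
    if n_clusters > tensor.n_bees:
        raise ValueError("more clusters than bees")
    X = tensor.flat
    Z = linkage(X, method="ward")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    W = within_group_variance(X, labels)
    reg = registry.set_index("bee_id")
    births = pd.to_datetime(reg.loc[tensor.bee_ids, "birth_date"])
    deaths = pd.to_datetime(reg.loc[tensor.bee_ids, "death_date"])
    lifespans = pd.Series((deaths - births).dt.days.to_numpy(),
                          index=tensor.bee_ids, name="lifespan_days")
    n_q = int(labels.max())
    means = np.full((n_q, tensor.amax, len(tensor.metrics)), np.nan)
    for q in range(1, n_q + 1):
        sel = labels == q
        obs = tensor.observed[sel]  # (m, amax)
        cnt = obs.sum(axis=0)
        sums = (tensor.B[sel] * obs[:, :, None]).sum(axis=0)
        means[q - 1] = np.where(cnt[:, None] > 0,
                                sums / np.maximum(cnt, 1)[:, None], np.nan)
    return LifeClusterAssignment(labels=labels, linkage=Z, within_variance=W,
                                 bee_ids=tensor.bee_ids, lifespans=lifespans,
                                 cluster_age_means=means)


def project_life_trajectories(assignment: LifeClusterAssignment,
                              embedding: EmbeddingModel) -> dict[int, pd.DataFrame]:
    """Average per-cluster lifetime paths through the behavioral-day embedding.

    For each cluster and each life-day with at least one observed bee, the
    mean metric vector (z units, observed bees only) is mapped into the
    fitted day embedding; the ordered points form that cluster's average
    trajectory through behavioral space.
    """
    if embedding is None:
        raise ValueError("day embedding has not been fitted")
    out = {}
    n_q = assignment.cluster_age_means.shape[0]
    for q in range(1, n_q + 1):
        means = assignment.cluster_age_means[q - 1]
        ok = np.isfinite(means[:, 0])
        pts = embedding.transform(means[ok]) if ok.any() else np.empty((0, 2))
        out[q] = pd.DataFrame({
            "life_day": np.flatnonzero(ok),
            "x": pts[:, 0] if len(pts) else [],
            "y": pts[:, 1] if len(pts) else [],
        })
    return out


def lifetime_summary(tensor: BeeLifeTensor,
                     assignment: LifeClusterAssignment | None = None) -> pd.DataFrame:
    """Per-bee lifetime means of each metric over observed days only (z units).

    Filled cells are excluded so the summary reflects what the bee actually
    did, not the population average used to complete the tensor.
    """
    cnt = tensor.observed.sum(axis=1)
    means = (np.where(tensor.observed[:, :, None], tensor.B, 0.0).sum(axis=1)
             / np.maximum(cnt, 1)[:, None])
    means[cnt == 0] = np.nan  # all observed days past amax: nothing to average
    df = pd.DataFrame(means, columns=tensor.metrics)
    df.insert(0, "bee_id", tensor.bee_ids)
    if assignment is not None:
        df["life_cluster"] = assignment.labels
    return df
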