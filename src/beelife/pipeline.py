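"""End-to-end drivers tying simulation, metrics, and the two analyses together.

Simulation and metric extraction run day by day, so the full detection
table (which can run to tens of millions of rows) never has to be held in
memory; only behavioral-day rows and ground truth accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import colony_sim, daily_metrics, day_space, life_space
from .colony_sim import GroundTruth, SimConfig
from .core_model import CombMapSeries, NestGeometry


@dataclass
class SimResult:
    config: SimConfig
    maps: CombMapSeries
    registry: pd.DataFrame
    ground_truth: GroundTruth
    behavioral_days: pd.DataFrame
    detections: pd.DataFrame | None = None

    @property
    def geometry(self) -> NestGeometry:
        return self.maps.geometry


def run_colony(config: SimConfig, seed: int | None = None,
               keep_detections: bool = False) -> SimResult:
    """Simulate a colony and compute behavioral days, streaming one day at a time."""
    s = config.seed if seed is None else seed
    maps = colony_sim.generate_nest_layout(config, seed=s)
    archetypes = colony_sim.generate_population(config, seed=s + 1)
    registry = colony_sim.registry_from_archetypes(archetypes, config)
    day_rows, occs, trips, dets = [], [], [], []
    for date, det, occ, trip in colony_sim.iter_detection_days(
            archetypes, maps, config, seed=s + 2):
        occs.append(occ)
        trips.append(trip)
        if keep_detections:
            dets.append(det)
        if len(det):
            day_rows.append(daily_metrics.compute_behavioral_days(
                det, maps, registry, config.frame_rate))
    behavioral_days = (pd.concat(day_rows, ignore_index=True) if day_rows
                       else pd.DataFrame())
    gt = GroundTruth(
        archetypes=colony_sim.archetypes_frame(archetypes, config),
        occupancy=pd.concat(occs, ignore_index=True),
        trips=pd.concat([t for t in trips if len(t)], ignore_index=True)
        if any(len(t) for t in trips) else trips[0],
    )
    return SimResult(config=config, maps=maps, registry=registry, ground_truth=gt,
                     behavioral_days=behavioral_days,
                     detections=pd.concat(dets, ignore_index=True) if dets else None)


@dataclass
class DayAnalysis:
    day_matrix: day_space.DayMatrix
    pca: day_space.PCAResult
    clusters: day_space.ClusterAssignment
    embedding: day_space.EmbeddingModel | None = None


def analyze_days(behavioral_days: pd.DataFrame, registry: pd.DataFrame,
                 maps: CombMapSeries, n_clusters: int = 5, seed: int = 0,
                 embed: bool = True, perplexity: float = 30.0,
                 n_iter: int = 1000) -> DayAnalysis:
    dm = day_space.build_day_matrix(behavioral_days, registry, maps)
    pca = day_space.day_pca(dm)
    clusters = day_space.ward_cluster(dm, n_clusters)
    emb = day_space.embed_days(pca, perplexity=perplexity, n_iter=n_iter,
                               seed=seed) if embed else None
    return DayAnalysis(day_matrix=dm, pca=pca, clusters=clusters, embedding=emb)


@dataclass
class LifeAnalysis:
    tensor: life_space.BeeLifeTensor
    pca: life_space.LifePCAResult
    clusters: life_space.LifeClusterAssignment
    trajectories: dict | None = None
    summary: pd.DataFrame | None = None


def analyze_lives(day_analysis: DayAnalysis, registry: pd.DataFrame,
                  amax: int = life_space.AMAX_DEFAULT,
                  dmin: int = life_space.DMIN_DEFAULT,
                  n_clusters: int = 5, observation_start=None) -> LifeAnalysis:
    tensor = life_space.build_life_tensor(day_analysis.day_matrix, registry,
                                          amax=amax, dmin=dmin,
                                          observation_start=observation_start)
    pca = life_space.life_pca(tensor)
    clusters = life_space.life_cluster(tensor, registry, n_clusters=n_clusters)
    traj = (life_space.project_life_trajectories(clusters, day_analysis.embedding)
            if day_analysis.embedding is not None else None)
    summary = life_space.lifetime_summary(tensor, clusters)
    return LifeAnalysis(tensor=tensor, pca=pca, clusters=clusters,
                        trajectories=traj, summary=summary)
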