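"""Post-processing: per-cluster box-plot outlier flagging on
distance-from-center, and the three-method benchmark harness.

Outlier flagging follows the Tukey box-plot rule on each cluster's
member-to-center Euclidean distances: quartiles by linear interpolation
between order statistics, upper fence at Q3 + 1.5*IQR.  Distances are
non-negative and right-skewed, so only the upper fence flags records.
Clusters with fewer than four members get fences but no flags.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .clustering import ClusteringResult, RunConfig, run
from .kdtree import PointSet
from .validation import DegenerateMSEError, mse_db

__all__ = [
    "ClusterBoxStats",
    "OutlierReport",
    "BenchmarkRecord",
    "distance_outliers",
    "run_benchmark",
    "benchmark_to_dataframe",
]

DEFAULT_FRACTIONS = tuple(range(10, 101, 10))


@dataclass
class ClusterBoxStats:
    cluster: int
    n_members: int
    q1: float
    median: float
    q3: float
    iqr: float
    upper_fence: float
    outlier_ids: list


@dataclass
class OutlierReport:
    clusters: list[ClusterBoxStats]
    distances: np.ndarray      # per-record distance to the assigned center
    is_outlier: np.ndarray     # per-record flag
    dead_centers: list[int]

    def to_frame(self, points: PointSet, assignments) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": points.ids,
                "cluster": np.asarray(assignments),
                "distance": self.distances,
                "is_outlier": self.is_outlier,
            }
        )


def distance_outliers(points: PointSet, result: ClusteringResult) -> OutlierReport:
    """Flag records unusually far from their assigned center, per cluster."""
    labels = np.asarray(result.assignments)
    if labels.shape != (points.n,):
        raise ValueError("result does not match the point set")
    centers = result.centers.centers
    dist = np.sqrt(((points.coords - centers[labels]) ** 2).sum(axis=1))
    is_outlier = np.zeros(points.n, dtype=bool)
    stats: list[ClusterBoxStats] = []
    dead: list[int] = []
    for c in range(result.centers.k):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            dead.append(c)
            continue
        d = dist[members]
        q1, med, q3 = np.percentile(d, [25, 50, 75])  # linear interpolation
        iqr = q3 - q1
        fence = q3 + 1.5 * iqr
        outlier_ids: list = []
        if members.size >= 4:
            flagged = members[d > fence]
            is_outlier[flagged] = True
            outlier_ids = list(points.ids[flagged])
        stats.append(
            ClusterBoxStats(c, int(members.size), float(q1), float(med), float(q3),
                            float(iqr), float(fence), outlier_ids)
        )
    return OutlierReport(stats, dist, is_outlier, dead)


@dataclass
class BenchmarkRecord:
    method: str
    fraction: float
    n_points: int
    runtime_s: float
    mse_db: float
    seed: int


def run_benchmark(
    points: PointSet,
    config: RunConfig,
    fractions=DEFAULT_FRACTIONS,
    seed: int = 0,
) -> list[BenchmarkRecord]:
    """Run each method on seeded random subsamples of increasing size.

    For every fraction (percent of the data) a subsample without replacement
    is drawn once and shared by the three methods, so the comparison is
    paired.  Wall time is informational; the quality measure is the final MSE
    in dB.
    """
    records: list[BenchmarkRecord] = []
    fractions = list(fractions)
    for f in fractions:
        if not (0 < f <= 100):
            raise ValueError("fractions must lie in (0, 100]")
    for method in ("lloyd", "macqueen", "fes"):
        for f in fractions:
            n_sub = int(round(f * points.n / 100.0))
            if n_sub < config.k:
                raise ValueError(
                    f"fraction {f}% yields {n_sub} points, fewer than k={config.k}"
                )
            rng = np.random.default_rng([seed, int(round(f * 1000))])
            idx = np.sort(rng.choice(points.n, size=n_sub, replace=False))
            sub = PointSet(points.coords[idx], points.ids[idx], points.dim_names)
            cfg = replace(config, method=method)
            t0 = time.perf_counter()
            result = run(sub, cfg)
            elapsed = time.perf_counter() - t0
            try:
                quality = mse_db(sub, result.assignments, result.centers)
            except DegenerateMSEError:
                quality = float("nan")
            records.append(
                BenchmarkRecord(method, float(f), n_sub, elapsed, quality, seed)
            )
    return records


def benchmark_to_dataframe(records: list[BenchmarkRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "method": r.method,
                "fraction": r.fraction,
                "n_points": r.n_points,
                "runtime_s": r.runtime_s,
                "mse_db": r.mse_db,
                "seed": r.seed,
            }
            for r in records
        ]
    )
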