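"""The multiple k-means (MkM) centroid ensemble.

N independently seeded k-means models are run on the same prepared matrix
ARN, with the number of centres sweeping an ordered set of values (by
default 2..30, ten instances each, N = 290).  All centroids are stacked
into a single matrix C0 of L = sum_i Nc_i rows, each tagged with its
(model, cluster) pair, and every municipality's label under every model is
recorded in the assignment matrix AC alongside its held-out PMR.

The ensemble is the replication device: each model runs a single Lloyd
optimisation from a random-point initialisation (no k-means++ by default,
no restarts), and per-model seeds are derived from the master seed by
position so that extending the ensemble never perturbs earlier models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

__all__ = ["EnsembleConfig", "MkMResult", "run_mkm", "coverage_curve", "model_seed"]


@dataclass(frozen=True)
class EnsembleConfig:
    """Configuration of the k-means ensemble.

    Defaults follow the reference setup: centre counts 2..30, ten
    independently initialised instances per count (290 models in all),
    convergence tolerance 1e-7, at most 10,000 Lloyd iterations.
    """

    nc_values: tuple[int, ...] = tuple(range(2, 31))
    reps_per_nc: int = 10
    tol: float = 1e-7
    max_iter: int = 10_000
    seed: int = 0
    init: str = "random"  # random data points; "k-means++" available

    def __post_init__(self) -> None:
        if not self.nc_values or any(nc < 2 for nc in self.nc_values):
            raise ValueError("every centre count must be >= 2")
        if len(set(self.nc_values)) != len(self.nc_values):
            raise ValueError("nc_values must be distinct")
        if self.reps_per_nc < 1:
            raise ValueError("reps_per_nc must be >= 1")
        if self.tol < 0 or self.max_iter < 1:
            raise ValueError("invalid tol/max_iter")

    @property
    def n_models(self) -> int:
        return len(self.nc_values) * self.reps_per_nc

    def model_nc(self) -> list[int]:
        """Centre count of each model, in execution order."""
        return [nc for nc in self.nc_values for _ in range(self.reps_per_nc)]


def model_seed(master_seed: int, model_index: int) -> int:
    """Stable per-model seed: a function of (master_seed, position) only."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(model_index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class MkMResult:
    """Pooled centroids (C0), assignment matrix (AC) and per-model stats."""

    centroids: pd.DataFrame    # model_index, cluster_index, f1..fH
    assignments: pd.DataFrame  # municipality_code, PMR, m0001..mN
    models: pd.DataFrame       # model_index, nc, seed, inertia, n_iter
    config: EnsembleConfig

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def n_centroids(self) -> int:
        """L = sum over models of the model's centre count."""
        return len(self.centroids)


def run_mkm(
    arn: pd.DataFrame,
    config: EnsembleConfig,
    pmr: pd.Series | None = None,
) -> MkMResult:
    """Run the ensemble on ARN (rows indexed by municipality code).

    ``pmr`` is the held-out PMR vector aligned with ARN's index; it becomes
    the first feature column of the assignment matrix AC.  Label columns
    are named ``m0001 .. mN`` in execution order (model i uses 1-based
    numbering).  Empty clusters are repaired by scikit-learn's standard
    relocation, so every model yields exactly its requested number of
    centroids.
    """
    X = arn.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("ARN contains non-finite values")
    n_rows = X.shape[0]
    if max(config.nc_values) > n_rows:
        raise ValueError(
            f"largest centre count {max(config.nc_values)} exceeds {n_rows} rows"
        )
    if pmr is not None and not arn.index.equals(pmr.index):
        raise ValueError("ARN and PMR are not aligned")

    centroid_frames: list[pd.DataFrame] = []
    labels: dict[str, np.ndarray] = {}
    model_rows = []
    feat_cols = [f"f{j + 1}" for j in range(X.shape[1])]

    n_degenerate = 0
    for i, nc in enumerate(config.model_nc(), start=1):
        seed_i = model_seed(config.seed, i)
        km = KMeans(
            n_clusters=nc,
            init=config.init,
            n_init=1,
            tol=config.tol,
            max_iter=config.max_iter,
            algorithm="lloyd",
            random_state=seed_i,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            km.fit(X)
        n_degenerate += sum(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
        frame = pd.DataFrame(km.cluster_centers_, columns=feat_cols)
        frame.insert(0, "cluster_index", np.arange(nc))
        frame.insert(0, "model_index", i)
        centroid_frames.append(frame)
        labels[f"m{i:04d}"] = km.labels_.astype(int)
        model_rows.append((i, nc, seed_i, float(km.inertia_), int(km.n_iter_)))

    if n_degenerate:
        logger.info(
            "run_mkm: %d models needed empty-cluster repair or converged "
            "with duplicate centres",
            n_degenerate,
        )
    centroids = pd.concat(centroid_frames, ignore_index=True)
    assignments = pd.DataFrame(labels, index=arn.index)
    assignments.insert(
        0,
        "PMR",
        pmr.to_numpy(dtype=float) if pmr is not None else np.nan,
    )
    assignments = assignments.rename_axis("municipality_code").reset_index()
    models = pd.DataFrame(
        model_rows, columns=["model_index", "nc", "seed", "inertia", "n_iter"]
    )
    return MkMResult(
        centroids=centroids, assignments=assignments, models=models, config=config
    )


def coverage_curve(result: MkMResult, flags: pd.DataFrame) -> pd.DataFrame:
    """Count clusters of interest per centre count.

    ``flags`` carries one row per (model_index, cluster_index) with a
    ``coi_flag`` column (``none`` / ``high`` / ``low``, as produced by the
    consensus stage).  Returns one row per distinct centre count with the
    number of flagged clusters among models of that count.  The trend is
    reported, not enforced.
    """
    tagged = flags.merge(
        result.models[["model_index", "nc"]], on="model_index", how="inner"
    )
    tagged["is_coi"] = (tagged["coi_flag"] != "none").astype(int)
    out = (
        tagged.groupby("nc", sort=True)["is_coi"]
        .sum()
        .rename("n_coi")
        .reset_index()
    )
    return out
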