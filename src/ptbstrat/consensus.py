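"""Consensus stage: clusters of interest, correlation, DBSCAN, mapping.

Each base cluster of the ensemble is scored by the mean PMR of its member
municipalities; clusters whose mean deviates from the national PMR by at
least 10% (relative, boundary inclusive) are flagged as clusters of
interest (CoI).  The pooled centroid matrix is filtered to the CoI rows,
a Pearson correlation matrix between the surviving centroid vectors is
built, reduced by PCA to 99% variance, min-max normalised, and clustered
with DBSCAN: recurring, mutually similar base clusters merge into final
clusters while unsupported centroids become noise.  Finally each
municipality is mapped to the final cluster it is most often assigned to,
typed high/low by where its memberships predominantly sit, with a signed
intensity (high-count minus low-count).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .featprep import pca_reduce

logger = logging.getLogger(__name__)

__all__ = [
    "DBSCANParams",
    "ConsensusResult",
    "cluster_pmr_stats",
    "select_coi",
    "centroid_correlation",
    "reduce_correlation",
    "dbscan_consensus",
    "final_cluster_types",
    "map_municipalities",
    "run_consensus",
]

NOISE = -1

_LABEL_COL = re.compile(r"^m\d+$")


def _label_columns(assignments: pd.DataFrame) -> list[str]:
    return [c for c in assignments.columns if _LABEL_COL.match(c)]


@dataclass(frozen=True)
class DBSCANParams:
    """Density parameters of the meta-clustering step.

    ``eps`` is the Euclidean neighbourhood radius on the normalised reduced
    correlation profiles; ``min_points`` is the recurrence-evidence
    threshold — the minimum number of mutually similar ensemble centroids
    (the point itself included) needed to found a final cluster.  The
    reference values are eps=0.06 and min_points=50 for a 290-model
    ensemble; scale min_points down proportionally for smaller ensembles.
    """

    eps: float = 0.06
    min_points: int = 50

    def __post_init__(self) -> None:
        if not self.eps > 0:
            raise ValueError("eps must be > 0")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")


def cluster_pmr_stats(
    assignments: pd.DataFrame,
    national_pmr: float,
    centroids: pd.DataFrame | None = None,
    *,
    coi_threshold: float = 0.10,
) -> pd.DataFrame:
    """Per-(model, cluster) membership count, mean PMR, relative deviation
    from the national PMR, and CoI flag.

    The mean PMR of a cluster is the plain average of its member
    municipalities' PMR values.  ``coi_flag`` is ``high`` when the relative
    deviation is >= +threshold, ``low`` when <= -threshold (boundary
    inclusive), else ``none``; an empty cluster (possible only when
    ``centroids`` supplies the full tag list) is forced to ``none``.
    """
    if not national_pmr > 0:
        raise ValueError("national_pmr must be > 0")
    label_cols = _label_columns(assignments)
    pmr = assignments["PMR"].to_numpy(dtype=float)

    frames = []
    for col in label_cols:
        i = int(col[1:])
        lab = assignments[col].to_numpy()
        grp = pd.DataFrame({"cluster_index": lab, "PMR": pmr}).groupby(
            "cluster_index", sort=True
        )["PMR"]
        stat = grp.agg(B="size", mean_pmr="mean").reset_index()
        stat.insert(0, "model_index", i)
        frames.append(stat)
    stats = pd.concat(frames, ignore_index=True)

    if centroids is not None:
        tags = centroids[["model_index", "cluster_index"]]
        stats = tags.merge(stats, on=["model_index", "cluster_index"], how="left")
        stats["B"] = stats["B"].fillna(0).astype(int)

    stats["deviation"] = (stats["mean_pmr"] - national_pmr) / national_pmr
    # boundary inclusive; epsilon so an exact +/-10% case is not lost to
    # floating-point rounding of the ratio
    tol = 1e-12
    flag = np.where(
        stats["deviation"] >= coi_threshold - tol,
        "high",
        np.where(stats["deviation"] <= -(coi_threshold - tol), "low", "none"),
    )
    flag = np.where(stats["B"].to_numpy() == 0, "none", flag)
    stats["coi_flag"] = flag
    return stats


def select_coi(stats: pd.DataFrame, centroids: pd.DataFrame) -> pd.DataFrame:
    """Filter the pooled centroid matrix to the clusters of interest (Cci),
    preserving the (model, cluster) tags.  An empty result is returned as
    such; downstream stages refuse it with a clear message."""
    flagged = stats.loc[
        stats["coi_flag"] != "none", ["model_index", "cluster_index"]
    ]
    return centroids.merge(
        flagged, on=["model_index", "cluster_index"], how="inner"
    ).reset_index(drop=True)


def _feature_cols(centroids: pd.DataFrame) -> list[str]:
    return [c for c in centroids.columns if c not in ("model_index", "cluster_index")]


def centroid_correlation(cci: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between centroid vectors across their features
    (matrix C1): symmetric, unit diagonal, indexed by the (model, cluster)
    tags.  A constant centroid vector has no defined correlation and is
    reported as an error naming its tag."""
    if len(cci) < 2:
        raise ValueError(
            "need at least 2 clusters of interest to correlate; got "
            f"{len(cci)} — no consensus is possible"
        )
    X = cci[_feature_cols(cci)].to_numpy(dtype=float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = cci.loc[sd == 0, ["model_index", "cluster_index"]].to_records(
            index=False
        )
        raise ValueError(f"constant centroid vector(s), correlation undefined: {list(bad)}")
    corr = np.corrcoef(X)
    np.fill_diagonal(corr, 1.0)
    tags = pd.MultiIndex.from_frame(
        cci[["model_index", "cluster_index"]], names=["model_index", "cluster_index"]
    )
    return pd.DataFrame(corr, index=tags, columns=tags)


def reduce_correlation(
    c1: pd.DataFrame, variance_target: float = 0.99
) -> pd.DataFrame:
    """PCA (rows as samples) to the smallest component count reaching the
    variance target, then per-column min-max to [0, 1] (matrix CRN)."""
    reduced, _ = pca_reduce(c1, variance_target)
    arr = reduced.to_numpy()
    lo, hi = arr.min(axis=0), arr.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    out = (arr - lo) / span
    out[:, hi == lo] = 0.0
    return pd.DataFrame(out, index=c1.index, columns=reduced.columns)


def dbscan_consensus(crn: pd.DataFrame, params: DBSCANParams) -> pd.Series:
    """Label each CoI centroid with its final cluster (or -1 for noise)
    using Euclidean DBSCAN; a core point needs at least ``min_points``
    neighbours within ``eps``, itself included."""
    arr = crn.to_numpy(dtype=float)
    labels = DBSCAN(
        eps=params.eps, min_samples=params.min_points, metric="euclidean"
    ).fit_predict(arr)
    return pd.Series(labels, index=crn.index, name="final_label")


def final_cluster_types(
    labels: pd.Series, stats: pd.DataFrame, national_pmr: float
) -> dict[int, str]:
    """Type each final cluster high/low by the mean over its member
    centroids of their base-cluster mean PMRs, relative to national.

    A final cluster mixing high- and low-flagged members is legal but
    surprising; it is reported as a warning.
    """
    tagged = labels.rename("final_label").reset_index()
    tagged = tagged.merge(stats, on=["model_index", "cluster_index"], how="left")
    types: dict[int, str] = {}
    for lab, grp in tagged[tagged["final_label"] != NOISE].groupby("final_label"):
        mixed = set(grp["coi_flag"].unique())
        if {"high", "low"} <= mixed:
            logger.warning(
                "final cluster %d mixes high- and low-PMR base clusters", lab
            )
        types[int(lab)] = (
            "high" if grp["mean_pmr"].mean() >= national_pmr else "low"
        )
    return types


@dataclass
class ConsensusResult:
    """Final-cluster labels per CoI centroid and the municipality mapping."""

    stats: pd.DataFrame            # per-(model, cluster) PMR stats + flags
    coi_labels: pd.Series          # final label (or -1) per CoI tag
    cluster_types: dict[int, str]  # final label -> "high" | "low"
    municipalities: pd.DataFrame   # per-municipality counts/dominant/type/intensity
    params: DBSCANParams
    national_pmr: float

    @property
    def final_clusters(self) -> list[int]:
        return sorted(self.cluster_types)

    @property
    def n_noise(self) -> int:
        return int((self.coi_labels == NOISE).sum())


def map_municipalities(
    assignments: pd.DataFrame,
    stats: pd.DataFrame,
    coi_labels: pd.Series,
    cluster_types: dict[int, str],
) -> pd.DataFrame:
    """Count, per municipality, how often its ensemble assignments land in
    each final cluster, and derive dominant cluster, high/low type and
    intensity.

    Rules: dominant cluster is the most frequent final cluster (ties to
    the lowest label, logged); a municipality with no CoI membership is
    unclassified; type is by majority between memberships of high- and
    low-typed final clusters (a nonzero tie falls back to the dominant
    cluster's type); intensity = high-count - low-count.
    """
    label_cols = _label_columns(assignments)
    long = assignments.melt(
        id_vars=["municipality_code"],
        value_vars=label_cols,
        var_name="model",
        value_name="cluster_index",
    )
    long["model_index"] = long["model"].str[1:].astype(int)
    lab_frame = coi_labels.rename("final_label").reset_index()
    lab_frame = lab_frame[lab_frame["final_label"] != NOISE]
    hits = long.merge(
        lab_frame, on=["model_index", "cluster_index"], how="inner"
    )

    counts = (
        hits.groupby(["municipality_code", "final_label"])
        .size()
        .unstack(fill_value=0)
    )
    counts = counts.reindex(
        index=assignments["municipality_code"], fill_value=0
    )
    for lab in sorted(cluster_types):
        if lab not in counts.columns:
            counts[lab] = 0
    counts = counts[sorted(counts.columns)]

    if counts.shape[1] == 0:
        # every CoI centroid was noise: no final clusters exist
        logger.warning("map_municipalities: no final clusters; all unclassified")
        return pd.DataFrame(
            {
                "municipality_code": assignments["municipality_code"],
                "n_high": 0,
                "n_low": 0,
                "dominant_cluster": NOISE,
                "type": "unclassified",
                "intensity": 0,
            }
        )

    arr = counts.to_numpy()
    total = arr.sum(axis=1)
    dominant = np.where(
        total > 0, np.asarray(counts.columns)[np.argmax(arr, axis=1)], NOISE
    )
    n_ties = int(
        ((arr == arr.max(axis=1, keepdims=True)).sum(axis=1) > 1)[total > 0].sum()
    )
    if n_ties:
        logger.info(
            "map_municipalities: %d dominant-cluster ties broken to lowest label",
            n_ties,
        )

    high_cols = [c for c in counts.columns if cluster_types.get(c) == "high"]
    low_cols = [c for c in counts.columns if cluster_types.get(c) == "low"]
    n_high = counts[high_cols].sum(axis=1).to_numpy()
    n_low = counts[low_cols].sum(axis=1).to_numpy()

    mtype = np.where(
        total == 0,
        "unclassified",
        np.where(
            n_high > n_low,
            "high",
            np.where(
                n_low > n_high,
                "low",
                # nonzero tie: fall back to the dominant cluster's type
                [cluster_types.get(d, "unclassified") for d in dominant],
            ),
        ),
    )

    out = counts.rename(columns=lambda c: f"count_{c}").reset_index()
    out["n_high"] = n_high
    out["n_low"] = n_low
    out["dominant_cluster"] = dominant
    out["type"] = mtype
    out["intensity"] = n_high - n_low
    return out


def run_consensus(
    mkm_result,
    national_pmr: float,
    *,
    coi_threshold: float = 0.10,
    variance_target: float = 0.99,
    params: DBSCANParams | None = None,
    correlate_unfiltered: bool = False,
) -> ConsensusResult:
    """Run the full consensus chain on an ensemble result.

    ``correlate_unfiltered`` computes the correlation matrix over all
    pooled centroids instead of the CoI subset (the reduced rows are then
    re-filtered to CoI before DBSCAN); the default correlates the filtered
    set.
    """
    params = params or DBSCANParams()
    stats = cluster_pmr_stats(
        mkm_result.assignments,
        national_pmr,
        mkm_result.centroids,
        coi_threshold=coi_threshold,
    )
    cci = select_coi(stats, mkm_result.centroids)
    if cci.empty:
        raise ValueError(
            "no clusters of interest at the configured threshold; "
            "consensus cannot proceed"
        )
    if correlate_unfiltered:
        c1 = centroid_correlation(mkm_result.centroids)
        crn = reduce_correlation(c1, variance_target)
        tags = pd.MultiIndex.from_frame(cci[["model_index", "cluster_index"]])
        crn = crn.loc[crn.index.isin(tags)]
    else:
        c1 = centroid_correlation(cci)
        crn = reduce_correlation(c1, variance_target)
    labels = dbscan_consensus(crn, params)
    types = final_cluster_types(labels, stats, national_pmr)
    municipalities = map_municipalities(
        mkm_result.assignments, stats, labels, types
    )
    return ConsensusResult(
        stats=stats,
        coi_labels=labels,
        cluster_types=types,
        municipalities=municipalities,
        params=params,
        national_pmr=national_pmr,
    )
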