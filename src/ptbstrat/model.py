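"""Model/Results interface over the whole stratification pipeline.

:class:`PTBStratification` is constructed from a municipality table (or
from the four record-level tables via :meth:`PTBStratification.from_tables`)
and holds the stage parameters; :meth:`~PTBStratification.fit` executes
feature preparation, the k-means centroid ensemble and the DBSCAN
consensus, returning a :class:`StratificationResults` that carries every
intermediate, exposes the evaluation layer, and prints a compact
``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import consensus as _consensus
from . import featprep as _featprep
from . import ingest as _ingest
from . import mkm as _mkm
from . import report as _report

__all__ = ["PTBStratification", "StratificationResults"]


class PTBStratification:
    """Municipality-level preterm-birth risk stratification model.

    Parameters
    ----------
    a0
        Municipality table: ``municipality_code``, ``PMR`` and one column
        per aggregated SES feature.
    outlier_k
        PMR outlier cut in standard deviations (default 3).
    variance_target
        Explained-variance share retained by the feature PCA (default 0.95).
    ensemble
        :class:`~ptbstrat.mkm.EnsembleConfig`; defaults to the reference
        2..30 x 10 ensemble.
    coi_threshold
        Relative PMR deviation flagging a cluster of interest (default 0.10).
    dbscan
        :class:`~ptbstrat.consensus.DBSCANParams` (default eps=0.06,
        min_points=50).
    corr_variance_target
        Explained-variance share retained when reducing the centroid
        correlation matrix (default 0.99).
    """

    def __init__(
        self,
        a0: pd.DataFrame,
        *,
        outlier_k: float = 3.0,
        variance_target: float = 0.95,
        ensemble: _mkm.EnsembleConfig | None = None,
        coi_threshold: float = 0.10,
        dbscan: _consensus.DBSCANParams | None = None,
        corr_variance_target: float = 0.99,
        pca_scale: bool = False,
        seed: int = 0,
    ) -> None:
        self.a0 = a0
        self.outlier_k = outlier_k
        self.variance_target = variance_target
        self.ensemble = ensemble or _mkm.EnsembleConfig(seed=seed)
        self.coi_threshold = coi_threshold
        self.dbscan = dbscan or _consensus.DBSCANParams()
        self.corr_variance_target = corr_variance_target
        self.pca_scale = pca_scale
        self.seed = seed

    @classmethod
    def from_tables(
        cls,
        births: pd.DataFrame,
        population: pd.DataFrame,
        persons: pd.DataFrame,
        households: pd.DataFrame,
        schema: _ingest.MicrodataSchema = _ingest.DEFAULT_SCHEMA,
        **kwargs,
    ) -> "PTBStratification":
        """Build the model from the four record-level tables by running the
        ingest chain first."""
        a0 = _ingest.build_municipality_table(
            births, population, persons, households, schema
        )
        return cls(a0, **kwargs)

    def fit(self) -> "StratificationResults":
        """Run preparation -> ensemble -> consensus and collect results."""
        prepared = _featprep.prepare(
            self.a0,
            outlier_k=self.outlier_k,
            variance_target=self.variance_target,
            scale=self.pca_scale,
        )
        mkm_result = _mkm.run_mkm(prepared.arn, self.ensemble, prepared.pmr)
        cons = _consensus.run_consensus(
            mkm_result,
            prepared.national_pmr,
            coi_threshold=self.coi_threshold,
            variance_target=self.corr_variance_target,
            params=self.dbscan,
        )
        return StratificationResults(
            model=self, prepared=prepared, mkm=mkm_result, consensus=cons
        )


@dataclass
class StratificationResults:
    """Fitted pipeline state: intermediates, diagnostics and reports."""

    model: PTBStratification
    prepared: _featprep.PreparedMatrix
    mkm: _mkm.MkMResult
    consensus: _consensus.ConsensusResult

    # -- headline quantities -------------------------------------------------
    @property
    def national_pmr(self) -> float:
        return self.prepared.national_pmr

    @property
    def n_models(self) -> int:
        return self.mkm.n_models

    @property
    def n_centroids(self) -> int:
        return self.mkm.n_centroids

    @property
    def n_coi(self) -> int:
        return int((self.consensus.stats["coi_flag"] != "none").sum())

    @property
    def final_clusters(self) -> list[int]:
        return self.consensus.final_clusters

    @property
    def municipalities(self) -> pd.DataFrame:
        return self.consensus.municipalities

    # -- evaluation layer ----------------------------------------------------
    def significance_matrix(
        self, alpha: float = 0.05, seed: int | None = None, **kwargs
    ) -> _report.SignificanceMatrix:
        return _report.pairwise_ttests(
            self.model.a0,
            self.consensus.municipalities,
            alpha=alpha,
            seed=self.model.seed if seed is None else seed,
            **kwargs,
        )

    def cluster_profiles(self, **kwargs) -> pd.DataFrame:
        return _report.cluster_profiles(
            self.model.a0, self.consensus.municipalities, **kwargs
        )

    def pmr_distributions(self) -> pd.DataFrame:
        return _report.pmr_distributions(
            self.consensus.stats,
            self.consensus.municipalities,
            self.consensus.coi_labels,
            self.prepared.pmr,
            self.national_pmr,
        )

    def segment_maps(self, segment_spec: dict[str, str], **kwargs):
        return _report.segment_maps(
            self.model.a0,
            self.consensus.municipalities,
            segment_spec,
            seed=kwargs.pop("seed", self.model.seed),
            **kwargs,
        )

    def coverage_curve(self) -> pd.DataFrame:
        return _mkm.coverage_curve(self.mkm, self.consensus.stats)

    # -- presentation --------------------------------------------------------
    def summary(self) -> str:
        """Human-readable run summary (counts per stage, final clusters)."""
        lines = [
            "Preterm-birth municipal stratification",
            "=" * 54,
            f"municipalities (input A0)      {len(self.model.a0):>8d}",
            f"PMR outliers removed           {len(self.prepared.removed_codes):>8d}",
            f"retained components (H)        {self.prepared.n_components:>8d}",
            f"national PMR                   {self.national_pmr:>12.3e}",
            f"ensemble models (N)            {self.n_models:>8d}",
            f"pooled centroids (L)           {self.n_centroids:>8d}",
            f"clusters of interest           {self.n_coi:>8d}",
            f"noise centroids                {self.consensus.n_noise:>8d}",
            f"final clusters                 {len(self.final_clusters):>8d}",
            "-" * 54,
            "final cluster   type   centroids   municipalities",
        ]
        counts = self.consensus.coi_labels.value_counts()
        dom = self.municipalities["dominant_cluster"]
        for lab in self.final_clusters:
            lines.append(
                f"{lab:>13d}   {self.consensus.cluster_types[lab]:<5s}"
                f"{int(counts.get(lab, 0)):>11d}   {int((dom == lab).sum()):>14d}"
            )
        n_high = int((self.municipalities['type'] == 'high').sum())
        n_low = int((self.municipalities['type'] == 'low').sum())
        n_unc = int((self.municipalities['type'] == 'unclassified').sum())
        lines += [
            "-" * 54,
            f"municipality types: high={n_high}  low={n_low}  unclassified={n_unc}",
        ]
        return "\n".join(lines)
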