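"""Evaluation layer: cluster contrasts, calibration and embedding maps.

Given the municipality table and the consensus mapping, this module
quantifies how distinct the final clusters are:

* pairwise Welch t-tests per SES variable between every pair of groups
  (final clusters plus the unclustered set ``N`` and the all-municipality
  set ``A``), summarised as the fraction of significantly different
  variables per pair — a cluster compared with itself uses a seeded random
  half-split, so its cell calibrates to the test level under the null;
* per-cluster profiles: mean, variance and percent difference against the
  national average for every variable;
* PMR distribution summaries per final cluster, at both the centroid and
  the municipality level;
* per-segment 2D t-SNE embeddings with an RBF-SVM boundary separating
  high- from low-typed municipalities (a visual diagnostic, not a claim).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "SignificanceMatrix",
    "SegmentMap",
    "pairwise_ttests",
    "cluster_profiles",
    "pmr_distributions",
    "segment_maps",
]


def _group_members(municipalities: pd.DataFrame) -> dict[str, pd.Index]:
    """Comparison sets: one per final cluster, N (unclassified), A (all)."""
    groups: dict[str, pd.Index] = {}
    dom = municipalities.set_index("municipality_code")["dominant_cluster"]
    for lab in sorted(c for c in dom.unique() if c >= 0):
        groups[str(int(lab))] = dom.index[dom == lab]
    groups["N"] = dom.index[dom < 0]
    groups["A"] = dom.index
    return groups


@dataclass
class SignificanceMatrix:
    """Fraction of significantly different variables per group pair."""

    matrix: pd.DataFrame    # groups x groups, fractions in [0, 1]
    pvalues: pd.DataFrame   # long: group_a, group_b, variable, pvalue
    alpha: float
    skipped: pd.DataFrame   # long: group_a, group_b, n_skipped


def _welch_fraction(
    xa: np.ndarray, xb: np.ndarray, alpha: float
) -> tuple[float, np.ndarray, int]:
    """Welch t-test per column; returns (fraction significant, p-values,
    number of skipped zero-variance columns)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.ttest_ind(xa, xb, axis=0, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    skipped = int(np.isnan(p).sum())
    valid = p[~np.isnan(p)]
    frac = float((valid < alpha).mean()) if valid.size else float("nan")
    return frac, p, skipped


def pairwise_ttests(
    a0: pd.DataFrame,
    municipalities: pd.DataFrame,
    *,
    alpha: float = 0.05,
    seed: int = 0,
    feature_cols: list[str] | None = None,
    bh_correct: bool = False,
    code_col: str = "municipality_code",
) -> SignificanceMatrix:
    """Welch two-sample t-tests per variable for every pair of groups.

    Cells hold the fraction of variables with p < ``alpha`` (significantly
    different).  The diagonal compares two disjoint seeded random halves of
    the same group.  Variables with zero variance in both groups yield an
    undefined test; they are skipped and tallied.  ``bh_correct`` applies a
    Benjamini-Hochberg adjustment within each pair before thresholding
    (off by default).
    """
    if feature_cols is None:
        feature_cols = [
            c
            for c in a0.columns
            if c not in (code_col, "PMR")
            and pd.api.types.is_numeric_dtype(a0[c])
        ]
    feats = a0.set_index(code_col)[feature_cols]
    groups = _group_members(municipalities)
    names = list(groups)
    rng = np.random.default_rng(seed)

    mat = pd.DataFrame(np.nan, index=names, columns=names)
    pvals_rows = []
    skipped_rows = []

    for ia, ga in enumerate(names):
        for gb in names[ia:]:
            if ga == gb:
                members = groups[ga]
                if len(members) < 4:
                    logger.warning(
                        "group %s too small (%d) for a half-split self test",
                        ga,
                        len(members),
                    )
                    continue
                perm = rng.permutation(len(members))
                half = len(members) // 2
                xa = feats.loc[members[perm[:half]]].to_numpy(float)
                xb = feats.loc[members[perm[half:]]].to_numpy(float)
            else:
                if len(groups[ga]) < 2 or len(groups[gb]) < 2:
                    logger.warning("pair (%s, %s) has a group with < 2 rows", ga, gb)
                    continue
                xa = feats.loc[groups[ga]].to_numpy(float)
                xb = feats.loc[groups[gb]].to_numpy(float)
            frac, p, n_skip = _welch_fraction(xa, xb, alpha)
            if bh_correct:
                valid = ~np.isnan(p)
                if valid.any():
                    adj = _benjamini_hochberg(p[valid])
                    frac = float((adj < alpha).mean())
                    p = p.copy()
                    p[valid] = adj
            mat.loc[ga, gb] = mat.loc[gb, ga] = frac
            skipped_rows.append((ga, gb, n_skip))
            pvals_rows.extend(
                (ga, gb, var, pv) for var, pv in zip(feature_cols, p)
            )

    pvalues = pd.DataFrame(
        pvals_rows, columns=["group_a", "group_b", "variable", "pvalue"]
    )
    skipped = pd.DataFrame(skipped_rows, columns=["group_a", "group_b", "n_skipped"])
    return SignificanceMatrix(matrix=mat, pvalues=pvalues, alpha=alpha, skipped=skipped)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    n = len(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        running = min(running, p[order[rank]] * n / (rank + 1))
        adj[order[rank]] = running
    return adj


def cluster_profiles(
    a0: pd.DataFrame,
    municipalities: pd.DataFrame,
    *,
    feature_cols: list[str] | None = None,
    code_col: str = "municipality_code",
) -> pd.DataFrame:
    """Per-cluster mean and variance of every variable plus the percent
    difference against the national (all-municipality) mean.

    percent difference = 100 * (cluster mean - national mean) / national
    mean; reported as missing where the national mean is zero.
    """
    if feature_cols is None:
        feature_cols = [
            c
            for c in a0.columns
            if c != code_col and pd.api.types.is_numeric_dtype(a0[c])
        ]
    feats = a0.set_index(code_col)[feature_cols]
    national = feats.mean()
    dom = municipalities.set_index("municipality_code")["dominant_cluster"]

    rows = []
    for lab in sorted(c for c in dom.unique() if c >= 0):
        members = feats.loc[dom.index[dom == lab]]
        mean = members.mean()
        var = members.var(ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * (mean - national) / national
        pct[national == 0] = np.nan
        for v in feature_cols:
            rows.append((int(lab), v, mean[v], var[v], pct[v]))
    return pd.DataFrame(
        rows, columns=["cluster", "variable", "mean", "variance", "pct_diff"]
    )


def pmr_distributions(
    stats: pd.DataFrame,
    municipalities: pd.DataFrame,
    coi_labels: pd.Series,
    pmr: pd.Series,
    national_pmr: float,
) -> pd.DataFrame:
    """Quartile summaries of PMR per final cluster, at two levels:
    ``centroid`` (mean PMRs of the member base clusters) and
    ``municipality`` (PMRs of the municipalities dominantly mapped there),
    with the national PMR as reference."""
    rows = []
    lab_frame = coi_labels.rename("final_label").reset_index()
    merged = lab_frame.merge(stats, on=["model_index", "cluster_index"], how="left")
    dom = municipalities.set_index("municipality_code")["dominant_cluster"]

    def _summary(values: np.ndarray, cluster: int, level: str):
        if len(values) == 0:
            return (cluster, level, 0, np.nan, np.nan, np.nan, np.nan, national_pmr)
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        return (cluster, level, len(values), float(np.mean(values)), q1, med, q3, national_pmr)

    for lab in sorted(l for l in merged["final_label"].unique() if l >= 0):
        cen = merged.loc[merged["final_label"] == lab, "mean_pmr"].to_numpy(float)
        rows.append(_summary(cen, int(lab), "centroid"))
        muni = pmr.loc[dom.index[dom == lab]].to_numpy(float)
        rows.append(_summary(muni, int(lab), "municipality"))
    return pd.DataFrame(
        rows,
        columns=["cluster", "level", "n", "mean", "q1", "median", "q3", "national_pmr"],
    )


@dataclass
class SegmentMap:
    """2D embedding of one SES segment with a high/low boundary accuracy."""

    segment: str
    embedding: pd.DataFrame  # municipality_code, x, y, type
    accuracy: float          # training accuracy of the RBF-SVM on the embedding


def segment_maps(
    a0: pd.DataFrame,
    municipalities: pd.DataFrame,
    segment_spec: dict[str, str],
    *,
    seed: int = 0,
    perplexity: float = 30.0,
    code_col: str = "municipality_code",
) -> list[SegmentMap]:
    """Per-segment t-SNE embeddings of the typed municipalities plus an
    RBF-SVM boundary separating high from low types.

    ``segment_spec`` maps each variable to exactly one segment (e.g.
    sanitation, employment, education...).  Segments with fewer than two
    variables are skipped with a warning.  Embeddings are seeded and hence
    reproducible; the classifier's training accuracy is a visual
    diagnostic of separability, not an inferential statistic.
    """
    from sklearn.manifold import TSNE
    from sklearn.svm import SVC

    typed = municipalities[municipalities["type"].isin(["high", "low"])]
    codes = typed["municipality_code"]
    feats = a0.set_index(code_col).loc[codes]
    y = typed.set_index("municipality_code").loc[codes, "type"]

    segments: dict[str, list[str]] = {}
    for var, seg in segment_spec.items():
        segments.setdefault(seg, []).append(var)

    out: list[SegmentMap] = []
    for seg, cols in sorted(segments.items()):
        missing = [c for c in cols if c not in feats.columns]
        if missing:
            raise KeyError(f"segment {seg!r} references unknown variables {missing}")
        if len(cols) < 2:
            logger.warning("segment %r has < 2 variables; skipped", seg)
            continue
        X = feats[cols].to_numpy(float)
        emb = TSNE(
            n_components=2,
            random_state=seed,
            init="pca",
            perplexity=min(perplexity, max(2.0, len(X) / 4)),
        ).fit_transform(X)
        svm = SVC(kernel="rbf", random_state=seed).fit(emb, y)
        acc = float(svm.score(emb, y))
        frame = pd.DataFrame(
            {
                "municipality_code": codes.to_numpy(),
                "x": emb[:, 0],
                "y": emb[:, 1],
                "type": y.to_numpy(),
            }
        )
        out.append(SegmentMap(segment=seg, embedding=frame, accuracy=acc))
    return out
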