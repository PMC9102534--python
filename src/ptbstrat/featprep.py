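"""Feature preparation: outlier removal, PCA, and the normalisation cascade.

Order of operations is fixed: municipalities whose PMR lies more than
``k`` standard deviations from the national mean are removed (A0 -> A1);
the PMR column is held out; the SES features are reduced by PCA to the
smallest number of components retaining the target share of variance
(A1 -> AR); and AR is normalised by the three-step cascade — per-column
Yeo-Johnson power transform, per-row L2 normalisation, per-column min-max
to [0, 1] — producing the clustering input ARN.

The national PMR used downstream by the cluster-of-interest rule is the
mean PMR over the retained (post-outlier-removal) municipalities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import PowerTransformer, minmax_scale, normalize

__all__ = [
    "PCAModel",
    "PreparedMatrix",
    "remove_pmr_outliers",
    "pca_reduce",
    "normalize_cascade",
    "prepare",
]


@dataclass
class PCAModel:
    """A fitted, sign-fixed principal-component rotation.

    The sign of each component is fixed so that its largest-magnitude
    loading is positive, making the rotation reproducible across runs and
    linear-algebra backends.
    """

    components: np.ndarray  # (n_components, n_features)
    mean: np.ndarray
    explained_variance_ratio: np.ndarray
    n_components: int
    scale: np.ndarray | None = None  # per-feature std if scaling was on

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scale is not None:
            X = X / self.scale
        return (X - self.mean) @ self.components.T


def remove_pmr_outliers(
    a0: pd.DataFrame, k: float = 3.0, *, pmr_col: str = "PMR"
) -> tuple[pd.DataFrame, list]:
    """Drop rows whose PMR deviates from the mean by more than ``k`` sample
    standard deviations (A0 -> A1).

    Mean and standard deviation are computed once on the full input (no
    iteration); with ``sd == 0`` or ``k == inf`` nothing is removed.
    Returns the filtered table and the removed municipality codes.
    """
    if len(a0) < 3:
        raise ValueError("outlier removal needs at least 3 rows")
    pmr = a0[pmr_col].to_numpy(dtype=float)
    mean, sd = pmr.mean(), pmr.std(ddof=1)
    if sd == 0 or math.isinf(k):
        return a0.copy(), []
    mask = np.abs(pmr - mean) <= k * sd
    removed = a0.loc[~mask, a0.columns[0]].tolist()
    return a0.loc[mask].copy(), removed


def _fit_pca(X: np.ndarray, variance_target: float, scale: bool) -> PCAModel:
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    sd = X.std(axis=0, ddof=1)
    if not np.any(sd > 0):
        raise ValueError("PCA input is constant: no variance to retain")
    scale_vec = None
    if scale:
        scale_vec = np.where(sd > 0, sd, 1.0)
        X = X / scale_vec
    pca = PCA(n_components=None, svd_solver="full").fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, len(cum))
    comps = pca.components_[:k].copy()
    # sign convention: largest-magnitude loading of each component positive
    for i in range(k):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PCAModel(
        components=comps,
        mean=pca.mean_,
        explained_variance_ratio=pca.explained_variance_ratio_[:k].copy(),
        n_components=k,
        scale=scale_vec,
    )


def pca_reduce(
    X: pd.DataFrame | np.ndarray,
    variance_target: float = 0.95,
    *,
    scale: bool = False,
) -> tuple[pd.DataFrame, PCAModel]:
    """Project onto the smallest number of principal components whose
    cumulative explained-variance ratio reaches ``variance_target``.

    Columns are centred (and optionally scaled to unit variance) before
    rotation; output columns are ordered by decreasing variance and named
    ``pc1..pcK``.
    """
    index = X.index if isinstance(X, pd.DataFrame) else None
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    model = _fit_pca(arr, variance_target, scale=scale)
    scores = model.transform(arr)
    cols = [f"pc{i + 1}" for i in range(model.n_components)]
    return pd.DataFrame(scores, index=index, columns=cols), model


def normalize_cascade(
    X: pd.DataFrame | np.ndarray,
    *,
    return_steps: bool = False,
):
    """The three-step normalisation: Yeo-Johnson per column (lambda fitted
    by maximum likelihood), L2 normalisation per row (zero rows stay zero),
    min-max per column to [0, 1] (constant columns map to 0).

    Returns the normalised matrix and the fitted per-column lambdas; with
    ``return_steps`` a dict of the intermediate matrices after each step is
    appended (keys ``yeo_johnson``, ``l2``, ``minmax``).
    """
    index = cols = None
    if isinstance(X, pd.DataFrame):
        index, cols = X.index, X.columns
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    pt = PowerTransformer(method="yeo-johnson", standardize=False)
    step1 = pt.fit_transform(X)
    step2 = normalize(step1, norm="l2")  # zero rows are left as zero
    step3 = minmax_scale(step2, feature_range=(0.0, 1.0))
    lambdas = np.asarray(pt.lambdas_, dtype=float)
    out = (
        pd.DataFrame(step3, index=index, columns=cols)
        if index is not None
        else step3
    )
    if return_steps:
        return out, lambdas, {"yeo_johnson": step1, "l2": step2, "minmax": step3}
    return out, lambdas


@dataclass
class PreparedMatrix:
    """Clustering-ready features plus everything needed to replay the fit."""

    arn: pd.DataFrame          # municipalities x H, values in [0, 1]
    pmr: pd.Series             # held-out PMR per retained municipality
    pca: PCAModel
    yeojohnson_lambdas: np.ndarray
    national_pmr: float        # mean PMR over retained municipalities
    removed_codes: list

    @property
    def n_components(self) -> int:
        return self.pca.n_components


def prepare(
    a0: pd.DataFrame,
    *,
    outlier_k: float = 3.0,
    variance_target: float = 0.95,
    scale: bool = False,
    code_col: str = "municipality_code",
    pmr_col: str = "PMR",
) -> PreparedMatrix:
    """Run the full preparation chain A0 -> A1 -> AR -> ARN."""
    a1, removed = remove_pmr_outliers(a0, outlier_k, pmr_col=pmr_col)
    pmr = pd.Series(
        a1[pmr_col].to_numpy(dtype=float),
        index=pd.Index(a1[code_col], name=code_col),
        name=pmr_col,
    )
    features = a1.drop(columns=[code_col, pmr_col]).set_index(pmr.index)
    ar, pca_model = pca_reduce(features, variance_target, scale=scale)
    arn, lambdas = normalize_cascade(ar)
    return PreparedMatrix(
        arn=arn,
        pmr=pmr,
        pca=pca_model,
        yeojohnson_lambdas=lambdas,
        national_pmr=float(pmr.mean()),
        removed_codes=removed,
    )
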