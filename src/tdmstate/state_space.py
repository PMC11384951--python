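"""Mahalanobis-distance state-space trajectory analysis.

The "multidimensional severity" view: every patient-day is a point in the
encoded, scaled feature space; the group of states with severity total 1 —
the healthiest well-sampled stratum of the cohort — defines a reference
distribution with mean mu and covariance Sigma.  The distance of state A to
the reference is

    D(A, R) = sqrt((A - mu) Sigma_reg^{-1} (A - mu)^T)

with Sigma_reg = Sigma + lambda * I to keep the inverse defined when the
reference members span fewer dimensions than there are features.  Daily
per-arm aggregates (cumulative sum, per-patient mean) are normalized by the
mean pairwise distance among reference members, so "distance 1" means "as
far apart as reference patients are from each other".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.utils.validation import check_is_fitted

DEFAULT_REFERENCE_SOFA = 1

#: lambda = REG_SCALE * trace(Sigma) / dim by default.
REG_SCALE = 1e-6


class MahalanobisReference(BaseEstimator, TransformerMixin):
    """Reference distribution and Mahalanobis distances to it.

    Fit on the member matrix (reference state vectors in encoded space).
    ``transform`` returns each row's distance to the reference, raw and
    normalized by the mean pairwise member distance ``norm_constant_``.

    Parameters
    ----------
    regularization : float or "auto"
        Ridge added to the member covariance before inversion.  "auto" uses
        ``1e-6 * trace(Sigma) / dim``; 0 requires a nonsingular covariance.
    """

    def __init__(self, regularization: float | str = "auto"):
        self.regularization = regularization

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D member matrix with >= 2 members")
        if np.unique(X, axis=0).shape[0] < 2:
            raise ValueError("need >= 2 distinct reference members")
        if not np.all(np.isfinite(X)):
            raise ValueError("reference members contain non-finite values")
        self.members_ = X
        self.mean_ = X.mean(axis=0)
        self.covariance_ = np.cov(X, rowvar=False, ddof=1)
        if self.covariance_.ndim == 0:  # single feature
            self.covariance_ = self.covariance_.reshape(1, 1)
        if not np.all(np.isfinite(self.covariance_)):
            raise ValueError("non-finite covariance")
        dim = X.shape[1]
        if self.regularization == "auto":
            lam = REG_SCALE * float(np.trace(self.covariance_)) / dim
        else:
            lam = float(self.regularization)
        self.regularization_ = lam
        sigma_reg = self.covariance_ + lam * np.eye(dim)
        # Distances via the Cholesky factor of Sigma_reg:
        # D(v)^2 = || R^{-1} v ||^2 with Sigma_reg = R R^T (lower R).
        self._chol_ = np.linalg.cholesky(sigma_reg)
        self.precision_ = cho_solve(cho_factor(sigma_reg, lower=True), np.eye(dim))
        self.precision_ = (self.precision_ + self.precision_.T) / 2.0
        pair = self._pairwise_members()
        c = float(pair.mean())
        if c <= 0.0:
            raise ValueError("degenerate reference: zero mean pairwise distance")
        self.norm_constant_ = c
        return self

    def _whiten(self, V: np.ndarray) -> np.ndarray:
        return solve_triangular(self._chol_, V.T, lower=True).T

    def _pairwise_members(self) -> np.ndarray:
        z = self._whiten(self.members_ - self.mean_)
        return pdist(z)

    def mahalanobis(self, A) -> np.ndarray:
        """Distance of each row of ``A`` to the reference distribution."""
        check_is_fitted(self, "mean_")
        A = np.atleast_2d(np.asarray(A, dtype=float))
        if A.shape[1] != self.mean_.shape[0]:
            raise ValueError(
                f"dimension mismatch: {A.shape[1]} vs {self.mean_.shape[0]}"
            )
        z = self._whiten(A - self.mean_)
        return np.sqrt((z ** 2).sum(axis=1))

    def pairwise(self, x, y) -> float:
        """Mahalanobis distance between two points under the reference metric."""
        check_is_fitted(self, "mean_")
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape or x.shape[0] != self.mean_.shape[0]:
            raise ValueError("dimension mismatch")
        z = self._whiten((x - y)[None, :])
        return float(np.sqrt((z ** 2).sum()))

    def transform(self, X) -> np.ndarray:
        """Column-stacked raw and normalized distances, one row per state."""
        d = self.mahalanobis(X)
        return np.column_stack([d, d / self.norm_constant_])


def build_reference(
    encoded: pd.DataFrame,
    sofa_totals,
    reference_sofa: int = DEFAULT_REFERENCE_SOFA,
    regularization: float | str = "auto",
) -> MahalanobisReference:
    """Fit the reference distribution from states at the reference severity.

    Errors if fewer than two states carry the requested severity total —
    the situation that forces a fallback to the next-best stratum.
    """
    totals = np.asarray(sofa_totals)
    mask = totals == reference_sofa
    if mask.sum() < 2:
        raise ValueError(
            f"fewer than 2 states with severity total {reference_sofa}; "
            "choose a better-populated reference stratum"
        )
    members = encoded.loc[np.asarray(mask)].to_numpy(dtype=float)
    return MahalanobisReference(regularization=regularization).fit(members)


def daily_trajectory(
    encoded: pd.DataFrame,
    meta: pd.DataFrame,
    reference: MahalanobisReference,
) -> pd.DataFrame:
    """Per-arm, per-day distance aggregates against the reference.

    Returns one row per (arm, day) on the full arm x day grid with columns
    ``n_patients`` (patients present), ``cumsum`` (summed distances),
    ``mean`` and their normalized variants; days with no patients carry
    explicit nulls.  The normalized per-patient mean is the headline
    trajectory; the cumulative sum is also reported because it conflates
    recovery with attrition when arm sizes shrink.
    """
    if len(encoded) != len(meta):
        raise ValueError("encoded table and metadata must align row-wise")
    d = reference.mahalanobis(encoded.to_numpy(dtype=float))
    table = meta[["patient_id", "arm", "day"]].copy()
    table["distance"] = d
    table["normalized_distance"] = d / reference.norm_constant_
    grid = pd.MultiIndex.from_product(
        [sorted(table["arm"].unique()), range(1, int(table["day"].max()) + 1)],
        names=["arm", "day"],
    )
    agg = table.groupby(["arm", "day"]).agg(
        n_patients=("patient_id", "nunique"),
        cumsum=("distance", "sum"),
        mean=("distance", "mean"),
    )
    agg = agg.reindex(grid)
    agg["n_patients"] = agg["n_patients"].fillna(0).astype(int)
    agg.loc[agg["n_patients"] == 0, ["cumsum", "mean"]] = np.nan
    agg["normalized_cumsum"] = agg["cumsum"] / reference.norm_constant_
    agg["normalized_mean"] = agg["mean"] / reference.norm_constant_
    out = agg.reset_index()
    out.attrs["per_patient"] = table
    return out


def normalize(metrics: pd.DataFrame, reference: MahalanobisReference) -> pd.DataFrame:
    """Divide the raw distance aggregates by the normalization constant."""
    c = reference.norm_constant_
    if not c > 0:
        raise ValueError("normalization constant must be positive")
    out = metrics.copy()
    for col in ("cumsum", "mean"):
        if col in out.columns:
            out[f"normalized_{col}"] = out[col] / c
    return out


def day1_similarity(
    encoded_day1: pd.DataFrame,
    arms,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Mean pairwise Euclidean distance per patient and an arm comparison.

    Each day-1 patient state gets the mean Euclidean distance to all other
    patients; arms are compared by the absolute difference of arm means of
    those per-patient means, with a label-permutation null.
    """
    X = encoded_day1.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 patients on day 1")
    arms = np.asarray(arms)
    D = squareform(pdist(X))
    per_patient = D.sum(axis=1) / (X.shape[0] - 1)
    table = pd.DataFrame(
        {"arm": arms, "mean_pairwise_distance": per_patient},
        index=encoded_day1.index,
    )
    labels = sorted(pd.unique(arms))
    if len(labels) == 2:
        a, b = labels
        observed = abs(
            per_patient[arms == a].mean() - per_patient[arms == b].mean()
        )
        rng = np.random.default_rng(seed)
        count = 0
        n_a = int((arms == a).sum())
        for _ in range(n_permutations):
            perm = rng.permutation(per_patient)
            stat = abs(perm[:n_a].mean() - perm[n_a:].mean())
            if stat >= observed - 1e-12:
                count += 1
        p_value = (count + 1) / (n_permutations + 1)
        comparison = {
            "arm_means": {
                a: float(per_patient[arms == a].mean()),
                b: float(per_patient[arms == b].mean()),
            },
            "observed_difference": float(observed),
            "p_value": float(p_value),
            "n_permutations": n_permutations,
        }
    else:
        comparison = {"arm_means": {}, "p_value": np.nan}
    return table, comparison


def embed_2d(
    encoded: pd.DataFrame, method: str = "linear_pca", seed: int = 0
) -> np.ndarray:
    """2-D embedding for visual inspection of day-1 exchangeability.

    The PCA path is deterministic (each component's largest-magnitude
    loading is made positive); the t-SNE path is a seeded delegation to the
    standard implementation.
    """
    X = np.asarray(encoded, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 states to embed")
    if method == "linear_pca":
        pca = PCA(n_components=2, svd_solver="full")
        coords = pca.fit_transform(X)
        for j, comp in enumerate(pca.components_):
            if comp[np.argmax(np.abs(comp))] < 0:
                coords[:, j] *= -1
        return coords
    if method == "tsne":
        perplexity = min(30.0, (X.shape[0] - 1) / 3)
        return TSNE(
            n_components=2, random_state=seed, perplexity=perplexity, init="pca"
        ).fit_transform(X)
    raise ValueError(f"unknown embedding method {method!r}")
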