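"""Strategic-profile -> coordination-ability model.

The three per-player strategy rates (closeness, equality, accession) are
z-scored, the covariance of the standardized data is eigendecomposed, and
the top two principal components define compressed features S1 and S2.
Individual coordination ability is then regressed on (1, S1, S2) by ordinary
least squares, and out-of-sample predictions are scored by the per-player
relative absolute error and its quartiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .stats import SR_COLUMNS


def _as_profile_array(profiles) -> np.ndarray:
    """Coerce profiles (DataFrame with SR columns, or array-like) to (n, 3)."""
    if isinstance(profiles, pd.DataFrame):
        arr = profiles[SR_COLUMNS].to_numpy(dtype=float)
    else:
        arr = np.atleast_2d(np.asarray(profiles, dtype=float))
    if arr.shape[1] != 3:
        raise ValueError(f"expected 3 strategy-rate columns, got {arr.shape[1]}")
    if np.isnan(arr).any():
        raise ValueError(
            "incomplete strategic profile(s); drop players with undefined "
            "strategy rates before fitting/projecting"
        )
    return arr


@dataclass(frozen=True)
class PCAModel:
    """Standardization plus orthonormal basis over the three SR dimensions.

    ``components`` rows are U1, U2, U3 sorted by descending eigenvalue; each
    row's largest-magnitude loading is made positive so the basis is
    reproducible across linear-algebra backends.
    """

    center: np.ndarray
    scale: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray

    def standardize(self, profiles) -> np.ndarray:
        arr = _as_profile_array(profiles)
        return (arr - self.center) / self.scale

    def project(self, profiles) -> np.ndarray:
        """All three principal scores (s1, s2, s3) per profile."""
        return self.standardize(profiles) @ self.components.T


def fit_pca(profiles) -> PCAModel:
    """Z-score each SR dimension and eigendecompose the covariance.

    Raises on zero-variance dimensions (the z-score is undefined there).
    """
    arr = _as_profile_array(profiles)
    if arr.shape[0] < 3:
        raise ValueError("PCA requires at least 3 complete profiles")
    center = arr.mean(axis=0)
    scale = arr.std(axis=0, ddof=1)
    for dim, mu, s in zip(SR_COLUMNS, center, scale):
        # tolerance: accumulated rounding in a constant column is ~eps*|mean|
        if s <= 1e-12 * max(1.0, abs(mu)):
            raise ValueError(f"zero variance in dimension {dim!r}")
    z = (arr - center) / scale
    cov = np.cov(z, rowvar=False, ddof=1)
    eigenvalues, vectors = np.linalg.eigh(cov)  # ascending
    order = np.argsort(np.abs(eigenvalues))[::-1]
    eigenvalues = eigenvalues[order]
    components = vectors[:, order].T
    for i in range(3):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
    return PCAModel(
        center=center,
        scale=scale,
        components=components,
        eigenvalues=np.clip(eigenvalues, 0.0, None),
    )


def retained_variance(profiles, pca: PCAModel, m: int) -> float:
    """Percent variance retained when reconstructing from the top-m components.

    retained = 1 - sum ||x - x_approx||^2 / sum ||x||^2, on the standardized
    vectors; with all three components this is exactly 100%.
    """
    if not 1 <= m <= 3:
        raise ValueError("m must be 1, 2, or 3")
    z = pca.standardize(profiles)
    basis = pca.components[:m]
    approx = z @ basis.T @ basis
    denom = float(np.sum(z**2))
    if denom == 0:
        return 100.0
    return float((1.0 - np.sum((z - approx) ** 2) / denom) * 100.0)


@dataclass(frozen=True)
class CompressedProfile:
    s1: float
    s2: float


def compress(profile, pca: PCAModel):
    """Project profile(s) onto (U1, U2).

    A single profile (1-D triple) returns a :class:`CompressedProfile`;
    multiple profiles return an (n, 2) array.
    """
    single = not isinstance(profile, pd.DataFrame) and np.ndim(profile) == 1
    scores = pca.project(profile)[:, :2]
    if single:
        return CompressedProfile(float(scores[0, 0]), float(scores[0, 1]))
    return scores


@dataclass(frozen=True)
class AbilityModel:
    """OLS fit of iCA on the compressed strategic profile (1, S1, S2)."""

    intercept: float
    coef_s1: float
    coef_s2: float
    r_squared: float
    f_stat: float
    f_pvalue: float
    var_error: float

    def predict(self, s: np.ndarray) -> np.ndarray:
        s = np.atleast_2d(np.asarray(s, dtype=float))
        return self.intercept + self.coef_s1 * s[:, 0] + self.coef_s2 * s[:, 1]


def fit_ability_model(compressed: np.ndarray, scores: Sequence[float]) -> AbilityModel:
    """Ordinary least squares of ability scores on (1, S1, S2)."""
    s = np.atleast_2d(np.asarray(compressed, dtype=float))
    y = np.asarray(scores, dtype=float)
    if s.shape[0] != y.size:
        raise ValueError("compressed profiles and scores differ in length")
    if s.shape[0] < 4:
        raise ValueError("need at least 4 paired observations")
    design = sm.add_constant(s[:, :2])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("collinear predictors: S1/S2 design is rank-deficient")
    fit = sm.OLS(y, design).fit()
    return AbilityModel(
        intercept=float(fit.params[0]),
        coef_s1=float(fit.params[1]),
        coef_s2=float(fit.params[2]),
        r_squared=float(fit.rsquared),
        f_stat=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        var_error=float(fit.mse_resid),
    )


def predict_ica(profiles, pca: PCAModel, model: AbilityModel) -> np.ndarray:
    """Compress profile(s) and apply the linear ability model."""
    s = pca.project(profiles)[:, :2]
    return model.predict(s)


@dataclass(frozen=True)
class ValidationReport:
    """Per-player relative absolute prediction error (%), with quartiles."""

    errors: np.ndarray
    p25: float
    p50: float
    p75: float
    n_excluded: int

    def as_dict(self) -> dict:
        return {
            "n": int(self.errors.size),
            "n_excluded": self.n_excluded,
            "p25": self.p25,
            "p50": self.p50,
            "p75": self.p75,
        }


def validate(predictions: Sequence[float], real_scores: Sequence[float]) -> ValidationReport:
    """Relative absolute error (%) of predicted vs. observed ability.

    error_i = |real_i - predicted_i| / real_i * 100.  Players with a zero
    observed score are excluded (the relative error is undefined) with a
    warning.  Percentiles use linear interpolation.
    """
    pred = np.asarray(predictions, dtype=float)
    real = np.asarray(real_scores, dtype=float)
    if pred.size != real.size:
        raise ValueError("predictions and real scores differ in length")
    keep = real > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        warnings.warn(
            f"excluding {n_excluded} player(s) with zero observed score",
            stacklevel=2,
        )
    errors = np.abs(real[keep] - pred[keep]) / real[keep] * 100.0
    if errors.size == 0:
        raise ValueError("no players with positive observed scores")
    p25, p50, p75 = np.percentile(errors, [25, 50, 75])
    return ValidationReport(
        errors=errors, p25=float(p25), p50=float(p50), p75=float(p75),
        n_excluded=n_excluded,
    )
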