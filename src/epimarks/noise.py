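"""Measurement-noise-corrected ("maximal") variance explained.

Observed per-gene phenotypes and covariates are averages over N individuals
and therefore carry measurement noise; ordinary R² is attenuated by that
noise on both sides of the regression.  Under an errors-in-variables model —
observed value = latent value + independent Gaussian noise, independent
across genes — the expected Gram matrix and total sum of squares are biased
upward by G times the noise variances, so the latent ("maximal") R² can be
approximated by

    R2_max = y'X (X'X - G D)^{-1} X'y  /  (y'y - G s2_y)

with X, y the observed mean-centered matrices, D the diagonal matrix of
per-covariate noise variances and s2_y the phenotype noise variance.  The
noise variances are estimated from the per-individual replicates as

    s2_hat = (1 / (N^2 G)) sum_i sum_g (v_ig - vbar_g)^2 .

Note this replicate estimator carries a factor (N-1)/N relative to the
noise variance of the mean; it is implemented exactly as displayed and the
small bias (order 1/N^2 of the per-individual noise) is documented rather
than adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

PD_TOLERANCE = 1e-10


@dataclass
class NoiseEstimates:
    """Replicate-based noise variances: phenotype scalar and covariate diagonal."""

    sigma_y2: float
    d: np.ndarray  # per-covariate noise variances (diagonal of D)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.sigma_y2 < 0 or np.any(self.d < 0):
            raise ValueError("noise variances must be non-negative")


@dataclass
class MaximalR2Input:
    """Observed mean-centered matrices plus the per-individual replicates."""

    y_obs: np.ndarray  # G
    x_obs: np.ndarray  # G x p
    per_individual_y: np.ndarray | None = None  # N x G
    per_individual_x: np.ndarray | None = None  # N x G x p

    def __post_init__(self) -> None:
        self.y_obs = np.asarray(self.y_obs, dtype=float)
        self.x_obs = np.asarray(self.x_obs, dtype=float)
        if self.x_obs.shape[0] != self.y_obs.shape[0]:
            raise ValueError("y_obs and x_obs must agree on gene count")
        g = self.y_obs.shape[0]
        if abs(self.y_obs.mean()) > 1e-6 * max(1.0, np.abs(self.y_obs).max()):
            raise ValueError("y_obs must be mean centered")
        col_means = self.x_obs.mean(axis=0)
        if np.any(np.abs(col_means) > 1e-6 * np.maximum(1.0, np.abs(self.x_obs).max(axis=0))):
            raise ValueError("x_obs columns must be mean centered")
        if self.per_individual_y is not None and self.per_individual_y.shape[1] != g:
            raise ValueError("per-individual y has inconsistent gene count")

    @classmethod
    def from_replicates(
        cls, per_individual_y: np.ndarray, per_individual_x: np.ndarray
    ) -> "MaximalR2Input":
        """Average replicates and mean-center the results."""
        per_individual_y = np.asarray(per_individual_y, dtype=float)
        per_individual_x = np.asarray(per_individual_x, dtype=float)
        y = per_individual_y.mean(axis=0)
        x = per_individual_x.mean(axis=0)
        return cls(
            y_obs=y - y.mean(),
            x_obs=x - x.mean(axis=0),
            per_individual_y=per_individual_y,
            per_individual_x=per_individual_x,
        )


def estimate_noise_variances(
    per_individual_y: np.ndarray, per_individual_x: np.ndarray
) -> NoiseEstimates:
    """Replicate-based noise-variance estimators.

    sigma_y2 = (1/(N^2 G)) sum_i sum_g (y_ig - ybar_g)^2, and analogously
    per covariate.  Requires N >= 2 replicates.
    """
    y = np.asarray(per_individual_y, dtype=float)
    x = np.asarray(per_individual_x, dtype=float)
    n, g = y.shape
    if n < 2:
        raise ValueError("noise is not estimable from a single replicate (N=1)")
    sigma_y2 = float(((y - y.mean(axis=0)) ** 2).sum() / (n * n * g))
    d = ((x - x.mean(axis=0)) ** 2).sum(axis=(0, 1)) / (n * n * g)
    return NoiseEstimates(sigma_y2=sigma_y2, d=d)


def maximal_r2(
    inp: MaximalR2Input, noise: NoiseEstimates
) -> tuple[float, float]:
    """Corrected and naive R² of the observed regression.

    Returns ``(corrected, naive)``.  The corrected value is the displayed
    errors-in-variables ratio; the naive value is the ordinary OLS R² of
    y_obs on x_obs.  Neither is clipped; the corrected estimator can exceed
    1 under sampling noise.  Raises when the corrected Gram matrix is not
    positive definite or the corrected denominator is non-positive (noise
    estimates too large for the data).
    """
    y = inp.y_obs
    x = inp.x_obs
    g = len(y)
    gram = x.T @ x
    xty = x.T @ y
    yty = float(y @ y)

    # naive OLS R2
    beta = linalg.solve(gram, xty, assume_a="pos")
    naive = float(xty @ beta / yty)

    gram_c = gram - g * np.diag(noise.d)
    eigmin = float(np.linalg.eigvalsh(gram_c).min())
    if eigmin <= PD_TOLERANCE:
        raise ValueError(
            "corrected Gram matrix X'X - G*D is not positive definite "
            f"(min eigenvalue {eigmin:.3g}); noise estimates too large for the data"
        )
    denom = yty - g * noise.sigma_y2
    if denom <= 0:
        raise ValueError(
            "corrected total sum of squares y'y - G*sigma_y2 is non-positive; "
            "noise estimates too large for the data"
        )
    beta_c = linalg.solve(gram_c, xty, assume_a="pos")
    corrected = float(xty @ beta_c / denom)
    return corrected, naive
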