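"""Median odds ratio (MOR) statistics for cluster-level heterogeneity.

The MOR translates a cluster-level variance on the log-odds scale into an
odds ratio: it is the median of the odds ratio between the higher- and
lower-risk member of a randomly drawn pair of clusters,

    MOR = exp( sqrt(2 * sigma2) * Phi^{-1}(0.75) ),

where ``sigma2`` is the between-cluster variance of the random effects and
``Phi^{-1}`` the standard normal quantile function.  It equals 1 when there
is no between-cluster variance and, unlike the intraclass correlation for
binary outcomes, does not depend on the outcome prevalence.

For a random-coefficient model with ward effects ``u0 + u1 * z`` (``z`` a
binary covariate), the effective ward variance differs by stratum of ``z``:
``sigma2_00`` when ``z = 0`` and ``sigma2_00 + 2*sigma_01 + sigma2_11`` when
``z = 1``; each stratum gets its own MOR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "MORResult",
    "mor_point",
    "mor_to_variance",
    "mor_interval",
    "stratum_variance",
    "stratified_mor",
]

# Phi^{-1}(0.75), the 75th percentile of the standard normal distribution.
_Z75 = 0.6744897501960817


@dataclass(frozen=True)
class MORResult:
    """A stratum label with an MOR point estimate and credibility interval.

    The point estimate is computed from the posterior mean (or median) of
    the variance while the bounds come from variance percentiles, so
    ``lower <= mor <= upper`` is not guaranteed; ``1 <= lower <= upper`` is.
    """

    stratum: str
    mor: float
    lower: float
    upper: float


def mor_point(ward_variance: float) -> float:
    """MOR for a given between-cluster variance on the log-odds scale.

    Strictly increasing in the variance and exactly 1 at zero variance.
    """
    v = float(ward_variance)
    if not np.isfinite(v) or v < 0:
        raise ValueError(f"cluster variance must be finite and >= 0, got {ward_variance!r}")
    return float(np.exp(np.sqrt(2.0 * v) * _Z75))


def mor_to_variance(mor: float) -> float:
    """Inverse of :func:`mor_point`: the variance implied by a target MOR.

    Useful for constructing simulations whose cluster variance corresponds
    to a published MOR value.
    """
    m = float(mor)
    if m < 1:
        raise ValueError(f"an MOR is >= 1 by construction, got {mor!r}")
    return (np.log(m) / _Z75) ** 2 / 2.0


def mor_interval(variance_draws: Sequence[float]) -> tuple[float, float]:
    """Credibility interval for the MOR from posterior variance draws.

    Applies the MOR formula to the 2.5th and 97.5th percentiles of the
    posterior draws of the cluster variance (monotonicity of the formula
    makes the order of percentile-taking and transformation irrelevant).
    """
    draws = np.asarray(variance_draws, dtype=float)
    if draws.size < 100:
        raise ValueError(f"need at least 100 variance draws, got {draws.size}")
    if np.any(draws < 0) or not np.all(np.isfinite(draws)):
        raise ValueError("variance draws must be finite and non-negative")
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return mor_point(lo), mor_point(hi)


def stratum_variance(ward_cov, slope_value: int) -> float:
    """Effective ward variance in one stratum of the random-slope covariate.

    Parameters
    ----------
    ward_cov
        Triplet ``(sigma2_00, sigma_01, sigma2_11)`` — intercept variance,
        intercept-slope covariance and slope variance of the ward effects.
    slope_value
        0 or 1, the value of the binary random-slope covariate.

    Returns
    -------
    ``sigma2_00`` for the reference stratum, and
    ``var(u0 + u1) = sigma2_00 + 2*sigma_01 + sigma2_11`` for the other.
    """
    s00, s01, s11 = (float(x) for x in ward_cov)
    if s00 < 0 or s11 < 0 or s01 * s01 > s00 * s11 + 1e-12:
        raise ValueError(f"ward covariance {ward_cov!r} is not positive semidefinite")
    if slope_value not in (0, 1):
        raise ValueError(f"slope_value must be 0 or 1, got {slope_value!r}")
    if slope_value == 0:
        return s00
    return s00 + 2.0 * s01 + s11


def stratified_mor(draws, point: str = "mean") -> list[MORResult]:
    """Stratum-specific MORs from the posterior draws of a fitted model.

    For a random-coefficient fit, the effective ward variance is combined
    draw-wise per stratum; the point MOR uses the posterior mean (default)
    or median of those variances, the interval their 2.5/97.5 percentiles.
    For a fit without a random slope a single "overall" MOR is returned.

    Parameters
    ----------
    draws
        A :class:`~ssiml.hierarchical_model.PosteriorDraws` (anything with a
        ``ward_cov`` array of shape (n, 1) or (n, 3) works).
    point
        "mean" or "median" — the posterior summary used for the point MOR.
    """
    if point not in ("mean", "median"):
        raise ValueError(f"point must be 'mean' or 'median', got {point!r}")
    reduce = np.mean if point == "mean" else np.median

    wc = np.asarray(draws.ward_cov, dtype=float)
    if wc.ndim == 1:
        wc = wc[:, None]

    def _one(stratum: str, var_draws: np.ndarray) -> MORResult:
        lo, hi = mor_interval(var_draws)
        return MORResult(stratum, mor_point(reduce(var_draws)), lo, hi)

    if wc.shape[1] == 1:
        return [_one("overall", wc[:, 0])]

    s00, s01, s11 = wc[:, 0], wc[:, 1], wc[:, 2]
    return [
        _one("followup_lt15", s00),
        _one("followup_ge15", s00 + 2.0 * s01 + s11),
    ]
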