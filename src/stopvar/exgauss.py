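"""Ex-Gaussian (exponentially modified Gaussian) distribution utilities.

The ex-Gaussian is the convolution of a Normal(mu, sigma) with an
Exponential of mean tau.  It is the standard descriptive model for
response-time distributions: mu and sigma capture the Gaussian body of
the distribution and tau the exponential right tail, so that the mean is
mu + tau and the variance sigma**2 + tau**2.

Density and log-density are computed with the scaled complementary error
function (erfcx) so they stay finite in log space for any finite
argument; cdf/sf/ppf and random variates delegate to
``scipy.stats.exponnorm`` (parameterised as K = tau/sigma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .exceptions import ParameterError

_SQRT2 = np.sqrt(2.0)
_LOG2 = np.log(2.0)


@dataclass(frozen=True)
class ExGaussParams:
    """Parameters of an ex-Gaussian distribution, in milliseconds."""

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu) and np.isfinite(self.sigma) and np.isfinite(self.tau)):
            raise ParameterError("ex-Gaussian parameters must be finite")
        if self.sigma <= 0 or self.tau <= 0:
            raise ParameterError(
                f"sigma and tau must be strictly positive (got sigma={self.sigma}, tau={self.tau})"
            )

    @property
    def mean(self) -> float:
        return self.mu + self.tau

    @property
    def var(self) -> float:
        return self.sigma**2 + self.tau**2

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.var))

    def frozen(self):
        """The equivalent ``scipy.stats.exponnorm`` frozen distribution."""
        return stats.exponnorm(self.tau / self.sigma, loc=self.mu, scale=self.sigma)


def _validate(mu, sigma, tau) -> None:
    if np.any(sigma <= 0) or np.any(tau <= 0):
        raise ParameterError("sigma and tau must be strictly positive")


def exgauss_logpdf(t, mu, sigma, tau):
    """Numerically stable log-density, finite for every finite ``t``.

    Uses ``log f = -log(2 tau) - z^2/2 + log erfcx(u/sqrt(2))`` with
    z = (t-mu)/sigma and u = sigma/tau - z; for u/sqrt(2) < -20,
    erfc(u/sqrt(2)) equals 2 to double precision, giving the asymptotic
    branch ``log 2 + u^2/2`` without overflow.
    """
    _validate(mu, sigma, tau)
    t = np.asarray(t, dtype=float)
    z = (t - mu) / sigma
    x = (sigma / tau - z) / _SQRT2
    small = x < -20.0
    log_erfcx = np.where(
        small,
        _LOG2 + x * x,
        np.log(special.erfcx(np.where(small, 0.0, x))),
    )
    return -np.log(2.0 * tau) - 0.5 * z * z + log_erfcx


def exgauss_pdf(t, mu, sigma, tau):
    return np.exp(exgauss_logpdf(t, mu, sigma, tau))


def exgauss_cdf(t, mu, sigma, tau):
    _validate(mu, sigma, tau)
    return stats.exponnorm.cdf(t, tau / sigma, loc=mu, scale=sigma)


def exgauss_logsf(t, mu, sigma, tau):
    """Log survival function via the identity ``S(t) = Phi(-z) + tau*f(t)``.

    Both terms are nonnegative; the second keeps the exponential tail
    accurate far beyond where the Gaussian term underflows.
    """
    t = np.asarray(t, dtype=float)
    z = (t - mu) / sigma
    return np.logaddexp(
        special.log_ndtr(-z), np.log(tau) + exgauss_logpdf(t, mu, sigma, tau)
    )


def exgauss_sf(t, mu, sigma, tau):
    return np.exp(exgauss_logsf(t, mu, sigma, tau))


def exgauss_ppf(q, mu, sigma, tau):
    _validate(mu, sigma, tau)
    return stats.exponnorm.ppf(q, tau / sigma, loc=mu, scale=sigma)


def exgauss_rvs(mu, sigma, tau, size=None, rng=None):
    """Draws as Normal(mu, sigma) + Exponential(mean tau)."""
    _validate(mu, sigma, tau)
    rng = np.random.default_rng(rng)
    return rng.normal(mu, sigma, size=size) + rng.exponential(tau, size=size)
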