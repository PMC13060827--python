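"""Distribution families for distributional regression of bounded, skewed features.

Three families form the model-selection hierarchy used by the fitting stage:

* ``SHASH`` — the four-parameter sinh-arcsinh family of Jones & Pewsey, in the
  "direct" parameterisation ``Y = mu + sigma * sinh((asinh(Z) + nu) / tau)``
  with ``Z ~ N(0, 1)``.  Under this form the CDF is
  ``F(y) = Phi(sinh(tau * asinh((y - mu)/sigma) - nu))`` and the quantile
  function is available in closed form, so quantile mapping is exact.
  At ``nu = 0, tau = 1`` the family reduces *exactly* to ``Normal(mu, sigma)``.
* ``GG`` — the three-parameter generalised gamma in the mean-oriented
  (mu, sigma, nu) form used throughout the GAMLSS literature:
  ``z = (y/mu)**nu`` and ``theta = 1/(sigma**2 * nu**2)`` with
  ``theta * z ~ Gamma(theta, 1)``.  Support is ``y > 0`` and ``mu > 0``.
  The CDF is a regularised incomplete gamma, hence closed-form inversion.
* ``NORMAL`` — the Gaussian terminal fallback.

Link conventions: identity on mu and nu, log on sigma and tau.  All density /
CDF / quantile routines are vectorised over both observations and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import special

__all__ = [
    "ParameterDomainError",
    "FamilySpec",
    "ParamVector",
    "get_family",
    "apply_link",
    "invert_link",
    "logpdf",
    "pdf",
    "cdf",
    "quantile",
]

_SQRT2 = np.sqrt(2.0)
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

# |nu| below this, the generalised gamma is evaluated in its log-normal limit
_GG_NU_EPS = 1e-5


class ParameterDomainError(ValueError):
    """A distributional parameter violates its domain (sigma <= 0, tau <= 0, non-finite)."""


@dataclass(frozen=True)
class FamilySpec:
    """A parametric family together with its per-parameter link functions."""

    name: str
    n_params: int
    links: dict = field(compare=False)

    @property
    def param_names(self) -> tuple:
        return ("mu", "sigma", "nu", "tau")[: self.n_params]

    def support(self) -> tuple:
        return (0.0, np.inf) if self.name == "GG" else (-np.inf, np.inf)


_FAMILIES = {
    "SHASH": FamilySpec(
        "SHASH", 4, {"mu": "identity", "sigma": "log", "nu": "identity", "tau": "log"}
    ),
    "GG": FamilySpec("GG", 3, {"mu": "identity", "sigma": "log", "nu": "identity"}),
    "NORMAL": FamilySpec("NORMAL", 2, {"mu": "identity", "sigma": "log"}),
}


def get_family(name: str) -> FamilySpec:
    try:
        return _FAMILIES[name.upper()]
    except KeyError:
        raise ValueError(f"unknown family {name!r}; expected one of {sorted(_FAMILIES)}")


@dataclass
class ParamVector:
    """Natural-scale distributional parameters; scalar or array valued."""

    mu: np.ndarray
    sigma: np.ndarray
    nu: Optional[np.ndarray] = None
    tau: Optional[np.ndarray] = None

    def validate(self, family: FamilySpec) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if not np.all(np.isfinite(mu)) or not np.all(np.isfinite(sigma)):
            raise ParameterDomainError("non-finite mu or sigma")
        if np.any(sigma <= 0):
            raise ParameterDomainError("sigma must be strictly positive")
        if family.n_params >= 3:
            if self.nu is None:
                raise ParameterDomainError(f"{family.name} requires nu")
            if not np.all(np.isfinite(np.asarray(self.nu, dtype=float))):
                raise ParameterDomainError("non-finite nu")
        if family.n_params >= 4:
            if self.tau is None:
                raise ParameterDomainError(f"{family.name} requires tau")
            tau = np.asarray(self.tau, dtype=float)
            if not np.all(np.isfinite(tau)):
                raise ParameterDomainError("non-finite tau")
            if np.any(tau <= 0):
                raise ParameterDomainError("tau must be strictly positive")
        if family.name == "GG" and np.any(mu <= 0):
            raise ParameterDomainError("GG requires mu > 0")


# ---------------------------------------------------------------------------
# Link functions
# ---------------------------------------------------------------------------

def apply_link(theta, link: str):
    """Map a natural-scale parameter to the linear-predictor (link) scale."""
    theta = np.asarray(theta, dtype=float)
    if link == "identity":
        return theta
    if link == "log":
        if np.any(theta <= 0):
            raise ParameterDomainError("log link requires a strictly positive argument")
        return np.log(theta)
    raise ValueError(f"unknown link {link!r}")


def invert_link(eta, link: str):
    """Map a link-scale value back to the natural parameter scale."""
    eta = np.asarray(eta, dtype=float)
    if link == "identity":
        return eta
    if link == "log":
        return np.exp(eta)
    raise ValueError(f"unknown link {link!r}")


# ---------------------------------------------------------------------------
# Normal
# ---------------------------------------------------------------------------

def _norm_logpdf(y, mu, sigma):
    r = (y - mu) / sigma
    return -0.5 * r * r - np.log(sigma) - _LOG_SQRT_2PI


def _norm_cdf(y, mu, sigma):
    return special.ndtr((y - mu) / sigma)


def _norm_quantile(c, mu, sigma):
    return mu + sigma * special.ndtri(c)


# ---------------------------------------------------------------------------
# SHASH (direct Jones-Pewsey form)
# ---------------------------------------------------------------------------

def _shash_logpdf(y, mu, sigma, nu, tau):
    r = (y - mu) / sigma
    s = np.arcsinh(r)
    u = tau * s - nu
    z = np.sinh(u)
    # log cosh(u) computed stably for large |u|
    log_cosh_u = np.abs(u) + np.log1p(np.exp(-2.0 * np.abs(u))) - np.log(2.0)
    return (
        -0.5 * z * z
        - _LOG_SQRT_2PI
        + np.log(tau)
        + log_cosh_u
        - np.log(sigma)
        - 0.5 * np.log1p(r * r)
    )


def _shash_cdf(y, mu, sigma, nu, tau):
    r = (y - mu) / sigma
    z = np.sinh(tau * np.arcsinh(r) - nu)
    return special.ndtr(z)


def _shash_quantile(c, mu, sigma, nu, tau):
    z = special.ndtri(c)
    return mu + sigma * np.sinh((np.arcsinh(z) + nu) / tau)


# ---------------------------------------------------------------------------
# Generalised gamma (mu, sigma, nu)
# ---------------------------------------------------------------------------
# z = (y / mu) ** nu, theta = 1 / (sigma^2 nu^2), theta * z ~ Gamma(theta, 1).
# As nu -> 0 the family converges to log-normal(log mu, sigma), which is used
# below a small |nu| threshold to avoid catastrophic cancellation.

def _gg_theta(sigma, nu):
    return 1.0 / (sigma * sigma * nu * nu)


def _gg_logpdf(y, mu, sigma, nu):
    y_b, mu, sigma, nu = np.broadcast_arrays(
        np.asarray(y, float), np.asarray(mu, float),
        np.asarray(sigma, float), np.asarray(nu, float)
    )
    out = np.full(y_b.shape, -np.inf, dtype=float)
    pos = y_b > 0
    if not np.any(pos):
        return out if out.ndim else float(out)
    yb, mub, sb, nb = y_b[pos], mu[pos], sigma[pos], nu[pos]
    small = np.abs(nb) < _GG_NU_EPS
    res = np.empty(yb.shape)
    if np.any(~small):
        yn, mn, sn, nn = yb[~small], mub[~small], sb[~small], nb[~small]
        theta = _gg_theta(sn, nn)
        logz = nn * (np.log(yn) - np.log(mn))
        res[~small] = (
            np.log(np.abs(nn))
            + theta * np.log(theta)
            + theta * logz
            - theta * np.exp(logz)
            - special.gammaln(theta)
            - np.log(yn)
        )
    if np.any(small):
        yn, mn, sn = yb[small], mub[small], sb[small]
        res[small] = _norm_logpdf(np.log(yn), np.log(mn), sn) - np.log(yn)
    out[pos] = res
    return out if out.ndim else float(out)


def _gg_cdf(y, mu, sigma, nu):
    y_b, mu, sigma, nu = np.broadcast_arrays(
        np.asarray(y, float), np.asarray(mu, float),
        np.asarray(sigma, float), np.asarray(nu, float)
    )
    out = np.zeros(y_b.shape, dtype=float)
    pos = y_b > 0
    if np.any(pos):
        yb, mub, sb, nb = y_b[pos], mu[pos], sigma[pos], nu[pos]
        small = np.abs(nb) < _GG_NU_EPS
        res = np.empty(yb.shape)
        if np.any(~small):
            yn, mn, sn, nn = yb[~small], mub[~small], sb[~small], nb[~small]
            theta = _gg_theta(sn, nn)
            z = (yn / mn) ** nn
            p = special.gammainc(theta, theta * z)
            res[~small] = np.where(nn > 0, p, 1.0 - p)
        if np.any(small):
            yn, mn, sn = yb[small], mub[small], sb[small]
            res[small] = _norm_cdf(np.log(yn), np.log(mn), sn)
        out[pos] = res
    return out if out.ndim else float(out)


def _gg_quantile(c, mu, sigma, nu):
    c_b, mu, sigma, nu = np.broadcast_arrays(
        np.asarray(c, float), np.asarray(mu, float),
        np.asarray(sigma, float), np.asarray(nu, float)
    )
    small = np.abs(nu) < _GG_NU_EPS
    out = np.empty(c_b.shape)
    if np.any(~small):
        cn, mn, sn, nn = c_b[~small], mu[~small], sigma[~small], nu[~small]
        theta = _gg_theta(sn, nn)
        p = np.where(nn > 0, cn, 1.0 - cn)
        z = special.gammaincinv(theta, p) / theta
        out[~small] = mn * z ** (1.0 / nn)
    if np.any(small):
        out[small] = np.exp(
            _norm_quantile(c_b[small], np.log(mu[small]), sigma[small])
        )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def _dispatch(family: FamilySpec, params: ParamVector, fn_shash, fn_gg, fn_norm, x):
    params.validate(family)
    mu = np.asarray(params.mu, dtype=float)
    sigma = np.asarray(params.sigma, dtype=float)
    x = np.asarray(x, dtype=float)
    if family.name == "SHASH":
        out = fn_shash(x, mu, sigma, np.asarray(params.nu, float), np.asarray(params.tau, float))
    elif family.name == "GG":
        out = fn_gg(x, mu, sigma, np.asarray(params.nu, float))
    else:
        out = fn_norm(x, mu, sigma)
    out = np.asarray(out, dtype=float)
    return float(out) if out.ndim == 0 else out


def logpdf(y, family: FamilySpec, params: ParamVector):
    """Log-density of ``y`` under the family; ``-inf`` outside the support."""
    return _dispatch(family, params, _shash_logpdf, _gg_logpdf, _norm_logpdf, y)


def pdf(y, family: FamilySpec, params: ParamVector):
    return np.exp(logpdf(y, family, params))


def cdf(y, family: FamilySpec, params: ParamVector):
    """CDF of ``y``; monotone non-decreasing in ``y`` with limits 0 and 1."""
    return _dispatch(family, params, _shash_cdf, _gg_cdf, _norm_cdf, y)


def quantile(c, family: FamilySpec, params: ParamVector):
    """Quantile function; ``c`` must lie strictly inside (0, 1)."""
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr <= 0.0) or np.any(c_arr >= 1.0) or not np.all(np.isfinite(c_arr)):
        raise ValueError("quantile requires centiles strictly inside the open interval (0, 1)")
    return _dispatch(family, params, _shash_quantile, _gg_quantile, _norm_quantile, c)
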