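"""Frank copula primitives.

The Frank copula

    C(u, v; theta) = -(1/theta) * log(1 + expm1(-theta*u) * expm1(-theta*v)
                                          / expm1(-theta))

is the single-parameter Archimedean family used throughout this package. It
spans the full dependence range (theta in (-inf, inf) \\ {0}, with +/- inf the
Frechet bounds), is radially symmetric, and has no tail dependence — a good
match for taxon-taxon covariation where both co-occurrence and co-exclusion
must be representable.

theta = 0 is a removable singularity; values within ``THETA_EPS`` of zero
dispatch to the independence-limit formulas (C = uv, c = 1) so that every
function here is continuous through the puncture. All arithmetic uses
``expm1``/``log1p`` so the formulas stay stable for |theta| up to
``THETA_MAX``.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate

__all__ = [
    "THETA_MAX",
    "THETA_EPS",
    "frank_cdf",
    "frank_pdf",
    "frank_conditional_cdf",
    "frank_inverse_conditional",
    "theta_to_kendall",
    "theta_to_spearman",
]

#: Working bound for the dependence parameter. At |theta| = 35 the Frank
#: copula is within ~1e-6 of the corresponding Frechet bound in Kendall's tau,
#: so optimizer excursions beyond it carry no statistical information.
THETA_MAX = 35.0

#: Below this magnitude theta is treated as the independence limit.
THETA_EPS = 1e-6


def _check_unit(name: str, x, open_interval: bool = False) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if open_interval:
        if np.any(x <= 0.0) or np.any(x >= 1.0):
            raise ValueError(f"{name} must lie strictly inside (0, 1)")
    else:
        if np.any(x < 0.0) or np.any(x > 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    return x


def _denominator(u, v, theta: float):
    """D = (1 - e^{-theta}) - (1 - e^{-theta u})(1 - e^{-theta v}), computed stably.

    For small |theta| the expm1 products avoid cancellation of the O(theta)
    terms; for larger |theta| the expanded form
    e^{-theta u} + e^{-theta v} - e^{-theta(u+v)} - e^{-theta} avoids the
    catastrophic cancellation of near-1 quantities as (u, v) -> (1, 1).
    Also returns E = 1 - e^{-theta}.
    """
    E = -np.expm1(-theta)
    if abs(theta) < 0.5:
        D = E - np.expm1(-theta * u) * np.expm1(-theta * v)
    else:
        D = (np.exp(-theta * u) + np.exp(-theta * v)
             - np.exp(-theta * (u + v)) - np.exp(-theta))
    return D, E


def frank_cdf(u, v, theta: float):
    """Frank copula distribution function C(u, v; theta).

    Boundary identities C(u, 0) = C(0, v) = 0, C(u, 1) = u, C(1, v) = v hold
    exactly; the independence limit returns u*v.
    """
    u = _check_unit("u", u)
    v = _check_unit("v", v)
    u, v = np.broadcast_arrays(u, v)
    if abs(theta) < THETA_EPS:
        return u * v if u.ndim else float(u * v)
    if abs(theta) < 0.5:
        frac = np.expm1(-theta * u) * np.expm1(-theta * v) / np.expm1(-theta)
        out = -np.log1p(frac) / theta
    else:
        D, E = _denominator(u, v, theta)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = -np.log(D / E) / theta
    # enforce exact boundary identities (they hold analytically; floating
    # point round-off otherwise leaves ~1 ulp residue)
    out = np.where(v == 1.0, u, np.where(u == 1.0, v, out))
    out = np.where((u == 0.0) | (v == 0.0), 0.0, out)
    return out if out.ndim else float(out)


def frank_pdf(u, v, theta: float):
    """Frank copula density c(u, v; theta) = d2 C / du dv for u, v in (0, 1)."""
    u = _check_unit("u", u, open_interval=True)
    v = _check_unit("v", v, open_interval=True)
    u, v = np.broadcast_arrays(u, v)
    if abs(theta) < THETA_EPS:
        out = np.ones_like(u)
        return out if out.ndim else 1.0
    D, E = _denominator(u, v, theta)
    out = theta * E * np.exp(-theta * (u + v)) / D**2
    return out if out.ndim else float(out)


def frank_conditional_cdf(u, v, theta: float):
    """Conditional distribution C_{V|U}(v | u; theta) = dC/du.

    Nondecreasing in v from 0 to 1; equals v at the independence limit.
    """
    u = _check_unit("u", u, open_interval=True)
    v = _check_unit("v", v)
    u, v = np.broadcast_arrays(u, v)
    if abs(theta) < THETA_EPS:
        return v if v.ndim else float(v)
    D, _ = _denominator(u, v, theta)
    ev = -np.expm1(-theta * v)
    out = np.exp(-theta * u) * ev / D
    out = np.where(v == 1.0, 1.0, np.where(v == 0.0, 0.0, out))
    return out if out.ndim else float(out)


def frank_inverse_conditional(b, u, theta: float):
    """Invert ``frank_conditional_cdf`` in v: the Rosenblatt inverse.

    Closed form: v = -(1/theta) log{1 + b*(e^{-theta}-1) / (b + e^{-theta u}(1-b))}.
    """
    b = _check_unit("b", b, open_interval=True)
    u = _check_unit("u", u, open_interval=True)
    b, u = np.broadcast_arrays(b, u)
    if abs(theta) < THETA_EPS:
        return b if b.ndim else float(b)
    # 1 + b(e^-theta - 1)/(b + e^{-theta u}(1-b))
    #   = (e^{-theta u}(1-b) + b e^{-theta}) / (b + e^{-theta u}(1-b)),
    # a ratio of positive sums: no cancellation at large |theta|
    eu = np.exp(-theta * u)
    out = -(np.log(eu * (1.0 - b) + b * np.exp(-theta)) - np.log(b + eu * (1.0 - b))) / theta
    return out if out.ndim else float(out)


def _debye1(theta: float) -> float:
    """First Debye function D1(theta) = (1/theta) * int_0^theta t/(e^t - 1) dt."""
    if theta == 0.0:
        return 1.0

    def integrand(t):
        # t/(e^t - 1), continuous at 0 with value 1
        return t / np.expm1(t) if t != 0.0 else 1.0

    val, _ = integrate.quad(integrand, 0.0, theta, limit=200)
    return val / theta


def theta_to_kendall(theta: float) -> float:
    """Kendall's tau for the Frank copula: tau = 1 + 4*(D1(theta) - 1)/theta."""
    if abs(theta) < THETA_EPS:
        return 0.0
    return 1.0 + 4.0 * (_debye1(theta) - 1.0) / theta


def theta_to_spearman(theta: float) -> float:
    """Spearman's rho for the Frank copula, rho_s = 12 * E[C(U,V)] - 3.

    Computed by double quadrature of the copula over the unit square.
    """
    if abs(theta) < THETA_EPS:
        return 0.0
    val, _ = integrate.dblquad(
        lambda v, u: frank_cdf(u, v, theta), 0.0, 1.0, 0.0, 1.0,
        epsabs=1e-10, epsrel=1e-10,
    )
    return 12.0 * val - 3.0
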