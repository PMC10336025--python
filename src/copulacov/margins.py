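"""Zero-inflated beta (ZIB) marginal distributions and their fitting.

A taxon's relative abundance x in [0, 1) is modeled as a mixture placing
probability p on the atom {0} and probability 1 - p on a beta density
parameterized by its mean mu and dispersion phi (shape parameters
a = mu*phi, b = (1 - mu)*phi):

    f(x) = p * I(x = 0) + (1 - p) * f_beta(x; mu, phi) * I(x > 0).

Each of (p, mu, phi) may depend on per-sample covariates through a GLM link
(logit/probit/loglog for p and mu; log/sqrt for phi), giving a zero-inflated
beta regression. The log-likelihood factorizes into a Bernoulli part for the
zero indicator and a beta part for the nonzero values, so the two blocks are
fitted separately:

* intercept-only models use the closed-form zero fraction and an in-package
  damped Newton iteration on the beta log-likelihood (the hot path inside
  jackknife and simulation loops);
* covariate models delegate to statsmodels (Binomial GLM and BetaModel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .errors import ConvergenceError, InsufficientDataError

__all__ = [
    "ZIBParams",
    "MarginModel",
    "MarginFit",
    "beta_pdf",
    "zib_pdf",
    "zib_cdf",
    "zib_quantile",
    "zib_loglik",
    "fit_margin",
    "clean_abundances",
]

_ONE_MINUS = 1.0 - 1e-12

# ---------------------------------------------------------------------------
# link functions


def _loglog(p):
    return -np.log(-np.log(p))


def _loglog_inv(z):
    return np.exp(-np.exp(-z))


LINKS = {
    "logit": (special.logit, special.expit),
    "probit": (special.ndtri, special.ndtr),
    "loglog": (_loglog, _loglog_inv),
    "log": (np.log, np.exp),
    "sqrt": (np.sqrt, np.square),
}

_MEAN_LINKS = ("logit", "probit", "loglog")
_PRECISION_LINKS = ("log", "sqrt")


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class ZIBParams:
    """Marginal parameter triple gamma = (p, mu, phi)."""

    p: float
    mu: float
    phi: float

    def __post_init__(self):
        if not (0.0 <= self.p < 1.0):
            raise ValueError(f"zero probability p must lie in [0, 1), got {self.p}")
        if not (0.0 < self.mu < 1.0):
            raise ValueError(f"beta mean mu must lie in (0, 1), got {self.mu}")
        if not self.phi > 0.0:
            raise ValueError(f"beta dispersion phi must be positive, got {self.phi}")

    @property
    def shape_a(self) -> float:
        return self.mu * self.phi

    @property
    def shape_b(self) -> float:
        return (1.0 - self.mu) * self.phi


@dataclass(frozen=True)
class MarginModel:
    """Covariate design and link specification for one ZIB margin.

    ``design_*`` are n x k matrices (include an intercept column explicitly);
    ``None`` means intercept-only for that block.
    """

    design_p: Optional[np.ndarray] = None
    design_mu: Optional[np.ndarray] = None
    design_phi: Optional[np.ndarray] = None
    link_p: str = "logit"
    link_mu: str = "logit"
    link_phi: str = "log"

    def __post_init__(self):
        if self.link_p not in _MEAN_LINKS or self.link_mu not in _MEAN_LINKS:
            raise ValueError(f"links for p and mu must be one of {_MEAN_LINKS}")
        if self.link_phi not in _PRECISION_LINKS:
            raise ValueError(f"link for phi must be one of {_PRECISION_LINKS}")
        ns = {np.asarray(d).shape[0] for d in
              (self.design_p, self.design_mu, self.design_phi) if d is not None}
        if len(ns) > 1:
            raise ValueError("design matrices must share the same number of rows")

    def n_rows(self) -> Optional[int]:
        for d in (self.design_p, self.design_mu, self.design_phi):
            if d is not None:
                return np.asarray(d).shape[0]
        return None

    def is_intercept_only(self) -> bool:
        def trivial(d):
            if d is None:
                return True
            d = np.asarray(d)
            return d.ndim == 2 and d.shape[1] == 1 and np.allclose(d, d[0, 0])

        return trivial(self.design_p) and trivial(self.design_mu) and trivial(self.design_phi)


def _design(d, n):
    if d is None:
        return np.ones((n, 1))
    d = np.asarray(d, dtype=float)
    if d.ndim == 1:
        d = d[:, None]
    if d.shape[0] != n:
        raise ValueError("design matrix row count does not match data length")
    return d


@dataclass
class MarginFit:
    """Fitted ZIB margin: link-scale coefficients and derived per-sample gamma."""

    rho: np.ndarray
    delta: np.ndarray
    kappa: np.ndarray
    p: np.ndarray
    mu: np.ndarray
    phi: np.ndarray
    loglik: float
    n_zero: int
    n: int
    converged: bool
    model: MarginModel
    se: dict = field(default_factory=dict)

    @property
    def gamma(self) -> ZIBParams:
        """Single ZIBParams for intercept-only fits (constant gamma across samples)."""
        return ZIBParams(float(self.p[0]), float(self.mu[0]), float(self.phi[0]))

    def cdf(self, x, left_limit: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return _zib_cdf_arrays(x, self.p, self.mu, self.phi, left_limit=left_limit)

    def log_density(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return _zib_logpdf_arrays(x, self.p, self.mu, self.phi)


# ---------------------------------------------------------------------------
# densities / distribution functions


def _check_support(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0) or np.any(x >= 1.0):
        raise ValueError("values must lie in [0, 1)")
    return x


def clean_abundances(x, name: str = "data") -> np.ndarray:
    """Validate abundances; clamp values >= 1 - 1e-12 into the open support with a warning."""
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    if np.any(x < 0.0):
        raise ValueError(f"{name} contains negative values")
    high = x >= _ONE_MINUS
    if np.any(high):
        warnings.warn(
            f"{int(high.sum())} value(s) in {name} at or above 1 - 1e-12 were "
            "clamped into the open support [0, 1)",
            stacklevel=2,
        )
        x = np.where(high, _ONE_MINUS, x)
    return x


def beta_pdf(x, mu: float, phi: float):
    """Mean/dispersion-parameterized beta density, computed on the log scale."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0) or np.any(x >= 1.0):
        raise ValueError("beta_pdf requires x strictly inside (0, 1)")
    g = ZIBParams(0.0, mu, phi)  # validates mu, phi
    out = np.exp(stats.beta.logpdf(x, g.shape_a, g.shape_b))
    return out if out.ndim else float(out)


def zib_pdf(x, gamma: ZIBParams):
    """ZIB density/mass: p at the atom, (1 - p) * beta_pdf elsewhere."""
    x = _check_support(x)
    out = np.where(
        x == 0.0,
        gamma.p,
        (1.0 - gamma.p)
        * np.exp(stats.beta.logpdf(np.where(x == 0.0, 0.5, x), gamma.shape_a, gamma.shape_b)),
    )
    return out if out.ndim else float(out)


def _zib_logpdf_arrays(x, p, mu, phi) -> np.ndarray:
    a = mu * phi
    b = (1.0 - mu) * phi
    zero = x == 0.0
    with np.errstate(divide="ignore"):
        lz = np.log(np.broadcast_to(p, x.shape))
        lnz = np.log1p(-p) + stats.beta.logpdf(np.where(zero, 0.5, x), a, b)
    return np.where(zero, lz, lnz)


def _zib_cdf_arrays(x, p, mu, phi, left_limit: bool = False) -> np.ndarray:
    a = mu * phi
    b = (1.0 - mu) * phi
    base = p + (1.0 - p) * stats.beta.cdf(x, a, b)
    if left_limit:
        # F(x-) = F(x) for x > 0; F(0-) = 0 at the atom
        return np.where(x == 0.0, 0.0, base)
    return base


def zib_cdf(x, gamma: ZIBParams, left_limit: bool = False):
    """ZIB distribution function F(x) = p + (1 - p) F_beta(x); jump of size p at 0."""
    x = _check_support(x)
    out = _zib_cdf_arrays(x, gamma.p, gamma.mu, gamma.phi, left_limit=left_limit)
    return out if out.ndim else float(out)


def zib_quantile(u, gamma: ZIBParams):
    """Inverse of ``zib_cdf``: 0 for u <= p, else the beta quantile of (u-p)/(1-p)."""
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("u must lie strictly inside (0, 1)")
    atom = u <= gamma.p
    rescaled = np.where(atom, 0.5, (u - gamma.p) / (1.0 - gamma.p))
    out = np.where(
        atom, 0.0, np.minimum(stats.beta.ppf(rescaled, gamma.shape_a, gamma.shape_b), _ONE_MINUS)
    )
    return out if out.ndim else float(out)


def zib_loglik(data, gamma) -> float:
    """ZIB log-likelihood; ``gamma`` is a ZIBParams or per-sample (p, mu, phi) arrays.

    Identical (to numerical precision) to the grouped closed form
    z*log p + (n - z)*log(1 - p) + the beta log-likelihood of the nonzero part.
    """
    x = _check_support(data)
    if x.size < 1:
        raise ValueError("at least one observation is required")
    if isinstance(gamma, ZIBParams):
        p, mu, phi = (np.full(x.shape, v) for v in (gamma.p, gamma.mu, gamma.phi))
    else:
        p, mu, phi = (np.broadcast_to(np.asarray(v, float), x.shape) for v in gamma)
    return float(np.sum(_zib_logpdf_arrays(x, p, mu, phi)))


# ---------------------------------------------------------------------------
# fitting


def _beta_mom(x: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(x))
    v = float(np.var(x))
    m = min(max(m, 1e-4), 1.0 - 1e-4)
    v = max(v, 1e-8)
    phi = max(m * (1.0 - m) / v - 1.0, 0.1)
    return m, phi


def _beta_loglik_ab(la: float, lb: float, m: int, s1: float, s2: float) -> float:
    a, b = np.exp(la), np.exp(lb)
    return (
        m * (special.gammaln(a + b) - special.gammaln(a) - special.gammaln(b))
        + (a - 1.0) * s1
        + (b - 1.0) * s2
    )


def _fit_beta_newton(x: np.ndarray, tol_grad: float = 1e-8, tol_ll: float = 1e-10,
                     max_iter: int = 100) -> tuple[float, float, np.ndarray, bool]:
    """Maximize the beta log-likelihood over (log a, log b) by damped Newton.

    Returns (mu, phi, covariance of (a, b), converged). Falls back to
    Nelder-Mead when the Newton iteration stalls (ill-conditioned small-n
    dispersion likelihoods).
    """
    m = x.size
    s1 = float(np.sum(np.log(x)))
    s2 = float(np.sum(np.log1p(-x)))
    mu0, phi0 = _beta_mom(x)
    la, lb = np.log(mu0 * phi0), np.log((1.0 - mu0) * phi0)
    ll = _beta_loglik_ab(la, lb, m, s1, s2)
    converged = False
    for _ in range(max_iter):
        a, b = np.exp(la), np.exp(lb)
        psi_ab = special.digamma(a + b)
        ga = m * (psi_ab - special.digamma(a)) + s1
        gb = m * (psi_ab - special.digamma(b)) + s2
        g = np.array([a * ga, b * gb])  # gradient in log parameters
        if np.max(np.abs(g)) <= tol_grad * max(1.0, m):
            converged = True
            break
        t_ab = m * special.polygamma(1, a + b)
        haa = m * (special.polygamma(1, a + b) - special.polygamma(1, a))
        hbb = m * (special.polygamma(1, a + b) - special.polygamma(1, b))
        H = np.array(
            [
                [a * a * haa + a * ga, a * b * t_ab],
                [a * b * t_ab, b * b * hbb + b * gb],
            ]
        )
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            step = g / max(np.max(np.abs(g)), 1.0)
        if g @ step <= 0.0:  # not an ascent direction: quasi-Newton fallback
            step = g / max(np.max(np.abs(g)), 1.0)
        # step halving
        scale = 1.0
        for _ in range(40):
            la_new, lb_new = la + scale * step[0], lb + scale * step[1]
            ll_new = _beta_loglik_ab(la_new, lb_new, m, s1, s2)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-14:
                break
            scale *= 0.5
        if abs(ll_new - ll) <= tol_ll * max(1.0, abs(ll)):
            la, lb, ll = la_new, lb_new, ll_new
            converged = True
            break
        la, lb, ll = la_new, lb_new, ll_new
    if not converged:
        res = optimize.minimize(
            lambda z: -_beta_loglik_ab(z[0], z[1], m, s1, s2),
            np.array([la, lb]),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        la, lb = res.x
        converged = bool(res.success)
    a, b = np.exp(la), np.exp(lb)
    # observed information in (a, b) for standard errors
    t_ab = m * special.polygamma(1, a + b)
    info = np.array(
        [
            [m * special.polygamma(1, a) - t_ab, -t_ab],
            [-t_ab, m * special.polygamma(1, b) - t_ab],
        ]
    )
    try:
        cov_ab = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov_ab = np.full((2, 2), np.nan)
    return a / (a + b), a + b, cov_ab, converged


def _link_intercept(link: str, value: float) -> float:
    fwd = LINKS[link][0]
    if link in _MEAN_LINKS:
        value = float(np.clip(value, 1e-10, 1.0 - 1e-10))
    else:  # positive-scale links (log, sqrt)
        value = max(value, 1e-10)
    return float(fwd(value))


def fit_margin(data, model: Optional[MarginModel] = None) -> MarginFit:
    """Maximum-likelihood fit of a (possibly covariate-adjusted) ZIB margin.

    Requires at least three nonzero observations (the identifiability floor
    for the three beta-block parameters). The zero part and the beta part are
    fitted separately; the likelihood factorizes exactly.
    """
    x = clean_abundances(data)
    if x.ndim != 1:
        raise ValueError("data must be one-dimensional")
    n = x.size
    model = model or MarginModel()
    nz_mask = x > 0.0
    m = int(nz_mask.sum())
    n_zero = n - m
    if m < 3:
        raise InsufficientDataError(
            f"margin fitting needs at least 3 nonzero observations, got {m}"
        )
    model_n = model.n_rows()
    if model_n is not None and model_n != n:
        raise ValueError("design matrices and data have mismatched lengths")

    se: dict = {}
    if model.is_intercept_only():
        p_hat = n_zero / n
        mu_hat, phi_hat, cov_ab, conv = _fit_beta_newton(x[nz_mask])
        rho = np.array([_link_intercept(model.link_p, p_hat)])
        delta = np.array([_link_intercept(model.link_mu, mu_hat)])
        kappa = np.array([_link_intercept(model.link_phi, phi_hat)])
        p_arr = np.full(n, p_hat)
        mu_arr = np.full(n, mu_hat)
        phi_arr = np.full(n, phi_hat)
        # delta-method SEs for (mu, phi) from the (a, b) covariance
        a, b = mu_hat * phi_hat, (1.0 - mu_hat) * phi_hat
        J = np.array([[b / (a + b) ** 2, -a / (a + b) ** 2], [1.0, 1.0]])
        cov_mp = J @ cov_ab @ J.T
        se = {
            "p": float(np.sqrt(max(p_hat * (1.0 - p_hat), 0.0) / n)),
            "mu": float(np.sqrt(max(cov_mp[0, 0], 0.0))),
            "phi": float(np.sqrt(max(cov_mp[1, 1], 0.0))),
        }
        converged = conv
    else:
        rho, p_arr, se_rho, conv_p = _fit_zero_part(nz_mask, model, n)
        delta, kappa, mu_arr, phi_arr, se_dk, conv_b = _fit_beta_part(x, nz_mask, model, n)
        se = {"rho": se_rho, **se_dk}
        converged = conv_p and conv_b

    ll = zib_loglik(x, (p_arr, mu_arr, phi_arr))
    return MarginFit(
        rho=np.asarray(rho, float),
        delta=np.asarray(delta, float),
        kappa=np.asarray(kappa, float),
        p=p_arr,
        mu=mu_arr,
        phi=phi_arr,
        loglik=ll,
        n_zero=n_zero,
        n=n,
        converged=bool(converged),
        model=model,
        se=se,
    )


def _sm_mean_link(name: str):
    from statsmodels.genmod.families import links

    return {"logit": links.Logit(), "probit": links.Probit(), "loglog": links.LogLog()}[name]


def _fit_zero_part(nz_mask, model: MarginModel, n: int):
    import statsmodels.api as sm

    Q = _design(model.design_p, n)
    y = (~nz_mask).astype(float)
    if y.sum() == 0.0:
        # no zeros: degenerate p = 0 (pure beta margin)
        rho = np.zeros(Q.shape[1])
        rho[0] = _link_intercept(model.link_p, 0.0)
        return rho, np.zeros(n), np.full(Q.shape[1], np.nan), True
    fam = sm.families.Binomial(link=_sm_mean_link(model.link_p))
    res = sm.GLM(y, Q, family=fam).fit()
    eta = Q @ res.params
    p_arr = LINKS[model.link_p][1](eta)
    return np.asarray(res.params), np.clip(p_arr, 0.0, 1.0 - 1e-12), np.asarray(res.bse), True


def _fit_beta_part(x, nz_mask, model: MarginModel, n: int):
    from statsmodels.genmod.families import links as sml
    from statsmodels.othermod.betareg import BetaModel

    W = _design(model.design_mu, n)
    Z = _design(model.design_phi, n)
    link_prec = {"log": sml.Log(), "sqrt": sml.Sqrt()}[model.link_phi]
    if W.shape[1] == 1 and Z.shape[1] == 1:
        mu_hat, phi_hat, _, conv = _fit_beta_newton(x[nz_mask])
        delta = np.array([_link_intercept(model.link_mu, mu_hat)])
        kappa = np.array([_link_intercept(model.link_phi, phi_hat)])
        return delta, kappa, np.full(n, mu_hat), np.full(n, phi_hat), {}, conv
    res = BetaModel(
        x[nz_mask],
        W[nz_mask],
        exog_precision=Z[nz_mask],
        link=_sm_mean_link(model.link_mu),
        link_precision=link_prec,
    ).fit(disp=False)
    w = W.shape[1]
    delta = np.asarray(res.params[:w])
    kappa = np.asarray(res.params[w:])
    mu_arr = LINKS[model.link_mu][1](W @ delta)
    phi_arr = LINKS[model.link_phi][1](Z @ kappa)
    se = {"delta": np.asarray(res.bse[:w]), "kappa": np.asarray(res.bse[w:])}
    return delta, kappa, np.clip(mu_arr, 1e-12, 1.0 - 1e-12), np.maximum(phi_arr, 1e-12), se, True


def gamma_from_coefficients(model: MarginModel, rho, delta, kappa, n: int):
    """Per-sample (p, mu, phi) arrays implied by link-scale coefficients."""
    Q, W, Z = (_design(model.design_p, n), _design(model.design_mu, n),
               _design(model.design_phi, n))
    p = np.clip(LINKS[model.link_p][1](Q @ np.asarray(rho, float)), 0.0, 1.0 - 1e-12)
    mu = np.clip(LINKS[model.link_mu][1](W @ np.asarray(delta, float)), 1e-12, 1.0 - 1e-12)
    phi = np.maximum(LINKS[model.link_phi][1](Z @ np.asarray(kappa, float)), 1e-12)
    return p, mu, phi
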