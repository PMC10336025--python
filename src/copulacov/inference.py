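"""Rescaled likelihood-ratio test for Frank-copula dependence, and FDR control.

The two-stage statistic is

    Lambda' = -2 * omega * [ l(theta_0, gamma_i~, gamma_j~) - l(theta~, gamma_i~, gamma_j~) ],

asymptotically chi-squared with 1 df. The factor omega in (0, 1] corrects for
the plugged-in marginal estimates; under the independence null theta_0 = 0
the cross-information blocks between theta and the marginal parameters
vanish, omega = 1 exactly, and Lambda' is the ordinary likelihood-ratio
statistic. For theta_0 != 0 the information blocks entering omega are
estimated by sample averages of numerically differentiated per-observation
scores at the fitted parameters.

Network-scale multiplicity is controlled with the Benjamini-Yekutieli
step-up procedure, valid under the arbitrary dependence among overlapping
taxon pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError
from .estimation import PairFit, two_stage_fit
from .joint import pair_log_density
from .margins import MarginModel, gamma_from_coefficients

__all__ = ["LRTResult", "two_stage_lrt", "lrt_from_pairfit", "omega_factor", "by_fdr"]


@dataclass
class LRTResult:
    """Rescaled likelihood-ratio test outcome for one taxon pair."""

    lambda_prime: float
    omega: float
    p_value: float
    theta_null: float
    theta_tilde: float
    df: int = 1
    at_boundary: bool = False

    def __post_init__(self):
        assert self.lambda_prime >= 0.0 and 0.0 <= self.p_value <= 1.0


def lrt_from_pairfit(fit: PairFit, theta_null: float = 0.0) -> LRTResult:
    """LRT of theta = theta_null from an existing two-stage fit (omega = 1 path).

    Only valid for the independence null, where the rescaling factor is
    exactly 1.
    """
    if theta_null != 0.0:
        raise ValueError("lrt_from_pairfit only supports the independence null; "
                         "use two_stage_lrt for theta_null != 0")
    lam = max(-2.0 * (fit.loglik_at_null - fit.loglik_at_max), 0.0)
    return LRTResult(
        lambda_prime=lam,
        omega=1.0,
        p_value=float(stats.chi2.sf(lam, 1)),
        theta_null=0.0,
        theta_tilde=fit.theta,
        at_boundary=fit.at_boundary,
    )


def two_stage_lrt(x_i, x_j, model_i: Optional[MarginModel] = None,
                  model_j: Optional[MarginModel] = None, *,
                  theta_null: float = 0.0,
                  fitted: Optional[PairFit] = None) -> LRTResult:
    """Two-stage rescaled likelihood-ratio test of H0: theta = theta_null."""
    if fitted is None:
        fitted = two_stage_fit(x_i, x_j, model_i, model_j)
    if theta_null == 0.0:
        return lrt_from_pairfit(fitted)
    from .joint import PairWorkspace

    ws = PairWorkspace.build(np.asarray(x_i, float), np.asarray(x_j, float),
                             fitted.margin_i, fitted.margin_j)
    ll_null = ws.loglik(theta_null)
    omega = omega_factor(x_i, x_j, fitted, theta_null, model_i=model_i, model_j=model_j)
    lam = max(-2.0 * omega * (ll_null - fitted.loglik_at_max), 0.0)
    return LRTResult(
        lambda_prime=lam,
        omega=omega,
        p_value=float(stats.chi2.sf(lam, 1)),
        theta_null=theta_null,
        theta_tilde=fitted.theta,
        at_boundary=fitted.at_boundary,
    )


def _coef_vector(fit) -> np.ndarray:
    return np.concatenate([fit.rho, fit.delta, fit.kappa])


def _split_coefs(fit, vec: np.ndarray):
    q, w = fit.rho.size, fit.delta.size
    return vec[:q], vec[q:q + w], vec[q + w:]


def omega_factor(x_i, x_j, fitted: PairFit, theta_null: float, *,
                 model_i: Optional[MarginModel] = None,
                 model_j: Optional[MarginModel] = None,
                 step: float = 1e-5, step2: float = 1e-4) -> float:
    """Rescaling factor omega for a non-independence null.

    omega = (1 + I_tt^-1 (I_t1 J11^-1 I_1t + I_t2 J22^-1 I_2t
                          + I_t1 J11^-1 J12 J22^-1 I_2t
                          + I_t2 J22^-1 J21 J11^-1 I_1t))^-1,

    with J_kl the marginal score (cross-)covariances and I_tk, I_tt expected
    negative second derivatives involving theta, all estimated by sample
    averages of central finite differences on the fitted (link-scale)
    coefficients. Returns 1.0 immediately for the independence null.
    """
    if theta_null == 0.0:
        return 1.0
    x_i = np.asarray(x_i, float)
    x_j = np.asarray(x_j, float)
    n = x_i.size
    mi = model_i or MarginModel()
    mj = model_j or MarginModel()
    ci = _coef_vector(fitted.margin_i)
    cj = _coef_vector(fitted.margin_j)
    theta = fitted.theta

    def logf(vec_i, vec_j, th) -> np.ndarray:
        gi = gamma_from_coefficients(mi, *_split_coefs(fitted.margin_i, vec_i), n=n)
        gj = gamma_from_coefficients(mj, *_split_coefs(fitted.margin_j, vec_j), n=n)
        return pair_log_density(x_i, x_j, gi, gj, th)

    from .margins import _zib_logpdf_arrays

    def logf_margin(which: int, vec) -> np.ndarray:
        # marginal log-density: the inference functions g_k are MARGINAL scores
        if which == 0:
            g = gamma_from_coefficients(mi, *_split_coefs(fitted.margin_i, vec), n=n)
            return _zib_logpdf_arrays(x_i, *g)
        g = gamma_from_coefficients(mj, *_split_coefs(fitted.margin_j, vec), n=n)
        return _zib_logpdf_arrays(x_j, *g)

    def margin_scores(which: int) -> np.ndarray:
        base = (ci, cj)[which]
        d = base.size
        G = np.empty((n, d))
        for a in range(d):
            e = np.zeros(d)
            e[a] = step
            G[:, a] = (logf_margin(which, base + e) - logf_margin(which, base - e)) / (2 * step)
        return G

    G1 = margin_scores(0)
    G2 = margin_scores(1)
    J11 = G1.T @ G1 / n
    J22 = G2.T @ G2 / n
    J12 = G1.T @ G2 / n

    f0 = logf(ci, cj, theta)
    fp = logf(ci, cj, theta + step2)
    fm = logf(ci, cj, theta - step2)
    I_tt = -float(np.mean((fp - 2.0 * f0 + fm) / step2**2))

    def mixed(which: int) -> np.ndarray:
        base = (ci, cj)
        d = base[which].size
        out = np.empty(d)
        for a in range(d):
            e = np.zeros(d)
            e[a] = step2
            args_pp = list(base); args_pp[which] = base[which] + e  # noqa: E702
            args_mm = list(base); args_mm[which] = base[which] - e  # noqa: E702
            fpp = logf(args_pp[0], args_pp[1], theta + step2)
            fpm = logf(args_pp[0], args_pp[1], theta - step2)
            fmp = logf(args_mm[0], args_mm[1], theta + step2)
            fmm = logf(args_mm[0], args_mm[1], theta - step2)
            out[a] = -float(np.mean((fpp - fpm - fmp + fmm) / (4.0 * step2**2)))
        return out

    I_t1 = mixed(0)
    I_t2 = mixed(1)

    try:
        s1 = np.linalg.solve(J11, I_t1)
        s2 = np.linalg.solve(J22, I_t2)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular marginal score covariance while estimating omega"
        ) from exc
    inner = (I_t1 @ s1 + I_t2 @ s2 + I_t1 @ np.linalg.solve(J11, J12 @ s2)
             + I_t2 @ np.linalg.solve(J22, J12.T @ s1))
    omega = 1.0 / (1.0 + inner / I_tt)
    return float(min(max(omega, 1e-8), 1.0))


def by_fdr(p_values, q: float = 0.01):
    """Benjamini-Yekutieli step-up FDR control.

    Returns ``(reject, p_adjusted)``: a boolean rejection mask at level ``q``
    and monotone BY-adjusted p-values (capped at 1). Empty input yields empty
    arrays.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_by")
    return reject, p_adj
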