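"""Bivariate joint density with mixed (atom + continuous) ZIB margins.

With margins F_i, F_j each carrying an atom at zero, the joint density of a
taxon pair splits into four scenarios per observation:

* S1 (both nonzero): c(F_i(x_i), F_j(x_j); theta) * f_i(x_i) * f_j(x_j),
  where f_k is the continuous part (1 - p_k) * f_beta and c the copula
  density;
* S2 (x_i = 0, x_j > 0): dC(p_i, v)/dv * f_j(x_j) — the conditional copula
  probability of the atom mass p_i given V = F_j(x_j);
* S3 (x_i > 0, x_j = 0): symmetric to S2;
* S4 (both zero): C(p_i, p_j; theta), the copula evaluated at the atom
  masses.

These are the four terms of the general mixed-margin construction (the
difference operator over the jump points collapses because F(0-) = 0).

``PairWorkspace`` precomputes everything theta-free (CDF transforms,
scenario masks, marginal log-densities), so that the profile log-likelihood
in theta — the stage-2 objective of the two-stage estimator — costs a few
vectorized copula evaluations per call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import frank
from .errors import DegenerateDataError
from .margins import MarginFit, ZIBParams, zib_cdf, zib_pdf

__all__ = ["PairWorkspace", "mixed_density", "profile_loglik", "scenario_masks"]

_LOG_FLOOR = np.log(1e-300)


def scenario_masks(x_i, x_j):
    """Boolean masks (s1, s2, s3, s4) for the four zero-pattern scenarios."""
    x_i = np.asarray(x_i, float)
    x_j = np.asarray(x_j, float)
    zi = x_i == 0.0
    zj = x_j == 0.0
    return (~zi & ~zj, zi & ~zj, ~zi & zj, zi & zj)


def mixed_density(x_i: float, x_j: float, gamma_i: ZIBParams, gamma_j: ZIBParams,
                  theta: float) -> float:
    """Joint density/mass of one paired observation under the four-case model."""
    if x_i == 0.0 and x_j == 0.0:
        return frank.frank_cdf(gamma_i.p, gamma_j.p, theta) if gamma_i.p * gamma_j.p > 0 else 0.0
    if x_i == 0.0:
        if gamma_i.p == 0.0:
            return 0.0
        v = zib_cdf(x_j, gamma_j)
        return frank.frank_conditional_cdf(v, gamma_i.p, theta) * zib_pdf(x_j, gamma_j)
    if x_j == 0.0:
        if gamma_j.p == 0.0:
            return 0.0
        u = zib_cdf(x_i, gamma_i)
        return frank.frank_conditional_cdf(u, gamma_j.p, theta) * zib_pdf(x_i, gamma_i)
    u = zib_cdf(x_i, gamma_i)
    v = zib_cdf(x_j, gamma_j)
    return frank.frank_pdf(u, v, theta) * zib_pdf(x_i, gamma_i) * zib_pdf(x_j, gamma_j)


@dataclass
class PairWorkspace:
    """Theta-free precomputation for a pair's profile log-likelihood."""

    u1: np.ndarray          # F_i(x_i) on S1
    v1: np.ndarray          # F_j(x_j) on S1
    v2: np.ndarray          # F_j(x_j) on S2
    p_i2: np.ndarray        # per-sample atom mass of margin i on S2
    u3: np.ndarray          # F_i(x_i) on S3
    p_j3: np.ndarray        # per-sample atom mass of margin j on S3
    p_i4: np.ndarray        # atom masses on S4
    p_j4: np.ndarray
    const: float            # theta-free marginal log-density contribution
    n: int
    counts: tuple

    @classmethod
    def build(cls, x_i, x_j, fit_i: MarginFit, fit_j: MarginFit) -> "PairWorkspace":
        x_i = np.asarray(x_i, float)
        x_j = np.asarray(x_j, float)
        s1, s2, s3, s4 = scenario_masks(x_i, x_j)
        if not np.any(s1 | s2 | s3):
            raise DegenerateDataError("all observations fall at the joint atom (0, 0)")
        u = fit_i.cdf(x_i)
        v = fit_j.cdf(x_j)
        eps = 1e-12
        clip = lambda a: np.clip(a, eps, 1.0 - eps)  # noqa: E731
        logf_i = fit_i.log_density(x_i)
        logf_j = fit_j.log_density(x_j)
        const = float(np.sum(logf_i[s1]) + np.sum(logf_j[s1])
                      + np.sum(logf_j[s2]) + np.sum(logf_i[s3]))
        return cls(
            u1=clip(u[s1]), v1=clip(v[s1]),
            v2=clip(v[s2]), p_i2=clip(fit_i.p[s2]),
            u3=clip(u[s3]), p_j3=clip(fit_j.p[s3]),
            p_i4=clip(fit_i.p[s4]), p_j4=clip(fit_j.p[s4]),
            const=const, n=x_i.size,
            counts=(int(s1.sum()), int(s2.sum()), int(s3.sum()), int(s4.sum())),
        )

    def loglik(self, theta: float) -> float:
        """Profile log-likelihood l(theta, gamma_i~, gamma_j~)."""
        total = self.const
        if self.u1.size:
            total += float(np.sum(_safe_log(frank.frank_pdf(self.u1, self.v1, theta))))
        if self.v2.size:
            total += float(np.sum(_safe_log(
                frank.frank_conditional_cdf(self.v2, self.p_i2, theta))))
        if self.u3.size:
            total += float(np.sum(_safe_log(
                frank.frank_conditional_cdf(self.u3, self.p_j3, theta))))
        if self.p_i4.size:
            total += float(np.sum(_safe_log(frank.frank_cdf(self.p_i4, self.p_j4, theta))))
        return total

    @property
    def n_joint_nonzero(self) -> int:
        return self.counts[0]


def _safe_log(x):
    return np.maximum(np.log(np.maximum(x, 1e-300)), _LOG_FLOOR)


def profile_loglik(x_i, x_j, fit_i: MarginFit, fit_j: MarginFit, theta: float) -> float:
    """Profile log-likelihood of theta with fitted margins plugged in (Eq.-style two-stage
    objective); equal to the sum of log ``mixed_density`` terms."""
    return PairWorkspace.build(x_i, x_j, fit_i, fit_j).loglik(theta)


def pair_log_density(x_i, x_j, gammas_i, gammas_j, theta: float) -> np.ndarray:
    """Per-observation log joint density for arbitrary per-sample parameter arrays.

    Used by the numeric information-matrix machinery of the rescaled LRT,
    where derivatives with respect to the marginal coefficients are taken.
    """
    x_i = np.asarray(x_i, float)
    x_j = np.asarray(x_j, float)
    p_i, mu_i, phi_i = (np.broadcast_to(np.asarray(a, float), x_i.shape) for a in gammas_i)
    p_j, mu_j, phi_j = (np.broadcast_to(np.asarray(a, float), x_j.shape) for a in gammas_j)
    from .margins import _zib_cdf_arrays, _zib_logpdf_arrays

    s1, s2, s3, s4 = scenario_masks(x_i, x_j)
    eps = 1e-12
    u = np.clip(_zib_cdf_arrays(x_i, p_i, mu_i, phi_i), eps, 1 - eps)
    v = np.clip(_zib_cdf_arrays(x_j, p_j, mu_j, phi_j), eps, 1 - eps)
    logf_i = _zib_logpdf_arrays(x_i, p_i, mu_i, phi_i)
    logf_j = _zib_logpdf_arrays(x_j, p_j, mu_j, phi_j)
    pi = np.clip(p_i, eps, 1 - eps)
    pj = np.clip(p_j, eps, 1 - eps)
    out = np.empty_like(x_i)
    if np.any(s1):
        out[s1] = (_safe_log(frank.frank_pdf(u[s1], v[s1], theta))
                   + logf_i[s1] + logf_j[s1])
    if np.any(s2):
        out[s2] = _safe_log(frank.frank_conditional_cdf(v[s2], pi[s2], theta)) + logf_j[s2]
    if np.any(s3):
        out[s3] = _safe_log(frank.frank_conditional_cdf(u[s3], pj[s3], theta)) + logf_i[s3]
    if np.any(s4):
        out[s4] = _safe_log(frank.frank_cdf(pi[s4], pj[s4], theta))
    return out
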