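"""Two-stage (inference-for-margins) maximum likelihood for a taxon pair.

Stage 1 fits each zero-inflated beta margin by its own likelihood; stage 2
plugs the fitted margins into the bivariate mixed-margin likelihood and
maximizes the resulting one-dimensional profile over the Frank dependence
parameter theta. The profile is smooth and in practice unimodal, so a coarse
grid scan followed by bounded Brent refinement is used; boundary solutions at
|theta| = THETA_MAX are flagged rather than hidden.

Uncertainty in theta~ is quantified by the leave-one-out jackknife
sigma2 = sum_l (theta~_(l) - theta~)^2, with both stages re-run on every
leave-one-out subset. The jackknife stands in for the analytic
inference-function covariance, whose mixed partial derivatives are
impractical to evaluate; it is known to be conservative (upwardly biased).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .errors import InsufficientDataError
from .frank import THETA_MAX
from .joint import PairWorkspace, scenario_masks
from .margins import MarginFit, MarginModel, fit_margin

__all__ = ["PairFit", "two_stage_fit", "jackknife_variance", "FrankCopulaPairModel"]

_GRID_SIZE = 25
_XATOL = 1e-8


@dataclass
class PairFit:
    """Two-stage estimates for one taxon pair."""

    margin_i: MarginFit
    margin_j: MarginFit
    theta: float
    loglik_at_max: float
    loglik_at_null: float
    var_theta: Optional[float] = None
    var_theta_partial: bool = False
    at_boundary: bool = False
    theta_bound: float = THETA_MAX
    diagnostics: dict = field(default_factory=dict)


def _subset_model(model: Optional[MarginModel], keep: np.ndarray) -> Optional[MarginModel]:
    if model is None:
        return None

    def sub(d):
        return None if d is None else np.asarray(d)[keep]

    return MarginModel(
        design_p=sub(model.design_p),
        design_mu=sub(model.design_mu),
        design_phi=sub(model.design_phi),
        link_p=model.link_p,
        link_mu=model.link_mu,
        link_phi=model.link_phi,
    )


def _check_pair_preconditions(x_i, x_j):
    x_i = np.asarray(x_i, float)
    x_j = np.asarray(x_j, float)
    if x_i.shape != x_j.shape or x_i.ndim != 1:
        raise ValueError("x_i and x_j must be one-dimensional and paired")
    for name, x in (("x_i", x_i), ("x_j", x_j)):
        if int((x > 0).sum()) < 3:
            raise InsufficientDataError(
                f"{name} has fewer than 3 nonzero observations; the margin is not identifiable"
            )
    joint = int(((x_i > 0) & (x_j > 0)).sum())
    if joint == 0:
        raise InsufficientDataError(
            "taxa are mutually exclusive (no jointly nonzero observation); "
            "the dependence parameter is not estimable"
        )
    if joint == 1:
        raise InsufficientDataError(
            "only one jointly nonzero observation; dependence estimation is unstable"
        )
    return x_i, x_j


def optimize_theta(workspace: PairWorkspace, bound: float = THETA_MAX,
                   warm_start: Optional[float] = None) -> tuple[float, float]:
    """Maximize the profile log-likelihood over theta in [-bound, bound].

    Coarse grid scan plus bounded Brent refinement around the best grid cell;
    a warm start narrows the scan to a neighborhood of the previous optimum
    (used by jackknife replicates) while keeping the refinement identical.
    """
    neg = lambda t: -workspace.loglik(t)  # noqa: E731
    if warm_start is not None:
        lo = max(-bound, warm_start - 5.0)
        hi = min(bound, warm_start + 5.0)
        grid = np.linspace(lo, hi, 11)
    else:
        grid = np.linspace(-bound, bound, _GRID_SIZE)
    vals = np.array([neg(t) for t in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                   options={"xatol": _XATOL})
    theta, ll = float(res.x), -float(res.fun)
    # guard against the refinement interval clipping the optimum
    if vals[k] < -ll:
        theta, ll = float(grid[k]), float(-vals[k])
    return theta, ll


def two_stage_fit(x_i, x_j, model_i: Optional[MarginModel] = None,
                  model_j: Optional[MarginModel] = None, *,
                  theta_bound: float = THETA_MAX,
                  compute_variance: bool = False) -> PairFit:
    """Two-stage MLE of (gamma_i, gamma_j, theta) for one taxon pair.

    Stage 1: independent marginal fits. Stage 2: one-dimensional profile
    maximization over theta. Set ``compute_variance`` to also run the
    jackknife.
    """
    from .margins import clean_abundances

    x_i, x_j = _check_pair_preconditions(x_i, x_j)
    x_i = clean_abundances(x_i, "x_i")
    x_j = clean_abundances(x_j, "x_j")
    fit_i = fit_margin(x_i, model_i)
    fit_j = fit_margin(x_j, model_j)
    ws = PairWorkspace.build(x_i, x_j, fit_i, fit_j)
    theta, ll_max = optimize_theta(ws, theta_bound)
    ll_null = ws.loglik(0.0)
    if ll_null > ll_max:  # theta = 0 is interior; never report a worse optimum
        theta, ll_max = 0.0, ll_null
    fit = PairFit(
        margin_i=fit_i,
        margin_j=fit_j,
        theta=theta,
        loglik_at_max=ll_max,
        loglik_at_null=ll_null,
        at_boundary=bool(abs(theta) >= theta_bound - 1e-6),
        theta_bound=theta_bound,
        diagnostics={"scenario_counts": ws.counts},
    )
    if compute_variance:
        fit.var_theta, fit.var_theta_partial = jackknife_variance(
            x_i, x_j, model_i, model_j, fit
        )
    return fit


def jackknife_variance(x_i, x_j, model_i: Optional[MarginModel],
                       model_j: Optional[MarginModel], fitted: PairFit,
                       *, scale: float = 1.0) -> tuple[float, bool]:
    """Leave-one-out jackknife variance of theta~.

    Both stages are re-run per replicate (warm-started at the full-data
    theta~). Replicates whose subset violates the estimability preconditions
    are skipped with a warning and the result is flagged partial. ``scale``
    multiplies the raw sum of squared deviations (the default matches the
    n^-1 * Xi~ usage: the sum itself is the variance of theta~).
    """
    x_i = np.asarray(x_i, float)
    x_j = np.asarray(x_j, float)
    n = x_i.size
    if n < 10:
        raise InsufficientDataError("jackknife variance needs at least 10 observations")
    devs = []
    skipped = 0
    for l in range(n):
        keep = np.ones(n, bool)
        keep[l] = False
        try:
            xi, xj = _check_pair_preconditions(x_i[keep], x_j[keep])
            fi = fit_margin(xi, _subset_model(model_i, keep))
            fj = fit_margin(xj, _subset_model(model_j, keep))
            ws = PairWorkspace.build(xi, xj, fi, fj)
            theta_l, _ = optimize_theta(ws, fitted.theta_bound, warm_start=fitted.theta)
        except (InsufficientDataError, ValueError):
            skipped += 1
            continue
        devs.append(theta_l - fitted.theta)
    if skipped:
        warnings.warn(
            f"{skipped} jackknife replicate(s) skipped (degenerate leave-one-out subset); "
            "variance is partial",
            stacklevel=2,
        )
    var = scale * float(np.sum(np.square(devs)))
    return var, skipped > 0


class FrankCopulaPairModel(BaseEstimator):
    """Frank-copula dependence model for one taxon pair (sklearn-style).

    Parameters
    ----------
    model_i, model_j : MarginModel or None
        Covariate designs and links for the two margins (None = intercept only).
    theta_bound : float
        Working bound for |theta|.
    compute_variance : bool
        Run the leave-one-out jackknife for ``var_theta_`` during ``fit``.

    Attributes (after ``fit``)
    --------------------------
    theta_ : two-stage estimate of the Frank dependence parameter
    margin_i_, margin_j_ : fitted ZIB margins
    loglik_ : profile log-likelihood at theta_
    var_theta_ : jackknife variance (if requested)
    """

    def __init__(self, model_i: Optional[MarginModel] = None,
                 model_j: Optional[MarginModel] = None,
                 theta_bound: float = THETA_MAX,
                 compute_variance: bool = False):
        self.model_i = model_i
        self.model_j = model_j
        self.theta_bound = theta_bound
        self.compute_variance = compute_variance

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of paired relative abundances")
        result = two_stage_fit(
            X[:, 0], X[:, 1], self.model_i, self.model_j,
            theta_bound=self.theta_bound, compute_variance=self.compute_variance,
        )
        self.result_ = result
        self.theta_ = result.theta
        self.margin_i_ = result.margin_i
        self.margin_j_ = result.margin_j
        self.loglik_ = result.loglik_at_max
        self.var_theta_ = result.var_theta
        self.n_features_in_ = 2
        return self

    def score(self, X, y=None) -> float:
        """Average joint log-density of held-out pairs under the fitted model."""
        from .joint import pair_log_density

        X = np.asarray(X, float)
        fi, fj = self.margin_i_, self.margin_j_
        ll = pair_log_density(
            X[:, 0], X[:, 1],
            (fi.p[0], fi.mu[0], fi.phi[0]),
            (fj.p[0], fj.mu[0], fj.phi[0]),
            self.theta_,
        )
        return float(np.mean(ll))

    def test_independence(self):
        """Rescaled likelihood-ratio test of theta = 0 for the fitted pair."""
        from .inference import lrt_from_pairfit

        return lrt_from_pairfit(self.result_)
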