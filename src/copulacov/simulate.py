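"""Synthetic paired and multivariate relative-abundance data.

Pairwise data are drawn by the Rosenblatt transform: U and B are independent
uniforms, V = C^{-1}_{v|u}(B | U; theta) inverts the Frank conditional
copula, and each uniform is pushed through the zero-inflated beta quantile
(0 below the atom mass, a beta quantile above it). Covariate-adjusted
variants draw a standard-normal confounder per sample and modulate the
presence-absence probability through a logistic model. A Gaussian-copula
variant supports misspecification experiments, and a multivariate
Gaussian-copula table with unit-sum rows emulates a full relative-abundance
dataset with known ground-truth dependent pairs.

Whole-dataset redo rules mirror the estimability preconditions: a dataset is
redrawn when either margin has fewer than three nonzero values, when the two
taxa are mutually exclusive, or when exactly one observation is jointly
nonzero. Redo is a truncation of the sampling distribution (acceptance
counts are reported in the returned diagnostics); ``redo_limit`` bounds the
attempts so degenerate configurations fail loudly instead of looping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import SimulationDegenerateError
from .frank import frank_inverse_conditional
from .margins import ZIBParams, zib_quantile

__all__ = [
    "SimulationConfig",
    "PairSample",
    "sample_pair",
    "sample_pair_covariate",
    "sample_gaussian_copula_pair",
    "sample_multivariate_table",
    "BETA_SETTINGS",
]

#: (mu, phi) settings of the no-covariate simulation grid.
BETA_SETTINGS = (
    (2 / 7, 7.0),
    (5 / 7, 7.0),
    (1 / 2, 4.0),
    (1 / 3, 9.0),
    (2 / 3, 9.0),
    (1 / 2, 6.0),
)

#: Logistic presence-absence coefficients of the covariate-adjusted grid
#: (low-low, low-high, high-high zero inflation).
LOGISTIC_SETTINGS = {
    "low-low": ((-0.5, 0.7), (-0.3, 0.4)),
    "low-high": ((-0.1, 0.7), (0.1, 0.4)),
    "high-high": ((0.5, 0.7), (0.8, 0.4)),
}

#: Beta-block parameters of the covariate-adjusted grid.
COVARIATE_MU = (np.exp(-0.7) / (1 + np.exp(-0.7)), np.exp(-1.0) / (1 + np.exp(-1.0)))
COVARIATE_PHI = float(np.exp(1.5))


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for one simulated taxon pair."""

    n: int
    theta: float
    gamma_i: ZIBParams
    gamma_j: ZIBParams
    seed: Optional[int] = None
    redo_limit: int = 1000
    copula: str = "frank"  # or "gaussian" (theta then read as a correlation)

    def __post_init__(self):
        if self.n < 4:
            raise ValueError("sample size must be at least 4")
        if self.redo_limit < 1:
            raise ValueError("redo_limit must be at least 1")
        if self.copula not in ("frank", "gaussian"):
            raise ValueError("copula must be 'frank' or 'gaussian'")


@dataclass
class PairSample:
    """One accepted paired dataset plus sampling diagnostics."""

    x_i: np.ndarray
    x_j: np.ndarray
    covariate_i: Optional[np.ndarray] = None
    covariate_j: Optional[np.ndarray] = None
    n_redo: int = 0
    diagnostics: dict = field(default_factory=dict)


def _acceptable(x_i: np.ndarray, x_j: np.ndarray) -> bool:
    nz_i = x_i > 0
    nz_j = x_j > 0
    if nz_i.sum() < 3 or nz_j.sum() < 3:
        return False
    return int((nz_i & nz_j).sum()) >= 2


def _quantile_per_sample(u: np.ndarray, p: np.ndarray, mu: float, phi: float) -> np.ndarray:
    """ZIB quantile with a per-sample atom mass (covariate-adjusted margins)."""
    g = ZIBParams(0.0, mu, phi)
    atom = u <= p
    rescaled = np.where(atom, 0.5, (u - p) / (1.0 - p))
    return np.where(atom, 0.0,
                    np.minimum(stats.beta.ppf(rescaled, g.shape_a, g.shape_b), 1 - 1e-12))


def _redo_loop(draw, redo_limit: int) -> PairSample:
    for attempt in range(redo_limit):
        sample = draw()
        if _acceptable(sample.x_i, sample.x_j):
            sample.n_redo = attempt
            sample.diagnostics["attempts"] = attempt + 1
            return sample
    raise SimulationDegenerateError(
        f"no acceptable dataset within {redo_limit} attempts; "
        "the configuration is degenerate (margins too sparse or mutually exclusive)"
    )


def sample_pair(config: Optional[SimulationConfig] = None, *,
                n: Optional[int] = None, theta: Optional[float] = None,
                gamma_i: Optional[ZIBParams] = None, gamma_j: Optional[ZIBParams] = None,
                rng: Optional[np.random.Generator] = None,
                redo_limit: int = 1000) -> PairSample:
    """Rosenblatt sampling of one Frank-copula ZIB pair."""
    if config is not None:
        n, theta, gamma_i, gamma_j = config.n, config.theta, config.gamma_i, config.gamma_j
        redo_limit = config.redo_limit
        if rng is None:
            rng = np.random.default_rng(config.seed)
        if config.copula == "gaussian":
            return sample_gaussian_copula_pair(
                n=n, correlation=theta, gamma_i=gamma_i, gamma_j=gamma_j,
                rng=rng, redo_limit=redo_limit)
    rng = rng if rng is not None else np.random.default_rng()

    def draw() -> PairSample:
        u = rng.uniform(1e-12, 1 - 1e-12, size=n)
        b = rng.uniform(1e-12, 1 - 1e-12, size=n)
        v = frank_inverse_conditional(b, u, theta)
        v = np.clip(v, 1e-12, 1 - 1e-12)
        return PairSample(x_i=zib_quantile(u, gamma_i), x_j=zib_quantile(v, gamma_j))

    return _redo_loop(draw, redo_limit)


def sample_pair_covariate(*, n: int, theta: float,
                          coef_i: Sequence[float] = LOGISTIC_SETTINGS["low-low"][0],
                          coef_j: Sequence[float] = LOGISTIC_SETTINGS["low-low"][1],
                          mu: Sequence[float] = COVARIATE_MU,
                          phi: float = COVARIATE_PHI,
                          rng: Optional[np.random.Generator] = None,
                          redo_limit: int = 1000) -> PairSample:
    """Frank-copula pair with a logistic covariate on each presence-absence probability.

    Per sample, Q_k ~ N(0, 1) and p_k = logit^{-1}(coef_k0 + coef_k1 * Q_k);
    the beta blocks are held at (mu_k, phi).
    """
    rng = rng if rng is not None else np.random.default_rng()
    ri0, ri1 = coef_i
    rj0, rj1 = coef_j

    def draw() -> PairSample:
        q_i = rng.standard_normal(n)
        q_j = rng.standard_normal(n)
        p_i = special.expit(ri0 + ri1 * q_i)
        p_j = special.expit(rj0 + rj1 * q_j)
        u = rng.uniform(1e-12, 1 - 1e-12, size=n)
        b = rng.uniform(1e-12, 1 - 1e-12, size=n)
        v = np.clip(frank_inverse_conditional(b, u, theta), 1e-12, 1 - 1e-12)
        return PairSample(
            x_i=_quantile_per_sample(u, p_i, mu[0], phi),
            x_j=_quantile_per_sample(v, p_j, mu[1], phi),
            covariate_i=q_i,
            covariate_j=q_j,
        )

    return _redo_loop(draw, redo_limit)


def sample_gaussian_copula_pair(*, n: int, correlation: float,
                                gamma_i: ZIBParams, gamma_j: ZIBParams,
                                rng: Optional[np.random.Generator] = None,
                                redo_limit: int = 1000) -> PairSample:
    """ZIB pair whose dependence follows a bivariate Gaussian copula.

    Used for robustness-to-misspecification experiments: the analysis model
    (Frank) differs from the generating copula.
    """
    if not -1.0 < correlation < 1.0:
        raise ValueError("correlation must lie in (-1, 1)")
    rng = rng if rng is not None else np.random.default_rng()
    chol = np.linalg.cholesky(np.array([[1.0, correlation], [correlation, 1.0]]))

    def draw() -> PairSample:
        z = rng.standard_normal((n, 2)) @ chol.T
        uv = np.clip(special.ndtr(z), 1e-12, 1 - 1e-12)
        return PairSample(x_i=zib_quantile(uv[:, 0], gamma_i),
                          x_j=zib_quantile(uv[:, 1], gamma_j))

    return _redo_loop(draw, redo_limit)


def _nearest_correlation(R: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped positive-definite repair, rescaled to unit diagonal."""
    vals, vecs = np.linalg.eigh(R)
    if vals.min() > eps:
        return R
    vals = np.clip(vals, eps, None)
    R2 = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(R2))
    return R2 / np.outer(d, d)


def sample_multivariate_table(*, n_taxa: int = 75, n_samples: int = 100,
                              dependency_graph: Optional[Sequence[tuple[int, int]]] = None,
                              true_pair_fraction: float = 0.10,
                              latent_correlation: float = 0.6,
                              seed: Optional[int] = None,
                              rng: Optional[np.random.Generator] = None,
                              p_range: tuple[float, float] = (0.1, 0.6)):
    """Multivariate Gaussian-copula table with ZIB margins and unit-sum rows.

    A subset of taxon pairs (``dependency_graph``, or a random
    ``true_pair_fraction`` of all pairs) carries latent correlation
    ``latent_correlation``; remaining pairs are latently uncorrelated. A
    non-positive-definite assembled matrix is repaired by eigenvalue clipping
    (warned), which slightly shrinks the realized correlations. Rows are
    normalized to unit sum over their nonzero entries, emulating the
    compositional constraint of relative-abundance data.

    Returns ``(table, truth)``: a samples x taxa DataFrame and a DataFrame of
    ground-truth dependent pairs (taxon_a, taxon_b, latent_correlation).
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = rng if rng is not None else np.random.default_rng(seed)
    all_pairs = [(i, j) for i in range(n_taxa) for j in range(i + 1, n_taxa)]
    if dependency_graph is None:
        k = int(round(true_pair_fraction * len(all_pairs)))
        idx = rng.choice(len(all_pairs), size=k, replace=False)
        dependency_graph = [all_pairs[i] for i in sorted(idx)]
    R = np.eye(n_taxa)
    for i, j in dependency_graph:
        R[i, j] = R[j, i] = latent_correlation
    vals = np.linalg.eigvalsh(R)
    if vals.min() <= 1e-6:
        warnings.warn(
            "assembled latent correlation matrix is not positive definite; "
            "repaired by eigenvalue clipping (realized correlations shrink)",
            stacklevel=2,
        )
        R = _nearest_correlation(R)
    chol = np.linalg.cholesky(R)
    # per-taxon ZIB margins: p ~ U(p_range), (mu, phi) from the standard grid
    p_taxa = rng.uniform(*p_range, size=n_taxa)
    beta_idx = rng.integers(0, len(BETA_SETTINGS), size=n_taxa)
    z = rng.standard_normal((n_samples, n_taxa)) @ chol.T
    U = np.clip(special.ndtr(z), 1e-12, 1 - 1e-12)
    X = np.empty_like(U)
    for t in range(n_taxa):
        mu_t, phi_t = BETA_SETTINGS[beta_idx[t]]
        X[:, t] = zib_quantile(U[:, t], ZIBParams(float(p_taxa[t]), mu_t, phi_t))
    row_sums = X.sum(axis=1)
    pos = row_sums > 0
    X[pos] = X[pos] / row_sums[pos, None]
    taxa = [f"taxon_{t:03d}" for t in range(n_taxa)]
    samples = [f"sample_{s:04d}" for s in range(n_samples)]
    table = pd.DataFrame(X, index=samples, columns=taxa)
    truth = pd.DataFrame(
        [(taxa[i], taxa[j], latent_correlation) for i, j in dependency_graph],
        columns=["taxon_a", "taxon_b", "latent_correlation"],
    )
    return table, truth
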