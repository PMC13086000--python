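"""Core four-parameter normal ogive (4PNO) model.

The 4PNO item response function gives the probability that examinee *i*
answers item *j* correctly as

    P_ij = g_j + (1 - s_j - g_j) * Phi(alpha_j * theta_i - beta_j),

where ``Phi`` is the standard normal CDF, ``alpha_j > 0`` is the item slope
(discrimination), ``beta_j`` the threshold (difficulty on the probit scale),
``g_j`` the lower asymptote (guessing / false endorsement) and ``s_j`` the
upper-asymptote shortfall (slipping / under-reporting).  Constraining
``s = 0`` yields the 3PNO model and ``g = s = 0`` the 2PNO model.

Sampling operates on an unconstrained parameterization

    alpha* = ln(alpha),  gamma = logit(g),  varsigma = logit(s),

with independent normal priors on (theta, alpha*, beta, gamma, varsigma).
Prior variances here are *variances*, not standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, log_ndtr, logit, ndtr

__all__ = [
    "PROB_FLOOR",
    "ResponseMatrix",
    "ItemParameters",
    "PriorSpec",
    "irf",
    "probability_surface",
    "log_likelihood",
    "item_log_posterior",
    "ability_log_posterior",
    "item_gradient",
    "ability_gradient",
    "constrain_submodel",
    "n_free_parameters",
    "MODEL_TAGS",
]

#: probabilities are clamped to [PROB_FLOOR, 1 - PROB_FLOOR] before any
#: logarithm or division; the likelihood and score divide by P(1 - P).
PROB_FLOOR = 1e-12

MODEL_TAGS = ("2pno", "3pno", "4pno")

_phi = lambda x: np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)  # noqa: E731


def _clamp(p):
    return np.clip(p, PROB_FLOOR, 1.0 - PROB_FLOOR)


@dataclass(frozen=True)
class ResponseMatrix:
    """An I x J matrix of dichotomous responses.

    Every entry must be exactly 0 or 1; missing values are rejected at
    construction (the model here has no missing-data mechanism).
    """

    data: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise ValueError("response matrix must be 2-dimensional")
        if arr.shape[0] < 2 or arr.shape[1] < 1:
            raise ValueError(
                f"need at least 2 examinees and 1 item, got shape {arr.shape}"
            )
        if not np.isfinite(arr.astype(float)).all():
            raise ValueError("response matrix contains non-finite entries")
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            bad = vals[~np.isin(vals, (0, 1))][0]
            raise ValueError(f"responses must be 0/1; found value {bad!r}")
        object.__setattr__(self, "data", np.ascontiguousarray(arr, dtype=np.int8))

    @property
    def n_examinees(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ItemParameters:
    """Item parameters for J items, stored on the natural scale.

    ``alpha`` must be positive and ``g``, ``s`` must lie strictly inside
    (0, 1) unless they are structurally fixed to 0 by a constrained
    submodel (2PNO/3PNO), in which case exact zeros are allowed.
    """

    alpha: np.ndarray
    beta: np.ndarray
    g: np.ndarray
    s: np.ndarray

    def __post_init__(self):
        for name in ("alpha", "beta", "g", "s"):
            object.__setattr__(
                self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            )
        J = self.alpha.shape[0]
        if not all(getattr(self, n).shape == (J,) for n in ("beta", "g", "s")):
            raise ValueError("alpha, beta, g, s must share one length")
        if not (np.isfinite(self.alpha).all() and np.isfinite(self.beta).all()):
            raise ValueError("non-finite item parameters")
        if (self.alpha <= 0).any():
            raise ValueError("alpha must be positive")
        if (self.g < 0).any() or (self.g >= 1).any() or (self.s < 0).any() or (self.s >= 1).any():
            raise ValueError("g and s must lie in [0, 1)")

    @property
    def n_items(self) -> int:
        return self.alpha.shape[0]

    # --- unconstrained (sampling-scale) views -------------------------------
    @property
    def alpha_star(self) -> np.ndarray:
        return np.log(self.alpha)

    @property
    def gamma(self) -> np.ndarray:
        return logit(_clamp(self.g))

    @property
    def varsigma(self) -> np.ndarray:
        return logit(_clamp(self.s))

    def unconstrained(self) -> np.ndarray:
        """(J, 4) array of rows (alpha*, beta, gamma, varsigma)."""
        return np.column_stack(
            [self.alpha_star, self.beta, self.gamma, self.varsigma]
        )

    @classmethod
    def from_unconstrained(cls, w: np.ndarray) -> "ItemParameters":
        w = np.atleast_2d(np.asarray(w, dtype=float))
        if w.shape[1] != 4:
            raise ValueError("expected (J, 4) unconstrained parameters")
        return cls(
            alpha=np.exp(w[:, 0]),
            beta=w[:, 1],
            g=expit(w[:, 2]),
            s=expit(w[:, 3]),
        )


@dataclass(frozen=True)
class PriorSpec:
    """Independent normal priors on the sampling (unconstrained) scale.

    Each entry is a ``(mean, variance)`` pair.  The defaults are the
    educational-scenario priors: ln(alpha) ~ N(0, 0.5), beta ~ N(0, 2),
    gamma, varsigma ~ N(-1.39, 0.5) (so the implied prior guess for g and
    s centres near invlogit(-1.39) = 0.20) and theta ~ N(0, 1).
    """

    theta: tuple[float, float] = (0.0, 1.0)
    alpha_star: tuple[float, float] = (0.0, 0.5)
    beta: tuple[float, float] = (0.0, 2.0)
    gamma: tuple[float, float] = (-1.39, 0.5)
    varsigma: tuple[float, float] = (-1.39, 0.5)

    def __post_init__(self):
        for name in ("theta", "alpha_star", "beta", "gamma", "varsigma"):
            mu, var = getattr(self, name)
            if not (np.isfinite(mu) and np.isfinite(var) and var > 0):
                raise ValueError(f"prior {name}: variance must be finite and > 0")

    @classmethod
    def educational(cls) -> "PriorSpec":
        return cls()

    @classmethod
    def psychological(cls) -> "PriorSpec":
        """Less informative asymptote priors: gamma, varsigma ~ N(-1.61, 0.8)."""
        return cls(gamma=(-1.61, 0.8), varsigma=(-1.61, 0.8))

    def item_means(self) -> np.ndarray:
        return np.array(
            [self.alpha_star[0], self.beta[0], self.gamma[0], self.varsigma[0]]
        )

    def item_variances(self) -> np.ndarray:
        return np.array(
            [self.alpha_star[1], self.beta[1], self.gamma[1], self.varsigma[1]]
        )


# --------------------------------------------------------------------------
# response function and likelihood
# --------------------------------------------------------------------------

def probability_surface(theta, items: ItemParameters):
    """Return (P*, P) for all examinee/item pairs: P* = Phi(a*th - b)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    eta = np.outer(theta, items.alpha) - items.beta
    p_star = ndtr(eta)
    p = items.g + (1.0 - items.s - items.g) * p_star
    return p_star, p


def irf(theta_i, item: ItemParameters):
    """4PNO item response function P = g + (1 - s - g) Phi(alpha*theta - beta)."""
    theta_i = np.asarray(theta_i, dtype=float)
    if not np.all(np.isfinite(theta_i)):
        raise ValueError("theta must be finite")
    eta = item.alpha * theta_i - item.beta
    return item.g + (1.0 - item.s - item.g) * ndtr(eta)


def log_likelihood(Y: ResponseMatrix | np.ndarray, theta, items: ItemParameters) -> float:
    """Joint Bernoulli log-likelihood sum_ij [y ln P + (1-y) ln(1-P)]."""
    y = Y.data if isinstance(Y, ResponseMatrix) else np.asarray(Y)
    _, p = probability_surface(theta, items)
    p = _clamp(p)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def _normal_logpdf(x, mu, var):
    return -0.5 * np.log(2.0 * np.pi * var) - 0.5 * (x - mu) ** 2 / var


def _item_block_loglik(w: np.ndarray, theta: np.ndarray, y_col: np.ndarray,
                       npar: int) -> float:
    alpha = np.exp(w[0])
    g = expit(w[2]) if npar >= 3 else 0.0
    s = expit(w[3]) if npar >= 4 else 0.0
    p_star = ndtr(alpha * theta - w[1])
    p = _clamp(g + (1.0 - s - g) * p_star)
    return float(np.sum(y_col * np.log(p) + (1 - y_col) * np.log1p(-p)))


def item_log_posterior(y_col, theta, w, prior: PriorSpec, model_tag: str = "4pno") -> float:
    """Log posterior (up to a constant) of one item's unconstrained block.

    ``w`` is the length-4 unconstrained vector (alpha*, beta, gamma,
    varsigma); for 2PNO/3PNO the fixed trailing entries are ignored in both
    likelihood and prior.
    """
    w = np.asarray(w, dtype=float)
    theta = np.asarray(theta, dtype=float)
    y_col = np.asarray(y_col)
    npar = n_free_parameters(model_tag)
    ll = _item_block_loglik(w, theta, y_col, npar)
    mus, vars_ = prior.item_means(), prior.item_variances()
    lp = float(np.sum(_normal_logpdf(w[:npar], mus[:npar], vars_[:npar])))
    return ll + lp


def ability_log_posterior(y_row, theta_i: float, items: ItemParameters,
                          prior: PriorSpec) -> float:
    """Log posterior of one examinee's ability given the item parameters."""
    y_row = np.asarray(y_row)
    p_star = ndtr(items.alpha * theta_i - items.beta)
    p = _clamp(items.g + (1.0 - items.s - items.g) * p_star)
    ll = float(np.sum(y_row * np.log(p) + (1 - y_row) * np.log1p(-p)))
    mu, var = prior.theta
    return ll + float(_normal_logpdf(theta_i, mu, var))


# --------------------------------------------------------------------------
# direct (observed-data) gradients on the unconstrained scale
# --------------------------------------------------------------------------

def item_gradient(y_col, theta, w, prior: PriorSpec, model_tag: str = "4pno") -> np.ndarray:
    """Score of the item-block log posterior w.r.t. (alpha*, beta, gamma, varsigma).

    The data term is sum_i (y - P) / (P(1-P)) * dP/d(param), with the chain
    rule carrying the likelihood through the transforms.  Returns a vector
    of the free-parameter length (2, 3 or 4).
    """
    w = np.asarray(w, dtype=float)
    theta = np.asarray(theta, dtype=float)
    y_col = np.asarray(y_col, dtype=float)
    npar = n_free_parameters(model_tag)

    alpha = np.exp(w[0])
    g = expit(w[2]) if npar >= 3 else 0.0
    s = expit(w[3]) if npar >= 4 else 0.0
    eta = alpha * theta - w[1]
    p_star = ndtr(eta)
    p = _clamp(g + (1.0 - s - g) * p_star)
    dens = _phi(eta)
    resid = (y_col - p) / (p * (1.0 - p))
    span = 1.0 - s - g

    grad = np.empty(npar)
    grad[0] = np.sum(resid * span * theta * alpha * dens)
    grad[1] = -np.sum(resid * span * dens)
    if npar >= 3:
        grad[2] = np.sum(resid * (1.0 - p_star) * g * (1.0 - g))
    if npar >= 4:
        grad[3] = -np.sum(resid * p_star * s * (1.0 - s))

    mus, vars_ = prior.item_means(), prior.item_variances()
    grad -= (w[:npar] - mus[:npar]) / vars_[:npar]
    return grad


def ability_gradient(y_row, theta_i: float, items: ItemParameters,
                     prior: PriorSpec) -> float:
    """Score of one examinee's log posterior w.r.t. theta_i."""
    y_row = np.asarray(y_row, dtype=float)
    eta = items.alpha * theta_i - items.beta
    p_star = ndtr(eta)
    span = 1.0 - items.s - items.g
    p = _clamp(items.g + span * p_star)
    resid = (y_row - p) / (p * (1.0 - p))
    mu, var = prior.theta
    return float(np.sum(resid * span * items.alpha * _phi(eta)) - (theta_i - mu) / var)


# --------------------------------------------------------------------------
# constrained submodels
# --------------------------------------------------------------------------

def n_free_parameters(model_tag: str) -> int:
    """Free item parameters per item: 2 (2PNO), 3 (3PNO) or 4 (4PNO)."""
    try:
        return {"2pno": 2, "3pno": 3, "4pno": 4}[model_tag.lower()]
    except KeyError:
        raise ValueError(f"unknown model tag {model_tag!r}; expected one of {MODEL_TAGS}")


def constrain_submodel(model_tag: str, items: ItemParameters) -> ItemParameters:
    """Apply the submodel constraint: s = 0 (3PNO) or g = s = 0 (2PNO)."""
    npar = n_free_parameters(model_tag)
    if npar == 4:
        return items
    zeros = np.zeros(items.n_items)
    if npar == 3:
        return replace(items, s=zeros)
    return replace(items, g=zeros, s=zeros.copy())
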