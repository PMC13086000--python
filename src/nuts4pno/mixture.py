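"""Mixture-modeling reformulation of the 4PNO model.

A latent indicator z_ij ~ Bernoulli(P*_ij) encodes whether examinee i
"knows" item j.  Given z, the response is Bernoulli(1 - s_j) when z = 1
and Bernoulli(g_j) when z = 0, which reproduces the 4PNO marginal
response probability.  MMNUTS replaces the observed-data score with the
expected complete-data score, evaluated at the posterior responsibility

    z^E = E[z | y, theta, items]
        = y * (1 - s) P* / P  +  (1 - y) * s P* / (1 - P).

Because z^E is the exact conditional expectation, the expected score
equals the observed-data score (Fisher identity), so the mixture
gradients target the same posterior as the direct ones.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, ndtr

from .model import PROB_FLOOR, ItemParameters, PriorSpec, n_free_parameters

__all__ = [
    "expected_z",
    "complete_data_loglik",
    "mm_item_gradient",
    "mm_ability_gradient",
]

_phi = lambda x: np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)  # noqa: E731


def _clamp(p):
    return np.clip(p, PROB_FLOOR, 1.0 - PROB_FLOOR)


def expected_z(y, p_star, p, g, s):
    """Posterior responsibility that the examinee knows the item.

    Vectorized over any broadcastable shapes.  Degenerates to ``y`` when
    g = s = 0 (the indicator is then observed).
    """
    y = np.asarray(y, dtype=float)
    p = _clamp(np.asarray(p, dtype=float))
    p_star = np.asarray(p_star, dtype=float)
    s = np.asarray(s, dtype=float)
    return y * (1.0 - s) * p_star / p + (1.0 - y) * s * p_star / (1.0 - p)


def complete_data_loglik(y, z, theta, items: ItemParameters) -> float:
    """Complete-data log-likelihood ln L(theta, W | Y, Z).

    ``z`` may be the hard indicators or their expectations; each cell
    contributes  z ln P* + (1-z) ln(1-P*) + y(1-z) ln g
    + (1-y)(1-z) ln(1-g) + (1-y) z ln s + y z ln(1-s).
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if (z < 0).any() or (z > 1).any():
        raise ValueError("z values must lie in [0, 1]")
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    eta = np.outer(theta, items.alpha) - items.beta
    p_star = _clamp(ndtr(eta))
    g = _clamp(items.g)
    s = _clamp(items.s)
    terms = (
        z * np.log(p_star)
        + (1 - z) * np.log1p(-p_star)
        + y * (1 - z) * np.log(g)
        + (1 - y) * (1 - z) * np.log1p(-g)
        + (1 - y) * z * np.log(s)
        + y * z * np.log1p(-s)
    )
    return float(np.sum(terms))


def _responsibility_col(y_col, theta, alpha, beta, g, s):
    p_star = ndtr(alpha * theta - beta)
    p = _clamp(g + (1.0 - s - g) * p_star)
    return p_star, expected_z(y_col, p_star, p, g, s)


def mm_item_gradient(y_col, theta, w, prior: PriorSpec, model_tag: str = "4pno",
                     z_e: np.ndarray | None = None) -> np.ndarray:
    """Expected-score gradient of one item block on the unconstrained scale.

    By default the responsibility z^E is recomputed from the current
    (theta, w) before the gradient is assembled, which is what makes the
    expected score equal the direct score at every point.  Passing ``z_e``
    freezes the responsibilities instead (e.g. held fixed across the
    leapfrog steps of one iteration, for fidelity experiments); the frozen
    gradient is then only an approximation of the posterior score.
    """
    w = np.asarray(w, dtype=float)
    theta = np.asarray(theta, dtype=float)
    y_col = np.asarray(y_col, dtype=float)
    npar = n_free_parameters(model_tag)

    alpha = np.exp(w[0])
    g = expit(w[2]) if npar >= 3 else 0.0
    s = expit(w[3]) if npar >= 4 else 0.0
    if z_e is None:
        p_star, z_e = _responsibility_col(y_col, theta, alpha, w[1], g, s)
    else:
        z_e = np.asarray(z_e, dtype=float)
        p_star = ndtr(alpha * theta - w[1])
    p_star_c = _clamp(p_star)
    ratio = (z_e - p_star) / (p_star_c * (1.0 - p_star_c))
    dens = _phi(alpha * theta - w[1])

    grad = np.empty(npar)
    grad[0] = np.sum(ratio * alpha * theta * dens)
    grad[1] = -np.sum(ratio * dens)
    if npar >= 3:
        grad[2] = np.sum((y_col - g) * (1.0 - z_e))
    if npar >= 4:
        grad[3] = np.sum((1.0 - y_col - s) * z_e)

    mus, vars_ = prior.item_means(), prior.item_variances()
    grad -= (w[:npar] - mus[:npar]) / vars_[:npar]
    return grad


def mm_ability_gradient(y_row, theta_i: float, items: ItemParameters,
                        prior: PriorSpec,
                        z_e: np.ndarray | None = None) -> float:
    """Expected-score gradient of one ability parameter.

    ``z_e`` freezes the responsibilities as in :func:`mm_item_gradient`.
    """
    y_row = np.asarray(y_row, dtype=float)
    eta = items.alpha * theta_i - items.beta
    p_star = ndtr(eta)
    p = _clamp(items.g + (1.0 - items.s - items.g) * p_star)
    if z_e is None:
        z_e = expected_z(y_row, p_star, p, items.g, items.s)
    p_star_c = _clamp(p_star)
    ratio = (z_e - p_star) / (p_star_c * (1.0 - p_star_c))
    mu, var = prior.theta
    return float(np.sum(ratio * items.alpha * _phi(eta)) - (theta_i - mu) / var)
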