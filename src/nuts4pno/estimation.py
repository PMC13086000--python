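"""Fit orchestration, convergence diagnostics and model comparison.

Multi-chain NUTS/MMNUTS fits are seeded from classical-test-theory (CTT)
statistics mapped to the sampling scale, monitored with the Gelman-Rubin
potential scale reduction factor, and summarized by posterior means and
standard deviations on the natural parameter scale.  Model comparison
uses a marginal log-likelihood (items fixed at their posterior means,
abilities integrated over their standard-normal prior by Gauss-Hermite
quadrature) together with AIC, BIC and likelihood-ratio tests between the
nested 2PNO/3PNO/4PNO models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtri
from scipy.special import logsumexp

from . import _engine
from .model import (
    ItemParameters,
    PriorSpec,
    ResponseMatrix,
    constrain_submodel,
    n_free_parameters,
    probability_surface,
)

__all__ = [
    "ChainSummary",
    "FitResult",
    "ModelFitResult",
    "RecoveryMetrics",
    "ctt_initial_values",
    "fit",
    "gelman_rubin",
    "recovery_metrics",
    "marginal_loglik",
    "information_criteria",
    "lr_test",
    "dichotomize",
]

SAMPLER_TAGS = ("nuts", "mmnuts")

#: fraction of examinees in the low/high extreme groups used by the CTT
#: guessing / slipping starting values (classical 27% convention)
EXTREME_GROUP_FRACTION = 0.27

_GH_ORDER = 61


# --------------------------------------------------------------------------
# initial values
# --------------------------------------------------------------------------

def ctt_centers(Y: ResponseMatrix, prior: PriorSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """CTT-based centers on the sampling scale.

    Returns ``(w_center, theta_center)`` where ``w_center`` is (J, 4) rows
    of (alpha*, beta, gamma, varsigma) and ``theta_center`` is (I,).

    Per item: the correct rate maps to the threshold via -ndtri(p), the
    item-total Pearson correlation to the log-slope via ln(max(0.3, 2r)),
    the bottom-27%-group correct rate to gamma and the top-27%-group error
    rate to varsigma through the logit.  Per examinee the mean score rate
    maps through ndtri.  Rates are clipped to [0.01, 0.99] and
    correlations to [0.05, 0.99] first.  Items with zero response variance
    fall back to the prior means with a warning.
    """
    prior = prior or PriorSpec()
    y = Y.data.astype(float)
    I, J = y.shape
    total = y.sum(axis=1)
    order = np.argsort(total, kind="stable")
    n_grp = max(1, int(round(EXTREME_GROUP_FRACTION * I)))
    low, high = order[:n_grp], order[-n_grp:]

    p = np.clip(y.mean(axis=0), 0.01, 0.99)
    low_rate = np.clip(y[low].mean(axis=0), 0.01, 0.99)
    high_err = np.clip(1.0 - y[high].mean(axis=0), 0.01, 0.99)

    w = np.empty((J, 4))
    degenerate = (y.std(axis=0) == 0.0)
    for j in range(J):
        if degenerate[j]:
            warnings.warn(
                f"item {j}: zero response variance; using prior-mean initials",
                stacklevel=2,
            )
            w[j] = [prior.alpha_star[0], prior.beta[0], prior.gamma[0],
                    prior.varsigma[0]]
            continue
        r = np.corrcoef(y[:, j], total)[0, 1]
        r = np.clip(r if np.isfinite(r) else 0.05, 0.05, 0.99)
        w[j, 0] = np.log(max(0.3, 2.0 * r))
        w[j, 1] = -ndtri(p[j])
        w[j, 2] = logit(low_rate[j])
        w[j, 3] = logit(high_err[j])

    theta_center = ndtri(np.clip(y.mean(axis=1), 0.01, 0.99))
    return w, theta_center


def ctt_initial_values(Y: ResponseMatrix, n_chains: int,
                       rng: np.random.Generator,
                       prior: PriorSpec | None = None,
                       ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-chain initial values: CTT centers jittered by unit-SD noise.

    All chains share the same transformed centers; the chain-specific
    draws make starting points distinct, which the Gelman-Rubin diagnostic
    requires.
    """
    w_c, th_c = ctt_centers(Y, prior)
    out = []
    for _ in range(n_chains):
        out.append((w_c + rng.standard_normal(w_c.shape),
                    th_c + rng.standard_normal(th_c.shape)))
    return out


# --------------------------------------------------------------------------
# diagnostics and recovery metrics
# --------------------------------------------------------------------------

def gelman_rubin(chains: np.ndarray) -> float | np.ndarray:
    """Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape (m, n) or (m, n, ...) with m >= 2 equal-length
    chains of length n >= 2.  Computes sqrt(((n-1)/n W + B/n) / W) with W
    the mean within-chain variance and B/n the variance of chain means.
    Zero within-chain variance yields ``inf``.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim < 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 chains of length >= 2")
    W = x.var(axis=1, ddof=1).mean(axis=0)
    B_over_n = x.mean(axis=1).var(axis=0, ddof=1)
    n = x.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(((n - 1) / n * W + B_over_n) / W)
        rhat = np.where(W > 0, rhat, np.inf)
    return float(rhat) if rhat.ndim == 0 else rhat


@dataclass(frozen=True)
class RecoveryMetrics:
    """Bias, RMSE and averaged posterior SD across replications."""

    bias: np.ndarray
    rmse: np.ndarray
    psd: np.ndarray
    n_replications: int


def recovery_metrics(estimates: np.ndarray, truth: np.ndarray,
                     posterior_sds: np.ndarray | None = None) -> RecoveryMetrics:
    """Replication-wise recovery summaries.

    ``estimates`` stacks R replication point estimates along axis 0;
    ``truth`` is the common true value.  bias = mean error,
    RMSE = sqrt(mean squared error), PSD = mean posterior SD (all across
    replications, elementwise otherwise).
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape[0] < 1:
        raise ValueError("need at least one replication")
    err = est - tru
    bias = err.mean(axis=0)
    rmse = np.sqrt((err ** 2).mean(axis=0))
    psd = (np.asarray(posterior_sds, dtype=float).mean(axis=0)
           if posterior_sds is not None else np.full_like(bias, np.nan))
    return RecoveryMetrics(bias=bias, rmse=rmse, psd=psd,
                           n_replications=est.shape[0])


# --------------------------------------------------------------------------
# model comparison
# --------------------------------------------------------------------------

def marginal_loglik(Y: ResponseMatrix | np.ndarray, items: ItemParameters,
                    model_tag: str = "4pno") -> float:
    """Marginal log-likelihood with abilities integrated out.

    sum_i ln int prod_j P^y (1-P)^(1-y) dPhi(theta), with the ability
    prior N(0, 1) and fixed-order (61) Gauss-Hermite quadrature; the inner
    sum is log-sum-exp stabilized.
    """
    y = Y.data if isinstance(Y, ResponseMatrix) else np.asarray(Y)
    items = constrain_submodel(model_tag, items)
    if items.n_items == 0 or y.shape[1] == 0:
        return 0.0
    nodes, weights = np.polynomial.hermite.hermgauss(_GH_ORDER)
    theta_grid = np.sqrt(2.0) * nodes
    log_w = np.log(weights) - 0.5 * np.log(np.pi)
    _, p = probability_surface(theta_grid, items)      # (K, J)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    log_p, log_q = np.log(p), np.log1p(-p)
    # (I, K) per-examinee conditional log-likelihood on the grid
    ll = y @ log_p.T + (1 - y) @ log_q.T
    return float(np.sum(logsumexp(ll + log_w, axis=1)))


@dataclass(frozen=True)
class ModelFitResult:
    """Fit statistics of one model: AIC = -2 LL + 2p, BIC = -2 LL + p ln I."""

    model_tag: str
    loglik: float
    n_params: int
    n_examinees: int
    aic: float = field(init=False)
    bic: float = field(init=False)
    lr_chisq: float | None = None
    lr_df: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "aic", -2.0 * self.loglik + 2.0 * self.n_params)
        object.__setattr__(
            self, "bic", -2.0 * self.loglik + self.n_params * np.log(self.n_examinees)
        )


def information_criteria(loglik: float, n_params: int, n_examinees: int,
                         model_tag: str = "4pno") -> ModelFitResult:
    return ModelFitResult(model_tag=model_tag, loglik=loglik,
                          n_params=n_params, n_examinees=n_examinees)


def lr_test(fit_big: ModelFitResult, fit_small: ModelFitResult) -> tuple[float, int]:
    """Likelihood-ratio chi-square and df between two nested model fits."""
    order = {"2pno": 2, "3pno": 3, "4pno": 4}
    if fit_big.model_tag not in order or fit_small.model_tag not in order:
        raise ValueError("lr_test expects 2pno/3pno/4pno fits")
    if order[fit_big.model_tag] <= order[fit_small.model_tag]:
        raise ValueError("models are not nested in the stated order")
    if fit_big.n_examinees != fit_small.n_examinees:
        raise ValueError("fits are on different data")
    chisq = 2.0 * (fit_big.loglik - fit_small.loglik)
    df = fit_big.n_params - fit_small.n_params
    return chisq, df


def dichotomize(raw: np.ndarray) -> ResponseMatrix:
    """Recode ordered frequency categories: 0 ('never') -> 0, >= 1 -> 1."""
    arr = np.asarray(raw)
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("raw responses must be numeric")
    if (arr < 0).any():
        raise ValueError("negative response categories are not allowed")
    return ResponseMatrix((arr >= 1).astype(np.int8))


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainSummary:
    """Posterior mean/SD and R-hat per parameter from a multi-chain run.

    Item arrays are (J, 4) on the natural (alpha, beta, g, s) scale; fixed
    submodel parameters carry zeros and R-hat 1.
    """

    item_mean: np.ndarray
    item_sd: np.ndarray
    item_rhat: np.ndarray
    theta_mean: np.ndarray
    theta_sd: np.ndarray
    theta_rhat: np.ndarray
    n_chains: int
    n_draws: int

    @property
    def rhat_max(self) -> float:
        return float(np.max(self.item_rhat))


@dataclass(frozen=True)
class FitResult:
    """A fitted 2/3/4PNO model."""

    model_tag: str
    sampler: str
    summary: ChainSummary
    items: ItemParameters
    draws: np.ndarray           # (chains, kept, J, 4), natural scale
    n_divergent: int
    prior: PriorSpec
    seed: int
    chain_seeds: np.ndarray     # replay: per-chain RNG seeds
    final_item_step_sizes: np.ndarray   # (chains, J) frozen epsilons

    def item_table(self) -> pd.DataFrame:
        s = self.summary
        J = s.item_mean.shape[0]
        return pd.DataFrame({
            "item": np.arange(1, J + 1),
            "alpha_est": s.item_mean[:, 0], "alpha_se": s.item_sd[:, 0],
            "beta_est": s.item_mean[:, 1], "beta_se": s.item_sd[:, 1],
            "g_est": s.item_mean[:, 2], "g_se": s.item_sd[:, 2],
            "s_est": s.item_mean[:, 3], "s_se": s.item_sd[:, 3],
            "rhat_max": s.item_rhat.max(axis=1),
        })


def _natural_draws(draws_w: np.ndarray, npar: int) -> np.ndarray:
    nat = np.empty_like(draws_w)
    nat[..., 0] = np.exp(draws_w[..., 0])
    nat[..., 1] = draws_w[..., 1]
    nat[..., 2] = expit(draws_w[..., 2]) if npar >= 3 else 0.0
    nat[..., 3] = expit(draws_w[..., 3]) if npar >= 4 else 0.0
    return nat


def fit(Y: ResponseMatrix, model_tag: str = "4pno", sampler: str = "mmnuts",
        prior: PriorSpec | None = None, n_chains: int = 4, n_iter: int = 2000,
        seed: int = 0, max_depth: int = 10, delta_max: float = 100.0,
        target_accept: float = 0.8, sqrt_k_scaling: bool = True,
        initials: list[tuple[np.ndarray, np.ndarray]] | None = None,
        ) -> FitResult:
    """Fit a 2/3/4PNO model by block-wise NUTS or MMNUTS.

    Defaults follow the reference settings: 4 chains of K = 2000
    iterations, the first half discarded as warm-up (during which the
    per-block step sizes are dual-averaged toward acceptance 0.8),
    divergence threshold 100, CTT-based initial values jittered per chain.
    More than half of the retained item transitions diverging raises
    ``RuntimeError``.
    """
    if sampler not in SAMPLER_TAGS:
        raise ValueError(f"unknown sampler {sampler!r}; expected one of {SAMPLER_TAGS}")
    prior = prior or PriorSpec()
    npar = n_free_parameters(model_tag)
    warmup = n_iter // 2
    if n_iter < 4 or warmup < 1:
        raise ValueError("n_iter too small")

    master = np.random.default_rng(seed)
    if initials is None:
        initials = ctt_initial_values(Y, n_chains, master, prior)
    elif len(initials) != n_chains:
        raise ValueError("need one initial-value pair per chain")
    chain_seeds = np.random.SeedSequence(seed).generate_state(n_chains) % (2 ** 31)

    Yf = np.ascontiguousarray(Y.data, dtype=np.float64)
    YTf = np.ascontiguousarray(Yf.T)
    mu_item, var_item = prior.item_means(), prior.item_variances()
    mm = 1 if sampler == "mmnuts" else 0

    all_w = []
    th_means, th_vars = [], []
    eps_chains = []
    n_div = 0
    for c in range(n_chains):
        w0, th0 = initials[c]
        w0 = np.ascontiguousarray(w0, dtype=np.float64)
        if npar < 4:
            w0 = w0.copy()
            w0[:, npar:] = 0.0
        draws_w, th_mean, th_m2, eps_it, _, ndv = _engine.run_chain(
            Yf, YTf, np.ascontiguousarray(th0, dtype=np.float64), w0,
            mu_item, var_item, prior.theta[0], prior.theta[1],
            npar, mm, n_iter, warmup, max_depth, float(delta_max),
            float(target_accept), 1 if sqrt_k_scaling else 0,
            int(chain_seeds[c]),
        )
        all_w.append(draws_w)
        kept = draws_w.shape[0]
        th_means.append(th_mean)
        th_vars.append(th_m2 / max(kept - 1, 1))
        eps_chains.append(eps_it)
        n_div += int(ndv)

    kept = all_w[0].shape[0]
    if n_div > n_chains * kept * Y.n_items // 2:
        raise RuntimeError(
            f"{n_div} of {n_chains * kept * Y.n_items} retained item "
            "transitions diverged; the sampler failed on this posterior"
        )

    draws_w = np.stack(all_w)                       # (chains, kept, J, 4)
    nat = _natural_draws(draws_w, npar)
    flat = nat.reshape(-1, Y.n_items, 4)
    item_mean = flat.mean(axis=0)
    item_sd = flat.std(axis=0, ddof=1)
    item_rhat = np.ones((Y.n_items, 4))
    if n_chains >= 2:
        item_rhat[:, :npar] = gelman_rubin(nat[..., :npar])
    else:
        item_rhat[:, :npar] = np.nan

    th_means = np.stack(th_means)
    th_vars = np.stack(th_vars)
    theta_mean = th_means.mean(axis=0)
    second = (th_vars * (kept - 1) / kept + th_means ** 2).mean(axis=0)
    theta_sd = np.sqrt(np.maximum(second - theta_mean ** 2, 0.0)
                       * kept * n_chains / max(kept * n_chains - 1, 1))
    if n_chains >= 2:
        W = th_vars.mean(axis=0)
        B_over_n = th_means.var(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            theta_rhat = np.where(
                W > 0, np.sqrt(((kept - 1) / kept * W + B_over_n) / W), np.inf
            )
    else:
        theta_rhat = np.full(Y.n_examinees, np.nan)

    summary = ChainSummary(
        item_mean=item_mean, item_sd=item_sd, item_rhat=item_rhat,
        theta_mean=theta_mean, theta_sd=theta_sd, theta_rhat=theta_rhat,
        n_chains=n_chains, n_draws=kept,
    )
    items = ItemParameters(
        alpha=item_mean[:, 0], beta=item_mean[:, 1],
        g=item_mean[:, 2] if npar >= 3 else np.zeros(Y.n_items),
        s=item_mean[:, 3] if npar >= 4 else np.zeros(Y.n_items),
    )
    return FitResult(model_tag=model_tag, sampler=sampler, summary=summary,
                     items=items, draws=nat, n_divergent=n_div, prior=prior,
                     seed=seed, chain_seeds=chain_seeds,
                     final_item_step_sizes=np.stack(eps_chains))


def model_fit(Y: ResponseMatrix, result: FitResult) -> ModelFitResult:
    """Marginal-likelihood fit statistics of a fitted model.

    The likelihood is evaluated at the item posterior means with abilities
    integrated over N(0, 1); the parameter count is the number of free
    item parameters (2J, 3J or 4J).
    """
    ll = marginal_loglik(Y, result.items, result.model_tag)
    p = n_free_parameters(result.model_tag) * Y.n_items
    return information_criteria(ll, p, Y.n_examinees, result.model_tag)


def compare_models(Y: ResponseMatrix, results: list[FitResult]) -> pd.DataFrame:
    """Fit-statistics table with LR tests of each submodel against the
    largest fitted model."""
    fits = {r.model_tag: model_fit(Y, r) for r in results}
    order = {"2pno": 2, "3pno": 3, "4pno": 4}
    biggest = max(fits.values(), key=lambda f: order[f.model_tag])
    rows = []
    for tag in sorted(fits, key=lambda t: order[t]):
        f = fits[tag]
        if order[tag] < order[biggest.model_tag]:
            chisq, df = lr_test(biggest, f)
        else:
            chisq, df = np.nan, 0
        rows.append({"model": tag, "loglik": f.loglik, "n_params": f.n_params,
                     "aic": f.aic, "bic": f.bic,
                     "lr_chisq": chisq, "lr_df": df})
    return pd.DataFrame(rows)
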