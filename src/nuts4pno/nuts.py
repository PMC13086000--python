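"""Block-wise No-U-Turn sampler (reference implementation).

A generic NUTS engine parameterized by a log-density-and-gradient
callback.  Each transition draws a fresh standard-normal momentum, sets a
log-scale slice level through an Exp(1) draw, and grows a trajectory by
recursive doubling (``build_tree``) until a U-turn, a divergence, or the
depth cap.  Step sizes are tuned by dual averaging toward a target
acceptance statistic during the warm-up half of the run and frozen
afterwards.

This module favours clarity over speed; the numba-compiled sampler in
``nuts4pno._engine`` reimplements the same algorithm for full-size item
response fits and is cross-checked against this one in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "NutsOptions",
    "PhaseState",
    "StepSizeState",
    "TreeResult",
    "leapfrog",
    "find_initial_epsilon",
    "sample_slice",
    "build_tree",
    "nuts_transition",
    "adapt_step_size",
    "nuts_sample",
    "run_block_sampler",
]

LogDensGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class NutsOptions:
    """Tuning constants of the sampler.

    ``delta_max`` is the energy-error bound beyond which tree growth is
    declared divergent (100 by default).  ``sqrt_k_scaling`` selects the
    dual-averaging shrinkage exponent sqrt(k)/0.05; the literal k/0.05
    variant is available for comparison.
    """

    max_depth: int = 10
    delta_max: float = 100.0
    target_accept: float = 0.8
    sqrt_k_scaling: bool = True
    max_epsilon_search: int = 50


@dataclass
class PhaseState:
    """Position/momentum pair with cached gradient and log density."""

    position: np.ndarray
    momentum: np.ndarray
    grad: np.ndarray
    logdens: float

    @property
    def xi(self) -> float:
        """Log density minus kinetic energy, the Hamiltonian's negative."""
        return self.logdens - 0.5 * float(self.momentum @ self.momentum)


@dataclass
class StepSizeState:
    """Per-block step size with dual-averaging accumulators."""

    epsilon: float
    iota: float
    epsilon_bar: float = 1.0
    H: float = 0.0
    k: int = 0

    def frozen(self) -> "StepSizeState":
        return StepSizeState(
            epsilon=self.epsilon_bar, iota=self.iota,
            epsilon_bar=self.epsilon_bar, H=self.H, k=self.k,
        )


@dataclass
class TreeResult:
    """Frontier states, proposal and stop/acceptance statistics of a subtree.

    ``stop`` ends trajectory growth (divergence or internal U-turn);
    ``diverged`` records specifically the energy-error condition.
    """

    minus: PhaseState
    plus: PhaseState
    proposal: PhaseState
    n_b: int
    stop: bool
    lam_a: float
    lam_b: float
    diverged: bool = False


def _evaluate(position: np.ndarray, lp_grad_fn: LogDensGrad) -> tuple[float, np.ndarray]:
    lp, grad = lp_grad_fn(position)
    if not np.isfinite(lp):
        lp = -np.inf
        grad = np.zeros_like(position)
    return float(lp), np.asarray(grad, dtype=float)


def leapfrog(state: PhaseState, epsilon, lp_grad_fn: LogDensGrad) -> PhaseState:
    """One leapfrog step: half momentum, full position, half momentum.

    A non-finite log density at the new position is flagged by
    ``logdens = -inf`` (a divergent state), never by raising.
    """
    eps = np.asarray(epsilon, dtype=float)
    r_half = state.momentum + 0.5 * eps * state.grad
    pos = state.position + eps * r_half
    lp, grad = _evaluate(pos, lp_grad_fn)
    r_new = r_half + 0.5 * eps * grad
    return PhaseState(pos, r_new, grad, lp)


def find_initial_epsilon(position: np.ndarray, lp_grad_fn: LogDensGrad,
                         rng: np.random.Generator,
                         options: NutsOptions | None = None) -> StepSizeState:
    """Find a reasonable initial step size by repeated doubling/halving.

    Starting from eps = 1 and a fresh momentum, the one-step acceptance
    ratio Omega = exp(xi1 - xi0) fixes the scaling direction
    rho = 2[Omega > 0.5] - 1 on the first probe; eps is then scaled by
    2^rho while Omega^rho > 2^(-rho).  The direction is frozen after the
    first probe so the search cannot oscillate around the crossing point.
    """
    options = options or NutsOptions()
    position = np.asarray(position, dtype=float)
    lp, grad = _evaluate(position, lp_grad_fn)
    momentum = rng.standard_normal(position.shape[0])
    start = PhaseState(position, momentum, grad, lp)
    xi0 = start.xi

    def one_step_dxi(eps):
        return leapfrog(start, eps, lp_grad_fn).xi - xi0

    eps = 1.0
    dxi = one_step_dxi(eps)
    rho = 1.0 if dxi > np.log(0.5) else -1.0
    for _ in range(options.max_epsilon_search):
        # Omega^rho > 2^-rho, compared in logs so Omega may underflow freely
        if not rho * dxi > -rho * np.log(2.0):
            break
        eps *= 2.0 ** rho
        dxi = one_step_dxi(eps)
    else:
        raise RuntimeError(
            "step-size search did not terminate within "
            f"{options.max_epsilon_search} doublings; target looks pathological"
        )
    return StepSizeState(epsilon=eps, iota=float(np.log(10.0 * eps)))


def sample_slice(xi0: float, rng: np.random.Generator) -> float:
    """Log-scale slice level u0 = xi0 - x with x ~ Exp(1).

    Equivalent to u ~ U[0, exp(xi0)] worked in logarithms.
    """
    return xi0 - rng.exponential()


def build_tree(direction: int, state: PhaseState, u0: float, xi0: float,
               depth: int, epsilon, lp_grad_fn: LogDensGrad,
               rng: np.random.Generator,
               options: NutsOptions | None = None) -> TreeResult:
    """Recursively double a trajectory segment of 2**depth leapfrog steps.

    Base case (depth 0): one leapfrog step of size ``direction * epsilon``
    from ``state``.  The leaf counts toward the slice-acceptable set when
    u0 < xi1, is divergent when xi1 <= u0 - delta_max, and contributes
    min(1, exp(xi1 - xi0)) to the acceptance-statistic accumulator.

    Recursive case: two half-depth subtrees grown in the same direction;
    the proposal of the second replaces the first's with probability
    n_b' / (n_b + n_b'), and the stop flag combines the subtree flags with
    the U-turn test on the merged span against both frontier momenta.
    """
    options = options or NutsOptions()
    if depth == 0:
        leaf = leapfrog(state, direction * np.asarray(epsilon, dtype=float), lp_grad_fn)
        xi1 = leaf.xi
        n_b = int(u0 < xi1)
        diverged = (u0 - options.delta_max) >= xi1
        lam_a = min(1.0, np.exp(min(xi1 - xi0, 0.0)))
        return TreeResult(leaf, leaf, leaf, n_b, bool(diverged), lam_a, 1.0,
                          bool(diverged))

    first = build_tree(direction, state, u0, xi0, depth - 1, epsilon,
                       lp_grad_fn, rng, options)
    if first.stop:
        return first
    grow_from = first.minus if direction == -1 else first.plus
    second = build_tree(direction, grow_from, u0, xi0, depth - 1, epsilon,
                        lp_grad_fn, rng, options)
    minus = second.minus if direction == -1 else first.minus
    plus = first.plus if direction == -1 else second.plus

    proposal = first.proposal
    total = first.n_b + second.n_b
    x = rng.random()
    if total > 0 and x < second.n_b / total:
        proposal = second.proposal

    span = plus.position - minus.position
    uturn = (span @ minus.momentum) < 0 or (span @ plus.momentum) < 0
    return TreeResult(
        minus, plus, proposal,
        total,
        bool(second.stop or uturn),
        first.lam_a + second.lam_a,
        first.lam_b + second.lam_b,
        first.diverged or second.diverged,
    )


def nuts_transition(position: np.ndarray, epsilon, lp_grad_fn: LogDensGrad,
                    rng: np.random.Generator,
                    options: NutsOptions | None = None,
                    ) -> tuple[np.ndarray, float, dict]:
    """One No-U-Turn transition from ``position``.

    Returns the new position, the acceptance statistic
    lambda_c = lam_a / lam_b accumulated over the whole transition, and a
    small info dict (tree depth reached, divergence flag).
    """
    options = options or NutsOptions()
    position = np.asarray(position, dtype=float)
    lp, grad = _evaluate(position, lp_grad_fn)
    momentum = rng.standard_normal(position.shape[0])
    start = PhaseState(position, momentum, grad, lp)
    xi0 = start.xi
    u0 = sample_slice(xi0, rng)

    minus = plus = start
    proposal = start
    n_a = 1
    lam_a_tot = 0.0
    lam_b_tot = 0.0
    depth = 0
    diverged = False
    while depth < options.max_depth:
        direction = -1 if rng.random() < 0.5 else 1
        frontier = minus if direction == -1 else plus
        tree = build_tree(direction, frontier, u0, xi0, depth, epsilon,
                          lp_grad_fn, rng, options)
        if direction == -1:
            minus = tree.minus
        else:
            plus = tree.plus
        x = rng.random()
        if not tree.stop and x < tree.n_b / n_a:
            proposal = tree.proposal
        n_a += tree.n_b
        lam_a_tot += tree.lam_a
        lam_b_tot += tree.lam_b
        depth += 1
        span = plus.position - minus.position
        uturn = (span @ minus.momentum) < 0 or (span @ plus.momentum) < 0
        if tree.stop or uturn:
            diverged = tree.diverged
            break

    lam_c = lam_a_tot / lam_b_tot if lam_b_tot > 0 else 0.0
    return proposal.position, lam_c, {"depth": depth, "diverged": diverged}


def adapt_step_size(state: StepSizeState, lambda_c: float,
                    options: NutsOptions | None = None) -> StepSizeState:
    """One dual-averaging update of the step size.

    With k the 1-based adaptation step, eta_a = 1/(k+10) and
    eta_b = k^(-0.75):

        H   <- (1 - eta_a) H + eta_a (target - lambda_c)
        eps <- exp(iota - sqrt(k)/0.05 * H)
        ln eps_bar <- (1 - eta_b) ln eps_bar + eta_b ln eps
    """
    options = options or NutsOptions()
    lam = min(max(lambda_c, 0.0), 1.0)
    k = state.k + 1
    eta_a = 1.0 / (k + 10.0)
    eta_b = k ** -0.75
    H = (1.0 - eta_a) * state.H + eta_a * (options.target_accept - lam)
    scale = (np.sqrt(k) if options.sqrt_k_scaling else k) / 0.05
    eps = float(np.exp(state.iota - scale * H))
    eps_bar = float(np.exp((1.0 - eta_b) * np.log(state.epsilon_bar)
                           + eta_b * np.log(eps)))
    return StepSizeState(epsilon=eps, iota=state.iota, epsilon_bar=eps_bar,
                         H=H, k=k)


def nuts_sample(lp_grad_fn: LogDensGrad, x0: np.ndarray, n_iter: int,
                rng: np.random.Generator,
                options: NutsOptions | None = None,
                warmup: int | None = None) -> np.ndarray:
    """Run a single-block NUTS chain and return post-warm-up draws.

    Warm-up defaults to the first half of ``n_iter``; the step size adapts
    during warm-up and is frozen at the dual-averaging mean afterwards.
    """
    options = options or NutsOptions()
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    warmup = n_iter // 2 if warmup is None else warmup
    step = find_initial_epsilon(x0, lp_grad_fn, rng, options)
    draws = np.empty((n_iter - warmup, x0.shape[0]))
    pos = x0
    for k in range(1, n_iter + 1):
        pos, lam_c, _ = nuts_transition(pos, step.epsilon, lp_grad_fn, rng, options)
        if k <= warmup:
            step = adapt_step_size(step, lam_c, options)
            if k == warmup:
                step = step.frozen()
        else:
            draws[k - warmup - 1] = pos
    return draws


def run_block_sampler(block_lp_grad, x0_blocks, n_iter: int, n_chains: int,
                      seed: int, options: NutsOptions | None = None,
                      warmup: int | None = None) -> list[list[np.ndarray]]:
    """Alternating block-wise NUTS over several blocks and chains.

    ``block_lp_grad(b, x_b, positions)`` must return the log posterior and
    gradient of block ``b`` at value ``x_b`` given the current positions of
    all blocks.  Each sweep updates the blocks in order; draws from the
    post-warm-up half are retained.  Returns
    ``draws[chain][block]`` arrays of shape (kept, dim_b).

    A block whose step-size search or every transition diverges raises
    ``RuntimeError`` with a diagnostic message.
    """
    options = options or NutsOptions()
    warmup = n_iter // 2 if warmup is None else warmup
    n_blocks = len(x0_blocks)
    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    all_draws: list[list[np.ndarray]] = []
    for chain in range(n_chains):
        rng = np.random.default_rng(seeds[chain])
        positions = [np.atleast_1d(np.asarray(x, dtype=float)).copy()
                     for x in x0_blocks]
        steps = []
        for b in range(n_blocks):
            fn = _bind_block(block_lp_grad, b, positions)
            steps.append(find_initial_epsilon(positions[b], fn, rng, options))
        kept = [np.empty((n_iter - warmup, positions[b].shape[0]))
                for b in range(n_blocks)]
        diverged_sweeps = 0
        for k in range(1, n_iter + 1):
            any_ok = False
            for b in range(n_blocks):
                fn = _bind_block(block_lp_grad, b, positions)
                new_pos, lam_c, info = nuts_transition(
                    positions[b], steps[b].epsilon, fn, rng, options)
                positions[b] = new_pos
                any_ok = any_ok or not info["diverged"]
                if k <= warmup:
                    steps[b] = adapt_step_size(steps[b], lam_c, options)
                    if k == warmup:
                        steps[b] = steps[b].frozen()
                else:
                    kept[b][k - warmup - 1] = new_pos
            diverged_sweeps = 0 if any_ok else diverged_sweeps + 1
            if diverged_sweeps >= 50:
                raise RuntimeError(
                    f"chain {chain}: all blocks diverged for 50 consecutive "
                    "sweeps; the target appears pathological"
                )
        all_draws.append(kept)
    return all_draws


def _bind_block(block_lp_grad, b, positions):
    def fn(x):
        return block_lp_grad(b, x, positions)
    return fn
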