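"""No-U-Turn Sampler with dual-averaging step-size and diagonal mass adaptation.

A self-contained NUTS implementation (slice-sampling tree variant) for
log-densities with analytic gradients.  The adaptation schedule follows the
usual warm-up layout: an initial fast interval tuning only the step size,
a sequence of doubling "slow" windows that estimate a diagonal mass matrix
from the warm-up draws, and a terminal fast interval.  Divergences are
flagged when the joint log-density drops by more than ``DELTA_MAX`` within
a trajectory.

Only ``numpy`` is required; determinism is guaranteed by the supplied
``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Tuple

import numpy as np

LogpGrad = Callable[[np.ndarray], Tuple[float, np.ndarray]]

DELTA_MAX = 1000.0  # divergence threshold on the joint log density


@dataclass
class _DualAveraging:
    """Nesterov dual averaging on log(step size) (gamma/t0/kappa defaults)."""

    mu: float
    target: float = 0.9
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    _t: int = 0
    _h_bar: float = 0.0
    _log_eps_bar: float = 0.0

    def update(self, accept_stat: float) -> float:
        self._t += 1
        eta = 1.0 / (self._t + self.t0)
        self._h_bar = (1 - eta) * self._h_bar + eta * (self.target - accept_stat)
        log_eps = self.mu - np.sqrt(self._t) / self.gamma * self._h_bar
        w = self._t ** (-self.kappa)
        self._log_eps_bar = w * log_eps + (1 - w) * self._log_eps_bar
        return float(np.exp(log_eps))

    @property
    def adapted_step(self) -> float:
        return float(np.exp(self._log_eps_bar))


@dataclass
class _Welford:
    """Running mean/variance accumulator for mass-matrix estimation."""

    dim: int
    n: int = 0
    mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    m2: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mean = np.zeros(self.dim)
        self.m2 = np.zeros(self.dim)

    def add(self, x: np.ndarray) -> None:
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (x - self.mean)

    def variance(self) -> np.ndarray:
        if self.n < 2:
            return np.ones(self.dim)
        var = self.m2 / (self.n - 1)
        # shrink toward a small constant, as is standard for warm-up estimates
        return var * (self.n / (self.n + 5.0)) + 1e-3 * (5.0 / (self.n + 5.0))


def _leapfrog(logp_grad, theta, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    theta = theta + eps * inv_mass * p
    logp, grad = logp_grad(theta)
    p = p + 0.5 * eps * grad
    return theta, p, logp, grad


def _joint(logp: float, p: np.ndarray, inv_mass: np.ndarray) -> float:
    return logp - 0.5 * float(np.dot(p * inv_mass, p))


def _find_initial_step(logp_grad, theta, rng, inv_mass) -> float:
    eps = 1.0
    logp, grad = logp_grad(theta)
    p = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    j0 = _joint(logp, p, inv_mass)
    _, p1, logp1, _ = _leapfrog(logp_grad, theta, p, grad, eps, inv_mass)
    j1 = _joint(logp1, p1, inv_mass)
    if not np.isfinite(j1):
        j1 = -np.inf
    direction = 1.0 if (j1 - j0) > np.log(0.5) else -1.0
    for _ in range(60):
        eps *= 2.0 ** direction
        _, p1, logp1, _ = _leapfrog(logp_grad, theta, p, grad, eps, inv_mass)
        j1 = _joint(logp1, p1, inv_mass) if np.isfinite(logp1) else -np.inf
        if direction * (j1 - j0) <= direction * np.log(0.5):
            break
    return eps


class _Tree:
    __slots__ = (
        "theta_minus", "p_minus", "grad_minus",
        "theta_plus", "p_plus", "grad_plus",
        "theta_prop", "logp_prop", "grad_prop",
        "n_valid", "keep_going", "accept_sum", "n_steps", "diverged",
    )


def _build_tree(logp_grad, theta, p, grad, log_u, direction, depth, eps,
                joint0, inv_mass, rng):
    """Recursively double the trajectory (slice-sampling NUTS)."""
    if depth == 0:
        theta1, p1, logp1, grad1 = _leapfrog(
            logp_grad, theta, p, grad, direction * eps, inv_mass)
        joint = _joint(logp1, p1, inv_mass) if np.isfinite(logp1) else -np.inf
        t = _Tree()
        t.theta_minus = t.theta_plus = t.theta_prop = theta1
        t.p_minus = t.p_plus = p1
        t.grad_minus = t.grad_plus = t.grad_prop = grad1
        t.logp_prop = logp1
        t.n_valid = int(log_u <= joint)
        t.diverged = (joint0 - joint) > DELTA_MAX or not np.isfinite(joint)
        t.keep_going = not t.diverged
        t.accept_sum = min(1.0, float(np.exp(min(0.0, joint - joint0))))
        t.n_steps = 1
        return t

    t = _build_tree(logp_grad, theta, p, grad, log_u, direction, depth - 1,
                    eps, joint0, inv_mass, rng)
    if t.keep_going:
        if direction == -1:
            t2 = _build_tree(logp_grad, t.theta_minus, t.p_minus, t.grad_minus,
                             log_u, direction, depth - 1, eps, joint0,
                             inv_mass, rng)
            t.theta_minus, t.p_minus, t.grad_minus = (
                t2.theta_minus, t2.p_minus, t2.grad_minus)
        else:
            t2 = _build_tree(logp_grad, t.theta_plus, t.p_plus, t.grad_plus,
                             log_u, direction, depth - 1, eps, joint0,
                             inv_mass, rng)
            t.theta_plus, t.p_plus, t.grad_plus = (
                t2.theta_plus, t2.p_plus, t2.grad_plus)
        total = t.n_valid + t2.n_valid
        if total > 0 and rng.random() < t2.n_valid / total:
            t.theta_prop = t2.theta_prop
            t.logp_prop = t2.logp_prop
            t.grad_prop = t2.grad_prop
        t.accept_sum += t2.accept_sum
        t.n_steps += t2.n_steps
        t.n_valid = total
        t.diverged = t.diverged or t2.diverged
        dtheta = t.theta_plus - t.theta_minus
        no_uturn = (np.dot(dtheta, inv_mass * t.p_minus) >= 0
                    and np.dot(dtheta, inv_mass * t.p_plus) >= 0)
        t.keep_going = t2.keep_going and no_uturn and not t.diverged
    return t


def _warmup_schedule(n_warmup: int):
    """(fast, slow-doubling windows, fast) boundaries a la Stan."""
    if n_warmup < 150:
        return [], n_warmup
    init_fast, term_fast, base_slow = 75, 50, 25
    slow_total = n_warmup - init_fast - term_fast
    boundaries = []
    pos, width = init_fast, base_slow
    while pos + width <= init_fast + slow_total:
        nxt = pos + width
        if nxt + 2 * width > init_fast + slow_total:
            nxt = init_fast + slow_total
        boundaries.append(nxt)
        pos = nxt
        width *= 2
    return boundaries, n_warmup


def sample_nuts(logp_grad: LogpGrad,
                theta0: np.ndarray,
                n_warmup: int,
                n_draws: int,
                rng: np.random.Generator,
                target_accept: float = 0.9,
                max_treedepth: int = 10):
    """Run a single NUTS chain.

    Returns ``(draws, stats)`` where ``draws`` has shape
    ``(n_draws, dim)`` (post-warm-up only) and ``stats`` records the number
    of divergent post-warm-up transitions, the adapted step size and the
    final diagonal of the inverse mass matrix.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    dim = theta.size
    inv_mass = np.ones(dim)
    logp, grad = logp_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_initial_step(logp_grad, theta, rng, inv_mass)
    da = _DualAveraging(mu=np.log(10.0 * eps), target=target_accept)
    boundaries, _ = _warmup_schedule(n_warmup)
    welford = _Welford(dim)
    slow_start = 75 if boundaries else n_warmup + 1

    draws = np.empty((n_draws, dim))
    divergences = 0
    depths = np.zeros(n_draws, dtype=np.int16)

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        p = rng.standard_normal(dim) / np.sqrt(inv_mass)
        joint0 = _joint(logp, p, inv_mass)
        log_u = joint0 - rng.exponential()

        t = _Tree()
        t.theta_minus = t.theta_plus = t.theta_prop = theta
        t.p_minus = t.p_plus = p
        t.grad_minus = t.grad_plus = t.grad_prop = grad
        t.logp_prop = logp
        t.n_valid, t.keep_going, t.diverged = 1, True, False

        depth = 0
        accept_sum, n_steps = 0.0, 0
        while t.keep_going and depth < max_treedepth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == -1:
                sub = _build_tree(logp_grad, t.theta_minus, t.p_minus,
                                  t.grad_minus, log_u, -1, depth, eps, joint0,
                                  inv_mass, rng)
                t.theta_minus, t.p_minus, t.grad_minus = (
                    sub.theta_minus, sub.p_minus, sub.grad_minus)
            else:
                sub = _build_tree(logp_grad, t.theta_plus, t.p_plus,
                                  t.grad_plus, log_u, 1, depth, eps, joint0,
                                  inv_mass, rng)
                t.theta_plus, t.p_plus, t.grad_plus = (
                    sub.theta_plus, sub.p_plus, sub.grad_plus)
            if sub.keep_going and sub.n_valid > 0:
                if rng.random() < sub.n_valid / max(t.n_valid, 1):
                    t.theta_prop = sub.theta_prop
                    t.logp_prop = sub.logp_prop
                    t.grad_prop = sub.grad_prop
            t.n_valid += sub.n_valid
            accept_sum += sub.accept_sum
            n_steps += sub.n_steps
            if sub.diverged:
                t.diverged = True
            dtheta = t.theta_plus - t.theta_minus
            no_uturn = (np.dot(dtheta, inv_mass * t.p_minus) >= 0
                        and np.dot(dtheta, inv_mass * t.p_plus) >= 0)
            t.keep_going = sub.keep_going and no_uturn
            depth += 1

        theta, logp, grad = t.theta_prop, t.logp_prop, t.grad_prop
        accept_stat = accept_sum / max(n_steps, 1)

        if warming:
            eps = da.update(accept_stat)
            if it >= slow_start and (not boundaries or it < boundaries[-1]):
                welford.add(theta)
            if boundaries and (it + 1) in boundaries:
                inv_mass = welford.variance()
                welford = _Welford(dim)
                eps = _find_initial_step(logp_grad, theta, rng, inv_mass)
                da = _DualAveraging(mu=np.log(10.0 * eps),
                                    target=target_accept)
            if it == n_warmup - 1:
                eps = da.adapted_step
        else:
            draws[it - n_warmup] = theta
            depths[it - n_warmup] = depth
            if t.diverged:
                divergences += 1

    stats = {
        "divergences": int(divergences),
        "step_size": float(eps),
        "inv_mass": inv_mass.copy(),
        "mean_treedepth": float(depths.mean()) if n_draws else 0.0,
    }
    return draws, stats
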