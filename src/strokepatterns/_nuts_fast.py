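"""Numba-compiled NUTS chain for the hierarchical logistic model.

Same algorithm as :mod:`._nuts` (slice-sampling NUTS, dual-averaging step
size, windowed diagonal mass adaptation) but specialized to the
sex-hierarchical logistic posterior and compiled end-to-end, which makes
repeated fits (downsampling repetitions, calibration studies) practical on
a single CPU.  The generic numpy implementation in :mod:`._nuts` serves as
the slow reference; both draw from the same posterior.

Parameter layout (non-centered):
``alpha | mu(k) | log_tau(k) | z_male(k) | z_female(k) | gamma(c)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_DELTA_MAX = 1000.0


@njit(cache=True)
def _logp_grad(theta, A, y, k, c, s_a, s_mu, s_tau, s_g):
    n = A.shape[0]
    m = 1 + 2 * k + c
    alpha = theta[0]
    coef = np.empty(m)
    coef[0] = alpha
    lp = -0.5 * (alpha / s_a) ** 2
    tau = np.empty(k)
    for j in range(k):
        mu = theta[1 + j]
        lt = theta[1 + k + j]
        t = np.exp(lt)
        tau[j] = t
        zm = theta[1 + 2 * k + j]
        zf = theta[1 + 3 * k + j]
        coef[1 + j] = mu + t * zm
        coef[1 + k + j] = mu + t * zf
        lp += (-0.5 * (mu / s_mu) ** 2 - 0.5 * (t / s_tau) ** 2 + lt
               - 0.5 * (zm * zm + zf * zf))
    for j in range(c):
        g = theta[1 + 4 * k + j]
        coef[1 + 2 * k + j] = g
        lp += -0.5 * (g / s_g) ** 2

    eta = A @ coef
    r = np.empty(n)
    for i in range(n):
        e = eta[i]
        if e >= 0.0:
            t = np.exp(-e)
            lp += y[i] * e - e - np.log1p(t)
            r[i] = y[i] - 1.0 / (1.0 + t)
        else:
            t = np.exp(e)
            lp += y[i] * e - np.log1p(t)
            r[i] = y[i] - t / (1.0 + t)

    gA = r @ A
    grad = np.empty(theta.shape[0])
    grad[0] = gA[0] - alpha / (s_a * s_a)
    for j in range(k):
        gm = gA[1 + j]
        gf = gA[1 + k + j]
        mu = theta[1 + j]
        zm = theta[1 + 2 * k + j]
        zf = theta[1 + 3 * k + j]
        t = tau[j]
        grad[1 + j] = gm + gf - mu / (s_mu * s_mu)
        grad[1 + k + j] = (t * (zm * gm + zf * gf)
                           - t * t / (s_tau * s_tau) + 1.0)
        grad[1 + 2 * k + j] = t * gm - zm
        grad[1 + 3 * k + j] = t * gf - zf
    for j in range(c):
        grad[1 + 4 * k + j] = gA[1 + 2 * k + j] - theta[1 + 4 * k + j] / (
            s_g * s_g)
    return lp, grad


@njit(cache=True)
def _leapfrog(theta, p, grad, eps, inv_mass, A, y, k, c, s_a, s_mu, s_tau,
              s_g):
    p1 = p + 0.5 * eps * grad
    theta1 = theta + eps * inv_mass * p1
    logp1, grad1 = _logp_grad(theta1, A, y, k, c, s_a, s_mu, s_tau, s_g)
    p1 = p1 + 0.5 * eps * grad1
    return theta1, p1, logp1, grad1


@njit(cache=True)
def _kinetic(p, inv_mass):
    s = 0.0
    for i in range(p.shape[0]):
        s += p[i] * p[i] * inv_mass[i]
    return 0.5 * s


@njit(cache=True)
def _build_tree(theta, p, grad, log_u, direction, depth, eps, joint0,
                inv_mass, A, y, k, c, s_a, s_mu, s_tau, s_g):
    """Recursive tree doubling; returns the full subtree state tuple."""
    if depth == 0:
        theta1, p1, logp1, grad1 = _leapfrog(
            theta, p, grad, direction * eps, inv_mass, A, y, k, c, s_a,
            s_mu, s_tau, s_g)
        if np.isfinite(logp1):
            joint = logp1 - _kinetic(p1, inv_mass)
        else:
            joint = -np.inf
        n_valid = 1 if log_u <= joint else 0
        diverged = (joint0 - joint) > _DELTA_MAX or not np.isfinite(joint)
        delta = joint - joint0
        accept = np.exp(delta) if delta < 0.0 else 1.0
        return (theta1, p1, grad1, theta1, p1, grad1, theta1, logp1, grad1,
                n_valid, not diverged, accept, 1, diverged)

    (tm, pm, gm, tp, pp, gp, tprop, lprop, gprop, n_valid, keep, acc,
     steps, div) = _build_tree(theta, p, grad, log_u, direction, depth - 1,
                               eps, joint0, inv_mass, A, y, k, c, s_a, s_mu,
                               s_tau, s_g)
    if keep:
        if direction == -1:
            (tm, pm, gm, _, _, _, tprop2, lprop2, gprop2, n2, keep2, acc2,
             steps2, div2) = _build_tree(tm, pm, gm, log_u, direction,
                                         depth - 1, eps, joint0, inv_mass,
                                         A, y, k, c, s_a, s_mu, s_tau, s_g)
        else:
            (_, _, _, tp, pp, gp, tprop2, lprop2, gprop2, n2, keep2, acc2,
             steps2, div2) = _build_tree(tp, pp, gp, log_u, direction,
                                         depth - 1, eps, joint0, inv_mass,
                                         A, y, k, c, s_a, s_mu, s_tau, s_g)
        total = n_valid + n2
        if total > 0 and np.random.random() < n2 / total:
            tprop, lprop, gprop = tprop2, lprop2, gprop2
        acc += acc2
        steps += steps2
        n_valid = total
        div = div or div2
        no_uturn = True
        sm = 0.0
        sp = 0.0
        for i in range(theta.shape[0]):
            d = tp[i] - tm[i]
            sm += d * inv_mass[i] * pm[i]
            sp += d * inv_mass[i] * pp[i]
        if sm < 0.0 or sp < 0.0:
            no_uturn = False
        keep = keep2 and no_uturn and not div
    return (tm, pm, gm, tp, pp, gp, tprop, lprop, gprop, n_valid, keep,
            acc, steps, div)


@njit(cache=True)
def _initial_step(theta, inv_mass, A, y, k, c, s_a, s_mu, s_tau, s_g):
    eps = 1.0
    logp, grad = _logp_grad(theta, A, y, k, c, s_a, s_mu, s_tau, s_g)
    p = np.random.standard_normal(theta.shape[0]) / np.sqrt(inv_mass)
    j0 = logp - _kinetic(p, inv_mass)
    _, p1, logp1, _ = _leapfrog(theta, p, grad, eps, inv_mass, A, y, k, c,
                                s_a, s_mu, s_tau, s_g)
    j1 = (logp1 - _kinetic(p1, inv_mass)) if np.isfinite(logp1) else -np.inf
    direction = 1.0 if (j1 - j0) > np.log(0.5) else -1.0
    for _ in range(60):
        eps *= 2.0 ** direction
        _, p1, logp1, _ = _leapfrog(theta, p, grad, eps, inv_mass, A, y, k,
                                    c, s_a, s_mu, s_tau, s_g)
        j1 = (logp1 - _kinetic(p1, inv_mass)) if np.isfinite(logp1) \
            else -np.inf
        if direction * (j1 - j0) <= direction * np.log(0.5):
            break
    return eps


@njit(cache=True)
def run_chain(A, y, k, c, s_a, s_mu, s_tau, s_g, theta0, n_warmup, n_draws,
              seed, target_accept, max_treedepth, boundaries):
    """One NUTS chain; returns (draws, n_divergent, step_size, mean_depth)."""
    np.random.seed(seed)
    dim = theta0.shape[0]
    theta = theta0.copy()
    inv_mass = np.ones(dim)
    logp, grad = _logp_grad(theta, A, y, k, c, s_a, s_mu, s_tau, s_g)

    eps = _initial_step(theta, inv_mass, A, y, k, c, s_a, s_mu, s_tau, s_g)
    # dual averaging state
    da_mu = np.log(10.0 * eps)
    da_t = 0
    da_hbar = 0.0
    da_logeps_bar = 0.0
    gamma_da, t0_da, kappa_da = 0.05, 10.0, 0.75

    wf_n = 0
    wf_mean = np.zeros(dim)
    wf_m2 = np.zeros(dim)
    slow_start = 75 if boundaries.shape[0] > 0 else n_warmup + 1
    b_idx = 0

    draws = np.empty((n_draws, dim))
    divergences = 0
    depth_sum = 0.0

    for it in range(n_warmup + n_draws):
        p = np.random.standard_normal(dim) / np.sqrt(inv_mass)
        joint0 = logp - _kinetic(p, inv_mass)
        log_u = joint0 - np.random.exponential()

        tm = theta.copy()
        pm = p.copy()
        gm = grad.copy()
        tp = theta.copy()
        pp = p.copy()
        gp = grad.copy()
        tprop = theta
        lprop = logp
        gprop = grad
        n_valid = 1
        keep = True
        diverged = False
        depth = 0
        acc_sum = 0.0
        n_steps = 0
        while keep and depth < max_treedepth:
            direction = -1 if np.random.random() < 0.5 else 1
            if direction == -1:
                (tm, pm, gm, _, _, _, tp2, lp2, gp2, n2, keep2, acc2,
                 steps2, div2) = _build_tree(
                    tm, pm, gm, log_u, direction, depth, eps, joint0,
                    inv_mass, A, y, k, c, s_a, s_mu, s_tau, s_g)
            else:
                (_, _, _, tp, pp, gp, tp2, lp2, gp2, n2, keep2, acc2,
                 steps2, div2) = _build_tree(
                    tp, pp, gp, log_u, direction, depth, eps, joint0,
                    inv_mass, A, y, k, c, s_a, s_mu, s_tau, s_g)
            if keep2 and n2 > 0:
                if np.random.random() < n2 / max(n_valid, 1):
                    tprop, lprop, gprop = tp2, lp2, gp2
            n_valid += n2
            acc_sum += acc2
            n_steps += steps2
            if div2:
                diverged = True
            no_uturn = True
            sm = 0.0
            sp = 0.0
            for i in range(dim):
                d = tp[i] - tm[i]
                sm += d * inv_mass[i] * pm[i]
                sp += d * inv_mass[i] * pp[i]
            if sm < 0.0 or sp < 0.0:
                no_uturn = False
            keep = keep2 and no_uturn
            depth += 1

        theta = tprop.copy()
        logp = lprop
        grad = gprop.copy()
        accept_stat = acc_sum / max(n_steps, 1)

        if it < n_warmup:
            da_t += 1
            eta_da = 1.0 / (da_t + t0_da)
            da_hbar = (1 - eta_da) * da_hbar + eta_da * (
                target_accept - accept_stat)
            log_eps = da_mu - np.sqrt(da_t) / gamma_da * da_hbar
            w = da_t ** (-kappa_da)
            da_logeps_bar = w * log_eps + (1 - w) * da_logeps_bar
            eps = np.exp(log_eps)
            in_slow = (boundaries.shape[0] > 0 and it >= slow_start
                       and it < boundaries[boundaries.shape[0] - 1])
            if in_slow:
                wf_n += 1
                for i in range(dim):
                    delta = theta[i] - wf_mean[i]
                    wf_mean[i] += delta / wf_n
                    wf_m2[i] += delta * (theta[i] - wf_mean[i])
            if b_idx < boundaries.shape[0] and (it + 1) == boundaries[b_idx]:
                if wf_n >= 2:
                    for i in range(dim):
                        var = wf_m2[i] / (wf_n - 1)
                        inv_mass[i] = (var * (wf_n / (wf_n + 5.0))
                                       + 1e-3 * (5.0 / (wf_n + 5.0)))
                wf_n = 0
                wf_mean[:] = 0.0
                wf_m2[:] = 0.0
                eps = _initial_step(theta, inv_mass, A, y, k, c, s_a, s_mu,
                                    s_tau, s_g)
                da_mu = np.log(10.0 * eps)
                da_t = 0
                da_hbar = 0.0
                da_logeps_bar = 0.0
                b_idx += 1
            if it == n_warmup - 1:
                eps = np.exp(da_logeps_bar)
        else:
            draws[it - n_warmup] = theta
            depth_sum += depth
            if diverged:
                divergences += 1

    mean_depth = depth_sum / n_draws if n_draws > 0 else 0.0
    return draws, divergences, eps, mean_depth


def warmup_boundaries(n_warmup: int) -> np.ndarray:
    """Slow-window end points (same schedule as the reference sampler)."""
    if n_warmup < 150:
        return np.empty(0, dtype=np.int64)
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
    return np.asarray(boundaries, dtype=np.int64)
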