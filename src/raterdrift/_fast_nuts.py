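"""Numba-compiled NUTS chain specialised to the rating-model density.

Same algorithm as :mod:`raterdrift.nuts` (dynamic trajectories with slice
sampling, dual-averaging step size, windowed diagonal metric), but the
whole chain loop is jitted and calls the model's log-density kernel
directly, avoiding Python overhead in the leapfrog loop.  Trajectory
doubling is iterative: within a depth-d subtree the states needed for the
nested U-turn checks are checkpointed in ``max_depth + 1`` slots indexed
by the trailing-zero count of the leaf number.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._density import PosteriorDensity, _logp_grad_kernel

_DELTA_MAX = 1000.0


@njit(cache=True)
def _chain(z0, jj, rr, tt, kk, J, R, T, K, D, rater_steps, markov, mu_sigma,
           temper, n_warmup, n_draws, windows, target_accept, max_depth, seed):
    np.random.seed(seed)
    dim = z0.size
    z = z0.copy()
    lp, grad = _logp_grad_kernel(z, jj, rr, tt, kk, J, R, T, K, D,
                                 rater_steps, markov, mu_sigma, temper)
    inv_mass = np.ones(dim)

    # --- find reasonable initial step size ---------------------------
    eps = 1.0
    p = np.random.standard_normal(dim) / np.sqrt(inv_mass)
    h0 = lp - 0.5 * np.sum(p * p * inv_mass)
    p1 = p + 0.5 * eps * grad
    z1 = z + eps * inv_mass * p1
    lp1, g1 = _logp_grad_kernel(z1, jj, rr, tt, kk, J, R, T, K, D,
                                rater_steps, markov, mu_sigma, temper)
    p1 = p1 + 0.5 * eps * g1
    h1 = lp1 - 0.5 * np.sum(p1 * p1 * inv_mass)
    diff = h1 - h0 if np.isfinite(h1) else -np.inf
    direction = 1.0 if diff > np.log(0.5) else -1.0
    for _ in range(60):
        eps *= 2.0 ** direction
        p1 = p + 0.5 * eps * grad
        z1 = z + eps * inv_mass * p1
        lp1, g1 = _logp_grad_kernel(z1, jj, rr, tt, kk, J, R, T, K, D,
                                    rater_steps, markov, mu_sigma, temper)
        p1 = p1 + 0.5 * eps * g1
        h1 = lp1 - 0.5 * np.sum(p1 * p1 * inv_mass)
        diff = h1 - h0 if np.isfinite(h1) else -np.inf
        if direction * diff <= -direction * np.log(2.0):
            break
        if not (1e-10 < eps < 1e7):
            break

    # --- dual averaging state ----------------------------------------
    da_mu = np.log(10.0 * eps)
    da_hbar = 0.0
    da_logebar = np.log(eps)
    da_count = 0
    gamma = 0.05
    t0 = 10.0
    kappa = 0.75

    # --- metric (Welford) state --------------------------------------
    win_idx = 0
    wf_n = 0
    wf_mean = np.zeros(dim)
    wf_m2 = np.zeros(dim)

    # --- checkpoint slots for iterative U-turn checks ----------------
    ck_z = np.empty((max_depth + 1, dim))
    ck_p = np.empty((max_depth + 1, dim))

    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    divergences = 0
    warmup_divergences = 0
    accept_sum = 0.0
    depth_sum = 0.0

    total = n_warmup + n_draws
    for it in range(total):
        p0 = np.random.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(p0 * p0 * inv_mass)
        log_u = h0 - np.random.exponential(1.0)

        z_minus = z.copy()
        z_plus = z.copy()
        p_minus = p0.copy()
        p_plus = p0.copy()
        g_minus = grad.copy()
        g_plus = grad.copy()
        z_prop = z
        g_prop = grad
        lp_prop = lp
        n_valid = 1
        keep = True
        iter_div = 0
        alpha_sum = 0.0
        n_alpha = 0
        depth = 0
        while keep and depth < max_depth:
            v = 1.0 if np.random.random() < 0.5 else -1.0
            if v > 0:
                z_cur = z_plus.copy()
                p_cur = p_plus.copy()
                g_cur = g_plus.copy()
            else:
                z_cur = z_minus.copy()
                p_cur = p_minus.copy()
                g_cur = g_minus.copy()
            n_leaf = 1 << depth
            sub_n = 0
            sub_keep = True
            z_sub = z_prop
            g_sub = g_prop
            lp_sub = lp_prop
            for i in range(n_leaf):
                # leapfrog one step in direction v
                p_cur = p_cur + 0.5 * v * eps * g_cur
                z_cur = z_cur + v * eps * inv_mass * p_cur
                lp_cur, g_new = _logp_grad_kernel(
                    z_cur, jj, rr, tt, kk, J, R, T, K, D,
                    rater_steps, markov, mu_sigma, temper,
                )
                if not np.isfinite(lp_cur):
                    lp_cur = -np.inf
                    g_new = np.zeros(dim)
                g_cur = g_new
                p_cur = p_cur + 0.5 * v * eps * g_cur
                h1 = lp_cur - 0.5 * np.sum(p_cur * p_cur * inv_mass)
                if not np.isfinite(h1):
                    h1 = -np.inf
                de = h1 - h0
                if de > 0.0:
                    alpha_sum += 1.0
                elif de > -700.0:
                    alpha_sum += np.exp(de)
                n_alpha += 1
                if not (log_u < h1 + _DELTA_MAX):
                    iter_div += 1
                    sub_keep = False
                    break
                if log_u <= h1:
                    sub_n += 1
                    if np.random.random() * sub_n < 1.0:
                        z_sub = z_cur.copy()
                        g_sub = g_cur.copy()
                        lp_sub = lp_cur
                if depth > 0:
                    if i % 2 == 0:
                        # checkpoint: this leaf starts nested blocks
                        if i == 0:
                            slot = max_depth
                        else:
                            slot = 0
                            ii = i
                            while ii % 2 == 0:
                                slot += 1
                                ii //= 2
                            slot -= 1
                            # slot = trailing_zeros(i) - 1 in 0..max_depth-1
                        ck_z[slot] = z_cur
                        ck_p[slot] = p_cur
                    # U-turn checks for blocks of size 2**l ending at i
                    l = 1
                    while sub_keep and l <= depth and (i + 1) % (1 << l) == 0:
                        jstart = i - (1 << l) + 1
                        if jstart == 0:
                            slot = max_depth
                        else:
                            slot = 0
                            ii = jstart
                            while ii % 2 == 0:
                                slot += 1
                                ii //= 2
                            slot -= 1
                        dz = v * (z_cur - ck_z[slot])
                        if (np.sum(dz * inv_mass * ck_p[slot]) < 0.0
                                or np.sum(dz * inv_mass * p_cur) < 0.0):
                            sub_keep = False
                        l += 1
                    if not sub_keep:
                        break
            if v > 0:
                z_plus = z_cur
                p_plus = p_cur
                g_plus = g_cur
            else:
                z_minus = z_cur
                p_minus = p_cur
                g_minus = g_cur
            if not sub_keep:
                keep = False
            else:
                if sub_n > 0 and np.random.random() * n_valid < sub_n:
                    z_prop = z_sub
                    g_prop = g_sub
                    lp_prop = lp_sub
                n_valid += sub_n
                dz = z_plus - z_minus
                keep = (
                    np.sum(dz * inv_mass * p_minus) >= 0.0
                    and np.sum(dz * inv_mass * p_plus) >= 0.0
                )
            depth += 1

        z = z_prop.copy()
        grad = g_prop.copy()
        lp = lp_prop
        accept_stat = alpha_sum / max(n_alpha, 1)

        if it < n_warmup:
            if iter_div > 0:
                warmup_divergences += 1
            # dual averaging
            da_count += 1
            w = 1.0 / (da_count + t0)
            da_hbar = (1.0 - w) * da_hbar + w * (target_accept - accept_stat)
            log_eps = da_mu - np.sqrt(da_count) / gamma * da_hbar
            eta = da_count ** (-kappa)
            da_logebar = eta * log_eps + (1.0 - eta) * da_logebar
            eps = np.exp(log_eps)
            if windows.size > 0 and win_idx < windows.size:
                wf_n += 1
                delta = z - wf_mean
                wf_mean += delta / wf_n
                wf_m2 += delta * (z - wf_mean)
                if it + 1 == windows[win_idx]:
                    if wf_n > 1:
                        var = wf_m2 / (wf_n - 1)
                        shrink = wf_n / (wf_n + 5.0)
                        inv_mass = shrink * var + 1e-3 * (1.0 - shrink)
                    wf_n = 0
                    wf_mean[:] = 0.0
                    wf_m2[:] = 0.0
                    win_idx += 1
                    # re-find step size in the new metric, restart averaging
                    eps = 1.0
                    p = np.random.standard_normal(dim) / np.sqrt(inv_mass)
                    hA = lp - 0.5 * np.sum(p * p * inv_mass)
                    p1 = p + 0.5 * eps * grad
                    z1 = z + eps * inv_mass * p1
                    lp1, g1 = _logp_grad_kernel(
                        z1, jj, rr, tt, kk, J, R, T, K, D,
                        rater_steps, markov, mu_sigma, temper,
                    )
                    p1 = p1 + 0.5 * eps * g1
                    hB = lp1 - 0.5 * np.sum(p1 * p1 * inv_mass)
                    diff = hB - hA if np.isfinite(hB) else -np.inf
                    direction = 1.0 if diff > np.log(0.5) else -1.0
                    for _ in range(60):
                        eps *= 2.0 ** direction
                        p1 = p + 0.5 * eps * grad
                        z1 = z + eps * inv_mass * p1
                        lp1, g1 = _logp_grad_kernel(
                            z1, jj, rr, tt, kk, J, R, T, K, D,
                            rater_steps, markov, mu_sigma, temper,
                        )
                        p1 = p1 + 0.5 * eps * g1
                        hB = lp1 - 0.5 * np.sum(p1 * p1 * inv_mass)
                        diff = hB - hA if np.isfinite(hB) else -np.inf
                        if direction * diff <= -direction * np.log(2.0):
                            break
                        if not (1e-10 < eps < 1e7):
                            break
                    da_mu = np.log(10.0 * eps)
                    da_hbar = 0.0
                    da_logebar = np.log(eps)
                    da_count = 0
            if it + 1 == n_warmup:
                eps = np.exp(da_logebar)
        else:
            if iter_div > 0:
                divergences += 1
            accept_sum += accept_stat
            depth_sum += depth
            draws[it - n_warmup] = z
            logps[it - n_warmup] = lp

    return (draws, logps, divergences, warmup_divergences,
            accept_sum / max(n_draws, 1), eps, inv_mass,
            depth_sum / max(n_draws, 1))


def _metric_windows(n_warmup, init_buffer=75, term_buffer=50, base_window=25):
    if n_warmup < init_buffer + term_buffer + base_window:
        return np.empty(0, dtype=np.int64)
    ends = []
    cur = init_buffer
    w = base_window
    while True:
        end = cur + w
        if end + 2 * w > n_warmup - term_buffer:
            ends.append(n_warmup - term_buffer)
            break
        ends.append(end)
        cur = end
        w *= 2
    return np.array(ends, dtype=np.int64)


def sample_chain(
    density: PosteriorDensity,
    z0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    seed: int,
    target_accept: float = 0.98,
    max_treedepth: int = 10,
):
    """Run one jitted NUTS chain on a model posterior."""
    from .model import SCALING_D

    windows = _metric_windows(n_warmup)
    out = _chain(
        np.ascontiguousarray(z0, dtype=np.float64),
        density._jj, density._rr, density._tt, density._kk,
        density.J, density.R, density.T, density.K, SCALING_D,
        density.rater_steps, density.markov,
        density.hyper.mu_sigma, density.temper,
        n_warmup, n_draws, windows, target_accept, max_treedepth,
        int(seed) % (2**31),
    )
    (draws, logps, div, wdiv, acc, eps, inv_mass, depth_mean) = out
    return {
        "draws": draws,
        "logp": logps,
        "divergences": int(div),
        "warmup_divergences": int(wdiv),
        "accept_mean": float(acc),
        "step_size": float(eps),
        "inv_mass": inv_mass,
        "treedepth_mean": float(depth_mean),
    }
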