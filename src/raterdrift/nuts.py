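"""No-U-turn Hamiltonian Monte Carlo on a differentiable log density.

A self-contained implementation of the dynamic-trajectory ("no-U-turn")
sampler with slice sampling across the trajectory, dual-averaging step-size
adaptation towards a target acceptance statistic, and windowed estimation
of a diagonal mass matrix during warmup.  The interface is a plain
callable ``logp_grad(z) -> (float, ndarray)``; nothing here knows about
the rating model.

Trajectories are doubled until the first U-turn (measured in the adapted
metric) or a maximum tree depth; a leapfrog state whose Hamiltonian error
exceeds 1000 is flagged as a divergent transition and its subtree is
rejected, mirroring common practice in gradient-based samplers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_DELTA_MAX = 1000.0


@dataclass
class NutsResult:
    """Draws and sampler statistics for one chain."""

    draws: np.ndarray            # (n_draws, dim), post-warmup only
    logp: np.ndarray             # (n_draws,)
    divergences: int             # post-warmup divergent transitions
    warmup_divergences: int
    accept_mean: float           # mean acceptance statistic, post-warmup
    step_size: float
    inv_mass: np.ndarray
    treedepth_mean: float


def _kinetic(p: np.ndarray, inv_mass: np.ndarray) -> float:
    return 0.5 * float(np.dot(p * p, inv_mass))


def _leapfrog(logp_grad, z, p, grad, eps, inv_mass):
    p1 = p + 0.5 * eps * grad
    z1 = z + eps * inv_mass * p1
    lp1, grad1 = logp_grad(z1)
    if not np.isfinite(lp1):
        lp1 = -np.inf
        grad1 = np.zeros_like(grad)
    p1 = p1 + 0.5 * eps * grad1
    return z1, p1, grad1, lp1


def _find_reasonable_epsilon(logp_grad, z, grad, lp, inv_mass, rng):
    eps = 1.0
    p = rng.standard_normal(z.size) / np.sqrt(inv_mass)
    h0 = lp - _kinetic(p, inv_mass)
    _, p1, _, lp1 = _leapfrog(logp_grad, z, p, grad, eps, inv_mass)
    h1 = lp1 - _kinetic(p1, inv_mass)
    diff = h1 - h0 if np.isfinite(h1) else -np.inf
    direction = 1.0 if diff > np.log(0.5) else -1.0
    for _ in range(60):
        eps *= 2.0 ** direction
        _, p1, _, lp1 = _leapfrog(logp_grad, z, p, grad, eps, inv_mass)
        h1 = lp1 - _kinetic(p1, inv_mass)
        diff = h1 - h0 if np.isfinite(h1) else -np.inf
        if direction * diff <= -direction * np.log(2.0):
            break
        if not (1e-10 < eps < 1e7):
            break
    return eps


def _no_uturn(z_minus, z_plus, p_minus, p_plus, inv_mass) -> bool:
    dz = z_plus - z_minus
    return (
        float(np.dot(dz, inv_mass * p_minus)) >= 0.0
        and float(np.dot(dz, inv_mass * p_plus)) >= 0.0
    )


def _build_tree(logp_grad, z, p, grad, log_u, v, depth, eps, h0, inv_mass, rng):
    """Recursively double the trajectory in direction ``v``.

    Returns (z-, p-, grad-, z+, p+, grad+, z_prop, grad_prop, lp_prop,
    n_valid, keep_going, alpha_sum, n_alpha, n_divergent).
    """
    if depth == 0:
        z1, p1, grad1, lp1 = _leapfrog(logp_grad, z, p, grad, v * eps, inv_mass)
        h1 = lp1 - _kinetic(p1, inv_mass) if np.isfinite(lp1) else -np.inf
        n_valid = int(log_u <= h1)
        divergent = not (log_u < h1 + _DELTA_MAX)
        alpha = min(1.0, float(np.exp(min(h1 - h0, 0.0)))) if np.isfinite(h1) else 0.0
        return (
            z1, p1, grad1, z1, p1, grad1, z1, grad1, lp1,
            n_valid, not divergent, alpha, 1, int(divergent),
        )
    out = _build_tree(
        logp_grad, z, p, grad, log_u, v, depth - 1, eps, h0, inv_mass, rng
    )
    (zm, pm, gm, zp, pp, gp, zc, gc, lpc,
     n1, keep, alpha, n_alpha, n_div) = out
    if keep:
        if v == -1:
            out2 = _build_tree(
                logp_grad, zm, pm, gm, log_u, v, depth - 1, eps, h0, inv_mass, rng
            )
            (zm, pm, gm, _, _, _, zc2, gc2, lpc2,
             n2, keep2, alpha2, n_alpha2, n_div2) = out2
        else:
            out2 = _build_tree(
                logp_grad, zp, pp, gp, log_u, v, depth - 1, eps, h0, inv_mass, rng
            )
            (_, _, _, zp, pp, gp, zc2, gc2, lpc2,
             n2, keep2, alpha2, n_alpha2, n_div2) = out2
        if n2 > 0 and rng.random() < n2 / max(n1 + n2, 1):
            zc, gc, lpc = zc2, gc2, lpc2
        n1 += n2
        alpha += alpha2
        n_alpha += n_alpha2
        n_div += n_div2
        keep = keep2 and _no_uturn(zm, zp, pm, pp, inv_mass)
    return zm, pm, gm, zp, pp, gp, zc, gc, lpc, n1, keep, alpha, n_alpha, n_div


def _metric_windows(n_warmup, init_buffer=75, term_buffer=50, base_window=25):
    """Iteration indices (0-based, exclusive ends) at which to update the metric."""
    if n_warmup < init_buffer + term_buffer + base_window:
        return []
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
    return ends


@dataclass
class _DualAveraging:
    target: float
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    mu: float = 0.0
    h_bar: float = 0.0
    log_eps_bar: float = 0.0
    count: int = 0

    def restart(self, eps: float) -> None:
        self.mu = np.log(10.0 * eps)
        self.h_bar = 0.0
        self.log_eps_bar = np.log(eps)
        self.count = 0

    def update(self, accept_stat: float) -> float:
        self.count += 1
        m = self.count
        w = 1.0 / (m + self.t0)
        self.h_bar = (1.0 - w) * self.h_bar + w * (self.target - accept_stat)
        log_eps = self.mu - np.sqrt(m) / self.gamma * self.h_bar
        eta = m ** (-self.kappa)
        self.log_eps_bar = eta * log_eps + (1.0 - eta) * self.log_eps_bar
        return float(np.exp(log_eps))

    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


def sample(
    logp_grad,
    z0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.98,
    max_treedepth: int = 10,
) -> NutsResult:
    """Run one NUTS chain and return post-warmup draws."""
    z = np.array(z0, dtype=float)
    dim = z.size
    lp, grad = logp_grad(z)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")
    inv_mass = np.ones(dim)

    eps = _find_reasonable_epsilon(logp_grad, z, grad, lp, inv_mass, rng)
    da = _DualAveraging(target=target_accept)
    da.restart(eps)

    windows = _metric_windows(n_warmup)
    win_idx = 0
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    divergences = 0
    warmup_divergences = 0
    accept_sum = 0.0
    depth_sum = 0

    total = n_warmup + n_draws
    for it in range(total):
        warm = it < n_warmup
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - _kinetic(p0, inv_mass)
        log_u = h0 - rng.exponential(1.0)
        zm = zp = z
        pm = pp = p0
        gm = gp = grad
        n_valid = 1
        keep = True
        alpha_sum = 0.0
        n_alpha = 0
        n_div = 0
        depth = 0
        while keep and depth < max_treedepth:
            v = 1 if rng.random() < 0.5 else -1
            if v == -1:
                (zm, pm, gm, _, _, _, zc, gc, lpc,
                 n1, keep1, a1, na1, nd1) = _build_tree(
                    logp_grad, zm, pm, gm, log_u, v, depth, eps, h0, inv_mass, rng
                )
            else:
                (_, _, _, zp, pp, gp, zc, gc, lpc,
                 n1, keep1, a1, na1, nd1) = _build_tree(
                    logp_grad, zp, pp, gp, log_u, v, depth, eps, h0, inv_mass, rng
                )
            alpha_sum += a1
            n_alpha += na1
            n_div += nd1
            if keep1 and rng.random() < min(1.0, n1 / max(n_valid, 1)):
                z, grad, lp = zc, gc, lpc
            n_valid += n1
            keep = keep1 and _no_uturn(zm, zp, pm, pp, inv_mass)
            depth += 1

        accept_stat = alpha_sum / max(n_alpha, 1)
        if warm:
            warmup_divergences += int(n_div > 0)
            eps = da.update(accept_stat)
            if windows and win_idx < len(windows):
                welford_n += 1
                delta = z - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (z - welford_mean)
                if it + 1 == windows[win_idx]:
                    if welford_n > 1:
                        var = welford_m2 / (welford_n - 1)
                        shrink = welford_n / (welford_n + 5.0)
                        inv_mass = shrink * var + 1e-3 * (1.0 - shrink)
                    welford_n = 0
                    welford_mean[:] = 0.0
                    welford_m2[:] = 0.0
                    win_idx += 1
                    eps = _find_reasonable_epsilon(
                        logp_grad, z, grad, lp, inv_mass, rng
                    )
                    da.restart(eps)
            if it + 1 == n_warmup:
                eps = da.adapted()
        else:
            divergences += int(n_div > 0)
            accept_sum += accept_stat
            depth_sum += depth
            draws[it - n_warmup] = z
            logps[it - n_warmup] = lp

    return NutsResult(
        draws=draws,
        logp=logps,
        divergences=divergences,
        warmup_divergences=warmup_divergences,
        accept_mean=accept_sum / max(n_draws, 1),
        step_size=eps,
        inv_mass=inv_mass,
        treedepth_mean=depth_sum / max(n_draws, 1),
    )
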