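"""Unconstrained posterior log-density and gradient for the four variants.

The sampler works on an unconstrained vector ``z`` laid out as

    [ theta (J) | beta (R*T, row-major) | free steps | log sigma (R)* ]

where the free-step block has R*(K-2) entries for rater-specific steps or
K-2 entries for shared steps, and the log-sigma block exists only for the
Markov variants.  Drift scales are sampled on the log scale, so the density
here equals the natural-parameter posterior plus the log-Jacobian
``sum_r log sigma_r`` of that transform.

A likelihood temperature is threaded through for WBIC's tempered runs:
``logp = temper * log_likelihood + log_prior``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .data import RatingDataset
from .model import (
    BaselineParameterSet,
    Hyperparameters,
    ParameterSet,
    SCALING_D,
    constrain_steps,
)

VARIANTS = ("proposed", "proposed_no_markov", "baseline", "baseline_markov")

_LOG_2PI = 1.8378770664093453


@njit(cache=True)
def _logp_grad_kernel(z, jj, rr, tt, kk, J, R, T, K, D,
                      rater_steps, markov, mu_sigma, temper):
    n_beta = R * T
    nfree = K - 2
    Rd = R if rater_steps else 1
    off_d = J + n_beta
    off_s = off_d + Rd * nfree

    # constrained cumulative steps per step-group
    cumd = np.zeros((Rd, K))
    for g in range(Rd):
        ssum = 0.0
        for m in range(1, K):
            if m <= K - 2:
                dm = z[off_d + g * nfree + (m - 1)]
                ssum += dm
            else:
                dm = -ssum
            cumd[g, m] = cumd[g, m - 1] + dm

    grad = np.zeros(z.size)
    ll = 0.0
    eta = np.empty(K)
    p = np.empty(K)
    N = jj.size
    for n in range(N):
        j = jj[n]
        r = rr[n]
        t = tt[n]
        c = kk[n]
        g = r if rater_steps else 0
        xv = z[j] - z[J + r * T + t]
        emax = -1e300
        for l in range(K):
            eta[l] = (l + 1) * D * xv - D * cumd[g, l]
            if eta[l] > emax:
                emax = eta[l]
        sume = 0.0
        for l in range(K):
            p[l] = np.exp(eta[l] - emax)
            sume += p[l]
        ll += eta[c] - (emax + np.log(sume))
        El = 0.0
        for l in range(K):
            p[l] /= sume
            El += (l + 1) * p[l]
        gx = D * ((c + 1) - El)
        grad[j] += gx
        grad[J + r * T + t] -= gx
        if nfree > 0:
            # d gradients on free coordinates: d_m free for m=1..K-2,
            # d_{K-1} = -sum(free); S = P(category index >= m)
            S = p[K - 1]
            ind = 1.0 if (K - 1) <= c else 0.0
            gd_last = -D * (ind - S)
            for m in range(K - 2, 0, -1):
                S += p[m]
                ind = 1.0 if m <= c else 0.0
                gd_m = -D * (ind - S)
                grad[off_d + g * nfree + (m - 1)] += gd_m - gd_last

    lp = temper * ll
    for i in range(z.size):
        grad[i] *= temper

    # priors ------------------------------------------------------------
    for j in range(J):
        lp += -0.5 * z[j] * z[j] - 0.5 * _LOG_2PI
        grad[j] += -z[j]
    if markov:
        for r in range(R):
            b0 = z[J + r * T]
            lp += -0.5 * b0 * b0 - 0.5 * _LOG_2PI
            grad[J + r * T] += -b0
            s = z[off_s + r]
            inv_var = np.exp(-2.0 * s)
            for t in range(1, T):
                diff = z[J + r * T + t] - z[J + r * T + t - 1]
                lp += -0.5 * diff * diff * inv_var - s - 0.5 * _LOG_2PI
                gdiff = -diff * inv_var
                grad[J + r * T + t] += gdiff
                grad[J + r * T + t - 1] -= gdiff
                grad[off_s + r] += -1.0 + diff * diff * inv_var
            ds = s - mu_sigma
            lp += -0.5 * ds * ds - 0.5 * _LOG_2PI
            grad[off_s + r] += -ds
    else:
        for i in range(J, J + n_beta):
            lp += -0.5 * z[i] * z[i] - 0.5 * _LOG_2PI
            grad[i] += -z[i]
    for i in range(off_d, off_d + Rd * nfree):
        lp += -0.5 * z[i] * z[i] - 0.5 * _LOG_2PI
        grad[i] += -z[i]
    return lp, grad


@njit(cache=True)
def _pointwise_kernel(theta_draws, beta_draws, cumd_draws,
                      jj, rr, tt, kk, D, rater_steps):
    S = theta_draws.shape[0]
    N = jj.size
    K = cumd_draws.shape[2]
    T = beta_draws.shape[2]
    out = np.empty((S, N))
    for s in range(S):
        for n in range(N):
            j = jj[n]
            r = rr[n]
            t = tt[n]
            c = kk[n]
            g = r if rater_steps else 0
            xv = theta_draws[s, j] - beta_draws[s, r, t]
            emax = -1e300
            target = 0.0
            for l in range(K):
                e = (l + 1) * D * xv - D * cumd_draws[s, g, l]
                if l == c:
                    target = e
                if e > emax:
                    emax = e
            sume = 0.0
            for l in range(K):
                sume += np.exp((l + 1) * D * xv - D * cumd_draws[s, g, l] - emax)
            out[s, n] = target - (emax + np.log(sume))
    return out


class PosteriorDensity:
    """Callable log-density + gradient of one model variant on one dataset."""

    def __init__(
        self,
        data: RatingDataset,
        variant: str = "proposed",
        hyper: Hyperparameters | None = None,
        temper: float = 1.0,
    ):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; expected {VARIANTS}")
        self.data = data
        self.variant = variant
        self.hyper = hyper if hyper is not None else Hyperparameters()
        self.temper = float(temper)
        self.rater_steps = variant in ("proposed", "proposed_no_markov")
        self.markov = variant in ("proposed", "baseline_markov")
        self.J, self.R, self.T, self.K = data.J, data.R, data.T, data.K
        # original-order arrays (pointwise likelihood follows data order)
        self._pjj = (data.examinee - 1).astype(np.int64)
        self._prr = (data.rater - 1).astype(np.int64)
        self._ptt = (data.time - 1).astype(np.int64)
        self._pkk = (data.score - 1).astype(np.int64)
        # canonical order for the accumulating kernel, so the density (and
        # hence the sampled chains) are invariant to observation order
        order = np.lexsort((self._ptt, self._prr, self._pjj))
        self._jj = self._pjj[order]
        self._rr = self._prr[order]
        self._tt = self._ptt[order]
        self._kk = self._pkk[order]
        self.n_step_groups = self.R if self.rater_steps else 1
        self.n_free = self.K - 2
        self.n_params = (
            self.J
            + self.R * self.T
            + self.n_step_groups * self.n_free
            + (self.R if self.markov else 0)
        )
        self._off_d = self.J + self.R * self.T
        self._off_s = self._off_d + self.n_step_groups * self.n_free

    # -- density --------------------------------------------------------

    def logp_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        return _logp_grad_kernel(
            np.ascontiguousarray(z, dtype=np.float64),
            self._jj, self._rr, self._tt, self._kk,
            self.J, self.R, self.T, self.K, SCALING_D,
            self.rater_steps, self.markov,
            self.hyper.mu_sigma, self.temper,
        )

    def logp(self, z: np.ndarray) -> float:
        return self.logp_grad(z)[0]

    # -- packing --------------------------------------------------------

    def pack(self, params) -> np.ndarray:
        """Flatten a parameter set into the unconstrained vector."""
        z = np.empty(self.n_params)
        z[: self.J] = params.theta
        z[self.J : self._off_d] = np.asarray(params.beta).ravel()
        d = np.atleast_2d(params.d)
        if self.n_free > 0:
            z[self._off_d : self._off_s] = d[:, 1:-1].ravel()
        if self.markov:
            z[self._off_s :] = np.log(params.sigma)
        return z

    def unpack(self, z: np.ndarray):
        """Rebuild a (constrained) parameter set from ``z``."""
        theta = z[: self.J].copy()
        beta = z[self.J : self._off_d].reshape(self.R, self.T).copy()
        free = z[self._off_d : self._off_s].reshape(self.n_step_groups, self.n_free)
        d = np.stack([constrain_steps(f) for f in free])
        sigma = np.exp(z[self._off_s :]) if self.markov else None
        if self.rater_steps:
            return ParameterSet(theta, beta, sigma, d)
        return BaselineParameterSet(theta, beta, d[0], sigma=sigma)

    def init_from_prior(self, rng: np.random.Generator, jitter: float = 0.1) -> np.ndarray:
        """Prior draw on the unconstrained scale, mildly jittered."""
        z = np.empty(self.n_params)
        z[: self.J] = rng.standard_normal(self.J)
        if self.markov:
            s = self.hyper.mu_sigma + rng.standard_normal(self.R)
            sigma = np.exp(s)
            beta = np.empty((self.R, self.T))
            beta[:, 0] = rng.standard_normal(self.R)
            for t in range(1, self.T):
                beta[:, t] = beta[:, t - 1] + sigma * rng.standard_normal(self.R)
            z[self.J : self._off_d] = beta.ravel()
            z[self._off_s :] = s
        else:
            z[self.J : self._off_d] = rng.standard_normal(self.R * self.T)
        z[self._off_d : self._off_s] = rng.standard_normal(
            self.n_step_groups * self.n_free
        )
        return z + jitter * rng.standard_normal(self.n_params)

    def param_names(self) -> list[str]:
        """Flat names aligned with ``z`` (free steps named by coordinate)."""
        names = [f"theta[{j + 1}]" for j in range(self.J)]
        names += [
            f"beta[{r + 1},{t + 1}]"
            for r in range(self.R)
            for t in range(self.T)
        ]
        for g in range(self.n_step_groups):
            tag = f"{g + 1}," if self.rater_steps else ""
            names += [f"dfree[{tag}{m + 2}]" for m in range(self.n_free)]
        if self.markov:
            names += [f"log_sigma[{r + 1}]" for r in range(self.R)]
        return names

    # -- pointwise likelihood (for WAIC/WBIC) ---------------------------

    def pointwise_loglik(self, z_draws: np.ndarray) -> np.ndarray:
        """(draws, observations) log-likelihood matrix at each draw."""
        z_draws = np.atleast_2d(np.ascontiguousarray(z_draws, dtype=np.float64))
        S = z_draws.shape[0]
        theta = z_draws[:, : self.J]
        beta = z_draws[:, self.J : self._off_d].reshape(S, self.R, self.T)
        free = z_draws[:, self._off_d : self._off_s].reshape(
            S, self.n_step_groups, self.n_free
        )
        d = np.zeros((S, self.n_step_groups, self.K))
        if self.n_free > 0:
            d[:, :, 1:-1] = free
            d[:, :, -1] = -free.sum(axis=2)
        cumd = np.cumsum(d, axis=2)
        return _pointwise_kernel(
            np.ascontiguousarray(theta),
            np.ascontiguousarray(beta),
            np.ascontiguousarray(cumd),
            self._pjj, self._prr, self._ptt, self._pkk,
            SCALING_D, self.rater_steps,
        )
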