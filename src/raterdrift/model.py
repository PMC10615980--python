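"""Many-facet Rasch model with time-specific rater severity.

Two probability kernels are defined here.  Both give the probability that a
performance receives score ``k`` out of ``1..K`` as an adjacent-category
logit model,

    P_k = exp( sum_{m<=k} D (theta - beta - d_m) )
          / sum_l exp( sum_{m<=l} D (theta - beta - d_m) ),

where ``theta`` is examinee ability, ``beta`` the rater's severity at the
time point of the rating, ``d_m`` step parameters and ``D = 1.7`` the usual
logistic scaling constant.  The *rater-specific* variant gives every rater
its own step vector ``d_{rm}``; the *baseline* variant shares one step
vector across raters.

The hierarchical prior couples a rater's severities over time through a
first-order random walk,

    theta_j ~ N(0,1),   beta_{r1} ~ N(0,1),
    beta_{rt} | beta_{r,t-1} ~ N(beta_{r,t-1}, sigma_r)   (t > 1),
    sigma_r ~ LogNormal(mu_sigma, 1),   d_{rm} ~ N(0,1),

with identification constraints d_{r1} = 0 and sum_{m>=2} d_{rm} = 0.  The
drift scale sigma_r summarises how strongly rater r's severity moves
between adjacent time points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import log_softmax, logsumexp

from .data import DimensionMismatchError, InvalidParameterError, RatingDataset

SCALING_D = 1.7
_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# step-parameter identification
# ---------------------------------------------------------------------------

def constrain_steps(free: np.ndarray) -> np.ndarray:
    """Map K-2 free coordinates to a constrained step vector of length K.

    The returned vector d satisfies d[0] = 0 (first step fixed) and
    sum(d[1:]) = 0 (remaining steps sum to zero), the identification
    convention of the model.  ``free`` may be empty, giving the K = 2 step
    vector (0, 0).
    """
    free = np.atleast_1d(np.asarray(free, dtype=float))
    if free.ndim != 1:
        raise DimensionMismatchError("free step coordinates must be 1-D")
    return np.concatenate([[0.0], free, [-free.sum()]])


def unconstrain_steps(d: np.ndarray) -> np.ndarray:
    """Inverse of :func:`constrain_steps`; validates both constraints."""
    d = np.asarray(d, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise DimensionMismatchError("step vector must be 1-D with K >= 2")
    if d[0] != 0.0:
        raise InvalidParameterError("first step parameter must be 0")
    if abs(d[1:].sum()) > 1e-8:
        raise InvalidParameterError("steps 2..K must sum to 0")
    return d[1:-1].copy()


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class Hyperparameters:
    """Hyperparameters of the drift-scale prior LogNormal(mu_sigma, 1).

    ``mu_sigma`` is the log-scale mean: small values (say -2 and below)
    encode the belief that few raters drift; values near 0 allow strong
    drift.  The log-scale standard deviation is fixed at one.
    """

    mu_sigma: float = -2.0
    prior_sd_sigma: float = 1.0

    def __post_init__(self):
        if self.prior_sd_sigma != 1.0:
            raise InvalidParameterError(
                "the drift-scale prior standard deviation is fixed at 1"
            )


@dataclass
class ParameterSet:
    """Parameters of the rater-specific-steps model.

    theta : (J,) examinee abilities
    beta  : (R, T) severity of rater r at time point t
    sigma : (R,) drift scales (standard deviation of the severity walk);
            ``None`` for the ablated variant without a severity chain
    d     : (R, K) constrained step parameters, d[:, 0] = 0, rows of
            d[:, 1:] sum to zero
    """

    theta: np.ndarray
    beta: np.ndarray
    sigma: np.ndarray | None
    d: np.ndarray
    scaling_D: float = SCALING_D

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        self.d = np.atleast_2d(np.asarray(self.d, dtype=float))
        self.validate()

    def validate(self) -> None:
        R, T = self.beta.shape
        if self.sigma is not None and self.sigma.shape != (R,):
            raise DimensionMismatchError(
                f"sigma has shape {self.sigma.shape}, expected ({R},)"
            )
        if self.d.shape[0] != R:
            raise DimensionMismatchError(
                f"d has {self.d.shape[0]} rows, expected R={R}"
            )
        if self.d.shape[1] < 2:
            raise DimensionMismatchError("d must have K >= 2 columns")
        arrays = [self.theta, self.beta, self.d]
        if self.sigma is not None:
            arrays.append(self.sigma)
        for arr in arrays:
            if not np.all(np.isfinite(arr)):
                raise InvalidParameterError("non-finite parameter value")
        if self.sigma is not None and np.any(self.sigma <= 0):
            raise InvalidParameterError("sigma must be strictly positive")
        if np.any(self.d[:, 0] != 0.0):
            raise InvalidParameterError("d[:, 0] must be 0 (identification)")
        if np.max(np.abs(self.d[:, 1:].sum(axis=1))) > 1e-8:
            raise InvalidParameterError("d[:, 1:] rows must sum to 0")

    @property
    def J(self) -> int:
        return self.theta.size

    @property
    def R(self) -> int:
        return self.beta.shape[0]

    @property
    def T(self) -> int:
        return self.beta.shape[1]

    @property
    def K(self) -> int:
        return self.d.shape[1]

    def to_json(self, path) -> None:
        payload = {
            "J": self.J, "R": self.R, "T": self.T, "K": self.K,
            "scaling_D": self.scaling_D,
            "theta": self.theta.tolist(),
            "beta": self.beta.tolist(),
            "sigma": None if self.sigma is None else self.sigma.tolist(),
            "d": self.d.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path) as fh:
            payload = json.load(fh)
        sigma = payload["sigma"]
        return cls(
            theta=np.array(payload["theta"]),
            beta=np.array(payload["beta"]),
            sigma=None if sigma is None else np.array(sigma),
            d=np.array(payload["d"]),
            scaling_D=float(payload.get("scaling_D", SCALING_D)),
        )


@dataclass
class BaselineParameterSet:
    """Parameters of the shared-steps (baseline) model: one step vector.

    ``sigma`` is present only for the baseline-with-severity-chain variant.
    """

    theta: np.ndarray
    beta: np.ndarray
    d: np.ndarray
    sigma: np.ndarray | None = None
    scaling_D: float = SCALING_D

    def __post_init__(self):
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if np.any(self.sigma <= 0):
                raise InvalidParameterError("sigma must be strictly positive")
        self.theta = np.asarray(self.theta, dtype=float)
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 1 or self.d.size < 2:
            raise DimensionMismatchError("d must be a 1-D step vector, K >= 2")
        if self.d[0] != 0.0:
            raise InvalidParameterError("d[0] must be 0 (identification)")
        if abs(self.d[1:].sum()) > 1e-8:
            raise InvalidParameterError("d[1:] must sum to 0")

    @property
    def J(self) -> int:
        return self.theta.size

    @property
    def R(self) -> int:
        return self.beta.shape[0]

    @property
    def T(self) -> int:
        return self.beta.shape[1]

    @property
    def K(self) -> int:
        return self.d.size


# ---------------------------------------------------------------------------
# probability kernel
# ---------------------------------------------------------------------------

def category_log_probabilities(theta, beta, d, D=SCALING_D) -> np.ndarray:
    """Log category probabilities, computed entirely in log space."""
    d = np.asarray(d, dtype=float)
    if d.ndim != 1:
        raise DimensionMismatchError("step vector must be 1-D")
    if not (np.isfinite(theta) and np.isfinite(beta) and np.all(np.isfinite(d))):
        raise InvalidParameterError("non-finite input to category probability")
    if d[0] != 0.0:
        raise InvalidParameterError("first step parameter must be 0")
    eta = np.cumsum(D * (theta - beta - d))
    return log_softmax(eta)


def category_probabilities(theta, beta, d, D=SCALING_D) -> np.ndarray:
    """Probability of each score category 1..K for one rating.

    Depends on ability and severity only through ``theta - beta``.
    """
    return np.exp(category_log_probabilities(theta, beta, d, D))


def baseline_category_probabilities(theta, beta, d, D=SCALING_D) -> np.ndarray:
    """Shared-steps kernel; identical maths, rater-independent ``d``."""
    return category_probabilities(theta, beta, d, D)


def _observation_log_probs(data: RatingDataset, theta, beta, d, D) -> np.ndarray:
    """Vectorised per-observation log probability; d is (R, K) or (K,)."""
    j = data.examinee - 1
    r = data.rater - 1
    t = data.time - 1
    x = theta[j] - beta[r, t]                        # (N,)
    d = np.atleast_2d(np.asarray(d, dtype=float))
    cumd = np.cumsum(d, axis=1)                      # (Rd, K)
    rows = r if d.shape[0] > 1 else np.zeros_like(r)
    K = d.shape[1]
    eta = D * (np.arange(1, K + 1) * x[:, None] - cumd[rows])   # (N, K)
    logp = eta - logsumexp(eta, axis=1, keepdims=True)
    return logp[np.arange(data.n_obs), data.score - 1]


def log_likelihood(data: RatingDataset, params) -> float:
    """Sum of per-observation log category probabilities.

    Accepts either a :class:`ParameterSet` (rater-specific steps) or a
    :class:`BaselineParameterSet` (shared steps).
    """
    _check_dims(data, params)
    if data.n_obs == 0:
        return 0.0
    lp = _observation_log_probs(
        data, params.theta, params.beta, params.d, params.scaling_D
    )
    return float(lp.sum())


def _check_dims(data: RatingDataset, params) -> None:
    if params.J != data.J:
        raise DimensionMismatchError(
            f"examinee axis: data J={data.J}, params J={params.J}"
        )
    if params.R != data.R:
        raise DimensionMismatchError(
            f"rater axis: data R={data.R}, params R={params.R}"
        )
    if params.T != data.T:
        raise DimensionMismatchError(
            f"time axis: data T={data.T}, params T={params.T}"
        )
    if params.K != data.K:
        raise DimensionMismatchError(
            f"category axis: data K={data.K}, params K={params.K}"
        )


def log_prior(params: ParameterSet, hyper: Hyperparameters | None = None) -> float:
    """Joint log prior density of a :class:`ParameterSet`.

    The Markov chain on severities contributes N(beta_r1 | 0, 1) at the
    first time point and N(beta_rt | beta_{r,t-1}, sigma_r) afterwards.
    The step-parameter prior is placed on the K-2 free coordinates; the
    two constrained entries carry no density of their own.
    """
    if hyper is None:
        hyper = Hyperparameters()
    params.validate()
    if params.sigma is None:
        raise InvalidParameterError("drift scales sigma are required")
    th, be, si, d = params.theta, params.beta, params.sigma, params.d

    def _std_normal(x):
        return float(-0.5 * np.sum(x * x) - 0.5 * _LOG_2PI * np.size(x))

    lp = _std_normal(th)
    lp += _std_normal(be[:, 0])
    if params.T > 1:
        diff = np.diff(be, axis=1)
        lp += float(
            np.sum(-0.5 * (diff / si[:, None]) ** 2
                   - np.log(si)[:, None] - 0.5 * _LOG_2PI)
        )
    # sigma_r ~ LogNormal(mu_sigma, 1)
    ls = np.log(si)
    lp += float(np.sum(-0.5 * (ls - hyper.mu_sigma) ** 2 - ls - 0.5 * _LOG_2PI))
    # free step coordinates ~ N(0, 1)
    if params.K > 2:
        free = d[:, 1:-1]
        lp += _std_normal(free)
    return lp


def log_posterior(
    data: RatingDataset,
    params: ParameterSet,
    hyper: Hyperparameters | None = None,
) -> float:
    """Unnormalised log posterior: log likelihood plus log prior."""
    return log_likelihood(data, params) + log_prior(params, hyper)
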