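"""Synthetic rating studies: true parameters, rating designs, score data.

The generator mirrors a longitudinal essay-rating session: each rater
grades their assigned examinees once, with the workload split as evenly as
possible over T contiguous rating periods (e.g. "a quarter of the essays
each day", in randomised order).  Most raters are stable while a minority
drift: drift scales are drawn from a 60/40 mixture of LogNormal(-3, 1)
(stable) and LogNormal(-1, 1) (drifting) components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import RatingDataset
from .model import ParameterSet, constrain_steps

DESIGNS = ("crossed", "link2", "link3")


@dataclass(frozen=True)
class SigmaMixtureSpec:
    """Two-component log-normal mixture for rater drift scales sigma_r."""

    stable_fraction: float = 0.60
    stable_logmean: float = -3.0
    drifting_logmean: float = -1.0
    logsd: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.stable_fraction <= 1.0:
            raise ValueError("stable_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class AssignmentDesign:
    """Which rater scores which examinee, and at which time point.

    ``examinee``, ``rater`` and ``time`` are parallel 1-based arrays; each
    (examinee, rater) pair appears at most once.
    """

    examinee: np.ndarray
    rater: np.ndarray
    time: np.ndarray
    J: int
    R: int
    T: int

    def __post_init__(self):
        for name in ("examinee", "rater", "time"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=np.int64)
            )
        pairs = np.stack([self.examinee, self.rater], axis=1)
        if np.unique(pairs, axis=0).shape[0] != pairs.shape[0]:
            raise ValueError("duplicate (examinee, rater) assignment")

    @property
    def n_pairs(self) -> int:
        return int(self.examinee.size)

    def pairs(self) -> set[tuple[int, int]]:
        return set(zip(self.examinee.tolist(), self.rater.tolist()))

    def time_of(self, examinee: int, rater: int) -> int:
        mask = (self.examinee == examinee) & (self.rater == rater)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise KeyError(f"pair ({examinee}, {rater}) not assigned")
        return int(self.time[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"examinee": self.examinee, "rater": self.rater, "time": self.time}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def draw_parameters(
    J: int,
    R: int,
    T: int,
    K: int = 5,
    mix: SigmaMixtureSpec | None = None,
    seed=None,
) -> ParameterSet:
    """Draw a true parameter set from the generative hierarchy.

    Abilities and first-period severities are standard normal; later
    severities follow the random walk with per-rater scale sigma_r; free
    step coordinates are standard normal.  Exactly floor(stable_fraction*R)
    raters receive the stable mixture component, the remainder the drifting
    one, and the component labels are randomly permuted over raters.
    """
    if mix is None:
        mix = SigmaMixtureSpec()
    if min(J, R, T) < 1 or K < 2:
        raise ValueError("need J, R, T >= 1 and K >= 2")
    rng = np.random.default_rng(seed)
    theta = rng.standard_normal(J)

    n_stable = int(np.floor(mix.stable_fraction * R))
    logmeans = np.concatenate(
        [np.full(n_stable, mix.stable_logmean),
         np.full(R - n_stable, mix.drifting_logmean)]
    )
    logmeans = rng.permutation(logmeans)
    sigma = np.exp(logmeans + mix.logsd * rng.standard_normal(R))

    beta = np.empty((R, T))
    beta[:, 0] = rng.standard_normal(R)
    for t in range(1, T):
        beta[:, t] = beta[:, t - 1] + sigma * rng.standard_normal(R)

    d = np.stack([constrain_steps(rng.standard_normal(K - 2)) for _ in range(R)])
    return ParameterSet(theta=theta, beta=beta, sigma=sigma, d=d)


def _time_blocks(J_indices: np.ndarray, T: int, rng) -> np.ndarray:
    """Assign a rater's examinees to T near-equal contiguous time blocks.

    The examinee order is randomised first, so block membership is random
    while block sizes differ by at most one (sizes ceil or floor of n/T).
    """
    n = J_indices.size
    order = rng.permutation(n)
    sizes = np.full(T, n // T)
    sizes[: n % T] += 1
    times = np.repeat(np.arange(1, T + 1), sizes)
    out = np.empty(n, dtype=np.int64)
    out[order] = times
    return out


def fully_crossed_design(J: int, R: int, T: int, seed=None) -> AssignmentDesign:
    """Every rater scores every examinee once, spread evenly over T periods."""
    rng = np.random.default_rng(seed)
    examinee = np.tile(np.arange(1, J + 1), R)
    rater = np.repeat(np.arange(1, R + 1), J)
    time = np.concatenate(
        [_time_blocks(np.arange(J), T, rng) for _ in range(R)]
    )
    return AssignmentDesign(examinee, rater, time, J=J, R=R, T=T)


def systematic_link_design(
    J: int, R: int, n_raters: int, T: int, seed=None
) -> AssignmentDesign:
    """Sparse connected design: cyclically consecutive raters per examinee.

    Examinee j is scored by the ``n_raters`` raters starting at rater
    ``((j-1) mod R) + 1`` and wrapping around, which chains all raters onto
    a common scale.  Each rater's workload is then split over time periods
    exactly as in the fully crossed design.
    """
    if not 1 <= n_raters <= R:
        raise ValueError(f"n_raters must be in 1..R={R}, got {n_raters}")
    rng = np.random.default_rng(seed)
    examinee_col = []
    rater_col = []
    for j in range(1, J + 1):
        start = (j - 1) % R
        for i in range(n_raters):
            examinee_col.append(j)
            rater_col.append((start + i) % R + 1)
    examinee = np.array(examinee_col, dtype=np.int64)
    rater = np.array(rater_col, dtype=np.int64)
    time = np.empty_like(examinee)
    for r in range(1, R + 1):
        mask = rater == r
        time[mask] = _time_blocks(np.flatnonzero(mask), T, rng)
    return AssignmentDesign(examinee, rater, time, J=J, R=R, T=T)


def make_design(kind: str, J: int, R: int, T: int, seed=None) -> AssignmentDesign:
    """Build one of the named designs: ``crossed``, ``link2`` or ``link3``."""
    if kind == "crossed":
        return fully_crossed_design(J, R, T, seed=seed)
    if kind in ("link2", "link3"):
        return systematic_link_design(J, R, int(kind[-1]), T, seed=seed)
    raise ValueError(f"unknown design {kind!r}; expected one of {DESIGNS}")


def simulate_scores(
    params: ParameterSet, design: AssignmentDesign, seed=None
) -> RatingDataset:
    """Draw one score per assigned (examinee, rater) pair from the model."""
    if design.J > params.J or design.R > params.R or design.T > params.T:
        raise ValueError("design indices exceed parameter dimensions")
    rng = np.random.default_rng(seed)
    j = design.examinee - 1
    r = design.rater - 1
    t = design.time - 1
    K = params.K
    x = params.theta[j] - params.beta[r, t]
    cumd = np.cumsum(params.d, axis=1)
    eta = params.scaling_D * (np.arange(1, K + 1) * x[:, None] - cumd[r])
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(design.n_pairs)
    score = 1 + (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    score = np.minimum(score, K)
    return RatingDataset(
        design.examinee, design.rater, design.time, score.astype(np.int64),
        J=params.J, R=params.R, T=params.T, K=K,
    )
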