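"""Posterior sampling, EAP point estimates and convergence diagnostics.

``fit`` samples one of four model variants:

========================  ==========================  =====================
variant                   step parameters             severity prior
========================  ==========================  =====================
``proposed``              rater-specific d_rm         first-order walk
``proposed_no_markov``    rater-specific d_rm         i.i.d. N(0, 1)
``baseline``              shared d_m                  i.i.d. N(0, 1)
``baseline_markov``       shared d_m                  first-order walk
========================  ==========================  =====================

Point estimates are expected-a-posteriori (EAP): the mean of the posterior
draws, pooled over chains.  Convergence is summarised by the split-chain
potential scale reduction statistic (R-hat) and the autocorrelation-based
effective sample size (ESS); non-convergence is reported, never raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _fast_nuts
from ._density import VARIANTS, PosteriorDensity
from .data import RatingDataset
from .model import BaselineParameterSet, Hyperparameters, ParameterSet, constrain_steps

RHAT_THRESHOLD = 1.1
ESS_THRESHOLD = 400.0


@dataclass
class SamplerConfig:
    """Sampler settings.

    Defaults: three chains, draws retained from iteration 2000 to 5000
    (2000 warmup plus 3000 kept per chain) and a high acceptance target
    of 0.98 chosen to reduce divergent transitions.
    """

    chains: int = 3
    iterations: int = 5000
    warmup: int = 2000
    target_acceptance: float = 0.98
    max_treedepth: int = 10
    seed: int = 0

    def __post_init__(self):
        if not self.warmup < self.iterations:
            raise ValueError("warmup must be smaller than iterations")
        if not 0.0 < self.target_acceptance < 1.0:
            raise ValueError("target_acceptance must lie in (0, 1)")

    @property
    def n_draws(self) -> int:
        return self.iterations - self.warmup


@dataclass
class PosteriorDraws:
    """Per-chain posterior draws plus sampler metadata."""

    variant: str
    z: np.ndarray                 # (chains, draws, dim) unconstrained
    density: PosteriorDensity
    divergences: np.ndarray       # per chain, post-warmup
    step_sizes: np.ndarray
    accept_means: np.ndarray
    treedepth_means: np.ndarray

    @property
    def n_chains(self) -> int:
        return self.z.shape[0]

    @property
    def n_draws(self) -> int:
        return self.z.shape[1]

    @property
    def divergence_count(self) -> int:
        return int(self.divergences.sum())

    @property
    def divergence_fraction(self) -> float:
        return self.divergence_count / (self.n_chains * self.n_draws)

    def merged(self) -> np.ndarray:
        """(chains*draws, dim) unconstrained draws, chains stacked."""
        return self.z.reshape(-1, self.z.shape[2])

    # structured views ---------------------------------------------------

    def theta(self) -> np.ndarray:
        return self.z[:, :, : self.density.J]

    def beta(self) -> np.ndarray:
        d = self.density
        block = self.z[:, :, d.J : d.J + d.R * d.T]
        return block.reshape(self.n_chains, self.n_draws, d.R, d.T)

    def sigma(self) -> np.ndarray | None:
        d = self.density
        if not d.markov:
            return None
        return np.exp(self.z[:, :, d._off_s :])

    def step_free(self) -> np.ndarray:
        d = self.density
        block = self.z[:, :, d._off_d : d._off_s]
        return block.reshape(self.n_chains, self.n_draws, d.n_step_groups, d.n_free)

    def scalar_draws(self) -> dict[str, np.ndarray]:
        """Every sampled scalar as a (chains, draws) matrix, by name."""
        names = self.density.param_names()
        return {name: self.z[:, :, i] for i, name in enumerate(names)}


def fit(
    data: RatingDataset,
    variant: str = "proposed",
    hyper: Hyperparameters | None = None,
    config: SamplerConfig | None = None,
    temper: float = 1.0,
) -> PosteriorDraws:
    """Sample the joint posterior of ``variant`` on ``data`` with NUTS.

    Drift scales are sampled on the log scale (Jacobian included).  Each
    chain is initialised at an independent jittered prior draw; chain seeds
    derive deterministically from ``config.seed``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected {VARIANTS}")
    if config is None:
        config = SamplerConfig()
    density = PosteriorDensity(data, variant, hyper, temper=temper)
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    z = np.empty((config.chains, config.n_draws, density.n_params))
    div = np.empty(config.chains, dtype=int)
    eps = np.empty(config.chains)
    acc = np.empty(config.chains)
    dep = np.empty(config.chains)
    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        z0 = density.init_from_prior(rng)
        res = _fast_nuts.sample_chain(
            density,
            z0,
            n_warmup=config.warmup,
            n_draws=config.n_draws,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            target_accept=config.target_acceptance,
            max_treedepth=config.max_treedepth,
        )
        z[c] = res["draws"]
        div[c] = res["divergences"]
        eps[c] = res["step_size"]
        acc[c] = res["accept_mean"]
        dep[c] = res["treedepth_mean"]
    return PosteriorDraws(
        variant=variant,
        z=z,
        density=density,
        divergences=div,
        step_sizes=eps,
        accept_means=acc,
        treedepth_means=dep,
    )


def eap(draws: PosteriorDraws):
    """Expected-a-posteriori point estimates from the pooled draws.

    Step-parameter means are taken on the free coordinates and then
    constrained, so the estimate satisfies the identification constraints
    exactly; drift scales are averaged on the natural (sigma) scale.
    """
    if draws.n_draws == 0:
        raise ValueError("no posterior draws")
    d = draws.density
    theta = draws.theta().mean(axis=(0, 1))
    beta = draws.beta().mean(axis=(0, 1))
    free = draws.step_free().mean(axis=(0, 1))
    dmat = np.stack([constrain_steps(f) for f in free])
    sig = draws.sigma()
    sigma = None if sig is None else sig.mean(axis=(0, 1))
    if d.rater_steps:
        return ParameterSet(theta, beta, sigma, dmat)
    return BaselineParameterSet(theta, beta, dmat[0], sigma=sigma)


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def _as_chain_matrix(chains: np.ndarray) -> np.ndarray:
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 4:
        raise ValueError("need a (chains >= 2, draws >= 4) matrix")
    return arr


def rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction statistic.

    Chains with zero within-chain variance but distinct levels yield
    ``inf``; a completely constant array yields 1 (no disagreement).
    """
    arr = _as_chain_matrix(chains)
    if np.ptp(arr) == 0.0:
        return 1.0
    half = arr.shape[1] // 2
    split = np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)
    if np.any(split.var(axis=1, ddof=1) == 0.0) and np.ptp(split.mean(axis=1)) > 0:
        return np.inf
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        value = float(az.rhat(arr, method="split"))
    return value if np.isfinite(value) else np.inf


def ess(chains: np.ndarray) -> float:
    """Autocorrelation-adjusted effective sample size (mean-statistic).

    Constant chains carry no information and return 0.
    """
    arr = _as_chain_matrix(chains)
    if np.ptp(arr) == 0.0:
        return 0.0
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        value = float(az.ess(arr, method="mean"))
    return value if np.isfinite(value) else 0.0


@dataclass
class DiagnosticsReport:
    """R-hat and ESS per scalar parameter plus divergence counts."""

    rhat: dict[str, float]
    ess: dict[str, float]
    divergent_count: int
    divergent_fraction: float

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def min_ess(self) -> float:
        return min(self.ess.values())

    @property
    def rhat_ok(self) -> bool:
        return self.max_rhat < RHAT_THRESHOLD

    @property
    def ess_ok(self) -> bool:
        return self.min_ess > ESS_THRESHOLD

    def summary(self) -> str:
        return (
            f"max R-hat {self.max_rhat:.3f} "
            f"({'ok' if self.rhat_ok else 'NOT converged'}), "
            f"min ESS {self.min_ess:.0f} "
            f"({'ok' if self.ess_ok else 'low'}), "
            f"divergent {self.divergent_count} "
            f"({100 * self.divergent_fraction:.2f}%)"
        )


def convergence_summary(draws: PosteriorDraws) -> dict:
    """Cheap whole-fit summary: worst R-hat, smallest ESS, divergences."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(draws.z)
        rhat_vals = az.rhat(ds, method="split")["x"].values.ravel()
        ess_vals = az.ess(ds, method="mean")["x"].values.ravel()
    rhat_vals = np.where(np.isfinite(rhat_vals), rhat_vals, np.inf)
    ess_vals = np.where(np.isfinite(ess_vals), ess_vals, 0.0)
    return {
        "rhat_max": float(rhat_vals.max()),
        "ess_min": float(ess_vals.min()),
        "divergence_fraction": draws.divergence_fraction,
        "divergence_count": draws.divergence_count,
    }


def diagnostics(draws: PosteriorDraws) -> DiagnosticsReport:
    """Convergence report over every sampled scalar parameter."""
    rhats: dict[str, float] = {}
    esses: dict[str, float] = {}
    for name, mat in draws.scalar_draws().items():
        rhats[name] = rhat(mat)
        esses[name] = ess(mat)
    return DiagnosticsReport(
        rhat=rhats,
        ess=esses,
        divergent_count=draws.divergence_count,
        divergent_fraction=draws.divergence_fraction,
    )
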