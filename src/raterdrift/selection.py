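"""Bayesian model comparison: WAIC from posterior draws, WBIC from a
tempered run.

WAIC is reported on the deviance scale,

    WAIC = -2 (lppd - p_waic),
    lppd = sum_i log mean_s exp(ll_si),
    p_waic = sum_i Var_s(ll_si)           (sample variance, n-1),

where ``ll_si`` is the log likelihood of observation i under draw s.  WBIC
is the expectation of the negative log likelihood (in nats) under the
posterior tempered to likelihood power 1 / log n; it approximates the
negative log marginal likelihood.  Lower is better for both, but the two
live on different scales by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data import RatingDataset
from .inference import PosteriorDraws, SamplerConfig, fit
from .model import Hyperparameters


def pointwise_loglik(data: RatingDataset, draws: PosteriorDraws) -> np.ndarray:
    """(draws, observations) matrix of per-observation log likelihoods."""
    if draws.density.data.n_obs != data.n_obs:
        raise ValueError(
            f"draws were fitted on {draws.density.data.n_obs} observations, "
            f"data has {data.n_obs}"
        )
    ll = draws.density.pointwise_loglik(draws.merged())
    assert np.all(np.isfinite(ll)) and np.all(ll <= 0.0)
    return ll


def waic(ll: np.ndarray) -> float:
    """Widely applicable information criterion on the deviance scale."""
    ll = np.atleast_2d(np.asarray(ll, dtype=float))
    S = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(S)))
    if S < 2:
        warnings.warn("single draw: effective-parameter penalty is zero")
        p_waic = 0.0
    else:
        p_waic = float(np.sum(ll.var(axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic)


def wbic(
    data: RatingDataset,
    variant: str = "proposed",
    hyper: Hyperparameters | None = None,
    config: SamplerConfig | None = None,
    temper: float | None = None,
) -> float:
    """Widely applicable Bayesian information criterion, in nats.

    Runs a dedicated sampling pass targeting the posterior with the
    likelihood raised to the power ``1 / log n`` and returns the tempered
    expectation of the negative log likelihood.  ``temper`` overrides the
    power (``temper=1.0`` recovers the ordinary posterior expectation of
    the negative log likelihood, a useful identity for testing).
    """
    n = data.n_obs
    if n < 2:
        raise ValueError("WBIC needs at least two observations (log n > 0)")
    if temper is None:
        temper = 1.0 / np.log(n)
    draws = fit(data, variant, hyper, config, temper=temper)
    ll = draws.density.pointwise_loglik(draws.merged())
    return float(-ll.sum(axis=1).mean())


@dataclass
class ComparisonRow:
    variant: str
    waic: float
    wbic: float


def compare_variants(
    data: RatingDataset,
    variants=("proposed", "proposed_no_markov", "baseline", "baseline_markov"),
    hyper: Hyperparameters | None = None,
    config: SamplerConfig | None = None,
) -> list[ComparisonRow]:
    """WAIC and WBIC for each variant on one dataset (lower is better)."""
    rows = []
    for variant in variants:
        draws = fit(data, variant, hyper, config)
        ll = pointwise_loglik(data, draws)
        rows.append(
            ComparisonRow(
                variant=variant,
                waic=waic(ll),
                wbic=wbic(data, variant, hyper, config),
            )
        )
    return rows
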