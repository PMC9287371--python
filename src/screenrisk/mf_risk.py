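"""Posterior-predictive risk estimation over latent reference profiles.

A fitted set of latent profiles M-hat serves as an empirical prior over
continuous severity trajectories.  The probability of observing state s
given latent value m is a discrete Gaussian-type emission

    p(s | m) = softmax_s( -(m - s)^2 / (2 sigma^2) ),

and the risk of a subject with history y at a future age t-hat is the
posterior-predictive mixture over reference profiles

    p(x_that = s | y)  ∝  sum_n p(s | M_n,that) p(y | M_n),

with per-profile history likelihoods p(y | M_n) = prod_i p(x_i | M_n,ti).
Because the likelihood factorizes over visits, a new exam multiplies one
more emission term into each profile weight: risk estimates update
incrementally as a history grows, without refitting M-hat.  All weight
arithmetic is in log space with a max shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .latent_profiles import (
    FactorizationConfig,
    GraphSpec,
    LatentProfileMatrix,
    emission_log_probs,
    fit_gdl,
    fit_swcmf,
)
from .screening_data import Cohort, ExamRecord, ScreeningHistory, to_state_matrix


@dataclass
class RiskTriple:
    """Normalized probabilities over the 3 observable states at one age."""

    probs: np.ndarray
    target_time: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (3,):
            raise ValueError("risk triple must have 3 entries")
        if (self.probs < 0).any() or abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("risk triple must be a probability vector")


@dataclass
class LikelihoodWeights:
    """Per-reference-profile log-likelihood of the observed history."""

    log_weights: np.ndarray
    last_time: float

    def __post_init__(self) -> None:
        self.log_weights = np.asarray(self.log_weights, dtype=float)
        if not (self.log_weights > -np.inf).any():
            raise ValueError("all profile weights vanished")


def emission_prob(m: float, s: int, sigma: float) -> float:
    """p(observed state = s | latent value m), s in {1, 2, 3}."""
    if s not in (1, 2, 3):
        raise ValueError("state must be in {1, 2, 3}")
    return float(np.exp(emission_log_probs(np.asarray(m), sigma)[..., s - 1]))


def history_log_likelihood(
    history: ScreeningHistory, profiles: LatentProfileMatrix
) -> np.ndarray:
    """Log-likelihood of a history under each reference profile row.

    Sum over records of the log emission probability of the observed
    state at the record's age bin.  A zero-record history returns all
    zeros (the empty-product convention).
    """
    log_w = np.zeros(profiles.values.shape[0])
    for rec in history.records:
        log_w = log_w + _record_log_term(rec, profiles)
    return log_w


def _record_log_term(rec: ExamRecord, profiles: LatentProfileMatrix) -> np.ndarray:
    col = profiles.grid.column(rec.time)
    lp = emission_log_probs(profiles.values[:, col], profiles.sigma)
    return lp[:, rec.state - 1]


def init_weights(
    history: ScreeningHistory, profiles: LatentProfileMatrix
) -> LikelihoodWeights:
    return LikelihoodWeights(
        log_weights=history_log_likelihood(history, profiles),
        last_time=history.records[-1].time,
    )


def update_likelihood(
    weights: LikelihoodWeights,
    record: ExamRecord,
    profiles: LatentProfileMatrix,
) -> LikelihoodWeights:
    """Fold one new exam into the per-profile history likelihoods.

    Equivalent (up to floating-point associativity) to recomputing the
    batch likelihood of the extended history.
    """
    if record.time <= weights.last_time:
        raise ValueError(
            f"record at {record.time} does not extend history ending at "
            f"{weights.last_time}"
        )
    return LikelihoodWeights(
        log_weights=weights.log_weights + _record_log_term(record, profiles),
        last_time=record.time,
    )


def predict_risk(
    weights: LikelihoodWeights,
    profiles: LatentProfileMatrix,
    t_hat: float,
) -> RiskTriple:
    """Posterior-predictive state probabilities at age ``t_hat``."""
    if t_hat <= weights.last_time:
        raise ValueError("prediction age must exceed the last incorporated exam")
    col = profiles.grid.column(t_hat)
    log_emit = emission_log_probs(profiles.values[:, col], profiles.sigma)  # (N, 3)
    log_w = weights.log_weights
    shift = log_w.max()
    w = np.exp(log_w - shift)
    mix = w @ np.exp(log_emit)
    total = mix.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("no reference profile is compatible with the history")
    return RiskTriple(probs=mix / total, target_time=t_hat)


class MatrixFactorizationRisk(BaseEstimator):
    """Risk estimator over factorization-derived latent profiles.

    Parameters
    ----------
    backend : {"swcmf", "gdl"}
        Convolutional (temporal-smoothness) or graph-regularized
        completion of the training state matrix.
    rank : int
        Number of latent factors.
    temporal_smoothness_weight, row_weight, time_weight : float
        Penalty weights; row/time weights apply to the "gdl" backend.

    Attributes
    ----------
    profiles_ : LatentProfileMatrix
        Completed latent severity matrix with its noise scale ``sigma``.
    """

    def __init__(
        self,
        backend: str = "swcmf",
        rank: int = 5,
        temporal_smoothness_weight: float = 10.0,
        row_weight: float = 1.0,
        time_weight: float = 10.0,
        max_iters: int = 100,
        tol: float = 1e-6,
        seed: int = 0,
    ):
        self.backend = backend
        self.rank = rank
        self.temporal_smoothness_weight = temporal_smoothness_weight
        self.row_weight = row_weight
        self.time_weight = time_weight
        self.max_iters = max_iters
        self.tol = tol
        self.seed = seed

    def fit(self, cohort: Cohort, grid=None) -> "MatrixFactorizationRisk":
        z = to_state_matrix(cohort, grid)
        config = FactorizationConfig(
            rank=self.rank,
            temporal_smoothness_weight=self.temporal_smoothness_weight,
            max_iters=self.max_iters,
            tol=self.tol,
            seed=self.seed,
        )
        if self.backend == "swcmf":
            self.profiles_ = fit_swcmf(z, config)
        elif self.backend == "gdl":
            config.temporal_smoothness_weight = 0.0
            graphs = GraphSpec(row_weight=self.row_weight, time_weight=self.time_weight)
            self.profiles_ = fit_gdl(z, graphs, config)
        else:
            raise ValueError("backend must be 'swcmf' or 'gdl'")
        return self

    # incremental-session interface shared by all risk estimators
    def begin(self, history: ScreeningHistory) -> LikelihoodWeights:
        return init_weights(history, self.profiles_)

    def update(
        self, session: LikelihoodWeights, record: ExamRecord
    ) -> LikelihoodWeights:
        return update_likelihood(session, record, self.profiles_)

    def predict_risk(self, session: LikelihoodWeights, t_hat: float) -> RiskTriple:
        return predict_risk(session, self.profiles_, t_hat)
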