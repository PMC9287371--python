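"""Continuous-time hidden Markov risk estimator.

Observed exam results originate from three hidden risk levels (normal /
low-risk / high-risk).  Hidden dynamics follow a continuous-time Markov
chain with intensity matrix Q, so the hidden-state transition kernel
over an inter-visit gap dt is expm(Q dt).  Filtering uses the forward
recursion over the unnormalized posterior

    alpha(h_t0) = p(h | t0) p(x_t0 | h_t0, rho_t0)
    alpha(h_ti) = p(x_ti | h_ti, rho_ti) sum_h' P_{h'h}(dt) alpha(h'),

with an age-banded prior p(h | t0) and per-exam-type emission matrices
p(x | h, rho).  A future state probability marginalizes over the future
hidden state and the future exam type, the latter weighted by the
normalized Poisson screening intensities lambda(rho | h):

    p(x_that = s) ∝ sum_rho sum_hhat sum_h p(s|hhat,rho) p(rho|hhat)
                    P_{h hhat}(that - tj) alpha(h).

Model parameters are consumed from configuration (they are estimated
elsewhere); this module implements filtering and prediction only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .markov import TransitionCache, validate_generator, validate_stochastic
from .mf_risk import RiskTriple
from .screening_data import EXAM_TYPES, Cohort, ExamRecord, ScreeningHistory

HIDDEN_STATES = ("normal", "low-risk", "high-risk")

# Documented default parameters used by tests and the experiment pipeline.
# These mirror the magnitudes of the synthetic-cohort generator: slow
# onset, fast regression of low-risk, noisier cytology than histology.
_DEFAULT = {
    "generator": [
        [-0.0235, 0.0220, 0.0015],
        [0.4000, -0.4600, 0.0600],
        [0.2500, 0.1500, -0.4000],
    ],
    "initial_law": {
        "band_edges": [36.0, 46.0],
        "probs": [
            [0.920, 0.065, 0.015],
            [0.945, 0.043, 0.012],
            [0.975, 0.019, 0.006],
        ],
    },
    "emission": {
        "cytology": [
            [0.940, 0.055, 0.005],
            [0.220, 0.680, 0.100],
            [0.020, 0.160, 0.820],
        ],
        "histology": [
            [0.985, 0.013, 0.002],
            [0.050, 0.880, 0.070],
            [0.005, 0.045, 0.950],
        ],
    },
    "exam_intensity": {
        "cytology": [0.50, 0.60, 0.70],
        "histology": [0.02, 0.30, 1.00],
    },
}


@dataclass
class HMMParams:
    """Hidden Markov model parameters consumed from configuration."""

    generator: np.ndarray
    initial_band_edges: tuple[float, ...]
    initial_probs: np.ndarray  # (n_bands, 3)
    emission: Mapping[str, np.ndarray]  # exam type -> (hidden, observed)
    exam_intensity: Mapping[str, np.ndarray]  # exam type -> rate per hidden state

    def __post_init__(self) -> None:
        self.generator = validate_generator(np.asarray(self.generator, dtype=float))
        self.initial_probs = validate_stochastic(
            np.asarray(self.initial_probs, dtype=float)
        )
        if self.initial_probs.shape[0] != len(self.initial_band_edges) + 1:
            raise ValueError("need one initial law per age band")
        self.emission = {
            k: validate_stochastic(np.asarray(v, dtype=float))
            for k, v in self.emission.items()
        }
        self.exam_intensity = {
            k: np.asarray(v, dtype=float) for k, v in self.exam_intensity.items()
        }
        for ex in EXAM_TYPES:
            if ex not in self.emission or ex not in self.exam_intensity:
                raise ValueError(f"missing parameters for exam type {ex!r}")
            if (self.exam_intensity[ex] < 0).any():
                raise ValueError("exam intensities must be nonnegative")
        rates = np.stack([self.exam_intensity[ex] for ex in EXAM_TYPES])
        if (rates.sum(axis=0) <= 0).any():
            raise ValueError("each hidden state needs a positive total exam rate")

    @classmethod
    def default(cls) -> "HMMParams":
        return cls.from_dict(_DEFAULT)

    @classmethod
    def from_dict(cls, d: Mapping) -> "HMMParams":
        try:
            return cls(
                generator=np.asarray(d["generator"], dtype=float),
                initial_band_edges=tuple(d["initial_law"]["band_edges"]),
                initial_probs=np.asarray(d["initial_law"]["probs"], dtype=float),
                emission={k: np.asarray(v) for k, v in d["emission"].items()},
                exam_intensity={
                    k: np.asarray(v) for k, v in d["exam_intensity"].items()
                },
            )
        except KeyError as err:
            raise ValueError(f"missing HMM parameter section: {err}") from err

    @classmethod
    def from_yaml(cls, path) -> "HMMParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def initial_law(self, age: float) -> np.ndarray:
        band = int(np.searchsorted(self.initial_band_edges, age, side="right"))
        return self.initial_probs[band]

    def exam_type_probs(self) -> np.ndarray:
        """p(rho | h) by rate normalization; shape (n_exam_types, 3)."""
        rates = np.stack([self.exam_intensity[ex] for ex in EXAM_TYPES])
        return rates / rates.sum(axis=0, keepdims=True)


@dataclass
class AlphaState:
    """Unnormalized filtered hidden-state log-probabilities at time ``time``."""

    log_alpha: np.ndarray
    time: float

    def __post_init__(self) -> None:
        self.log_alpha = np.asarray(self.log_alpha, dtype=float)
        if not (self.log_alpha > -np.inf).any():
            raise ValueError("filtered distribution has no support")

    @property
    def probs(self) -> np.ndarray:
        p = np.exp(self.log_alpha - self.log_alpha.max())
        return p / p.sum()


def init_alpha(record: ExamRecord, params: HMMParams) -> AlphaState:
    """alpha(h_t0) = p(h | t0) p(x_t0 | h, rho_t0), in log space."""
    prior = params.initial_law(record.time)
    emit = params.emission[record.exam_type][:, record.state - 1]
    with np.errstate(divide="ignore"):
        log_alpha = np.log(prior) + np.log(emit)
    return AlphaState(log_alpha=log_alpha, time=record.time)


def forward_update(
    alpha: AlphaState,
    record: ExamRecord,
    params: HMMParams,
    _cache: TransitionCache | None = None,
) -> AlphaState:
    """One step of the forward recursion over an inter-visit gap."""
    if record.time <= alpha.time:
        raise ValueError("records must strictly advance in time")
    cache = _cache or TransitionCache(params.generator)
    p = cache(record.time - alpha.time)
    with np.errstate(divide="ignore"):
        log_trans = np.log(p)  # (from, to)
        log_emit = np.log(params.emission[record.exam_type][:, record.state - 1])
    log_pred = logsumexp(alpha.log_alpha[:, None] + log_trans, axis=0)
    return AlphaState(log_alpha=log_emit + log_pred, time=record.time)


def predict_state_probs(
    alpha: AlphaState,
    t_hat: float,
    params: HMMParams,
    _cache: TransitionCache | None = None,
) -> RiskTriple:
    """Marginal observed-state probabilities at a future age."""
    if t_hat <= alpha.time:
        raise ValueError("prediction age must exceed the filter time")
    cache = _cache or TransitionCache(params.generator)
    p_future_hidden = alpha.probs @ cache(t_hat - alpha.time)  # over h-hat
    exam_probs = params.exam_type_probs()  # (exam, hidden)
    probs = np.zeros(3)
    for e, ex in enumerate(EXAM_TYPES):
        probs += (p_future_hidden * exam_probs[e]) @ params.emission[ex]
    total = probs.sum()
    if total <= 0:
        raise ValueError("degenerate prediction: zero total mass")
    return RiskTriple(probs=probs / total, target_time=t_hat)


def filter_history(history: ScreeningHistory, params: HMMParams) -> AlphaState:
    """Run the forward recursion over a whole history."""
    cache = TransitionCache(params.generator)
    alpha = init_alpha(history.records[0], params)
    for rec in history.records[1:]:
        alpha = forward_update(alpha, rec, params, _cache=cache)
    return alpha


class HiddenMarkovRisk(BaseEstimator):
    """Risk estimator wrapping the forward filter and predictive marginal.

    Parameters are consumed as configuration (a mapping or ``HMMParams``);
    ``fit`` validates them and compiles the transition cache.

    Attributes
    ----------
    params_ : HMMParams
    """

    def __init__(self, params: HMMParams | Mapping | None = None):
        self.params = params

    def fit(self, cohort: Cohort | None = None, grid=None) -> "HiddenMarkovRisk":
        p = self.params
        if p is None:
            p = HMMParams.default()
        elif isinstance(p, Mapping):
            p = HMMParams.from_dict(p)
        self.params_ = p
        self._cache = TransitionCache(p.generator)
        return self

    def begin(self, history: ScreeningHistory) -> AlphaState:
        alpha = init_alpha(history.records[0], self.params_)
        for rec in history.records[1:]:
            alpha = forward_update(alpha, rec, self.params_, _cache=self._cache)
        return alpha

    def update(self, session: AlphaState, record: ExamRecord) -> AlphaState:
        return forward_update(session, record, self.params_, _cache=self._cache)

    def predict_risk(self, session: AlphaState, t_hat: float) -> RiskTriple:
        return predict_state_probs(session, t_hat, self.params_, _cache=self._cache)
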