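"""Cross-sectional machine-learning comparators.

Logistic regression, random forest and gradient tree boosting treat each
prediction as an independent classification problem.  Their inputs are
hand-built summaries of the revealed history: cumulative counts of each
observed state conditioned on exam type (6 counts), the age at the last
revealed exam and the target age.  The learners themselves are the
scikit-learn implementations; this module owns only the features, the
Z-score normalization and the warm-start refit protocol.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .mf_risk import RiskTriple
from .screening_data import EXAM_TYPES, STATES, ExamRecord, ScreeningHistory

logger = logging.getLogger(__name__)

FEATURE_NAMES = tuple(
    f"count_{ex}_{s}" for ex in EXAM_TYPES for s in STATES
) + ("last_exam_age", "target_age")


def build_features(
    history: ScreeningHistory, cut_time: float, t_hat: float
) -> np.ndarray:
    """Cumulative state-by-exam-type counts and time stamps at a cut.

    Counts cover records with ``time <= cut_time``; a pure function of
    (history, cut_time, t_hat).
    """
    if cut_time >= t_hat:
        raise ValueError("cut_time must precede the target age")
    revealed = [r for r in history.records if r.time <= cut_time]
    if not revealed:
        raise ValueError("no records at or before the cut time")
    counts = {(ex, s): 0 for ex in EXAM_TYPES for s in STATES}
    for rec in revealed:
        counts[(rec.exam_type, rec.state)] += 1
    vec = [counts[(ex, s)] for ex in EXAM_TYPES for s in STATES]
    vec += [revealed[-1].time, t_hat]
    return np.asarray(vec, dtype=float)


@dataclass
class ZScoreParams:
    mean: np.ndarray
    sd: np.ndarray
    floored: np.ndarray  # features whose sd hit the floor


def zscore_fit(train: np.ndarray, sd_floor: float = 1e-8) -> ZScoreParams:
    """Estimate per-feature moments from a hold-out feature matrix."""
    train = np.atleast_2d(np.asarray(train, dtype=float))
    if train.size == 0:
        raise ValueError("cannot fit Z-scoring on an empty set")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)  # population convention
    floored = sd < sd_floor
    if floored.any():
        warnings.warn(
            f"zero-variance features floored: {np.flatnonzero(floored).tolist()}"
        )
    return ZScoreParams(mean=mean, sd=np.where(floored, 1.0, sd), floored=floored)


def zscore_apply(x: np.ndarray, params: ZScoreParams) -> np.ndarray:
    """Apply frozen normalization; never recomputes moments."""
    x = np.asarray(x, dtype=float)
    out = (x - params.mean) / params.sd
    if params.floored.any():
        out[..., params.floored] = 0.0
    return out


def zscore_fit_apply(train: np.ndarray, apply: np.ndarray):
    params = zscore_fit(train)
    return zscore_apply(apply, params), params


def warm_start_refit(model, x_new: np.ndarray, y_new: np.ndarray):
    """Refit with additional rows, reusing current parameters where possible.

    Logistic regression supports true warm starts (current coefficients
    initialize the solver); the tree ensembles are refit from scratch on
    the pooled data, with a notice logged.  The pooled data is tracked on
    the model as ``_pooled_x`` / ``_pooled_y``.
    """
    x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
    y_new = np.asarray(y_new)
    if not hasattr(model, "_pooled_x"):
        raise ValueError("model must be fit before warm-start refitting")
    if x_new.size and x_new.shape[1] != model._pooled_x.shape[1]:
        raise ValueError("new rows do not match the training schema")
    if x_new.shape[0] == 0:
        return model
    x = np.vstack([model._pooled_x, x_new])
    y = np.concatenate([model._pooled_y, y_new])
    if isinstance(model, LogisticRegression):
        model.set_params(warm_start=True)
    else:
        logger.info(
            "%s does not support parameter warm starts; refitting on pooled data",
            type(model).__name__,
        )
    model.fit(x, y)
    model._pooled_x, model._pooled_y = x, y
    return model


def _make_learner(kind: str, seed: int):
    if kind == "lr":
        return LogisticRegression(max_iter=2000)
    if kind == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if kind == "gtb":
        return GradientBoostingClassifier(random_state=seed)
    raise ValueError("learner must be one of 'lr', 'rf', 'gtb'")


class CountFeatureRisk(BaseEstimator):
    """Adapter giving LR/RF/GTB the shared incremental-risk interface.

    Training examples replay each training history: for every exam from
    the third onward whose predecessor clears the horizon gap, the
    features summarize the history up to ``horizon`` years before the
    exam and the label is the exam's observed state.

    Attributes
    ----------
    model_ : fitted scikit-learn classifier
    zscore_ : ZScoreParams or None
        Normalization (logistic regression only), frozen from training.
    """

    def __init__(self, learner: str = "lr", horizon: float = 0.5, seed: int = 0):
        self.learner = learner
        self.horizon = horizon
        self.seed = seed

    def fit(self, cohort, grid=None) -> "CountFeatureRisk":
        xs, ys = [], []
        for history in cohort:
            for j in range(2, len(history)):
                t_target = history.records[j].time
                cut = t_target - self.horizon
                if history.records[j - 1].time > cut:
                    continue
                xs.append(build_features(history, cut, t_target))
                ys.append(history.records[j].state)
        if not xs:
            raise ValueError("no usable training targets in the cohort")
        x = np.asarray(xs)
        y = np.asarray(ys)
        self.zscore_ = None
        if self.learner == "lr":
            self.zscore_ = zscore_fit(x)
            x = zscore_apply(x, self.zscore_)
        self.model_ = _make_learner(self.learner, self.seed)
        self.model_.fit(x, y)
        self.model_._pooled_x, self.model_._pooled_y = x, y
        return self

    def begin(self, history: ScreeningHistory) -> ScreeningHistory:
        return history

    def update(self, session: ScreeningHistory, record: ExamRecord):
        return ScreeningHistory(
            subject_id=session.subject_id, records=session.records + (record,)
        )

    def predict_risk(self, session: ScreeningHistory, t_hat: float) -> RiskTriple:
        x = build_features(session, session.records[-1].time, t_hat)[None, :]
        if self.zscore_ is not None:
            x = zscore_apply(x, self.zscore_)
        proba = self.model_.predict_proba(x)[0]
        probs = np.zeros(3)
        for cls, p in zip(self.model_.classes_, proba):
            probs[int(cls) - 1] = p
        total = probs.sum()
        return RiskTriple(probs=probs / total, target_time=t_hat)
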