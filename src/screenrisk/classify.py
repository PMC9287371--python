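"""State classification from risk triples under class imbalance.

The default strategy picks the most probable state.  Because screening
data is heavily skewed towards normal results, the default rule rarely
predicts the minority states; the adaptive strategy instead applies
state-specific probability thresholds, evaluated in severity order
(high-grade first, then low-grade, normal as fallback) so that false
positives are preferred to false negatives.  Thresholds are fit per
female age interval — the state mix drifts with age — by maximizing the
K-category Matthews correlation coefficient

    R_K = (c n - sum_s phat_s n_s) / sqrt((n^2 - sum phat_s^2)(n^2 - sum n_s^2))

with a seeded differential-evolution search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import differential_evolution
from sklearn.base import BaseEstimator

DEFAULT_INTERVALS = ((20.0, 36.0), (36.0, 46.0), (46.0, np.inf))


@dataclass(frozen=True)
class AgeIntervals:
    """Ordered, non-overlapping, gap-free age intervals [lo, hi)."""

    bounds: tuple[tuple[float, float], ...] = DEFAULT_INTERVALS

    def __post_init__(self) -> None:
        b = self.bounds
        if not b:
            raise ValueError("need at least one interval")
        for (alo, ahi), (blo, bhi) in zip(b, b[1:]):
            if ahi != blo:
                raise ValueError("intervals must be contiguous and ordered")
        if any(lo >= hi for lo, hi in b):
            raise ValueError("intervals must be non-degenerate")

    def __len__(self) -> int:
        return len(self.bounds)

    def index(self, age: float) -> int:
        for k, (lo, hi) in enumerate(self.bounds):
            if lo <= age < hi:
                return k
        raise ValueError(f"age {age} outside the covered range")

    def contains(self, ages: np.ndarray) -> np.ndarray:
        """Boolean mask of ages inside the covered range."""
        ages = np.asarray(ages, dtype=float)
        return (ages >= self.bounds[0][0]) & (ages < self.bounds[-1][1])

    def indices(self, ages: np.ndarray) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        lows = np.array([lo for lo, _ in self.bounds])
        idx = np.searchsorted(lows, ages, side="right") - 1
        his = np.array([hi for _, hi in self.bounds])
        bad = (idx < 0) | (ages >= his[np.clip(idx, 0, len(his) - 1)])
        if bad.any():
            raise ValueError(f"ages outside the covered range: {ages[bad][:5]}")
        return idx


@dataclass
class ThresholdSet:
    """Per-age-interval thresholds for the low- and high-grade states."""

    intervals: AgeIntervals
    delta2: np.ndarray  # threshold on p(low-grade) per interval
    delta3: np.ndarray  # threshold on p(high-grade) per interval
    achieved_mcc: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delta2 = np.asarray(self.delta2, dtype=float)
        self.delta3 = np.asarray(self.delta3, dtype=float)
        k = len(self.intervals)
        if self.delta2.shape != (k,) or self.delta3.shape != (k,):
            raise ValueError("need one (delta2, delta3) pair per interval")
        for d in (self.delta2, self.delta3):
            if ((d <= 0) | (d >= 1)).any():
                raise ValueError("thresholds must lie strictly in (0, 1)")


def classify_default(probs: np.ndarray) -> int | np.ndarray:
    """Most probable state; ties broken towards the more severe state."""
    p = np.asarray(probs, dtype=float)
    rev = p[..., ::-1]  # scan severe-to-mild so argmax keeps the severe tie
    return (3 - np.argmax(rev, axis=-1)).astype(int) if p.ndim > 1 else int(
        3 - np.argmax(rev)
    )


def classify_adaptive(
    probs: np.ndarray,
    ages: np.ndarray | float,
    thresholds: ThresholdSet,
) -> int | np.ndarray:
    """Severity-ordered thresholding with age-interval-specific cutoffs."""
    p = np.atleast_2d(np.asarray(probs, dtype=float))
    scalar = np.isscalar(ages) or np.ndim(ages) == 0
    idx = thresholds.intervals.indices(np.atleast_1d(ages))
    d2 = thresholds.delta2[idx]
    d3 = thresholds.delta3[idx]
    out = np.ones(p.shape[0], dtype=int)
    out[p[:, 1] >= d2] = 2
    out[p[:, 2] >= d3] = 3  # high-grade evaluated first, so it wins
    return int(out[0]) if scalar and p.shape[0] == 1 else out


def mcc_multiclass(truth: Sequence[int], pred: Sequence[int]) -> float:
    """K-category Matthews correlation coefficient.

    Degenerate denominators (single-class truth or prediction) return 0.
    """
    t = np.asarray(truth)
    p = np.asarray(pred)
    if t.shape != p.shape or t.ndim != 1 or len(t) < 1:
        raise ValueError("truth and prediction must be equal-length vectors")
    n = len(t)
    classes = np.union1d(t, p)
    n_correct = int((t == p).sum())
    n_s = np.array([(t == c).sum() for c in classes])
    nhat_s = np.array([(p == c).sum() for c in classes])
    num = n_correct * n - int((nhat_s * n_s).sum())
    den = np.sqrt(float(n**2 - (nhat_s**2).sum()) * float(n**2 - (n_s**2).sum()))
    return float(num / den) if den > 0 else 0.0


def _mcc_for_thresholds(delta, probs, truth, ages_mask):
    pred = np.ones(len(truth), dtype=int)
    pred[probs[:, 1] >= delta[0]] = 2
    pred[probs[:, 2] >= delta[1]] = 3
    return mcc_multiclass(truth, pred)


def fit_thresholds(
    probs: np.ndarray,
    truth: Sequence[int],
    ages: Sequence[float],
    intervals: AgeIntervals | None = None,
    seed: int = 0,
    popsize: int = 30,
    maxiter: int = 200,
    tol: float = 1e-8,
    bounds: tuple[float, float] = (0.001, 0.999),
) -> ThresholdSet:
    """Fit per-interval thresholds by maximizing R_K with differential evolution.

    Intervals whose samples contain fewer than two distinct true states
    cannot support threshold selection; they fall back to 0.5 with a
    warning.  Runs are reproducible under ``seed``.
    """
    intervals = intervals or AgeIntervals()
    probs = np.asarray(probs, dtype=float)
    truth = np.asarray(truth)
    ages = np.asarray(ages, dtype=float)
    if not (len(probs) == len(truth) == len(ages)):
        raise ValueError("probs, truth and ages must align")
    idx = intervals.indices(ages)
    k = len(intervals)
    d2 = np.full(k, 0.5)
    d3 = np.full(k, 0.5)
    achieved = np.full(k, np.nan)
    for band in range(k):
        sel = idx == band
        if sel.sum() == 0 or len(np.unique(truth[sel])) < 2:
            warnings.warn(
                f"age interval {intervals.bounds[band]} lacks class variety; "
                "using default thresholds 0.5"
            )
            continue
        p_band, t_band = probs[sel], truth[sel]
        res = differential_evolution(
            lambda d: -_mcc_for_thresholds(d, p_band, t_band, None),
            bounds=[bounds, bounds],
            seed=seed,
            popsize=popsize,
            maxiter=maxiter,
            tol=tol,
            polish=False,
        )
        # optimizer sanity floor: never do worse than the default cutoff
        base = _mcc_for_thresholds((0.5, 0.5), p_band, t_band, None)
        if -res.fun >= base:
            d2[band], d3[band] = res.x
            achieved[band] = -res.fun
        else:
            achieved[band] = base
    return ThresholdSet(
        intervals=intervals, delta2=d2, delta3=d3, achieved_mcc=achieved
    )


class AdaptiveThresholdClassifier(BaseEstimator):
    """Scikit-learn-style wrapper around the adaptive thresholding rule.

    ``fit`` consumes risk triples, true states and ages; ``predict``
    applies the fitted per-interval thresholds.

    Attributes
    ----------
    thresholds_ : ThresholdSet
    """

    def __init__(
        self,
        intervals: AgeIntervals | None = None,
        seed: int = 0,
        popsize: int = 30,
        maxiter: int = 200,
    ):
        self.intervals = intervals
        self.seed = seed
        self.popsize = popsize
        self.maxiter = maxiter

    def fit(self, probs, truth, ages) -> "AdaptiveThresholdClassifier":
        self.thresholds_ = fit_thresholds(
            probs,
            truth,
            ages,
            intervals=self.intervals or AgeIntervals(),
            seed=self.seed,
            popsize=self.popsize,
            maxiter=self.maxiter,
        )
        return self

    def predict(self, probs, ages) -> np.ndarray:
        return classify_adaptive(probs, ages, self.thresholds_)
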