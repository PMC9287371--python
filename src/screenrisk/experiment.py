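"""End-to-end longitudinal prediction experiment.

The pipeline mirrors a registry-style evaluation: simulate (or load) a
cohort, sample training histories weighted by their most severe result,
restrict the test set to histories starting at ages 20-30, fit every
estimator on the training side, then replay each test history with a
moving window — reveal the first two exams, predict the third, fold in
the previous exam and move to the next — always conditioning only on
data at least six months older than the target.  Classification
thresholds are fit on a validation split carved from the training side,
never on test subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .baselines import CountFeatureRisk
from .classify import (
    AgeIntervals,
    ThresholdSet,
    classify_adaptive,
    classify_default,
    fit_thresholds,
    mcc_multiclass,
)
from .evaluate import (
    DEFAULT_WINDOW_YEARS,
    absolute_risk_curve,
    brier_stratified,
    eta_by_state,
)
from .hmm_risk import HiddenMarkovRisk
from .mf_risk import MatrixFactorizationRisk, RiskTriple
from .screening_data import (
    AgeGrid,
    Cohort,
    ScreeningHistory,
    history_prefix,
    most_severe_state,
)
from .synthetic_cohort import GeneratorConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_train: int = 10_000
    n_validation: int = 1_000
    n_test: int = 50_000
    min_exams: int = 3
    test_first_exam_age: tuple[float, float] = (20.0, 30.0)
    horizon: float = 0.5  # years between last usable exam and the target
    estimators: tuple[str, ...] = ("mf", "hmm", "gdl", "lr", "rf", "gtb")
    intervals: AgeIntervals = field(default_factory=AgeIntervals)
    grid: AgeGrid = field(default_factory=AgeGrid)
    window: float = DEFAULT_WINDOW_YEARS
    mf_rank: int = 5
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("prediction horizon must be positive")
        if self.min_exams < 3:
            raise ValueError("rolling prediction needs at least 3 exams")


class ExperimentError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"experiment stage {stage!r} failed: {err}")
        self.stage = stage


def sample_train_test(
    cohort: Cohort, config: ExperimentConfig, rng: np.random.Generator
) -> tuple[Cohort, Cohort, Cohort]:
    """Severity-weighted train/validation sample and an age-filtered test set.

    Training (and validation) histories are drawn without replacement with
    selection probability proportional to the most severe state in the
    history; the test set is drawn uniformly from the remainder restricted
    to first exams at ages 20-30.  The three sets are disjoint.
    """
    eligible = [h for h in cohort if len(h) >= config.min_exams]
    if len(eligible) < config.n_train:
        raise ValueError(
            f"only {len(eligible)} histories with >= {config.min_exams} exams; "
            f"need {config.n_train} for training"
        )
    weights = np.array([most_severe_state(h) for h in eligible], dtype=float)
    pick = rng.choice(
        len(eligible), size=config.n_train, replace=False, p=weights / weights.sum()
    )
    picked = set(pick.tolist())
    train_ids = [eligible[i].subject_id for i in pick]
    # validation and test follow the same selection law (uniform over the
    # remainder, first exam at the recommended starting ages) so that
    # thresholds fit on validation transfer to the test population
    lo, hi = config.test_first_exam_age
    rest = [
        h
        for i, h in enumerate(eligible)
        if i not in picked and lo <= h.records[0].time <= hi
    ]
    n_held_out = config.n_test + config.n_validation
    if len(rest) < n_held_out:
        raise ValueError(
            f"only {len(rest)} eligible held-out histories; need {n_held_out}"
        )
    held_pick = rng.choice(len(rest), size=n_held_out, replace=False)
    test_ids = [rest[i].subject_id for i in held_pick[: config.n_test]]
    val_ids = [rest[i].subject_id for i in held_pick[config.n_test :]]
    return (
        cohort.subset(train_ids),
        cohort.subset(val_ids),
        cohort.subset(test_ids),
    )


class OracleRisk:
    """Audit estimator reading the simulator's true latent states.

    For a target exam it returns the exact conditional distribution of
    the observed result given the true state at that visit: the exam-type
    law mixed through the per-exam confusion matrices.  This is the best
    any history-based predictor can do and bounds the achievable
    calibration from below.
    """

    def __init__(self, generator_config: GeneratorConfig):
        self.config = generator_config

    def fit(self, cohort: Cohort, grid=None) -> "OracleRisk":
        return self

    def set_truth(self, cohort: Cohort) -> None:
        truths = cohort.metadata.get("true_states")
        if truths is None:
            raise ValueError("cohort carries no simulator truth")
        self._lookup = {}
        for h in cohort:
            for rec, true_state in zip(h.records, truths[h.subject_id]):
                self._lookup[(h.subject_id, round(rec.time, 9))] = true_state

    def begin(self, history: ScreeningHistory) -> str:
        return history.subject_id

    def update(self, session: str, record) -> str:
        return session

    def predict_risk(self, session: str, t_hat: float) -> RiskTriple:
        true_state = self._lookup[(session, round(t_hat, 9))]
        cfg = self.config
        p_hist = cfg.p_histology_given_state[true_state - 1]
        probs = (1 - p_hist) * np.asarray(cfg.confusion_cytology)[true_state - 1] + (
            p_hist * np.asarray(cfg.confusion_histology)[true_state - 1]
        )
        return RiskTriple(probs=probs / probs.sum(), target_time=t_hat)


def make_estimator(name: str, config: ExperimentConfig):
    if name == "mf":
        return MatrixFactorizationRisk(backend="swcmf", rank=config.mf_rank,
                                       seed=config.seed)
    if name == "gdl":
        return MatrixFactorizationRisk(backend="gdl", rank=config.mf_rank,
                                       seed=config.seed)
    if name == "hmm":
        return HiddenMarkovRisk()
    if name in ("lr", "rf", "gtb"):
        return CountFeatureRisk(learner=name, horizon=config.horizon,
                                seed=config.seed)
    if name == "oracle":
        return OracleRisk(config.generator)
    raise ValueError(f"unknown estimator {name!r}")


def rolling_prediction(
    estimator, history: ScreeningHistory, horizon: float = 0.5
) -> list[dict]:
    """Moving-window predictions along one history.

    The first two exams are revealed up front; each later exam is a
    prediction target, after which it is folded into the estimator state.
    A target is skipped (and logged) when its preceding exam falls inside
    the horizon gap, so the conditioning set always lags the target by at
    least ``horizon`` years.
    """
    if len(history) < 3:
        raise ValueError("rolling prediction needs at least 3 records")
    session = estimator.begin(history_prefix(history, 2))
    out = []
    for j in range(2, len(history)):
        if j > 2:
            session = estimator.update(session, history.records[j - 1])
        target = history.records[j]
        if history.records[j - 1].time > target.time - horizon:
            logger.debug(
                "subject %s target %d inside the %.2fy horizon; skipped",
                history.subject_id, j, horizon,
            )
            continue
        risk = estimator.predict_risk(session, target.time)
        out.append(
            {
                "subject_id": history.subject_id,
                "target_index": j,
                "age": target.time,
                "truth": target.state,
                "p1": float(risk.probs[0]),
                "p2": float(risk.probs[1]),
                "p3": float(risk.probs[2]),
            }
        )
    return out


def predict_cohort(estimator, cohort: Cohort, horizon: float) -> pd.DataFrame:
    """Rolling predictions over a cohort as a long-format log."""
    rows = []
    for history in cohort:
        try:
            rows.extend(rolling_prediction(estimator, history, horizon))
        except Exception as err:  # noqa: BLE001 - continue over subjects
            logger.warning("subject %s aborted: %s", history.subject_id, err)
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "target_index", "age", "truth", "p1", "p2", "p3",
        ],
    )


def _metrics_for_model(
    log: pd.DataFrame,
    thresholds: ThresholdSet,
    intervals: AgeIntervals,
    window: float,
    origin: float,
) -> dict:
    probs = log[["p1", "p2", "p3"]].to_numpy()
    truth = log["truth"].to_numpy()
    ages = log["age"].to_numpy()
    pred_default = classify_default(probs)
    pred_adaptive = classify_adaptive(probs, ages, thresholds)
    brier = brier_stratified(probs, truth)
    idx = intervals.indices(ages)
    rk = {}
    for band, bnds in enumerate(intervals.bounds):
        sel = idx == band
        rk[bnds] = {
            "default": mcc_multiclass(truth[sel], pred_default[sel]) if sel.any() else np.nan,
            "adaptive": mcc_multiclass(truth[sel], pred_adaptive[sel]) if sel.any() else np.nan,
            "n": int(sel.sum()),
        }
    overall = {
        "default": mcc_multiclass(truth, pred_default),
        "adaptive": mcc_multiclass(truth, pred_adaptive),
    }
    strategy = "adaptive" if overall["adaptive"] >= overall["default"] else "default"
    labels = pred_adaptive if strategy == "adaptive" else pred_default
    ref_curve = absolute_risk_curve(ages, truth, window, origin=origin)
    pred_curve = absolute_risk_curve(ages, labels, window, origin=origin)
    return {
        "brier": brier,
        "rk_by_interval": rk,
        "rk_overall": overall,
        "strategy": strategy,
        "eta": eta_by_state(ref_curve, pred_curve),
        "reference_curve": ref_curve,
        "predicted_curve": pred_curve,
        "labels_default": pred_default,
        "labels_adaptive": pred_adaptive,
    }


def run_experiment(config: ExperimentConfig) -> dict:
    """Simulate, sample, fit, predict, classify and score; returns a bundle.

    The bundle maps model names to per-prediction logs and metric tables;
    everything is reproducible from ``config`` alone.  When ``out_dir``
    is set, the per-prediction log and the metric tables are written as
    CSV.
    """
    stage = "simulate"
    try:
        generator = replace(config.generator)
        cohort = simulate_cohort(generator)
        stage = "sample"
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**20]))
        train, validation, test = sample_train_test(cohort, config, rng)
        logger.info(
            "sampled %d train / %d validation / %d test histories",
            len(train), len(validation), len(test),
        )
        bundle = {"config": config, "models": {}}
        for name in config.estimators:
            stage = f"fit:{name}"
            est = make_estimator(name, config)
            est.fit(train, config.grid)
            if isinstance(est, OracleRisk):
                est.set_truth(cohort)
            stage = f"predict:{name}"
            val_log = predict_cohort(est, validation, config.horizon)
            test_log = predict_cohort(est, test, config.horizon)
            # classification is defined only on the configured age range
            val_log = val_log[config.intervals.contains(val_log["age"])]
            n_out = int((~config.intervals.contains(test_log["age"])).sum())
            if n_out:
                logger.info("dropping %d test targets outside the age range", n_out)
            test_log = test_log[config.intervals.contains(test_log["age"])]
            test_log = test_log.reset_index(drop=True)
            stage = f"thresholds:{name}"
            thresholds = fit_thresholds(
                val_log[["p1", "p2", "p3"]].to_numpy(),
                val_log["truth"].to_numpy(),
                val_log["age"].to_numpy(),
                intervals=config.intervals,
                seed=config.seed,
            )
            stage = f"score:{name}"
            origin = float(test_log["age"].min())
            metrics = _metrics_for_model(
                test_log, thresholds, config.intervals, config.window, origin
            )
            metrics["thresholds"] = thresholds
            bundle["models"][name] = {"log": test_log, "metrics": metrics}
        if config.out_dir:
            _write_report(bundle, Path(config.out_dir))
        return bundle
    except ExperimentError:
        raise
    except Exception as err:  # noqa: BLE001
        raise ExperimentError(stage, err) from err


def _write_report(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    brier_rows, rk_rows, eta_rows = [], [], []
    for name, entry in bundle["models"].items():
        log = entry["log"].copy()
        log.insert(0, "model", name)
        log.to_csv(out_dir / f"predictions_{name}.csv", index=False)
        m = entry["metrics"]
        brier_rows.append({"model": name, **{f"state_{s}": v for s, v in m["brier"].items()}})
        for bnds, vals in m["rk_by_interval"].items():
            rk_rows.append({
                "model": name, "age_lo": bnds[0], "age_hi": bnds[1],
                "rk_default": vals["default"], "rk_adaptive": vals["adaptive"],
                "n": vals["n"],
            })
        eta_rows.append({
            "model": name, "strategy": m["strategy"],
            **{f"state_{s}": v for s, v in m["eta"].items()},
        })
    pd.DataFrame(brier_rows).to_csv(out_dir / "brier_by_state.csv", index=False)
    pd.DataFrame(rk_rows).to_csv(out_dir / "rk_by_interval.csv", index=False)
    pd.DataFrame(eta_rows).to_csv(out_dir / "eta_by_state.csv", index=False)


def audit_no_leakage(
    cohort: Cohort, logs: pd.DataFrame, horizon: float
) -> bool:
    """Independent check that every prediction respects the horizon gap.

    For each logged prediction, the conditioning set is the set of
    records preceding the target index; all must be at least ``horizon``
    years older than the target age.
    """
    by_id = {h.subject_id: h for h in cohort}
    for row in logs.itertuples():
        history = by_id[row.subject_id]
        j = int(row.target_index)
        conditioning = history.records[:j]
        if any(r.time > row.age - horizon + 1e-12 for r in conditioning):
            return False
    return True
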