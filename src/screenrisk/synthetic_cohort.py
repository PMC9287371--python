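"""Synthetic screening-cohort generator.

Registry screening data is access-restricted, so estimators and metrics
are exercised on simulated cohorts that reproduce the population's
summary structure: a heavy skew towards normal results (>85% normal,
<5% high-grade overall), a normal proportion drifting from about 0.87
below age 36 up to about 0.93 from age 46, inter-exam gaps from about a
month to two decades, a median of 6 exams per history, and first exams
concentrated at ages 20-30.

The generative model is a 3-state continuous-time Markov chain over the
true disease state (normal / low-grade / high-grade) with age-band
piecewise intensity matrices; low-grade lesions may regress and
high-grade states exit through treatment.  At each visit an exam type is
drawn (histology more likely after abnormality) and the observed state
is the true state passed through a per-exam-type confusion matrix,
cytology being the noisier modality.  None of these mechanisms is meant
as a registry-calibrated disease model; they are the simplest dynamics
reproducing the summaries above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .markov import TransitionCache, validate_generator, validate_stochastic
from .screening_data import Cohort, ExamRecord, ScreeningHistory

# Intensity matrices (events per year) per age band.  Rates are chosen so
# that the observed-state mix, after exam noise, drifts from ~0.87 normal
# below age 36 towards ~0.93 normal from age 46.
_Q_YOUNG = [
    [-0.037, 0.035, 0.002],
    [0.400, -0.460, 0.060],
    [0.250, 0.150, -0.400],
]
_Q_MID = [
    [-0.0235, 0.022, 0.0015],
    [0.400, -0.460, 0.060],
    [0.250, 0.150, -0.400],
]
_Q_OLD = [
    [-0.009, 0.008, 0.001],
    [0.400, -0.460, 0.060],
    [0.250, 0.150, -0.400],
]

# Row-stochastic confusion matrices (true state -> observed state).
_CONFUSION_CYTOLOGY = [
    [0.940, 0.055, 0.005],
    [0.220, 0.680, 0.100],
    [0.020, 0.160, 0.820],
]
_CONFUSION_HISTOLOGY = [
    [0.985, 0.013, 0.002],
    [0.050, 0.880, 0.070],
    [0.005, 0.045, 0.950],
]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort simulator.

    The defaults are calibrated against published cohort summaries (state
    mix, age drift, exam-count median, gap range); every law is exposed so
    alternative scenarios can be simulated.
    """

    seed: int = 0
    n_histories: int = 1000
    # Age at first exam: truncated normal, concentrated at ages 20-30.
    first_exam_age_mean: float = 25.0
    first_exam_age_sd: float = 3.0
    first_exam_age_bounds: tuple[float, float] = (18.0, 45.0)
    # Number of exams per history: 1 + Poisson(rate); rate 5.5 gives median 6.
    exam_count_rate: float = 5.5
    # Inter-exam gaps: log-normal (years), clipped to ~1 month .. 20 years.
    visit_gap_log_mean: float = float(np.log(1.6))
    visit_gap_log_sd: float = 0.85
    visit_gap_bounds: tuple[float, float] = (1.0 / 12.0, 20.0)
    # Histories are truncated at this age (the default age-grid upper edge).
    max_age: float = 80.0
    # True-state dynamics: piecewise CTMC generators per age band.
    age_band_edges: tuple[float, float] = (36.0, 46.0)
    age_band_intensities: tuple = (_Q_YOUNG, _Q_MID, _Q_OLD)
    # True state at the first exam.
    initial_state_probs: tuple[float, float, float] = (0.920, 0.065, 0.015)
    # P(histology | current true state); histology follows abnormality.
    p_histology_given_state: tuple[float, float, float] = (0.04, 0.35, 0.70)
    # Misclassification per exam type (true -> observed).
    confusion_cytology: Sequence = field(
        default_factory=lambda: [row[:] for row in _CONFUSION_CYTOLOGY]
    )
    confusion_histology: Sequence = field(
        default_factory=lambda: [row[:] for row in _CONFUSION_HISTOLOGY]
    )

    def validate(self) -> None:
        if self.n_histories < 1:
            raise ValueError("n_histories must be >= 1")
        if len(self.age_band_intensities) != len(self.age_band_edges) + 1:
            raise ValueError("need one intensity matrix per age band")
        for q in self.age_band_intensities:
            validate_generator(np.asarray(q, dtype=float))
        validate_stochastic(np.asarray(self.confusion_cytology))
        validate_stochastic(np.asarray(self.confusion_histology))
        validate_stochastic(np.asarray(self.initial_state_probs))
        if not all(0.0 <= p <= 1.0 for p in self.p_histology_given_state):
            raise ValueError("p_histology_given_state entries must be in [0, 1]")
        lo, hi = self.visit_gap_bounds
        if not (0 < lo < hi):
            raise ValueError("visit gap bounds must satisfy 0 < lo < hi")


class _Dynamics:
    """Compiled per-band transition caches for one configuration."""

    def __init__(self, config: GeneratorConfig):
        config.validate()
        self.config = config
        self.caches = [
            TransitionCache(np.asarray(q, dtype=float))
            for q in config.age_band_intensities
        ]
        self.confusion = {
            "cytology": np.asarray(config.confusion_cytology, dtype=float),
            "histology": np.asarray(config.confusion_histology, dtype=float),
        }

    def band(self, age: float) -> int:
        return int(np.searchsorted(self.config.age_band_edges, age, side="right"))

    def evolve(self, state0: int, t_from: float, t_to: float, rng) -> int:
        """Propagate the true state, splitting the gap at band boundaries.

        ``state0`` is a 0-based state index.
        """
        t, state = t_from, state0
        while t < t_to - 1e-12:
            b = self.band(t)
            t_next = min(
                t_to,
                *(e for e in self.config.age_band_edges if e > t + 1e-12),
                self.config.max_age + 100.0,
            )
            p = self.caches[b](t_next - t)
            state = int(rng.choice(3, p=p[state]))
            t = t_next
        return state


def simulate_history(
    config: GeneratorConfig,
    rng: np.random.Generator,
    subject_id: str = "s0",
) -> tuple[ScreeningHistory, tuple[int, ...]]:
    """Simulate one screening history.

    Returns the history and the parallel tuple of true (latent) states at
    each visit, for use by oracle evaluations.
    """
    dyn = _Dynamics(config)
    return _simulate_one(dyn, rng, subject_id)


def _simulate_one(dyn, rng, subject_id):
    cfg = dyn.config
    lo, hi = cfg.first_exam_age_bounds
    while True:
        age = rng.normal(cfg.first_exam_age_mean, cfg.first_exam_age_sd)
        if lo <= age <= hi:
            break
    n_visits = 1 + int(rng.poisson(cfg.exam_count_rate))
    state = int(rng.choice(3, p=np.asarray(cfg.initial_state_probs)))
    records, true_states = [], []
    for visit in range(n_visits):
        p_hist = cfg.p_histology_given_state[state]
        exam = "histology" if rng.random() < p_hist else "cytology"
        observed = int(rng.choice(3, p=dyn.confusion[exam][state])) + 1
        records.append(ExamRecord(time=age, exam_type=exam, state=observed))
        true_states.append(state + 1)
        if visit == n_visits - 1:
            break
        gap = float(
            np.clip(
                rng.lognormal(cfg.visit_gap_log_mean, cfg.visit_gap_log_sd),
                *cfg.visit_gap_bounds,
            )
        )
        if age + gap >= cfg.max_age:
            break
        state = dyn.evolve(state, age, age + gap, rng)
        age += gap
    history = ScreeningHistory(subject_id=subject_id, records=tuple(records))
    return history, tuple(true_states)


def simulate_cohort(config: GeneratorConfig) -> Cohort:
    """Simulate an independent cohort, reproducible under ``config.seed``.

    Each subject uses its own random substream, so cohorts of different
    sizes share the histories of their common prefix.  True latent states
    per visit are stored in ``cohort.metadata["true_states"]``.
    """
    dyn = _Dynamics(config)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_histories)
    histories, truths = [], {}
    for i, ss in enumerate(seeds):
        sid = f"s{i:06d}"
        history, true_states = _simulate_one(
            dyn, np.random.default_rng(ss), sid
        )
        histories.append(history)
        truths[sid] = true_states
    return Cohort(
        histories=histories,
        metadata={"generator_seed": config.seed, "true_states": truths},
    )


def state_distribution_by_age(
    cohort: Cohort, age_bins: Sequence[tuple[float, float]]
) -> pd.DataFrame:
    """Per-age-bin proportions of observed states.

    ``age_bins`` are half-open intervals [lo, hi).  Returns a frame with
    one row per bin: exam count ``n`` and proportions ``p1, p2, p3``
    (NaN and ``empty=True`` for bins with no exams).
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    bins = sorted(age_bins)
    for (alo, ahi), (blo, bhi) in zip(bins, bins[1:]):
        if bhi <= blo or ahi > blo:
            raise ValueError("age bins must be non-overlapping intervals")
    ages = np.concatenate([h.times for h in cohort])
    states = np.concatenate([h.states for h in cohort])
    rows = []
    for lo, hi in age_bins:
        sel = (ages >= lo) & (ages < hi)
        n = int(sel.sum())
        if n == 0:
            rows.append((lo, hi, 0, np.nan, np.nan, np.nan, True))
            continue
        props = [float((states[sel] == s).mean()) for s in (1, 2, 3)]
        rows.append((lo, hi, n, *props, False))
    return pd.DataFrame(
        rows, columns=["age_lo", "age_hi", "n", "p1", "p2", "p3", "empty"]
    )
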