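# Methods

## Data model

A screening history is a strictly time-ordered sequence of exam records
`(age, exam_type, state)` with ages in decimal years inside [16, 100],
exam type cytology or histology, and state 1 (normal), 2 (low-grade) or
3 (high-grade).  Histories are gridded onto a discrete age axis —
default 16–80 years at 4 bins/year (T = 256 columns), a record at age
`t` landing in bin `floor((t − 16) · 4)` — to form the partially
observed state matrix used by the profile estimators.  Quarterly bins
are a compromise: fine enough that within-bin collisions are rare, and
coarse enough that cancer risk can be treated as constant within a bin.
When two records of one subject do collide in a bin, the more severe
state is kept; in a screening context a false positive is preferred to a
masked abnormality.

## Synthetic cohort generator

The generator exists because registry screening data cannot be
redistributed.  It is calibrated to published cohort summaries, not to
registry microdata, and makes no claim to biological fidelity beyond
them.

* **True-state dynamics.** A 3-state continuous-time Markov chain with
  piecewise-constant intensity matrices over three age bands (<36,
  36–45, 46+).  Progression rates (1→2, 2→3) decline with age while
  regression (2→1, rate 0.40/yr) and high-grade exit (0.40/yr total,
  treatment and regression) are age-constant; this produces the drift of
  the observed normal proportion from ≈0.87 below age 36 towards ≈0.93
  at 46+.  Gaps spanning a band boundary are propagated piecewise with
  the matrix exponential of each band's generator.
* **Visit process.** Age at first exam is truncated normal (mean 25,
  sd 3, bounds 18–45), concentrating first exams at ages 20–30.
  Inter-exam gaps are log-normal (median ≈1.6 years, log-sd 0.85)
  clipped to [1 month, 20 years].  The number of exams per history is
  1 + Poisson(5.5), giving a median of 6 exams.  Histories truncate at
  age 80.
* **Observation process.** The exam type is histology with probability
  0.04 / 0.35 / 0.70 given true state 1 / 2 / 3 (tissue exams follow
  abnormality), and the observed state is the true state passed through
  a row-stochastic confusion matrix per exam type, cytology
  (sensitivity ≈0.68–0.82 for abnormal states) noisier than histology
  (≈0.88–0.95).  Magnitudes are in the range of published cytology
  performance but are free parameters of the simulator.
* **Seeding.** One master seed spawns one substream per subject, so
  cohorts are reproducible and a cohort of size n shares its first m
  histories with any smaller cohort of size m under the same seed.

What the generator does **not** emulate: HPV infection status and
vaccination, calendar-time effects (screening-guideline changes,
technology shifts), informative visit timing beyond the state-dependent
exam-type law, and within-subject correlation of misclassification.
Tests passing on this cohort therefore demonstrate the correctness and
the qualitative imbalance behaviour of the estimators, not their
clinical performance on registry data.

## Latent-profile estimation

Both profile backends minimize

    || W ⊙ (Z − shift − U Vᵀ) ||² + tr(Uᵀ L_r U) + tr(Vᵀ L_t V)
      + ridge (||U||² + ||V||²)

by exact alternating least squares, where `W` is the observation mask
and `shift = 1` anchors unobserved regions at the normal state.  The
convolutional backend uses `L_r = 0` and `L_t = λ DᵀD` with `D` the
forward-difference operator (a path-graph Laplacian; default λ = 10),
encoding slowly varying profiles.  The graph-regularized backend uses
the Laplacian of a subject-similarity graph for `L_r` and a path graph
over age bins for `L_t`.  The subject graph is learned from data:
Gaussian-kernel weights on mean squared differences over co-observed
bins, an adaptive per-node bandwidth (distance to the 7th neighbour),
and a median sparsity threshold, so node degrees vary with how typical a
history is and pairs with no co-observations get weight zero.  Each ALS
half-step solves its (row-coupled, when a Laplacian is present) linear
system exactly, so the objective is non-increasing; iteration stops at a
relative objective change below 1e−6 or at 100 iterations (with a
warning).  Factors are initialized from a seeded normal draw, making
fits deterministic.

Defaults: rank 5, ridge 1e−3.  Rank is deliberately small — state
trajectories are low-complexity and heavy regularization towards the
normal baseline is the point.

### Emission model and σ

The emission probability of discrete state `s` given latent value `m` is
the softmax over `s ∈ {1,2,3}` of `−(m − s)²/(2σ²)` — a discrete
Gaussian kernel normalized over the three states, which is the only
normalization making it a proper distribution over results.  σ is
estimated by maximizing the summed log emission probability of the
observed cells given the fitted profiles, via a coarse log-scale scan on
[0.01, 10] refined by bounded 1-D minimization.  When every observation
already sits at its nearest state the likelihood is maximized at the
boundary; σ is then pinned at 0.01 with a warning.

## Posterior-predictive risk

The reference profiles act as an empirical prior over latent
trajectories: the risk triple is the mixture of per-profile emissions at
the target bin, weighted by each profile's history likelihood.  The
approximations involved: the future result is conditionally independent
of the history given the latent value; the intractable prior over
trajectories is replaced by the uniform empirical distribution over
fitted profile rows (the training sample is already severity-reweighted,
so no additional row weighting is applied); and predictions are made at
the target's grid bin (ages are floored to their bin).  All weight
arithmetic is in log space with a max shift; individual profile
underflow is tolerated as long as one profile survives, and a history
incompatible with every profile raises an error rather than returning an
arbitrary triple.

## Hidden Markov filter

Hidden states (normal / low-risk / high-risk) follow a time-homogeneous
CTMC by default; the structure supports age-banded generators but the
packaged defaults use a single intensity matrix.  The filter is the
standard forward recursion in log space over unnormalized `α`, with the
transition kernel `expm(Q Δt)` evaluated through a cached
eigendecomposition (falling back to `expm` if the generator is
defective).  The initial law `p(h | t₀)` is banded by age (<36, 36–45,
46+) rather than continuous in age — a discretization choice, matching
the granularity of everything else in the pipeline.  Prediction
marginalizes over the future hidden state and exam type; `p(ρ | h)` is
obtained by normalizing per-hidden-state Poisson screening intensities
across exam types, the simplest reading of rate-based exam propensities.
Parameters are consumed from configuration (YAML or mapping) with
schema validation; no fitting of HMM parameters from data is performed
here.  The packaged defaults mirror the synthetic generator's magnitudes
so that the filter is well-specified on simulated cohorts.

## Baselines

Features are cumulative counts of each state × exam type over the
revealed history (6 counts) plus the age at the last revealed exam and
the target age.  "Time stamps" could also be read as per-state last-seen
ages; the simpler reading is used and the feature builder is the single
place to extend.  Logistic regression features are Z-scored with
moments frozen from the training features (population-sd convention,
floored for constant features).  Warm-start refitting reuses current
coefficients for logistic regression; the tree ensembles do not support
parameter-initialized refits and are refit from scratch on pooled data
with a logged notice.

## Classification and threshold fitting

The default rule is argmax with ties broken towards severity.  The
adaptive rule checks `p̂(3) ≥ δ₃` first, then `p̂(2) ≥ δ₂`, else predicts
normal; only δ₂ and δ₃ are free since normal is the fallback and a δ₁
is never evaluated.  Thresholds are fit per age interval (20–36, 36–46,
46+) by maximizing the K-category Matthews correlation coefficient with
differential evolution (bounds (0.001, 0.999), population 30, up to 200
generations, seeded, no polishing — the objective is piecewise
constant).  A fitted interval never reports an objective below the
δ = (0.5, 0.5) baseline; intervals whose samples contain a single true
class fall back to δ = 0.5 with a warning.  `R_K` uses the standard
K-category definition with predicted-count marginals; a zero denominator
(constant truth or prediction) returns 0 by convention.

## Evaluation

Stratified Brier scores: within the stratum of targets whose true state
is `s`, `B_s = mean (p̂(s) − 1)²` — the outcome indicator is identically
1 inside the stratum, so `B_s` directly measures how much probability
the model withholds from the realized state.  Absolute-risk curves use
consecutive 10-month age windows anchored at a common origin so that
reference and prediction curves share their grid; `η` integrates the
absolute gap between the curves by trapezoidal quadrature on the shared
window centers, normalized by the reference integral.

## Experiment protocol

Training histories (and nothing else) are sampled with probability
proportional to the most severe state in the history, enriching
abnormal trajectories.  Validation and test sets are both drawn
uniformly from the remaining histories with first exams at ages 20–30,
so the validation split on which thresholds (and nothing on the test
side) are fit follows the same distribution as the test population —
fitting thresholds on the severity-enriched sample would bias them
towards over-calling abnormality.  Only histories with at least 3 exams
enter any split.

The moving-window protocol reveals the first two exams, predicts the
third, folds the previous exam into the estimator state, and advances.
A target is skipped (and logged) when its preceding exam lies within
six months of it: the conditioning set must lag the target by at least
the prediction horizon, and since exam times are increasing, checking
the immediately preceding exam guarantees the whole conditioning set
complies.  An independent audit pass re-checks this on the prediction
log, and threshold fitting is audited to never touch test subjects.

For each model the reported `η` uses the strategy (default or adaptive)
with the higher overall `R_K`.  The oracle estimator reads the
simulator's true state at the target visit and returns the exact
conditional distribution of the observed result (exam-type law mixed
through the confusion matrices); it bounds what any history-based
predictor can achieve and anchors the calibration comparison.

## Problem sizes and tolerances in the shipped tests

The acceptance-scale experiment uses 1,000 training, 5,000 validation
and 2,000 test histories from an 11,000-history cohort: large enough
that the imbalance pattern and the adaptive-vs-default direction are
stable, small enough to run routinely.  The validation split is
deliberately larger than the training sample because threshold fitting
is the step most sensitive to minority-class sampling noise.  Paired
comparisons of `R_K` across strategies carry a 0.05 allowance and
comparisons of `η` against the oracle a 0.02 allowance, reflecting two
standard errors of these statistics in the sparsest age interval
(roughly 650 predictions, of which a dozen are high-grade) at this
cohort size.  Exact identities (recursive vs batch likelihoods, filter
vs path enumeration, mixture vs brute-force summation) are checked at
1e−9 to 1e−12.

## Known limitations

* The factorization backends share one ALS core; a convolutional basis
  for the temporal factor is not implemented (the smoothness penalty
  plays that role behind the same interface).
* Exam-type information does not enter the factorization weights; only
  the HMM uses exam types in inference.
* HMM parameters are configuration, not estimates; results on real data
  would require externally fitted parameters.
* The generator's confusion and intensity magnitudes are plausible but
  not registry-calibrated; absolute metric values on synthetic cohorts
  should not be read as clinical performance.
* Predictions are made at grid-bin resolution (3 months by default);
  sub-bin target times are floored.
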