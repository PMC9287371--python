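"""Calibration and performance statistics.

Three complementary views of predictive quality:

* Brier scores stratified by the true state: within the stratum of
  targets whose true state is s, B_s = mean (p-hat(s) - 1)^2.  Under a
  normal-biased model B is small for the normal stratum and large for
  the minority strata.
* Absolute-risk curves: the proportion of each state among samples in
  consecutive age windows of about 10 months, for observed truth or
  predicted labels.
* The eta indicator: integrated absolute deviation between a predicted
  and a reference risk curve, normalized by the reference's integral;
  eta = 0 means the prediction tracks the reference exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_WINDOW_YEARS = 10.0 / 12.0


def brier_stratified(probs: np.ndarray, truth: np.ndarray) -> dict[int, float]:
    """Per-true-state Brier scores; states with no samples map to NaN."""
    probs = np.asarray(probs, dtype=float)
    truth = np.asarray(truth)
    if probs.ndim != 2 or probs.shape[1] != 3 or probs.shape[0] != truth.shape[0]:
        raise ValueError("need aligned (n, 3) probabilities and n truths")
    out = {}
    for s in (1, 2, 3):
        sel = truth == s
        out[s] = (
            float(((probs[sel, s - 1] - 1.0) ** 2).mean()) if sel.any() else np.nan
        )
    return out


@dataclass
class RiskCurve:
    """Per-age-window state proportions (empty windows excluded)."""

    centers: np.ndarray
    proportions: np.ndarray  # (n_windows, 3)
    counts: np.ndarray
    window: float

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if not np.allclose(self.proportions.sum(axis=1), 1.0):
            raise ValueError("window proportions must sum to one over states")

    def state(self, s: int) -> np.ndarray:
        return self.proportions[:, s - 1]


def absolute_risk_curve(
    times: np.ndarray,
    states: np.ndarray,
    window: float = DEFAULT_WINDOW_YEARS,
    origin: float | None = None,
) -> RiskCurve:
    """State proportions over consecutive age windows.

    ``origin`` anchors the window edges so that two curves built with the
    same origin and width share a grid and can be compared with ``eta``.
    """
    if window <= 0:
        raise ValueError("window width must be positive")
    times = np.asarray(times, dtype=float)
    states = np.asarray(states)
    if times.size == 0:
        raise ValueError("no samples")
    start = float(times.min()) if origin is None else float(origin)
    idx = np.floor((times - start) / window).astype(int)
    centers, props, counts = [], [], []
    for k in range(idx.min(), idx.max() + 1):
        sel = idx == k
        n = int(sel.sum())
        if n == 0:
            continue
        centers.append(start + (k + 0.5) * window)
        props.append([float((states[sel] == s).mean()) for s in (1, 2, 3)])
        counts.append(n)
    return RiskCurve(
        centers=np.array(centers),
        proportions=np.array(props),
        counts=np.array(counts),
        window=window,
    )


def eta(
    reference: RiskCurve, predicted: RiskCurve, state: int
) -> float:
    """Relative integrated deviation between risk curves for one state.

    eta = int |r(t) - r-hat(t)| dt / int r(t) dt, by trapezoidal
    quadrature on the shared window centers.  Curves are aligned on the
    intersection of their center grids.
    """
    shared, ref_idx, pred_idx = np.intersect1d(
        np.round(reference.centers, 9),
        np.round(predicted.centers, 9),
        return_indices=True,
    )
    if shared.size < 2:
        raise ValueError("curves share fewer than two window centers")
    r = reference.state(state)[ref_idx]
    r_hat = predicted.state(state)[pred_idx]
    denom = float(np.trapezoid(r, shared))
    if denom <= 0:
        raise ValueError("reference curve integrates to zero for this state")
    num = float(np.trapezoid(np.abs(r - r_hat), shared))
    return num / denom


def eta_by_state(reference: RiskCurve, predicted: RiskCurve) -> dict[int, float]:
    """eta per state; states whose reference integral vanishes map to NaN."""
    out = {}
    for s in (1, 2, 3):
        try:
            out[s] = eta(reference, predicted, s)
        except ValueError:
            out[s] = np.nan
    return out


def plot_risk_curves(reference: RiskCurve, predicted: dict, path=None):
    """Plot reference vs predicted absolute-risk curves, one column per state.

    ``predicted`` maps model names to RiskCurves.  Returns the figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_models = max(len(predicted), 1)
    fig, axes = plt.subplots(
        n_models, 3, figsize=(12, 2.5 * n_models), squeeze=False
    )
    names = list(predicted) or ["reference"]
    for row, name in enumerate(names):
        for col, s in enumerate((1, 2, 3)):
            ax = axes[row][col]
            ax.plot(reference.centers, reference.state(s), "k-", label="observed")
            if name in predicted:
                curve = predicted[name]
                ax.plot(curve.centers, curve.state(s), "C1--", label=name)
            ax.set_title(f"{name}: state {s}")
            if row == 0 and col == 0:
                ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
    return fig
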