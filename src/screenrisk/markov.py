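"""Continuous-time Markov chain helpers.

Disease dynamics here are 3-state CTMCs specified by an intensity
(generator) matrix Q with nonnegative off-diagonal rates and zero row
sums; the transition kernel over an elapsed time dt is expm(Q * dt).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm


def validate_generator(q: np.ndarray, atol: float = 1e-10) -> np.ndarray:
    """Check that ``q`` is a valid transition intensity matrix."""
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1]:
        raise ValueError("generator must be square")
    off = q.copy()
    np.fill_diagonal(off, 0.0)
    if (off < -atol).any():
        raise ValueError("generator off-diagonal rates must be nonnegative")
    if not np.allclose(q.sum(axis=1), 0.0, atol=atol):
        raise ValueError("generator rows must sum to zero")
    return q


def validate_stochastic(p: np.ndarray, atol: float = 1e-12) -> np.ndarray:
    """Check that ``p`` is row-stochastic."""
    p = np.asarray(p, dtype=float)
    if (p < -atol).any():
        raise ValueError("probabilities must be nonnegative")
    if not np.allclose(p.sum(axis=-1), 1.0, atol=max(atol, 1e-9)):
        raise ValueError("rows must sum to one")
    return p


def transition_matrix(q: np.ndarray, dt: float) -> np.ndarray:
    """Transition probabilities expm(Q * dt), clipped to a stochastic matrix."""
    if dt < 0:
        raise ValueError("elapsed time must be nonnegative")
    p = expm(np.asarray(q, dtype=float) * dt)
    p = np.clip(p, 0.0, None)
    return p / p.sum(axis=1, keepdims=True)


class TransitionCache:
    """Fast repeated evaluation of expm(Q * dt) via eigendecomposition.

    Falls back to scipy's expm when Q is defective or the spectral
    reconstruction is inaccurate.
    """

    def __init__(self, q: np.ndarray):
        self.q = validate_generator(q)
        self._use_eig = False
        try:
            w, v = np.linalg.eig(self.q)
            vinv = np.linalg.inv(v)
            ref = expm(self.q)  # probe at dt = 1
            approx = (v * np.exp(w)) @ vinv
            if np.max(np.abs(approx.real - ref)) < 1e-10:
                self._w, self._v, self._vinv = w, v, vinv
                self._use_eig = True
        except np.linalg.LinAlgError:
            pass

    def __call__(self, dt: float) -> np.ndarray:
        if dt < 0:
            raise ValueError("elapsed time must be nonnegative")
        if self._use_eig:
            p = ((self._v * np.exp(self._w * dt)) @ self._vinv).real
        else:
            p = expm(self.q * dt)
        p = np.clip(p, 0.0, None)
        return p / p.sum(axis=1, keepdims=True)


def stationary_distribution(q: np.ndarray) -> np.ndarray:
    """Stationary law pi with pi @ Q = 0, normalized to sum 1."""
    q = validate_generator(q)
    k = q.shape[0]
    a = np.vstack([q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def gillespie_state_after(
    q: np.ndarray, start_state: int, dt: float, rng: np.random.Generator
) -> int:
    """Event-by-event simulation of the chain over dt (test oracle).

    States are 0-based indices into Q.
    """
    q = np.asarray(q, dtype=float)
    state, t = start_state, 0.0
    while True:
        rate = -q[state, state]
        if rate <= 0:
            return state
        t += rng.exponential(1.0 / rate)
        if t >= dt:
            return state
        jump = q[state].copy()
        jump[state] = 0.0
        state = rng.choice(len(jump), p=jump / jump.sum())
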