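"""Latent state-profile estimation by masked matrix factorization.

Discrete exam results are treated as noisy readouts of a continuous
latent severity trajectory m(t) per subject.  The partially observed
state matrix Z (subjects x age bins) is completed as

    M-hat = shift + U V^T,

with U (N x r) the subject factors and V (T x r) the temporal factors,
by minimizing the masked squared reconstruction error plus quadratic
roughness penalties.  Two backends share the same alternating
least-squares core and differ only in the penalties:

* the convolutional-MF backend penalizes squared forward differences of
  the temporal factor (a path-graph Laplacian), encoding slowly varying
  profiles;
* the graph-regularized backend adds Laplacian penalties from two
  similarity graphs — one learned over subjects, one a path graph over
  age bins — so profiles are smooth along both graphs.

The emission noise scale sigma is estimated by maximum likelihood under
the discrete-state emission model shared with the risk estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize_scalar
from scipy.sparse.linalg import spsolve

from .screening_data import AgeGrid, StateMatrix

SIGMA_MIN = 1e-2
SIGMA_MAX = 10.0


@dataclass
class FactorizationConfig:
    rank: int = 5
    temporal_smoothness_weight: float = 10.0
    shift_value: float = 1.0
    max_iters: int = 100
    tol: float = 1e-6
    ridge: float = 1e-3
    seed: int = 0

    def validate(self, n: int, t: int) -> None:
        if not (1 <= self.rank <= min(n, t)):
            raise ValueError(f"rank must be in [1, min(N, T)] = [1, {min(n, t)}]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.temporal_smoothness_weight < 0:
            raise ValueError("temporal smoothness weight must be nonnegative")


@dataclass
class GraphSpec:
    """Similarity graphs steering the graph-regularized backend.

    ``row_graph``: symmetric nonnegative adjacency over subjects (learned
    from data when not supplied).  ``time_graph``: adjacency over age
    bins; ``None`` selects a path graph linking consecutive bins, the
    statement that risk does not change rapidly within a year.
    """

    row_graph: np.ndarray | None = None
    time_graph: np.ndarray | None = None
    row_weight: float = 1.0
    time_weight: float = 10.0
    # row-graph learning parameters
    n_neighbors: int = 7
    sparsity_quantile: float = 0.5

    @staticmethod
    def _check_adjacency(a: np.ndarray, name: str) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"{name} must be square")
        if (a < 0).any():
            raise ValueError(f"{name} must be nonnegative")
        if not np.allclose(a, a.T):
            raise ValueError(f"{name} must be symmetric")
        if np.abs(np.diag(a)).max(initial=0.0) > 0:
            raise ValueError(f"{name} must have a zero diagonal")
        return a


@dataclass
class LatentProfileMatrix:
    """Complete N x T latent severity matrix with its noise scale."""

    values: np.ndarray
    grid: AgeGrid
    sigma: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("latent profiles must be finite")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def path_laplacian(t: int) -> sp.csr_matrix:
    """Laplacian of the path graph over T consecutive bins (D^T D)."""
    d = sp.diags([np.full(t - 1, -1.0), np.ones(t - 1)], [0, 1], shape=(t - 1, t))
    return (d.T @ d).tocsr()


def graph_laplacian(adjacency: np.ndarray) -> sp.csr_matrix:
    a = sp.csr_matrix(adjacency)
    deg = np.asarray(a.sum(axis=1)).ravel()
    return (sp.diags(deg) - a).tocsr()


def _solve_factor(w, r, other, lap, ridge):
    """Solve one ALS half-step.

    Minimizes ||W * (R - F other^T)||_F^2 + tr(F^T L F) + ridge ||F||^2
    over F, where rows of F are coupled through the Laplacian L.  With
    L = 0 the system is block diagonal and solved row by row; otherwise
    the full sparse system over vec(F) is solved.
    """
    n, rank = w.shape[0], other.shape[1]
    if lap is None or (sp.issparse(lap) and lap.nnz == 0):
        f = np.empty((n, rank))
        for i in range(n):
            wi = w[i]
            g = (other * wi[:, None]).T @ other + ridge * np.eye(rank)
            b = (other * wi[:, None]).T @ r[i]
            f[i] = np.linalg.solve(g, b)
        return f
    # Row-coupled system: (blockdiag(G_i) + L kron I_r + ridge I) vec(F) = b
    blocks = []
    rhs = np.empty((n, rank))
    for i in range(n):
        wi = w[i]
        blocks.append((other * wi[:, None]).T @ other + ridge * np.eye(rank))
        rhs[i] = (other * wi[:, None]).T @ r[i]
    a = sp.block_diag(blocks, format="csr") + sp.kron(
        lap, sp.eye(rank), format="csr"
    )
    sol = spsolve(a.tocsc(), rhs.ravel())
    return sol.reshape(n, rank)


def _objective(w, resid, u, v, lap_u, lap_v, ridge):
    val = float((w * resid**2).sum())
    val += ridge * (float((u**2).sum()) + float((v**2).sum()))
    if lap_u is not None:
        val += float((u * (lap_u @ u)).sum())
    if lap_v is not None:
        val += float((v * (lap_v @ v)).sum())
    return val


def _masked_als(z, mask, config, lap_rows, lap_time):
    """Alternating least squares for the shared masked-factorization core.

    Returns (M-hat, objective trace).  The objective (masked squared error
    + Laplacian penalties + ridge) is non-increasing across iterations
    because each half step solves its subproblem exactly.
    """
    n, t = z.shape
    config.validate(n, t)
    empty = ~mask.any(axis=1)
    if empty.any():
        raise ValueError(f"rows without observations: {np.flatnonzero(empty).tolist()}")
    w = mask.astype(float)
    r = np.where(mask, z - config.shift_value, 0.0)
    rng = np.random.default_rng(config.seed)
    u = 0.1 * rng.standard_normal((n, config.rank))
    v = 0.1 * rng.standard_normal((t, config.rank))
    trace = []
    prev = np.inf
    for it in range(config.max_iters):
        u = _solve_factor(w, r, v, lap_rows, config.ridge)
        v = _solve_factor(w.T, r.T, u, lap_time, config.ridge)
        obj = _objective(w, r - u @ v.T, u, v, lap_rows, lap_time, config.ridge)
        trace.append(obj)
        if prev - obj <= config.tol * max(abs(prev), 1.0):
            break
        prev = obj
    else:
        warnings.warn("factorization did not converge within max_iters")
    return config.shift_value + u @ v.T, np.array(trace)


def fit_swcmf(
    z: StateMatrix, config: FactorizationConfig | None = None
) -> LatentProfileMatrix:
    """Complete Z with the shift + low-rank + temporal-smoothness model."""
    config = config or FactorizationConfig()
    t = z.shape[1]
    lap_time = (
        config.temporal_smoothness_weight * path_laplacian(t)
        if config.temporal_smoothness_weight > 0
        else None
    )
    m, trace = _masked_als(z.values, z.mask, config, None, lap_time)
    sigma = estimate_sigma(m, z)
    out = LatentProfileMatrix(values=m, grid=z.grid, sigma=sigma)
    out.objective_trace = trace
    return out


def learn_row_graph(
    z: StateMatrix, n_neighbors: int = 7, sparsity_quantile: float = 0.5
) -> np.ndarray:
    """Learn a subject-similarity graph from co-observed states.

    Weights are Gaussian kernels of the mean squared difference over
    co-observed age bins with a per-node adaptive bandwidth (distance to
    the ``n_neighbors``-th neighbour); weights below the given quantile of
    the positive weights are dropped, so node degrees vary with how
    typical a history is.  Subject pairs with no co-observed bins get
    weight zero.
    """
    n = z.shape[0]
    if n < 2:
        raise ValueError("row graph needs at least 2 histories")
    vals = np.where(z.mask, z.values, 0.0)
    m = z.mask.astype(float)
    # co-observation counts and masked squared distances, all pairs
    counts = m @ m.T
    sq = vals**2
    cross = vals @ vals.T
    d2 = (sq @ m.T) + (m @ sq.T) - 2 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_d2 = np.where(counts > 0, d2 / np.maximum(counts, 1), np.inf)
    np.fill_diagonal(mean_d2, np.inf)
    dist = np.sqrt(np.maximum(mean_d2, 0.0))
    # adaptive bandwidth: distance to the k-th nearest co-observed neighbour
    k = min(n_neighbors, n - 1)
    finite = np.where(np.isfinite(dist), dist, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        kth = np.nanpercentile(finite, 100.0 * k / max(n - 1, 1), axis=1)
    kth = np.where(np.isfinite(kth) & (kth > 0), kth, 1.0)
    bw = np.sqrt(np.outer(kth, kth))
    with np.errstate(over="ignore"):
        wgt = np.exp(-(dist**2) / (bw**2 + 1e-12))
    wgt[~np.isfinite(dist)] = 0.0
    np.fill_diagonal(wgt, 0.0)
    wgt = 0.5 * (wgt + wgt.T)
    pos = wgt[wgt > 0]
    if pos.size:
        thr = np.quantile(pos, sparsity_quantile)
        wgt[wgt < thr] = 0.0
    return wgt


def fit_gdl(
    z: StateMatrix,
    graphs: GraphSpec | None = None,
    config: FactorizationConfig | None = None,
) -> LatentProfileMatrix:
    """Complete Z with Laplacian penalties from subject and time graphs."""
    graphs = graphs or GraphSpec()
    config = config or FactorizationConfig(temporal_smoothness_weight=0.0)
    n, t = z.shape
    row_adj = graphs.row_graph
    if row_adj is None and graphs.row_weight > 0:
        row_adj = learn_row_graph(z, graphs.n_neighbors, graphs.sparsity_quantile)
    lap_rows = None
    if row_adj is not None and graphs.row_weight > 0:
        row_adj = GraphSpec._check_adjacency(row_adj, "row_graph")
        if row_adj.shape[0] != n:
            raise ValueError("row graph size does not match number of histories")
        lap_rows = graphs.row_weight * graph_laplacian(row_adj)
    lap_time = None
    if graphs.time_weight > 0:
        if graphs.time_graph is None:
            lap_time = graphs.time_weight * path_laplacian(t)
        else:
            time_adj = GraphSpec._check_adjacency(graphs.time_graph, "time_graph")
            if time_adj.shape[0] != t:
                raise ValueError("time graph size does not match number of age bins")
            lap_time = graphs.time_weight * graph_laplacian(time_adj)
    m, trace = _masked_als(z.values, z.mask, config, lap_rows, lap_time)
    sigma = estimate_sigma(m, z)
    out = LatentProfileMatrix(values=m, grid=z.grid, sigma=sigma)
    out.objective_trace = trace
    return out


def emission_log_probs(m: np.ndarray, sigma: float) -> np.ndarray:
    """log p(s | m) over s in {1,2,3}: softmax of -(m - s)^2 / (2 sigma^2).

    ``m`` is broadcast; the returned array has a trailing axis of size 3.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    m = np.asarray(m, dtype=float)
    states = np.array([1.0, 2.0, 3.0])
    logits = -((m[..., None] - states) ** 2) / (2.0 * sigma**2)
    shift = logits.max(axis=-1, keepdims=True)
    logz = shift + np.log(np.exp(logits - shift).sum(axis=-1, keepdims=True))
    return logits - logz


def estimate_sigma(
    m_values: np.ndarray,
    z: StateMatrix,
    bounds: tuple[float, float] = (SIGMA_MIN, SIGMA_MAX),
) -> float:
    """MLE of the emission noise scale over the observed cells of Z.

    Maximizes the product of normalized emission probabilities of the
    observed discrete states given the fitted latent values, by bounded
    1-D search over log sigma.
    """
    mask = z.mask
    if not mask.any():
        raise ValueError("need at least one observed entry")
    m_obs = np.asarray(m_values)[mask]
    x_obs = z.values[mask].astype(int)
    if np.allclose(m_obs, x_obs):
        warnings.warn("all residuals are zero; sigma pinned at the lower bound")
        return bounds[0]

    idx = x_obs - 1

    def nll(log_sigma: float) -> float:
        lp = emission_log_probs(m_obs, float(np.exp(log_sigma)))
        return -float(lp[np.arange(len(idx)), idx].sum())

    # coarse bracket on the log scale, then local refinement; boundary
    # optima (e.g. every observation already at its nearest state) are kept
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    coarse = np.linspace(lo, hi, 101)
    vals = np.array([nll(x) for x in coarse])
    k = int(np.argmin(vals))
    left = coarse[max(k - 1, 0)]
    right = coarse[min(k + 1, len(coarse) - 1)]
    res = minimize_scalar(
        nll, bounds=(left, right), method="bounded", options={"xatol": 1e-10}
    )
    candidates = [(nll(lo), lo), (nll(hi), hi), (vals[k], coarse[k]), (res.fun, res.x)]
    best = min(candidates, key=lambda c: c[0])
    return float(np.exp(best[1]))
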