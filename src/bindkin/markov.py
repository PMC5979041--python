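"""Markov state model estimation.

Sliding-window transition counts, the largest reversibly connected state set,
maximum-likelihood reversible transition matrices (detailed-balance
fixed-point iteration), implied timescales, and k-means discretization of
reduced coordinates (deterministic in-package Lloyd iteration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator


from .exceptions import ConvergenceError, NotIrreducibleError
from .synthetic import DiscreteTrajectory


def _pairwise_sq(X, C):
    """Squared distances (chunk-friendly): |x|^2 - 2 x.c + |c|^2."""
    return (
        np.einsum("ij,ij->i", X, X)[:, None]
        - 2.0 * X @ C.T
        + np.einsum("ij,ij->i", C, C)[None, :]
    )


def _init_maximin(X, k):
    """Deterministic farthest-point (maximin) seeding.

    Guarantees that any well-separated cluster receives a center regardless
    of its population — k-means++ D^2 sampling can miss metastable states
    whose stationary weight is orders of magnitude below the rest.
    """
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[np.argmin(np.linalg.norm(X - X.mean(axis=0), axis=1))]
    d2 = np.einsum("ij,ij->i", X - centers[0], X - centers[0])
    for j in range(1, k):
        idx = int(np.argmax(d2))
        centers[j] = X[idx]
        nd = np.einsum("ij,ij->i", X - centers[j], X - centers[j])
        np.minimum(d2, nd, out=d2)
    return centers


def _init_plusplus(X, k, rng):
    """Classic k-means++ D^2 sampling."""
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(X.shape[0])]
    d2 = np.einsum("ij,ij->i", X - centers[0], X - centers[0])
    for j in range(1, k):
        p = d2 / d2.sum()
        idx = rng.choice(X.shape[0], p=p)
        centers[j] = X[idx]
        nd = np.einsum("ij,ij->i", X - centers[j], X - centers[j])
        np.minimum(d2, nd, out=d2)
    return centers


def cluster_kmeans(reduced_trajectories, k: int = 100, seed: int = 0,
                   max_iter: int = 100, tol: float = 1e-8,
                   frame_interval: float = 1.0, init: str = "maximin",
                   chunk: int = 200_000):
    """Discretize reduced trajectories into ``k`` clusters by Lloyd k-means.

    Deterministic per seed.  ``init="maximin"`` (default) uses farthest-point
    seeding, which always covers geometrically separated low-population
    states; ``init="kmeans++"`` is the classic seeded D^2 sampling.
    Assignment is by nearest center with ties broken toward the lowest center
    index; clusters that empty out are re-seeded from the point farthest from
    its current center.  Returns (list of :class:`DiscreteTrajectory`,
    cluster centers).
    """
    single = isinstance(reduced_trajectories, np.ndarray)
    trajs = [reduced_trajectories] if single else list(reduced_trajectories)
    arrays = [np.atleast_2d(np.asarray(t, float)) for t in trajs]
    arrays = [a.T if a.shape[0] == 1 and a.size > 1 else a for a in arrays]
    X = np.vstack(arrays)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"{n} frames cannot support {k} clusters")
    rng = np.random.default_rng(int(seed))
    if init == "maximin":
        centers = _init_maximin(X, k)
    elif init == "kmeans++":
        centers = _init_plusplus(X, k, rng)
    else:
        raise ValueError("init must be 'maximin' or 'kmeans++'")

    labels = np.empty(n, dtype=np.int64)
    mind2 = np.empty(n)
    for _ in range(max_iter):
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            d2 = _pairwise_sq(X[lo:hi], centers)
            labels[lo:hi] = np.argmin(d2, axis=1)  # argmin -> lowest index on ties
            mind2[lo:hi] = d2[np.arange(hi - lo), labels[lo:hi]]
        new_centers = centers.copy()
        counts = np.bincount(labels, minlength=k)
        sums = np.zeros_like(centers)
        np.add.at(sums, labels, X)
        nonempty = counts > 0
        new_centers[nonempty] = sums[nonempty] / counts[nonempty, None]
        for j in np.where(~nonempty)[0]:
            far = int(np.argmax(mind2))
            new_centers[j] = X[far]
            mind2[far] = 0.0
        shift = np.max(np.einsum("ij,ij->i", new_centers - centers, new_centers - centers))
        centers = new_centers
        if shift < tol:
            break
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        labels[lo:hi] = np.argmin(_pairwise_sq(X[lo:hi], centers), axis=1)

    out, pos = [], 0
    for a in arrays:
        out.append(DiscreteTrajectory(labels[pos:pos + a.shape[0]], frame_interval))
        pos += a.shape[0]
    return (out[0] if single else out), centers


def largest_connected_set(counts) -> np.ndarray:
    """States in the largest connected component of the symmetrized count
    graph (ties broken toward more counts)."""
    C = np.asarray(counts)
    sym = C + C.T
    ncomp, labels = connected_components(sym > 0, directed=False)
    best, best_key = 0, (-1, -1)
    for c in range(ncomp):
        members = np.where(labels == c)[0]
        key = (members.size, int(C[np.ix_(members, members)].sum()))
        if key > best_key:
            best, best_key = c, key
    return np.where(labels == best)[0]


@dataclass
class CountResult:
    """Transition counts at a lag plus connectivity information."""

    counts: np.ndarray       # (n, n) integer counts over all observed states
    lag_frames: int
    lag_time: float          # ns
    active_set: np.ndarray   # states in the largest connected component

    def active_counts(self) -> np.ndarray:
        return self.counts[np.ix_(self.active_set, self.active_set)]


def count_matrix(dtrajs, lag: float, n_states: int | None = None) -> CountResult:
    """Sliding-window transition counts c_ij = #{t : s_t = i, s_{t+lag} = j}.

    ``lag`` is in ns and must be a positive multiple of the frame interval.
    The active set is the largest connected component of the symmetrized
    count graph (ties broken toward more counts).
    """
    if isinstance(dtrajs, DiscreteTrajectory):
        dtrajs = [dtrajs]
    dt = dtrajs[0].frame_interval
    lag_frames = int(round(lag / dt))
    if lag_frames < 1 or abs(lag_frames * dt - lag) > 1e-9 * max(1.0, lag):
        raise ValueError("lag must be a positive multiple of the frame interval")
    if n_states is None:
        n_states = int(max(d.states.max() for d in dtrajs)) + 1
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    any_usable = False
    for d in dtrajs:
        s = d.states
        if len(s) <= lag_frames:
            continue
        any_usable = True
        np.add.at(counts, (s[:-lag_frames], s[lag_frames:]), 1)
    if not any_usable:
        raise ValueError("lag exceeds the length of every trajectory")
    return CountResult(counts, lag_frames, lag, largest_connected_set(counts))


@dataclass
class MarkovModel:
    """A reversible Markov state model at lag tau.

    Invariants (checked on construction): rows of T sum to 1 within 1e-12,
    pi T = pi within 1e-10, detailed balance pi_i T_ij = pi_j T_ji within
    1e-10, and the leading eigenvalue is 1.
    """

    transition_matrix: np.ndarray
    lag_time: float  # ns
    stationary_distribution: np.ndarray
    active_set: np.ndarray = None
    eigenvalues: np.ndarray = field(init=False)

    def __post_init__(self):
        T = np.asarray(self.transition_matrix, float)
        pi = np.asarray(self.stationary_distribution, float)
        n = T.shape[0]
        if self.active_set is None:
            self.active_set = np.arange(n)
        if np.max(np.abs(T.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("transition matrix rows must sum to 1 within 1e-12")
        if np.max(np.abs(pi @ T - pi)) > 1e-10:
            raise ValueError("stationary distribution must satisfy pi T = pi within 1e-10")
        flux = pi[:, None] * T
        if np.max(np.abs(flux - flux.T)) > 1e-10:
            raise ValueError("detailed balance violated beyond 1e-10")
        self.transition_matrix = T
        self.stationary_distribution = pi
        # reversible => real spectrum via symmetrization
        d = np.sqrt(pi)
        sym = (d[:, None] * T) / d[None, :]
        evals = np.linalg.eigvalsh((sym + sym.T) / 2.0)
        self.eigenvalues = np.sort(evals)[::-1]

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def timescales(self, k: int | None = None) -> np.ndarray:
        """Implied timescales t_i = -tau/ln(lambda_i) (ns), slowest first,
        NaN where lambda_i <= 0."""
        lam = self.eigenvalues[1:k if k is None else k + 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(lam > 0, -self.lag_time / np.log(lam), np.nan)


def estimate_reversible(counts, lag_time: float = 1.0, tol: float = 1e-10,
                        max_iter: int = 100000) -> MarkovModel:
    """Maximum-likelihood reversible transition matrix.

    Self-consistent fixed point for the symmetric pair weights x_ij:
    x_ij <- (c_ij + c_ji) / (c_i/x_i + c_j/x_j); converged when the maximum
    change of T between sweeps drops below ``tol``.
    """
    if isinstance(counts, CountResult):
        C = counts.active_counts().astype(float)
        lag_time = counts.lag_time
        active = counts.active_set
    else:
        C = np.asarray(counts, float)
        active = np.arange(C.shape[0])
    n = C.shape[0]
    sym = C + C.T
    ncomp, _ = connected_components(sym > 0, directed=False)
    if n > 1 and ncomp != 1:
        raise NotIrreducibleError("count matrix is not connected on its active set")
    ci = C.sum(axis=1)
    if np.any(ci == 0):
        raise NotIrreducibleError("a state has no outgoing counts")
    X = sym.copy()
    X /= X.sum()
    T_prev = X / X.sum(axis=1, keepdims=True)
    for _ in range(max_iter):
        xi = X.sum(axis=1)
        denom = (ci / xi)[:, None] + (ci / xi)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            X = np.where(sym > 0, sym / denom, 0.0)
        X /= X.sum()
        T = X / X.sum(axis=1, keepdims=True)
        delta = np.max(np.abs(T - T_prev))
        T_prev = T
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"reversible MLE did not converge (last max change {delta:.2e})"
        )
    pi = X.sum(axis=1)
    pi /= pi.sum()
    # polish: exact row-stochasticity and detailed balance from X's symmetry
    Xs = (X + X.T) / 2.0
    pi = Xs.sum(axis=1)
    pi /= pi.sum()
    T = Xs / Xs.sum(axis=1, keepdims=True)
    return MarkovModel(T, lag_time, pi, active_set=active)


def reversible_log_likelihood(T, counts) -> float:
    """log L = sum_ij c_ij log T_ij (terms with c_ij = 0 skipped)."""
    C = np.asarray(counts, float)
    mask = C > 0
    return float(np.sum(C[mask] * np.log(np.asarray(T)[mask])))


class MaximumLikelihoodMSM(BaseEstimator):
    """Estimator facade: dtrajs -> reversible MSM at a lag.

    Fitted attributes: ``model_`` (:class:`MarkovModel`),
    ``transition_matrix_``, ``stationary_distribution_``, ``eigenvalues_``,
    ``active_set_``, ``count_result_``.
    """

    def __init__(self, lag_time=10.0):
        self.lag_time = lag_time

    def fit(self, dtrajs, y=None):
        self.count_result_ = count_matrix(dtrajs, self.lag_time)
        self.model_ = estimate_reversible(self.count_result_)
        self.transition_matrix_ = self.model_.transition_matrix
        self.stationary_distribution_ = self.model_.stationary_distribution
        self.eigenvalues_ = self.model_.eigenvalues
        self.active_set_ = self.model_.active_set
        return self

    def timescales(self, k=None):
        return self.model_.timescales(k)


def implied_timescales(dtrajs, lags, n_timescales: int = 3) -> pd.DataFrame:
    """Implied-timescale table t_i(tau) = -tau/ln(lambda_i(tau)) across lags.

    Rows are lags (ns); columns ``t2..t{m+1}`` are the slowest relaxation
    timescales; ``t2_rel_change`` is the plateau diagnostic (relative change
    of t2 between successive lags; small values mean Markovian behaviour).
    """
    rows = []
    for lag in lags:
        model = estimate_reversible(count_matrix(dtrajs, lag))
        ts = model.timescales(n_timescales)
        rows.append([lag, *ts])
    cols = ["lag_ns"] + [f"t{i+2}" for i in range(n_timescales)]
    df = pd.DataFrame(rows, columns=cols)
    t2 = df["t2"].to_numpy()
    rel = np.full(len(df), np.nan)
    rel[1:] = np.abs(np.diff(t2)) / t2[:-1]
    df["t2_rel_change"] = rel
    return df


def save_markov_model(path, model: MarkovModel) -> None:
    """Serialize a MarkovModel to an .npz bundle."""
    np.savez_compressed(path, transition_matrix=model.transition_matrix,
                        lag_time=model.lag_time,
                        stationary_distribution=model.stationary_distribution,
                        active_set=model.active_set)


def load_markov_model(path) -> MarkovModel:
    with np.load(path) as d:
        return MarkovModel(d["transition_matrix"], float(d["lag_time"]),
                           d["stationary_distribution"], d["active_set"])
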