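"""Coarse-graining of microstate MSMs into a few metastable macrostates.

Memberships are initialized by PCCA+ spectral clustering of the reversible
transition matrix and refined by Baum-Welch estimation of a discrete-emission
hidden Markov model (each hidden macrostate emits microstate indices from a
categorical distribution).  Macrostate populations come from the HMM's
stationary distribution; lifetimes are lag / (1 - Ttilde_ii).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import CategoricalHMM
from sklearn.base import BaseEstimator

from .exceptions import ConvergenceError
from .markov import MarkovModel, MaximumLikelihoodMSM
from .synthetic import DiscreteTrajectory


def pcca_memberships(model: MarkovModel, n: int) -> np.ndarray:
    """PCCA+ fuzzy memberships (microstates x n, rows sum to 1).

    Inner-simplex construction on the top-n right eigenvectors with a
    feasibility projection (negative memberships clipped, rows renormalized).
    """
    T = model.transition_matrix
    pi = model.stationary_distribution
    m = T.shape[0]
    if n > m:
        raise ValueError("more macrostates than microstates")
    if n == m:
        return np.eye(m)
    d = np.sqrt(pi)
    sym = (d[:, None] * T) / d[None, :]
    evals, evecs = np.linalg.eigh((sym + sym.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    if n < m and abs(evals[n - 1] - evals[n]) < 1e-6:
        warnings.warn(
            f"degenerate spectral gap at {n} states "
            f"(lambda_{n}={evals[n-1]:.6f}, lambda_{n+1}={evals[n]:.6f})",
            stacklevel=2,
        )
    psi = evecs[:, order[:n]] / d[:, None]  # right eigenvectors
    psi[:, 0] = 1.0
    # inner simplex: greedily pick the most exterior rows as vertices
    verts = [int(np.argmax(np.linalg.norm(psi - psi.mean(axis=0), axis=1)))]
    for _ in range(1, n):
        basis = psi[verts]
        proj = psi @ np.linalg.pinv(basis) @ basis
        verts.append(int(np.argmax(np.linalg.norm(psi - proj, axis=1))))
    chi = psi @ np.linalg.inv(psi[verts])
    chi = np.clip(chi, 0.0, None)
    chi /= chi.sum(axis=1, keepdims=True)
    return chi


@dataclass
class MacrostateModel:
    """Fuzzy macrostate decomposition of a microstate MSM."""

    memberships: np.ndarray          # (n_micro, n_macro), rows sum to 1
    coarse_transition_matrix: np.ndarray
    lag_time: float                  # ns
    populations: np.ndarray
    lifetimes: np.ndarray            # ns
    emission_probabilities: np.ndarray | None = None  # (n_macro, n_micro)
    active_set: np.ndarray | None = None

    def __post_init__(self):
        chi = np.asarray(self.memberships, float)
        if np.any(chi < -1e-12) or np.any(chi > 1 + 1e-12):
            raise ValueError("memberships must lie in [0, 1]")
        if np.max(np.abs(chi.sum(axis=1) - 1.0)) > 1e-8:
            raise ValueError("membership rows must sum to 1")
        if abs(self.populations.sum() - 1.0) > 1e-8:
            raise ValueError("macrostate populations must sum to 1")
        if np.any(self.lifetimes <= 0):
            raise ValueError("macrostate lifetimes must be positive")

    @property
    def n_macrostates(self) -> int:
        return self.coarse_transition_matrix.shape[0]

    def markov_model(self) -> MarkovModel:
        """The coarse matrix as a (possibly non-reversible) transition model.

        Returned without the reversible MarkovModel invariant checks; use for
        MFPT/committor computations on the macrostate network.
        """
        return self.coarse_transition_matrix


def _coarse_project(T, pi, chi):
    """Project a microstate matrix onto macrostates: (chi' D chi)^-1 chi' D T chi."""
    D = pi[:, None] * chi
    W = chi.T @ D
    Tc = np.linalg.solve(W, chi.T @ (pi[:, None] * (T @ chi)))
    Tc = np.clip(Tc, 1e-12, None)
    return Tc / Tc.sum(axis=1, keepdims=True)


def _stationary_of(T):
    evals, evecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(evals - 1.0)))
    pi = np.real(evecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _lagged_sequences(states, lag_frames):
    """All phase-shifted stride-``lag_frames`` subsequences of a state array."""
    return [states[o::lag_frames] for o in range(lag_frames) if len(states[o::lag_frames]) > 1]


class HiddenMarkovMSM(BaseEstimator):
    """Estimator: discrete trajectories -> n-macrostate hidden Markov model.

    A reversible microstate MSM at the same lag provides the PCCA+
    initialization; Baum-Welch then refines transition and categorical
    emission matrices (convergence on log-likelihood change < ``tol``,
    iteration cap ``max_iter``).

    Fitted attributes: ``model_`` (:class:`MacrostateModel`),
    ``memberships_``, ``coarse_transition_matrix_``, ``populations_``,
    ``lifetimes_``.
    """

    def __init__(self, n_macrostates=4, lag_time=10.0, max_iter=100, tol=1e-8,
                 random_state=0):
        self.n_macrostates = n_macrostates
        self.lag_time = lag_time
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, dtrajs, y=None, msm: MaximumLikelihoodMSM | None = None):
        if isinstance(dtrajs, DiscreteTrajectory):
            dtrajs = [dtrajs]
        if msm is None:
            msm = MaximumLikelihoodMSM(lag_time=self.lag_time).fit(dtrajs)
        micro = msm.model_
        active = msm.active_set_
        n = self.n_macrostates
        if n > micro.n_states:
            raise ValueError("more macrostates than active microstates")

        chi0 = pcca_memberships(micro, n)
        if n == micro.n_states:
            self.model_ = MacrostateModel(
                chi0, micro.transition_matrix, self.lag_time,
                micro.stationary_distribution,
                self.lag_time / np.clip(1.0 - np.diag(micro.transition_matrix), 1e-12, None),
                emission_probabilities=chi0.T.copy(), active_set=active,
            )
            self._expose()
            return self

        # crisp-partition initialization: fuzzy memberships are sensitive to
        # eigenvector noise when one state dominates, so EM starts from the
        # argmax assignment with count-based macro transition estimates
        pi_micro = micro.stationary_distribution
        crisp = np.argmax(chi0, axis=1)
        B0 = np.full((n, micro.n_states), 1e-8)
        for a in range(n):
            members = crisp == a
            w = pi_micro[members]
            B0[a, members] += w / w.sum() if w.sum() > 0 else 1.0
        B0 /= B0.sum(axis=1, keepdims=True)

        lag_frames = msm.count_result_.lag_frames
        active_map = -np.ones(int(active.max()) + 1, dtype=np.int64)
        active_map[active] = np.arange(active.size)
        sequences = []
        for d in dtrajs:
            s = d.states
            mapped = np.where(s <= active.max(), active_map[np.clip(s, 0, active.max())], -1)
            # split runs at frames outside the active set
            for chunk in _split_on_negative(mapped):
                sequences.extend(_lagged_sequences(chunk, lag_frames))
        if not sequences:
            raise ValueError("no usable sequences at this lag")

        # macro transition counts of the crisp-mapped sequences at the lag
        C0 = np.ones((n, n)) * 1e-3  # pseudocount keeps rows stochastic
        for s in sequences:
            ms = crisp[s]
            np.add.at(C0, (ms[:-1], ms[1:]), 1.0)
        T0 = C0 / C0.sum(axis=1, keepdims=True)
        pops0 = _stationary_of(T0)

        hmm = CategoricalHMM(
            n_components=n, n_iter=self.max_iter, tol=self.tol,
            init_params="", params="ste", random_state=self.random_state,
        )
        hmm.n_features = active.size
        hmm.startprob_ = np.clip(pops0, 1e-12, None) / np.clip(pops0, 1e-12, None).sum()
        hmm.transmat_ = T0
        hmm.emissionprob_ = B0
        X = np.concatenate(sequences)[:, None]
        lengths = [len(s) for s in sequences]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hmm.fit(X, lengths)
        hist = list(hmm.monitor_.history)
        if len(hist) == 2 and hist[1] < hist[0] - 1e-6 * max(1.0, abs(hist[0])):
            raise ConvergenceError("EM log-likelihood decreased (implementation bug guard)")

        Tc = hmm.transmat_
        pops = _stationary_of(Tc)
        B = hmm.emissionprob_
        chi = (pops[:, None] * B).T
        chi /= np.clip(chi.sum(axis=1, keepdims=True), 1e-300, None)
        lifetimes = self.lag_time / np.clip(1.0 - np.diag(Tc), 1e-12, None)
        self.model_ = MacrostateModel(
            chi, Tc, self.lag_time, pops, lifetimes,
            emission_probabilities=B, active_set=active,
        )
        self._expose()
        return self

    def _expose(self):
        m = self.model_
        self.memberships_ = m.memberships
        self.coarse_transition_matrix_ = m.coarse_transition_matrix
        self.populations_ = m.populations
        self.lifetimes_ = m.lifetimes
        return self


def _split_on_negative(arr):
    """Split an int array into maximal chunks of non-negative entries."""
    out = []
    bad = np.flatnonzero(arr < 0)
    start = 0
    for b in bad:
        if b > start:
            out.append(arr[start:b])
        start = b + 1
    if start < len(arr):
        out.append(arr[start:])
    return out


def coarse_grain(dtrajs, n: int = 4, lag: float = 10.0,
                 msm: MaximumLikelihoodMSM | None = None, **kwargs) -> MacrostateModel:
    """Coarse-grain discrete trajectories into ``n`` macrostates (PCCA+ init
    on the microstate MSM, Baum-Welch refinement).  A pre-fitted
    :class:`MaximumLikelihoodMSM` at the same lag may be supplied to skip
    re-estimation."""
    if msm is not None and abs(lag - msm.lag_time) > 1e-12:
        msm = None
    hmm = HiddenMarkovMSM(n_macrostates=n, lag_time=lag, **kwargs)
    hmm.fit(dtrajs, msm=msm)
    return hmm.model_
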