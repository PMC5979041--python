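"""Transition path theory on Markov models.

Forward/backward committors by linear solve, gross and net reactive fluxes
f_ij = pi_i q-_i T_ij q+_j, the total A->B flux and TPT rate, and greedy
max-bottleneck decomposition of the net flux into ranked pathways with flux
fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coarse import MacrostateModel
from .exceptions import SingularSystemError
from .kinetics import _matrix_lag_pi
from .markov import MarkovModel
from .synthetic import _as_index_set


def committor_forward(model, source, target) -> np.ndarray:
    """Forward committor q+: probability of reaching B before A, per state.

    Solves the harmonic system T q+ = q+ on the complement of A u B with
    boundary values q+ = 0 on A and q+ = 1 on B (exact on the boundary).
    """
    T, _, _ = _matrix_lag_pi(model) if not isinstance(model, np.ndarray) else (model, None, None)
    n = T.shape[0]
    A = _as_index_set(source, n)
    B = _as_index_set(target, n)
    if A & B:
        raise ValueError("source and target sets must be disjoint")
    q = np.zeros(n)
    q[sorted(B)] = 1.0
    inter = [i for i in range(n) if i not in A | B]
    if inter:
        Tii = T[np.ix_(inter, inter)]
        rhs = T[np.ix_(inter, sorted(B))].sum(axis=1)
        try:
            q[inter] = np.linalg.solve(np.eye(len(inter)) - Tii, rhs)
        except np.linalg.LinAlgError as exc:
            raise SingularSystemError("committor system singular (disconnected?)") from exc
    if np.any(q < -1e-10) or np.any(q > 1 + 1e-10):
        raise SingularSystemError("committor outside [0, 1]: inconsistent model")
    return np.clip(q, 0.0, 1.0)


def committor_backward(model, source, target) -> np.ndarray:
    """Backward committor q-: probability the chain last came from A.

    Computed on the time-reversed chain Ttilde_ij = pi_j T_ji / pi_i; for a
    reversible model q- = 1 - q+.
    """
    T, _, pi = _matrix_lag_pi(model)
    Trev = (pi[None, :] * T.T) / pi[:, None]
    Trev /= Trev.sum(axis=1, keepdims=True)
    return committor_forward(Trev, target, source)


@dataclass
class TPTResult:
    """Committors, reactive fluxes and ranked pathways for an A->B process.

    Fluxes are per lag time; ``rate`` is the TPT transition rate (per ns).
    """

    source: list
    target: list
    forward_committor: np.ndarray
    backward_committor: np.ndarray
    gross_flux: np.ndarray
    net_flux: np.ndarray
    total_flux: float
    rate: float  # 1/ns
    pathways: list  # [(state tuple, flux, fraction), ...] ranked by flux


def reactive_flux(model, source, target, residual_fraction: float = 0.01) -> TPTResult:
    """Full TPT analysis of the A->B process on a transition matrix model.

    Gross flux f_ij = pi_i q-_i T_ij q+_j (i != j), net flux
    f+_ij = max(f_ij - f_ji, 0); flux conservation is verified at every
    intermediate state (residual > 1e-8 raises).  Pathways come from
    :func:`decompose_pathways`.
    """
    T, lag, pi = _matrix_lag_pi(model)
    n = T.shape[0]
    A = sorted(_as_index_set(source, n))
    B = sorted(_as_index_set(target, n))
    qf = committor_forward(model, A, B)
    qb = committor_backward(model, A, B)
    f = pi[:, None] * qb[:, None] * T * qf[None, :]
    np.fill_diagonal(f, 0.0)
    fnet = np.clip(f - f.T, 0.0, None)
    inter = [i for i in range(n) if i not in set(A) | set(B)]
    imbalance = np.abs(f.sum(axis=1) - f.sum(axis=0))[inter]
    if imbalance.size and imbalance.max() > 1e-8:
        raise ValueError(
            f"reactive flux not conserved at intermediates (max residual {imbalance.max():.2e})"
        )
    notA = [i for i in range(n) if i not in set(A)]
    total = float(f[np.ix_(A, notA)].sum())
    rate = total / lag if lag else float("nan")
    paths = decompose_pathways(fnet, A, B, residual_fraction, total_flux=total)
    return TPTResult(list(A), list(B), qf, qb, f, fnet, total, rate, paths)


def _bottleneck_path(F, A, B):
    """Max-bottleneck A->B path via a Dijkstra-style widest-path search."""
    n = F.shape[0]
    width = np.full(n, -1.0)
    prev = np.full(n, -1, dtype=int)
    width[list(A)] = np.inf
    visited = np.zeros(n, bool)
    while True:
        cand = np.where(~visited & (width > 0))[0]
        if cand.size == 0:
            return None, 0.0
        u = cand[np.argmax(width[cand])]
        if u in B:
            path = [int(u)]
            while prev[path[-1]] != -1:
                path.append(int(prev[path[-1]]))
            # walk back to the A state the search started from
            return path[::-1], float(width[u])
        visited[u] = True
        for v in range(n):
            if F[u, v] > 0 and not visited[v]:
                w = min(width[u], F[u, v])
                if w > width[v]:
                    width[v] = w
                    prev[v] = u
    # unreachable


def decompose_pathways(net_flux, source, target, residual_fraction: float = 0.01,
                       total_flux: float | None = None) -> list:
    """Greedy max-bottleneck pathway decomposition of a net flux matrix.

    Repeatedly extract the A->B path whose minimal edge is maximal, subtract
    its bottleneck flux along the path, and stop when the remaining flux
    drops below ``residual_fraction`` of the total.  Returns
    ``[(path states, flux, fraction of total), ...]`` in extraction order
    (strongest first).  The greedy subtraction order is part of the
    definition; alternative orders can re-partition near-degenerate paths.
    """
    F = np.array(net_flux, float)
    n = F.shape[0]
    A = _as_index_set(source, n)
    B = _as_index_set(target, n)
    if total_flux is None:
        notA = [i for i in range(n) if i not in A]
        total_flux = float(F[np.ix_(sorted(A), notA)].sum())
    if total_flux <= 0:
        return []
    remaining = total_flux
    out = []
    for _ in range(10000):
        if remaining <= residual_fraction * total_flux + 1e-300:
            break
        path, width = _bottleneck_path(F, A, B)
        if path is None or width <= 0:
            break
        for u, v in zip(path[:-1], path[1:]):
            F[u, v] -= width
        out.append((tuple(path), width, width / total_flux))
        remaining -= width
    return out


def pathways_table(result: TPTResult):
    """Pathway decomposition as a DataFrame (path, flux, fraction)."""
    import pandas as pd

    return pd.DataFrame(
        [{"path": "->".join(map(str, p)), "flux": fl, "fraction": fr}
         for p, fl, fr in result.pathways]
    )
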