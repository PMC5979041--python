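"""Binding kinetics and thermodynamics from Markov models.

Mean first-passage times on (macro)state transition matrices, conversion to
bimolecular on-rates and unimolecular off-rates (k_on = 1/(MFPT_on C),
k_off = 1/MFPT_off), stationary-population binding free energies with the
1 M standard-state correction, activation barriers from transition-path
times via k_off = (1/tau_TPT) exp(-dG*/RT), and trajectory-level bootstrap
uncertainties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .coarse import MacrostateModel
from .exceptions import SingularSystemError
from .markov import MarkovModel
from .synthetic import _as_index_set
from .units import DEFAULT_TEMPERATURE_K, KB_KCAL_MOL_K, NS_PER_S


def _matrix_lag_pi(model):
    if isinstance(model, MarkovModel):
        return model.transition_matrix, model.lag_time, model.stationary_distribution
    if isinstance(model, MacrostateModel):
        return model.coarse_transition_matrix, model.lag_time, model.populations
    raise TypeError("model must be a MarkovModel or MacrostateModel")


def mfpt(model, source, target, weights: str = "stationary") -> float:
    """Mean first-passage time (ns) from state set A to state set B.

    Solves (I - T_CC) m = tau 1 on the complement C of B; the A-average uses
    the stationary distribution restricted to A (``weights="uniform"``
    switches to a flat average).  Includes indirect routes through
    intermediate states.
    """
    T, lag, pi = _matrix_lag_pi(model)
    n = T.shape[0]
    A = _as_index_set(source, n)
    B = _as_index_set(target, n)
    if A & B:
        if A == B or A <= B:
            return 0.0
        raise ValueError("source and target sets must be disjoint")
    comp = [i for i in range(n) if i not in B]
    Tcc = T[np.ix_(comp, comp)]
    try:
        m = np.linalg.solve(np.eye(len(comp)) - Tcc, lag * np.ones(len(comp)))
    except np.linalg.LinAlgError as exc:
        raise SingularSystemError("target set unreachable from source set") from exc
    if np.any(m < 0) or not np.all(np.isfinite(m)):
        raise SingularSystemError("target set unreachable from source set")
    full = np.zeros(n)
    full[comp] = m
    idx = sorted(A)
    if weights == "stationary":
        w = pi[idx]
    elif weights == "uniform":
        w = np.ones(len(idx))
    else:
        raise ValueError("weights must be 'stationary' or 'uniform'")
    if w.sum() <= 0:
        raise ValueError("source set has zero stationary weight")
    return float(np.dot(full[idx], w / w.sum()))


def rates_from_mfpt(mfpt_on: float, mfpt_off: float, concentration: float):
    """(k_on [1/(M s)], k_off [1/s]) from MFPTs in ns and concentration in M.

    k_on = 1/(MFPT_on * C), k_off = 1/MFPT_off.
    """
    if mfpt_on <= 0 or mfpt_off <= 0:
        raise ValueError("MFPTs must be positive")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    k_on = 1.0 / (mfpt_on / NS_PER_S * concentration)
    k_off = 1.0 / (mfpt_off / NS_PER_S)
    return k_on, k_off


def binding_dG(
    pi_bound: float,
    pi_unbound: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
    concentration: float = 9.55e-3,
    standard_state: float = 1.0,
):
    """(dG_sim, dG0) in kcal/mol from stationary bound/unbound populations.

    dG_sim = -kB T ln(pi_bound/pi_unbound) at the simulated ligand
    concentration; dG0 = dG_sim + R T ln(C / C0) references the 1 M standard
    state (ideal-dilute rescaling of the unbound population).
    """
    if pi_bound <= 0 or pi_unbound <= 0:
        raise ValueError("populations must be positive")
    if concentration <= 0 or standard_state <= 0:
        raise ValueError("concentrations must be positive")
    rt = KB_KCAL_MOL_K * temperature
    dg_sim = -rt * np.log(pi_bound / pi_unbound)
    dg0 = dg_sim + rt * np.log(concentration / standard_state)
    return float(dg_sim), float(dg0)


def barrier_unbinding(tau_tpt: float, k_off: float,
                      temperature: float = DEFAULT_TEMPERATURE_K):
    """Unbinding activation free energy from k_off = (1/tau_TPT) e^{-dG*/RT}.

    ``tau_tpt`` in ns, ``k_off`` in 1/s.  Returns (dG* in RT units, dG* in
    kcal/mol); warns when tau_TPT * k_off >= 1 (non-positive barrier).
    """
    if tau_tpt <= 0 or k_off <= 0:
        raise ValueError("tau_TPT and k_off must be positive")
    x = tau_tpt / NS_PER_S * k_off
    if x >= 1:
        warnings.warn("tau_TPT * k_off >= 1: inferred barrier is non-positive",
                      stacklevel=2)
    rt_units = float(-np.log(x))
    return rt_units, rt_units * KB_KCAL_MOL_K * temperature


def barrier_binding(dG_binding: float, dG_star_unbinding_rt: float,
                    temperature: float = DEFAULT_TEMPERATURE_K):
    """Binding barrier from dG_binding = dG*_binding - dG*_unbinding.

    ``dG_binding`` in kcal/mol, ``dG_star_unbinding_rt`` in RT units.
    Returns (dG*_binding in RT, in kcal/mol).
    """
    rt = KB_KCAL_MOL_K * temperature
    rt_units = dG_binding / rt + dG_star_unbinding_rt
    return float(rt_units), float(rt_units * rt)


@dataclass
class KineticsSummary:
    """Headline binding kinetics/thermodynamics with their conventions."""

    mfpt_on: float       # ns
    mfpt_off: float      # ns
    k_on: float          # 1/(M s)
    k_off: float         # 1/s
    concentration: float  # mol/L
    temperature: float   # K
    dG_sim: float        # kcal/mol
    dG0: float           # kcal/mol, 1 M standard state

    def __post_init__(self):
        if self.mfpt_on <= 0 or self.mfpt_off <= 0:
            raise ValueError("MFPTs must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def kinetics_summary(
    model,
    unbound,
    bound,
    concentration: float = 9.55e-3,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> KineticsSummary:
    """Full kinetics/thermodynamics summary from a (macro)state model: MFPTs, rates
    and binding free energies between an unbound and a bound state set."""
    _, _, pi = _matrix_lag_pi(model)
    m_on = mfpt(model, unbound, bound)
    m_off = mfpt(model, bound, unbound)
    k_on, k_off = rates_from_mfpt(m_on, m_off, concentration)
    pb = float(np.sum(pi[sorted(_as_index_set(bound, len(pi)))]))
    pu = float(np.sum(pi[sorted(_as_index_set(unbound, len(pi)))]))
    dg_sim, dg0 = binding_dG(pb, pu, temperature, concentration)
    return KineticsSummary(m_on, m_off, k_on, k_off, concentration,
                           temperature, dg_sim, dg0)


@dataclass
class BarrierEstimate:
    """Activation barriers inferred from transition-path times."""

    tau_tpt: float                 # ns
    dG_star_unbinding_rt: float
    dG_star_unbinding_kcal: float
    dG_star_binding_rt: float
    dG_star_binding_kcal: float
    k_off_source: float            # 1/s
    dG_binding_source: float       # kcal/mol
    temperature: float             # K

    def to_dict(self) -> dict:
        return asdict(self)


def barrier_estimate(
    tau_tpt: float,
    k_off: float,
    dG_binding: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> BarrierEstimate:
    """Combine :func:`barrier_unbinding` and :func:`barrier_binding`."""
    unb_rt, unb_kcal = barrier_unbinding(tau_tpt, k_off, temperature)
    b_rt, b_kcal = barrier_binding(dG_binding, unb_rt, temperature)
    return BarrierEstimate(tau_tpt, unb_rt, unb_kcal, b_rt, b_kcal,
                           k_off, dG_binding, temperature)


def bootstrap_ci(
    trajectories,
    estimator,
    n_boot: int = 100,
    seed: int = 0,
    percentiles=(2.5, 97.5),
    return_replicates: bool = False,
):
    """Trajectory-level bootstrap of a scalar or vector estimator.

    ``estimator`` maps a list of trajectories to a number or array.
    Replicates where the estimator raises are dropped and counted; more than
    20% drops is an error.  Returns (mean, sd, (lo, hi), n_dropped).
    """
    trajectories = list(trajectories)
    if len(trajectories) < 2:
        raise ValueError("bootstrap needs at least 2 trajectories")
    rng = np.random.default_rng(seed)
    reps, dropped = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(trajectories), size=len(trajectories))
        sample = [trajectories[i] for i in idx]
        try:
            reps.append(np.asarray(estimator(sample), float))
        except Exception:
            dropped += 1
    if dropped > 0.2 * n_boot:
        raise RuntimeError(f"estimator failed on {dropped}/{n_boot} bootstrap replicates")
    reps = np.stack(reps)
    lo, hi = np.percentile(reps, percentiles, axis=0)
    summary = (reps.mean(axis=0), reps.std(axis=0, ddof=1), (lo, hi), dropped)
    return (*summary, reps) if return_replicates else summary
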