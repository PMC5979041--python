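"""Synthetic trajectory generation with exact ground truth.

This module stands in for tens of microseconds of MD: it provides

* continuous-time kinetic networks (:class:`KineticNetwork`) with analytic
  stationary distributions, mean first-passage times and committors,
* a Gillespie sampler discretized on a saving grid (:func:`simulate_ctmc`),
* overdamped Langevin dynamics on analytic potentials (:func:`simulate_langevin`),
* state-conditioned Gaussian feature emission (:func:`emit_features`), and
* a bundled four-state benchmark network whose stationary populations and
  lifetimes match the magnitudes of the benzene/T4L macrostate model
  (one dominant bound state at ~99.8%, a rare unbound state at ~0.1%, and
  two short-lived intermediates).

Every stochastic routine takes an explicit integer seed; ensembles derive
per-trajectory seeds from a master seed with :func:`spawn_seeds`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from . import _kernels
from .exceptions import NonFiniteDynamicsError, NotIrreducibleError, SingularSystemError
from .potentials import PotentialSpec


def spawn_seeds(master_seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent 31-bit child seeds from a master seed.

    Child ``i`` is ``SeedSequence(master_seed).generate_state(n)[i] % 2**31``;
    the scheme is deterministic and documented so ensembles are reproducible
    trajectory by trajectory.
    """
    state = np.random.SeedSequence(int(master_seed)).generate_state(n, dtype=np.uint64)
    return (state % (2**31)).astype(np.int64)


@dataclass
class DiscreteTrajectory:
    """An integer state sequence saved on a regular time grid."""

    states: np.ndarray
    frame_interval: float  # ns

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.states.ndim != 1:
            raise ValueError("states must be a 1D integer sequence")

    def __len__(self):
        return len(self.states)

    @property
    def total_time(self) -> float:
        return (len(self.states) - 1) * self.frame_interval


@dataclass
class ContinuousTrajectory:
    """Positions per frame (frames, dim) on a regular time grid."""

    positions: np.ndarray
    frame_interval: float  # ns

    def __post_init__(self):
        self.positions = np.atleast_1d(np.asarray(self.positions, float))
        if self.positions.ndim == 1:
            self.positions = self.positions[:, None]
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")


class KineticNetwork:
    """A labelled, irreducible continuous-time Markov chain.

    Parameters
    ----------
    rate_matrix : (n, n) array
        Generator Q in 1/ns; off-diagonal entries are transition rates and
        each diagonal equals minus the row's off-diagonal sum (rows sum to 0;
        the diagonal may be omitted by passing zeros there).
    state_labels : sequence of str, optional
    """

    def __init__(self, rate_matrix, state_labels=None):
        Q = np.array(rate_matrix, dtype=float)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
            raise ValueError("rate matrix must be square")
        n = Q.shape[0]
        off = Q - np.diag(np.diag(Q))
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        self.Q = Q
        self.n_states = n
        self.state_labels = (
            list(state_labels) if state_labels is not None else [f"S{i}" for i in range(n)]
        )
        if len(self.state_labels) != n:
            raise ValueError("one label per state required")
        ncomp, _ = connected_components(off > 0, directed=True, connection="strong")
        if n > 1 and ncomp != 1:
            raise NotIrreducibleError(
                f"rate matrix has {ncomp} communicating classes; must be irreducible"
            )
        if np.any(self.exit_rates <= 0) and n > 1:
            raise ValueError("every state needs a positive total exit rate")

    @property
    def exit_rates(self) -> np.ndarray:
        """Total exit rate per state, 1/ns."""
        return -np.diag(self.Q)

    @property
    def lifetimes(self) -> np.ndarray:
        """Mean dwell time per state, ns."""
        return 1.0 / self.exit_rates

    def stationary_distribution(self) -> np.ndarray:
        """pi solving pi Q = 0, sum(pi) = 1."""
        n = self.n_states
        A = np.vstack([self.Q.T, np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.any(pi <= 0):
            raise SingularSystemError("stationary distribution not strictly positive")
        return pi / pi.sum()

    def mfpt_matrix(self) -> np.ndarray:
        """Pairwise mean first-passage times in ns; M[i, j] = MFPT(i -> j), M[j, j] = 0."""
        n = self.n_states
        M = np.zeros((n, n))
        for j in range(n):
            keep = [i for i in range(n) if i != j]
            Qs = self.Q[np.ix_(keep, keep)]
            try:
                m = np.linalg.solve(Qs, -np.ones(n - 1))
            except np.linalg.LinAlgError as exc:
                raise SingularSystemError(f"MFPT system singular for target {j}") from exc
            M[keep, j] = m
        return M

    def committor(self, source, sink) -> np.ndarray:
        """Forward committor q+ (probability of reaching sink before source)."""
        A = _as_index_set(source, self.n_states)
        B = _as_index_set(sink, self.n_states)
        if A & B:
            raise ValueError("source and sink must be disjoint")
        q = np.zeros(self.n_states)
        q[list(B)] = 1.0
        inter = [i for i in range(self.n_states) if i not in A | B]
        if inter:
            Qii = self.Q[np.ix_(inter, inter)]
            rhs = -self.Q[np.ix_(inter, sorted(B))].sum(axis=1)
            try:
                q[inter] = np.linalg.solve(Qii, rhs)
            except np.linalg.LinAlgError as exc:
                raise SingularSystemError("committor system singular") from exc
        return q


@dataclass(frozen=True)
class CTMCOracle:
    """Exact reference quantities for a kinetic network."""

    stationary: np.ndarray
    mfpt: np.ndarray  # ns, (n, n)
    committor: np.ndarray | None = None


def ctmc_oracle(network: KineticNetwork, source=None, sink=None) -> CTMCOracle:
    """Analytic stationary distribution, MFPT matrix and (optionally) committor."""
    q = network.committor(source, sink) if source is not None and sink is not None else None
    return CTMCOracle(network.stationary_distribution(), network.mfpt_matrix(), q)


def gillespie_jumps(network: KineticNetwork, total_time: float, seed: int, start=None):
    """Exact jump-process sample: (jump_times, states), states[i] occupied from
    jump_times[i] until jump_times[i+1]."""
    rng = np.random.default_rng(seed)
    n = network.n_states
    exit_rates = network.exit_rates
    jump_p = network.Q - np.diag(np.diag(network.Q))
    jump_p = jump_p / exit_rates[:, None]
    if start is None:
        s = int(rng.choice(n, p=network.stationary_distribution()))
    else:
        s = int(start)
    t = 0.0
    times = [0.0]
    states = [s]
    while t < total_time:
        t += rng.exponential(1.0 / exit_rates[s])
        s = int(rng.choice(n, p=jump_p[s]))
        times.append(t)
        states.append(s)
    return np.array(times), np.array(states, dtype=np.int64)


def simulate_ctmc(
    network: KineticNetwork,
    total_time: float,
    frame_interval: float,
    seed: int,
    start=None,
) -> DiscreteTrajectory:
    """Gillespie sample discretized by point-sampling on the frame grid.

    The state recorded at grid time t is the state occupied at t (as MD frames
    are saved), not a majority vote over the interval.  ``start`` is an
    initial state index or None to draw from the stationary distribution.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    if total_time < 10 * frame_interval:
        raise ValueError("total_time must cover at least 10 frame intervals")
    times, states = gillespie_jumps(network, total_time, seed, start)
    n_frames = int(np.floor(total_time / frame_interval)) + 1
    grid = np.arange(n_frames) * frame_interval
    idx = np.searchsorted(times, grid, side="right") - 1
    return DiscreteTrajectory(states[idx], frame_interval)


@dataclass(frozen=True)
class LangevinParams:
    """Overdamped Langevin integration parameters.

    ``friction`` is the drag coefficient entering the update
    x <- x - (dt/friction) dU/dx + sqrt(2 kT dt / friction) xi
    (units kcal/mol * ns / nm^2 so that dt/friction has nm^2 mol/kcal).
    """

    dt: float  # ns
    kT: float  # kcal/mol
    friction: float
    n_steps: int
    seed: int
    stride: int = 1

    def __post_init__(self):
        if self.dt <= 0 or self.kT <= 0 or self.friction <= 0:
            raise ValueError("dt, kT and friction must all be positive")
        if self.n_steps < 1 or self.stride < 1:
            raise ValueError("n_steps and stride must be >= 1")


def simulate_langevin(
    potential: PotentialSpec, params: LangevinParams, start
) -> ContinuousTrajectory:
    """Overdamped Langevin trajectory on an analytic potential.

    Raises :class:`NonFiniteDynamicsError` (with the offending step index) if
    the energy/gradient or position becomes non-finite, and ``ValueError`` if
    the deterministic per-step displacement is large compared with the
    potential's length scale (time step too coarse).
    """
    start = np.atleast_1d(np.asarray(start, float))
    if not np.all(np.isfinite(start)):
        raise ValueError("start position must be finite")
    p = potential.flat_params()
    _check_timestep(potential, params, start)
    seed = int(params.seed) % (2**31)
    if potential.dim == 1:
        traj, err = _kernels._simulate_1d(
            potential.code, p, float(start[0]), params.n_steps, params.stride,
            params.dt, params.kT, params.friction, seed,
        )
        positions = traj[:, None]
    else:
        if start.size != 2:
            raise ValueError("2D potential requires a 2D start position")
        positions, err = _kernels._simulate_2d(
            p, float(start[0]), float(start[1]), params.n_steps, params.stride,
            params.dt, params.kT, params.friction, seed,
        )
    if err != -1:
        raise NonFiniteDynamicsError(
            f"non-finite energy/gradient or position at integration step {err}", frame=int(err)
        )
    return ContinuousTrajectory(positions, params.dt * params.stride)


def _check_timestep(potential, params, start):
    """Heuristic: max drift per step over a probe region must stay below the
    potential's own length scale."""
    scale = _length_scale(potential)
    probe = np.linspace(-2 * scale, 2 * scale, 41)
    if potential.dim == 1:
        g = np.max(np.abs(potential.gradient(probe)))
    else:
        xy = np.stack(np.meshgrid(probe, probe), axis=-1).reshape(-1, 2)
        g = np.max(np.abs(potential.gradient(xy)))
    if not np.isfinite(g):
        raise NonFiniteDynamicsError("potential gradient non-finite on probe grid", frame=0)
    if params.dt * g / params.friction > 0.5 * scale:
        raise ValueError(
            "time step too large: deterministic drift per step exceeds half the "
            "potential length scale; reduce dt or increase friction"
        )


def _length_scale(potential: PotentialSpec) -> float:
    if potential.form == "double_well":
        return potential.flat_params()[1]
    if potential.form == "binding_landscape_2d":
        return potential.flat_params()[1]
    return 1.0


def emit_features(
    dtraj: DiscreteTrajectory,
    emission_centers,
    emission_spread,
    seed: int,
) -> np.ndarray:
    """Per-frame feature vectors from each state's spherical Gaussian.

    ``emission_centers`` is (n_states, d); ``emission_spread`` a scalar or
    per-state positive scale.  Returns a (n_frames, d) array.
    """
    centers = np.atleast_2d(np.asarray(emission_centers, float))
    n_states = centers.shape[0]
    if dtraj.states.min() < 0 or dtraj.states.max() >= n_states:
        raise ValueError("trajectory refers to states without an emission center")
    spread = np.broadcast_to(np.asarray(emission_spread, float), (n_states,)).copy()
    if np.any(spread < 0):
        raise ValueError("emission spreads must be non-negative")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((len(dtraj), centers.shape[1]))
    return centers[dtraj.states] + spread[dtraj.states, None] * noise


# ---------------------------------------------------------------------------
# Bundled four-state benchmark
# ---------------------------------------------------------------------------

#: Stationary populations of the benchmark macrostates (unbound MS0, two
#: intermediates MS1/MS2, bound MS3), normalized from 0.11 / 6.4e-3 / 4.7e-2
#: / 99.83 percent.
BENCHMARK_POPULATIONS = np.array([0.11, 6.4e-3, 4.7e-2, 99.83]) / 99.9934

#: Mean lifetimes of the benchmark macrostates in ns (2.6e3, 69, 742, 9e5).
BENCHMARK_LIFETIMES = np.array([2.6e3, 69.0, 742.0, 9.0e5])

# Symmetric stationary fluxes F[i, j] = pi_i * k_ij (1/ns) chosen so that both
# the populations and the lifetimes above are matched exactly under detailed
# balance.  The split between the direct 0-3 channel and the two intermediate
# channels is an artifact choice.
_BENCHMARK_FLUXES = {
    (0, 1): 3.0e-7,
    (1, 3): 5.876e-7,
    (0, 2): 9.745e-8,
    (2, 3): 4.9602e-7,
    (0, 3): 2.566e-8,
    (1, 2): 4.0e-8,
}

BENCHMARK_LABELS = ["MS0", "MS1", "MS2", "MS3"]

#: Default emission model for the benchmark: one unit-axis center per state in
#: 4 feature dimensions plus 2 pure-noise dimensions, spherical spread 0.15.
BENCHMARK_EMISSION_SPREAD = 0.15
BENCHMARK_NOISE_DIMS = 2


def benchmark_network(time_scale: float = 1.0) -> KineticNetwork:
    """The bundled reversible four-state binding network.

    ``time_scale`` multiplies every rate (dividing every lifetime) without
    changing the stationary distribution; desk-scale studies compress the
    native micro-to-millisecond hierarchy this way.
    """
    if time_scale <= 0:
        raise ValueError("time_scale must be positive")
    pi = BENCHMARK_POPULATIONS
    Q = np.zeros((4, 4))
    for (i, j), flux in _BENCHMARK_FLUXES.items():
        Q[i, j] = flux / pi[i]
        Q[j, i] = flux / pi[j]
    return KineticNetwork(Q * time_scale, BENCHMARK_LABELS)


def benchmark_emission_centers(n_noise: int = BENCHMARK_NOISE_DIMS) -> np.ndarray:
    """Unit-axis emission centers for the 4 benchmark states, padded with
    ``n_noise`` uninformative dimensions."""
    centers = np.eye(4)
    if n_noise:
        centers = np.hstack([centers, np.zeros((4, n_noise))])
    return centers


def benchmark_ensemble(
    n_trajectories: int,
    n_frames: int,
    frame_interval: float,
    master_seed: int,
    time_scale: float = 1.0,
    emission_spread: float = BENCHMARK_EMISSION_SPREAD,
    n_noise: int = BENCHMARK_NOISE_DIMS,
):
    """Generate a benchmark ensemble: (discrete trajectories, feature
    trajectories, network).  Initial states are drawn from the stationary
    distribution; seeds derive from ``master_seed`` via :func:`spawn_seeds`."""
    network = benchmark_network(time_scale)
    centers = benchmark_emission_centers(n_noise)
    spread = np.full(4, emission_spread)
    if n_noise:
        # noise dims get state-independent jitter through the spherical spread
        pass
    seeds = spawn_seeds(master_seed, 2 * n_trajectories)
    total_time = (n_frames - 1) * frame_interval
    dtrajs, ftrajs = [], []
    for i in range(n_trajectories):
        d = simulate_ctmc(network, total_time, frame_interval, int(seeds[2 * i]))
        d.states = d.states[:n_frames]
        f = emit_features(d, centers, spread, int(seeds[2 * i + 1]))
        dtrajs.append(d)
        ftrajs.append(f)
    return dtrajs, ftrajs, network


def _as_index_set(sel, n) -> set:
    if np.isscalar(sel):
        sel = [sel]
    out = set(int(i) for i in sel)
    if not out:
        raise ValueError("state set must be non-empty")
    if any(i < 0 or i >= n for i in out):
        raise ValueError("state index out of range")
    return out
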