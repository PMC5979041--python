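"""Umbrella sampling and the weighted histogram analysis method (WHAM).

Windows restrain the 1D collective variable with a harmonic potential
U(x) + 1/2 k (x - c)^2 (force constant in kJ/mol/nm^2, as conventionally
quoted); WHAM self-consistently reweights the window histograms into an
unbiased potential of mean force pinned to min 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .exceptions import ConvergenceError, WindowOverlapError
from .potentials import PotentialSpec
from .synthetic import LangevinParams, spawn_seeds
from .units import DEFAULT_TEMPERATURE_K, KB_KCAL_MOL_K, kj_to_kcal


@dataclass
class UmbrellaWindow:
    """Samples of the CV under one harmonic restraint."""

    center: float          # nm
    force_constant: float  # kJ/mol/nm^2
    samples: np.ndarray    # CV values, nm
    sampling_time: float   # ns

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float)
        if self.force_constant <= 0:
            raise ValueError("force constant must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window samples must be finite")


def harvest_windows(
    potential: PotentialSpec,
    centers,
    params: LangevinParams,
    force_constant: float = 8000.0,  # kJ/mol/nm^2
    equilibration_fraction: float = 0.1,
) -> list:
    """Sample one umbrella window per center (default spacing in studies:
    0.05 nm) under U(x) + 1/2 k (x - c)^2, starting each window at its
    center.  Warns when a window's sample mean drifts more than 3 sample
    standard deviations from its center.
    """
    centers = np.asarray(centers, float)
    if np.any(np.diff(centers) <= 0):
        raise ValueError("window centers must be sorted and strictly increasing")
    if potential.dim != 1:
        raise ValueError("umbrella sampling supports 1D potentials only")
    k_kcal = kj_to_kcal(force_constant)
    if params.dt * k_kcal / params.friction > 0.5:
        raise ValueError(
            "time step unstable for this restraint stiffness: need "
            f"dt < {0.5 * params.friction / k_kcal:.2g} ns at k = {force_constant} kJ/mol/nm^2"
        )
    p = potential.flat_params()
    seeds = spawn_seeds(params.seed, len(centers))
    n_equil = int(equilibration_fraction * params.n_steps)
    windows = []
    for c, seed in zip(centers, seeds):
        samples = _kernels._umbrella_1d(
            potential.code, p, float(c), k_kcal, float(c),
            params.n_steps + n_equil, params.stride, params.dt, params.kT,
            params.friction, int(seed),
        )
        samples = samples[n_equil // params.stride:]
        w = UmbrellaWindow(float(c), force_constant, samples,
                           params.n_steps * params.dt)
        sd = samples.std()
        if sd > 0 and abs(samples.mean() - c) > 3 * sd:
            warnings.warn(f"window at {c} nm drifted beyond 3 sigma from its center",
                          stacklevel=2)
        windows.append(w)
    return windows


@dataclass
class PMFProfile:
    """Potential of mean force on bins with nonzero counts, min pinned to 0."""

    bin_centers: np.ndarray   # nm
    free_energy: np.ndarray   # kcal/mol
    window_counts: np.ndarray  # (n_windows, n_bins) diagnostics

    def __post_init__(self):
        if abs(np.nanmin(self.free_energy)) > 1e-9:
            raise ValueError("PMF minimum must be pinned to 0")


def wham_solve(
    windows,
    n_bins: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 100000,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> PMFProfile:
    """Standard WHAM self-consistency on binned window histograms.

    Unbiased bin probabilities p_b and window shifts f_i are iterated until
    the maximum relative change of the shifts drops below ``tol``.  The
    default bin width is half the smallest window spacing (2 bins per
    spacing).  Consecutive windows must overlap (their sampled supports must
    touch), otherwise :class:`WindowOverlapError` lists the gap.
    """
    if not windows:
        raise ValueError("at least one window required")
    windows = sorted(windows, key=lambda w: w.center)
    kT = KB_KCAL_MOL_K * temperature
    for a, b in zip(windows[:-1], windows[1:]):
        if a.samples.max() < b.samples.min():
            raise WindowOverlapError(
                f"no overlap between windows at {a.center} and {b.center} nm "
                f"(gap {b.samples.min() - a.samples.max():.3g} nm)"
            )
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    if n_bins is None:
        if len(windows) > 1:
            spacing = np.min(np.diff([w.center for w in windows]))
            n_bins = max(10, int(np.ceil((hi - lo) / (spacing / 2.0))))
        else:
            n_bins = 50
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_w = len(windows)
    counts = np.zeros((n_w, n_bins))
    for i, w in enumerate(windows):
        counts[i], _ = np.histogram(w.samples, bins=edges)
    total_b = counts.sum(axis=0)
    N_i = counts.sum(axis=1)
    bias = np.array([
        0.5 * kj_to_kcal(w.force_constant) * (centers - w.center) ** 2 for w in windows
    ])
    boltz = np.exp(-bias / kT)  # (n_w, n_bins)

    # The WHAM self-consistency equations are the stationarity conditions of a
    # convex likelihood in the window shifts a_i = ln g_i; minimize it with
    # L-BFGS (fast even with weak window coupling), then certify convergence
    # with fixed-point sweeps at the requested tolerance.
    occupied = total_b > 0

    def objective(a):
        w = N_i * np.exp(a)
        D = w @ boltz  # (n_bins,)
        val = float(np.sum(total_b[occupied] * np.log(D[occupied])) - np.dot(N_i, a))
        ratio = np.where(occupied, total_b / np.where(D > 0, D, 1.0), 0.0)
        grad = w * (boltz @ ratio) - N_i
        return val, grad

    from scipy.optimize import minimize

    res = minimize(objective, np.zeros(n_w), jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12})
    g = np.exp(res.x - res.x[0])
    rel = np.inf
    for _ in range(max_iter):
        denom = (N_i * g) @ boltz  # (n_bins,)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, total_b / denom, 0.0)
        z = boltz @ p
        g_new = 1.0 / z
        g_new /= g_new[0]
        rel = np.max(np.abs(g_new - g) / g_new)
        g = g_new
        if rel < tol:
            break
    else:
        raise ConvergenceError(f"WHAM did not converge (last shift change {rel:.2e})")
    denom = (N_i * g) @ boltz
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom > 0, total_b / denom, 0.0)
    mask = total_b > 0
    with np.errstate(divide="ignore"):
        fe = -kT * np.log(np.where(mask, p, np.nan))
    fe = fe[mask] - np.nanmin(fe[mask])
    return PMFProfile(centers[mask], fe, counts[:, mask])


def dG_between(profile: PMFProfile, x1: float, x2: float) -> float:
    """Free-energy difference G(x2) - G(x1) in kcal/mol by linear
    interpolation between bin centers; querying outside the sampled support
    is an error."""
    lo, hi = profile.bin_centers.min(), profile.bin_centers.max()
    for x in (x1, x2):
        if x < lo or x > hi:
            raise ValueError(f"query {x} nm outside the PMF support [{lo:.3g}, {hi:.3g}]")
    g1, g2 = np.interp([x1, x2], profile.bin_centers, profile.free_energy)
    return float(g2 - g1)


def fold_change(dG: float, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Boltzmann population fold change e^{dG/RT} for dG in kcal/mol."""
    return float(np.exp(dG / (KB_KCAL_MOL_K * temperature)))
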