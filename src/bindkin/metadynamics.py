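"""Infrequent well-tempered metadynamics and rate recovery.

History-dependent Gaussian bias along a 1D CV with tempered hill heights
(h_k = h0 exp(-V(s_k)/((Gamma-1) kT))); runs stop at the first frame beyond
an escape threshold.  The acceleration factor alpha = <exp(V(s,t)/kT)>_t
(bias evaluated at the pre-deposition instant) rescales simulated escape
times to unbiased ones; an ensemble of rescaled times is then checked
against the Poisson/exponential null by a Kolmogorov-Smirnov test and
converted to a rate.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from . import _kernels
from .exceptions import CensoredRunError
from .potentials import PotentialSpec
from .synthetic import LangevinParams, spawn_seeds
from .units import NS_PER_S, kcal_to_kj, kj_to_kcal


@dataclass
class HillsLog:
    """Deposited Gaussian hills of one metadynamics run."""

    times: np.ndarray      # ns, strictly increasing
    centers: np.ndarray    # CV units
    sigma: float           # CV units (constant width per run)
    heights: np.ndarray    # kJ/mol, post-tempering
    bias_factor: float     # Gamma
    pace: float            # ns

    def __post_init__(self):
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("hill deposition times must be strictly increasing")
        if np.any(self.heights < 0):
            raise ValueError("hill heights must be non-negative")


@dataclass
class EscapeRecord:
    """One (possibly rescaled) escape event."""

    simulated_time: float  # ns
    acceleration: float    # alpha, dimensionless
    rescaled_time: float   # ns, = simulated_time * alpha
    seed: int

    def __post_init__(self):
        if self.acceleration < 1.0 - 1e-9:
            raise ValueError("acceleration factor must be >= 1")

    def to_dict(self):
        return asdict(self)


def bias_value(log: HillsLog, s, t: float):
    """Total bias (kJ/mol) at CV value(s) ``s`` from hills deposited before ``t``."""
    s = np.asarray(s, float)
    live = log.times < t
    if not np.any(live):
        return np.zeros_like(s) if s.ndim else 0.0
    c = log.centers[live]
    h = log.heights[live]
    v = (h[None, :] * np.exp(
        -((np.atleast_1d(s)[:, None] - c[None, :]) ** 2) / (2.0 * log.sigma**2)
    )).sum(axis=1)
    return v if s.ndim else float(v[0])


def run_infrequent_metadyn(
    potential: PotentialSpec,
    params: LangevinParams,
    start: float,
    escape_threshold: float,
    width: float,
    pace: float = 0.01,       # ns
    height0: float = 1.2,     # kJ/mol
    bias_factor: float = 6.0,  # Gamma
    constant_bias: float = 0.0,  # kJ/mol, added to the bookkeeping bias only
    grid_padding: float = 1.0,
    n_grid: int = 1200,
):
    """One infrequent-metadynamics escape run on the CV s = x.

    Returns ``(EscapeRecord, HillsLog)``; a run that does not escape within
    ``params.n_steps`` raises :class:`CensoredRunError`.  ``constant_bias``
    models an externally imposed flat bias: it exerts no force but enters
    the acceleration factor exactly as exp(V0/kT).
    """
    if potential.dim != 1:
        raise ValueError("metadynamics supports 1D collective variables only")
    if bias_factor <= 1:
        raise ValueError("well-tempered bias factor must exceed 1")
    if width <= 0:
        raise ValueError("hill width must be positive")
    pace_steps = int(round(pace / params.dt))
    if pace_steps < 2:
        raise ValueError("pace must be at least two time steps")
    p = potential.flat_params()
    lo = min(float(start), -abs(escape_threshold)) - grid_padding
    hi = max(float(start), escape_threshold) + grid_padding
    step, alpha, ht, hc, hh, n_hills = _kernels._metadyn_1d(
        potential.code, p, float(start), float(escape_threshold),
        params.dt, params.kT, params.friction, int(params.seed) % (2**31),
        pace_steps, kj_to_kcal(height0), float(width), float(bias_factor),
        lo, hi, n_grid, params.n_steps,
    )
    alpha *= float(np.exp(kj_to_kcal(constant_bias) / params.kT))
    log = HillsLog(ht[:n_hills], hc[:n_hills], float(width),
                   kcal_to_kj(hh[:n_hills]), bias_factor, pace)
    if step < 0:
        raise CensoredRunError(
            f"no escape within {params.n_steps} steps (alpha so far {alpha:.3g})"
        )
    sim_t = step * params.dt
    rec = EscapeRecord(sim_t, float(alpha), sim_t * float(alpha), params.seed)
    return rec, log


def run_escape_ensemble(
    potential: PotentialSpec,
    params: LangevinParams,
    start: float,
    escape_threshold: float,
    width: float,
    n_runs: int = 15,
    **kwargs,
):
    """Seeded ensemble of escape runs; censored runs are excluded from the
    returned records but counted.  Returns (records, logs, n_censored)."""
    seeds = spawn_seeds(params.seed, n_runs)
    records, logs, censored = [], [], 0
    for s in seeds:
        run_params = LangevinParams(params.dt, params.kT, params.friction,
                                    params.n_steps, int(s), params.stride)
        try:
            rec, log = run_infrequent_metadyn(
                potential, run_params, start, escape_threshold, width, **kwargs
            )
            records.append(rec)
            logs.append(log)
        except CensoredRunError:
            censored += 1
    return records, logs, censored


@dataclass
class RateFit:
    """Poisson/KS reliability analysis of an escape-time ensemble."""

    n_events: int
    mean_time: float   # ns (MLE = sample mean)
    rate: float        # 1/s
    ks_statistic: float
    p_value: float

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self):
        return asdict(self)


def fit_poisson_ks(times_ns) -> RateFit:
    """Fit escape times to the exponential (Poisson) law and test the fit.

    Mean by maximum likelihood (sample mean); KS statistic between the
    empirical CDF and 1 - exp(-t/mean); p-value from the asymptotic
    Kolmogorov distribution.  Estimating the mean from the same sample
    inflates the p-value somewhat; the test is used as a consistency check,
    as is conventional for metadynamics rate recovery.
    """
    t = np.asarray([x.rescaled_time if isinstance(x, EscapeRecord) else x
                    for x in np.atleast_1d(times_ns)], float)
    if t.size < 5:
        raise ValueError("at least 5 escape events required")
    if np.any(t <= 0):
        raise ValueError("escape times must be positive")
    mean = float(t.mean())
    ks = stats.kstest(t, "expon", args=(0.0, mean), method="asymp")
    return RateFit(int(t.size), mean, NS_PER_S / mean,
                   float(ks.statistic), float(ks.pvalue))


def write_hills(path, log: HillsLog) -> None:
    """HILLS-style CSV: time_ns, center, sigma, height_kj_mol, bias_factor."""
    import pandas as pd

    pd.DataFrame({
        "time_ns": log.times, "center": log.centers,
        "sigma": np.full(len(log.times), log.sigma),
        "height_kj_mol": log.heights,
        "bias_factor": np.full(len(log.times), log.bias_factor),
    }).to_csv(path, index=False)
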