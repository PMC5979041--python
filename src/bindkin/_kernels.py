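"""Numba-compiled inner loops for Langevin dynamics, biased sampling and
discrete-chain Monte Carlo.

All kernels take the potential as an integer form code plus a flat parameter
vector so they stay nopython-compilable:

* code 0 — harmonic:            p = [k, x0]
* code 1 — double well:         p = [h, a]           U = h ((x/a)^2 - 1)^2
* code 2 — 2D binding landscape p = [conf, L, (A, bx, by, w) x n_basins]

Energies kcal/mol, lengths nm, times ns. The overdamped update is
x <- x - (dt/gamma) dU/dx + sqrt(2 kT dt / gamma) xi.
"""

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _ene1(code, p, x):
    if code == 0:
        return 0.5 * p[0] * (x - p[1]) ** 2
    # double well
    u = (x / p[1]) ** 2 - 1.0
    return p[0] * u * u


@njit(cache=True, inline="always")
def _grad1(code, p, x):
    if code == 0:
        return p[0] * (x - p[1])
    u = (x / p[1]) ** 2 - 1.0
    return 4.0 * p[0] * u * x / (p[1] * p[1])


@njit(cache=True, inline="always")
def _ene2(p, x, y):
    r2 = x * x + y * y
    l2 = p[1] * p[1]
    e = p[0] * (r2 / l2) ** 2
    nb = (p.shape[0] - 2) // 4
    for b in range(nb):
        A = p[2 + 4 * b]
        dx = x - p[3 + 4 * b]
        dy = y - p[4 + 4 * b]
        w2 = p[5 + 4 * b] ** 2
        e -= A * np.exp(-(dx * dx + dy * dy) / (2.0 * w2))
    return e


@njit(cache=True, inline="always")
def _grad2(p, x, y):
    r2 = x * x + y * y
    l2 = p[1] * p[1]
    common = 4.0 * p[0] * r2 / (l2 * l2)
    gx = common * x
    gy = common * y
    nb = (p.shape[0] - 2) // 4
    for b in range(nb):
        A = p[2 + 4 * b]
        dx = x - p[3 + 4 * b]
        dy = y - p[4 + 4 * b]
        w2 = p[5 + 4 * b] ** 2
        e = A * np.exp(-(dx * dx + dy * dy) / (2.0 * w2))
        gx += e * dx / w2
        gy += e * dy / w2
    return gx, gy


@njit(cache=True)
def _simulate_1d(code, p, x0, n_steps, stride, dt, kT, gamma, seed):
    """Overdamped Langevin in 1D; returns (positions at every stride, error step).

    error step is -1 on success, else the first step with a non-finite state.
    """
    np.random.seed(seed)
    n_out = n_steps // stride + 1
    out = np.empty(n_out, dtype=np.float64)
    out[0] = x0
    x = x0
    mob = dt / gamma
    noise = np.sqrt(2.0 * kT * dt / gamma)
    j = 1
    for step in range(1, n_steps + 1):
        g = _grad1(code, p, x)
        if not np.isfinite(g):
            return out[:j], step
        x = x - mob * g + noise * np.random.normal()
        if not np.isfinite(x):
            return out[:j], step
        if step % stride == 0:
            out[j] = x
            j += 1
    return out, -1


@njit(cache=True)
def _simulate_2d(p, x0, y0, n_steps, stride, dt, kT, gamma, seed):
    np.random.seed(seed)
    n_out = n_steps // stride + 1
    out = np.empty((n_out, 2), dtype=np.float64)
    out[0, 0] = x0
    out[0, 1] = y0
    x, y = x0, y0
    mob = dt / gamma
    noise = np.sqrt(2.0 * kT * dt / gamma)
    j = 1
    for step in range(1, n_steps + 1):
        gx, gy = _grad2(p, x, y)
        if not (np.isfinite(gx) and np.isfinite(gy)):
            return out[:j], step
        x = x - mob * gx + noise * np.random.normal()
        y = y - mob * gy + noise * np.random.normal()
        if not (np.isfinite(x) and np.isfinite(y)):
            return out[:j], step
        if step % stride == 0:
            out[j, 0] = x
            out[j, 1] = y
            j += 1
    return out, -1


@njit(cache=True)
def _umbrella_1d(code, p, center, k_spring, x0, n_steps, stride, dt, kT, gamma, seed):
    """Langevin under U(x) + 0.5 k (x - c)^2; returns sampled CV values."""
    np.random.seed(seed)
    n_out = n_steps // stride
    out = np.empty(n_out, dtype=np.float64)
    x = x0
    mob = dt / gamma
    noise = np.sqrt(2.0 * kT * dt / gamma)
    j = 0
    for step in range(1, n_steps + 1):
        g = _grad1(code, p, x) + k_spring * (x - center)
        x = x - mob * g + noise * np.random.normal()
        if step % stride == 0:
            out[j] = x
            j += 1
    return out


@njit(cache=True)
def _first_passage_1d(code, p, x0, threshold, dt, kT, gamma, seed, max_steps):
    """Steps until |CV| first exceeds threshold; -1 if censored."""
    np.random.seed(seed)
    x = x0
    mob = dt / gamma
    noise = np.sqrt(2.0 * kT * dt / gamma)
    for step in range(1, max_steps + 1):
        g = _grad1(code, p, x)
        x = x - mob * g + noise * np.random.normal()
        if x > threshold:
            return step
    return -1


@njit(cache=True)
def _metadyn_1d(
    code,
    p,
    x0,
    escape_threshold,
    dt,
    kT,
    gamma,
    seed,
    pace_steps,
    height0,
    sigma,
    bias_factor,
    grid_lo,
    grid_hi,
    n_grid,
    max_steps,
):
    """Infrequent well-tempered metadynamics on the 1D CV s = x.

    The bias and its spatial derivative are accumulated on a grid (analytic
    Gaussian derivatives, linear interpolation between nodes). The
    acceleration factor is the running time average of exp(V(s_t, t)/kT),
    with V evaluated *before* any hill deposited at that step.

    Returns (escape_step, alpha, hill_times, hill_centers, hill_heights, n_hills).
    escape_step is -1 for a censored run.
    """
    np.random.seed(seed)
    vgrid = np.zeros(n_grid, dtype=np.float64)
    dgrid = np.zeros(n_grid, dtype=np.float64)
    s_nodes = np.linspace(grid_lo, grid_hi, n_grid)
    dx_grid = (grid_hi - grid_lo) / (n_grid - 1)
    max_hills = max_steps // pace_steps + 1
    hill_t = np.empty(max_hills, dtype=np.float64)
    hill_c = np.empty(max_hills, dtype=np.float64)
    hill_h = np.empty(max_hills, dtype=np.float64)
    n_hills = 0

    x = x0
    mob = dt / gamma
    noise = np.sqrt(2.0 * kT * dt / gamma)
    sum_exp = 0.0

    for step in range(1, max_steps + 1):
        # interpolate bias and derivative at current position
        u = (x - grid_lo) / dx_grid
        i = int(np.floor(u))
        if i < 0:
            i = 0
        if i > n_grid - 2:
            i = n_grid - 2
        frac = u - i
        if frac < 0.0:
            frac = 0.0
        if frac > 1.0:
            frac = 1.0
        v_here = vgrid[i] * (1.0 - frac) + vgrid[i + 1] * frac
        dv_here = dgrid[i] * (1.0 - frac) + dgrid[i + 1] * frac

        sum_exp += np.exp(v_here / kT)

        if step % pace_steps == 0:
            h = height0 * np.exp(-v_here / ((bias_factor - 1.0) * kT))
            hill_t[n_hills] = step * dt
            hill_c[n_hills] = x
            hill_h[n_hills] = h
            n_hills += 1
            inv2s2 = 1.0 / (2.0 * sigma * sigma)
            for jg in range(n_grid):
                d = s_nodes[jg] - x
                e = h * np.exp(-d * d * inv2s2)
                vgrid[jg] += e
                dgrid[jg] += -d / (sigma * sigma) * e
            # re-read bias after deposition for the force
            v0 = vgrid[i] * (1.0 - frac) + vgrid[i + 1] * frac
            dv_here = dgrid[i] * (1.0 - frac) + dgrid[i + 1] * frac
            v_here = v0

        g = _grad1(code, p, x) + dv_here
        x = x - mob * g + noise * np.random.normal()
        if x > escape_threshold:
            alpha = sum_exp / step
            return step, alpha, hill_t[:n_hills], hill_c[:n_hills], hill_h[:n_hills], n_hills
    alpha = sum_exp / max_steps
    return -1, alpha, hill_t[:n_hills], hill_c[:n_hills], hill_h[:n_hills], n_hills


@njit(cache=True)
def _sample_chain(cum_rows, s0, n_steps, seed):
    """Sample a discrete Markov chain from row-wise cumulative probabilities."""
    np.random.seed(seed)
    out = np.empty(n_steps + 1, dtype=np.int64)
    out[0] = s0
    s = s0
    n = cum_rows.shape[1]
    for t in range(1, n_steps + 1):
        r = np.random.random()
        row = cum_rows[s]
        nxt = n - 1
        for j in range(n):
            if r < row[j]:
                nxt = j
                break
        s = nxt
        out[t] = s
    return out


@njit(cache=True)
def _first_hit_probs(cum_rows, in_a, in_b, n_chains, seed, max_steps):
    """Per-state probability of hitting B before A (Monte Carlo committor)."""
    np.random.seed(seed)
    n = cum_rows.shape[0]
    hits = np.zeros(n, dtype=np.float64)
    for s0 in range(n):
        if in_a[s0]:
            continue
        if in_b[s0]:
            hits[s0] = 1.0
            continue
        nb = 0
        for _ in range(n_chains):
            s = s0
            for _t in range(max_steps):
                r = np.random.random()
                row = cum_rows[s]
                nxt = n - 1
                for j in range(n):
                    if r < row[j]:
                        nxt = j
                        break
                s = nxt
                if in_b[s]:
                    nb += 1
                    break
                if in_a[s]:
                    break
        hits[s0] = nb / n_chains
    return hits


@njit(cache=True)
def _count_reactive_transitions(states, in_a, in_b):
    """Count A->B reactive events in a state sequence (last-in-A to first-in-B)."""
    n_events = 0
    came_from_a = False
    for t in range(states.shape[0]):
        s = states[t]
        if in_a[s]:
            came_from_a = True
        elif in_b[s]:
            if came_from_a:
                n_events += 1
            came_from_a = False
    return n_events
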