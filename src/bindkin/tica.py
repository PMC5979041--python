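"""Time-lagged independent component analysis (tICA).

Linear projection maximizing autocorrelation at a lag: solve the generalized
eigenproblem C_tau v = lambda C_0 v with symmetrized covariance estimates, so
the spectrum is real and bounded by 1.  Components are ordered by eigenvalue
(slowness); each component's kinetic variance fraction is
lambda_i^2 / sum_j lambda_j^2.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, TransformerMixin

from .io import FeatureTrajectory


def _as_arrays(trajectories, frame_interval):
    """Normalize input to (list of 2D arrays, frame_interval)."""
    if isinstance(trajectories, (np.ndarray, FeatureTrajectory)):
        trajectories = [trajectories]
    arrays, dt = [], frame_interval
    for tr in trajectories:
        if isinstance(tr, FeatureTrajectory):
            if dt is None:
                dt = tr.frame_interval
            elif abs(dt - tr.frame_interval) > 1e-12:
                raise ValueError("trajectories disagree on frame_interval")
            arrays.append(tr.values)
        else:
            arrays.append(np.atleast_2d(np.asarray(tr, float)))
    if dt is None:
        raise ValueError("frame_interval required when passing bare arrays")
    return arrays, dt


class TICA(BaseEstimator, TransformerMixin):
    """tICA transformer.

    Parameters
    ----------
    lag_time : float
        Correlation lag in ns (must be a positive multiple of the frame
        interval; default 20 ns as in the binding study).
    n_components : int, optional
        Fixed number of components kept by :meth:`transform`.
    kinetic_variance : float, optional
        Alternative selection rule: keep the smallest number of components
        whose cumulative kinetic variance fraction reaches this threshold.
    regularization : float
        Scale of the ridge added to C0's diagonal, as a fraction of
        trace(C0)/dim (binary contact features are rank deficient).
    """

    def __init__(self, lag_time=20.0, n_components=None, kinetic_variance=None,
                 regularization=1e-10):
        self.lag_time = lag_time
        self.n_components = n_components
        self.kinetic_variance = kinetic_variance
        self.regularization = regularization

    def fit(self, X, y=None, frame_interval=None):
        if self.lag_time <= 0:
            raise ValueError("lag_time must be positive")
        arrays, dt = _as_arrays(X, frame_interval)
        lag = int(round(self.lag_time / dt))
        if lag < 1 or abs(lag * dt - self.lag_time) > 1e-9 * max(1.0, self.lag_time):
            raise ValueError("lag_time must be a positive multiple of the frame interval")
        usable = []
        for i, a in enumerate(arrays):
            if a.shape[0] <= lag:
                warnings.warn(f"trajectory {i} shorter than the lag; skipped", stacklevel=2)
            else:
                usable.append(a)
        if not usable:
            raise ValueError("no trajectory longer than the lag time")
        dim = usable[0].shape[1]
        mean = np.zeros(dim)
        n = 0
        for a in usable:
            mean += a.sum(axis=0)
            n += a.shape[0]
        mean /= n

        c0 = np.zeros((dim, dim))
        ct = np.zeros((dim, dim))
        pairs = 0
        for a in usable:
            x0 = a[:-lag] - mean
            xt = a[lag:] - mean
            c0 += x0.T @ x0 + xt.T @ xt
            ct += x0.T @ xt
            pairs += x0.shape[0]
        c0 /= 2.0 * pairs
        ct = (ct + ct.T) / (2.0 * pairs)
        if not (np.all(np.isfinite(c0)) and np.all(np.isfinite(ct))):
            raise ValueError("non-finite covariance estimate")
        eps = self.regularization * np.trace(c0) / dim
        c0_reg = c0 + eps * np.eye(dim)

        evals, evecs = eigh(ct, c0_reg)
        order = np.argsort(evals)[::-1]
        self.eigenvalues_ = evals[order]
        self.eigenvectors_ = evecs[:, order]
        self.mean_ = mean
        self.lag_frames_ = lag
        self.frame_interval_ = dt
        total = np.sum(self.eigenvalues_**2)
        self.kinetic_variance_fractions_ = (
            self.eigenvalues_**2 / total if total > 0 else np.full(dim, 1.0 / dim)
        )
        return self

    def _select_n(self, n_components=None, kinetic_variance=None):
        n = n_components if n_components is not None else self.n_components
        thresh = kinetic_variance if kinetic_variance is not None else self.kinetic_variance
        dim = len(self.eigenvalues_)
        if n is not None:
            if n > dim:
                raise ValueError(f"{n} components requested, {dim} available")
            return int(n)
        if thresh is not None:
            if thresh > 1:
                raise ValueError("kinetic variance threshold cannot exceed 1")
            cum = np.cumsum(self.kinetic_variance_fractions_)
            return int(np.searchsorted(cum, thresh - 1e-12) + 1)
        return dim

    def transform(self, X, n_components=None, kinetic_variance=None):
        n = self._select_n(n_components, kinetic_variance)
        single = isinstance(X, (np.ndarray, FeatureTrajectory))
        arrays, _ = _as_arrays(X, getattr(self, "frame_interval_", 1.0))
        out = [(a - self.mean_) @ self.eigenvectors_[:, :n] for a in arrays]
        return out[0] if single else out

    def timescales(self) -> np.ndarray:
        """Implied timescales -lag/ln(lambda) in ns (NaN for lambda <= 0)."""
        lam = self.eigenvalues_
        with np.errstate(divide="ignore", invalid="ignore"):
            ts = np.where(lam > 0, -self.lag_time / np.log(lam), np.nan)
        return ts


def estimate_tica(features, lag: float = 20.0, frame_interval=None, **kwargs) -> TICA:
    """Fit a :class:`TICA` model on a trajectory or a set of trajectories."""
    model = TICA(lag_time=lag, **kwargs)
    return model.fit(features, frame_interval=frame_interval)


def project_tica(model: TICA, features, n_components=None, kinetic_variance=None):
    """Project features on leading components (fixed n or cumulative kinetic
    variance threshold rule)."""
    return model.transform(features, n_components=n_components,
                           kinetic_variance=kinetic_variance)
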