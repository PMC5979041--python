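"""Analytic model potentials used by the synthetic simulators.

Three forms are supported:

``harmonic``
    U(x) = 1/2 k (x - x0)^2.  Params: ``k`` (kcal/mol/nm^2), ``x0`` (nm).
``double_well``
    U(x) = h ((x/a)^2 - 1)^2 — minima at +-a, barrier h at x = 0.
    Params: ``barrier`` (kcal/mol), ``half_width`` (nm).
``binding_landscape_2d``
    A bounded 2D landscape emulating a ligand-binding topology: a quartic
    confinement plus Gaussian basins (one deep "cavity" at the origin, two
    shallow "gateway" intermediates, one broad "bulk" basin).  Params:
    ``confinement`` (kcal/mol), ``box`` (nm) and a ``basins`` list of
    (depth kcal/mol, x nm, y nm, width nm) tuples.

The default 2D parameter values are artifact choices recorded here in code;
they produce four metastable basins with the cavity deepest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels

_FORM_CODES = {"harmonic": 0, "double_well": 1, "binding_landscape_2d": 2}

#: Default basin layout of the 2D binding landscape:
#: (depth kcal/mol, x nm, y nm, width nm) — cavity, gateway A, gateway B, bulk.
DEFAULT_BASINS = (
    (8.0, 0.0, 0.0, 0.15),
    (2.5, 0.55, 0.35, 0.12),
    (2.5, 0.55, -0.35, 0.12),
    (4.0, 1.2, 0.0, 0.35),
)


@dataclass(frozen=True)
class PotentialSpec:
    """An analytic potential identified by form name + named parameters."""

    form: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.form not in _FORM_CODES:
            raise ValueError(
                f"unknown potential form {self.form!r}; choose from {sorted(_FORM_CODES)}"
            )
        if not np.all(np.isfinite(self.flat_params())):
            raise ValueError("potential parameters must be finite")

    @property
    def code(self) -> int:
        return _FORM_CODES[self.form]

    @property
    def dim(self) -> int:
        return 2 if self.form == "binding_landscape_2d" else 1

    def flat_params(self) -> np.ndarray:
        """Flat parameter vector for the compiled kernels."""
        p = self.params
        if self.form == "harmonic":
            return np.array([p.get("k", 10.0), p.get("x0", 0.0)], float)
        if self.form == "double_well":
            return np.array([p.get("barrier", 3.0), p.get("half_width", 1.0)], float)
        basins = p.get("basins", DEFAULT_BASINS)
        flat = [p.get("confinement", 3.0), p.get("box", 1.6)]
        for depth, bx, by, w in basins:
            flat.extend([depth, bx, by, w])
        return np.array(flat, float)

    def energy(self, x) -> np.ndarray:
        """Potential energy, kcal/mol. x is scalar/array (1D) or (..., 2) (2D)."""
        p = self.flat_params()
        x = np.asarray(x, float)
        if self.dim == 1:
            return np.vectorize(lambda v: _kernels._ene1(self.code, p, v))(x)
        pts = x.reshape(-1, 2)
        out = np.array([_kernels._ene2(p, a, b) for a, b in pts])
        return out.reshape(x.shape[:-1])

    def gradient(self, x) -> np.ndarray:
        """dU/dx, kcal/mol/nm, same shape convention as :meth:`energy`."""
        p = self.flat_params()
        x = np.asarray(x, float)
        if self.dim == 1:
            return np.vectorize(lambda v: _kernels._grad1(self.code, p, v))(x)
        pts = x.reshape(-1, 2)
        out = np.array([_kernels._grad2(p, a, b) for a, b in pts])
        return out.reshape(x.shape)


def binding_landscape_2d(**overrides) -> PotentialSpec:
    """The default 4-basin 2D binding landscape (bulk, 2 gateways, cavity)."""
    params = {"confinement": 3.0, "box": 1.6, "basins": DEFAULT_BASINS}
    params.update(overrides)
    return PotentialSpec("binding_landscape_2d", params)
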