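"""Structure and trajectory I/O.

Structures are read from a strict fixed-column PDB dialect: ATOM/HETATM
records only, altLoc blank or 'A', first MODEL only, coordinates converted
Angstrom -> nm.  Trajectories and feature tables travel as delimited text
(header row, first column ``time_ns``); ``.npz`` serves as the binary
container for large runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError

#: Atomic masses (u) for centroid weighting.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845,
}


@dataclass
class StructureModel:
    """Parsed structure: parallel per-atom arrays, coordinates in nm."""

    serial: np.ndarray
    name: np.ndarray
    element: np.ndarray
    res_name: np.ndarray
    res_seq: np.ndarray
    chain: np.ndarray
    xyz: np.ndarray  # (n_atoms, 3) nm
    is_het: np.ndarray  # True for HETATM records
    provenance: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    @property
    def heavy(self) -> np.ndarray:
        return self.element != "H"

    def protein_heavy_indices(self) -> np.ndarray:
        return np.where(~self.is_het & self.heavy)[0]

    def ligand_heavy_indices(self, res_name: str | None = None) -> np.ndarray:
        mask = self.is_het & self.heavy & (self.res_name != "HOH")
        if res_name is not None:
            mask &= self.res_name == res_name
        return np.where(mask)[0]

    def masses(self) -> np.ndarray:
        out = np.empty(self.n_atoms)
        for i, el in enumerate(self.element):
            try:
                out[i] = ATOMIC_MASSES[el]
            except KeyError:
                raise KeyError(f"unknown element symbol {el!r} for atom {self.serial[i]}")
        return out


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    # two-letter elements keep their column-13 character (e.g. 'FE', 'CL')
    letters = "".join(c for c in stripped if c.isalpha())
    if len(atom_name) >= 2 and atom_name[0].isalpha() and letters[:2].upper() in ATOMIC_MASSES:
        return letters[:2].upper()
    return letters[:1].upper()


def read_structure(text: str, provenance: str = "") -> StructureModel:
    """Parse fixed-column PDB text (see module docstring for the dialect)."""
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "ENDMDL":
            break  # first model only
        if rec not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise ParseError(f"line {lineno}: record too short for fixed-column coordinates")
        alt = line[16]
        if alt not in (" ", "A"):
            continue
        try:
            serial = int(line[6:11])
            res_seq = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: malformed fixed columns ({exc})") from exc
        if not all(np.isfinite([x, y, z])):
            raise ParseError(f"line {lineno}: non-finite coordinates")
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
        if not element:
            element = _infer_element(line[12:16])
        rows.append(
            (serial, line[12:16].strip(), element, line[17:20].strip(),
             res_seq, line[21].strip(), x, y, z, rec == "HETATM")
        )
    if not rows:
        raise ParseError("zero atoms parsed from structure input")
    serial, name, element, res_name, res_seq, chain, x, y, z, het = zip(*rows)
    xyz = np.column_stack([x, y, z]) * 0.1  # Angstrom -> nm
    return StructureModel(
        serial=np.array(serial), name=np.array(name, dtype="U6"),
        element=np.array(element, dtype="U4"),
        res_name=np.array(res_name, dtype="U6"), res_seq=np.array(res_seq),
        chain=np.array(chain, dtype="U2"),
        xyz=xyz, is_het=np.array(het), provenance=provenance,
    )


def read_structure_file(path) -> StructureModel:
    path = Path(path)
    return read_structure(path.read_text(), provenance=str(path))


@dataclass
class CoordinateTrajectory:
    """Time-ordered atom positions: (n_frames, n_atoms, 3) in nm."""

    frames: np.ndarray
    frame_interval: float  # ns
    structure: StructureModel | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class FeatureTrajectory:
    """A frames x features matrix with column labels and a frame interval."""

    values: np.ndarray
    labels: list = field(default_factory=list)
    frame_interval: float = 1.0

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if not self.labels:
            self.labels = [f"f{i}" for i in range(self.values.shape[1])]
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("label count must equal feature column count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[0]) * self.frame_interval


def write_features(path, ftraj: FeatureTrajectory) -> None:
    df = pd.DataFrame(ftraj.values, columns=ftraj.labels)
    df.insert(0, "time_ns", ftraj.times)
    df.to_csv(path, index=False)


def read_features(path) -> FeatureTrajectory:
    df = pd.read_csv(path)
    if "time_ns" not in df.columns:
        raise ParseError("feature table must have a 'time_ns' first column")
    t = df.pop("time_ns").to_numpy()
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    return FeatureTrajectory(df.to_numpy(float), list(df.columns), dt)


def write_dtraj(path, dtraj) -> None:
    t = np.arange(len(dtraj.states)) * dtraj.frame_interval
    pd.DataFrame({"time_ns": t, "state": dtraj.states}).to_csv(path, index=False)


def read_dtraj(path):
    from .synthetic import DiscreteTrajectory

    df = pd.read_csv(path)
    t = df["time_ns"].to_numpy()
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    return DiscreteTrajectory(df["state"].to_numpy(np.int64), dt)


def write_labels(path, times_ns, bound) -> None:
    pd.DataFrame({"time_ns": times_ns, "bound": np.asarray(bound, int)}).to_csv(
        path, index=False
    )


def save_array_bundle(path, **arrays) -> None:
    """Binary container for large runs (NumPy .npz)."""
    np.savez_compressed(path, **arrays)


def load_array_bundle(path) -> dict:
    with np.load(path, allow_pickle=False) as data:
        return {k: data[k] for k in data.files}
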