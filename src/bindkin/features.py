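"""Geometric featurization of binding trajectories.

Implements the pocket definition (protein heavy atoms within a cutoff of the
ligand in the holo structure), binary ligand-residue contact features,
pocket-ligand center-of-mass distances, superposition RMSD, the dual
RMSD/distance bound-state criterion with a minimum dwell, and extraction of
transition-path segments from an order-parameter series.

All thresholds are inclusive (<=).  Distances are nm, times ns.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .io import CoordinateTrajectory, FeatureTrajectory, StructureModel


def define_pocket(
    holo: StructureModel, ligand_selection, cutoff: float = 0.5
) -> np.ndarray:
    """Protein heavy atoms within ``cutoff`` nm of any ligand heavy atom.

    Returns sorted atom indices into ``holo``; warns (does not raise) when the
    selection comes out empty.
    """
    ligand = np.asarray(ligand_selection, int)
    if ligand.size == 0:
        raise ValueError("ligand selection must be non-empty")
    protein = holo.protein_heavy_indices()
    protein = protein[~np.isin(protein, ligand)]
    if protein.size == 0:
        raise ValueError("structure has no protein heavy atoms")
    d = cdist(holo.xyz[protein], holo.xyz[ligand]).min(axis=1)
    pocket = protein[d <= cutoff]
    if pocket.size == 0:
        warnings.warn("binding pocket is empty at this cutoff", stacklevel=2)
    return pocket


def contact_features(
    traj: CoordinateTrajectory,
    ligand_atoms,
    residue_groups: dict,
    cutoff: float = 0.5,
) -> FeatureTrajectory:
    """Binary per-residue contact features.

    ``residue_groups`` maps a residue label to the protein heavy-atom indices
    of that residue.  A frame's feature is 1 when the minimum ligand-residue
    heavy-atom distance is <= ``cutoff`` nm.
    """
    ligand = np.asarray(ligand_atoms, int)
    if ligand.size == 0:
        raise ValueError("ligand selection must be non-empty")
    labels = list(residue_groups)
    for label in labels:
        if len(residue_groups[label]) == 0:
            raise ValueError(f"residue group {label!r} is empty")
    out = np.zeros((traj.n_frames, len(labels)))
    for f in range(traj.n_frames):
        lig_xyz = traj.frames[f, ligand]
        for j, label in enumerate(labels):
            grp = np.asarray(residue_groups[label], int)
            dmin = cdist(traj.frames[f, grp], lig_xyz).min()
            out[f, j] = 1.0 if dmin <= cutoff else 0.0
    return FeatureTrajectory(out, [str(x) for x in labels], traj.frame_interval)


def _com(xyz: np.ndarray, masses: np.ndarray) -> np.ndarray:
    return (xyz * masses[:, None]).sum(axis=0) / masses.sum()


def pocket_ligand_distance(
    traj: CoordinateTrajectory, pocket_atoms, ligand_atoms, masses=None
) -> np.ndarray:
    """Per-frame distance (nm) between mass-weighted centroids of the pocket
    and the ligand.  Masses come from the trajectory's structure metadata
    unless given explicitly."""
    pocket = np.asarray(pocket_atoms, int)
    ligand = np.asarray(ligand_atoms, int)
    if pocket.size == 0 or ligand.size == 0:
        raise ValueError("pocket and ligand selections must be non-empty")
    if masses is None:
        if traj.structure is None:
            raise ValueError("masses required when the trajectory has no structure metadata")
        masses = traj.structure.masses()
    masses = np.asarray(masses, float)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        cp = _com(traj.frames[f, pocket], masses[pocket])
        cl = _com(traj.frames[f, ligand], masses[ligand])
        out[f] = np.linalg.norm(cp - cl)
    return out


def superpose_rmsd(
    traj: CoordinateTrajectory, reference: StructureModel, selection
) -> np.ndarray:
    """Optimal-superposition RMSD series (nm) over ``selection``.

    Each frame is least-squares superposed on the reference (proper rotation,
    Kabsch via SVD) before the deviation is computed.
    """
    sel = np.asarray(selection, int)
    if sel.size < 3:
        raise ValueError("selection needs at least 3 atoms for superposition")
    ref = reference.xyz[sel]
    ref_c = ref - ref.mean(axis=0)
    s = np.linalg.svd(ref_c, compute_uv=False)
    if s[1] < 1e-10:
        raise ValueError("selection is collinear; superposition is degenerate")
    out = np.empty(traj.n_frames)
    n = sel.size
    for f in range(traj.n_frames):
        mob = traj.frames[f, sel]
        mob_c = mob - mob.mean(axis=0)
        _, rssd = Rotation.align_vectors(ref_c, mob_c)
        out[f] = rssd / math.sqrt(n)
    return out


def bound_state_labels(
    rmsd_series,
    distance_series,
    frame_interval: float,
    rmsd_max: float = 0.5,
    dist_max: float = 0.2,
    dwell_min: float = 100.0,
):
    """Dual-criterion bound-state labelling with a minimum dwell.

    A frame is *bound* iff it begins a window of at least ``dwell_min`` ns
    during which RMSD <= ``rmsd_max`` and the pocket-ligand distance <=
    ``dist_max`` hold continuously (a window of w frames spans w *
    ``frame_interval``).  Returns ``(labels, first_binding_time_ns)`` with
    ``first_binding_time_ns`` None when no frame qualifies.
    """
    rmsd = np.asarray(rmsd_series, float)
    dist = np.asarray(distance_series, float)
    if rmsd.shape != dist.shape:
        raise ValueError("RMSD and distance series must share the frame grid")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    ok = (rmsd <= rmsd_max) & (dist <= dist_max)
    w = max(1, math.ceil(dwell_min / frame_interval - 1e-9))
    n = len(ok)
    # run_ahead[i] = number of consecutive qualifying frames starting at i
    run_ahead = np.zeros(n, dtype=int)
    run = 0
    for i in range(n - 1, -1, -1):
        run = run + 1 if ok[i] else 0
        run_ahead[i] = run
    labels = run_ahead >= w
    idx = np.flatnonzero(labels)
    first = float(idx[0] * frame_interval) if idx.size else None
    return labels, first


def transition_path_segments(
    series,
    frame_interval: float,
    bound_below: float = 0.38,
    unbound_above: float = 0.6,
    direction: str = "binding",
) -> list:
    """Transition-path durations (ns) from an order-parameter series.

    For ``direction="binding"`` a segment runs from the frame after the last
    visit to the unbound region (series >= ``unbound_above``) to the first
    subsequent frame in the bound region (series <= ``bound_below``); a
    re-entry to the origin region resets the segment, and excursions within
    the intermediate region are absorbed.  ``direction="unbinding"`` swaps
    the roles of the two regions.
    """
    if bound_below >= unbound_above:
        raise ValueError("require bound_below < unbound_above")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    x = np.asarray(series, float)
    if direction == "binding":
        in_origin = x >= unbound_above
        in_dest = x <= bound_below
    elif direction == "unbinding":
        in_origin = x <= bound_below
        in_dest = x >= unbound_above
    else:
        raise ValueError("direction must be 'binding' or 'unbinding'")
    durations = []
    last_origin = None
    for i in range(len(x)):
        if in_origin[i]:
            last_origin = i
        elif in_dest[i] and last_origin is not None:
            durations.append((i - last_origin - 1) * frame_interval)
            last_origin = None
    return durations
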