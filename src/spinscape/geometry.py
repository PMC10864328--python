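"""Micelle and aggregate geometry.

Per-frame micelle membership by an any-atom distance cut-off, the
mass-weighted radius of gyration used as the micelle radius proxy,
Stokes-Einstein rotational timescales for a rigid sphere (with both the
D_r = 1/(6 pi tau) convention used throughout this package and the
textbook tau = 1/(6 D_r) convention), principal-axis angles between two
peptides, and removal of overall rotation by least-squares superposition.

Coordinates are plain numpy arrays in nm; orthorhombic periodic boxes
are supported for the distance computations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FrameCoordinates",
    "MicelleComposition",
    "micelle_members",
    "radius_of_gyration",
    "stokes_einstein_timescale",
    "invert_radius",
    "invert_viscosity",
    "principal_axis_angle",
    "remove_rotation",
    "KB",
]

KB = 1.380649e-23  # J/K


@dataclass
class FrameCoordinates:
    """One frame of coordinates grouped into molecules.

    positions in nm, shape (n_atoms, 3); ``molecule_ids`` assigns every
    atom to a molecule (any hashable id); ``box`` is orthorhombic edge
    lengths in nm or None for a non-periodic frame.
    """

    positions: np.ndarray
    molecule_ids: np.ndarray
    masses: np.ndarray | None = None
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.molecule_ids = np.asarray(self.molecule_ids)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.molecule_ids.shape != (self.positions.shape[0],):
            raise ValueError("one molecule id per atom required")
        if self.masses is None:
            self.masses = np.ones(self.positions.shape[0])
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (self.positions.shape[0],):
                raise ValueError("one mass per atom required")
            if np.any(self.masses <= 0):
                raise ValueError("masses must be positive")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be 3 positive orthorhombic edge lengths")

    def atoms_of(self, ids) -> np.ndarray:
        """Boolean mask of atoms belonging to any of the given molecule ids."""
        return np.isin(self.molecule_ids, list(ids))


@dataclass
class MicelleComposition:
    """Per-frame micelle membership and radius of gyration."""

    members: list[set]          # per frame
    rg_nm: np.ndarray           # per frame
    cutoff_nm: float

    @property
    def mean_n_members(self) -> float:
        return float(np.mean([len(m) for m in self.members]))

    @property
    def mean_rg_nm(self) -> float:
        return float(np.mean(self.rg_nm))


def _min_image_delta(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    delta = a[:, None, :] - b[None, :, :]
    if box is not None:
        delta -= box * np.round(delta / box)
    return delta


def micelle_members(frame: FrameCoordinates, peptide_ids, candidate_ids,
                    cutoff_nm: float = 1.8) -> set:
    """Molecules with any atom within ``cutoff_nm`` of any peptide atom.

    The 1.8 nm default is a practical choice for SDS micelles; the
    appropriate cut-off is system specific (typically 1.4-1.8 nm) and
    should be checked against the resulting membership time series.
    """
    if cutoff_nm <= 0:
        raise ValueError("cutoff_nm must be positive")
    pep_mask = frame.atoms_of(peptide_ids)
    if not np.any(pep_mask):
        raise ValueError("peptide selection is empty")
    pep_pos = frame.positions[pep_mask]
    members = set()
    for mol in set(candidate_ids):
        mol_pos = frame.positions[frame.molecule_ids == mol]
        if mol_pos.size == 0:
            continue
        d = np.linalg.norm(_min_image_delta(mol_pos, pep_pos, frame.box), axis=2)
        if np.min(d) <= cutoff_nm:
            members.add(mol)
    return members


def radius_of_gyration(frame: FrameCoordinates, ids) -> float:
    """Mass-weighted radius of gyration (nm) of the selected molecules."""
    mask = frame.atoms_of(ids)
    if not np.any(mask):
        raise ValueError("empty selection")
    pos = frame.positions[mask]
    m = frame.masses[mask]
    com = np.average(pos, axis=0, weights=m)
    return float(np.sqrt(np.average(np.sum((pos - com) ** 2, axis=1), weights=m)))


def micelle_composition(frames: list[FrameCoordinates], peptide_ids, candidate_ids,
                        cutoff_nm: float = 1.8) -> MicelleComposition:
    """Per-frame membership and Rg of the micelle (members plus peptide)."""
    members = []
    rgs = []
    for frame in frames:
        mem = micelle_members(frame, peptide_ids, candidate_ids, cutoff_nm)
        members.append(mem)
        rgs.append(radius_of_gyration(frame, set(peptide_ids) | mem))
    return MicelleComposition(members, np.asarray(rgs), cutoff_nm)


# ---------------------------------------------------------------------------
# Stokes-Einstein


def _check_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")


def stokes_einstein_timescale(r_nm: float, T_K: float, eta_mPas: float,
                              convention: str = "sixpi") -> float:
    """Rotational timescale (ns) of a rigid sphere of radius r in a fluid.

    The rotational diffusion coefficient is D_r = k_B T / (8 pi eta r^3).
    Two conventions relate it to a timescale:

    * ``"sixpi"`` (default): D_r = 1/(6 pi tau), i.e. tau = 8 eta r^3 / (6 k_B T)
    * ``"standard"``: tau = 1/(6 D_r), the textbook P2 correlation time
      (a factor pi longer).
    """
    _check_positive(r_nm=r_nm, T_K=T_K, eta_mPas=eta_mPas)
    r = r_nm * 1e-9
    eta = eta_mPas * 1e-3
    Dr = KB * T_K / (8.0 * np.pi * eta * r**3)
    if convention == "sixpi":
        tau = 1.0 / (6.0 * np.pi * Dr)
    elif convention == "standard":
        tau = 1.0 / (6.0 * Dr)
    else:
        raise ValueError("convention must be 'sixpi' or 'standard'")
    return tau * 1e9


def invert_radius(tau_ns: float, T_K: float, eta_mPas: float,
                  convention: str = "sixpi") -> float:
    """Sphere radius (nm) reproducing a rotational timescale; inverse of
    :func:`stokes_einstein_timescale` in r."""
    _check_positive(tau_ns=tau_ns, T_K=T_K, eta_mPas=eta_mPas)
    tau = tau_ns * 1e-9
    eta = eta_mPas * 1e-3
    if convention == "sixpi":
        r3 = 6.0 * tau * KB * T_K / (8.0 * eta)
    elif convention == "standard":
        r3 = 6.0 * tau * KB * T_K / (8.0 * np.pi * eta)
    else:
        raise ValueError("convention must be 'sixpi' or 'standard'")
    return r3 ** (1.0 / 3.0) * 1e9


def invert_viscosity(tau_ns: float, T_K: float, r_nm: float,
                     convention: str = "sixpi") -> float:
    """Viscosity (mPa s) reproducing a rotational timescale at fixed radius."""
    _check_positive(tau_ns=tau_ns, T_K=T_K, r_nm=r_nm)
    tau = tau_ns * 1e-9
    r = r_nm * 1e-9
    if convention == "sixpi":
        eta = 6.0 * tau * KB * T_K / (8.0 * r**3)
    elif convention == "standard":
        eta = 6.0 * tau * KB * T_K / (8.0 * np.pi * r**3)
    else:
        raise ValueError("convention must be 'sixpi' or 'standard'")
    return eta * 1e3


# ---------------------------------------------------------------------------
# Principal axes and superposition


def principal_axis_angle(coordsA: np.ndarray, coordsB: np.ndarray,
                         massesA: np.ndarray | None = None,
                         massesB: np.ndarray | None = None) -> float:
    """Angle (degrees, folded into [0, 90]) between dominant principal axes.

    The dominant axis of a selection is the gyration-tensor eigenvector
    with the largest eigenvalue (the long axis of an elongated peptide).
    Selections whose two largest eigenvalues are degenerate (spherical or
    planar-isotropic shapes, or all atoms coincident) have no unique
    dominant axis and raise ValueError.
    """
    def dominant_axis(coords, masses):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 2:
            raise ValueError("need at least 2 atoms with xyz coordinates")
        m = np.ones(coords.shape[0]) if masses is None else np.asarray(masses, float)
        com = np.average(coords, axis=0, weights=m)
        x = coords - com
        gyr = (x * m[:, None]).T @ x / m.sum()
        evals, evecs = np.linalg.eigh(gyr)  # ascending
        if evals[-1] <= 0:
            raise ValueError("degenerate selection: all atoms coincident")
        if (evals[-1] - evals[-2]) / evals[-1] < 1e-6:
            raise ValueError("degenerate selection: dominant principal axis "
                             "is not unique")
        return evecs[:, -1]

    a = dominant_axis(coordsA, massesA)
    b = dominant_axis(coordsB, massesB)
    cosang = np.clip(abs(float(np.dot(a, b))), 0.0, 1.0)  # axis sign folded out
    return float(np.degrees(np.arccos(cosang)))


def remove_rotation(frames: np.ndarray, reference_indices=None,
                    masses: np.ndarray | None = None) -> np.ndarray:
    """Remove overall rotation by least-squares superposition onto frame 0.

    Each frame is superposed (rotation only, about centers of mass of the
    reference selection; proper rotation enforced, never a reflection)
    onto the first frame. Use this to study detergent motion relative to
    a rigid peptide's frame. Only meaningful for reference selections
    that stay internally rigid.

    Parameters
    ----------
    frames:
        Coordinates of shape (n_frames, n_atoms, 3).
    reference_indices:
        Atom indices used for the superposition (default: all atoms).
    masses:
        Optional per-atom weights for the fit.

    Returns the transformed coordinates (same shape).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[2] != 3:
        raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
    ref_idx = np.arange(frames.shape[1]) if reference_indices is None \
        else np.asarray(reference_indices)
    if ref_idx.size < 3:
        raise ValueError("reference selection needs at least 3 atoms")
    w = np.ones(ref_idx.size) if masses is None else np.asarray(masses, float)[ref_idx]

    ref = frames[0, ref_idx]
    com_ref = np.average(ref, axis=0, weights=w)
    ref_c = ref - com_ref
    if np.linalg.matrix_rank(ref_c, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) reference selection")

    out = np.empty_like(frames)
    out[0] = frames[0]
    for f in range(1, frames.shape[0]):
        mob = frames[f, ref_idx]
        com = np.average(mob, axis=0, weights=w)
        # Kabsch with proper-rotation constraint
        H = (ref_c * w[:, None]).T @ (mob - com)
        U, _, Vt = np.linalg.svd(H)
        sign = np.sign(np.linalg.det(U @ Vt))
        R = U @ np.diag([1.0, 1.0, sign]) @ Vt
        out[f] = (frames[f] - com) @ R.T + com_ref
    return out
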