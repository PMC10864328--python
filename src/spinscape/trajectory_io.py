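"""Bond-vector extraction from MD trajectories and plain-text table I/O.

Two self-defined text dialects are used for tool interoperability:

* vector tables — TSV blocks introduced by ``# site <label>`` lines with
  columns ``time_ps  x  y  z`` (unit vectors);
* secondary-structure tables — a residue-label header followed by one
  whitespace-separated row of DSSP one-letter codes per frame.

Both are UTF-8, use ``.`` as the decimal separator and ``#`` for comments.
All times are picoseconds throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VectorTrajectory",
    "SSTrajectory",
    "extract_bond_vectors",
    "read_vector_table",
    "write_vector_table",
    "read_ss_table",
    "write_ss_table",
    "DSSP_ALPHABET",
    "VectorTableError",
    "SSTableError",
    "SelectionError",
]

#: DSSP one-letter secondary-structure codes ("~" for loop/irregular).
DSSP_ALPHABET = frozenset("HGIEBTS~")

_NORM_WARN = 1e-4   # renormalize with warning above this deviation
_NORM_HARD = 0.1    # reject the file above this deviation


class VectorTableError(ValueError):
    """Malformed vector-table file."""


class SSTableError(ValueError):
    """Malformed secondary-structure table file."""


class SelectionError(KeyError):
    """Atom selection did not resolve to the expected atoms."""


def _check_uniform_times(times: np.ndarray, rtol: float = 1e-9) -> float:
    """Return dt, raising if spacing is not uniform to ``rtol`` (relative)."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("need at least two frame times")
    diffs = np.diff(times)
    dt = diffs[0]
    if dt <= 0 or np.any(diffs <= 0):
        raise ValueError("frame times must be strictly increasing")
    if np.max(np.abs(diffs - dt)) > rtol * max(abs(dt), 1.0) + 1e-12:
        raise ValueError(
            "non-uniform frame spacing: the correlation machinery assumes "
            f"constant dt (found spacings between {diffs.min():g} and "
            f"{diffs.max():g} ps)"
        )
    return float(dt)


@dataclass
class VectorTrajectory:
    """Uniformly sampled unit bond-vector time series for labelled sites.

    Parameters
    ----------
    site_labels:
        One identifier per site, e.g. ``"A12:N-H"`` or ``"SDS23:C2-H"``.
    times:
        Frame times in ps, strictly increasing with constant spacing.
    vectors:
        Array of shape ``(n_sites, n_frames, 3)``; every row a unit vector
        (heavy-atom → light-atom convention).
    """

    site_labels: list[str]
    times: np.ndarray
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.site_labels = list(self.site_labels)
        self.times = np.asarray(self.times, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 3 or self.vectors.shape[2] != 3:
            raise ValueError("vectors must have shape (n_sites, n_frames, 3)")
        if self.vectors.shape[0] != len(self.site_labels):
            raise ValueError("one label per site required")
        if self.vectors.shape[1] != self.times.size:
            raise ValueError("all sites must have the same number of frames "
                             "matching the time axis")
        _check_uniform_times(self.times)
        norms = np.linalg.norm(self.vectors, axis=2)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            worst = float(np.max(np.abs(norms - 1.0)))
            raise ValueError(f"vectors must be unit length (worst |norm-1| = {worst:g})")

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def n_sites(self) -> int:
        return len(self.site_labels)

    @property
    def dt(self) -> float:
        """Frame spacing in ps."""
        return float(self.times[1] - self.times[0])

    def site(self, label: str) -> np.ndarray:
        """Vectors of one site, shape (n_frames, 3)."""
        try:
            idx = self.site_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown site label {label!r}") from None
        return self.vectors[idx]


@dataclass
class SSTrajectory:
    """Per-frame DSSP secondary-structure codes for a set of residues."""

    residue_labels: list[str]
    codes: np.ndarray = field(repr=False)  # (n_frames, n_residues) of 1-char strings

    def __post_init__(self) -> None:
        self.residue_labels = list(self.residue_labels)
        self.codes = np.asarray(self.codes, dtype="U1")
        if self.codes.ndim != 2:
            raise ValueError("codes must be a frames x residues matrix")
        if self.codes.shape[1] != len(self.residue_labels):
            raise ValueError("one label per residue column required")
        bad = set(np.unique(self.codes)) - DSSP_ALPHABET
        if bad:
            raise ValueError(f"codes outside the DSSP alphabet: {sorted(bad)}")

    @property
    def n_frames(self) -> int:
        return int(self.codes.shape[0])

    @property
    def n_residues(self) -> int:
        return int(self.codes.shape[1])


# ---------------------------------------------------------------------------
# MD trajectory extraction


def _normalize_pairs(pair_selection) -> list[tuple[str, str, str]]:
    out = []
    for item in pair_selection:
        if isinstance(item, dict):
            out.append((str(item["label"]), str(item["heavy"]), str(item["light"])))
        else:
            label, heavy, light = item
            out.append((str(label), str(heavy), str(light)))
    if not out:
        raise ValueError("pair_selection is empty")
    return out


def backbone_nh_pairs(universe, selection: str = "protein"):
    """Build (label, heavy, light) backbone amide pairs for every residue of
    ``selection`` that has both an N and an H (or HN) atom. Prolines and the
    N-terminus drop out naturally."""
    pairs = []
    for res in universe.select_atoms(selection).residues:
        names = set(res.atoms.names)
        h_name = "H" if "H" in names else ("HN" if "HN" in names else None)
        if "N" not in names or h_name is None:
            continue
        base = f"resid {res.resid} and segid {res.segid}" if res.segid.strip() else f"resid {res.resid}"
        pairs.append((f"{res.resname}{res.resid}:N-H",
                      f"({base}) and name N",
                      f"({base}) and name {h_name}"))
    return pairs


def extract_bond_vectors(trajectory_path, topology_path, pair_selection) -> VectorTrajectory:
    """Extract unit bond vectors (heavy → light atom) from an MD trajectory.

    Parameters
    ----------
    trajectory_path, topology_path:
        Any coordinate/topology pair MDAnalysis can read (XTC/TRR + GRO/PDB).
    pair_selection:
        Iterable of ``(label, heavy_selection, light_selection)`` tuples or
        ``{"label":, "heavy":, "light":}`` dicts; each selection must resolve
        to exactly one atom.

    The intra-pair displacement is minimum-imaged under the frame's periodic
    box, so bonds straddling a box edge are handled correctly. Frame times
    are taken from the trajectory and must be uniformly spaced.
    """
    import MDAnalysis as mda
    from MDAnalysis.lib.distances import minimize_vectors

    pairs = _normalize_pairs(pair_selection)
    u = mda.Universe(str(topology_path), str(trajectory_path))

    heavy_idx = np.empty(len(pairs), dtype=np.intp)
    light_idx = np.empty(len(pairs), dtype=np.intp)
    labels = []
    for i, (label, hsel, lsel) in enumerate(pairs):
        for sel, which, store in ((hsel, "heavy", heavy_idx), (lsel, "light", light_idx)):
            ag = u.select_atoms(sel)
            if len(ag) == 0:
                raise SelectionError(f"site {label!r}: {which} selection {sel!r} matches no atom")
            if len(ag) > 1:
                raise SelectionError(
                    f"site {label!r}: {which} selection {sel!r} matches {len(ag)} atoms, expected 1")
            store[i] = ag.indices[0]
        labels.append(label)

    n_frames = len(u.trajectory)
    if n_frames < 2:
        raise ValueError("trajectory must contain at least two frames")
    vectors = np.empty((len(pairs), n_frames, 3))
    times = np.empty(n_frames)
    for f, ts in enumerate(u.trajectory):
        times[f] = ts.time
        disp = ts.positions[light_idx] - ts.positions[heavy_idx]
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            disp = minimize_vectors(disp.astype(np.float64), ts.dimensions)
        norms = np.linalg.norm(disp, axis=1)
        if np.any(norms == 0):
            bad = labels[int(np.argmin(norms))]
            raise ValueError(f"zero-length bond vector for site {bad!r}")
        vectors[:, f, :] = disp / norms[:, None]

    # Trajectory times are stored in float32 by XTC; rebuild an exactly
    # uniform axis after validating spacing at file precision.
    diffs = np.diff(times)
    dt = float(diffs[0])
    if dt <= 0 or np.max(np.abs(diffs - dt)) > 1e-4 * max(dt, 1.0):
        raise ValueError("non-uniform frame spacing in trajectory "
                         "(the correlation machinery assumes constant dt)")
    times = times[0] + dt * np.arange(n_frames)
    return VectorTrajectory(labels, times, vectors)


# ---------------------------------------------------------------------------
# Vector-table dialect


def write_vector_table(vt: VectorTrajectory, path) -> None:
    """Write a :class:`VectorTrajectory` as TSV blocks, 9 significant digits."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# spinscape vector table\n")
        fh.write("# columns: time_ps\tx\ty\tz\n")
        for s, label in enumerate(vt.site_labels):
            fh.write(f"# site {label}\n")
            for t, v in zip(vt.times, vt.vectors[s]):
                fh.write(f"{t:.9g}\t{v[0]:.9g}\t{v[1]:.9g}\t{v[2]:.9g}\n")


def read_vector_table(path) -> VectorTrajectory:
    """Read the TSV vector-table dialect written by :func:`write_vector_table`.

    Vectors are re-normalized on read; deviations of the stored norm from 1
    beyond 1e-3 trigger a warning and beyond 0.1 a hard error.
    """
    labels: list[str] = []
    blocks: list[list[list[float]]] = []
    max_dev = 0.0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("site "):
                    labels.append(body[5:].strip())
                    blocks.append([])
                continue
            if not blocks:
                raise VectorTableError(
                    f"{path}:{lineno}: data row before any '# site <label>' header")
            parts = line.split()
            if len(parts) != 4:
                raise VectorTableError(
                    f"{path}:{lineno}: expected 4 columns (time_ps x y z), got {len(parts)}")
            try:
                row = [float(p) for p in parts]
            except ValueError:
                raise VectorTableError(f"{path}:{lineno}: non-numeric value") from None
            norm = (row[1] ** 2 + row[2] ** 2 + row[3] ** 2) ** 0.5
            dev = abs(norm - 1.0)
            if dev > _NORM_HARD:
                raise VectorTableError(
                    f"{path}:{lineno}: vector norm {norm:.6g} deviates from 1 by more than {_NORM_HARD}")
            max_dev = max(max_dev, dev)
            blocks[-1].append(row)
    if not blocks:
        raise VectorTableError(f"{path}: no site blocks found")
    n_frames = len(blocks[0])
    if any(len(b) != n_frames for b in blocks):
        raise VectorTableError(f"{path}: site blocks have unequal frame counts")
    if max_dev > _NORM_WARN:
        warnings.warn(
            f"{path}: vector norms deviate from 1 by up to {max_dev:.2g}; re-normalizing",
            stacklevel=2)
    data = np.asarray(blocks, dtype=float)  # (sites, frames, 4)
    times = data[0, :, 0]
    for s in range(1, data.shape[0]):
        if not np.allclose(data[s, :, 0], times, rtol=0, atol=1e-9):
            raise VectorTableError(f"{path}: site blocks disagree on frame times")
    vectors = data[:, :, 1:4]
    vectors /= np.linalg.norm(vectors, axis=2, keepdims=True)
    return VectorTrajectory(labels, times, vectors)


# ---------------------------------------------------------------------------
# Secondary-structure tables


def write_ss_table(ss: SSTrajectory, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# spinscape secondary-structure table (DSSP codes)\n")
        fh.write(" ".join(ss.residue_labels) + "\n")
        for row in ss.codes:
            fh.write(" ".join(row) + "\n")


def read_ss_table(path) -> SSTrajectory:
    """Read a whitespace-separated DSSP code matrix with a residue header."""
    labels: list[str] | None = None
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if labels is None:
                labels = parts
                continue
            if len(parts) != len(labels):
                raise SSTableError(
                    f"{path}:{lineno}: ragged row — {len(parts)} codes for {len(labels)} residues")
            for code in parts:
                if len(code) != 1 or code not in DSSP_ALPHABET:
                    raise SSTableError(f"{path}:{lineno}: unknown DSSP code {code!r}")
            rows.append(parts)
    if labels is None or not rows:
        raise SSTableError(f"{path}: no header or no frame rows")
    return SSTrajectory(labels, np.asarray(rows, dtype="U1"))
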