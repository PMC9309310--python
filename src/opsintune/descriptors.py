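"""Chromophore geometry and fluctuation descriptors from trajectories.

The photopigment lambda-max regressions consume a handful of scalar
descriptors of the 11-cis retinal chromophore and its Schiff-base lysine
(the LYS+RET moiety), measured over a molecular-dynamics trajectory:

* ``torsion15`` — median C7-C6-C5-C18 dihedral (beta-ionone ring twist);
* ``angle3``    — median C3-C7-C8 geometric angle (vertex C7);
* ``torsion3``  — median C15-C14-C13-C20 dihedral;
* ``torsion12`` — median C19-C9-C8-C7 dihedral;
* ``rmsf_auc``  — area under the per-atom RMSF curve of the LYS+RET atom
  series after least-squares rigid superposition.

Angles are in degrees, coordinates and RMSF in Angstrom. Medians of
dihedral series are circular-aware: per-frame values are re-branched
around the circular mean before the ordinary median is taken, so
distributions straddling the +/-180 deg seam are handled without wrap
artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Trajectory",
    "DescriptorSet",
    "ANGLE_SPECS",
    "LYS_RET_ATOM_ORDER",
    "dihedral",
    "bond_angle",
    "circular_median",
    "angle_series_median",
    "rmsf_per_atom",
    "rmsf_auc",
    "compute_descriptors",
    "read_trajectory_pdb",
    "write_trajectory_pdb",
    "read_trajectory_tsv",
    "write_trajectory_tsv",
    "write_descriptors_tsv",
]

#: Canonical atom order of the LYS+RET moiety: lysine backbone/side chain,
#: then the retinal polyene chain from the Schiff-base end (C15) to the
#: beta-ionone ring (C1), with each methyl carbon following its parent.
LYS_RET_ATOM_ORDER: tuple[str, ...] = (
    "N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ",
    "C15", "C14", "C13", "C20", "C12", "C11", "C10",
    "C9", "C19", "C8", "C7", "C6", "C5", "C18",
    "C4", "C3", "C2", "C1", "C16", "C17",
)

#: Named angle specifications; 4 atoms = dihedral, 3 atoms = geometric angle.
ANGLE_SPECS: dict[str, tuple[str, ...]] = {
    "torsion15": ("C7", "C6", "C5", "C18"),
    "angle3": ("C3", "C7", "C8"),
    "torsion3": ("C15", "C14", "C13", "C20"),
    "torsion12": ("C19", "C9", "C8", "C7"),
}

_EPS = 1e-10


@dataclass
class Trajectory:
    """Per-frame 3D coordinates of a fixed, ordered atom set.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom.
    """

    atoms: tuple[str, ...]
    coords: np.ndarray
    frame_spacing: float = 1.0  # informational, arbitrary time units

    def __post_init__(self) -> None:
        self.atoms = tuple(self.atoms)
        self.coords = np.asarray(self.coords, dtype=float)
        if len(set(self.atoms)) != len(self.atoms):
            raise ValueError("atom labels must be unique")
        if self.coords.ndim != 3 or self.coords.shape[1:] != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} inconsistent with "
                f"{len(self.atoms)} atoms")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def index_of(self, names: tuple[str, ...]) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.atoms)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise ValueError(f"atoms missing from trajectory: {missing}")
        return np.array([lookup[n] for n in names])


@dataclass
class DescriptorSet:
    """The scalar descriptors feeding the lambda-max regressions."""

    pigment_id: str = ""
    torsion15_median: float | None = None
    angle3_median: float | None = None
    torsion3_median: float | None = None
    torsion12_median: float | None = None
    rmsf_auc: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("torsion15_median", "torsion3_median", "torsion12_median"):
            v = getattr(self, name)
            if v is not None and not (-180.0 < v <= 180.0):
                raise ValueError(f"{name}={v} outside (-180, 180]")
        if self.angle3_median is not None and not (
                0.0 <= self.angle3_median <= 180.0):
            raise ValueError(f"angle3_median={self.angle3_median} outside [0, 180]")
        if self.rmsf_auc is not None and self.rmsf_auc < 0:
            raise ValueError(f"rmsf_auc={self.rmsf_auc} negative")


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle of four points, degrees in (-180, 180].

    Sign convention: ((0,0,0),(1,0,0),(1,1,0),(1,1,1)) -> -90 deg.
    Reversing the atom order preserves the value; mirroring the
    coordinates negates it. Planar cis -> 0, planar trans -> 180.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS:
        raise ValueError("undefined dihedral: collinear atom triple")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def bond_angle(p1, p2, p3) -> float:
    """Geometric angle at vertex p2, degrees in [0, 180]."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    v1 = p1 - p2
    v2 = p3 - p2
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < _EPS or n2 < _EPS:
        raise ValueError("undefined angle: zero-length vector")
    cos = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def _wrap_deg(x: np.ndarray | float):
    """Wrap angle(s) to (-180, 180]."""
    w = (np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0
    w = np.where(np.isclose(w, -180.0), 180.0, w)
    return w if w.ndim else float(w)


def circular_median(values_deg: np.ndarray) -> float:
    """Median of a circular series, degrees in (-180, 180].

    Values are re-branched around the circular mean so a distribution
    straddling the +/-180 seam (e.g. alternating +179/-179) yields 180,
    not the meaningless linear median 0.
    """
    values = np.asarray(values_deg, dtype=float)
    rad = np.radians(values)
    mean = np.degrees(np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad))))
    rebranched = mean + _wrap_deg(values - mean)
    return float(_wrap_deg(np.median(rebranched)))


def angle_series_median(traj: Trajectory, angle_spec: tuple[str, ...] | str
                        ) -> float:
    """Per-frame angle series reduced to its (circular-aware) median.

    ``angle_spec`` is a named descriptor key or an explicit tuple of 3
    (geometric angle) or 4 (dihedral) atom labels.
    """
    if isinstance(angle_spec, str):
        angle_spec = ANGLE_SPECS[angle_spec]
    idx = traj.index_of(tuple(angle_spec))
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        pts = traj.coords[f, idx]
        try:
            if len(idx) == 4:
                values[f] = dihedral(*pts)
            elif len(idx) == 3:
                values[f] = bond_angle(*pts)
            else:
                raise ValueError("angle_spec must name 3 or 4 atoms")
        except ValueError as exc:
            raise ValueError(f"frame {f}: {exc}") from exc
    if len(idx) == 4:
        return circular_median(values)
    return float(np.median(values))


def _superpose(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares rigid fit of every frame onto a reference structure."""
    ref_centered = reference - reference.mean(axis=0)
    if np.allclose(ref_centered, 0.0):
        raise ValueError("degenerate superposition: reference atoms coincide")
    out = np.empty_like(frames)
    for f in range(frames.shape[0]):
        frame = frames[f]
        centered = frame - frame.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_centered, centered)
        out[f] = rot.apply(centered) + reference.mean(axis=0)
    return out


def rmsf_per_atom(traj: Trajectory, selection: tuple[str, ...] | None = None,
                  reference: np.ndarray | None = None,
                  n_iter: int = 3) -> np.ndarray:
    """Per-atom root mean square fluctuation after rigid superposition.

    Frames are superposed onto the mean structure of the selected atoms
    themselves (iterated to self-consistency), so global rigid-body motion
    contributes nothing. A user-supplied ``reference`` frame replaces the
    internal mean-structure reference when given.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for fluctuation statistics")
    names = tuple(selection) if selection is not None else traj.atoms
    if not names:
        raise ValueError("empty atom selection")
    idx = traj.index_of(names)
    frames = traj.coords[:, idx, :]
    if reference is not None:
        fitted = _superpose(frames, np.asarray(reference, dtype=float))
    else:
        ref = frames[0]
        fitted = frames
        for _ in range(n_iter):
            fitted = _superpose(frames, ref)
            new_ref = fitted.mean(axis=0)
            if np.allclose(new_ref, ref, atol=1e-12):
                ref = new_ref
                break
            ref = new_ref
    mean_pos = fitted.mean(axis=0)
    return np.sqrt(np.mean(np.sum((fitted - mean_pos) ** 2, axis=2), axis=0))


def rmsf_auc(per_atom_values: np.ndarray,
             atom_order: tuple[str, ...] | None = None) -> float:
    """Trapezoidal area under the RMSF-vs-atom-index curve (unit spacing).

    When ``atom_order`` is given, values are assumed to be labelled in that
    order already; it only asserts the length matches.
    """
    values = np.asarray(per_atom_values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 atoms for an area")
    if atom_order is not None and len(atom_order) != values.size:
        raise ValueError("atom_order length does not match values")
    return float(np.trapezoid(values))


def compute_descriptors(traj: Trajectory, pigment_id: str = "") -> DescriptorSet:
    """All five descriptors from one chromophore trajectory.

    The RMSF curve runs over the trajectory's atoms in their stored order,
    which for the canonical LYS+RET moiety is :data:`LYS_RET_ATOM_ORDER`.
    """
    needed = {a for spec in ANGLE_SPECS.values() for a in spec}
    missing = sorted(needed - set(traj.atoms))
    if missing:
        raise ValueError(f"trajectory lacks named atoms: {missing}")
    per_atom = rmsf_per_atom(traj)
    return DescriptorSet(
        pigment_id=pigment_id,
        torsion15_median=angle_series_median(traj, "torsion15"),
        angle3_median=angle_series_median(traj, "angle3"),
        torsion3_median=angle_series_median(traj, "torsion3"),
        torsion12_median=angle_series_median(traj, "torsion12"),
        rmsf_auc=rmsf_auc(per_atom, traj.atoms),
    )


# ---------------------------------------------------------------------------
# trajectory I/O: multi-model PDB and plain TSV dialects


def _element_of(name: str) -> str:
    return name[0] if name[0] in ("C", "N", "O") else "C"


def write_trajectory_pdb(traj: Trajectory, path: str | Path) -> None:
    """Multi-model PDB; atoms carried in trajectory order, 1-based models."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for i, name in enumerate(traj.atoms):
                x, y, z = traj.coords[f, i]
                resname = "LYS" if name in ("N", "CA", "C", "O", "CB", "CG",
                                            "CD", "CE", "NZ") else "RET"
                fh.write(
                    f"ATOM  {i + 1:5d} {name:>4s} {resname:<3s} A{1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {_element_of(name):>2s}\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_trajectory_pdb(path: str | Path) -> Trajectory:
    """Read a multi-model PDB into a Trajectory (atoms matched by name)."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:  # single model
        coords = coords[None]
    atoms = tuple(str(a) for a in stack.atom_name)
    return Trajectory(atoms=atoms, coords=coords)


def write_trajectory_tsv(traj: Trajectory, path: str | Path) -> None:
    """Plain TSV dialect: frame (1-based), atom, x, y, z in Angstrom."""
    with open(path, "w") as fh:
        fh.write("frame\tatom\tx\ty\tz\n")
        for f in range(traj.n_frames):
            for i, name in enumerate(traj.atoms):
                x, y, z = traj.coords[f, i]
                fh.write(f"{f + 1}\t{name}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def read_trajectory_tsv(path: str | Path) -> Trajectory:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    frames = sorted(df["frame"].unique())
    atoms = tuple(df[df["frame"] == frames[0]]["atom"])
    coords = np.empty((len(frames), len(atoms), 3))
    for fi, f in enumerate(frames):
        sub = df[df["frame"] == f].set_index("atom").loc[list(atoms)]
        coords[fi] = sub[["x", "y", "z"]].to_numpy()
    return Trajectory(atoms=atoms, coords=coords)


def write_descriptors_tsv(descriptors: list[DescriptorSet],
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pigment_id\ttorsion15\tangle3\ttorsion3\ttorsion12\trmsf_auc\n")
        for d in descriptors:
            def fmt(v):
                return "" if v is None else f"{v:.6g}"
            fh.write(f"{d.pigment_id}\t{fmt(d.torsion15_median)}\t"
                     f"{fmt(d.angle3_median)}\t{fmt(d.torsion3_median)}\t"
                     f"{fmt(d.torsion12_median)}\t{fmt(d.rmsf_auc)}\n")
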