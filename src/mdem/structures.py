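"""Molecular reference structures, body frames, poses and their algebra.

A molecule is represented by a :class:`BeadStructure` (bead coordinates in
nm, per-bead masses in amu and a backbone selection mask).  Its body frame
is obtained by :func:`canonicalize_frame`, which moves the mass-weighted
center to the origin and aligns the principal component axes in descending
order of spread.  Rigid-body placement is handled by :class:`Pose`
(translation + unit quaternion) and the relative placement of one molecule
in another's body frame by :class:`Configuration`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "BeadStructure",
    "Configuration",
    "EulerConvention",
    "Pose",
    "canonicalize_frame",
    "gyration_radii",
    "pose_compose",
    "pose_inverse",
    "read_structure",
    "relative_config",
    "write_xyz",
    "wrap_angle",
]

# Default atomic masses (amu) for bead mass assignment.
_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "FE": 55.845, "ZN": 65.38, "MG": 24.305, "CA": 40.078,
}


class EulerConvention(enum.Enum):
    """Euler angle conventions for (alpha, beta, gamma) triples.

    Values are :mod:`scipy.spatial.transform` axis sequences; lowercase
    means extrinsic (fixed-frame) rotations, uppercase intrinsic.
    """

    ZYX_INTRINSIC = "ZYX"
    XYZ_INTRINSIC = "XYZ"
    ZXZ_INTRINSIC = "ZXZ"
    XYZ_EXTRINSIC = "xyz"
    ZYX_EXTRINSIC = "zyx"
    ZXZ_EXTRINSIC = "zxz"


#: Convention used when none is given explicitly.
DEFAULT_EULER = EulerConvention.ZYX_INTRINSIC


def wrap_angle(a):
    """Wrap angle(s) to the interval (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    wrapped = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    return wrapped if wrapped.shape else float(wrapped)


def euler_to_rotation(angles, convention: EulerConvention = DEFAULT_EULER) -> Rotation:
    return Rotation.from_euler(convention.value, angles)


def rotation_to_euler(rot: Rotation, convention: EulerConvention = DEFAULT_EULER):
    return wrap_angle(rot.as_euler(convention.value))


@dataclass(frozen=True)
class Pose:
    """Rigid-body placement: translation (nm) and unit quaternion (x,y,z,w)."""

    translation: np.ndarray
    quaternion: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.translation, dtype=float).reshape(3)
        q = np.asarray(self.quaternion, dtype=float).reshape(4)
        n = np.linalg.norm(q)
        if not np.isfinite(t).all() or not np.isfinite(q).all():
            raise ValueError("pose components must be finite")
        if abs(n - 1.0) > 1e-6:
            q = q / n
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "quaternion", q / np.linalg.norm(q))

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.zeros(3), np.array([0.0, 0.0, 0.0, 1.0]))

    @classmethod
    def from_rotation(cls, translation, rot: Rotation) -> "Pose":
        return cls(np.asarray(translation, dtype=float), rot.as_quat())

    @classmethod
    def from_euler(cls, translation, angles,
                   convention: EulerConvention = DEFAULT_EULER) -> "Pose":
        return cls.from_rotation(translation, euler_to_rotation(angles, convention))

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.quaternion)

    @property
    def matrix(self) -> np.ndarray:
        return self.rotation.as_matrix()

    def euler(self, convention: EulerConvention = DEFAULT_EULER) -> np.ndarray:
        return rotation_to_euler(self.rotation, convention)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform body-frame points to the parent frame."""
        return np.asarray(points, dtype=float) @ self.matrix.T + self.translation

    def homogeneous(self) -> np.ndarray:
        H = np.eye(4)
        H[:3, :3] = self.matrix
        H[:3, 3] = self.translation
        return H


def pose_compose(p1: Pose, p2: Pose) -> Pose:
    """Pose of (p2 expressed in p1's parent frame): p1 then p2."""
    r1 = p1.rotation
    return Pose.from_rotation(p1.translation + r1.apply(p2.translation), r1 * p2.rotation)


def pose_inverse(p: Pose) -> Pose:
    rinv = p.rotation.inv()
    return Pose.from_rotation(-rinv.apply(p.translation), rinv)


@dataclass(frozen=True)
class Configuration:
    """Relative pose of molecule B in molecule A's body frame.

    Positions in nm, Euler angles in rad wrapped to (-pi, pi].  The Euler
    convention used for the angle fields is carried along so that the
    rotational part is unambiguous.
    """

    x: float
    y: float
    z: float
    alpha: float
    beta: float
    gamma: float
    convention: EulerConvention = DEFAULT_EULER

    def __post_init__(self):
        vals = (self.x, self.y, self.z, self.alpha, self.beta, self.gamma)
        if not np.all(np.isfinite(vals)):
            raise ValueError("configuration components must be finite")
        object.__setattr__(self, "alpha", wrap_angle(self.alpha))
        object.__setattr__(self, "beta", wrap_angle(self.beta))
        object.__setattr__(self, "gamma", wrap_angle(self.gamma))

    @classmethod
    def from_pose(cls, pose: Pose,
                  convention: EulerConvention = DEFAULT_EULER) -> "Configuration":
        ang = pose.euler(convention)
        t = pose.translation
        return cls(t[0], t[1], t[2], ang[0], ang[1], ang[2], convention)

    @classmethod
    def from_array(cls, arr, convention: EulerConvention = DEFAULT_EULER) -> "Configuration":
        arr = np.asarray(arr, dtype=float).reshape(6)
        return cls(*arr, convention)

    def to_pose(self) -> Pose:
        return Pose.from_euler(
            (self.x, self.y, self.z), (self.alpha, self.beta, self.gamma), self.convention
        )

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z, self.alpha, self.beta, self.gamma])

    def inverse(self) -> "Configuration":
        return Configuration.from_pose(pose_inverse(self.to_pose()), self.convention)


def relative_config(pose_a: Pose, pose_b: Pose,
                    convention: EulerConvention = DEFAULT_EULER) -> Configuration:
    """Configuration of B in A's body frame."""
    return Configuration.from_pose(pose_compose(pose_inverse(pose_a), pose_b), convention)


@dataclass
class BeadStructure:
    """A bead-level molecular structure.

    Coordinates in nm; ``backbone_mask`` flags the beads used for the
    minimum-distance and RMSD descriptors; masses in amu.
    """

    name: str
    bead_coords: np.ndarray
    backbone_mask: np.ndarray = None
    bead_masses: np.ndarray = None
    canonical: bool = field(default=False, compare=False)

    def __post_init__(self):
        c = np.atleast_2d(np.asarray(self.bead_coords, dtype=float))
        if c.shape[0] < 1 or c.shape[1] != 3:
            raise ValueError("structure needs >= 1 bead with 3 coordinates")
        if not np.isfinite(c).all():
            raise ValueError("bead coordinates must be finite")
        self.bead_coords = c
        n = c.shape[0]
        if self.backbone_mask is None:
            self.backbone_mask = np.ones(n, dtype=bool)
        else:
            self.backbone_mask = np.asarray(self.backbone_mask, dtype=bool).reshape(n)
        if not self.backbone_mask.any():
            raise ValueError("backbone selection is empty")
        if self.bead_masses is None:
            self.bead_masses = np.ones(n, dtype=float)
        else:
            self.bead_masses = np.asarray(self.bead_masses, dtype=float).reshape(n)

    @property
    def n_beads(self) -> int:
        return self.bead_coords.shape[0]

    @property
    def backbone_coords(self) -> np.ndarray:
        return self.bead_coords[self.backbone_mask]

    @property
    def total_mass(self) -> float:
        return float(self.bead_masses.sum())

    def center_of_mass(self) -> np.ndarray:
        m = self.bead_masses
        return (self.bead_coords * m[:, None]).sum(axis=0) / m.sum()

    def inertia_tensor(self) -> np.ndarray:
        """Mass-weighted inertia tensor about the center of mass (amu nm^2)."""
        r = self.bead_coords - self.center_of_mass()
        m = self.bead_masses
        r2 = (r * r).sum(axis=1)
        eye = np.eye(3)
        return (m[:, None, None] * (r2[:, None, None] * eye - r[:, :, None] * r[:, None, :])).sum(axis=0)


def _principal_axes(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Rows are principal axes sorted by descending spread, right-handed."""
    w = masses / masses.sum()
    cov = (coords * w[:, None]).T @ coords
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order].T
    # Deterministic sign: the largest-|coordinate| bead along each of the
    # first two axes gets a positive coordinate; third axis closes the
    # right-handed triad.
    for k in range(2):
        proj = coords @ axes[k]
        i = int(np.argmax(np.abs(proj)))
        if proj[i] < 0:
            axes[k] = -axes[k]
    axes[2] = np.cross(axes[0], axes[1])
    return axes


def canonicalize_frame(structure: BeadStructure):
    """Center at the mass-weighted origin and align principal axes.

    Returns ``(canonical_structure, transform)`` where ``transform`` is the
    :class:`Pose` that maps canonical coordinates back to the input frame.
    """
    com = structure.center_of_mass()
    centered = structure.bead_coords - com
    axes = _principal_axes(centered, structure.bead_masses)
    new_coords = centered @ axes.T
    canonical = replace(structure, bead_coords=new_coords, canonical=True)
    transform = Pose.from_rotation(com, Rotation.from_matrix(axes.T))
    return canonical, transform


def gyration_radii(structure: BeadStructure) -> np.ndarray:
    """Per-axis gyration radius about each body axis (nm).

    The radius about axis ``i`` is the mass-weighted RMS of the two
    coordinate components perpendicular to that axis, so the longest
    principal axis yields the smallest value.
    """
    r = structure.bead_coords
    w = structure.bead_masses / structure.bead_masses.sum()
    sq = (r * r * w[:, None]).sum(axis=0)
    return np.sqrt(sq.sum() - sq)


# ---------------------------------------------------------------------------
# File I/O (PDB first model ATOM/HETATM records; simple XYZ in nm)

def _parse_pdb(path: str, selection: str):
    coords, names, masses = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "ENDMDL":
                break  # first model only
            if rec not in ("ATOM", "HETATM"):
                continue
            try:
                name = line[12:16].strip()
                x = float(line[30:38]) / 10.0  # Angstrom -> nm
                y = float(line[38:46]) / 10.0
                z = float(line[46:54]) / 10.0
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: unparsable PDB record at line {lineno}") from exc
            elem = line[76:78].strip().upper() or name[:1].upper()
            coords.append((x, y, z))
            names.append(name)
            masses.append(_ELEMENT_MASSES.get(elem, 1.0))
    if not coords:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    names = np.array(names)
    if selection == "CA":
        mask = names == "CA"
    elif selection == "backbone":
        mask = np.isin(names, ("N", "CA", "C", "O"))
    elif selection == "all":
        mask = np.ones(len(names), dtype=bool)
    else:
        raise ValueError(f"unknown selection policy {selection!r}")
    if not mask.any():
        raise ValueError(f"{path}: selection {selection!r} matched no atoms")
    return np.array(coords), mask, np.array(masses)


def _parse_xyz(path: str):
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: bad XYZ count at line 1") from exc
    coords, masses = [], []
    for lineno, line in enumerate(lines[2:2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: bad XYZ record at line {lineno}")
        try:
            coords.append([float(v) for v in parts[1:4]])
        except ValueError as exc:
            raise ValueError(f"{path}: bad XYZ record at line {lineno}") from exc
        masses.append(_ELEMENT_MASSES.get(parts[0].upper(), 1.0))
    if len(coords) != n:
        raise ValueError(f"{path}: expected {n} records, found {len(coords)}")
    return np.array(coords), np.ones(n, dtype=bool), np.array(masses)


def read_structure(path: str, format: str = None, selection: str = "all") -> BeadStructure:
    """Read a bead structure from a PDB or XYZ file.

    ``selection`` ('CA', 'backbone' or 'all') sets the backbone mask for
    PDB input; XYZ beads are all backbone.  XYZ coordinates are taken in
    nm, PDB coordinates converted from Angstrom.
    """
    path = str(path)
    if format is None:
        format = "pdb" if path.lower().endswith(".pdb") else "xyz"
    format = format.lower()
    if format == "pdb":
        coords, mask, masses = _parse_pdb(path, selection)
    elif format == "xyz":
        coords, mask, masses = _parse_xyz(path)
    else:
        raise ValueError(f"unsupported format {format!r}")
    import os

    name = os.path.splitext(os.path.basename(path))[0]
    return BeadStructure(name=name, bead_coords=coords,
                         backbone_mask=mask, bead_masses=masses)


def write_xyz(structure: BeadStructure, path: str, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{structure.n_beads}\n{comment}\n")
        for xyz in structure.bead_coords:
            fh.write("X {:.9f} {:.9f} {:.9f}\n".format(*xyz))
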