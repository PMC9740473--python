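"""Spatial descriptors for pair configurations.

Two scalar descriptors characterise a relative placement of molecule B in
molecule A's body frame: the minimum backbone bead-bead distance ``delta_m``
and, between two placements, the backbone RMSD ``delta_r`` which serves as
the configuration-space metric everywhere (neighborhoods, variograms,
binding proximity).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from mdem.structures import (
    BeadStructure,
    Configuration,
    Pose,
    pose_inverse,
)

__all__ = [
    "config_distance",
    "config_distance_matrix",
    "count_collisions",
    "min_distance",
    "min_distance_many",
    "place_beads",
    "placed_cloud",
    "random_config",
    "symmetrize_config",
]


def place_beads(structure: BeadStructure, config_or_pose, backbone_only: bool = True) -> np.ndarray:
    """Bead coordinates of a structure placed at a configuration/pose."""
    pose = config_or_pose.to_pose() if isinstance(config_or_pose, Configuration) else config_or_pose
    pts = structure.backbone_coords if backbone_only else structure.bead_coords
    return pose.apply(pts)


def placed_cloud(structure: BeadStructure, configs: np.ndarray,
                 convention=None) -> np.ndarray:
    """Backbone clouds (n, n_beads, 3) for an (n, 6) array of configurations."""
    from mdem.structures import DEFAULT_EULER, euler_to_rotation

    configs = np.atleast_2d(np.asarray(configs, dtype=float))
    conv = convention or DEFAULT_EULER
    rots = euler_to_rotation(configs[:, 3:6], conv)
    mats = np.atleast_3d(rots.as_matrix()).reshape(len(configs), 3, 3)
    pts = structure.backbone_coords
    return np.einsum("nij,bj->nbi", mats, pts) + configs[:, None, :3]


def min_distance(struct_a: BeadStructure, struct_b: BeadStructure,
                 config: Configuration, backbone_only: bool = True) -> float:
    """Minimum distance delta_m (nm) between beads of A and placed B."""
    pts_a = struct_a.backbone_coords if backbone_only else struct_a.bead_coords
    pts_b = place_beads(struct_b, config, backbone_only)
    return float(cdist(pts_a, pts_b).min())


def min_distance_many(struct_a: BeadStructure, struct_b: BeadStructure,
                      configs: np.ndarray, backbone_only: bool = True,
                      convention=None, chunk: int = 2048) -> np.ndarray:
    """Vectorised :func:`min_distance` over an (n, 6) configuration array."""
    configs = np.atleast_2d(configs)
    pts_a = struct_a.backbone_coords if backbone_only else struct_a.bead_coords
    out = np.empty(len(configs))
    for lo in range(0, len(configs), chunk):
        hi = min(lo + chunk, len(configs))
        clouds = placed_cloud(struct_b, configs[lo:hi], convention)
        if not backbone_only:
            from mdem.structures import DEFAULT_EULER, euler_to_rotation

            conv = convention or DEFAULT_EULER
            rots = euler_to_rotation(configs[lo:hi, 3:6], conv)
            mats = np.atleast_3d(rots.as_matrix()).reshape(hi - lo, 3, 3)
            clouds = np.einsum("nij,bj->nbi", mats, struct_b.bead_coords) + configs[lo:hi, None, :3]
        d = clouds[:, :, None, :] - pts_a[None, None, :, :]
        out[lo:hi] = np.sqrt((d * d).sum(axis=-1)).reshape(hi - lo, -1).min(axis=1)
    return out


def config_distance(c1: Configuration, c2: Configuration,
                    struct_b: BeadStructure) -> float:
    """RMSD delta_r (nm) of B's backbone beads between two placements."""
    p1 = place_beads(struct_b, c1)
    p2 = place_beads(struct_b, c2)
    return float(np.sqrt(np.mean(np.sum((p1 - p2) ** 2, axis=1))))


def config_distance_matrix(clouds_a: np.ndarray, clouds_b: np.ndarray,
                           chunk: int = 512) -> np.ndarray:
    """Pairwise delta_r between two stacks of placed backbone clouds.

    ``clouds_*`` have shape (n, n_beads, 3); returns (n_a, n_b).
    """
    clouds_a = np.asarray(clouds_a)
    clouds_b = np.asarray(clouds_b)
    na = clouds_a.shape[0]
    out = np.empty((na, clouds_b.shape[0]))
    for lo in range(0, na, chunk):
        hi = min(lo + chunk, na)
        d = clouds_a[lo:hi, None, :, :] - clouds_b[None, :, :, :]
        out[lo:hi] = np.sqrt((d * d).sum(axis=-1).mean(axis=-1))
    return out


def count_collisions(struct_a: BeadStructure, struct_b: BeadStructure,
                     config: Configuration, threshold: float = 0.4,
                     backbone_only: bool = False) -> int:
    """Number of bead pairs closer than ``threshold`` (nm).

    By default all beads are considered (the placement filter of the data
    generation uses any-atom contacts); set ``backbone_only`` for the
    backbone-restricted count used by virtual-point insertion rules.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    pts_a = struct_a.backbone_coords if backbone_only else struct_a.bead_coords
    pose = config.to_pose()
    pts_b = pose.apply(struct_b.backbone_coords if backbone_only else struct_b.bead_coords)
    return int((cdist(pts_a, pts_b) < threshold).sum())


def symmetrize_config(config: Configuration) -> Configuration:
    """The same physical contact described with the roles of A and B swapped."""
    return Configuration.from_pose(pose_inverse(config.to_pose()), config.convention)


def random_config(rng: np.random.Generator, r_min: float, r_max: float,
                  struct_a: BeadStructure, struct_b: BeadStructure,
                  d_coll: float = 0.4, max_tries: int = 1000,
                  convention=None) -> Configuration:
    """Uniform random non-colliding configuration within a radial shell.

    The position is volume-uniform in the shell ``r_min <= |x| <= r_max``,
    the orientation uniform on SO(3); draws violating the any-bead
    collision distance ``d_coll`` are rejected and retried.
    """
    from mdem.structures import DEFAULT_EULER

    if r_max <= r_min or r_min < 0:
        raise ValueError("invalid radial bounds")
    conv = convention or DEFAULT_EULER
    for _ in range(max_tries):
        u = rng.random()
        r = (r_min ** 3 + u * (r_max ** 3 - r_min ** 3)) ** (1.0 / 3.0)
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        rot = Rotation.random(rng=rng)
        pose = Pose.from_rotation(r * v, rot)
        config = Configuration.from_pose(pose, conv)
        if min_distance(struct_a, struct_b, config, backbone_only=False) >= d_coll:
            return config
    raise RuntimeError(
        f"no collision-free configuration found in shell [{r_min}, {r_max}] nm "
        f"after {max_tries} tries"
    )
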