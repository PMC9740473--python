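"""6D potential grids, interpolation, and gradient forces/torques.

Potentials are stored on homogeneous grids over (x, y, z, alpha, beta,
gamma) with periodic angle axes.  Look-up is multilinear; forces are
central differences over the spatial axes and torques central differences
with respect to small quaternion-composed rotations of molecule B about
molecule A's body axes.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field as dfield
from itertools import product

import numpy as np
from scipy.spatial.transform import Rotation

from mdem.descriptors import count_collisions, min_distance_many
from mdem.structures import (
    BeadStructure,
    Configuration,
    DEFAULT_EULER,
    euler_to_rotation,
)

__all__ = [
    "AnalyticField",
    "CollisionParams",
    "EmpiricalBindingSpec",
    "ForceTorque",
    "GridAxis",
    "MultiGrid",
    "PotentialGrid",
    "build_grid",
    "collision_penalty",
    "correct_overlap",
    "force_torque",
    "insert_empirical",
    "load_field",
    "save_field",
]

MAGIC = b"MDEMFLD1"
FORMAT_VERSION = 1


@dataclass(frozen=True)
class GridAxis:
    """One grid axis; periodic axes cover a full 2*pi turn."""

    minimum: float
    maximum: float
    step: float
    periodic: bool = False

    @property
    def n(self) -> int:
        if self.maximum <= self.minimum:
            return 1
        # node count includes both ends for bounded axes; periodic axes
        # carry n nodes with wrap period n * step
        return int(round((self.maximum - self.minimum) / self.step)) + 1

    @property
    def nodes(self) -> np.ndarray:
        if self.n == 1:
            return np.array([self.minimum])
        return self.minimum + self.step * np.arange(self.n)

    @classmethod
    def angle(cls, step: float) -> "GridAxis":
        n = max(int(round(2.0 * np.pi / step)), 1)
        s = 2.0 * np.pi / n
        return cls(-np.pi + s, np.pi, s, periodic=True)

    @classmethod
    def fixed(cls, value: float = 0.0) -> "GridAxis":
        return cls(value, value, 1.0, periodic=False)


@dataclass(frozen=True)
class ForceTorque:
    """Force (kJ/mol/nm) and torque (kJ/mol/rad) in a body frame."""

    force: np.ndarray
    torque: np.ndarray


@dataclass
class EmpiricalBindingSpec:
    """Virtual binding-well insertion parameters."""

    binding_configs: list
    u_center: float = -1400.0
    u_outer: float = -1000.0
    r_bind: float = 1.0
    max_extra_collisions: int = 10

    def __post_init__(self):
        if not (self.u_center <= self.u_outer <= 0.0):
            raise ValueError("need u_center <= u_outer <= 0")
        if self.r_bind <= 0:
            raise ValueError("r_bind must be positive")

    def well(self, delta_r):
        """Gaussian well from u_center to u_outer over delta_r, clipped at r_bind."""
        d = np.clip(np.asarray(delta_r, dtype=float), 0.0, self.r_bind)
        w = self.r_bind / 2.0
        return self.u_outer + (self.u_center - self.u_outer) * np.exp(-d ** 2 / (2.0 * w ** 2))


@dataclass
class CollisionParams:
    """Effective collision model: penalty per colliding bead pair, tapered
    by the delta_r distance to the nearest sampled configuration."""

    k_coll: float = 100.0
    d_flex: float = 0.5
    threshold: float = 0.4

    def __post_init__(self):
        if self.k_coll < 0 or self.d_flex <= 0:
            raise ValueError("invalid collision parameters")


class PotentialGrid:
    """Homogeneous 6D grid of potential (and optionally variance) values."""

    def __init__(self, axes, values=None, variance=None, mask=None,
                 species=("A", "A"), components=("total",),
                 convention=DEFAULT_EULER, interaction_range=None):
        self.axes = list(axes)
        if len(self.axes) != 6:
            raise ValueError("exactly six axes required")
        self.shape = tuple(ax.n for ax in self.axes)
        self.values = (np.zeros(self.shape) if values is None
                       else np.asarray(values, dtype=float).reshape(self.shape))
        self.variance = (None if variance is None
                         else np.asarray(variance, dtype=float).reshape(self.shape))
        self.mask = (np.zeros(self.shape, dtype=bool) if mask is None
                     else np.asarray(mask, dtype=bool).reshape(self.shape))
        self.species = tuple(species)
        self.components = tuple(components)
        self.convention = convention
        self.interaction_range = interaction_range

    # -- geometry ----------------------------------------------------------
    @property
    def steps(self) -> np.ndarray:
        return np.array([ax.step if ax.n > 1 else 0.0 for ax in self.axes])

    def node_configs(self) -> np.ndarray:
        """All node coordinates as an (n_nodes, 6) array in C order."""
        grids = np.meshgrid(*[ax.nodes for ax in self.axes], indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)

    def _locate(self, q: np.ndarray):
        """Cell indices/fractions per axis; returns (i0, i1, frac, inside)."""
        nq = q.shape[0]
        i0 = np.zeros((6, nq), dtype=int)
        i1 = np.zeros((6, nq), dtype=int)
        fr = np.zeros((6, nq))
        inside = np.ones(nq, dtype=bool)
        for k, ax in enumerate(self.axes):
            if ax.n == 1:
                continue
            if ax.periodic:
                period = ax.n * ax.step
                t = np.mod(q[:, k] - ax.minimum, period) / ax.step
                base = np.floor(t).astype(int)
                i0[k] = base % ax.n
                i1[k] = (base + 1) % ax.n
                fr[k] = t - np.floor(t)
            else:
                t = (q[:, k] - ax.minimum) / ax.step
                inside &= (t >= -1e-9) & (t <= ax.n - 1 + 1e-9)
                t = np.clip(t, 0.0, ax.n - 1)
                base = np.minimum(np.floor(t).astype(int), ax.n - 2)
                i0[k] = base
                i1[k] = base + 1
                fr[k] = t - base
        return i0, i1, fr, inside

    def _interpolate(self, arr: np.ndarray, q: np.ndarray) -> np.ndarray:
        i0, i1, fr, inside = self._locate(q)
        nq = q.shape[0]
        strides = np.array([int(np.prod(self.shape[k + 1:])) for k in range(6)])
        bits = ((np.arange(64)[:, None] >> np.arange(5, -1, -1)) & 1).astype(bool)
        idx = np.zeros((64, nq), dtype=np.int64)
        w = np.ones((64, nq))
        for k in range(6):
            sel = np.where(bits[:, k, None], i1[k], i0[k])
            idx += sel * strides[k]
            w *= np.where(bits[:, k, None], fr[k], 1.0 - fr[k])
        out = (arr.ravel()[idx] * w).sum(axis=0)
        out[~inside] = 0.0
        return out

    def value_many(self, configs: np.ndarray) -> np.ndarray:
        return self._interpolate(self.values, np.atleast_2d(np.asarray(configs, dtype=float)))

    def value_at(self, config) -> float:
        arr = config.to_array() if isinstance(config, Configuration) else np.asarray(config)
        return float(self.value_many(arr[None])[0])

    def variance_many(self, configs: np.ndarray) -> np.ndarray:
        if self.variance is None:
            raise ValueError("grid has no variance array")
        return self._interpolate(self.variance, np.atleast_2d(configs))

    def is_masked(self, config) -> bool:
        arr = config.to_array() if isinstance(config, Configuration) else np.asarray(config)
        i0, i1, _, inside = self._locate(np.atleast_2d(arr))
        if not inside[0]:
            return True
        for corner in product((0, 1), repeat=6):
            idx = tuple((i1 if c else i0)[k][0] for k, c in enumerate(corner))
            if not self.mask[idx]:
                return False
        return True


class AnalyticField:
    """Closed-form potential wrapped with the grid look-up interface.

    Useful for verification and for driving the simulator with designed
    potentials without a kriging pass.
    """

    def __init__(self, fn, steps, convention=DEFAULT_EULER, interaction_range=None):
        self._fn = fn
        self.steps = np.asarray(steps, dtype=float)
        self.convention = convention
        self.interaction_range = interaction_range

    def value_many(self, configs):
        return np.asarray(self._fn(np.atleast_2d(np.asarray(configs, dtype=float))))

    def value_at(self, config):
        arr = config.to_array() if isinstance(config, Configuration) else np.asarray(config)
        return float(self.value_many(arr[None])[0])

    def is_masked(self, config):
        return False


class MultiGrid:
    """Two-level grid: a fine grid inside its extent, a coarse fallback."""

    def __init__(self, fine: PotentialGrid, coarse: PotentialGrid):
        self.fine = fine
        self.coarse = coarse
        self.convention = fine.convention
        self.steps = fine.steps
        self.interaction_range = coarse.interaction_range

    def _inside_fine(self, q):
        ok = np.ones(q.shape[0], dtype=bool)
        for k, ax in enumerate(self.fine.axes):
            if ax.periodic or ax.n == 1:
                continue
            ok &= (q[:, k] >= ax.minimum) & (q[:, k] <= ax.maximum)
        return ok

    def value_many(self, configs):
        q = np.atleast_2d(np.asarray(configs, dtype=float))
        out = self.coarse.value_many(q)
        m = self._inside_fine(q)
        if m.any():
            out[m] = self.fine.value_many(q[m])
        return out

    def value_at(self, config):
        arr = config.to_array() if isinstance(config, Configuration) else np.asarray(config)
        return float(self.value_many(arr[None])[0])

    def is_masked(self, config):
        arr = config.to_array() if isinstance(config, Configuration) else np.asarray(config)
        if self._inside_fine(np.atleast_2d(arr))[0]:
            return self.fine.is_masked(config)
        return self.coarse.is_masked(config)


# ---------------------------------------------------------------------------
# Grid construction

def build_grid(engine, axes, n_pot: int = 100, n_var: int = None,
               collision: CollisionParams = None,
               struct_a: BeadStructure = None, struct_b: BeadStructure = None,
               memory_cap: float = 2e7, species=("A", "A")) -> PotentialGrid:
    """Evaluate the kriging engine at every grid node.

    Nodes beyond the engine's interaction range in delta_m are set to zero
    and masked gradient-free.  With ``collision`` given, the effective
    collision penalty is added at build time.
    """
    grid = PotentialGrid(axes, species=species,
                         components=tuple(engine.samples.components),
                         convention=engine.samples.convention,
                         interaction_range=engine.interaction_range)
    n_nodes = int(np.prod(grid.shape))
    if n_nodes > memory_cap:
        raise MemoryError(f"grid would need {n_nodes} nodes (cap {int(memory_cap)})")
    nodes = grid.node_configs()
    sb = engine.samples.struct_b
    sa = struct_a if struct_a is not None else sb
    dm = min_distance_many(sa, sb, nodes, convention=grid.convention)
    inside = dm <= engine.interaction_range
    vals = np.zeros(n_nodes)
    var = np.zeros(n_nodes)
    if inside.any():
        v, s2 = engine.estimate_many(nodes[inside], n_pot=n_pot, n_var=n_var)
        vals[inside] = v
        var[inside] = s2
    if collision is not None:
        pen = collision_penalty_many(sa, sb, nodes[inside], engine.samples, collision)
        vals[inside] = vals[inside] + pen
    grid.values = vals.reshape(grid.shape)
    grid.variance = var.reshape(grid.shape)
    grid.mask = (~inside).reshape(grid.shape)
    return grid


def collision_penalty(struct_a: BeadStructure, struct_b: BeadStructure,
                      config: Configuration, samples, params: CollisionParams) -> float:
    """Penalty k_coll * n_coll * ramp(delta_r_nearest / d_flex) >= 0."""
    n_coll = count_collisions(struct_a, struct_b, config, params.threshold)
    if n_coll == 0:
        return 0.0
    dr_near = float(samples.delta_r_to(config.to_array()).min()) if len(samples) else np.inf
    ramp = np.clip(dr_near / params.d_flex, 0.0, 1.0)
    return float(params.k_coll * n_coll * ramp)


def collision_penalty_many(struct_a, struct_b, configs, samples,
                           params: CollisionParams) -> np.ndarray:
    configs = np.atleast_2d(configs)
    out = np.zeros(len(configs))
    if len(configs) == 0:
        return out
    dr_near = samples.delta_r_to(configs).min(axis=1) if len(samples) else np.full(len(configs), np.inf)
    ramp = np.clip(dr_near / params.d_flex, 0.0, 1.0)
    for i, cfg in enumerate(configs):
        if ramp[i] == 0.0:
            continue
        c = Configuration.from_array(cfg, samples.convention)
        n_coll = count_collisions(struct_a, struct_b, c, params.threshold)
        out[i] = params.k_coll * n_coll * ramp[i]
    return out


# ---------------------------------------------------------------------------
# Empirical binding insertion

def correct_overlap(config: Configuration, struct_a, struct_b,
                    d_coll: float = 0.4, step_t: float = 0.2,
                    step_r: float = np.deg2rad(10.0), n_steps: int = 5):
    """Closest collision-free configuration by per-axis grid search.

    Coordinate-descent over the six axes, trying up to ``n_steps`` steps in
    both directions, minimising delta_r to the original configuration among
    collision-free candidates.
    """
    from mdem.descriptors import config_distance

    def collides(c):
        return count_collisions(struct_a, struct_b, c, d_coll) > 0

    if not collides(config):
        return config
    best = None
    current = config.to_array()
    for _ in range(3):
        improved = False
        for axis in range(6):
            step = step_t if axis < 3 else step_r
            for k in range(1, n_steps + 1):
                for sign in (+1, -1):
                    cand = current.copy()
                    cand[axis] += sign * k * step
                    c = Configuration.from_array(cand, config.convention)
                    if collides(c):
                        continue
                    d = config_distance(config, c, struct_b)
                    if best is None or d < best[0]:
                        best = (d, cand)
                        improved = True
        if best is not None and not improved:
            break
        if best is not None:
            current = best[1]
    if best is None:
        raise RuntimeError("no collision-free configuration found near binding site")
    return Configuration.from_array(best[1], config.convention)


def insert_empirical(samples, spec: EmpiricalBindingSpec,
                     struct_a: BeadStructure, struct_b: BeadStructure,
                     component: str = None, r_char: float = None,
                     d_coll: float = 0.4, log_fn=None):
    """Append virtual binding-well data points to the sample set.

    Set 1 places the constant center value at each binding configuration
    and its +-0.1 nm axis offsets (rotational equivalent via
    ``delta_angle = 0.1 / r_char``); set 2 traces the Gaussian well at
    +-0.2/0.4 nm offsets.  Points farther than ``r_bind`` in delta_r or
    adding more than ``max_extra_collisions`` backbone collisions are
    dropped.  Returns the number of points inserted.
    """
    from mdem.descriptors import config_distance
    from mdem.structures import gyration_radii

    if component is None:
        component = samples.components[0]
    if r_char is None:
        r_char = float(np.max(gyration_radii(struct_b)))
        if r_char <= 0:
            r_char = 1.0
    inserted = 0
    for bc in spec.binding_configs:
        base = correct_overlap(bc, struct_a, struct_b, d_coll)
        base_ncoll = count_collisions(struct_a, struct_b, base, d_coll,
                                      backbone_only=True)
        if base_ncoll > spec.max_extra_collisions:
            raise ValueError(
                f"binding configuration {base} itself adds {base_ncoll} backbone collisions"
            )
        offsets = [np.zeros(6)]
        for axis in range(6):
            d_step = 0.1 if axis < 3 else 0.1 / r_char
            for sign in (+1, -1):
                off = np.zeros(6)
                off[axis] = sign * d_step
                offsets.append(off)
        set2 = []
        for axis in range(6):
            for mag in (-0.4, -0.2, 0.2, 0.4):
                off = np.zeros(6)
                off[axis] = mag if axis < 3 else mag / r_char
                set2.append(off)
        for group, offs in (("center", offsets), ("well", set2)):
            for off in offs:
                cfg = Configuration.from_array(base.to_array() + off, base.convention)
                dr = config_distance(base, cfg, struct_b)
                if dr > spec.r_bind:
                    if log_fn:
                        log_fn(f"virtual point dropped (delta_r {dr:.2f} > r_bind)")
                    continue
                ncoll = count_collisions(struct_a, struct_b, cfg, d_coll,
                                         backbone_only=True)
                if ncoll - base_ncoll > spec.max_extra_collisions:
                    if log_fn:
                        log_fn(f"virtual point dropped ({ncoll - base_ncoll} extra collisions)")
                    continue
                value = spec.u_center if group == "center" else float(spec.well(dr))
                pots = {c: 0.0 for c in samples.components}
                pots[component] = value
                from mdem.descriptors import min_distance

                dm = min_distance(struct_a, struct_b, cfg)
                samples.append(cfg.to_array()[None], dm, pots, provenance="virtual")
                inserted += 1
    return inserted


# ---------------------------------------------------------------------------
# Forces and torques

def force_torque_batch(fieldlike, configs: np.ndarray, check_mask: bool = True):
    """Vectorised gradient forces/torques for many relative configurations.

    Returns ``(fa, ta, fb, tb, energy)``: forces/torques on A in A's body
    frame and on B in B's body frame, each (n, 3), plus the field value at
    each configuration.  The force on B is the negative central difference
    over x, y, z; the torque on B comes from quaternion-composed
    perturbations of B's orientation about A's body axes.  The reaction on
    A balances force and torque exactly.  Masked configurations yield
    zeros.
    """
    configs = np.atleast_2d(np.asarray(configs, dtype=float))
    n = len(configs)
    steps = np.asarray(fieldlike.steps, dtype=float)
    conv = fieldlike.convention
    rot0 = euler_to_rotation(configs[:, 3:6], conv)

    queries = [configs]
    slots = []
    for k in range(3):
        h = steps[k]
        if h <= 0:
            continue
        for sign in (+1, -1):
            q = configs.copy()
            q[:, k] += sign * h
            queries.append(q)
        slots.append(("f", k, h))
    for k in range(3):
        h = steps[3 + k]
        if h <= 0:
            continue
        axis = np.zeros(3)
        axis[k] = 1.0
        for sign in (+1, -1):
            rp = Rotation.from_rotvec(sign * h * axis) * rot0
            q = configs.copy()
            q[:, 3:6] = np.atleast_2d(rp.as_euler(conv.value))
            queries.append(q)
        slots.append(("t", k, h))
    vals = fieldlike.value_many(np.concatenate(queries, axis=0)).reshape(len(queries), n)
    energy = vals[0]
    force_b = np.zeros((n, 3))
    torque_b = np.zeros((n, 3))
    for i, (kind, k, h) in enumerate(slots):
        g = -(vals[1 + 2 * i] - vals[2 + 2 * i]) / (2.0 * h)
        if kind == "f":
            force_b[:, k] = g
        else:
            torque_b[:, k] = g
    if check_mask:
        masked = _masked_many(fieldlike, configs)
        if masked.any():
            force_b[masked] = 0.0
            torque_b[masked] = 0.0
    force_a = -force_b
    torque_a = -torque_b - np.cross(configs[:, :3], force_b)
    mats = np.atleast_3d(rot0.as_matrix()).reshape(n, 3, 3)
    fb_body = np.einsum("nji,nj->ni", mats, force_b)
    tb_body = np.einsum("nji,nj->ni", mats, torque_b)
    return force_a, torque_a, fb_body, tb_body, energy


def _masked_many(fieldlike, configs: np.ndarray) -> np.ndarray:
    if isinstance(fieldlike, PotentialGrid):
        frac = fieldlike._interpolate(fieldlike.mask.astype(float), configs)
        i0, i1, fr, inside = fieldlike._locate(configs)
        return (frac >= 1.0 - 1e-9) | ~inside
    if isinstance(fieldlike, MultiGrid):
        out = np.array([fieldlike.is_masked(Configuration.from_array(c, fieldlike.convention))
                        for c in configs])
        return out
    return np.zeros(len(configs), dtype=bool)


def force_torque(fieldlike, config: Configuration):
    """Gradient force/torque pair for one relative configuration.

    Returns ``(ft_a, ft_b)``: the action on molecule A (in A's body frame)
    and on molecule B (in B's body frame); see :func:`force_torque_batch`.
    """
    fa, ta, fb, tb, _ = force_torque_batch(fieldlike, config.to_array()[None])
    return ForceTorque(fa[0], ta[0]), ForceTorque(fb[0], tb[0])


# ---------------------------------------------------------------------------
# Binary field format

def _write_str(fh, s: str):
    data = s.encode("utf-8")
    fh.write(struct.pack("<I", len(data)))
    fh.write(data)


def _read_str(fh) -> str:
    (n,) = struct.unpack("<I", _read_exact(fh, 4))
    return _read_exact(fh, n).decode("utf-8")


def _read_exact(fh, n: int) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise ValueError("truncated field file")
    return data


def save_field(grid: PotentialGrid, path) -> None:
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<I", FORMAT_VERSION))
        _write_str(fh, grid.species[0])
        _write_str(fh, grid.species[1])
        fh.write(struct.pack("<I", len(grid.components)))
        for c in grid.components:
            _write_str(fh, c)
        for ax in grid.axes:
            fh.write(struct.pack("<dddB", ax.minimum, ax.maximum, ax.step,
                                 1 if ax.periodic else 0))
        flags = (1 if grid.variance is not None else 0) | 2  # mask always saved
        fh.write(struct.pack("<B", flags))
        fh.write(grid.values.astype("<f4").tobytes())
        if grid.variance is not None:
            fh.write(grid.variance.astype("<f4").tobytes())
        fh.write(np.packbits(grid.mask.ravel()).tobytes())


def read_field_version(path) -> int:
    with open(path, "rb") as fh:
        if _read_exact(fh, 8) != MAGIC:
            raise ValueError("not a field file (bad magic)")
        (version,) = struct.unpack("<I", _read_exact(fh, 4))
    return version


def load_field(path) -> PotentialGrid:
    with open(path, "rb") as fh:
        if _read_exact(fh, 8) != MAGIC:
            raise ValueError("not a field file (bad magic)")
        (version,) = struct.unpack("<I", _read_exact(fh, 4))
        if version != FORMAT_VERSION:
            raise ValueError(f"unsupported field format version {version}")
        species = (_read_str(fh), _read_str(fh))
        (ncomp,) = struct.unpack("<I", _read_exact(fh, 4))
        components = tuple(_read_str(fh) for _ in range(ncomp))
        axes = []
        for _ in range(6):
            mn, mx, st, per = struct.unpack("<dddB", _read_exact(fh, 25))
            axes.append(GridAxis(mn, mx, st, bool(per)))
        (flags,) = struct.unpack("<B", _read_exact(fh, 1))
        shape = tuple(ax.n for ax in axes)
        n = int(np.prod(shape))
        values = np.frombuffer(_read_exact(fh, 4 * n), dtype="<f4").astype(float)
        variance = None
        if flags & 1:
            variance = np.frombuffer(_read_exact(fh, 4 * n), dtype="<f4").astype(float)
        mask = None
        if flags & 2:
            nbytes = (n + 7) // 8
            bits = np.unpackbits(np.frombuffer(_read_exact(fh, nbytes), dtype=np.uint8))
            mask = bits[:n].astype(bool)
    return PotentialGrid(axes, values, variance, mask, species, components)
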