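"""Anisotropic rigid-body Langevin dynamics with periodic boundaries.

Each molecule carries a pose, linear velocity and body-frame angular
velocity.  Friction is diagonal in the body frame with per-axis
coefficients ``zeta_i = k_B T_ref / D_i`` (Einstein relation against the
parameterised diffusion coefficients); the random force satisfies
fluctuation-dissipation at the current temperature.  The integrator uses
the exact Ornstein-Uhlenbeck propagator per axis with forces held constant
across the step, which reduces to damped leap-frog at low friction and to
Brownian displacement statistics in the overdamped limit, and remains
stable for any ``zeta dt / m``.

Units: nm, ns, kJ/mol, amu, rad, K.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.spatial.transform import Rotation

from mdem.structures import BeadStructure, Pose

__all__ = [
    "KB",
    "DiffusionCoefficients",
    "NeighborList",
    "ProtocolConfig",
    "SimState",
    "Simulator",
    "Trajectory",
    "free_diffusion_probe",
    "molecule_count",
    "rpy_drag_ratios",
    "scale_viscosity",
]

KB = 0.00831446261815324  # kJ/(mol K)
AMU = 1e-6                # amu -> kJ/mol ns^2 / nm^2
UM2_PER_S = 1e-3          # um^2/s -> nm^2/ns
MRAD2_PER_S = 1e-3        # Mrad^2/s -> rad^2/ns


@dataclass(frozen=True)
class DiffusionCoefficients:
    """Body-frame anisotropic diffusion coefficients (nm^2/ns, rad^2/ns)."""

    d_t: np.ndarray
    d_r: np.ndarray
    temperature: float = 293.0
    viscosity: float = 1.0074e-3

    def __post_init__(self):
        object.__setattr__(self, "d_t", np.asarray(self.d_t, dtype=float).reshape(3))
        object.__setattr__(self, "d_r", np.asarray(self.d_r, dtype=float).reshape(3))
        if (self.d_t <= 0).any() or (self.d_r <= 0).any():
            raise ValueError("diffusion coefficients must be positive")

    @classmethod
    def from_table(cls, d_t_um2_s, d_r_mrad2_s, temperature: float = 293.0,
                   viscosity: float = 1.0074e-3) -> "DiffusionCoefficients":
        """Convert from table units (um^2/s, Mrad^2/s)."""
        return cls(np.asarray(d_t_um2_s, dtype=float) * UM2_PER_S,
                   np.asarray(d_r_mrad2_s, dtype=float) * MRAD2_PER_S,
                   temperature, viscosity)

    def friction_t(self) -> np.ndarray:
        return KB * self.temperature / self.d_t

    def friction_r(self) -> np.ndarray:
        return KB * self.temperature / self.d_r


def scale_viscosity(coeffs: DiffusionCoefficients, factor: float) -> DiffusionCoefficients:
    """Stokes-Einstein rescaling: D ~ 1/viscosity."""
    if factor <= 0:
        raise ValueError("viscosity factor must be positive")
    return DiffusionCoefficients(coeffs.d_t / factor, coeffs.d_r / factor,
                                 coeffs.temperature, coeffs.viscosity * factor)


@dataclass
class SimState:
    """Rigid-body ensemble state."""

    positions: np.ndarray       # (n, 3) nm
    quaternions: np.ndarray     # (n, 4) scalar-last
    velocities: np.ndarray      # (n, 3) nm/ns, lab frame
    omegas: np.ndarray          # (n, 3) rad/ns, body frame
    box: np.ndarray             # (3,) nm
    time: float = 0.0
    temperature: float = 293.0
    mobile: np.ndarray = None

    def __post_init__(self):
        n = len(self.positions)
        self.positions = np.asarray(self.positions, dtype=float).reshape(n, 3)
        self.quaternions = np.asarray(self.quaternions, dtype=float).reshape(n, 4)
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(n, 3)
        self.omegas = np.asarray(self.omegas, dtype=float).reshape(n, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if self.mobile is None:
            self.mobile = np.ones(n, dtype=bool)
        self.wrap()

    @property
    def n(self) -> int:
        return len(self.positions)

    def wrap(self):
        self.positions = np.mod(self.positions, self.box)
        norms = np.linalg.norm(self.quaternions, axis=1, keepdims=True)
        self.quaternions = self.quaternions / norms

    def pose(self, i: int) -> Pose:
        return Pose(self.positions[i], self.quaternions[i])

    def minimum_image(self, d: np.ndarray) -> np.ndarray:
        return d - self.box * np.round(d / self.box)


@dataclass
class ProtocolConfig:
    """Simulation protocol parameters (times in ns, box in nm)."""

    protocol: str = "SP3"
    dt: float = 1e-4
    duration: float = 10.0
    save_interval: float = 1.0
    temperature: float = 293.0
    viscosity_scale: float = 1.0
    concentration: float = None   # uM (monomer) for SP3
    box: float = 200.0
    seed: int = 0
    monomer_concentration: bool = True

    def __post_init__(self):
        if self.dt <= 0 or self.duration < 0:
            raise ValueError("invalid protocol timing")


def molecule_count(concentration_um: float, box_nm: float,
                   monomer_concentration: bool = True) -> int:
    """Number of simulated molecules for a protein concentration.

    The stated concentration counts monomers while the simulated unit is
    the dimer, hence the division by two (switchable).
    """
    avogadro = 6.02214076e23
    volume_l = (box_nm * 1e-9) ** 3 * 1e3  # m^3 -> L
    monomers = concentration_um * 1e-6 * avogadro * volume_l
    return int(round(monomers / 2.0)) if monomer_concentration else int(round(monomers))


class NeighborList:
    """Verlet list with skin under the minimum-image convention."""

    def __init__(self, r_interaction: float, skin: float = 1.0):
        self.r_interaction = float(r_interaction)
        self.skin = float(skin)
        self.pairs = np.empty((0, 2), dtype=int)
        self._build_positions = None

    def build(self, state: SimState):
        n = state.n
        pairs = []
        cut = self.r_interaction + self.skin
        for i in range(n - 1):
            d = state.minimum_image(state.positions[i + 1:] - state.positions[i])
            dist = np.linalg.norm(d, axis=1)
            for j in np.flatnonzero(dist < cut):
                pairs.append((i, i + 1 + j))
        self.pairs = np.array(pairs, dtype=int).reshape(-1, 2)
        self._build_positions = state.positions.copy()
        return self.pairs

    def needs_rebuild(self, state: SimState) -> bool:
        if self._build_positions is None or len(self._build_positions) != state.n:
            return True
        d = state.minimum_image(state.positions - self._build_positions)
        return bool(np.linalg.norm(d, axis=1).max(initial=0.0) > self.skin / 2.0)

    def current(self, state: SimState):
        if self.needs_rebuild(state):
            self.build(state)
        return self.pairs


# ---------------------------------------------------------------------------
# Exact per-axis Ornstein-Uhlenbeck propagation

def _ou_coefficients(zeta: np.ndarray, mass: np.ndarray, dt: float,
                     temperature: float):
    """Per-axis propagator constants for one step of length dt."""
    gamma = zeta / mass
    gdt = gamma * dt
    c = np.exp(-gdt)
    tau = 1.0 / gamma
    kT = KB * temperature
    var_v = (kT / mass) * (1.0 - c ** 2)
    var_x = (kT / mass) * tau ** 2 * (2.0 * gdt - 3.0 + 4.0 * c - c ** 2)
    cov = (kT / mass) * tau * (1.0 - c) ** 2
    return c, tau, var_v, np.clip(var_x, 0.0, None), cov


def _ou_step(v, force, zeta, mass, dt, temperature, rng):
    """Advance velocity and return (v_new, displacement) per axis."""
    c, tau, var_v, var_x, cov = _ou_coefficients(zeta, mass, dt, temperature)
    drift_v = c * v + (1.0 - c) * force / zeta
    drift_x = tau * (1.0 - c) * v + (dt - tau * (1.0 - c)) * force / zeta
    if temperature > 0.0 and rng is not None:
        z1 = rng.standard_normal(v.shape)
        z2 = rng.standard_normal(v.shape)
        xi_v = np.sqrt(var_v) * z1
        resid = np.clip(var_x - cov ** 2 / np.clip(var_v, 1e-300, None), 0.0, None)
        xi_x = (cov / np.clip(var_v, 1e-300, None)) * xi_v + np.sqrt(resid) * z2
        return drift_v + xi_v, drift_x + xi_x
    return drift_v, drift_x


class Simulator:
    """Pairwise-field Langevin simulator for one molecule species."""

    def __init__(self, structure: BeadStructure, coeffs: DiffusionCoefficients,
                 fieldlike=None, r_interaction: float = None, skin: float = 1.0,
                 max_step_fraction: float = 0.25):
        self.structure = structure
        self.coeffs = coeffs
        self.field = fieldlike
        inertia = np.diag(structure.inertia_tensor()) * AMU
        self.mass = structure.total_mass * AMU
        zr = coeffs.friction_r()
        # floor degenerate inertia so the rotational OU stays overdamped
        self.inertia = np.maximum(inertia, zr * 1e-9)
        if r_interaction is None:
            span = float(np.linalg.norm(structure.bead_coords, axis=1).max())
            reach = fieldlike.interaction_range if (fieldlike is not None and
                                                    fieldlike.interaction_range) else 2.0
            r_interaction = 2.0 * span + reach
        self.neighbor_list = NeighborList(r_interaction, skin)
        self.max_step_fraction = max_step_fraction

    # -- forces ------------------------------------------------------------
    def pair_forces(self, state: SimState):
        """Lab-frame forces and body-frame torques from all pair fields."""
        n = state.n
        forces = np.zeros((n, 3))
        torques = np.zeros((n, 3))
        energy = 0.0
        if self.field is None:
            return forces, torques, energy
        pairs = self.neighbor_list.current(state)
        if len(pairs) == 0:
            return forces, torques, energy
        from mdem.field import force_torque_batch
        from mdem.structures import wrap_angle

        ii, jj = pairs[:, 0], pairs[:, 1]
        dvec = state.minimum_image(state.positions[jj] - state.positions[ii])
        rots = Rotation.from_quat(state.quaternions)
        rot_i = rots[ii]
        rot_j = rots[jj]
        rel = rot_i.inv() * rot_j
        t_rel = rot_i.inv().apply(dvec)
        angles = wrap_angle(np.atleast_2d(rel.as_euler(self.field.convention.value)))
        configs = np.hstack([t_rel, angles])
        # masked grid regions hold zero values, so the gradient vanishes
        # there anyway; skip the explicit mask interpolation for speed
        fa, ta, fb, tb, evals = force_torque_batch(self.field, configs,
                                                   check_mask=False)
        np.add.at(forces, ii, rot_i.apply(fa))
        np.add.at(forces, jj, rot_j.apply(fb))
        np.add.at(torques, ii, ta)
        np.add.at(torques, jj, tb)
        energy = float(evals.sum())
        return forces, torques, energy

    def total_energy(self, state: SimState) -> float:
        return self.pair_forces(state)[2]

    # -- stepping ----------------------------------------------------------
    def langevin_step(self, state: SimState, dt: float, rng,
                      forces=None, torques=None) -> SimState:
        """One integration step; advances the state in place."""
        if forces is None or torques is None:
            forces, torques, _ = self.pair_forces(state)
        zt = self.coeffs.friction_t()
        zr = self.coeffs.friction_r()
        rots = Rotation.from_quat(state.quaternions)
        mats = np.atleast_3d(rots.as_matrix()).reshape(state.n, 3, 3)
        noise_rng = rng if state.temperature > 0 else None
        v_body = np.einsum("nji,nj->ni", mats, state.velocities)
        f_body = np.einsum("nji,nj->ni", mats, forces)
        v_body, dx_body = _ou_step(v_body, f_body, zt[None, :],
                                   self.mass, dt, state.temperature, noise_rng)
        omega, dth = _ou_step(state.omegas, torques, zr[None, :],
                              self.inertia[None, :], dt, state.temperature,
                              noise_rng)
        dx_lab = np.einsum("nij,nj->ni", mats, dx_body)
        mob = state.mobile
        disp = np.linalg.norm(dx_lab[mob], axis=1)
        max_disp = float(disp.max()) if len(disp) else 0.0
        state.positions[mob] += dx_lab[mob]
        state.velocities[mob] = np.einsum("nij,nj->ni", mats, v_body)[mob]
        state.omegas[mob] = omega[mob]
        new_quats = (rots * Rotation.from_rotvec(dth)).as_quat().reshape(state.n, 4)
        state.quaternions[mob] = new_quats[mob]
        if max_disp > self.neighbor_list.skin / 2.0:
            raise RuntimeError(
                f"per-step displacement {max_disp:.3f} nm exceeds half the Verlet "
                "skin; reduce dt")
        # critical-step guard applies to tabulated grids only; analytic
        # fields carry stencil steps, not a resolution limit
        from mdem.field import MultiGrid, PotentialGrid

        steps = (self.field.steps if isinstance(self.field, (PotentialGrid, MultiGrid))
                 else None)
        if steps is not None:
            spatial = np.asarray(steps)[:3]
            spatial = spatial[spatial > 0]
            if len(spatial) and max_disp > self.max_step_fraction * spatial.min():
                raise RuntimeError(
                    f"per-step displacement {max_disp:.3f} nm exceeds "
                    f"{self.max_step_fraction} of the finest grid step; reduce dt")
        state.time += dt
        state.wrap()
        return state

    # -- protocols ---------------------------------------------------------
    def random_state(self, n: int, box: float, temperature: float, rng,
                     min_separation: float = None) -> SimState:
        span = float(np.linalg.norm(self.structure.bead_coords, axis=1).max())
        if min_separation is None:
            min_separation = 2.0 * span
        positions = []
        tries = 0
        while len(positions) < n:
            cand = rng.uniform(0.0, box, size=3)
            ok = True
            for p in positions:
                d = cand - p
                d -= box * np.round(d / box)
                if np.linalg.norm(d) < min_separation:
                    ok = False
                    break
            if ok:
                positions.append(cand)
            tries += 1
            if tries > 1000 * max(n, 1):
                raise RuntimeError("could not place molecules without overlap")
        quats = Rotation.random(num=n, rng=rng).as_quat().reshape(n, 4)
        return SimState(np.array(positions), quats, np.zeros((n, 3)),
                        np.zeros((n, 3)), np.full(3, float(box)),
                        temperature=temperature)

    def run(self, state: SimState, config: ProtocolConfig) -> "Trajectory":
        """Run a protocol from a prepared state, saving frames periodically."""
        rng = np.random.default_rng(config.seed)
        if config.protocol.upper() == "SP1":
            state.temperature = 0.0
        else:
            state.temperature = config.temperature
        traj = Trajectory(box=state.box.copy(), metadata={
            "protocol": config.protocol, "dt": config.dt, "seed": config.seed,
            "temperature": state.temperature,
        })
        n_steps = int(round(config.duration / config.dt))
        save_every = max(int(round(config.save_interval / config.dt)), 1)
        forces, torques, energy = self.pair_forces(state)
        traj.add_frame(state, energy)
        for step in range(1, n_steps + 1):
            self.langevin_step(state, config.dt, rng, forces, torques)
            forces, torques, energy = self.pair_forces(state)
            if step % save_every == 0 or step == n_steps:
                traj.add_frame(state, energy)
        return traj

    def run_protocol(self, config: ProtocolConfig, initial_state: SimState = None) -> "Trajectory":
        rng = np.random.default_rng(config.seed)
        coeffs = self.coeffs
        if config.viscosity_scale != 1.0:
            self.coeffs = scale_viscosity(coeffs, config.viscosity_scale)
        try:
            if initial_state is None:
                if config.protocol.upper() != "SP3":
                    raise ValueError("SP1/SP2 need an initial state")
                n = molecule_count(config.concentration, config.box,
                                   config.monomer_concentration)
                initial_state = self.random_state(n, config.box,
                                                  config.temperature, rng)
            return self.run(initial_state, config)
        finally:
            self.coeffs = coeffs


@dataclass
class Trajectory:
    """Saved frames of a run: times (ns), poses and per-frame energy."""

    box: np.ndarray = None
    times: list = dfield(default_factory=list)
    frames: list = dfield(default_factory=list)     # (n, 7): xyz + quat
    energies: list = dfield(default_factory=list)
    metadata: dict = dfield(default_factory=dict)

    def add_frame(self, state: SimState, energy: float = np.nan):
        self.times.append(state.time)
        self.frames.append(np.hstack([state.positions.copy(),
                                      state.quaternions.copy()]))
        self.energies.append(float(energy))

    @property
    def n_frames(self):
        return len(self.frames)

    def poses(self, frame: int):
        arr = self.frames[frame]
        return [Pose(arr[i, :3], arr[i, 3:]) for i in range(len(arr))]

    def save(self, path, sidecar: bool = True):
        with open(path, "w") as fh:
            for t, arr in zip(self.times, self.frames):
                fh.write(f"t={t:.9g}\n")
                for i, row in enumerate(arr):
                    x, y, z, qx, qy, qz, qw = row
                    fh.write(f"{i} {x:.6f} {y:.6f} {z:.6f} "
                             f"{qw:.9f} {qx:.9f} {qy:.9f} {qz:.9f}\n")
        if sidecar:
            meta = dict(self.metadata)
            meta["box"] = list(map(float, self.box)) if self.box is not None else None
            meta["energies"] = self.energies
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path):
        traj = cls()
        with open(path) as fh:
            current = None
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("t="):
                    if current is not None:
                        traj.frames.append(np.array(current))
                    traj.times.append(float(line[2:]))
                    current = []
                else:
                    parts = line.split()
                    _, x, y, z, qw, qx, qy, qz = parts[:8]
                    current.append([float(x), float(y), float(z),
                                    float(qx), float(qy), float(qz), float(qw)])
            if current is not None:
                traj.frames.append(np.array(current))
        import os

        if os.path.exists(str(path) + ".json"):
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
            traj.energies = meta.pop("energies", [])
            box = meta.pop("box", None)
            traj.box = np.array(box) if box else None
            traj.metadata = meta
        return traj


def free_diffusion_probe(coeffs: DiffusionCoefficients, structure: BeadStructure,
                         temperature: float, dt: float, n_steps: int,
                         seed: int = 0):
    """Recover body-frame diffusion coefficients from a free-molecule run.

    Runs the package integrator on a single interaction-free molecule and
    accumulates squared body-frame displacement and rotation increments;
    returns ``(D_t_est, D_r_est)`` in nm^2/ns and rad^2/ns as mean squared
    increment / (2 dt).
    """
    sim = Simulator(structure, coeffs, fieldlike=None, r_interaction=1.0,
                    skin=1e9)
    state = SimState(np.zeros((1, 3)), np.array([[0.0, 0.0, 0.0, 1.0]]),
                     np.zeros((1, 3)), np.zeros((1, 3)),
                     np.full(3, 1e9), temperature=temperature)
    rng = np.random.default_rng(seed)
    zt = coeffs.friction_t()
    zr = coeffs.friction_r()
    mass = np.full(3, sim.mass)
    sum_dx2 = np.zeros(3)
    sum_dth2 = np.zeros(3)
    rot = Rotation.from_quat(state.quaternions[0])
    v_body = np.zeros(3)
    omega = np.zeros(3)
    for _ in range(n_steps):
        v_body, dx_body = _ou_step(v_body, np.zeros(3), zt, mass, dt,
                                   temperature, rng)
        omega, dth = _ou_step(omega, np.zeros(3), zr, sim.inertia, dt,
                              temperature, rng)
        sum_dx2 += dx_body ** 2
        sum_dth2 += dth ** 2
        rot = rot * Rotation.from_rotvec(dth)
    d_t = sum_dx2 / (2.0 * dt * n_steps)
    d_r = sum_dth2 / (2.0 * dt * n_steps)
    return d_t, d_r


# ---------------------------------------------------------------------------
# Rotne-Prager-Yamakawa drag validation

def rpy_mobility(positions: np.ndarray, radius: float, eta: float = 1.0) -> np.ndarray:
    """3N x 3N far-field RPY mobility matrix for equal spheres."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    M = np.zeros((3 * n, 3 * n))
    self_mob = 1.0 / (6.0 * np.pi * eta * radius)
    for i in range(n):
        M[3 * i:3 * i + 3, 3 * i:3 * i + 3] = self_mob * np.eye(3)
        for j in range(i + 1, n):
            r = positions[j] - positions[i]
            d = np.linalg.norm(r)
            if d < 2.0 * radius:
                raise ValueError("overlapping spheres are not supported")
            rhat = np.outer(r, r) / d ** 2
            a2 = radius ** 2 / d ** 2
            block = (1.0 / (8.0 * np.pi * eta * d)) * (
                (1.0 + 2.0 * a2 / 3.0) * np.eye(3) + (1.0 - 2.0 * a2) * rhat
            )
            M[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
            M[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
    return M


def rpy_drag_ratios(positions, radius: float, axis, eta: float = 1.0,
                    sphere: int = 0) -> float:
    """Drag on one sphere under rigid co-motion, relative to Stokes drag.

    Builds the RPY mobility matrix, inverts it to the friction matrix,
    imposes identical unit velocity on all spheres along ``axis`` and
    returns the force component on ``sphere`` divided by ``6 pi eta R``.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    axis = np.asarray(axis, dtype=float).reshape(3)
    axis = axis / np.linalg.norm(axis)
    M = rpy_mobility(positions, radius, eta)
    Z = np.linalg.inv(M)
    v = np.tile(axis, len(positions))
    F = Z @ v
    f_axis = float(F[3 * sphere:3 * sphere + 3] @ axis)
    return f_axis / (6.0 * np.pi * eta * radius)
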