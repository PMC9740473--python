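import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mdem import synthetic
from mdem.dynamics import (
    AMU,
    KB,
    DiffusionCoefficients,
    NeighborList,
    ProtocolConfig,
    SimState,
    Simulator,
    Trajectory,
    free_diffusion_probe,
    molecule_count,
    rpy_drag_ratios,
    rpy_mobility,
    scale_viscosity,
)
from mdem.field import AnalyticField


@pytest.fixture(scope="module")
def coeffs():
    c = synthetic.hbcag_constants()
    return DiffusionCoefficients.from_table(c["D_t"], c["D_r"])


@pytest.fixture(scope="module")
def light():
    return synthetic.make_test_dimer(bead_mass=10.0)


# ---------------------------------------------------------------------------
# coefficients and viscosity

def test_table_conversion(coeffs):
    assert coeffs.d_t[0] == pytest.approx(0.08769)  # nm^2/ns
    assert coeffs.d_r[0] == pytest.approx(0.01205)  # rad^2/ns


def test_scale_viscosity_tenth(coeffs):
    scaled = scale_viscosity(coeffs, 0.1)
    assert np.allclose(scaled.d_t, coeffs.d_t * 10.0)
    assert np.allclose(scaled.d_r, coeffs.d_r * 10.0)
    assert scaled.viscosity == pytest.approx(coeffs.viscosity * 0.1)


def test_scale_viscosity_identity(coeffs):
    scaled = scale_viscosity(coeffs, 1.0)
    assert np.allclose(scaled.d_t, coeffs.d_t)


def test_scale_viscosity_composition(coeffs):
    a = scale_viscosity(scale_viscosity(coeffs, 0.5), 0.2)
    b = scale_viscosity(coeffs, 0.1)
    assert np.allclose(a.d_t, b.d_t)
    assert np.allclose(a.d_r, b.d_r)


def test_invalid_viscosity_factor(coeffs):
    with pytest.raises(ValueError):
        scale_viscosity(coeffs, 0.0)


# ---------------------------------------------------------------------------
# integrator behavior

def test_zero_temperature_pure_damping(coeffs, light):
    sim = Simulator(light, coeffs, None, r_interaction=1.0, skin=1e9)
    state = SimState(np.array([[5.0, 5, 5]]), np.array([[0, 0, 0, 1.0]]),
                     np.array([[1.0, 0, 0]]), np.zeros((1, 3)),
                     np.full(3, 1e6), temperature=0.0)
    rng = np.random.default_rng(0)
    speeds = []
    for _ in range(20):
        sim.langevin_step(state, 1e-5, rng)
        speeds.append(np.linalg.norm(state.velocities[0]))
    assert all(a >= b for a, b in zip(speeds, speeds[1:]))
    assert speeds[-1] < speeds[0]


def test_velocity_equipartition(coeffs, light):
    # free particle velocity variance per DOF -> kB T / m
    sim = Simulator(light, coeffs, None, r_interaction=1.0, skin=1e9)
    T = 293.0
    m = light.total_mass * AMU
    state = SimState(np.zeros((1, 3)), np.array([[0, 0, 0, 1.0]]),
                     np.zeros((1, 3)), np.zeros((1, 3)), np.full(3, 1e6),
                     temperature=T)
    rng = np.random.default_rng(7)
    # choose dt comparable to the momentum relaxation time so velocities decorrelate
    dt = m / (KB * T / coeffs.d_t[0])
    vs = []
    for step in range(6000):
        sim.langevin_step(state, dt, rng)
        if step > 500:
            vs.append(state.velocities[0].copy())
    vs = np.array(vs)
    expect = KB * T / m
    se = expect * np.sqrt(2.0 / len(vs)) * 3.0 + 0.05 * expect
    assert abs(vs[:, 0].var() - expect) < 3 * se


def test_diffusion_recovery_fast(coeffs, light):
    d_t, d_r = free_diffusion_probe(coeffs, light, 293.0, dt=1e-3,
                                    n_steps=60000, seed=3)
    assert np.all(np.abs(d_t / coeffs.d_t - 1.0) < 0.05)
    assert np.all(np.abs(d_r / coeffs.d_r - 1.0) < 0.05)


def test_harmonic_trap_equipartition(coeffs, light):
    k_trap = 50.0
    trap = AnalyticField(lambda q: 0.5 * k_trap * (q[:, 0] ** 2 + q[:, 1] ** 2
                                                   + q[:, 2] ** 2),
                         steps=[0.02] * 3 + [0.05] * 3)
    sim = Simulator(light, coeffs, trap, r_interaction=50.0, skin=1e9)
    state = SimState(np.array([[50.0, 50, 50], [50.2, 50, 50]]),
                     np.array([[0, 0, 0, 1.0], [0, 0, 0, 1.0]]),
                     np.zeros((2, 3)), np.zeros((2, 3)), np.full(3, 100.0),
                     temperature=293.0, mobile=np.array([False, True]))
    rng = np.random.default_rng(11)
    xs = []
    for step in range(30000):
        sim.langevin_step(state, 2e-3, rng)
        if step > 3000 and step % 10 == 0:
            xs.append((state.positions[1] - state.positions[0]).copy())
    xs = np.array(xs)
    kT = KB * 293.0
    expect = kT / k_trap
    # ~100 independent samples -> 3 sigma of the variance estimator
    tol = 3.0 * expect * np.sqrt(2.0 / 100.0)
    for axis in range(3):
        assert abs(xs[:, axis].var() - expect) < tol


def test_step_displacement_guard(coeffs, light):
    sim = Simulator(light, coeffs, None, r_interaction=1.0, skin=0.001)
    state = SimState(np.zeros((1, 3)), np.array([[0, 0, 0, 1.0]]),
                     np.array([[1000.0, 0, 0]]), np.zeros((1, 3)),
                     np.full(3, 1e6), temperature=0.0)
    with pytest.raises(RuntimeError, match="skin"):
        sim.langevin_step(state, 1e-3, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# neighbor list

def test_neighbor_list_empty_far():
    nl = NeighborList(2.0, 1.0)
    state = SimState(np.array([[0.0, 0, 0], [50.0, 0, 0]]),
                     np.tile([0, 0, 0, 1.0], (2, 1)), np.zeros((2, 3)),
                     np.zeros((2, 3)), np.full(3, 100.0))
    assert len(nl.build(state)) == 0


def test_neighbor_list_brute_force(rng):
    n = 100
    box = 20.0
    pos = rng.uniform(0, box, (n, 3))
    state = SimState(pos, np.tile([0, 0, 0, 1.0], (n, 1)), np.zeros((n, 3)),
                     np.zeros((n, 3)), np.full(3, box))
    nl = NeighborList(3.0, 1.0)
    pairs = set(map(tuple, nl.build(state)))
    expect = set()
    for i in range(n):
        for j in range(i + 1, n):
            d = state.positions[j] - state.positions[i]
            d -= box * np.round(d / box)
            if np.linalg.norm(d) < 4.0:
                expect.add((i, j))
    assert pairs == expect


def test_neighbor_list_periodic_pair():
    box = 20.0
    state = SimState(np.array([[0.5, 10, 10], [19.5, 10, 10]]),
                     np.tile([0, 0, 0, 1.0], (2, 1)), np.zeros((2, 3)),
                     np.zeros((2, 3)), np.full(3, box))
    nl = NeighborList(2.0, 0.5)
    assert len(nl.build(state)) == 1


# ---------------------------------------------------------------------------
# protocols and trajectory

def test_molecule_count_arithmetic():
    # 5 uM in a (0.2 um)^3 box -> 12 dimers
    assert molecule_count(5.0, 200.0) == 12


def test_zero_duration_initial_frame_only(coeffs, light):
    sim = Simulator(light, coeffs, None, r_interaction=2.0, skin=2.0)
    state = sim.random_state(3, 30.0, 293.0, np.random.default_rng(0))
    traj = sim.run(state, ProtocolConfig(protocol="SP2", dt=1e-3, duration=0.0,
                                         save_interval=1.0, seed=0))
    assert traj.n_frames == 1


def test_trajectory_determinism(tmp_path, coeffs, light):
    def one(path):
        sim = Simulator(light, coeffs, None, r_interaction=2.0, skin=1e9)
        state = sim.random_state(4, 30.0, 293.0, np.random.default_rng(3))
        cfg = ProtocolConfig(protocol="SP2", dt=1e-3, duration=0.05,
                             save_interval=0.01, seed=9)
        traj = sim.run(state, cfg)
        traj.save(path, sidecar=False)
        return path.read_bytes()

    assert one(tmp_path / "a.txt") == one(tmp_path / "b.txt")


def test_trajectory_round_trip(tmp_path, coeffs, light):
    sim = Simulator(light, coeffs, None, r_interaction=2.0, skin=1e9)
    state = sim.random_state(3, 30.0, 293.0, np.random.default_rng(3))
    traj = sim.run(state, ProtocolConfig(protocol="SP2", dt=1e-3, duration=0.02,
                                         save_interval=0.01, seed=1))
    path = tmp_path / "t.txt"
    traj.save(path)
    back = Trajectory.load(path)
    assert back.n_frames == traj.n_frames
    assert np.allclose(back.frames[-1], traj.frames[-1], atol=1e-6)
    assert np.allclose(back.box, traj.box)


def test_sp3_placement_respects_separation(coeffs, light):
    sim = Simulator(light, coeffs, None, r_interaction=2.0, skin=2.0)
    state = sim.random_state(10, 25.0, 293.0, np.random.default_rng(0),
                             min_separation=4.0)
    from scipy.spatial.distance import pdist

    d = pdist(state.positions)
    assert d.min() >= 3.0  # minimum image can shorten slightly at the boundary


# ---------------------------------------------------------------------------
# RPY drag

def test_rpy_single_sphere():
    assert rpy_drag_ratios(np.zeros((1, 3)), 1.0, [1, 0, 0]) == pytest.approx(1.0)


def test_rpy_two_sphere_closed_form():
    r = 3.0
    pos = np.array([[0.0, 0, 0], [r, 0, 0]])
    ratio = rpy_drag_ratios(pos, 1.0, [1, 0, 0])
    # closed-form 2x2 pair inversion along the line of centers
    a = 1.0 / (6 * np.pi)
    b = (1.0 / (8 * np.pi * r)) * ((1 + 2 / (3 * r ** 2)) + (1 - 2 / r ** 2))
    expect = np.linalg.inv([[a, b], [b, a]]).sum(axis=1)[0] / (6 * np.pi)
    assert ratio == pytest.approx(expect, abs=1e-12)


def test_rpy_overlap_error():
    pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
    with pytest.raises(ValueError, match="overlap"):
        rpy_mobility(pos, 1.0)


def test_rpy_mobility_symmetric_positive(rng):
    pos = rng.uniform(0, 10, (4, 3))
    pos[1:] += 5.0 * np.arange(1, 4)[:, None]  # keep apart
    M = rpy_mobility(pos, 1.0)
    assert np.allclose(M, M.T)
    assert np.linalg.eigvalsh(M).min() > 0
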