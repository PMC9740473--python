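import numpy as np
import pytest

from mdem.field import (
    AnalyticField,
    CollisionParams,
    EmpiricalBindingSpec,
    GridAxis,
    MultiGrid,
    PotentialGrid,
    build_grid,
    collision_penalty,
    correct_overlap,
    force_torque,
    force_torque_batch,
    insert_empirical,
    load_field,
    read_field_version,
    save_field,
)
from mdem.kriging import KrigingEngine, fit_pair_models
from mdem.structures import Configuration
from mdem.synthetic import make_point_structure, make_test_dimer
from mdem.trend_variogram import SampleSet, TrendModel, VariogramModel


def spatial_axes(extent=2.0, step=0.5):
    ax = GridAxis(-extent, extent, step)
    return [ax, ax, ax, GridAxis.fixed(), GridAxis.fixed(), GridAxis.fixed()]


def line_engine(xs, values):
    s = SampleSet(make_point_structure(), ["A-B"])
    configs = np.zeros((len(xs), 6))
    configs[:, 0] = xs
    s.append(configs, np.abs(np.asarray(xs, dtype=float)), {"A-B": values})
    trend = TrendModel("A-B", "constant", np.array([0.0]), 0.0, (0, 10))
    vg = VariogramModel("A-B", "exponential", 0.0, 1.0, 1.0)
    return KrigingEngine(s, {"A-B": trend}, {"A-B": [vg]}, [(0, 10)], 10.0, ["A-B"])


# ---------------------------------------------------------------------------
# axes and interpolation

def test_angle_axis_covers_full_turn():
    ax = GridAxis.angle(2 * np.pi / 5)
    assert ax.n == 5
    assert ax.n * ax.step == pytest.approx(2 * np.pi)
    assert ax.nodes[-1] == pytest.approx(np.pi)


def test_periodic_wrap_continuity(rng):
    axes = [GridAxis(-1, 1, 1.0)] * 3 + [GridAxis.angle(2 * np.pi / 6)] * 3
    g = PotentialGrid(axes)
    g.values = rng.normal(size=g.shape)
    a = g.value_many(np.array([[0, 0, 0, -np.pi + 0.05, 0.2, 0.1]]))[0]
    b = g.value_many(np.array([[0, 0, 0, np.pi + 0.05, 0.2, 0.1]]))[0]
    assert a == pytest.approx(b, abs=1e-12)


def test_value_at_node_exact(rng):
    g = PotentialGrid(spatial_axes())
    g.values = rng.normal(size=g.shape)
    nodes = g.node_configs()
    k = 17
    assert g.value_many(nodes[k:k + 1])[0] == pytest.approx(g.values.ravel()[k])


def test_multilinear_reproduces_linear_field():
    g = PotentialGrid(spatial_axes())
    nodes = g.node_configs()
    g.values = (2.0 * nodes[:, 0] - 0.5 * nodes[:, 1]).reshape(g.shape)
    q = np.array([[0.13, -0.77, 0.41, 0, 0, 0]])
    assert g.value_many(q)[0] == pytest.approx(2.0 * 0.13 + 0.5 * 0.77, abs=1e-12)


def test_outside_extent_zero():
    g = PotentialGrid(spatial_axes())
    g.values = np.ones(g.shape)
    assert g.value_many(np.array([[5.0, 0, 0, 0, 0, 0]]))[0] == 0.0


# ---------------------------------------------------------------------------
# forces and torques

def test_flat_field_zero_force():
    f = AnalyticField(lambda q: np.full(len(q), 7.0), steps=[0.1] * 6)
    ft_a, ft_b = force_torque(f, Configuration(1, 0, 0, 0.2, 0, 0))
    assert np.allclose(ft_a.force, 0.0, atol=1e-10)
    assert np.allclose(ft_b.torque, 0.0, atol=1e-10)


def test_quadratic_field_force():
    k = 2.5
    f = AnalyticField(lambda q: k * q[:, 0] ** 2, steps=[0.01] * 6)
    cfg = Configuration(1.2, 0, 0, 0, 0, 0)
    ft_a, ft_b = force_torque(f, cfg)
    # force on B along -x (A frame == B frame here)
    assert ft_b.force[0] == pytest.approx(-2 * k * 1.2, rel=1e-4)
    assert ft_a.force[0] == pytest.approx(2 * k * 1.2, rel=1e-4)


def test_rotation_invariant_field_zero_torque():
    f = AnalyticField(lambda q: np.linalg.norm(q[:, :3], axis=1) ** 2, steps=[0.02] * 6)
    cfg = Configuration(1.0, 0.5, -0.3, 0.4, 0.2, -0.1)
    _, ft_b = force_torque(f, cfg)
    assert np.linalg.norm(ft_b.torque) < 1e-8


def test_newton_consistency(rng):
    def fn(q):
        return (np.sin(q[:, 0]) + 0.5 * q[:, 1] ** 2 + np.cos(q[:, 3])
                + 0.3 * q[:, 2] * np.sin(q[:, 4]))

    f = AnalyticField(fn, steps=[0.01] * 3 + [0.01] * 3)
    from mdem.structures import euler_to_rotation

    for _ in range(5):
        arr = np.concatenate([rng.uniform(-1, 1, 3), rng.uniform(-1, 1, 3)])
        cfg = Configuration.from_array(arr)
        ft_a, ft_b = force_torque(f, cfg)
        rot = euler_to_rotation(arr[3:6], cfg.convention)
        f_b_lab = rot.apply(ft_b.force)  # B body -> A frame
        assert np.allclose(ft_a.force + f_b_lab, 0.0, atol=1e-9)
        # torque balance about A's origin (all in A frame)
        t_b_in_a = rot.apply(ft_b.torque)
        total = ft_a.torque + t_b_in_a + np.cross(arr[:3], f_b_lab)
        assert np.allclose(total, 0.0, atol=1e-9)


def test_energy_consistency_along_path():
    k = 1.7
    f = AnalyticField(lambda q: k * (q[:, 0] ** 2 + q[:, 1] ** 2), steps=[0.02] * 6)
    xs = np.linspace(0.5, 1.5, 101)
    work = 0.0
    for x0, x1 in zip(xs[:-1], xs[1:]):
        xm = 0.5 * (x0 + x1)
        _, ft_b = force_torque(f, Configuration(xm, 0, 0, 0, 0, 0))
        work += ft_b.force[0] * (x1 - x0)
    du = k * (1.5 ** 2 - 0.5 ** 2)
    assert work == pytest.approx(-du, rel=1e-3)


def test_masked_region_zero_force():
    g = PotentialGrid(spatial_axes())
    g.values = np.ones(g.shape) * 3.0
    g.mask = np.ones(g.shape, dtype=bool)
    ft_a, ft_b = force_torque(g, Configuration(0.2, 0.1, 0, 0, 0, 0))
    assert np.allclose(ft_a.force, 0.0)
    assert np.allclose(ft_b.torque, 0.0)


def test_batch_matches_scalar(rng):
    f = AnalyticField(lambda q: np.sin(q[:, 0]) * np.cos(q[:, 4]), steps=[0.01] * 6)
    configs = np.column_stack([rng.uniform(-1, 1, (4, 3)), rng.uniform(-1, 1, (4, 3))])
    fa, ta, fb, tb, en = force_torque_batch(f, configs)
    for k in range(4):
        ft_a, ft_b = force_torque(f, Configuration.from_array(configs[k]))
        assert np.allclose(fa[k], ft_a.force, atol=1e-12)
        assert np.allclose(tb[k], ft_b.torque, atol=1e-12)


# ---------------------------------------------------------------------------
# grid building

def test_build_grid_counts_and_mask():
    eng = line_engine([0.5, 1.0, 1.5], [1.0, 2.0, 3.0])
    axes = [GridAxis(-1, 1, 2.0)] * 3 + [GridAxis.fixed()] * 3
    eng.interaction_range = 100.0
    g = build_grid(eng, axes, n_pot=3)
    assert g.values.size == 8


def test_build_grid_masks_beyond_range():
    eng = line_engine([0.5, 1.0], [1.0, 2.0])
    eng.interaction_range = 1.2
    axes = [GridAxis(0, 3, 1.0), GridAxis.fixed(), GridAxis.fixed(),
            GridAxis.fixed(), GridAxis.fixed(), GridAxis.fixed()]
    g = build_grid(eng, axes, n_pot=2)
    vals = g.values.ravel()
    mask = g.mask.ravel()
    assert mask[-1]  # x=3 beyond range
    assert vals[-1] == 0.0


def test_build_grid_memory_cap():
    eng = line_engine([0.5], [1.0])
    axes = [GridAxis(-10, 10, 0.1)] * 3 + [GridAxis.fixed()] * 3
    with pytest.raises(MemoryError):
        build_grid(eng, axes, memory_cap=1000)


# ---------------------------------------------------------------------------
# collision model

def test_collision_penalty_zero_when_apart(dimer):
    s = SampleSet(dimer, ["A-B"])
    params = CollisionParams(k_coll=10.0, d_flex=0.5)
    c = Configuration(20.0, 0, 0, 0, 0, 0)
    assert collision_penalty(dimer, dimer, c, s, params) == 0.0


def test_collision_penalty_trusted_at_data(dimer):
    s = SampleSet(dimer, ["A-B"])
    c = Configuration(0.0, 0, 0, 0, 0, 0)
    from mdem.descriptors import min_distance

    s.append(c.to_array()[None], min_distance(dimer, dimer, c), {"A-B": 0.0})
    params = CollisionParams(k_coll=10.0, d_flex=0.5)
    # the colliding configuration coincides with a datum -> ramp = 0
    assert collision_penalty(dimer, dimer, c, s, params) == 0.0


def test_collision_penalty_monotone_in_overlap(dimer):
    s = SampleSet(dimer, ["A-B"])  # empty set -> ramp = 1 everywhere
    params = CollisionParams(k_coll=5.0, d_flex=0.5)
    pens = [collision_penalty(dimer, dimer, Configuration(x, 0, 0, 0, 0, 0), s, params)
            for x in (0.0, 1.0, 3.0, 10.0)]
    assert all(a >= b for a, b in zip(pens, pens[1:]))
    assert pens[0] > 0


# ---------------------------------------------------------------------------
# empirical insertion

@pytest.fixture(scope="module")
def toy_insertion():
    dimer = make_test_dimer(scale=0.818)
    s = SampleSet(dimer, ["A-B"])
    site = Configuration(4.0, 0, 0, 0, 0, 0)
    spec = EmpiricalBindingSpec([site], -1400.0, -1000.0, 1.0)
    n = insert_empirical(s, spec, dimer, dimer, component="A-B")
    return dimer, s, site, spec, n

def test_insertion_counts_and_provenance(toy_insertion):
    _, s, site, spec, n = toy_insertion
    assert n == len(s)
    assert n > 10
    assert all(p == "virtual" for p in s.provenance)


def test_insertion_respects_r_bind(toy_insertion):
    dimer, s, site, spec, _ = toy_insertion
    from mdem.descriptors import config_distance

    for k in range(len(s)):
        c = Configuration.from_array(s.configs[k])
        assert config_distance(site, c, dimer) <= spec.r_bind + 1e-9


def test_insertion_center_value(toy_insertion):
    _, s, site, _, _ = toy_insertion
    center_rows = np.flatnonzero(
        np.linalg.norm(s.configs - site.to_array(), axis=1) < 1e-9)
    assert len(center_rows) >= 1
    assert np.allclose(s.potentials["A-B"][center_rows], -1400.0)


def test_insertion_well_profile(toy_insertion):
    _, _, _, spec, _ = toy_insertion
    assert spec.well(0.0) == pytest.approx(-1400.0)
    assert spec.well(spec.r_bind) == pytest.approx(
        -1000.0 + (-400.0) * np.exp(-2.0), rel=1e-6)


def test_insertion_infeasible_binding_error():
    dimer = make_test_dimer()
    s = SampleSet(dimer, ["A-B"])
    spec = EmpiricalBindingSpec([Configuration(0, 0, 0, 0, 0, 0)],
                                -1400.0, -1000.0, 1.0, max_extra_collisions=0)
    # collision distance larger than the reachable search window: the
    # overlap cannot be corrected
    with pytest.raises((ValueError, RuntimeError)):
        insert_empirical(s, spec, dimer, dimer, component="A-B", d_coll=50.0)


def test_correct_overlap_noop_when_clear():
    dimer = make_test_dimer()
    c = Configuration(20.0, 0, 0, 0, 0, 0)
    assert correct_overlap(c, dimer, dimer) is c


def test_correct_overlap_moves_out():
    dimer = make_test_dimer()
    c = Configuration(0.5, 0, 0, 0, 0, 0)
    fixed = correct_overlap(c, dimer, dimer)
    from mdem.descriptors import count_collisions

    assert count_collisions(dimer, dimer, fixed, 0.4) == 0


# ---------------------------------------------------------------------------
# binary format

def test_field_round_trip(tmp_path, rng):
    axes = [GridAxis(-1, 1, 0.5)] * 3 + [GridAxis.angle(2 * np.pi / 4)] * 3
    g = PotentialGrid(axes, species=("mol", "mol"), components=("A-B", "solvent"))
    g.values = rng.normal(size=g.shape).astype(np.float32).astype(float)
    g.variance = np.abs(rng.normal(size=g.shape)).astype(np.float32).astype(float)
    g.mask = rng.random(g.shape) < 0.3
    path = tmp_path / "f.mdemfld"
    save_field(g, path)
    back = load_field(path)
    assert np.array_equal(back.values, g.values)
    assert np.array_equal(back.variance, g.variance)
    assert np.array_equal(back.mask, g.mask)
    assert back.species == g.species
    assert back.components == g.components
    for a, b in zip(back.axes, g.axes):
        assert a.n == b.n and a.periodic == b.periodic


def test_field_version_readable_without_payload(tmp_path, rng):
    g = PotentialGrid([GridAxis(-1, 1, 1.0)] * 3 + [GridAxis.fixed()] * 3)
    path = tmp_path / "f.mdemfld"
    save_field(g, path)
    assert read_field_version(path) == 1


def test_field_truncated_error(tmp_path):
    g = PotentialGrid([GridAxis(-1, 1, 1.0)] * 3 + [GridAxis.fixed()] * 3)
    path = tmp_path / "f.mdemfld"
    save_field(g, path)
    data = path.read_bytes()
    path.write_bytes(data[: len(data) // 2])
    with pytest.raises(ValueError, match="truncated"):
        load_field(path)


def test_field_bad_magic(tmp_path):
    path = tmp_path / "junk.mdemfld"
    path.write_bytes(b"NOTAFIELDXXXX")
    with pytest.raises(ValueError, match="magic"):
        load_field(path)


# ---------------------------------------------------------------------------
# multigrid

def test_multigrid_prefers_fine():
    coarse = PotentialGrid(spatial_axes(4.0, 2.0))
    coarse.values = np.ones(coarse.shape)
    fine = PotentialGrid(spatial_axes(1.0, 0.5))
    fine.values = np.full(fine.shape, 5.0)
    mg = MultiGrid(fine, coarse)
    assert mg.value_many(np.array([[0.2, 0, 0, 0, 0, 0]]))[0] == pytest.approx(5.0)
    assert mg.value_many(np.array([[3.0, 0, 0, 0, 0, 0]]))[0] == pytest.approx(1.0)
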