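import numpy as np
import pytest

from mdem.analysis import (
    ContactRecord,
    classify_contacts,
    find_structures,
    fit_kinetics,
    global_stats,
    lifetimes,
    size_class,
    stability_objective,
    transitions,
    StructureRecord,
)
from mdem.structures import Configuration, Pose
from mdem.synthetic import make_test_dimer


@pytest.fixture(scope="module")
def dimer_s():
    return make_test_dimer()


@pytest.fixture(scope="module")
def binding():
    return [Configuration(4.8, 0, 0, 0, 0, 0), Configuration(-4.8, 0, 0, 0, 0, 0)]


def pose(x, y=0.0, z=0.0):
    return Pose(np.array([x, y, z]), np.array([0, 0, 0, 1.0]))


# ---------------------------------------------------------------------------
# contact classification

def test_far_pair_no_record(dimer_s, binding):
    records = classify_contacts([pose(0), pose(30.0)], dimer_s, binding)
    assert records == []


def test_structured_contact_with_offset(dimer_s, binding):
    records = classify_contacts([pose(0), pose(5.3)], dimer_s, binding)
    assert len(records) == 1
    assert records[0].kind == "structured"
    assert records[0].delta_r == pytest.approx(0.5, abs=1e-6)


def test_classification_symmetric_in_order(dimer_s, binding):
    a = classify_contacts([pose(0), pose(5.3)], dimer_s, binding)
    b = classify_contacts([pose(5.3), pose(0)], dimer_s, binding)
    assert a[0].kind == b[0].kind
    assert a[0].delta_r == pytest.approx(b[0].delta_r, abs=1e-9)


def test_unstructured_touching_pair(dimer_s, binding):
    # side-by-side along y: touching but far from binding geometry in delta_r
    from scipy.optimize import brentq

    from mdem.descriptors import min_distance

    def gap(d):
        return min_distance(dimer_s, dimer_s, Configuration(0, d, 0, 0, 0, 0)) - 0.25

    d_touch = brentq(gap, 0.05, 10.0)
    records = classify_contacts([pose(0), pose(0, d_touch)], dimer_s, binding)
    assert len(records) == 1
    assert records[0].kind == "unstructured"
    assert records[0].delta_m <= 0.3


# ---------------------------------------------------------------------------
# structures

def test_no_contacts_singletons():
    recs = find_structures([], 10)
    assert len(recs) == 10
    assert all(r.n_sas == 1 for r in recs)
    assert sum(r.n_sas for r in recs) == 10


def test_chain_component():
    contacts = [ContactRecord(0, 1, "structured", 0, 0.1, 0.2),
                ContactRecord(1, 2, "structured", 0, 0.1, 0.2)]
    recs = find_structures(contacts, 4)
    sizes = sorted(r.n_sas for r in recs)
    assert sizes == [1, 3]


def test_components_vs_networkx(rng):
    import networkx as nx

    n = 40
    edges = [(int(a), int(b)) for a, b in rng.integers(0, n, (30, 2)) if a != b]
    contacts = [ContactRecord(a, b, "structured", 0, 0.1, 0.2) for a, b in edges]
    recs = find_structures(contacts, n)
    mine = {frozenset(r.members) for r in recs}
    g = nx.Graph(edges)
    g.add_nodes_from(range(n))
    theirs = {frozenset(c) for c in nx.connected_components(g)}
    assert mine == theirs


def test_gyration_diameter_unwrapped():
    # two molecules straddling the periodic boundary
    contacts = [ContactRecord(0, 1, "structured", 0, 0.1, 0.2)]
    positions = np.array([[0.5, 0, 0], [19.5, 0, 0]])
    recs = find_structures(contacts, 2, positions, box=np.full(3, 20.0))
    big = [r for r in recs if r.n_sas == 2][0]
    # true separation is 1.0 via the boundary -> d_gyr = 2 * 0.5
    assert big.d_sas_gyr == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# stats

def test_global_stats_single_pair():
    contacts = [ContactRecord(0, 1, "structured", 0, 0.1, 0.2)]
    stats = global_stats(contacts, 2)
    assert stats.xi_struc == pytest.approx(1.0)
    assert stats.xi_unstruc == 0.0
    assert stats.phi_struc == pytest.approx(1.0)


def test_global_stats_no_contacts_nan_phi():
    stats = global_stats([], 5)
    assert stats.xi_struc == 0.0
    assert np.isnan(stats.phi_struc)


def test_global_stats_capsid(capsid):
    from mdem import synthetic
    from mdem.analysis import classify_contacts

    struct = synthetic.fixture_structure()
    bconfigs = synthetic.binding_configurations(capsid.convention)
    contacts = classify_contacts(capsid.poses, struct, bconfigs)
    stats = global_stats(contacts, capsid.n_poses)
    assert stats.xi_struc == pytest.approx(4.0)
    assert stats.xi_unstruc == 0.0


# ---------------------------------------------------------------------------
# size classes

@pytest.mark.parametrize("n,expect", [
    (1, 1), (5, 5), (6, 10), (7, 10), (15, 10), (16, 20), (25, 20), (26, 30),
    (96, 100), (105, 100), (106, 110), (200, 200), (205, 200), (206, 206),
    (500, 206),
])
def test_size_class_examples(n, expect):
    assert size_class(n) == expect


def test_size_class_partitions_integers():
    for n in range(1, 400):
        c = size_class(n)
        if n <= 5:
            assert c == n
        elif n >= 206:
            assert c == 206
        else:
            assert c - 4 <= n <= c + 5


# ---------------------------------------------------------------------------
# transitions

def frame(sizes_by_member):
    """Build StructureRecords from a list of member tuples."""
    return [StructureRecord(i, tuple(m), len(m), 0.0)
            for i, m in enumerate(sizes_by_member)]


def test_transitions_static_zero():
    frames = [frame([(0, 1), (2,)]), frame([(0, 1), (2,)])]
    classes, gross, net, signed = transitions(frames, 3)
    assert gross.sum() == 0.0


def test_transitions_join_counts():
    # dimer 2 joins pair {0,1}: 2 goes 1->3, 0 and 1 go 2->3
    frames = [frame([(0, 1), (2,)]), frame([(0, 1, 2)])]
    classes, gross, net, signed = transitions(frames, 3)
    i1, i2, i3 = classes.index(1), classes.index(2), classes.index(3)
    assert gross[i1, i3] == pytest.approx(1 / 3)
    assert gross[i2, i3] == pytest.approx(2 / 3)
    assert net[i3, i1] == pytest.approx(1 / 3)  # symmetric sum
    assert signed[i1, i3] == pytest.approx(1 / 3)


def test_transitions_requires_two_frames():
    with pytest.raises(ValueError):
        transitions([frame([(0,)])], 1)


# ---------------------------------------------------------------------------
# lifetimes

def test_lifetime_whole_run_censored():
    frames = [frame([(0, 1)])] * 5
    recs = lifetimes(frames, [0.0, 1.0, 2.0, 3.0, 4.0])
    assert len(recs) == 1
    assert recs[0].birth_time == 0.0
    assert recs[0].death_time == 4.0


def test_lifetime_finite_interval():
    frames = ([frame([(0,), (1,)])] * 3 + [frame([(0, 1)])] * 5
              + [frame([(0,), (1,)])] * 2)
    times = list(np.arange(10.0))
    recs = lifetimes(frames, times)
    pair = [r for r in recs if r.n_sas == 2]
    assert len(pair) == 1
    # exists in frames 3..7 -> four saving intervals
    assert pair[0].death_time - pair[0].birth_time == pytest.approx(4.0)


def test_lifetime_merge_keeps_larger_parent():
    frames = [frame([(0, 1, 2), (3, 4)]), frame([(0, 1, 2, 3, 4)])]
    recs = lifetimes(frames, [0.0, 1.0])
    # the smaller parent's lifetime ends (last seen at t=0); the larger
    # parent's identity continues into the merged structure
    ended = [r for r in recs if r.n_sas == 2]
    assert len(ended) == 1
    assert ended[0].death_time == 0.0
    survivor = [r for r in recs if r.n_sas == 5]
    assert len(survivor) == 1
    assert survivor[0].birth_time == 0.0


# ---------------------------------------------------------------------------
# kinetics

def test_kinetics_exact_recovery():
    t = np.linspace(0, 5, 60)
    y = 100.0 + (1.0 - 100.0) * np.exp(-t / 0.5)
    fit = fit_kinetics(t, y)
    assert fit.asymptote == pytest.approx(100.0, abs=1e-6)
    assert fit.time_constant == pytest.approx(0.5, abs=1e-6)


def test_kinetics_constant_series():
    fit = fit_kinetics([0, 1, 2, 3], [7.0, 7.0, 7.0, 7.0])
    assert fit.degenerate
    assert fit.asymptote == 7.0
    assert np.isinf(fit.time_constant)


def test_kinetics_noisy_recovery():
    rng = np.random.default_rng(0)
    oks = 0
    for seed in range(6):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 4, 50)
        y = 100.0 + (5.0 - 100.0) * np.exp(-t / 0.8) + rng.normal(0, 2.0, 50)
        fit = fit_kinetics(t, y)
        if abs(fit.asymptote - 100) / 100 < 0.05 and abs(fit.time_constant - 0.8) / 0.8 < 0.15:
            oks += 1
    assert oks >= 5


# ---------------------------------------------------------------------------
# stability objective

def ref_contacts(n):
    return [ContactRecord(i, i + 1, "structured", 0, 0.1, 0.2) for i in range(n)]


def test_stability_untouched():
    ref = ref_contacts(20)
    assert stability_objective(ref, ref).value == 1.0


def test_stability_dissociated():
    ref = ref_contacts(20)
    assert stability_objective([], ref).value == 0.0


def test_stability_fraction():
    ref = ref_contacts(20)
    now = ref[:18]
    assert stability_objective(now, ref).value == pytest.approx(0.9)
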