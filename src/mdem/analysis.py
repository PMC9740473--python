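"""Assembly postprocessing: contacts, structures, kinetics, transitions.

Contacts between molecule pairs are classified as structured (within
delta_r of 1 nm from a known binding configuration) or unstructured
(touching, delta_m <= 0.3 nm, but away from binding geometry).  Connected
components over all contacts form self-assembled structures whose size,
extent, transitions and lifetimes are tracked over a trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from mdem.descriptors import (
    config_distance_matrix,
    min_distance,
    placed_cloud,
)
from mdem.structures import BeadStructure, Configuration, Pose, relative_config

__all__ = [
    "AssemblyStats",
    "ContactRecord",
    "KineticsFit",
    "StabilityObjective",
    "StructureRecord",
    "classify_contacts",
    "find_structures",
    "fit_kinetics",
    "global_stats",
    "lifetimes",
    "size_class",
    "stability_objective",
    "transitions",
]

STRUCTURED_DR = 1.0     # nm
UNSTRUCTURED_DM = 0.3   # nm


@dataclass(frozen=True)
class ContactRecord:
    i: int
    j: int
    kind: str               # "structured" | "unstructured"
    best_binding: int
    delta_r: float
    delta_m: float


@dataclass
class StructureRecord:
    structure_id: int
    members: tuple
    n_sas: int
    d_sas_gyr: float
    birth_time: float = np.nan
    death_time: float = np.nan


@dataclass
class AssemblyStats:
    xi_struc: float
    xi_unstruc: float
    phi_struc: float


@dataclass
class KineticsFit:
    asymptote: float        # N_SAS at t -> inf
    time_constant: float
    initial_value: float
    residual: float
    degenerate: bool = False


@dataclass
class StabilityObjective:
    value: float
    definition: str = "surrogate"


def _symmetrized_binding_clouds(binding_configs, struct_b: BeadStructure):
    configs = []
    for c in binding_configs:
        configs.append(c.to_array())
        configs.append(c.inverse().to_array())
    arr = np.array(configs)
    conv = binding_configs[0].convention
    return placed_cloud(struct_b, arr, conv), conv


def classify_contacts(poses, struct_b: BeadStructure, binding_configs,
                      box=None, cutoff: float = None,
                      structured_dr: float = STRUCTURED_DR,
                      unstructured_dm: float = UNSTRUCTURED_DM):
    """Classify all candidate molecule pairs of one frame.

    ``poses`` is a list of :class:`Pose`; ``binding_configs`` the known
    binding configurations (both orderings are generated internally, and
    both pair orderings evaluated, so classification is symmetric).
    """
    bclouds, conv = _symmetrized_binding_clouds(binding_configs, struct_b)
    if cutoff is None:
        span = float(np.linalg.norm(struct_b.backbone_coords, axis=1).max())
        reach = max(np.linalg.norm(c.to_array()[:3]) for c in binding_configs)
        cutoff = reach + 2.0 * span
    positions = np.array([p.translation for p in poses])
    box_arr = None if box is None else np.asarray(box, dtype=float)
    records = []
    n = len(poses)
    for i in range(n):
        for j in range(i + 1, n):
            d = positions[j] - positions[i]
            if box_arr is not None:
                d = d - box_arr * np.round(d / box_arr)
            if np.linalg.norm(d) > cutoff:
                continue
            pose_j = Pose(positions[i] + d, poses[j].quaternion)
            cfg_ij = relative_config(poses[i], pose_j, conv)
            cfg_ji = relative_config(pose_j, poses[i], conv)
            q = placed_cloud(struct_b, np.array([cfg_ij.to_array(),
                                                 cfg_ji.to_array()]), conv)
            dr = config_distance_matrix(q, bclouds)
            best = int(np.unravel_index(np.argmin(dr), dr.shape)[1])
            dr_min = float(dr.min())
            if dr_min <= structured_dr:
                dm = min_distance(struct_b, struct_b, cfg_ij)
                records.append(ContactRecord(i, j, "structured", best, dr_min, dm))
            else:
                dm = min_distance(struct_b, struct_b, cfg_ij)
                if dm <= unstructured_dm:
                    records.append(ContactRecord(i, j, "unstructured", best,
                                                 dr_min, dm))
    return records


def _components(contacts, n_molecules: int):
    parent = list(range(n_molecules))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for c in contacts:
        ra, rb = find(c.i), find(c.j)
        if ra != rb:
            parent[rb] = ra
    groups = {}
    for m in range(n_molecules):
        groups.setdefault(find(m), []).append(m)
    return list(groups.values())


def find_structures(contacts, n_molecules: int, positions=None, box=None):
    """Connected components over all contacts with size and extent.

    ``d_SAS_gyr`` is twice the RMS distance of member centers from the
    component centroid, computed on minimum-image-unwrapped coordinates
    (members are unwrapped by BFS over the contact graph).
    """
    comps = _components(contacts, n_molecules)
    adj = {}
    for c in contacts:
        adj.setdefault(c.i, []).append(c.j)
        adj.setdefault(c.j, []).append(c.i)
    records = []
    box_arr = None if box is None else np.asarray(box, dtype=float)
    for sid, members in enumerate(sorted(comps, key=min)):
        d_gyr = 0.0
        if positions is not None and len(members) > 1:
            unwrapped = {members[0]: np.asarray(positions[members[0]], dtype=float)}
            queue = [members[0]]
            while queue:
                a = queue.pop()
                for b in adj.get(a, ()):
                    if b in unwrapped:
                        continue
                    d = np.asarray(positions[b], dtype=float) - np.asarray(positions[a], dtype=float)
                    if box_arr is not None:
                        d = d - box_arr * np.round(d / box_arr)
                    unwrapped[b] = unwrapped[a] + d
                    queue.append(b)
            pts = np.array([unwrapped.get(m, positions[m]) for m in members])
            centroid = pts.mean(axis=0)
            d_gyr = 2.0 * float(np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1))))
        records.append(StructureRecord(sid, tuple(sorted(members)),
                                       len(members), d_gyr))
    return records


def global_stats(contacts, n_molecules: int) -> AssemblyStats:
    """Average structured/unstructured connections per molecule and the
    structured fraction (NaN when there are no contacts at all)."""
    ns = sum(1 for c in contacts if c.kind == "structured")
    nu = sum(1 for c in contacts if c.kind == "unstructured")
    xi_s = 2.0 * ns / n_molecules if n_molecules else 0.0
    xi_u = 2.0 * nu / n_molecules if n_molecules else 0.0
    phi = xi_s / (xi_s + xi_u) if (xi_s + xi_u) > 0 else np.nan
    return AssemblyStats(xi_s, xi_u, phi)


SIZE_CLASSES = tuple([1, 2, 3, 4, 5] + list(range(10, 201, 10)) + [206])


def size_class(n: int) -> int:
    """Structure-size class: 1-5 individually, then decades (class c covers
    c-4..c+5), everything >= 206 in the top class."""
    if n < 1:
        raise ValueError("size must be >= 1")
    if n <= 5:
        return int(n)
    if n >= 206:
        return 206
    return min(10 * ((n + 4) // 10), 200)


def transitions(frames_structures, n_molecules: int):
    """Per-molecule size-class transition matrices over consecutive frames.

    Returns ``(classes, gross, net, signed)`` where ``gross[a, b]`` counts
    molecules moving from class a to class b (diagonal excluded),
    normalised by the molecule count; ``net`` is the both-direction sum
    ``gross + gross.T`` and ``signed`` the difference.
    """
    if len(frames_structures) < 2:
        raise ValueError("need at least two frames")
    classes = list(SIZE_CLASSES)
    index = {c: k for k, c in enumerate(classes)}
    gross = np.zeros((len(classes), len(classes)))
    prev = None
    for structures in frames_structures:
        sizes = np.zeros(n_molecules, dtype=int)
        for s in structures:
            for m in s.members:
                sizes[m] = s.n_sas
        cls = np.array([index[size_class(max(int(v), 1))] for v in sizes])
        if prev is not None:
            for a, b in zip(prev, cls):
                if a != b:
                    gross[a, b] += 1
        prev = cls
    gross /= max(n_molecules, 1)
    return classes, gross, gross + gross.T, gross - gross.T


def lifetimes(frames_structures, times, min_size: int = 2):
    """Track structure identities and return completed/censored lifetimes.

    Only structures with at least ``min_size`` members are tracked.
    Identity follows the previous structure with the largest member
    overlap when that overlap exceeds half of its size (so the larger
    parent survives a merge).  ``death_time`` is the last frame time at
    which the structure existed (equal to the final frame time for
    censored structures), so the lifetime of a structure seen in frames
    3..7 is four saving intervals.
    """
    next_id = 0
    live = {}       # id -> (members set, birth, last_seen)
    finished = []
    for t, structures in zip(times, frames_structures):
        new_assign = {}
        claimed = set()
        for s in sorted(structures, key=lambda s: -s.n_sas):
            if s.n_sas < min_size:
                continue
            members = set(s.members)
            best_id, best_ov = None, 0
            for sid, (pm, _, _) in live.items():
                if sid in claimed:
                    continue
                ov = len(members & pm)
                if ov > best_ov:
                    best_id, best_ov = sid, ov
            if best_id is not None and best_ov > 0.5 * len(live[best_id][0]):
                new_assign[best_id] = (members, live[best_id][1], t)
                claimed.add(best_id)
            else:
                new_assign[next_id] = (members, t, t)
                next_id += 1
        for sid, (pm, birth, last_seen) in live.items():
            if sid not in new_assign:
                finished.append(StructureRecord(sid, tuple(sorted(pm)), len(pm),
                                                0.0, birth, last_seen))
        live = new_assign
    for sid, (pm, birth, last_seen) in live.items():
        finished.append(StructureRecord(sid, tuple(sorted(pm)), len(pm),
                                        0.0, birth, last_seen))
    return finished


def fit_kinetics(times, mean_n_sas) -> KineticsFit:
    """Least-squares fit of ``N(t) = s + (N0 - s) exp(-t / r)``.

    ``N0`` is fixed to the first observation.  A constant series returns
    the degenerate fit (s = constant, unconstrained time scale).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(mean_n_sas, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least three time points")
    n0 = float(y[0])
    if np.ptp(y) < 1e-12:
        return KineticsFit(n0, np.inf, n0, 0.0, degenerate=True)

    def model(tt, s, r):
        return s + (n0 - s) * np.exp(-tt / r)

    span = max(float(t[-1] - t[0]), 1e-12)
    p0 = [float(y[-1]), span / 3.0]
    try:
        params, _ = curve_fit(model, t, y, p0=p0,
                              bounds=([1.0, 1e-12], [np.inf, np.inf]),
                              maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise RuntimeError(f"kinetics fit did not converge: {exc}") from exc
    s, r = params
    resid = float(np.sqrt(np.mean((model(t, s, r) - y) ** 2)))
    return KineticsFit(float(s), float(r), n0, resid)


def stability_objective(contacts, reference_contacts) -> StabilityObjective:
    """Surrogate capsid-stability objective in [0, 1].

    The fraction of the reference frame's structured contacts that are
    retained (same molecule pair, still structured).
    """
    ref_pairs = {(c.i, c.j) for c in reference_contacts if c.kind == "structured"}
    if not ref_pairs:
        return StabilityObjective(0.0)
    now_pairs = {(c.i, c.j) for c in contacts if c.kind == "structured"}
    retained = len(ref_pairs & now_pairs)
    return StabilityObjective(min(retained / len(ref_pairs), 1.0))
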