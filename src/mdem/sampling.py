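"""Oracle contract, initial sampling and supervised iterative refinement.

An :class:`Oracle` stands in for expensive pair simulations: it evaluates
per-component potentials at a 6D configuration (or rejects colliding
ones).  The refinement loop alternates model fitting, grid estimation,
criterion-driven selection of new configurations and oracle evaluation,
recording a convergence trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from mdem.structures import Configuration

__all__ = [
    "Oracle",
    "RefinementConfig",
    "convergence_metrics",
    "initial_sample",
    "refine",
    "score_resampling",
]


class Oracle(object):
    """Contract for a potential-sampling oracle.

    Subclasses provide :meth:`evaluate` returning a dict of per-component
    potentials (kJ/mol) or ``None`` for rejected (colliding)
    configurations, and :meth:`random_config` drawing a placement from the
    oracle's sampling domain.  Evaluation must be deterministic given
    ``(config, seed)``.
    """

    def __init__(self, components, interaction_range: float,
                 d_coll: float = 0.4, identical_species: bool = True):
        self.components = list(components)
        self.interaction_range = float(interaction_range)
        self.d_coll = float(d_coll)
        self.identical_species = bool(identical_species)

    def evaluate(self, config: Configuration, seed: int = 0):
        raise NotImplementedError

    def random_config(self, rng) -> Configuration:
        raise NotImplementedError


@dataclass
class RefinementConfig:
    """Schedule of the supervised refinement loop."""

    iterations: int = 8
    samples_per_iteration: int = 10
    criteria: tuple = None  # per-iteration criterion names
    min_spacing: float = 0.2
    seed: int = 0
    n_pot: int = 60
    n_var: int = 40

    def __post_init__(self):
        if self.iterations < 0 or self.samples_per_iteration < 1:
            raise ValueError("invalid refinement configuration")
        if self.criteria is None:
            # variance-type criteria first, extrema for the final third
            crit = []
            for i in range(self.iterations):
                if i < max(self.iterations * 2 // 3, self.iterations - 9):
                    crit.append("normalized_variance" if i % 2 else "variance")
                else:
                    crit.append("extrema")
            self.criteria = tuple(crit)

    def criterion(self, iteration: int) -> str:
        if not self.criteria:
            return "variance"
        return self.criteria[min(iteration, len(self.criteria) - 1)]


def initial_sample(oracle: Oracle, n: int, seed: int = 0,
                   samples=None, max_rejects: int = None):
    """Draw n accepted oracle evaluations (rejections are retried).

    For identical species each evaluation contributes the configuration
    and its role-swapped twin.  Returns a
    :class:`~mdem.trend_variogram.SampleSet`.
    """
    from mdem.descriptors import min_distance
    from mdem.trend_variogram import SampleSet

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if samples is None:
        samples = SampleSet(oracle.struct_b, oracle.components)
    max_rejects = max_rejects or max(100 * n, 1000)
    accepted = rejected = 0
    while accepted < n:
        cfg = oracle.random_config(rng)
        vals = oracle.evaluate(cfg, seed=int(rng.integers(2 ** 31)))
        if vals is None:
            rejected += 1
            if rejected > max_rejects:
                raise RuntimeError(
                    "oracle acceptance rate below 1%; widen the sampling bounds"
                )
            continue
        dm = min_distance(oracle.struct_a, oracle.struct_b, cfg)
        samples.append_symmetrized(cfg, dm, vals,
                                   identical_species=oracle.identical_species)
        accepted += 1
    return samples


def _local_extrema_mask(values: np.ndarray, mode: str) -> np.ndarray:
    """Nodes that are local minima/maxima against axis-neighbor stencils."""
    cmp = np.less if mode == "min" else np.greater
    mask = np.ones_like(values, dtype=bool)
    for axis in range(values.ndim):
        if values.shape[axis] < 2:
            continue
        fwd = np.roll(values, -1, axis=axis)
        bwd = np.roll(values, 1, axis=axis)
        mask &= cmp(values, fwd) & cmp(values, bwd)
    return mask


def _gradient_magnitude(grid) -> np.ndarray:
    g2 = np.zeros(grid.values.shape)
    for axis in range(6):
        if grid.values.shape[axis] < 2:
            continue
        step = grid.axes[axis].step
        d = (np.roll(grid.values, -1, axis=axis)
             - np.roll(grid.values, 1, axis=axis)) / (2.0 * step)
        g2 += d * d
    return np.sqrt(g2)


def score_resampling(grid, criterion: str, k: int, spacing: float = 0.2,
                     struct_b=None, rng=None, eps: float = None):
    """Select k new sampling configurations from a built grid.

    ``variance`` ranks cells by estimation variance,
    ``normalized_variance`` by variance / (|U| + eps), ``extrema`` by the
    union of local potential minima/maxima and gradient maxima.  Selected
    points are mutually at least ``spacing`` apart in delta_r.
    """
    if grid.variance is None and criterion != "extrema":
        raise ValueError("grid has no variance array")
    nodes = grid.node_configs()
    free = ~grid.mask.ravel()
    if criterion == "variance":
        score = grid.variance.ravel().copy()
    elif criterion == "normalized_variance":
        if eps is None:
            # floor at a fraction of the field scale so flat far-field
            # cells do not dominate the normalised score
            eps = max(0.05 * float(np.abs(grid.values).max()), 1e-9)
        score = grid.variance.ravel() / (np.abs(grid.values.ravel()) + eps)
    elif criterion == "extrema":
        minima = _local_extrema_mask(grid.values, "min").ravel()
        maxima = _local_extrema_mask(grid.values, "max").ravel()
        gmag = _gradient_magnitude(grid).ravel()
        gthresh = np.quantile(gmag[free], 0.95) if free.any() else 0.0
        gmax = gmag.max() if gmag.size else 0.0
        # potential extrema outrank gradient-maximum candidates
        score = np.where(minima | maxima,
                         np.abs(grid.values.ravel()) + gmax, 0.0)
        score = np.maximum(score, np.where(gmag >= gthresh, gmag, 0.0))
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    score[~free] = -np.inf
    finite = score[np.isfinite(score)]
    if len(finite) == 0 or np.ptp(finite) < 1e-12:
        # degenerate (flat) score: fall back to uniform-random free cells
        rng = rng or np.random.default_rng(0)
        cand = np.flatnonzero(free)
        rng.shuffle(cand)
        order = cand
    else:
        order = np.argsort(score)[::-1]
        order = order[np.isfinite(score[order])]
    picked = []
    picked_clouds = []
    from mdem.descriptors import placed_cloud

    for idx in order:
        if len(picked) >= k:
            break
        cfg = nodes[idx]
        if struct_b is not None and spacing > 0 and picked_clouds:
            cloud = placed_cloud(struct_b, cfg[None], grid.convention)[0]
            dr = np.sqrt(np.mean(np.sum(
                (np.array(picked_clouds) - cloud) ** 2, axis=-1), axis=-1))
            if dr.min() < spacing:
                continue
            picked_clouds.append(cloud)
        elif struct_b is not None and spacing > 0:
            picked_clouds.append(placed_cloud(struct_b, cfg[None], grid.convention)[0])
        picked.append(idx)
    configs = [Configuration.from_array(nodes[i], grid.convention) for i in picked]
    return configs


def convergence_metrics(field_now, field_prev):
    """(dU_rms, dU_max, var_rms, var_max) over mutually unmasked cells."""
    if field_now.values.shape != field_prev.values.shape:
        raise ValueError("mismatched grids")
    live = ~(field_now.mask | field_prev.mask)
    if not live.any():
        return 0.0, 0.0, 0.0, 0.0
    du = field_now.values[live] - field_prev.values[live]
    var = field_now.variance[live] if field_now.variance is not None else np.zeros(1)
    return (float(np.sqrt(np.mean(du ** 2))), float(np.max(np.abs(du))),
            float(np.sqrt(np.mean(var ** 2))), float(np.max(var)))


def refine(oracle: Oracle, samples, config: RefinementConfig, axes,
           fit_kwargs=None, grid_kwargs=None):
    """Supervised refinement loop.

    Each iteration refits trend and variograms, rebuilds the grid, scores
    the scheduled criterion, evaluates the oracle at the selected
    configurations and appends the (symmetrised) points.  Returns
    ``(samples, trace, last_grid, last_engine)`` where ``trace`` is a list
    of per-iteration metric dicts.
    """
    from mdem.field import build_grid
    from mdem.kriging import fit_pair_models

    fit_kwargs = dict(fit_kwargs or {})
    grid_kwargs = dict(grid_kwargs or {})
    rng = np.random.default_rng(config.seed)
    trace = []
    prev_grid = None
    engine = fit_pair_models(samples, oracle.interaction_range, **fit_kwargs)
    grid = build_grid(engine, axes, n_pot=config.n_pot, n_var=config.n_var,
                      **grid_kwargs)
    for it in range(config.iterations):
        criterion = config.criterion(it)
        try:
            new_configs = score_resampling(
                grid, criterion, config.samples_per_iteration,
                spacing=config.min_spacing, struct_b=oracle.struct_b, rng=rng)
        except ValueError:
            new_configs = []
        n_new = 0
        from mdem.descriptors import min_distance

        for cfg in new_configs:
            vals = oracle.evaluate(cfg, seed=int(rng.integers(2 ** 31)))
            if vals is None:
                continue
            dm = min_distance(oracle.struct_a, oracle.struct_b, cfg)
            samples.append_symmetrized(cfg, dm, vals,
                                       identical_species=oracle.identical_species)
            n_new += 1
        engine = fit_pair_models(samples, oracle.interaction_range, **fit_kwargs)
        prev_grid = grid
        grid = build_grid(engine, axes, n_pot=config.n_pot, n_var=config.n_var,
                          **grid_kwargs)
        du_rms, du_max, var_rms, var_max = convergence_metrics(grid, prev_grid)
        trace.append({
            "iteration": it + 1, "criterion": criterion, "n_new": n_new,
            "n_samples": len(samples), "du_rms": du_rms, "du_max": du_max,
            "var_rms": var_rms, "var_max": var_max,
        })
    return samples, trace, grid, engine
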