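"""Universal Kriging of per-component pair potentials in 6D.

For a query configuration the estimator takes the N nearest data points in
delta_r, solves the constrained UK system (variogram block, unbiasedness
row, trend-basis rows) via a truncated SVD, and returns the best linear
unbiased estimate together with the estimation variance.  Components
without usable spatial correlation fall back to their trend value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from mdem.descriptors import config_distance_matrix, placed_cloud
from mdem.structures import Configuration
from mdem.trend_variogram import (
    SampleSet,
    TrendModel,
    VariogramModel,
    compute_residuals,
    density_weights,
    empirical_variogram,
    fit_trend,
    fit_variogram,
    partition_regions,
)

log = logging.getLogger(__name__)

__all__ = [
    "KrigingEngine",
    "KrigingResult",
    "assemble_uk_system",
    "find_neighborhood",
    "fit_pair_models",
    "solve_uk",
]

SVD_RCOND = 1e-6  # singular values below max_sv * SVD_RCOND are discarded


@dataclass
class KrigingResult:
    """Estimate at one configuration."""

    components: dict
    total: float
    variances: dict
    weights: dict
    multipliers: dict
    neighborhood: dict


def find_neighborhood(samples: SampleSet, query, n: int) -> np.ndarray:
    """Ids of the N smallest-delta_r points, ascending, ties by id."""
    if n < 1:
        raise ValueError("neighborhood size must be >= 1")
    if len(samples) == 0:
        raise ValueError("empty sample set")
    if isinstance(query, Configuration):
        query = query.to_array()
    dr = samples.delta_r_to(query)[0]
    order = np.lexsort((np.arange(len(dr)), dr))
    return order[: min(n, len(dr))]


def assemble_uk_system(dr_block: np.ndarray, dr_query: np.ndarray,
                       basis_block: np.ndarray, basis_query: np.ndarray,
                       variogram: VariogramModel):
    """Build the normalised (N+M+1) UK matrix and right-hand side.

    ``dr_block`` is the neighbor-neighbor delta_r matrix, ``dr_query`` the
    neighbor-query distances, ``basis_block`` the (M+1, N) trend-basis
    values at the neighbors (constant row first) and ``basis_query`` the
    (M+1,) values at the query.  Variogram entries are scaled by the sill
    and each basis row by its maximum magnitude so all blocks are O(1).
    """
    n = dr_block.shape[0]
    m1 = basis_block.shape[0]
    sill = max(variogram.sill, 1e-12)
    gam = variogram(dr_block) / sill
    np.fill_diagonal(gam, 0.0)
    fscale = np.maximum(
        np.max(np.abs(np.c_[basis_block, basis_query[:, None]]), axis=1), 1e-12
    )
    fb = basis_block / fscale[:, None]
    fq = basis_query / fscale
    size = n + m1
    A = np.zeros((size, size))
    A[:n, :n] = gam
    A[:n, n:] = fb.T
    A[n:, :n] = fb
    b = np.zeros(size)
    b[:n] = variogram(dr_query) / sill
    b[n:] = fq
    return A, b, sill, fscale


def solve_uk(A: np.ndarray, b: np.ndarray, n: int):
    """Least-norm SVD solution; returns (weights, multipliers).

    Singular values smaller than ``max_sv * 1e-6`` are discarded.
    """
    u, s, vt = np.linalg.svd(A)
    if s[0] <= 0 or not np.isfinite(s[0]):
        raise np.linalg.LinAlgError("UK system has no usable singular values")
    keep = s > s[0] * SVD_RCOND
    if not keep.any():
        raise np.linalg.LinAlgError("all singular values discarded")
    x = vt[keep].T @ ((u[:, keep].T @ b) / s[keep])
    return x[:n], x[n:]


class KrigingEngine:
    """Estimation engine for one species pair.

    Bundles the sample set, per-component trend models, sectional
    variograms and the delta_m region layout.  ``kriged_components`` lists
    the components estimated by UK; the rest use their trend only.
    """

    def __init__(self, samples: SampleSet, trends: dict, variograms: dict,
                 region_bounds, interaction_range: float,
                 kriged_components=None, residual_variances=None):
        self.samples = samples
        self.trends = trends
        self.variograms = variograms
        self.region_bounds = list(region_bounds)
        self.interaction_range = float(interaction_range)
        if kriged_components is None:
            kriged_components = [c for c in trends if variograms.get(c)]
        self.kriged_components = list(kriged_components)
        self.residual_variances = residual_variances or {}
        self.extrapolation_count = 0
        self.negative_variance_count = 0
        self._pair_dr = None

    # -- helpers -----------------------------------------------------------
    def _pairwise_dr(self) -> np.ndarray:
        if self._pair_dr is None or self._pair_dr.shape[0] != len(self.samples):
            c = self.samples.clouds
            self._pair_dr = config_distance_matrix(c, c)
        return self._pair_dr

    def region_for(self, delta_m: float) -> int:
        centers = np.array([0.5 * (lo + hi) for lo, hi in self.region_bounds])
        return int(np.argmin(np.abs(centers - delta_m)))

    def variogram_for(self, component: str, delta_m: float) -> VariogramModel:
        models = self.variograms[component]
        return models[min(self.region_for(delta_m), len(models) - 1)]

    def _component_estimate(self, component, nbr, dr_q, delta_m_q):
        trend = self.trends[component]
        vg = self.variogram_for(component, delta_m_q)
        dm_n = self.samples.delta_m[nbr]
        basis_block = trend.basis_values(dm_n)
        basis_query = trend.basis_values(delta_m_q)[:, 0]
        dr_block = self._pairwise_dr()[np.ix_(nbr, nbr)]
        A, b, sill, _ = assemble_uk_system(dr_block, dr_q, basis_block,
                                           basis_query, vg)
        w, lam = solve_uk(A, b, len(nbr))
        est = float(w @ self.samples.potentials[component][nbr])
        var = sill * float(w @ b[: len(nbr)] + lam @ b[len(nbr):])
        if var < 0:
            if var < -1e-6 * max(sill, 1.0):
                self.negative_variance_count += 1
            var = 0.0
        return est, var, w, lam

    # -- public API --------------------------------------------------------
    def estimate(self, query, n_pot: int = 100, n_var: int = None) -> KrigingResult:
        """Per-component UK estimate and variance at one configuration."""
        if isinstance(query, Configuration):
            qarr = query.to_array()
        else:
            qarr = np.asarray(query, dtype=float).reshape(6)
        from mdem.descriptors import min_distance_many

        dm_q = float(min_distance_many(self.samples.struct_b, self.samples.struct_b,
                                       qarr[None], convention=self.samples.convention)[0])
        return self._estimate_prepared(qarr, dm_q, n_pot, n_var)

    def _estimate_prepared(self, qarr, dm_q, n_pot, n_var=None):
        dr_all = self.samples.delta_r_to(qarr)[0]
        order = np.lexsort((np.arange(len(dr_all)), dr_all))
        nbr_pot = order[: min(n_pot, len(order))]
        nbr_var = order[: min(n_var or n_pot, len(order))]
        comps, variances, weights, lams = {}, {}, {}, {}
        for comp, trend in self.trends.items():
            if comp in self.kriged_components:
                est, _, w, lam = self._component_estimate(
                    comp, nbr_pot, dr_all[nbr_pot], dm_q)
                if len(nbr_var) != len(nbr_pot):
                    _, var, _, _ = self._component_estimate(
                        comp, nbr_var, dr_all[nbr_var], dm_q)
                else:
                    var = self._component_estimate(comp, nbr_var,
                                                   dr_all[nbr_var], dm_q)[1]
                comps[comp] = est
                variances[comp] = var
                weights[comp] = w
                lams[comp] = lam
            else:
                lo, hi = trend.delta_m_range
                if dm_q > hi or dm_q < lo:
                    self.extrapolation_count += 1
                comps[comp] = float(trend(dm_q))
                variances[comp] = float(self.residual_variances.get(comp, 0.0))
        return KrigingResult(
            components=comps, total=float(sum(comps.values())),
            variances=variances, weights=weights, multipliers=lams,
            neighborhood={"potential": nbr_pot, "variance": nbr_var},
        )

    def estimate_many(self, configs: np.ndarray, n_pot: int = 100,
                      n_var: int = None, chunk: int = 256):
        """Vectorised estimation: returns (totals, total_variances).

        Variances are summed over kriged components (trend-only components
        contribute their constant residual variance).
        """
        configs = np.atleast_2d(configs)
        from mdem.descriptors import min_distance_many

        dm = min_distance_many(self.samples.struct_b, self.samples.struct_b,
                               configs, convention=self.samples.convention)
        totals = np.empty(len(configs))
        variances = np.empty(len(configs))
        for lo in range(0, len(configs), chunk):
            hi = min(lo + chunk, len(configs))
            q_clouds = placed_cloud(self.samples.struct_b, configs[lo:hi],
                                    self.samples.convention)
            dr_chunk = config_distance_matrix(q_clouds, self.samples.clouds)
            for k in range(hi - lo):
                res = self._estimate_from_dr(dr_chunk[k], dm[lo + k], n_pot, n_var)
                totals[lo + k], variances[lo + k] = res
        return totals, variances

    def _estimate_from_dr(self, dr_all, dm_q, n_pot, n_var=None):
        order = np.lexsort((np.arange(len(dr_all)), dr_all))
        nbr_pot = order[: min(n_pot, len(order))]
        nbr_var = order[: min(n_var or n_pot, len(order))]
        total = 0.0
        var_total = 0.0
        for comp, trend in self.trends.items():
            if comp in self.kriged_components:
                est, var_p, _, _ = self._component_estimate(
                    comp, nbr_pot, dr_all[nbr_pot], dm_q)
                if len(nbr_var) != len(nbr_pot):
                    var_p = self._component_estimate(
                        comp, nbr_var, dr_all[nbr_var], dm_q)[1]
                total += est
                var_total += var_p
            else:
                total += float(trend(dm_q))
                var_total += float(self.residual_variances.get(comp, 0.0))
        return total, var_total


def fit_pair_models(samples: SampleSet, interaction_range: float,
                    n_regions: int = 5, kernel_width: float = 2.0,
                    kriged_components=None, variogram_kwargs=None,
                    trend_families=None,
                    variogram_families=("spherical", "exponential", "gaussian"),
                    variogram_override=None) -> KrigingEngine:
    """Fit trends and sectional variograms and build a kriging engine.

    When ``kriged_components`` is None a component qualifies for kriging if
    its structured variogram part carries at least 20% of the sill in the
    majority of regions.
    """
    variogram_kwargs = variogram_kwargs or {}
    density_weights(samples, kernel_width)
    _, selectors = partition_regions(samples.delta_m, n_regions, interaction_range)
    bounds, _ = partition_regions(samples.delta_m, n_regions, interaction_range)
    trends, variograms, resvar = {}, {}, {}
    for comp in samples.components:
        trend = fit_trend(samples, comp, families=trend_families)
        res = compute_residuals(samples, trend)
        resvar[comp] = float(np.var(res))
        if variogram_override and comp in variogram_override:
            # externally supplied spatial-continuity models (e.g., fitted
            # once from a dense reference rather than the sparse samples)
            trends[comp] = trend
            variograms[comp] = list(variogram_override[comp])
            continue
        models = []
        for k, sel in enumerate(selectors):
            try:
                bins = empirical_variogram(samples, comp, sel, **variogram_kwargs)
                if len(bins) < 3:
                    raise ValueError("too few bins")
                vg = fit_variogram(bins, comp, families=variogram_families,
                                   region=k, delta_m_bounds=bounds[k])
            except (ValueError, RuntimeError):
                vg = VariogramModel(comp, "nugget", resvar[comp],
                                    resvar[comp], 1.0, k, bounds[k])
            models.append(vg)
        trends[comp] = trend
        variograms[comp] = models
    if kriged_components is None:
        kriged_components = []
        for comp, models in variograms.items():
            frac = [
                (m.sill - m.nugget) / m.sill if m.sill > 0 else 0.0 for m in models
            ]
            if np.median(frac) > 0.2:
                kriged_components.append(comp)
    return KrigingEngine(samples, trends, variograms, bounds,
                         interaction_range, kriged_components, resvar)
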