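"""Trend modelling over delta_m and sectional residual variograms.

Each potential component is decomposed into a systematic trend over the
minimum distance plus a spatially correlated residual.  The trend is a
weighted least-squares fit of a constant plus one decaying basic function;
the residual's spatial continuity is modelled per delta_m region by a
variogram over the configuration metric delta_r.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.optimize import curve_fit

from mdem.descriptors import (
    config_distance_matrix,
    min_distance_many,
    placed_cloud,
)
from mdem.structures import BeadStructure, Configuration

__all__ = [
    "DataPoint",
    "SampleSet",
    "TrendModel",
    "VariogramModel",
    "compute_residuals",
    "density_weights",
    "empirical_variogram",
    "fit_trend",
    "fit_variogram",
    "partition_regions",
]


@dataclass
class DataPoint:
    """One oracle evaluation at a 6D configuration."""

    id: int
    config: Configuration
    delta_m: float
    potentials: dict
    residuals: dict = dfield(default_factory=dict)
    weight: float = 1.0
    provenance: str = "oracle"


class SampleSet:
    """Columnar store of data points for one species pair.

    Caches placed backbone clouds of molecule B so that delta_r look-ups
    against the whole set are a single vectorised operation.
    """

    def __init__(self, struct_b: BeadStructure, components, convention=None):
        from mdem.structures import DEFAULT_EULER

        self.struct_b = struct_b
        self.components = list(components)
        self.convention = convention or DEFAULT_EULER
        self.configs = np.empty((0, 6))
        self.delta_m = np.empty(0)
        self.potentials = {c: np.empty(0) for c in self.components}
        self.residuals = {c: np.empty(0) for c in self.components}
        self.weights = np.empty(0)
        self.provenance = []
        self._clouds = np.empty((0, struct_b.backbone_coords.shape[0], 3))

    def __len__(self):
        return self.configs.shape[0]

    @property
    def clouds(self) -> np.ndarray:
        return self._clouds

    def append(self, configs, delta_m, potentials: dict, provenance="oracle"):
        configs = np.atleast_2d(np.asarray(configs, dtype=float))
        n = len(configs)
        delta_m = np.broadcast_to(np.asarray(delta_m, dtype=float), (n,))
        self.configs = np.vstack([self.configs, configs])
        self.delta_m = np.concatenate([self.delta_m, delta_m])
        for c in self.components:
            vals = np.broadcast_to(np.asarray(potentials[c], dtype=float), (n,))
            if not np.isfinite(vals).all():
                raise ValueError(f"non-finite potential values for component {c!r}")
            self.potentials[c] = np.concatenate([self.potentials[c], vals])
            self.residuals[c] = np.concatenate([self.residuals[c], np.full(n, np.nan)])
        self.weights = np.concatenate([self.weights, np.ones(n)])
        prov = [provenance] * n if isinstance(provenance, str) else list(provenance)
        self.provenance.extend(prov)
        self._clouds = np.vstack(
            [self._clouds, placed_cloud(self.struct_b, configs, self.convention)]
        )

    def append_symmetrized(self, config: Configuration, delta_m, potentials: dict,
                           provenance="oracle", identical_species: bool = True):
        """Add a point and, for identical species, its role-swapped twin."""
        self.append(config.to_array()[None], delta_m, potentials, provenance)
        if identical_species:
            inv = config.inverse()
            self.append(inv.to_array()[None], delta_m, potentials, provenance)

    def delta_r_to(self, configs) -> np.ndarray:
        """delta_r from each query configuration to every stored point: (nq, n)."""
        q = placed_cloud(self.struct_b, np.atleast_2d(configs), self.convention)
        return config_distance_matrix(q, self._clouds)

    def point(self, i: int) -> DataPoint:
        cfg = Configuration.from_array(self.configs[i], self.convention)
        return DataPoint(
            id=i, config=cfg, delta_m=float(self.delta_m[i]),
            potentials={c: float(self.potentials[c][i]) for c in self.components},
            residuals={c: float(self.residuals[c][i]) for c in self.components},
            weight=float(self.weights[i]), provenance=self.provenance[i],
        )

    # -- CSV round trip ----------------------------------------------------
    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.configs, columns=["x", "y", "z", "alpha", "beta", "gamma"])
        df.insert(0, "id", np.arange(len(self)))
        df["delta_m"] = self.delta_m
        for c in self.components:
            df[f"pot_{c}"] = self.potentials[c]
        df["provenance"] = self.provenance
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, struct_b: BeadStructure, convention=None) -> "SampleSet":
        import pandas as pd

        df = pd.read_csv(path)
        comps = [c[4:] for c in df.columns if c.startswith("pot_")]
        ss = cls(struct_b, comps, convention)
        ss.append(
            df[["x", "y", "z", "alpha", "beta", "gamma"]].to_numpy(),
            df["delta_m"].to_numpy(),
            {c: df[f"pot_{c}"].to_numpy() for c in comps},
            provenance=list(df["provenance"]),
        )
        return ss


def density_weights(samples: SampleSet, kernel_width: float = 2.0,
                    chunk: int = 512) -> np.ndarray:
    """Inverse Gaussian-kernel density weights over delta_r.

    ``w_i = 1 / sum_j exp(-delta_r(i,j)^2 / (2 h^2))``; dense clusters are
    down-weighted so sampling heterogeneity does not bias trend fits.
    """
    if kernel_width <= 0:
        raise ValueError("kernel width must be positive")
    n = len(samples)
    dens = np.empty(n)
    clouds = samples.clouds
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        dr = config_distance_matrix(clouds[lo:hi], clouds)
        dens[lo:hi] = np.exp(-dr ** 2 / (2.0 * kernel_width ** 2)).sum(axis=1)
    w = 1.0 / dens
    samples.weights = w
    return w


# ---------------------------------------------------------------------------
# Trend models

def _basis_constant(d, b0):
    return np.full_like(np.asarray(d, dtype=float), b0)


def _basis_gaussian(d, b0, amp, rng):
    return b0 + amp * np.exp(-np.asarray(d) ** 2 / (2.0 * rng ** 2))


def _basis_exponential(d, b0, amp, rng):
    return b0 + amp * np.exp(-np.asarray(d) / rng)


def _make_power(k):
    def f(d, b0, amp, c):
        return b0 + amp / (np.asarray(d) + c) ** k
    f.__name__ = f"power{k}"
    return f


TREND_FAMILIES = {
    "constant": (_basis_constant, [0.0], None),
    "gaussian": (_basis_gaussian, [0.0, -100.0, 1.0],
                 ([-np.inf, -np.inf, 1e-3], [np.inf, np.inf, np.inf])),
    "exponential": (_basis_exponential, [0.0, -100.0, 1.0],
                    ([-np.inf, -np.inf, 1e-3], [np.inf, np.inf, np.inf])),
    "power1": (_make_power(1), [0.0, -10.0, 0.5],
               ([-np.inf, -np.inf, 1e-2], [np.inf, np.inf, np.inf])),
    "power6": (_make_power(6), [0.0, -10.0, 0.5],
               ([-np.inf, -np.inf, 1e-2], [np.inf, np.inf, np.inf])),
    "power12": (_make_power(12), [0.0, -10.0, 0.5],
                ([-np.inf, -np.inf, 1e-2], [np.inf, np.inf, np.inf])),
}


@dataclass
class TrendModel:
    """Fitted trend mu(delta_m) = constant + one decaying basic function."""

    component: str
    family: str
    params: np.ndarray
    r_squared: float
    delta_m_range: tuple

    def __call__(self, delta_m):
        f = TREND_FAMILIES[self.family][0]
        d = np.clip(np.asarray(delta_m, dtype=float), 0.0, None)
        return f(d, *self.params)

    def basis_values(self, delta_m):
        """Rows of the UK basis block: constant and the non-constant part."""
        d = np.clip(np.atleast_1d(np.asarray(delta_m, dtype=float)), 0.0, None)
        rows = [np.ones_like(d)]
        if self.family != "constant":
            f = TREND_FAMILIES[self.family][0]
            shifted = np.asarray(f(d, 0.0, *self.params[1:]), dtype=float)
            rows.append(shifted)
        return np.array(rows)

    def to_dict(self):
        return {
            "component": self.component, "family": self.family,
            "params": list(map(float, self.params)),
            "r_squared": float(self.r_squared),
            "delta_m_range": list(map(float, self.delta_m_range)),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(d["component"], d["family"], np.array(d["params"]),
                   d["r_squared"], tuple(d["delta_m_range"]))


def _weighted_r2(y, yhat, w):
    ybar = np.average(y, weights=w)
    ss_tot = np.sum(w * (y - ybar) ** 2)
    ss_res = np.sum(w * (y - yhat) ** 2)
    if ss_tot < 1e-12:
        return 1.0 if ss_res < 1e-9 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_trend(samples: SampleSet, component: str,
              families=None) -> TrendModel:
    """Weighted least-squares trend fit; the highest-R^2 family wins.

    Every candidate includes the constant basis; a rank-deficient or
    failing fit falls back to the weighted mean with a warning.
    """
    d = samples.delta_m
    y = samples.potentials[component]
    w = samples.weights
    if families is None:
        families = list(TREND_FAMILIES)
    sigma = 1.0 / np.sqrt(np.clip(w, 1e-12, None))
    best = None
    const_val = float(np.average(y, weights=w))
    for fam in families:
        f, p0, bounds = TREND_FAMILIES[fam]
        if fam == "constant":
            params = np.array([const_val])
            r2 = _weighted_r2(y, np.full_like(y, const_val), w)
        else:
            if len(d) < len(p0) + 1:
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p0_ = list(p0)
                    p0_[0] = const_val
                    p0_[1] = float(y.min() - const_val) or -1.0
                    kw = {"bounds": bounds} if bounds else {}
                    params, _ = curve_fit(f, d, y, p0=p0_, sigma=sigma,
                                          maxfev=20000, **kw)
            except (RuntimeError, ValueError):
                continue
            r2 = _weighted_r2(y, f(d, *params), w)
        if best is None or r2 > best[0] + 1e-12:
            best = (r2, fam, np.asarray(params, dtype=float))
    if best is None or not np.isfinite(best[0]):
        warnings.warn(f"trend fit failed for {component}; constant fallback")
        best = (0.0, "constant", np.array([const_val]))
    r2, fam, params = best
    return TrendModel(component, fam, params, r2,
                      (float(d.min()) if len(d) else 0.0,
                       float(d.max()) if len(d) else 0.0))


def compute_residuals(samples: SampleSet, trend: TrendModel) -> np.ndarray:
    """Store and return R_i = U_i - mu(delta_m_i) for the trend's component."""
    res = samples.potentials[trend.component] - trend(samples.delta_m)
    samples.residuals[trend.component] = res
    return res


# ---------------------------------------------------------------------------
# Regions and variograms

def partition_regions(delta_m: np.ndarray, n_regions: int = 5,
                      interaction_range: float = None):
    """Equal-width delta_m regions over [0, interaction_range].

    Returns ``(bounds, selectors)``: ``bounds[k] = (lo, hi)`` and
    ``selectors[k]`` a boolean mask including the region and its adjacent
    regions (for variogram statistics).
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    delta_m = np.asarray(delta_m, dtype=float)
    if interaction_range is None:
        interaction_range = float(delta_m.max()) if len(delta_m) else 1.0
    edges = np.linspace(0.0, interaction_range, n_regions + 1)
    bounds = [(edges[k], edges[k + 1]) for k in range(n_regions)]
    selectors = []
    for k in range(n_regions):
        lo = edges[max(k - 1, 0)]
        hi = edges[min(k + 2, n_regions)]
        mask = (delta_m >= lo) & (delta_m <= hi)
        if not mask.any():
            warnings.warn(f"region {k} empty; widened to full range")
            mask = np.ones_like(delta_m, dtype=bool)
        selectors.append(mask)
    return bounds, selectors


def empirical_variogram(samples: SampleSet, component: str, selector=None,
                        bin_width: float = 0.1, cutoff: float = 4.0,
                        max_points: int = 1500, rng=None):
    """Binned semivariance of residuals over delta_r.

    Returns an array of rows ``(bin_center, semivariance, std, count)``;
    empty bins are dropped.  Pair statistics are computed over at most
    ``max_points`` points (seeded subsample) to bound the quadratic cost.
    """
    if selector is None:
        selector = np.ones(len(samples), dtype=bool)
    idx = np.flatnonzero(selector)
    if len(idx) < 2:
        raise ValueError("need at least two samples in selector")
    if len(idx) > max_points:
        rng = rng or np.random.default_rng(0)
        idx = rng.choice(idx, size=max_points, replace=False)
    res = samples.residuals[component][idx]
    if np.isnan(res).any():
        raise ValueError("residuals not computed; fit the trend first")
    clouds = samples.clouds[idx]
    dr = config_distance_matrix(clouds, clouds)
    iu = np.triu_indices(len(idx), k=1)
    h = dr[iu]
    sv = 0.5 * (res[iu[0]] - res[iu[1]]) ** 2
    keep = h <= cutoff
    h, sv = h[keep], sv[keep]
    nbins = max(int(np.ceil(cutoff / bin_width)), 1)
    which = np.minimum((h / bin_width).astype(int), nbins - 1)
    rows = []
    for b in range(nbins):
        m = which == b
        cnt = int(m.sum())
        if cnt == 0:
            continue
        rows.append(((b + 0.5) * bin_width, float(sv[m].mean()),
                     float(sv[m].std()), cnt))
    return np.array(rows)


def _vg_spherical(h, nugget, psill, rng):
    h = np.asarray(h, dtype=float)
    inside = np.clip(h / rng, 0.0, 1.0)
    return nugget + psill * (1.5 * inside - 0.5 * inside ** 3)


def _vg_exponential(h, nugget, psill, rng):
    return nugget + psill * (1.0 - np.exp(-np.asarray(h, dtype=float) / rng))


def _vg_gaussian(h, nugget, psill, rng):
    return nugget + psill * (1.0 - np.exp(-(np.asarray(h, dtype=float) / rng) ** 2))


VARIOGRAM_FAMILIES = {
    "spherical": _vg_spherical,
    "exponential": _vg_exponential,
    "gaussian": _vg_gaussian,
}


@dataclass
class VariogramModel:
    """Bounded variogram model: nugget + structured part rising to the sill."""

    component: str
    family: str
    nugget: float
    sill: float
    range: float
    region: int = 0
    delta_m_bounds: tuple = (0.0, np.inf)

    def __post_init__(self):
        if self.nugget < 0 or self.sill < self.nugget or self.range <= 0:
            raise ValueError("invalid variogram parameters")

    def __call__(self, h):
        h = np.asarray(h, dtype=float)
        if self.family == "nugget":
            return np.full_like(h, self.nugget)
        g = VARIOGRAM_FAMILIES[self.family](h, self.nugget,
                                            self.sill - self.nugget, self.range)
        return g

    def covariance(self, h):
        """C(h) = sill - gamma(h); C(0) = sill."""
        h = np.asarray(h, dtype=float)
        c = self.sill - self(h)
        return np.where(h <= 0, self.sill, c)

    def to_dict(self):
        return {
            "component": self.component, "family": self.family,
            "nugget": float(self.nugget), "sill": float(self.sill),
            "range": float(self.range), "region": int(self.region),
            "delta_m_bounds": [float(b) for b in np.clip(self.delta_m_bounds, -1e30, 1e30)],
        }

    @classmethod
    def from_dict(cls, d):
        return cls(d["component"], d["family"], d["nugget"], d["sill"],
                   d["range"], d.get("region", 0),
                   tuple(d.get("delta_m_bounds", (0.0, np.inf))))


def fit_variogram(bins: np.ndarray, component: str = "",
                  families=("spherical", "exponential", "gaussian"),
                  region: int = 0, delta_m_bounds=(0.0, np.inf)) -> VariogramModel:
    """Weighted least-squares variogram fit; per-bin std is the uncertainty.

    The best-scoring family wins; if every candidate fails, a pure-nugget
    model at the empirical variance is returned with a warning.
    """
    bins = np.asarray(bins, dtype=float)
    if bins.ndim != 2 or len(bins) < 3:
        raise ValueError("need >= 3 non-empty variogram bins")
    h, g, s = bins[:, 0], bins[:, 1], bins[:, 2]
    sigma = np.clip(s, max(1e-9, 1e-3 * max(g.max(), 1e-12)), None)
    gmax = max(g.max(), 1e-12)
    best = None
    for fam in families:
        f = VARIOGRAM_FAMILIES[fam]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p0 = [max(g[0] * 0.5, 1e-9 * gmax), gmax, max(h.max() / 3.0, 1e-3)]
                # keep the range within the observed lag window and the sill
                # near the observed semivariance scale
                params, _ = curve_fit(
                    f, h, g, p0=p0, sigma=sigma,
                    bounds=([0.0, 0.0, 1e-6], [10.0 * gmax, 10.0 * gmax, 3.0 * h.max()]),
                    maxfev=20000,
                )
        except (RuntimeError, ValueError):
            continue
        score = np.sum(((g - f(h, *params)) / sigma) ** 2)
        if np.isfinite(score) and (best is None or score < best[0]):
            best = (score, fam, params)
    if best is None:
        warnings.warn(f"variogram fit failed for {component}; pure-nugget fallback")
        return VariogramModel(component, "nugget", float(g.mean()),
                              float(g.mean()), 1.0, region, delta_m_bounds)
    _, fam, (nug, psill, rng) = best
    return VariogramModel(component, fam, float(nug), float(nug + psill),
                          float(rng), region, delta_m_bounds)


def save_models(path, trends, variograms):
    """Serialise trend and variogram models to a JSON file."""
    doc = {
        "trends": {c: t.to_dict() for c, t in trends.items()},
        "variograms": {c: [v.to_dict() for v in vs] for c, vs in variograms.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_models(path):
    with open(path) as fh:
        doc = json.load(fh)
    trends = {c: TrendModel.from_dict(d) for c, d in doc["trends"].items()}
    variograms = {c: [VariogramModel.from_dict(v) for v in vs]
                  for c, vs in doc["variograms"].items()}
    return trends, variograms
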