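"""Synthetic-data generators with controlled ground truth.

Every input class the analyses consume can be generated here: ultrametric
Yule trees, multivariate traits under λ-transformed Brownian motion,
gradient climate rasters for the five bioclimatic variables, occurrence
clouds sampled proportionally to Gaussian climatic suitability, and
insect/host occurrence pairs whose niches are either equivalent or
truncated to the colder half of the host's niche.  All generators are
pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .core_io import BIOCLIM_VARIABLES, ClimateRaster, TimeTree
from .disparity import _psd_factor
from .signal import lambda_transform, tree_vcv

#: desk-scale defaults: a 60 × 120-cell raster stack at 0.5°, 40-tip tree,
#: 30 occurrences per species.
DESK_EXTENT = (-30.0, 20.0, 30.0, 50.0)
DESK_RESOLUTION = 0.5
DESK_N_TIPS = 40
DESK_OCC_PER_SPECIES = 30

#: latitudinal gradients (value = intercept + slope·|lat|), in °C / mm —
#: roughly temperate-Northern-Hemisphere magnitudes.
DEFAULT_GRADIENTS = {
    "BIO5": {"intercept": 42.0, "lat_slope": -0.45, "noise_sd": 1.0},
    "BIO6": {"intercept": 22.0, "lat_slope": -0.90, "noise_sd": 1.5},
    "BIO10": {"intercept": 38.0, "lat_slope": -0.50, "noise_sd": 1.0},
    "BIO11": {"intercept": 28.0, "lat_slope": -0.80, "noise_sd": 1.5},
    "BIO17": {"intercept": 20.0, "lat_slope": 3.0, "noise_sd": 8.0},
}


@dataclass
class NicheSpec:
    """Gaussian climatic suitability: optimum and breadth per variable.

    ``truncation`` optionally imposes a hard one-sided cut, e.g.
    ``{"BIO5": ("le", 26.0)}`` zeroes suitability wherever BIO5 > 26.
    """

    center: dict[str, float]
    breadth: dict[str, float]
    truncation: dict[str, tuple[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v, b in self.breadth.items():
            if b <= 0:
                raise ValueError(f"breadth for {v} must be > 0")


def simulate_yule_tree(n_tips: int, birth_rate: float = 0.1,
                       seed: int = 0) -> TimeTree:
    """Ultrametric pure-birth tree with tips labeled t1..tn.

    Lineages split at per-capita rate ``birth_rate`` (per Ma) starting
    from a root bifurcation; after the n-th lineage appears the clock
    runs one further exponential interval so no tip sits exactly on the
    last divergence.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    birth_time: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    tree.seed_node.edge.length = 0.0
    active = [tree.seed_node]
    t = 0.0
    while len(active) < n_tips + 1:
        k = len(active)
        if k > 1:  # the root split happens at t = 0
            t += rng.exponential(1.0 / (birth_rate * k))
        if k == n_tips:
            break
        node = active.pop(int(rng.integers(k)))
        node.edge.length = t - birth_time[node]
        for _ in range(2):
            child = node.new_child()
            birth_time[child] = t
            active.append(child)
    order = rng.permutation(len(active))
    for i, j in enumerate(order):
        leaf = active[j]
        leaf.edge.length = t - birth_time[leaf]
        leaf.taxon = taxa.new_taxon(label=f"t{i + 1}")
    return TimeTree(tree, is_ultrametric=True)


def simulate_lambda_bm(tree: TimeTree, lam: float,
                       sigma: pd.DataFrame | np.ndarray,
                       root: np.ndarray | float = 0.0,
                       seed: int = 0) -> pd.DataFrame:
    """Traits from the λ-transformed Brownian model.

    One draw from the Gaussian with tip covariance C(λ) ⊗ Σ and mean the
    root state, returned as species × variable DataFrame.
    """
    sig = np.asarray(sigma, dtype=float)
    if sig.ndim == 0:
        sig = sig.reshape(1, 1)
    if not np.any(np.diag(sig) > 0):
        raise ValueError("rate matrix must have a positive diagonal")
    columns = (list(sigma.columns) if isinstance(sigma, pd.DataFrame)
               else [f"v{i}" for i in range(sig.shape[0])])
    C = tree_vcv(tree)
    Clam = lambda_transform(C.to_numpy(), lam)
    L = _psd_factor(Clam)
    A = _psd_factor(sig)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((C.shape[0], sig.shape[0]))
    X = L @ Z @ A.T + np.broadcast_to(np.asarray(root, dtype=float),
                                      (C.shape[0], sig.shape[0]))
    return pd.DataFrame(X, index=list(C.index), columns=columns)


def make_synthetic_rasters(extent: tuple[float, float, float, float]
                           = DESK_EXTENT,
                           resolution: float = DESK_RESOLUTION,
                           params: dict[str, dict] | None = None,
                           noise_corr: np.ndarray | None = None,
                           nodata_border: int = 0,
                           seed: int = 0) -> list[ClimateRaster]:
    """Gradient-plus-noise rasters for the five bioclimatic variables.

    Each variable is ``intercept + lat_slope·|lat| + lon_slope·lon`` at
    the cell center plus Gaussian noise; ``noise_corr`` (variable ×
    variable correlation matrix) couples the noise fields cell-wise.
    ``nodata_border`` masks that many cells around the edge.
    """
    params = {**DEFAULT_GRADIENTS, **(params or {})}
    variables = list(params)
    lon_min, lat_min, lon_max, lat_max = extent
    ncols = int(round((lon_max - lon_min) / resolution))
    nrows = int(round((lat_max - lat_min) / resolution))
    lons = lon_min + (np.arange(ncols) + 0.5) * resolution
    lats = lat_max - (np.arange(nrows) + 0.5) * resolution
    lon_grid, lat_grid = np.meshgrid(lons, lats)
    rng = np.random.default_rng(seed)
    if noise_corr is None:
        noise = rng.standard_normal((len(variables), nrows, ncols))
    else:
        A = _psd_factor(np.asarray(noise_corr, dtype=float))
        white = rng.standard_normal((len(variables), nrows * ncols))
        noise = (A @ white).reshape(len(variables), nrows, ncols)
    rasters = []
    for i, var in enumerate(variables):
        p = params[var]
        values = (p["intercept"]
                  + p.get("lat_slope", 0.0) * np.abs(lat_grid)
                  + p.get("lon_slope", 0.0) * lon_grid
                  + p.get("noise_sd", 0.0) * noise[i])
        raster = ClimateRaster(values, extent, resolution,
                               nodata=-9999.0, variable_id=var)
        if nodata_border > 0:
            b = nodata_border
            v = raster.values
            v[:b, :] = v[-b:, :] = raster.nodata
            v[:, :b] = v[:, -b:] = raster.nodata
        rasters.append(raster)
    return rasters


def _suitability(rasters: list[ClimateRaster],
                 niche: NicheSpec) -> np.ndarray:
    """Per-cell Gaussian suitability with hard truncation; 0 on nodata."""
    log_s = np.zeros(rasters[0].shape)
    valid = np.ones(rasters[0].shape, dtype=bool)
    by_var = {r.variable_id: r for r in rasters}
    for var, c in niche.center.items():
        r = by_var[var]
        b = niche.breadth[var]
        valid &= ~r.mask
        log_s = log_s - (r.values - c) ** 2 / (2.0 * b * b)
    s = np.where(valid, np.exp(log_s), 0.0)
    for var, (side, cut) in niche.truncation.items():
        vals = by_var[var].values
        if side == "le":
            s = np.where(vals <= cut, s, 0.0)
        elif side == "ge":
            s = np.where(vals >= cut, s, 0.0)
        else:
            raise ValueError(f"truncation side must be 'le' or 'ge', "
                             f"got {side!r}")
    return s


def sample_occurrences(rasters: list[ClimateRaster], niche: NicheSpec,
                       n: int, seed: int = 0,
                       species: str = "sp") -> pd.DataFrame:
    """Occurrence cloud sampled proportionally to climatic suitability.

    Cells are drawn with probability proportional to suitability (with
    replacement) and each point is placed uniformly within its cell.
    """
    ref = rasters[0]
    s = _suitability(rasters, niche)
    total = s.sum()
    if total <= 0:
        raise ValueError("all-zero suitability: nothing to sample")
    probs = (s / total).ravel()
    rng = np.random.default_rng(seed)
    cells = rng.choice(probs.size, size=n, p=probs)
    rows, cols = np.unravel_index(cells, s.shape)
    lon_min, _, _, lat_max = ref.extent
    res = ref.resolution
    lon = lon_min + (cols + rng.random(n)) * res
    lat = lat_max - (rows + rng.random(n)) * res
    return pd.DataFrame({"species": species, "lon": lon, "lat": lat})


def default_niche(lat_optimum: float = 35.0,
                  breadth_scale: float = 1.0) -> NicheSpec:
    """A broad niche centered on the gradient climate at one latitude."""
    center = {v: p["intercept"] + p["lat_slope"] * abs(lat_optimum)
              for v, p in DEFAULT_GRADIENTS.items()}
    breadth = {"BIO5": 4.0, "BIO6": 6.0, "BIO10": 4.0, "BIO11": 5.0,
               "BIO17": 25.0}
    return NicheSpec(center=center,
                     breadth={v: b * breadth_scale
                              for v, b in breadth.items()})


def make_pair_scenario(kind: str, n_insect: int = 50, n_host: int = 50,
                       lat_optimum: float = 35.0,
                       host_breadth_scale: float = 2.0, seed: int = 0
                       ) -> tuple[pd.DataFrame, pd.DataFrame,
                                  list[ClimateRaster], dict]:
    """An insect/host occurrence pair with known equivalency status.

    The host pool is a climate generalist — its niche breadths are twice
    the single-species defaults, so its realized range spans a wide
    climatic band, as a union of several tree species' ranges does.
    ``kind="equivalent"``: the insect is sampled from the same broad
    niche.  ``kind="truncated"``: the insect's suitability is hard-zeroed
    wherever BIO5 exceeds the niche optimum, confining it to the colder
    half of the host's niche (the classic narrower-than-host pattern).
    Returns (insect table, host table, rasters, truth record).
    """
    if kind not in ("equivalent", "truncated"):
        raise ValueError(f"unknown scenario kind {kind!r}")
    rng = np.random.default_rng(seed)
    raster_seed, host_seed, insect_seed = rng.integers(2 ** 31, size=3)
    rasters = make_synthetic_rasters(seed=int(raster_seed))
    host_niche = default_niche(lat_optimum, breadth_scale=host_breadth_scale)
    insect_niche = NicheSpec(center=dict(host_niche.center),
                             breadth=dict(host_niche.breadth))
    if kind == "truncated":
        insect_niche.truncation = {"BIO5": ("le",
                                            host_niche.center["BIO5"])}
    host = sample_occurrences(rasters, host_niche, n_host,
                              seed=int(host_seed), species="host")
    insect = sample_occurrences(rasters, insect_niche, n_insect,
                                seed=int(insect_seed), species="insect")
    truth = {"kind": kind, "seed": seed, "n_insect": n_insect,
             "n_host": n_host, "lat_optimum": lat_optimum,
             "center": host_niche.center, "breadth": host_niche.breadth,
             "truncation": insect_niche.truncation}
    return insect, host, rasters, truth


def make_clade_scenario(n_species: int = DESK_N_TIPS,
                        occ_per_species: int = DESK_OCC_PER_SPECIES,
                        lam: float = 1.0, birth_rate: float = 0.1,
                        seed: int = 0
                        ) -> tuple[TimeTree, pd.DataFrame,
                                   list[ClimateRaster], dict]:
    """A whole-clade scenario for the signal and disparity analyses.

    A latitudinal optimum evolves along a Yule tree under λ-transformed
    Brownian motion (so climatic niches inherit the requested amount of
    phylogenetic signal through the raster gradients); each species'
    occurrences are then sampled around its own niche.  Returns
    (tree, occurrence table, rasters, truth record).
    """
    rng = np.random.default_rng(seed)
    tree_seed, trait_seed, raster_seed = rng.integers(2 ** 31, size=3)
    tree = simulate_yule_tree(n_species, birth_rate=birth_rate,
                              seed=int(tree_seed))
    # per-Ma variance of the latitudinal optimum; scaled so a ~30 Ma-deep
    # clade spreads over a realistic band of latitudes
    sigma_lat = np.array([[1.5]]) / max(tree.depth, 1.0) * 30.0
    lat_opt = simulate_lambda_bm(tree, lam, sigma_lat, root=35.0,
                                 seed=int(trait_seed)).iloc[:, 0]
    lat_opt = lat_opt.clip(22.0, 48.0)  # keep optima inside the raster
    rasters = make_synthetic_rasters(seed=int(raster_seed))
    tables = []
    for i, sp in enumerate(tree.tip_names):
        niche = default_niche(float(lat_opt[sp]), breadth_scale=0.6)
        tables.append(sample_occurrences(
            rasters, niche, occ_per_species,
            seed=int((seed * 100003 + i) % (2 ** 31)), species=sp))
    occ = pd.concat(tables, ignore_index=True)
    truth = {"lambda": lam, "seed": seed, "n_species": n_species,
             "occ_per_species": occ_per_species,
             "lat_optima": {sp: float(lat_opt[sp])
                            for sp in tree.tip_names}}
    return tree, occ, rasters, truth
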