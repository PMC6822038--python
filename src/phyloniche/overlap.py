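"""Niche overlap in environmental space and the equivalency test.

The machinery follows the environmental-PCA kernel approach: for a pair
of entities (an insect and the pooled range of its host plants) build a
geographic background rectangle per entity (occurrence bounding box
buffered by 10° and clipped to the rasters), run one PCA over the pooled
background pixels of the pair, project occurrences and backgrounds onto
the first two axes, and grid the scores at resolution R×R with Gaussian
kernels.  Occupancy is corrected for availability — occurrence density
divided by background density — so overlap measures preference rather
than background climate frequency.  Overlap is Schoener's
D = 1 − ½·Σ|z₁ − z₂|; equivalency is tested by pooling the two
occurrence sets, resplitting them at the original sizes, and comparing
the observed D to the null distribution (one-sided: low D rejects
equivalency).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .climate import extract_at_points
from .core_io import ClimateRaster, deduplicate

logger = logging.getLogger("phyloniche")

#: background cells whose availability density is at or below this
#: fraction of the modal (maximum) availability are treated as absent
#: from the study area and excluded from occupancy (z = 0).  The o/e
#: correction is only meaningful where the environment actually occurs:
#: with Gaussian-tailed kernel densities a looser guard lets a large
#: share of occupancy mass land in essentially non-existent climates.
AVAILABILITY_THRESHOLD = 0.05

DEFAULT_BUFFER_DEG = 10.0
DEFAULT_GRID_R = 100
DEFAULT_REPS = 100


@dataclass
class EnvBackground:
    """Climate values of every valid raster cell in a buffered rectangle."""

    rectangle: tuple[float, float, float, float]
    pixel_scores: pd.DataFrame  # one row per valid cell, one col per variable


@dataclass
class PcaSpace:
    """A 2-axis environmental PCA (centered, unit-scaled variables)."""

    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray          # (2, n_variables), orthonormal rows
    explained_variance_ratio: np.ndarray
    variables: list[str]

    def transform(self, values: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(values, pd.DataFrame):
            values = values[self.variables].to_numpy(dtype=float)
        z = (np.asarray(values, dtype=float) - self.center) / self.scale
        return z @ self.loadings.T


@dataclass
class OccupancyGrid:
    """R×R densities in PCA score space: occurrence o, availability e,
    corrected occupancy z (sums to 1)."""

    R: int
    extent: tuple[float, float, float, float]  # x_min, x_max, y_min, y_max
    o: np.ndarray
    e: np.ndarray
    z: np.ndarray


@dataclass
class EquivalencyResult:
    """Observed Schoener's D against the pooled-split null."""

    d_obs: float
    null_d: list[float]
    n_reps: int
    p_value: float
    seed: int
    n_a: int = 0
    n_b: int = 0

    def to_dict(self) -> dict:
        return {"D_obs": self.d_obs, "p_value": self.p_value,
                "n_reps": self.n_reps, "seed": self.seed,
                "n_occurrences_a": self.n_a, "n_occurrences_b": self.n_b,
                "null_d": self.null_d}


def host_union(insect: str, assoc: dict[str, set[str]],
               host_occ: pd.DataFrame) -> pd.DataFrame:
    """Pooled occurrences of every host associated with an insect entity.

    The union is deduplicated on coordinates and relabeled with a single
    pseudo-species label so it behaves as one entity downstream.  Hosts
    with no records are logged, not fatal; an entity whose hosts have no
    records at all is an error.
    """
    if insect not in assoc:
        raise KeyError(f"no host association for {insect!r}")
    hosts = sorted(assoc[insect])
    present = host_occ[host_occ["species"].isin(hosts)]
    missing = set(hosts) - set(present["species"])
    if missing:
        logger.warning("hosts of %s without occurrences: %s",
                       insect, sorted(missing))
    if present.empty:
        raise ValueError(f"no host of {insect!r} has any occurrence")
    pooled = present.copy()
    pooled["species"] = f"hosts_of_{insect}"
    return deduplicate(pooled)


def build_background(occ: pd.DataFrame, rasters: list[ClimateRaster],
                     buffer: float = DEFAULT_BUFFER_DEG) -> EnvBackground:
    """Buffered bounding-box background of an entity.

    The rectangle is the occurrence bounding box expanded by ``buffer``
    degrees on all sides, clipped to the raster extent and to latitude
    [-90, 90].  Pixel scores come from every cell center inside the
    rectangle with valid values in all variables.
    """
    if occ.empty:
        raise ValueError("cannot build a background from zero occurrences")
    ref = rasters[0]
    lon_min = occ["lon"].min() - buffer
    lon_max = occ["lon"].max() + buffer
    lat_min = max(occ["lat"].min() - buffer, -90.0)
    lat_max = min(occ["lat"].max() + buffer, 90.0)
    e_lon_min, e_lat_min, e_lon_max, e_lat_max = ref.extent
    rect = (max(lon_min, e_lon_min), max(lat_min, e_lat_min),
            min(lon_max, e_lon_max), min(lat_max, e_lat_max))
    lons, lats = ref.cell_centers()
    in_lon = (lons >= rect[0]) & (lons < rect[2])
    in_lat = (lats >= rect[1]) & (lats < rect[3])
    cols = np.where(in_lon)[0]
    rows = np.where(in_lat)[0]
    if cols.size == 0 or rows.size == 0:
        raise ValueError("background rectangle contains zero raster cells")
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    valid = np.ones(rr.shape, dtype=bool)
    data = {}
    for r in rasters:
        vals = r.values[rr, cc]
        valid &= ~r.mask[rr, cc]
        data[r.variable_id] = vals
    if not valid.any():
        raise ValueError("background rectangle contains zero valid cells")
    table = pd.DataFrame({v: a[valid] for v, a in data.items()})
    return EnvBackground(rectangle=rect, pixel_scores=table)


def pca_env(bg_a: EnvBackground, bg_b: EnvBackground) -> PcaSpace:
    """PCA calibrated on the pooled background pixels of the entity pair.

    Variables are centered and scaled to unit (sample) variance before the
    decomposition; the first two axes are retained.
    """
    pooled = pd.concat([bg_a.pixel_scores, bg_b.pixel_scores],
                       ignore_index=True)
    if len(pooled) < 3:
        raise ValueError("fewer than 3 pooled background pixels")
    X = pooled.to_numpy(dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    nonzero = scale > 0
    if nonzero.sum() < 2:
        raise ValueError("fewer than 2 variables with nonzero variance")
    scale = np.where(nonzero, scale, 1.0)
    Z = (X - center) / scale
    pca = PCA(n_components=2, svd_solver="full")
    pca.fit(Z)
    return PcaSpace(center=center, scale=scale,
                    loadings=pca.components_,
                    explained_variance_ratio=pca.explained_variance_ratio_,
                    variables=list(pooled.columns))


def _axis_bandwidth(scores: np.ndarray) -> float:
    """Normal-reference bandwidth for a 2-D product Gaussian kernel:
    h = σ · n^(−1/6) per axis (Scott/Silverman rule at d = 2)."""
    n = scores.shape[0]
    sd = float(np.std(scores, ddof=1))
    if sd == 0:
        raise ValueError("zero bandwidth: all scores identical on an axis")
    return sd * n ** (-1.0 / 6.0)


def _kernel_density_grid(points: np.ndarray, xc: np.ndarray, yc: np.ndarray,
                         hx: float, hy: float) -> np.ndarray:
    """Product-Gaussian KDE of ``points`` at the grid of cell centers.

    Separable kernels make this a pair of (n × R) evaluations and one
    matrix product.
    """
    n = points.shape[0]
    ux = (xc[None, :] - points[:, 0][:, None]) / hx
    uy = (yc[None, :] - points[:, 1][:, None]) / hy
    gx = np.exp(-0.5 * ux ** 2)
    gy = np.exp(-0.5 * uy ** 2)
    return (gy.T @ gx) / (n * 2.0 * np.pi * hx * hy)


def occupancy_grid(occ_scores: np.ndarray, bg_scores: np.ndarray,
                   extent: tuple[float, float, float, float],
                   R: int = DEFAULT_GRID_R,
                   e: np.ndarray | None = None,
                   bg_bandwidths: tuple[float, float] | None = None
                   ) -> OccupancyGrid:
    """Corrected occupancy of an entity on an R×R environmental grid.

    ``o`` is the kernel density of the occurrence scores at the cell
    centers, ``e`` the same for the background scores; occupancy is o/e
    where availability exceeds ``AVAILABILITY_THRESHOLD``·max(e) and 0
    elsewhere, normalized to sum 1 as ``z``.  A precomputed ``e`` may be
    passed so permutation replicates reuse the frozen availability
    surface.
    """
    occ_scores = np.asarray(occ_scores, dtype=float)
    if occ_scores.shape[0] < 5:
        raise ValueError("need at least 5 occurrence scores")
    x_min, x_max, y_min, y_max = extent
    xc = x_min + (np.arange(R) + 0.5) * (x_max - x_min) / R
    yc = y_min + (np.arange(R) + 0.5) * (y_max - y_min) / R
    hx = _axis_bandwidth(occ_scores[:, 0])
    hy = _axis_bandwidth(occ_scores[:, 1])
    o = _kernel_density_grid(occ_scores, xc, yc, hx, hy)
    if e is None:
        bg_scores = np.asarray(bg_scores, dtype=float)
        if bg_bandwidths is None:
            bg_bandwidths = (_axis_bandwidth(bg_scores[:, 0]),
                             _axis_bandwidth(bg_scores[:, 1]))
        e = _kernel_density_grid(bg_scores, xc, yc, *bg_bandwidths)
    available = e > AVAILABILITY_THRESHOLD * e.max()
    raw = np.where(available, o / np.where(available, e, 1.0), 0.0)
    total = raw.sum()
    if total <= 0:
        raise ValueError("all occurrence density fell on unavailable cells")
    return OccupancyGrid(R=R, extent=extent, o=o, e=e, z=raw / total)


def schoener_d(z_a: np.ndarray, z_b: np.ndarray) -> float:
    """Schoener's D = 1 − ½·Σ|z_a − z_b| over grid cells."""
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    if z_a.shape != z_b.shape:
        raise ValueError("occupancy grids have different shapes")
    return float(1.0 - 0.5 * np.abs(z_a - z_b).sum())


def _shared_extent(*score_sets: np.ndarray
                   ) -> tuple[float, float, float, float]:
    pooled = np.vstack(score_sets)
    return (float(pooled[:, 0].min()), float(pooled[:, 0].max()),
            float(pooled[:, 1].min()), float(pooled[:, 1].max()))


def equivalency_test(occ_a: pd.DataFrame, occ_b: pd.DataFrame,
                     rasters: list[ClimateRaster],
                     reps: int = DEFAULT_REPS, seed: int = 0,
                     R: int = DEFAULT_GRID_R,
                     buffer: float = DEFAULT_BUFFER_DEG,
                     two_sided: bool = False) -> EquivalencyResult:
    """Pooled-split niche-equivalency test between two occurrence sets.

    Pipeline: per-entity backgrounds → one PCA on the pooled background
    pixels → shared grid extent (range of pooled background scores) →
    corrected occupancy grids → observed D.  The null pools the two
    entities' occurrence scores and, ``reps`` times, reshuffles and
    resplits them at the original sizes (backgrounds, PCA, availability
    surfaces and their bandwidths stay frozen; occurrence bandwidths are
    recomputed per split), rebuilding both grids and recording D.  The
    p-value is (#{null ≤ D_obs} + 1)/(reps + 1), one-sided: a low
    observed D rejects equivalency.
    """
    vals_a = extract_at_points(rasters, occ_a)
    vals_b = extract_at_points(rasters, occ_b)
    if len(vals_a) < 5 or len(vals_b) < 5:
        raise ValueError("each entity needs >= 5 records with valid climate")
    bg_a = build_background(occ_a, rasters, buffer=buffer)
    bg_b = build_background(occ_b, rasters, buffer=buffer)
    space = pca_env(bg_a, bg_b)
    variables = space.variables
    bg_scores_a = space.transform(bg_a.pixel_scores)
    bg_scores_b = space.transform(bg_b.pixel_scores)
    scores_a = space.transform(vals_a[variables])
    scores_b = space.transform(vals_b[variables])
    extent = _shared_extent(bg_scores_a, bg_scores_b)

    grid_a = occupancy_grid(scores_a, bg_scores_a, extent, R=R)
    grid_b = occupancy_grid(scores_b, bg_scores_b, extent, R=R)
    d_obs = schoener_d(grid_a.z, grid_b.z)

    pooled = np.vstack([scores_a, scores_b])
    n_a = scores_a.shape[0]
    rng = np.random.default_rng(seed)
    null_d: list[float] = []
    for _ in range(reps):
        perm = rng.permutation(pooled.shape[0])
        part_a = pooled[perm[:n_a]]
        part_b = pooled[perm[n_a:]]
        ga = occupancy_grid(part_a, None, extent, R=R, e=grid_a.e)
        gb = occupancy_grid(part_b, None, extent, R=R, e=grid_b.e)
        null_d.append(schoener_d(ga.z, gb.z))
    arr = np.asarray(null_d)
    p_low = (int((arr <= d_obs).sum()) + 1) / (reps + 1)
    if two_sided:
        p_high = (int((arr >= d_obs).sum()) + 1) / (reps + 1)
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        p = p_low
    return EquivalencyResult(d_obs=d_obs, null_d=[float(d) for d in null_d],
                             n_reps=reps, p_value=float(p), seed=seed,
                             n_a=n_a, n_b=scores_b.shape[0])
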