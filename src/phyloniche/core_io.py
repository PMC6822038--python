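"""Input/output layer: time trees, occurrence tables, climate rasters.

Everything downstream (climate extraction, phylogenetic signal, disparity,
niche overlap) consumes the containers defined here.  Trees are wrapped
dendropy trees with branch lengths in millions of years; occurrence tables
are plain pandas DataFrames with ``species``/``lon``/``lat`` columns;
rasters are dataclasses over a numpy grid with an ESRI-ASCII-style extent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("phyloniche")

#: relative tolerance on the root-to-tip depth spread below which a tree is
#: called ultrametric; beyond it we warn and flag rather than fail, since
#: time-calibrated trees written to file carry rounding noise.
ULTRAMETRIC_RTOL = 1e-6

REQUIRED_OCC_COLUMNS = ("species", "lon", "lat")

#: the five bioclimatic variables the analyses run on.
BIOCLIM_VARIABLES = ("BIO5", "BIO6", "BIO10", "BIO11", "BIO17")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class TreeError(ValueError):
    """Malformed or unusable phylogeny."""


@dataclass
class TimeTree:
    """A rooted, time-calibrated phylogeny.

    Parameters
    ----------
    tree:
        The underlying dendropy tree.  Branch lengths are interpreted as
        absolute time (Ma).  A missing root edge length is treated as 0.
    is_ultrametric:
        True when all root-to-tip path lengths agree to a relative
        tolerance of ``ULTRAMETRIC_RTOL``.
    """

    tree: dendropy.Tree
    is_ultrametric: bool = field(default=True)

    def __post_init__(self) -> None:
        labels = self.tip_names
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate tip labels in tree")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeError(f"negative branch length {edge.length!r}")

    @property
    def tip_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def node_depths(self) -> dict[dendropy.Node, float]:
        """Depth (time from the root) of every node."""
        depths: dict[dendropy.Node, float] = {}
        for node in self.tree.preorder_node_iter():
            parent = node.parent_node
            edge = node.edge.length or 0.0
            depths[node] = edge if parent is None else depths[parent] + edge
        return depths

    def tip_depths(self) -> dict[str, float]:
        depths = self.node_depths()
        return {leaf.taxon.label: depths[leaf]
                for leaf in self.tree.leaf_node_iter()}

    @property
    def depth(self) -> float:
        """Maximum root-to-tip path length (tree height, Ma)."""
        return max(self.tip_depths().values())

    def prune_to(self, keep: list[str]) -> "TimeTree":
        """Return a copy restricted to ``keep`` tips.

        Degree-2 internal nodes left by the pruning are suppressed with
        their branch lengths summed, so remaining root-to-tip depths are
        unchanged.
        """
        missing = set(keep) - set(self.tip_names)
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")
        if len(keep) < 3:
            raise TreeError(
                f"pruning would leave {len(keep)} tips; at least 3 required")
        clone = self.tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if t.label in set(keep)]
        clone.retain_taxa(taxa, suppress_unifurcations=True)
        # dendropy may leave a unifurcation at the root; fold it in.
        while clone.seed_node.num_child_nodes() == 1:
            child = clone.seed_node.child_nodes()[0]
            extra = clone.seed_node.edge.length or 0.0
            clone.seed_node = child
            child.parent_node = None
            child.edge.length = (child.edge.length or 0.0) + extra
        return TimeTree(clone, is_ultrametric=self.is_ultrametric)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick",
                                   suppress_rooting=True).strip()


def _check_ultrametric(tree: dendropy.Tree) -> bool:
    depths = []
    cache: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        cache[node] = edge if parent is None else cache[parent] + edge
        if node.is_leaf():
            depths.append(cache[node])
    if not depths:
        return True
    spread = max(depths) - min(depths)
    scale = max(abs(d) for d in depths) or 1.0
    return spread <= ULTRAMETRIC_RTOL * scale


def read_tree(path: str | Path) -> TimeTree:
    """Read a Newick tree; warn and flag if it is not ultrametric.

    Node support annotations are ignored.  Malformed input raises
    :class:`TreeError` naming the character position when the parser
    reports one.
    """
    path = Path(path)
    text = path.read_text()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several error types
        offset = getattr(exc, "col_num", None)
        where = f" near character {offset}" if offset is not None else ""
        raise TreeError(f"malformed Newick in {path}{where}: {exc}") from exc
    ultra = _check_ultrametric(tree)
    if not ultra:
        logger.warning("tree %s is not ultrametric (root-to-tip depths "
                       "differ beyond rtol=%g)", path, ULTRAMETRIC_RTOL)
    return TimeTree(tree, is_ultrametric=ultra)


def read_trees(path: str | Path) -> list[TimeTree]:
    """Read a multi-tree Newick file (e.g. a posterior sample)."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick",
                                  suppress_internal_node_taxa=True)
    return [TimeTree(t, is_ultrametric=_check_ultrametric(t)) for t in trees]


# ---------------------------------------------------------------------------
# Occurrence tables
# ---------------------------------------------------------------------------

def read_occurrences(path: str | Path) -> pd.DataFrame:
    """Load a CSV of georeferenced records.

    The file must carry ``species``, ``lon`` and ``lat`` columns; any extra
    columns are preserved as source metadata.  Rows with unparseable or
    out-of-bounds coordinates are rejected with a log line, longitudes are
    normalized to [-180, 180], and exact (species, lon, lat) duplicates are
    dropped.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_OCC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        logger.warning("%s: empty occurrence file", path)
        return df.reset_index(drop=True)
    n0 = len(df)
    df = df.copy()
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    bad_parse = df["lon"].isna() | df["lat"].isna()
    if bad_parse.any():
        logger.info("%s: rejected %d rows with unparseable coordinates",
                    path, int(bad_parse.sum()))
    df = df[~bad_parse]
    df["lon"] = ((df["lon"] + 180.0) % 360.0) - 180.0
    oob = (df["lat"] < -90) | (df["lat"] > 90)
    if oob.any():
        logger.info("%s: rejected %d rows with out-of-bounds latitude",
                    path, int(oob.sum()))
    df = df[~oob]
    df = deduplicate(df)
    logger.info("%s: %d records read, %d retained", path, n0, len(df))
    return df.reset_index(drop=True)


def deduplicate(occ: pd.DataFrame) -> pd.DataFrame:
    """Drop exact (species, lon, lat) duplicates, keeping first."""
    before = len(occ)
    out = occ.drop_duplicates(subset=["species", "lon", "lat"],
                              keep="first").reset_index(drop=True)
    dropped = before - len(out)
    if dropped:
        logger.info("removed %d duplicate records", dropped)
    return out


def read_species_groups(path: str | Path) -> tuple[dict[str, str], set[str]]:
    """Read a species→group CSV (columns ``species,group``).

    A row whose group is empty or the literal ``DROP`` puts the species on
    the drop list.  Returns ``(mapping, drop_list)``.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    if not {"species", "group"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns species,group")
    mapping: dict[str, str] = {}
    drop: set[str] = set()
    for _, row in df.iterrows():
        sp, grp = row["species"].strip(), row["group"].strip()
        if grp in ("", "DROP"):
            drop.add(sp)
        elif sp in mapping and mapping[sp] != grp:
            raise ValueError(f"{path}: species {sp!r} mapped to two groups")
        else:
            mapping[sp] = grp
    return mapping, drop


def read_host_association(path: str | Path) -> dict[str, set[str]]:
    """Read an insect→host CSV (columns ``insect,host``)."""
    df = pd.read_csv(path, dtype=str)
    if not {"insect", "host"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns insect,host")
    assoc: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        assoc.setdefault(row["insect"].strip(), set()).add(row["host"].strip())
    for insect, hosts in assoc.items():
        if not hosts:
            raise ValueError(f"insect {insect!r} has no hosts")
    return assoc


def apply_species_groups(occ: pd.DataFrame, mapping: dict[str, str],
                         drop_list: set[str] | None = None) -> pd.DataFrame:
    """Relabel species to their group and remove drop-listed species.

    Unmapped species pass through unchanged; the operation is idempotent
    because group labels are themselves unmapped.
    """
    drop_list = drop_list or set()
    out = occ[~occ["species"].isin(drop_list)].copy()
    out["species"] = out["species"].map(lambda s: mapping.get(s, s))
    return deduplicate(out)


def filter_min_occurrences(occ: pd.DataFrame, tree: TimeTree,
                           min_n: int = 5) -> tuple[pd.DataFrame, TimeTree]:
    """Drop species with fewer than ``min_n`` records and prune the tree.

    Mirrors the standard comparative-methods filter: species must be both
    adequately sampled and present on the tree.  Tree tips without enough
    records are pruned; table species absent from the tree are dropped too,
    so the returned objects are label-aligned.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    counts = occ.groupby("species").size()
    keep_species = set(counts[counts >= min_n].index)
    tips = set(tree.tip_names)
    keep_tips = sorted(keep_species & tips)
    n_pruned = len(tips) - len(keep_tips)
    if len(keep_tips) < 3:
        raise TreeError(
            f"filter would leave {len(keep_tips)} tips (< 3)")
    pruned = tree.prune_to(keep_tips) if n_pruned else tree
    out = occ[occ["species"].isin(keep_tips)].reset_index(drop=True)
    logger.info("min-occurrence filter (n >= %d): %d -> %d records, "
                "%d -> %d tips", min_n, len(occ), len(out),
                len(tips), len(keep_tips))
    return out, pruned


# ---------------------------------------------------------------------------
# Climate rasters
# ---------------------------------------------------------------------------

class RasterError(ValueError):
    """Unreadable or unsupported raster input."""


@dataclass
class ClimateRaster:
    """A single-band geographic grid of one bioclimatic variable.

    ``values`` has row 0 at the northern edge (the ESRI ASCII layout);
    ``extent`` is ``(lon_min, lat_min, lon_max, lat_max)`` in decimal
    degrees; cells are squares of ``resolution`` degrees.  Cells equal to
    ``nodata`` are invalid and excluded from every statistic.
    """

    values: np.ndarray
    extent: tuple[float, float, float, float]
    resolution: float
    nodata: float = -9999.0
    variable_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise RasterError("raster values must be a 2-D grid")
        lon_min, lat_min, lon_max, lat_max = self.extent
        nrows, ncols = self.values.shape
        if (not math.isclose(lon_min + ncols * self.resolution, lon_max,
                             rel_tol=0, abs_tol=1e-6 * self.resolution)
                or not math.isclose(lat_min + nrows * self.resolution,
                                    lat_max, rel_tol=0,
                                    abs_tol=1e-6 * self.resolution)):
            raise RasterError("grid shape inconsistent with extent/resolution")

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid, True where the cell is nodata/invalid."""
        with np.errstate(invalid="ignore"):
            return np.isnan(self.values) | (self.values == self.nodata)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lons of columns, lats of rows), cell-center convention."""
        lon_min, lat_min, lon_max, lat_max = self.extent
        nrows, ncols = self.values.shape
        lons = lon_min + (np.arange(ncols) + 0.5) * self.resolution
        lats = lat_max - (np.arange(nrows) + 0.5) * self.resolution
        return lons, lats

    def index_of(self, lon: np.ndarray,
                 lat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point, plus validity.

        Cells are half-open ``[x, x + res)`` on both axes, so a point on an
        interior edge lands in the higher-coordinate cell.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        lon_min, lat_min, _, _ = self.extent
        nrows, ncols = self.values.shape
        col = np.floor((lon - lon_min) / self.resolution).astype(int)
        from_south = np.floor((lat - lat_min) / self.resolution).astype(int)
        row = nrows - 1 - from_south
        inside = (col >= 0) & (col < ncols) & (row >= 0) & (row < nrows)
        return row, col, inside


def read_raster(path: str | Path, variable_id: str = "") -> ClimateRaster:
    """Read a single-band GeoTIFF or ESRI ASCII grid.

    Only geographic lon/lat rasters are supported; a projected GeoTIFF or a
    multi-band file raises :class:`RasterError` (no reprojection is done).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return _read_geotiff(path, variable_id)
    return _read_ascii_grid(path, variable_id)


def write_raster(raster: ClimateRaster, path: str | Path) -> None:
    """Write as ESRI ASCII (.asc/.txt) or GeoTIFF (.tif) by extension."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        _write_geotiff(raster, path)
    else:
        _write_ascii_grid(raster, path)


def _read_ascii_grid(path: Path, variable_id: str) -> ClimateRaster:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2:
                break
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError:
                break
            pos = fh.tell()
        fh.seek(pos)
        try:
            values = np.loadtxt(fh, dtype=float, ndmin=2)
        except ValueError as exc:
            raise RasterError(f"{path}: cannot parse grid body: {exc}")
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise RasterError(f"{path}: missing ASCII-grid header {key!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    res = header["cellsize"]
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - res / 2
        yll = header["yllcenter"] - res / 2
    else:
        raise RasterError(f"{path}: missing xllcorner/xllcenter header")
    nodata = header.get("nodata_value", -9999.0)
    if values.shape != (nrows, ncols):
        raise RasterError(f"{path}: body shape {values.shape} != header "
                          f"({nrows}, {ncols})")
    extent = (xll, yll, xll + ncols * res, yll + nrows * res)
    return ClimateRaster(values, extent, res, nodata, variable_id)


def _write_ascii_grid(raster: ClimateRaster, path: Path) -> None:
    lon_min, lat_min, _, _ = raster.extent
    nrows, ncols = raster.shape
    vals = np.where(np.isnan(raster.values), raster.nodata, raster.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n"
                 f"xllcorner {lon_min!r}\nyllcorner {lat_min!r}\n"
                 f"cellsize {raster.resolution!r}\n"
                 f"NODATA_value {raster.nodata!r}\n")
        np.savetxt(fh, vals, fmt="%.10g")


# GeoTIFF tag ids (the minimal georeferencing subset).
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113
_GT_MODEL_TYPE_GEOGRAPHIC = 2


def _read_geotiff(path: Path, variable_id: str) -> ClimateRaster:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        if len(tif.pages) != 1:
            raise RasterError(f"{path}: multi-page TIFF not supported")
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise RasterError(f"{path}: multi-band raster not supported")
        values = page.asarray().astype(float)
        tags = page.tags
        if _TAG_GEO_KEYS in tags:
            keys = tags[_TAG_GEO_KEYS].value
            # GeoKey entries are (id, location, count, value) quadruples
            # after the 4-entry header.
            for i in range(4, len(keys), 4):
                if keys[i] == 1024 and keys[i + 3] != _GT_MODEL_TYPE_GEOGRAPHIC:
                    raise RasterError(
                        f"{path}: CRS is not geographic lon/lat")
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise RasterError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        tie = tags[_TAG_TIEPOINT].value
        # tiepoint maps raster (i, j, k) -> model (x, y, z); by convention
        # (0, 0) is the outer corner of the top-left pixel.
        lon_min, lat_max = tie[3], tie[4]
        if not math.isclose(sx, sy, rel_tol=1e-9):
            raise RasterError(f"{path}: anisotropic pixels not supported")
        nodata = -9999.0
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
        nrows, ncols = values.shape
        extent = (lon_min, lat_max - nrows * sy, lon_min + ncols * sx, lat_max)
        return ClimateRaster(values, extent, sx, nodata, variable_id)


def _write_geotiff(raster: ClimateRaster, path: Path) -> None:
    import tifffile

    lon_min, _, _, lat_max = raster.extent
    res = raster.resolution
    vals = np.where(np.isnan(raster.values), raster.nodata, raster.values)
    geo_keys = (1, 1, 0, 1,       # version header, 1 key
                1024, 0, 1, _GT_MODEL_TYPE_GEOGRAPHIC)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (res, res, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, lon_min, lat_max, 0.0)),
        (_TAG_GEO_KEYS, "H", len(geo_keys), geo_keys),
        (_TAG_GDAL_NODATA, "s", 0, str(raster.nodata)),
    ]
    tifffile.imwrite(str(path), vals, extratags=extratags)


def read_raster_stack(paths: dict[str, str | Path]) -> list[ClimateRaster]:
    """Read several variables' rasters and check they share one grid."""
    rasters = [read_raster(p, variable_id=v) for v, p in paths.items()]
    ref = rasters[0]
    for r in rasters[1:]:
        if r.shape != ref.shape or r.extent != ref.extent:
            raise RasterError("rasters do not share extent/resolution")
    return rasters
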