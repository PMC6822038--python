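"""Climate extraction: raster sampling at points and per-species summaries.

The trait matrix built here — one row per species, one column per
bioclimatic variable, entries a chosen order statistic (median by default)
— is the input to the phylogenetic-signal and disparity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ClimateRaster, RasterError

logger = logging.getLogger("phyloniche")

SUMMARY_STATS = ("median", "min", "max")


@dataclass
class TraitMatrix:
    """Species × variable climate summaries.

    ``data`` is indexed by species label; ``standardized`` records whether
    columns have been z-scored (each analysis that requires equal variable
    weighting checks this flag).
    """

    data: pd.DataFrame
    standardized: bool = False

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def aligned_to(self, tip_names: list[str]) -> "TraitMatrix":
        """Reorder rows to a tree's tip order; labels must match exactly."""
        missing = set(tip_names) - set(self.data.index)
        if missing:
            raise ValueError(f"traits missing for tips: {sorted(missing)}")
        return TraitMatrix(self.data.loc[list(tip_names)], self.standardized)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def extract_at_points(rasters: list[ClimateRaster],
                      occ: pd.DataFrame) -> pd.DataFrame:
    """Sample every raster at every occurrence (nearest cell, no
    interpolation).

    Returns one row per retained record with the original ``species``,
    ``lon``, ``lat`` plus one column per raster variable.  Records outside
    the shared raster extent, or hitting nodata in any variable, are
    dropped with a log line.
    """
    ref = rasters[0]
    for r in rasters[1:]:
        if r.shape != ref.shape or r.extent != ref.extent:
            raise RasterError("rasters do not share extent/resolution")
    row, col, inside = ref.index_of(occ["lon"].to_numpy(),
                                    occ["lat"].to_numpy())
    n_outside = int((~inside).sum())
    if n_outside:
        logger.warning("%d records fall outside the raster extent", n_outside)
    row_c = np.clip(row, 0, ref.shape[0] - 1)
    col_c = np.clip(col, 0, ref.shape[1] - 1)
    out = occ.loc[:, ["species", "lon", "lat"]].copy()
    valid = inside.copy()
    for r in rasters:
        vals = r.values[row_c, col_c]
        bad = r.mask[row_c, col_c]
        vals = np.where(bad, np.nan, vals)
        out[r.variable_id or "band"] = vals
        valid &= ~bad
    n_nodata = int((inside & ~valid).sum())
    if n_nodata:
        logger.info("%d records dropped on nodata cells", n_nodata)
    return out[valid].reset_index(drop=True)


def summarize_species(values: pd.DataFrame,
                      variables: list[str] | None = None) -> pd.DataFrame:
    """Per-species median/min/max of each variable.

    ``values`` is the output of :func:`extract_at_points`.  The median of
    an even number of records is the midpoint of the two central order
    statistics.  Species with zero valid records simply do not appear.
    Returns a frame with a (species, stat) row MultiIndex unstacked into
    columns ``(variable, stat)``.
    """
    if variables is None:
        variables = [c for c in values.columns
                     if c not in ("species", "lon", "lat")]
    if values.empty:
        raise ValueError("no valid records to summarize")
    grouped = values.groupby("species")[variables]
    frames = {"median": grouped.median(), "min": grouped.min(),
              "max": grouped.max()}
    out = pd.concat(frames, axis=1).swaplevel(axis=1)
    out = out.reindex(columns=pd.MultiIndex.from_product(
        [variables, ["median", "min", "max"]]))
    out.columns.names = ["variable", "stat"]
    out["n_used"] = grouped.size()
    return out


def trait_matrix(summaries: pd.DataFrame, stat: str = "median") -> TraitMatrix:
    """Pick one summary statistic per variable as the trait matrix."""
    if stat not in SUMMARY_STATS:
        raise ValueError(f"stat must be one of {SUMMARY_STATS}")
    variables = [v for v in summaries.columns.get_level_values(0).unique()
                 if v != "n_used"]
    data = pd.DataFrame({v: summaries[(v, stat)] for v in variables})
    data.index.name = "species"
    return TraitMatrix(data, standardized=False)


def standardize(tm: TraitMatrix) -> TraitMatrix:
    """Column-wise z-scores (sample sd, n−1 denominator).

    Standardization gives every variable the same weight in multivariate
    disparity.  A zero-variance column is an error naming the variable.
    """
    data = tm.data.astype(float)
    sd = data.std(ddof=1)
    zero = sd[(sd == 0) | sd.isna()]
    if len(zero):
        raise ValueError(
            f"zero-variance variable(s): {list(zero.index)}")
    z = (data - data.mean()) / sd
    return TraitMatrix(z, standardized=True)
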