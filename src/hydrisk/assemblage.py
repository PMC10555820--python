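"""Assemblage hydraulic-risk metrics on a grid.

Species ranges are rasterized to a sparse species x cells occupancy
structure; per-pixel statistics (mean, min, sample variance, count below a
threshold, richness) over the trait values of co-occurring species form the
risk layers. Risk layers are exported as -HSM so that higher values mean
higher risk; raw-HSM layers are also available.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .grids import AssemblageGrid, cell_centers

__all__ = [
    "rasterize_ranges",
    "aggregate_metric",
    "clamp_quantiles",
    "compute_assemblage_grid",
]


def rasterize_ranges(ranges, grid_shape: tuple[int, int]):
    """Species x cells boolean occupancy (CSR) plus the species order.

    Accepts a SpeciesRangeSet / mapping of explicit cell lists (passed
    through verbatim) or a mapping of shapely polygons, rasterized by the
    cell-center rule: a cell is occupied iff its center point falls inside
    the polygon. Invalid geometries are skipped with a warning.
    """
    nrows, ncols = grid_shape
    n_cells = nrows * ncols
    cells = ranges.cells if hasattr(ranges, "cells") else dict(ranges)
    rows, cols = [], []
    skipped, species = [], []
    xs = ys = None
    for sp_name in sorted(cells):
        geom = cells[sp_name]
        if hasattr(geom, "geom_type"):  # shapely geometry
            import shapely

            if not geom.is_valid:
                skipped.append(sp_name)
                continue
            if xs is None:
                xs, ys = cell_centers(grid_shape)
            occ = np.flatnonzero(shapely.contains_xy(geom, xs, ys))
        else:
            occ = np.asarray(geom, dtype=int)
            if occ.size and (occ.min() < 0 or occ.max() >= n_cells):
                raise ValueError(f"cell index out of grid for species {sp_name!r}")
        rows.append(np.full(occ.size, len(species)))
        cols.append(occ)
        species.append(sp_name)
    if skipped:
        warnings.warn(f"{len(skipped)} species with invalid geometry skipped: {skipped[:10]}")
    data_rows = np.concatenate(rows) if rows else np.empty(0, dtype=int)
    data_cols = np.concatenate(cols) if cols else np.empty(0, dtype=int)
    occ_mat = sp.csr_matrix(
        (np.ones(data_rows.size, dtype=bool), (data_rows, data_cols)),
        shape=(len(species), n_cells),
    )
    return occ_mat, species


def aggregate_metric(
    occupancy: sp.spmatrix,
    species_values: pd.Series | Sequence[float],
    stat: str,
    grid_shape: tuple[int, int],
    threshold: float = 0.0,
) -> np.ndarray:
    """Per-cell statistic over the values of occupying species.

    ``stat`` is one of mean | min | variance | count_below | richness.
    Species with missing values are excluded from that cell's statistic
    (richness still counts them). Variance is the sample variance (n-1
    denominator); cells with fewer than two valued species get NaN.
    ``count_below`` uses strict ``< threshold``. Unoccupied cells are NaN
    (0 for the count statistics).
    """
    nrows, ncols = grid_shape
    n_species, n_cells = occupancy.shape
    if nrows * ncols != n_cells:
        raise ValueError("grid_shape does not match occupancy")
    values = np.asarray(species_values, dtype=float)
    if values.shape != (n_species,):
        raise ValueError("species_values must align with occupancy rows")

    occ = occupancy.tocsr().astype(float)
    valued = np.isfinite(values)
    occ_valued = occ.multiply(sp.csr_matrix(valued.astype(float)[:, None]))
    counts = np.asarray(occ_valued.sum(axis=0)).ravel()
    richness = np.asarray(occ.sum(axis=0)).ravel()
    if not richness.any():
        warnings.warn("no occupied cells; returning empty layer")

    if stat == "richness":
        return richness.reshape(nrows, ncols)
    if stat == "count_below":
        below = valued & (values < threshold)
        out = np.asarray(
            occ.multiply(sp.csr_matrix(below.astype(float)[:, None])).sum(axis=0)
        ).ravel()
        return out.reshape(nrows, ncols)

    safe_vals = np.where(valued, values, 0.0)
    sums = np.asarray(occ_valued.multiply(safe_vals[:, None]).sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / counts, np.nan)
    if stat == "mean":
        return mean.reshape(nrows, ncols)
    if stat == "variance":
        sq = np.asarray(occ_valued.multiply((safe_vals**2)[:, None]).sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            var = np.where(counts >= 2, (sq - counts * mean**2) / (counts - 1), np.nan)
        return np.clip(var, 0.0, None).reshape(nrows, ncols)
    if stat == "min":
        csc = occ_valued.tocsc()
        out = np.full(n_cells, np.nan)
        for cell in range(n_cells):
            idx = csc.indices[csc.indptr[cell]: csc.indptr[cell + 1]]
            if idx.size:
                out[cell] = safe_vals[idx].min()
        return out.reshape(nrows, ncols)
    raise ValueError(f"unknown stat {stat!r}")


def clamp_quantiles(
    layer: np.ndarray, lower_q: float = 0.05, upper_q: float = 0.95
) -> np.ndarray:
    """Clamp a display layer to its sample quantiles (linear interpolation).

    For visualization only; analysis layers are never clamped.
    """
    finite = np.isfinite(layer)
    if not finite.any():
        raise ValueError("layer has no finite values")
    lo = np.nanquantile(layer, lower_q)
    hi = np.nanquantile(layer, upper_q)
    return np.clip(layer, lo, hi)


_TRAIT_LAYERS: Mapping[str, Sequence[str]] = {
    "p_min": ("mean", "variance"),
    "p50": ("mean", "variance"),
}


def compute_assemblage_grid(
    occupancy: sp.spmatrix,
    species: Sequence[str],
    traits: pd.DataFrame,
    grid_shape: tuple[int, int],
) -> AssemblageGrid:
    """Standard layer set from a completed trait table.

    Produces richness, per-trait mean/variance, and for each HSM variant
    present (``hsm``, ``hsm_50_88``): mean(-HSM), raw mean, min, variance
    and the count of species with HSM < 0.
    """
    vals = traits.reindex(species)
    grid = AssemblageGrid(tuple(grid_shape))
    grid.add("richness", aggregate_metric(occupancy, np.ones(len(species)), "richness", grid_shape))
    for trait, stats_ in _TRAIT_LAYERS.items():
        if trait not in vals.columns:
            continue
        v = vals[trait]
        for st in stats_:
            name = f"{'mean' if st == 'mean' else 'var'}_{trait.replace('_', '')}"
            grid.add(name, aggregate_metric(occupancy, v, st, grid_shape))
    for hsm_col, suffix in (("hsm", ""), ("hsm_50_88", "_5088")):
        if hsm_col not in vals.columns:
            continue
        v = vals[hsm_col]
        grid.add(f"mean_neg_hsm{suffix}", -aggregate_metric(occupancy, v, "mean", grid_shape))
        grid.add(f"mean_hsm{suffix}", aggregate_metric(occupancy, v, "mean", grid_shape))
        grid.add(f"min_hsm{suffix}", aggregate_metric(occupancy, v, "min", grid_shape))
        grid.add(f"var_hsm{suffix}", aggregate_metric(occupancy, v, "variance", grid_shape))
        grid.add(
            f"n_hsm_neg{suffix}",
            aggregate_metric(occupancy, v, "count_below", grid_shape, threshold=0.0),
        )
    return grid
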