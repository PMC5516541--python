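"""Vector-to-raster conversion and gridded age/sex count production.

Unit-level attributes become rasters by cell-center containment on a fixed
grid template -- every layer in a run shares the template bit-exactly, so
cellwise map algebra is well defined.  Gridded age/sex counts are the
cellwise product of a gridded proportion layer and the population-count
surface, after the population surface has been scaled per country to
match national reference totals.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping

import numpy as np
import pandas as pd
from shapely import intersects_xy

from .boundaries import AdminBoundarySet
from .grid import GridTemplate, RasterLayer, require_aligned, zonal_sum
from .schema import STANDARD_14

SEXES = ("male", "female")


def rasterize_attribute(
    boundaries: AdminBoundarySet,
    attribute: str | None,
    template: GridTemplate,
    unit_index: bool = False,
) -> RasterLayer:
    """Burn a numeric polygon attribute onto the grid template.

    Each cell takes the value of the polygon containing its center; cells
    whose center falls in no polygon get nodata.  A center lying exactly
    on a shared edge goes to the first polygon in file order (containment
    is tested boundary-inclusive, first assignment wins), which makes the
    operation deterministic.  With ``unit_index=True`` the polygon's unit
    id is burned instead of an attribute.
    """
    if unit_index:
        values = pd.Series(boundaries.unit_ids, index=boundaries.attributes.index)
    else:
        if attribute not in boundaries.attributes.columns:
            raise ValueError(f"attribute {attribute!r} missing from boundaries")
        values = boundaries.attributes[attribute]
        if values.isna().any():
            bad = list(values[values.isna()].index)
            raise ValueError(f"attribute {attribute!r} missing on polygon(s) {bad}")
    xs, ys = template.cell_centers()
    out = np.full(template.shape, template.nodata)
    unassigned = np.ones(template.shape, dtype=bool)
    for geom, (uid, val) in zip(boundaries.geometries, values.items()):
        hit = intersects_xy(geom, xs, ys) & unassigned
        if not hit.any():
            warnings.warn(f"polygon {uid!r} covers no cell center")
            continue
        out[hit] = float(val)
        unassigned &= ~hit
    semantics = "iso-code" if unit_index else "count"
    return RasterLayer(template, out, semantics)


def table_to_proportion_layers(
    boundaries: AdminBoundarySet,
    table: pd.DataFrame,
    template: GridTemplate,
) -> tuple[dict[str, RasterLayer], dict[str, RasterLayer]]:
    """Rasterise a standard table into age and sex proportion stacks.

    The table (percent scale, indexed by unit id matching the boundaries)
    is joined to the polygons and each age group and the two-way sex split
    are burned as fraction layers in [0, 1].
    """
    joined = boundaries.join(table)
    age_stack = {}
    for lab in STANDARD_14.labels:
        lyr = rasterize_attribute(joined, lab, template)
        lyr.values[lyr.data_mask()] /= 100.0
        lyr.semantics = "proportion-fraction"
        age_stack[lab] = lyr
    sex_stack = {}
    for sex, col in (("male", "MPROP"), ("female", "FPROP")):
        lyr = rasterize_attribute(joined, col, template)
        lyr.values[lyr.data_mask()] /= 100.0
        lyr.semantics = "proportion-fraction"
        sex_stack[sex] = lyr
    return age_stack, sex_stack


def adjust_to_national_totals(
    pop: RasterLayer, iso: RasterLayer, targets: Mapping[int, float]
) -> RasterLayer:
    """Scale each country's population cells to a national reference total.

    Cells of country ``c`` are multiplied by ``target_c / current_sum_c``;
    post-adjustment country sums match targets to within float error.
    """
    require_aligned(pop, iso)
    sums = zonal_sum(pop, iso)
    missing = sorted(set(sums) - set(int(k) for k in targets))
    if missing:
        raise ValueError(f"no national target for country code(s) {missing}")
    out = pop.values.copy()
    mask = pop.data_mask() & iso.data_mask()
    for code, current in sums.items():
        target = float(targets[code])
        if current == 0:
            if target > 0:
                raise ValueError(
                    f"country {code} has zero population but positive target {target}"
                )
            continue
        sel = mask & (iso.values == code)
        out[sel] *= target / current
    return pop.with_values(out)


def disaggregate_age_sex(
    prop_stack: Mapping[str, RasterLayer],
    population: RasterLayer,
    sex_stack: Mapping[str, RasterLayer] | None = None,
    tol: float = 1e-6,
) -> dict[str, RasterLayer]:
    """Gridded age(/sex) counts: proportion layer x population, cellwise.

    ``prop_stack`` maps age-group labels to gridded proportion layers that
    must sum to 1 cellwise (checked to ``tol``) wherever data exist.  If
    ``sex_stack`` is given, each age-count layer is further multiplied by
    the male/female proportion layers (uniform across ages within a unit),
    yielding keys like ``A0004_male``.  Nodata propagates; insertion order
    of the stack is preserved.
    """
    layers = list(prop_stack.values())
    require_aligned(population, *layers)
    if sex_stack is not None:
        require_aligned(population, *sex_stack.values())
    mask = population.data_mask()
    for lyr in layers:
        mask &= lyr.data_mask()
    cellwise = sum(lyr.values * mask for lyr in layers)
    bad = mask & (np.abs(cellwise - 1.0) > tol)
    if bad.any():
        raise ValueError(
            f"age-proportion stack does not sum to 1 within {tol} on "
            f"{int(bad.sum())} cell(s)"
        )
    out: dict[str, RasterLayer] = {}
    for lab, prop in prop_stack.items():
        counts = np.where(mask, prop.values * population.values, population.nodata)
        if sex_stack is None:
            out[lab] = population.with_values(counts, "count")
        else:
            for sex, sp in sex_stack.items():
                vals = np.where(
                    mask & sp.data_mask(), counts * sp.values, population.nodata
                )
                out[f"{lab}_{sex}"] = population.with_values(vals, "count")
    return out


def extract_country(
    layer: RasterLayer, iso: RasterLayer, code: int, crop: bool = False
) -> RasterLayer:
    """Mask a layer to one country of the ISO-code raster.

    Cells where the mask equals ``code`` are kept, everything else becomes
    nodata.  With ``crop=True`` the window is trimmed to the country's
    bounding box by whole cells, preserving grid alignment.
    """
    require_aligned(layer, iso)
    keep = iso.data_mask() & (iso.values == code) & layer.data_mask()
    if not keep.any():
        warnings.warn(f"country code {code} absent from mask: all-nodata layer")
    vals = np.where(keep, layer.values, layer.nodata)
    if not crop or not keep.any():
        return layer.with_values(vals)
    rows = np.flatnonzero(keep.any(axis=1))
    cols = np.flatnonzero(keep.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    t = layer.template
    sub = GridTemplate(
        west=t.west + c0 * t.resolution,
        north=t.north - r0 * t.resolution,
        resolution=t.resolution,
        n_rows=r1 - r0,
        n_cols=c1 - c0,
        crs=t.crs,
        nodata=t.nodata,
    )
    return RasterLayer(sub, vals[r0:r1, c0:c1], layer.semantics)


def rasterize_ratios(
    boundaries: AdminBoundarySet,
    ratios: pd.DataFrame,
    template: GridTemplate,
) -> dict[str, RasterLayer]:
    """Constant-within-unit CDR/YDR/ODR surfaces from a unit ratio table."""
    joined = boundaries.join(ratios[["CDR", "YDR", "ODR"]])
    out = {}
    for name in ("CDR", "YDR", "ODR"):
        lyr = rasterize_attribute(joined, name, template)
        lyr.semantics = "ratio"
        out[name] = lyr
    return out
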