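"""Rasterisation, alignment, national-total adjustment, disaggregation and
country extraction, checked against cell-center containment and zonal
oracles."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box

from demogrid import (
    AdminBoundarySet,
    GridTemplate,
    RasterLayer,
    adjust_to_national_totals,
    disaggregate_age_sex,
    extract_country,
    rasterize_attribute,
    read_ascii_grid,
    write_ascii_grid,
    zonal_sum,
)
from demogrid.grid import AlignmentError


def _tmpl(n=4, res=1.0):
    return GridTemplate(west=0.0, north=n * res, resolution=res, n_rows=n, n_cols=n)


def _bset(geoms, values=None, name="v"):
    attrs = pd.DataFrame(
        {name: values if values is not None else [0.0] * len(geoms)},
        index=pd.Index(range(1, len(geoms) + 1), name="unit_id"),
    )
    return AdminBoundarySet(geoms, attrs)


def _layer(tmpl, values, semantics="count"):
    return RasterLayer(tmpl, np.asarray(values, dtype=float), semantics)


class TestRasterize:
    def test_single_polygon_fills_grid(self):
        tmpl = _tmpl(4)
        b = _bset([box(0, 0, 4, 4)], [0.3])
        out = rasterize_attribute(b, "v", tmpl)
        assert (out.values == 0.3).all()

    def test_two_half_rectangles(self):
        tmpl = _tmpl(4)
        b = _bset([box(0, 0, 2, 4), box(2, 0, 4, 4)], [0.2, 0.8])
        out = rasterize_attribute(b, "v", tmpl)
        assert (out.values[:, :2] == 0.2).all()
        assert (out.values[:, 2:] == 0.8).all()
        assert out.data_mask().all()

    def test_polygon_covering_no_center_warns(self):
        tmpl = _tmpl(4)
        sliver = box(0.9, 0.9, 1.1, 1.1)  # between cell centers at .5 and 1.5
        with pytest.warns(UserWarning, match="covers no cell center"):
            out = rasterize_attribute(_bset([sliver], [1.0]), "v", tmpl)
        assert not out.data_mask().any()

    def test_missing_attribute_errors(self):
        b = _bset([box(0, 0, 4, 4)], [1.0])
        with pytest.raises(ValueError, match="missing"):
            rasterize_attribute(b, "nope", _tmpl(4))

    def test_shared_edge_goes_to_first_polygon(self):
        # centers on x=1.5 lie exactly on the shared edge of these boxes
        tmpl = GridTemplate(west=0.0, north=1.0, resolution=1.0, n_rows=1, n_cols=3)
        left = box(0, 0, 1.5, 1)
        right = box(1.5, 0, 3, 1)
        out = rasterize_attribute(_bset([left, right], [1.0, 2.0]), "v", tmpl)
        assert out.values[0, 1] == 1.0  # boundary tie -> first in file order

    def test_matches_center_containment_oracle_on_random_mosaics(self, rng):
        """Random rectangle mosaics: compare against a per-cell loop that
        asks shapely directly which polygon contains each center."""
        for _ in range(5):
            n = 6
            tmpl = _tmpl(n)
            # random vertical splits into three rectangles
            xs = np.sort(rng.choice(np.arange(1, n), 2, replace=False))
            geoms = [
                box(0, 0, xs[0], n),
                box(xs[0], 0, xs[1], n),
                box(xs[1], 0, n, n),
            ]
            vals = rng.uniform(1, 9, 3)
            out = rasterize_attribute(_bset(geoms, list(vals)), "v", tmpl)
            cx, cy = tmpl.cell_centers()
            for r in range(n):
                for c in range(n):
                    p = Point(cx[r, c], cy[r, c])
                    expected = next(
                        (v for g, v in zip(geoms, vals) if g.intersects(p)),
                        tmpl.nodata,
                    )
                    assert out.values[r, c] == expected


class TestAdjustment:
    def test_uniform_scale_factor(self):
        tmpl = _tmpl(2)
        pop = _layer(tmpl, np.full((2, 2), 20.0))
        iso = _layer(tmpl, np.ones((2, 2)), "iso-code")
        out = adjust_to_national_totals(pop, iso, {1: 100.0})
        assert np.allclose(out.values, 25.0)

    def test_identity_when_target_matches(self):
        tmpl = _tmpl(2)
        pop = _layer(tmpl, [[1.0, 2.0], [3.0, 4.0]])
        iso = _layer(tmpl, np.ones((2, 2)), "iso-code")
        out = adjust_to_national_totals(pop, iso, {1: 10.0})
        assert np.array_equal(out.values, pop.values)

    def test_two_country_zonal_oracle(self):
        tmpl = _tmpl(2)
        pop = _layer(tmpl, [[10.0, 10.0], [30.0, 30.0]])
        iso = _layer(tmpl, [[1.0, 1.0], [2.0, 2.0]], "iso-code")
        out = adjust_to_national_totals(pop, iso, {1: 50.0, 2: 30.0})
        sums = zonal_sum(out, iso)
        assert sums[1] == pytest.approx(50.0, rel=1e-9)
        assert sums[2] == pytest.approx(30.0, rel=1e-9)

    def test_zero_sum_positive_target_errors(self):
        tmpl = _tmpl(2)
        pop = _layer(tmpl, np.zeros((2, 2)))
        iso = _layer(tmpl, np.ones((2, 2)), "iso-code")
        with pytest.raises(ValueError, match="zero population"):
            adjust_to_national_totals(pop, iso, {1: 10.0})

    def test_missing_target_errors(self):
        tmpl = _tmpl(2)
        pop = _layer(tmpl, np.ones((2, 2)))
        iso = _layer(tmpl, [[1.0, 1.0], [2.0, 2.0]], "iso-code")
        with pytest.raises(ValueError, match="no national target.*2"):
            adjust_to_national_totals(pop, iso, {1: 4.0})


class TestDisaggregation:
    def test_uniform_quarter_proportions(self):
        tmpl = _tmpl(2)
        prop = {f"G{i}": _layer(tmpl, np.full((2, 2), 0.25), "proportion-fraction")
               for i in range(4)}
        population = _layer(tmpl, np.full((2, 2), 400.0))
        counts_stack = disaggregate_age_sex(prop, population)
        for lyr in counts_stack.values():
            assert (lyr.values == 100.0).all()

    def test_cellwise_conservation_identity(self, rng):
        tmpl = _tmpl(3)
        props = rng.dirichlet(np.ones(5), size=9).reshape(3, 3, 5)
        prop = {f"G{i}": _layer(tmpl, props[:, :, i], "proportion-fraction")
               for i in range(5)}
        population = _layer(tmpl, rng.uniform(10, 500, (3, 3)))
        counts_stack = disaggregate_age_sex(prop, population)
        total = sum(l.values for l in counts_stack.values())
        assert np.allclose(total, population.values, rtol=1e-9)

    def test_sex_split_layers(self):
        tmpl = _tmpl(2)
        prop = {"G0": _layer(tmpl, np.full((2, 2), 1.0), "proportion-fraction")}
        population = _layer(tmpl, np.full((2, 2), 100.0))
        sex = {
            "male": _layer(tmpl, np.full((2, 2), 0.6), "proportion-fraction"),
            "female": _layer(tmpl, np.full((2, 2), 0.4), "proportion-fraction"),
        }
        counts_stack = disaggregate_age_sex(prop, population, sex)
        assert (counts_stack["G0_male"].values == 60.0).all()
        assert (counts_stack["G0_female"].values == 40.0).all()

    def test_misaligned_grids_error(self):
        prop = {"G0": _layer(_tmpl(2), np.ones((2, 2)), "proportion-fraction")}
        population = _layer(_tmpl(3), np.ones((3, 3)))
        with pytest.raises(AlignmentError):
            disaggregate_age_sex(prop, population)

    def test_stack_not_summing_to_one_rejected(self):
        tmpl = _tmpl(2)
        prop = {"G0": _layer(tmpl, np.full((2, 2), 0.7), "proportion-fraction")}
        population = _layer(tmpl, np.ones((2, 2)))
        with pytest.raises(ValueError, match="does not sum to 1"):
            disaggregate_age_sex(prop, population)

    def test_nodata_propagates(self):
        tmpl = _tmpl(2)
        vals = np.full((2, 2), 1.0)
        vals[0, 0] = tmpl.nodata
        prop = {"G0": _layer(tmpl, vals, "proportion-fraction")}
        population = _layer(tmpl, np.full((2, 2), 10.0))
        counts_stack = disaggregate_age_sex(prop, population)
        assert counts_stack["G0"].values[0, 0] == tmpl.nodata
        assert counts_stack["G0"].values[1, 1] == 10.0


class TestExtraction:
    def test_single_code_identity(self):
        tmpl = _tmpl(2)
        layer = _layer(tmpl, [[1.0, 2.0], [3.0, 4.0]])
        iso = _layer(tmpl, np.ones((2, 2)), "iso-code")
        out = extract_country(layer, iso, 1)
        assert np.array_equal(out.values, layer.values)

    def test_absent_code_warns_all_nodata(self):
        tmpl = _tmpl(2)
        layer = _layer(tmpl, np.ones((2, 2)))
        iso = _layer(tmpl, np.ones((2, 2)), "iso-code")
        with pytest.warns(UserWarning, match="absent"):
            out = extract_country(layer, iso, 9)
        assert not out.data_mask().any()

    def test_partition_oracle_sum_over_codes(self):
        tmpl = _tmpl(4)
        rng = np.random.default_rng(5)
        layer = _layer(tmpl, rng.uniform(0, 10, (4, 4)))
        iso = _layer(tmpl, rng.integers(1, 4, (4, 4)).astype(float), "iso-code")
        total = sum(
            extract_country(layer, iso, code).total() for code in (1, 2, 3)
        )
        assert total == pytest.approx(layer.total(), rel=1e-12)

    def test_crop_preserves_alignment(self):
        tmpl = _tmpl(4)
        layer = _layer(tmpl, np.arange(16.0).reshape(4, 4))
        iso_vals = np.full((4, 4), 2.0)
        iso_vals[1:3, 1:3] = 1.0
        iso = _layer(tmpl, iso_vals, "iso-code")
        out = extract_country(layer, iso, 1, crop=True)
        assert out.template.shape == (2, 2)
        assert out.template.west == tmpl.west + 1.0
        assert out.template.north == tmpl.north - 1.0
        assert np.array_equal(out.values, layer.values[1:3, 1:3])


class TestAsciiGridIO:
    def test_round_trip(self, tmp_path, rng):
        tmpl = GridTemplate(west=-3.0, north=50.0, resolution=0.25, n_rows=5, n_cols=7)
        vals = rng.uniform(-5, 5, (5, 7))
        vals[0, 0] = tmpl.nodata
        layer = RasterLayer(tmpl, vals, "ratio")
        path = tmp_path / "layer.asc"
        write_ascii_grid(layer, path)
        back = read_ascii_grid(path, "ratio")
        assert back.template.aligned_with(tmpl)
        assert np.allclose(back.values, vals)
        assert back.nodata == tmpl.nodata


class TestEndToEndZonal:
    def test_agc_zonal_sums_recover_true_structure(self, small_spec, small_country):
        """Full gridded route on the synthetic country: per-unit zonal sums
        of each age-count layer must equal unit population x true age share."""
        from demogrid import table_to_proportion_layers

        table = small_country.structure.to_standard_table()
        age_stack, sex_stack = table_to_proportion_layers(
            small_country.boundaries, table, small_spec.grid
        )
        counts_stack = disaggregate_age_sex(age_stack, small_country.population)
        units = rasterize_attribute(
            small_country.boundaries, None, small_spec.grid, unit_index=True
        )
        truth = small_country.structure.age_proportions()
        pops = small_country.structure.unit_populations
        for lab, lyr in counts_stack.items():
            sums = zonal_sum(lyr, units)
            for uid in pops.index:
                expected = pops.loc[uid] * truth.loc[uid, lab]
                assert sums[uid] == pytest.approx(expected, rel=1e-6, abs=1e-6)
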