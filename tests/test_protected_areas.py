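"""Protected-area overlays: year filters, category shares, inside/outside rates."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box

from landconvert.grid import EpochRaster, GridGeometry
from landconvert.harmonization import HarmonizedClass
from landconvert.layers import IUCN_CATEGORIES, PACollection, PARecord, ZoneLayer
from landconvert.protected_areas import (
    OUTSIDE,
    conversion_rates,
    filter_by_year,
    inside_outside_decomposition,
    pa_conversion,
)
from landconvert.synthetic import SyntheticScenario, generate_landscape
from landconvert.transitions import TransitionCode, detect_transitions, global_totals

C = HarmonizedClass


def _pa(pa_id, geometry, category="II", year=1990, **kw):
    return PARecord(pa_id=pa_id, geometry=geometry, iucn_category=category,
                    establishment_year=year, **kw)


def _uniform_pair(t0_class, conv_cols, shape=(10, 10), cell=100.0):
    """t0 uniform in one class; columns in conv_cols become cultivated."""
    v0 = np.full(shape, int(t0_class))
    v1 = v0.copy()
    v1[:, conv_cols] = int(C.CULTIVATED)
    geom = GridGeometry(0, shape[0] * cell, cell, *shape)
    t0 = EpochRaster(values=v0, year=2000, dataset_id="synthetic", geom=geom)
    t1 = EpochRaster(values=v1, year=2010, dataset_id="synthetic", geom=geom)
    return t0, t1, geom


def _whole_zone(geom):
    xmin, ymin, xmax, ymax = geom.extent()
    pad = geom.cell_size
    return ZoneLayer(["Z"], [box(xmin - pad, ymin - pad, xmax + pad, ymax + pad)])


class TestFilterByYear:
    def test_strict_inequality_at_cutoff(self):
        years = [1990, 1999, 2000, 2015]
        pas = PACollection(
            [_pa(f"p{i}", box(0, 0, 1, 1), year=y) for i, y in enumerate(years)]
        )
        kept, report = filter_by_year(pas, 2000)
        assert len(kept) == 2
        assert {r.establishment_year for r in kept} == {1990, 1999}
        assert report["n_excluded_established_later"] == 2

    def test_empty_input(self):
        kept, report = filter_by_year(PACollection(), 2000)
        assert len(kept) == 0 and report["n_input"] == 0

    def test_unknown_year_excluded_and_reported(self):
        pas = PACollection(
            [_pa("a", box(0, 0, 1, 1), year=1990),
             _pa("b", box(0, 0, 1, 1), year=None)]
        )
        kept, report = filter_by_year(pas, 2000)
        assert len(kept) == 1
        assert report["n_excluded_unknown_year"] == 1


class TestPAConversion:
    def test_all_conversion_in_one_category_ii_pa(self):
        t0, t1, geom = _uniform_pair(C.GRASS_SHRUB, conv_cols=[0, 1])
        tr = detect_transitions(t0, t1)
        pas = PACollection([_pa("p", box(-10, -10, 5000, 5000), category="II")])
        areas, props = pa_conversion(tr, t0, pas)
        grass = props[props.land_class == "GRASS_SHRUB"].set_index("category")
        vec = [grass.loc[cat, "proportion"] for cat in IUCN_CATEGORIES]
        assert vec == [0.0, 1.0, 0.0, 0.0, 0.0, 0.0]

    def test_no_pa_overlap_gives_all_zero(self):
        t0, t1, geom = _uniform_pair(C.FOREST, conv_cols=[3])
        tr = detect_transitions(t0, t1)
        pas = PACollection([_pa("far", box(1e6, 1e6, 1e6 + 10, 1e6 + 10))])
        areas, _ = pa_conversion(tr, t0, pas)
        assert (areas.converted_area_ha == 0).all()

    def test_overlapping_pas_attributed_to_strictest_category(self):
        t0, t1, geom = _uniform_pair(C.GRASS_SHRUB, conv_cols=list(range(10)))
        tr = detect_transitions(t0, t1)
        pas = PACollection(
            [
                _pa("loose", box(-10, -10, 5000, 5000), category="V"),
                _pa("strict", box(-10, -10, 210, 5000), category="II"),
            ]
        )
        areas, _ = pa_conversion(tr, t0, pas)
        g = areas[areas.land_class == "GRASS_SHRUB"].set_index("category")
        assert g.loc["II", "converted_area_ha"] == pytest.approx(20.0)  # 2 cols
        assert g.loc["V", "converted_area_ha"] == pytest.approx(80.0)

    def test_ia_ib_collapse_to_category_i(self):
        rec = _pa("x", box(0, 0, 1, 1), category="Ia")
        assert rec.iucn_category == "I"

    def test_marine_pas_excluded_from_land_analysis(self):
        t0, t1, geom = _uniform_pair(C.GRASS_SHRUB, conv_cols=[0])
        tr = detect_transitions(t0, t1)
        pas = PACollection(
            [_pa("sea", box(-10, -10, 5000, 5000), category="II", marine_flag=True)]
        )
        areas, _ = pa_conversion(tr, t0, pas)
        assert (areas.converted_area_ha == 0).all()

    def test_areas_match_bruteforce_cell_enumeration(self, scenario, landscape,
                                                     layers, transition):
        """Category/class converted areas equal an exhaustive loop over cells
        with point-in-polygon tests and strictest-category attribution."""
        t0, _, _ = landscape
        pas, _, _, _ = layers
        areas, _ = pa_conversion(transition, t0, pas)
        g = transition.geom
        cell_ha = g.cell_size**2 / 1e4
        conv_code_by_class = {
            "GRASS_SHRUB": TransitionCode.CONV_GRASS,
            "NONFOREST_WETLAND": TransitionCode.CONV_WETLAND,
            "FOREST": TransitionCode.CONV_FOREST,
        }
        expected = {(lc, cat): 0 for lc in conv_code_by_class for cat in IUCN_CATEGORIES}
        for r in range(g.nrows):
            for c in range(g.ncols):
                code = int(transition.values[r, c])
                pt = Point(g.origin_x + (c + 0.5) * g.cell_size,
                           g.origin_y - (r + 0.5) * g.cell_size)
                cats = [
                    rec.iucn_category for rec in pas
                    if not rec.marine_flag and rec.geometry.contains(pt)
                ]
                if not cats:
                    continue
                strictest = min(cats, key=IUCN_CATEGORIES.index)
                for lc, tc in conv_code_by_class.items():
                    if code == int(tc):
                        expected[(lc, strictest)] += 1
        got = areas.set_index(["land_class", "category"]).converted_area_ha
        for key, count in expected.items():
            assert got[key] == pytest.approx(count * cell_ha, abs=1e-9), key


class TestConversionRates:
    def test_ten_percent_rate_arithmetic(self):
        # 100 grass cells of 1 ha inside the PA; 10 convert
        t0, t1, geom = _uniform_pair(C.GRASS_SHRUB, conv_cols=[0])
        tr = detect_transitions(t0, t1)
        pas = PACollection([_pa("p", box(-10, -10, 5000, 5000), category="III")])
        rates = conversion_rates(tr, t0, pas, _whole_zone(geom))
        r = rates.set_index(["land_class", "category"])
        assert r.loc[("GRASS_SHRUB", "III"), "baseline_area_ha"] == pytest.approx(100.0)
        assert r.loc[("GRASS_SHRUB", "III"), "converted_area_ha"] == pytest.approx(10.0)
        assert r.loc[("GRASS_SHRUB", "III"), "rate"] == pytest.approx(0.10)

    def test_conversion_only_outside_pas(self):
        t0, t1, geom = _uniform_pair(C.FOREST, conv_cols=[8, 9])
        tr = detect_transitions(t0, t1)
        pas = PACollection([_pa("p", box(-10, -10, 300, 5000), category="I")])
        rates = conversion_rates(tr, t0, pas, _whole_zone(geom))
        r = rates.set_index(["land_class", "category"])
        assert r.loc[("FOREST", "I"), "rate"] == 0.0
        assert r.loc[("FOREST", OUTSIDE), "rate"] > 0.0

    def test_zero_baseline_flagged_undefined(self):
        t0, t1, geom = _uniform_pair(C.FOREST, conv_cols=[0])
        tr = detect_transitions(t0, t1)
        pas = PACollection([_pa("p", box(-10, -10, 5000, 5000), category="II")])
        rates = conversion_rates(tr, t0, pas, _whole_zone(geom))
        wet = rates.set_index(["land_class", "category"]).loc[("NONFOREST_WETLAND", "II")]
        assert not wet.rate_defined
        assert np.isnan(wet.rate)

    def test_rates_bounded_and_decompose(self, landscape, layers, transition):
        t0, _, _ = landscape
        pas, _, zones, _ = layers
        rates = conversion_rates(transition, t0, pas, zones)
        defined = rates[rates.rate_defined]
        assert ((defined.rate >= 0) & (defined.rate <= 1)).all()
        # inside (all categories) + outside converted area == total converted
        totals = global_totals(transition).set_index("transition_code").area_ha
        decomp = inside_outside_decomposition(rates)
        class_to_code = {
            "GRASS_SHRUB": "CONV_GRASS",
            "NONFOREST_WETLAND": "CONV_WETLAND",
            "FOREST": "CONV_FOREST",
        }
        for lc, code in class_to_code.items():
            summed = decomp[decomp.land_class == lc].total_converted_ha.sum()
            assert summed == pytest.approx(totals[code], rel=1e-9)

    def test_enlarging_pa_never_decreases_baseline(self, landscape):
        t0, t1, _ = landscape
        tr = detect_transitions(t0, t1)
        geom = t0.geom
        small = PACollection([_pa("p", box(1000, 1000, 3000, 3000), category="IV")])
        big = PACollection([_pa("p", box(500, 500, 4500, 4500), category="IV")])
        zones = _whole_zone(geom)
        r_small = conversion_rates(tr, t0, small, zones).set_index(["land_class", "category"])
        r_big = conversion_rates(tr, t0, big, zones).set_index(["land_class", "category"])
        for lc in ("GRASS_SHRUB", "NONFOREST_WETLAND", "FOREST"):
            assert (
                r_big.loc[(lc, "IV"), "baseline_area_ha"]
                >= r_small.loc[(lc, "IV"), "baseline_area_ha"]
            )

    def test_rates_match_vector_overlay_oracle_small_instance(self):
        """Rates on a small grid equal a direct count with per-cell
        point-in-polygon evaluation."""
        scenario = SyntheticScenario(grid_shape=(30, 30), seed=33)
        t0, t1, _ = generate_landscape(scenario)
        tr = detect_transitions(t0, t1)
        g = t0.geom
        pa_geom = box(333.0, 431.0, 1777.0, 2311.0)  # off cell boundaries
        pas = PACollection([_pa("p", pa_geom, category="VI")])
        rates = conversion_rates(tr, t0, pas, _whole_zone(g))
        r = rates.set_index(["land_class", "category"])
        for lc, cls, code in [
            ("GRASS_SHRUB", C.GRASS_SHRUB, TransitionCode.CONV_GRASS),
            ("FOREST", C.FOREST, TransitionCode.CONV_FOREST),
        ]:
            base = conv = 0
            for rr in range(g.nrows):
                for cc in range(g.ncols):
                    pt = Point(g.origin_x + (cc + 0.5) * g.cell_size,
                               g.origin_y - (rr + 0.5) * g.cell_size)
                    if not pa_geom.contains(pt):
                        continue
                    if t0.values[rr, cc] == int(cls):
                        base += 1
                        if tr.values[rr, cc] == int(code):
                            conv += 1
            if base:
                assert r.loc[(lc, "VI"), "rate"] == pytest.approx(conv / base)

    def test_no_artificial_pa_effect_on_uniform_landscape(self):
        """With a spatially uniform conversion probability and randomly
        placed PAs, inside and outside rates agree within 3 binomial SE."""
        p = 0.10
        scenario = SyntheticScenario(
            grid_shape=(150, 150),
            transition_matrix={(C.GRASS_SHRUB, C.CULTIVATED): p},
            n_pas=6,
            seed=55,
        )
        t0, t1, _ = generate_landscape(scenario)
        from landconvert.synthetic import generate_conservation_layers

        pas, _, _ = generate_conservation_layers(scenario, t0)
        tr = detect_transitions(t0, t1)
        inside = pas.union_mask(t0.geom)
        grass = t0.values == int(C.GRASS_SHRUB)
        conv = tr.values == int(TransitionCode.CONV_GRASS)
        n_in, k_in = int((grass & inside).sum()), int((conv & inside).sum())
        n_out, k_out = int((grass & ~inside).sum()), int((conv & ~inside).sum())
        p_in, p_out = k_in / n_in, k_out / n_out
        pooled = (k_in + k_out) / (n_in + n_out)
        se = np.sqrt(pooled * (1 - pooled) * (1 / n_in + 1 / n_out))
        assert abs(p_in - p_out) < 3 * se
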