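import numpy as np
import pytest

from qfib.morphometry import FiberString, MorphometryConfig
from qfib.parameters import (
    aggregate_parameters,
    canonical_name,
    classify_parameter_name,
    compute_parameters,
    parameter_schema,
    periportal_schema,
    rps_schema,
)
from qfib.published import SCREEN_PVALUES

from conftest import make_regions


class TestSchema:
    def test_counts(self):
        assert len(parameter_schema()) == 56
        assert len(periportal_schema()) == 28
        assert len(rps_schema()) == 28
        assert len(set(parameter_schema())) == 56

    def test_order_periportal_then_rps(self):
        schema = parameter_schema()
        assert schema[:28] == periportal_schema()
        assert schema[28:] == rps_schema()
        assert schema[0] == "%Periportal"
        assert schema[27] == "#IntersectionPeriportal"
        assert schema[55] == "#IntersectionRPS"

    @pytest.mark.parametrize(
        "alias,canonical",
        [
            ("#ThickStrPS", "#ThickStrRPS"),
            ("StrWidthPSAgg", "StrWidthRPSAgg"),
            ("%PS", "%RPS"),
            ("#StrPeriportal", "#StrPeriportal"),
        ],
    )
    def test_alias_resolution(self, alias, canonical):
        assert canonical_name(alias) == canonical

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            canonical_name("#BogusStrPeriportal")


class TestNameGrammar:
    @pytest.mark.parametrize(
        "name,family,stratum,metric",
        [
            ("#LongStrPeriportalAgg", "periportal", "Agg", "count"),
            ("StrWidthPSAgg", "perisinusoidal", "Agg", "width"),
            ("%Periportal", "periportal", "all", "percent"),
            ("#IntersectionRPS", "perisinusoidal", "all", "intersection"),
            ("StrAreaRPSDis", "perisinusoidal", "Dis", "area"),
            ("StrLengthPeriportal", "periportal", "all", "length"),
        ],
    )
    def test_parse(self, name, family, stratum, metric):
        got = classify_parameter_name(name)
        assert got == {"region_family": family, "stratum": stratum, "metric": metric}

    def test_discovery_screen_family_split(self):
        """The published discovery screen names: 20 periportal, 8 perisinusoidal."""
        fams = [classify_parameter_name(n)["region_family"] for n in SCREEN_PVALUES]
        assert fams.count("periportal") == 20
        assert fams.count("perisinusoidal") == 8


def _fiber(i, region, area=5.0, length=10.0, agg=False, long_=False, thick=False):
    f = FiberString(i, int(area / 0.390625**2), area, length, area / length,
                    region=region)
    f.is_aggregated = agg
    f.is_long = long_
    f.is_thick = thick
    return f


class TestCompute:
    def test_no_fibers_all_zero(self, full_rps_regions):
        vec = compute_parameters([], full_rps_regions, {})
        assert all(v == 0.0 for v in vec.values.values())

    def test_stratum_counts(self):
        fibers = [_fiber(i, "periportal", agg=(i < 4)) for i in range(10)]
        vec = aggregate_parameters(fibers, {"periportal": 1e4, "rps": 1e4}, {})
        assert vec["#StrPeriportal"] == 10
        assert vec["#StrPeriportalAgg"] == 4
        assert vec["#StrPeriportalDis"] == 6
        assert vec["#StrRPS"] == 0

    def test_percent_is_area_fraction_of_region(self, cal):
        periportal = np.zeros((128, 128), bool)
        periportal[:100, :100] = True  # 10000 px
        regions = make_regions((128, 128), periportal=periportal, cal=cal)
        area = 100 * cal.um2_per_pixel
        fibers = [_fiber(1, "periportal", area=area)]
        vec = compute_parameters(fibers, regions, {})
        assert vec["%Periportal"] == pytest.approx(1.0)

    def test_intersections_passed_through(self, full_rps_regions):
        vec = compute_parameters([], full_rps_regions, {"periportal": 3, "rps": 7})
        assert vec["#IntersectionPeriportal"] == 3
        assert vec["#IntersectionRPS"] == 7

    def test_portal_fibers_contribute_nothing(self, full_rps_regions):
        vec = compute_parameters([_fiber(1, "portal", area=50.0)],
                                 full_rps_regions, {})
        assert all(v == 0.0 for v in vec.values.values())

    def test_zero_area_region_warns_and_zeroes(self, caplog):
        import logging
        fibers = [_fiber(1, "periportal")]
        with caplog.at_level(logging.WARNING, logger="qfib.parameters"):
            vec = aggregate_parameters(fibers, {"periportal": 0.0, "rps": 1.0}, {})
        assert vec["%Periportal"] == 0.0
        assert vec["#StrPeriportal"] == 1.0
        assert any("zero area" in rec.message for rec in caplog.records)

    def test_unknown_region_label_rejected(self, full_rps_regions):
        bad = _fiber(1, "rps")
        bad.region = "lobular"
        with pytest.raises(ValueError):
            aggregate_parameters([bad], {"periportal": 1.0, "rps": 1.0}, {})


class TestInvariants:
    def _random_fibers(self, rng, n=40):
        fibers = []
        for i in range(n):
            region = rng.choice(["periportal", "rps", "portal"])
            length = float(rng.uniform(1, 40))
            width = float(rng.uniform(0.5, 8))
            f = FiberString(i + 1, 10, length * width, length, width, region=region)
            fibers.append(f)
        cfg = MorphometryConfig()
        for f in fibers:
            f.is_long = f.length_um >= cfg.long_length_um
            f.is_thick = f.width_um >= cfg.thick_width_um
            f.is_aggregated = f.area_um2 >= cfg.aggregated_component_area_um2
        return fibers

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_agg_dis_additivity(self, seed):
        rng = np.random.default_rng(seed)
        vec = aggregate_parameters(self._random_fibers(rng),
                                   {"periportal": 2e4, "rps": 3e4}, {})
        for region in ("Periportal", "RPS"):
            assert vec[f"%{region}"] == pytest.approx(
                vec[f"%{region}Agg"] + vec[f"%{region}Dis"], abs=1e-9)
            assert vec[f"#Str{region}"] == pytest.approx(
                vec[f"#Str{region}Agg"] + vec[f"#Str{region}Dis"], abs=1e-9)
            # count dichotomies per stratum
            for s in ("", "Agg", "Dis"):
                assert (vec[f"#ShortStr{region}{s}"] + vec[f"#LongStr{region}{s}"]
                        == vec[f"#Str{region}{s}"])
                assert (vec[f"#ThinStr{region}{s}"] + vec[f"#ThickStr{region}{s}"]
                        == vec[f"#Str{region}{s}"])

    def test_percentages_bounded_counts_integral(self):
        rng = np.random.default_rng(7)
        vec = aggregate_parameters(self._random_fibers(rng),
                                   {"periportal": 1e5, "rps": 1e5}, {})
        for name, value in vec.values.items():
            meta = classify_parameter_name(name)
            if meta["metric"] == "percent":
                assert 0.0 <= value <= 100.0
            if meta["metric"] in ("count", "intersection"):
                assert value == int(value) >= 0

    def test_fiber_order_irrelevant(self):
        rng = np.random.default_rng(11)
        fibers = self._random_fibers(rng)
        v1 = aggregate_parameters(fibers, {"periportal": 1e4, "rps": 1e4}, {})
        v2 = aggregate_parameters(fibers[::-1], {"periportal": 1e4, "rps": 1e4}, {})
        assert v1.values == v2.values
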