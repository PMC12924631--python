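import json
import math

import numpy as np
import pytest

from swinesim import params as P
from swinesim._tables import (
    AA_RATIOS,
    DEFAULT_BWG_COEFFS,
    MICRONUTRIENT_POINTS,
    MICRONUTRIENT_REFERENCE_BWS,
)
from swinesim.params import (
    ConfigError,
    HerdConfig,
    build_micronutrient_table,
    compute_pd_max,
    default_sex_params,
    fit_bwg_polynomial,
    fit_loglinear_coefficients,
    load_config,
    load_micronutrient_table,
    write_micronutrient_csv,
)


# ---------------------------------------------------------------------------
# config loading
# ---------------------------------------------------------------------------

class TestLoadConfig:
    def test_empty_file_gives_all_defaults(self, tmp_path):
        path = tmp_path / "cfg.json"
        path.write_text("")
        cfg = load_config(path)
        assert cfg.run_days == 140
        assert cfg.bw_final == 130
        assert cfg.me_content == 3300
        assert cfg.n_barns == 5
        assert cfg.bw_initial_mean == 20
        assert cfg.temperature == 20
        assert cfg.fdm == 0.88

    def test_yaml_values_applied(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("feed_wastage: 0.05\ntemperature: 18\nseed: 3\n")
        cfg = load_config(path)
        assert cfg.feed_wastage == 0.05
        assert cfg.temperature == 18
        assert cfg.seed == 3

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_config(tmp_path / "nope.json")

    def test_physical_bound_names_key(self, tmp_path):
        path = tmp_path / "cfg.json"
        path.write_text(json.dumps({"temperature": -300}))
        with pytest.raises(ConfigError, match="temperature"):
            load_config(path)

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.json"
        path.write_text(json.dumps({"fed_wastage": 0.05}))
        with pytest.raises(ConfigError, match="fed_wastage"):
            load_config(path)

    def test_type_mismatch_names_key(self, tmp_path):
        path = tmp_path / "cfg.json"
        path.write_text(json.dumps({"run_days": "many"}))
        with pytest.raises(ConfigError, match="run_days"):
            load_config(path)

    @pytest.mark.parametrize(
        "key,value",
        [
            ("feed_wastage", 1.0),
            ("fdm", 0.0),
            ("fdm", 1.5),
            ("bw_final", -1),
            ("noise_cv", -0.1),
            ("n_replications", 0),
        ],
    )
    def test_invariant_violations(self, key, value):
        with pytest.raises(ConfigError, match=key):
            HerdConfig(**{key: value})

    def test_initial_must_be_below_final(self):
        with pytest.raises(ConfigError):
            HerdConfig(bw_initial_mean=130, bw_final=130)

    def test_unknown_sex_rejected(self):
        with pytest.raises(ConfigError, match="sow"):
            HerdConfig(sexes=("gilt", "sow"))

    def test_bwg_coeffs_list_applies_to_all_sexes(self, tmp_path):
        path = tmp_path / "cfg.json"
        path.write_text(json.dumps({"bwg_coeffs": [500.0, 8.0, -0.05]}))
        cfg = load_config(path)
        for sex in ("gilt", "barrow", "boar"):
            assert cfg.sex_params(sex).bwg_coeffs == (500.0, 8.0, -0.05)

    def test_boar_fi_override(self):
        cfg = HerdConfig(boar_fi_coeffs=(2.8, -4.7, 1.2))
        sp = cfg.sex_params("boar")
        assert sp.fi_x == 2.8 and sp.fi_y == -4.7 and sp.fi_z == 1.2


# ---------------------------------------------------------------------------
# shipped coefficients
# ---------------------------------------------------------------------------

def test_shipped_pd_coefficients_digit_for_digit(gilt, barrow, boar):
    assert (gilt.pd_a, gilt.pd_b, gilt.pd_c, gilt.pd_d, gilt.pd_e) == (
        137, 0.7066, 0.013289, -1.3120e-4, 2.8627e-7)
    assert (barrow.pd_a, barrow.pd_b, barrow.pd_c, barrow.pd_d, barrow.pd_e) == (
        133, 0.7078, 0.013764, -1.4211e-4, 3.2698e-7)
    assert (boar.pd_a, boar.pd_b, boar.pd_c, boar.pd_d, boar.pd_e) == (
        151, 0.6558, 0.012740, -1.0390e-4, 1.64001e-7)


def test_shipped_intake_coefficients_digit_for_digit(gilt, barrow, boar):
    assert (gilt.mei_a, gilt.mei_b, gilt.mei_c) == (10967, -3.803, 0.9072)
    assert (barrow.mei_a, barrow.mei_b, barrow.mei_c) == (10447, -4.283, 1.0843)
    assert (boar.mei_a, boar.mei_b, boar.mei_c) == (10638, -3.803, 0.9072)
    assert (gilt.fi_x, gilt.fi_y, gilt.fi_z) == (2.755, -4.755, 1.214)
    assert (barrow.fi_x, barrow.fi_y, barrow.fi_z) == (2.88, -5.921, 1.512)
    assert boar.fi_x is None


def test_amino_acid_ratios_bit_for_bit():
    printed_percent = {
        "arginine": 45.7, "histidine": 34.4, "isoleucine": 52.2,
        "leucine": 100.7, "methionine": 28.9, "methionine+cysteine": 56.4,
        "phenylalanine": 59.7, "phenylalanine+tyrosine": 93.8,
        "threonine": 60.3, "tryptophan": 17.1, "valine": 64.9,
        "nitrogen": 214.8,
    }
    assert set(AA_RATIOS) == set(printed_percent)
    for name, pct in printed_percent.items():
        assert AA_RATIOS[name] == pytest.approx(pct / 100, abs=1e-12)


# ---------------------------------------------------------------------------
# polynomial fit
# ---------------------------------------------------------------------------

class TestFitBwgPolynomial:
    def test_recovers_printed_polynomial(self):
        bws = np.linspace(20, 110, 10)
        pts = [(bw, 485.17 + 8.8503 * bw - 0.0477 * bw**2) for bw in bws]
        coeffs = fit_bwg_polynomial(pts)
        assert coeffs == pytest.approx(DEFAULT_BWG_COEFFS, rel=1e-7)
        resid = [c - y for (bw, y), c in zip(
            pts, (coeffs[0] + coeffs[1] * bws + coeffs[2] * bws**2))]
        assert max(abs(r) for r in resid) < 1e-8

    def test_zero_data(self):
        coeffs = fit_bwg_polynomial([(bw, 0.0) for bw in (20, 40, 60, 80)])
        assert coeffs == pytest.approx((0, 0, 0), abs=1e-12)

    def test_three_points_interpolate_exactly(self):
        # oracle: solve the 3x3 Vandermonde system directly
        rng = np.random.default_rng(5)
        bws = np.array([25.0, 61.0, 104.0])
        ys = rng.normal(800, 100, size=3)
        expected = np.linalg.solve(np.vander(bws, 3, increasing=True), ys)
        coeffs = fit_bwg_polynomial(list(zip(bws, ys)))
        assert coeffs == pytest.approx(expected, rel=1e-9)
        fitted = coeffs[0] + coeffs[1] * bws + coeffs[2] * bws**2
        assert fitted == pytest.approx(ys, abs=1e-8)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_bwg_polynomial([(20, 600), (40, 700)])

    def test_collinear_bws(self):
        with pytest.raises(ValueError, match="collinear"):
            fit_bwg_polynomial([(20, 600), (20, 650), (40, 700)])


# ---------------------------------------------------------------------------
# log-linear fit
# ---------------------------------------------------------------------------

def _textbook_loglinear(points):
    x = np.log([p[0] for p in points])
    y = np.array([p[1] for p in points])
    slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    return y.mean() - slope * x.mean(), slope


class TestFitLoglinear:
    def test_sodium_against_textbook_oracle(self):
        points = [(126.55, 2.92), (127.99, 2.94), (123.55, 2.90)]
        nc = fit_loglinear_coefficients(points, nutrient="sodium", units="g/d")
        intercept, slope = _textbook_loglinear(points)
        assert nc.intercept == pytest.approx(intercept, rel=1e-10)
        assert nc.slope == pytest.approx(slope, rel=1e-10)
        for bw, printed in points:
            assert round(nc.evaluate(bw), 2) == printed

    def test_equal_requirements_give_zero_slope(self):
        nc = fit_loglinear_coefficients([(100, 0.40), (120, 0.40)])
        assert nc.slope == pytest.approx(0, abs=1e-10)
        assert nc.intercept == pytest.approx(0.40, abs=1e-10)

    def test_iodine_constant(self):
        pts = list(zip(MICRONUTRIENT_REFERENCE_BWS, (0.40, 0.40, 0.40)))
        nc = fit_loglinear_coefficients(pts, nutrient="iodine")
        assert nc.evaluate(126.55) == pytest.approx(0.40, abs=1e-10)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            fit_loglinear_coefficients([(100, 1.0)])

    def test_identical_bws_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_loglinear_coefficients([(100, 1.0), (100, 2.0)])


class TestMicronutrientTable:
    def test_back_evaluation_errors(self):
        # every fitted row reproduces its three source values within 0.015
        # printed units, except vitamin A whose three printed values are not
        # log-linear-consistent (best fit leaves a 0.039 residual)
        bws = np.array(MICRONUTRIENT_REFERENCE_BWS)
        for nc in build_micronutrient_table():
            values = np.array(MICRONUTRIENT_POINTS[nc.nutrient][2])
            err = np.abs(nc.intercept + nc.slope * np.log(bws) - values).max()
            bound = 0.05 if nc.nutrient == "vitamin_a" else 0.015
            assert err <= bound, nc.nutrient

    def test_packaged_csv_matches_fresh_fit(self):
        fresh = {nc.nutrient: nc for nc in build_micronutrient_table()}
        loaded = {nc.nutrient: nc for nc in load_micronutrient_table()}
        assert set(fresh) == set(loaded)
        for name in fresh:
            assert loaded[name].intercept == pytest.approx(fresh[name].intercept, rel=1e-14)
            assert loaded[name].slope == pytest.approx(fresh[name].slope, rel=1e-14)
            assert loaded[name].klass == fresh[name].klass
            assert loaded[name].units == fresh[name].units

    def test_write_csv_roundtrip(self, tmp_path):
        path = write_micronutrient_csv(tmp_path / "coeffs.csv")
        header = path.read_text().splitlines()[0]
        assert header == "nutrient,class,intercept,slope,units"
        assert len(path.read_text().splitlines()) == 25  # header + 24 nutrients


# ---------------------------------------------------------------------------
# Pd maximum
# ---------------------------------------------------------------------------

class TestComputePdMax:
    @staticmethod
    def _grid_max(params):
        bw = np.arange(20, 130 + 1e-9, 0.01)
        pd = params.pd_a * (params.pd_b + params.pd_c * bw
                            + params.pd_d * bw**2 + params.pd_e * bw**3)
        return pd.max(), bw[pd.argmax()]

    def test_gilt_matches_grid_oracle(self, gilt):
        grid_max, argmax = self._grid_max(gilt)
        assert compute_pd_max(gilt) == pytest.approx(grid_max, abs=1e-6)
        assert argmax == pytest.approx(64.09, abs=0.05)
        assert gilt.pd_max == pytest.approx(150.0, abs=0.05)

    def test_all_sexes_match_grid_oracle(self, all_params):
        for sp in all_params.values():
            grid_max, _ = self._grid_max(sp)
            assert compute_pd_max(sp) == pytest.approx(grid_max, abs=1e-6)

    def test_boar_exceeds_gilt(self, gilt, boar):
        assert boar.pd_max > gilt.pd_max

    def test_monotone_cubic_peaks_at_endpoint(self):
        sp = P.SexParams(sex="gilt", pd_a=137, pd_b=1.0, pd_c=0.01,
                         pd_d=0.0, pd_e=0.0, mei_a=1.0, mei_b=0, mei_c=1,
                         fi_x=None, fi_y=None, fi_z=None)
        assert compute_pd_max(sp) == pytest.approx(137 * (1.0 + 0.01 * 130))

    def test_positive_over_working_range(self, all_params):
        bw = np.linspace(20, 130, 500)
        for sp in all_params.values():
            pd = sp.pd_a * (sp.pd_b + sp.pd_c * bw + sp.pd_d * bw**2 + sp.pd_e * bw**3)
            assert (pd > 0).all()


def test_default_sex_params_unknown_sex():
    with pytest.raises(ConfigError, match="sow"):
        default_sex_params("sow")
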