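"""Calibration of the C unit, ploidy binning, and the cytometry table."""

import numpy as np
import pytest

from meioscope import imaging, meiosis, ploidy
from meioscope.ploidy import (
    CalibrationError,
    PloidyScale,
    assign_ploidies,
    assign_ploidy,
    calibrate,
    crosstab,
    population_percentages,
)


class Rec:
    def __init__(self, cell_class, iod):
        self.cell_class = cell_class
        self.iod = iod


class TestCalibrate:
    def test_exact_bimodal(self):
        iods = [50.0] * 600 + [100.0] * 400
        scale = calibrate(iods, {1, 2})
        assert scale.c_unit == pytest.approx(50.0, rel=1e-3)
        assert scale.method == "constrained_mixture"

    def test_somatic_reference_mode(self):
        rng = np.random.default_rng(0)
        reference = rng.normal(150.0, 3.0, 400)
        scale = calibrate([60.0] * 40, {1, 2, 3}, reference=reference, base_ploidy=3)
        assert scale.method == "reference_population"
        assert scale.c_unit == pytest.approx(50.0, rel=0.02)

    def test_reference_requires_base_ploidy(self):
        with pytest.raises(CalibrationError):
            calibrate([60.0] * 40, {1, 2}, reference=[150.0] * 40)

    def test_too_few_values(self):
        with pytest.raises(CalibrationError):
            calibrate([50.0] * 10, {1, 2})

    def test_simulated_canonical_recovery(self):
        """On canonical-meiosis IODs at 8% CV the mixture fit recovers the C
        unit within 3% and places component means on integer multiples."""
        rng = np.random.default_rng(123)
        cells = meiosis.sample_population(
            {"A_CANONICAL": 1.0},
            {"spermatozoon": 0.55, "spermatogonium": 0.45},
            {2: 1.0},
            1000,
            0.08,
            rng,
            content_weights={"spermatogonium": {2.0: 35 / 45, 4.0: 10 / 45}},
        )
        iods = [c.measured_c * imaging.DEFAULT_OD_PER_C for c in cells]
        scale = calibrate(iods, {1, 2, 4})
        assert scale.c_unit == pytest.approx(imaging.DEFAULT_OD_PER_C, rel=0.03)
        # fitted component means sit at k·c_unit by construction; check the
        # empirical population means agree within 5%
        ks, _ = assign_ploidies(iods, scale, (1, 2, 4))
        for k in (1, 2, 4):
            sel = np.asarray(iods)[ks == k]
            assert sel.mean() == pytest.approx(k * scale.c_unit, rel=0.05)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        iods = np.concatenate([rng.normal(50, 4, 500), rng.normal(100, 8, 300)])
        iods = iods[iods > 0]
        s1 = calibrate(iods, {1, 2})
        s2 = calibrate(iods * 7.0, {1, 2})
        assert s2.c_unit == pytest.approx(7.0 * s1.c_unit, rel=1e-3)
        k1, _ = assign_ploidies(iods, s1, (1, 2))
        k2, _ = assign_ploidies(iods * 7.0, s2, (1, 2))
        np.testing.assert_array_equal(k1, k2)


class TestAssign:
    SCALE = PloidyScale(c_unit=50.0, method="reference_population", residual=0.0)

    @pytest.mark.parametrize(
        "iod,expected",
        [(100.0, 2), (50.0, 1), (210.0, 4), (np.sqrt(2) * 50.0, 2)],  # tie → upper
    )
    def test_bins_and_tie_rule(self, iod, expected):
        assert assign_ploidy(iod, self.SCALE, {1, 2, 4}) == expected

    def test_out_of_range_flagged(self):
        ks, flags = assign_ploidies([10.0, 50.0, 1000.0], self.SCALE, {1, 2, 4})
        assert list(ks) == [1, 1, 4]
        assert list(flags) == [True, False, True]

    def test_non_positive_iod_raises(self):
        with pytest.raises(ValueError):
            assign_ploidy(-5.0, self.SCALE, {1, 2})

    def test_triploid_modified_meiosis_modal_bin(self):
        """Unreduced triploid germ cells concentrate in the 3C bin."""
        rng = np.random.default_rng(7)
        cells = meiosis.sample_population(
            {"B_MODIFIED": 1.0},
            {"spermatozoon": 0.6, "spermatid": 0.4},
            {3: 1.0},
            500,
            0.08,
            rng,
        )
        iods = [c.measured_c * imaging.DEFAULT_OD_PER_C for c in cells]
        scale = PloidyScale(imaging.DEFAULT_OD_PER_C, "reference_population", 0.0)
        ks, _ = assign_ploidies(iods, scale, (1, 2, 3, 4, 6))
        assert np.bincount(ks).argmax() == 3


class TestCrosstab:
    SCALE = PloidyScale(c_unit=50.0, method="reference_population", residual=0.0)

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({1: 488, 2: 343, 4: 80}, {1: 53.57, 2: 37.65, 4: 8.78}),
            ({1: 233, 2: 251, 4: 37}, {1: 44.72, 2: 48.18, 4: 7.10}),
            (
                {1: 5, 2: 25, 3: 155, 4: 50, 6: 16},
                {1: 1.99, 2: 9.96, 3: 61.75, 4: 19.92, 6: 6.37},
            ),
        ],
    )
    def test_population_percentages_two_decimals(self, counts, expected):
        assert population_percentages(counts) == expected

    def test_crosstab_counts_and_percentage_sum(self):
        rng = np.random.default_rng(3)
        records = (
            [Rec("spermatozoon", v) for v in rng.normal(50, 4, 488)]
            + [Rec("spermatocyte", v) for v in rng.normal(100, 8, 343)]
            + [Rec("spermatocyte", v) for v in rng.normal(200, 16, 80)]
            + [Rec("debris", v) for v in rng.normal(500, 10, 100)]
        )
        table = crosstab(records, self.SCALE, (1, 2, 4))
        assert table.total == 911  # debris excluded
        assert table.percentages.sum() == pytest.approx(100.0, abs=0.02)
        assert "debris" not in table.counts.index

    def test_single_cell_population_sd_suppressed(self):
        records = [Rec("spermatid", 50.0)]
        table = crosstab(records, self.SCALE, (1, 2))
        assert table.percentages[1] == 100.00
        assert np.isnan(table.sd_iod[1])  # SD withheld below six cells

    def test_empty_records_raise(self):
        with pytest.raises(ValueError):
            crosstab([], self.SCALE, (1, 2))

    def test_mean_iod_reported_per_population(self):
        records = [Rec("spermatid", v) for v in (48, 50, 52, 49, 51, 50, 99, 101)]
        table = crosstab(records, self.SCALE, (1, 2))
        assert table.mean_iod[1] == pytest.approx(50.0)
        assert table.mean_iod[2] == pytest.approx(100.0)
        assert np.isfinite(table.sd_iod[1])
        assert np.isnan(table.sd_iod[2])  # only two 2C cells

    def test_json_round_trip(self, tmp_path):
        records = [Rec("spermatid", 50.0)] * 10 + [Rec("spermatocyte", 100.0)] * 5
        table = crosstab(records, self.SCALE, (1, 2))
        table.to_json(tmp_path / "t.json")
        import json

        d = json.loads((tmp_path / "t.json").read_text())
        assert d["total_sorted_cells"] == 15
        assert d["population_percentages"]["1"] == pytest.approx(66.67)
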