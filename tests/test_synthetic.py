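"""Generator ground-truth contracts: determinism, noise scaling and the
exact noiseless patterns each generator promises."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from bretpharm import synthetic
from bretpharm.synthetic import (
    AttributionTruth,
    NoiseModel,
    PlateDesign,
    SensorTruth,
    gen_bret_plate,
    gen_coloc_table,
    gen_erk_timecourses,
    gen_phospho_plate,
    gen_quartet_responses,
)


class TestBretPlate:
    def test_identical_seed_gives_identical_tables(self, small_design, responder_truth):
        noise = NoiseModel(sd_ratio=0.01, seed=7)
        truths = {("b2AR", "F5"): responder_truth}
        a = gen_bret_plate(small_design, truths, noise)
        b = gen_bret_plate(small_design, truths, noise)
        assert_frame_equal(a, b, check_exact=True)

    def test_mock_wells_carry_only_labeling_background(
        self, small_design, responder_truth
    ):
        wells = gen_bret_plate(
            small_design, {("b2AR", "F5"): responder_truth}, NoiseModel(seed=0)
        )
        mock = wells[wells["labeling"] == "mock"]
        assert (mock["bret_ratio"] == small_design.mock_background).all()

    def test_empirical_residual_sd_matches_configuration(self, responder_truth):
        design = PlateDesign(
            receptors=("b2AR",),
            sensors=("F2", "F3", "F5", "F6"),
            concentrations_uM=(0.001, 0.01, 0.1, 1.0, 10.0),
            timepoints_min=(-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
        )
        truths = {
            ("b2AR", s): SensorTruth("b2AR", s, 0.0, 0.2, -1.0, 1.0, True)
            for s in design.sensors
        }
        clean = gen_bret_plate(design, truths, NoiseModel(sd_ratio=0.0, seed=3))
        noisy = gen_bret_plate(design, truths, NoiseModel(sd_ratio=0.01, seed=3))
        resid = noisy["bret_ratio"] - clean["bret_ratio"]
        assert len(resid) >= 1000
        assert abs(resid.std() - 0.01) < 0.001  # within 10% of configured sd

    def test_residual_sd_scales_linearly(self, small_design, responder_truth):
        truths = {("b2AR", "F5"): responder_truth}
        clean = gen_bret_plate(small_design, truths, NoiseModel(sd_ratio=0.0, seed=3))
        sds = []
        for sd in (0.005, 0.01, 0.02):
            noisy = gen_bret_plate(
                small_design, truths, NoiseModel(sd_ratio=sd, seed=3)
            )
            sds.append((noisy["bret_ratio"] - clean["bret_ratio"]).std())
        ratios = np.diff(np.log(sds))
        assert np.allclose(np.exp(ratios), 2.0, rtol=0.05)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(concentrations_uM=()),
            dict(concentrations_uM=(-1.0, 1.0)),
            dict(receptors=()),
            dict(timepoints_min=(1.0, 2.0, 3.0)),  # no baseline
            dict(timepoints_min=(-3.0, 0.0, 1.0)),  # no 2-4 min coverage
        ],
    )
    def test_invalid_designs_rejected(self, small_design, bad):
        kwargs = dict(
            receptors=small_design.receptors,
            sensors=small_design.sensors,
            concentrations_uM=small_design.concentrations_uM,
            timepoints_min=small_design.timepoints_min,
        )
        kwargs.update(bad)
        with pytest.raises(ValueError):
            PlateDesign(**kwargs)

    def test_replicate_count_below_one_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(replicate_count=0)


class TestSensorTruth:
    def test_flat_nonresponder_requires_top_equal_bottom(self):
        with pytest.raises(ValueError):
            SensorTruth("r", "F1", 0.0, 0.1, -1.0, 1.0, responder=False)

    def test_responder_requires_span_and_slope(self):
        with pytest.raises(ValueError):
            SensorTruth("r", "F1", 0.1, 0.1, -1.0, 1.0, responder=True)
        with pytest.raises(ValueError):
            SensorTruth("r", "F1", 0.0, 0.1, -1.0, 0.0, responder=True)

    def test_half_maximal_response_at_ec50(self, responder_truth):
        assert responder_truth.response(0.1) == pytest.approx(0.1, abs=1e-15)


class TestQuartet:
    def test_tail_only_pattern(self):
        truth = AttributionTruth("r", "tail", tail_effect=1.0)
        q = gen_quartet_responses(truth, base=0.0, sd=0.0)
        assert [q[n] for n in ("b2AR", "b2V2", "V2b2", "V2R")] == [0, 1, 0, 1]

    def test_core_only_pattern(self):
        truth = AttributionTruth("r", "core", core_effect=1.0)
        q = gen_quartet_responses(truth, base=0.0, sd=0.0)
        assert [q[n] for n in ("b2AR", "b2V2", "V2b2", "V2R")] == [0, 0, 1, 1]

    def test_balanced_mix_cancels_in_coefficient(self):
        from bretpharm.transferability import transferability_coefficient

        truth = AttributionTruth(
            "r", "mixed", tail_effect=1.0, core_effect=1.0, mix_weight=0.5
        )
        q = gen_quartet_responses(truth, base=0.0, sd=0.0)
        assert transferability_coefficient(q).coefficient == pytest.approx(0.0)

    def test_unknown_driver_rejected(self):
        with pytest.raises(ValueError):
            AttributionTruth("r", "both")


class TestErk:
    def test_noiseless_baseline_at_time_zero(self):
        tc = gen_erk_timecourses(
            "transient", (0.0, 2.0, 5.0, 10.0, 30.0), baseline=1.3, replicate_count=1
        )
        assert tc.loc[tc["time_min"] == 0.0, "pErk"].iloc[0] == pytest.approx(1.3)

    @pytest.mark.parametrize(
        "kinetic_class,peak_min", [("transient", 2.0), ("sustained", 5.0)]
    )
    def test_noiseless_peak_time_on_grid(self, kinetic_class, peak_min):
        tc = gen_erk_timecourses(
            kinetic_class, (0.0, 2.0, 5.0, 10.0, 30.0), replicate_count=1
        )
        assert tc.loc[tc["pErk"].idxmax(), "time_min"] == peak_min

    def test_transient_decays_toward_baseline_by_ten_minutes(self):
        tc = gen_erk_timecourses(
            "transient", (0.0, 2.0, 5.0, 10.0, 30.0), replicate_count=1
        )
        by_time = tc.set_index("time_min")["pErk"]
        rise_at_peak = by_time[2.0] - by_time[0.0]
        rise_at_ten = by_time[10.0] - by_time[0.0]
        assert rise_at_ten < 0.1 * rise_at_peak

    def test_unsorted_timepoints_rejected(self):
        with pytest.raises(ValueError):
            gen_erk_timecourses("transient", (0.0, 5.0, 2.0, 10.0))


class TestPhosphoAndColoc:
    def test_noiseless_plate_inverts_to_truth(self):
        from bretpharm.readouts import quantify_phospho

        truth = {
            ("b2AR", "proximal", "vehicle", 0.0): 0.0,
            ("b2AR", "proximal", "Iso", 10.0): 1.0,
            ("b2AR", "proximal", "Iso", 0.1): 0.4,
        }
        plate = gen_phospho_plate(truth, NoiseModel(sd_od=0.0, replicate_count=2))
        values = quantify_phospho(plate).set_index(["condition", "conc_uM"])
        assert values.loc[("vehicle", 0.0), "value_pct"].mean() == pytest.approx(0.0)
        assert values.loc[("Iso", 10.0), "value_pct"].mean() == pytest.approx(100.0)
        assert values.loc[("Iso", 0.1), "value_pct"].mean() == pytest.approx(40.0)

    def test_noiseless_coloc_inverts_to_truth(self):
        from bretpharm.readouts import normalize_coloc

        truth = {("arrestin-Rab5", "V2R", "Control", "stimulated"): 2.0}
        table = gen_coloc_table(truth, sd=0.0, seed=0)
        folds = normalize_coloc(table)
        stim = folds[folds["stim_state"] == "stimulated"]
        assert stim["fold"].iloc[0] == pytest.approx(2.0)

    def test_seeded_determinism(self):
        truth = {("arrestin-Rab5", "V2R", "Control", "stimulated"): 2.0}
        a = gen_coloc_table(truth, sd=0.1, seed=11)
        b = gen_coloc_table(truth, sd=0.1, seed=11)
        assert_frame_equal(a, b, check_exact=True)
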