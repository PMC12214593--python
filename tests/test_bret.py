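"""BRET processing chain: each normalization step against hand
arithmetic, plus order-of-operations and round-trip properties."""

import numpy as np
import pandas as pd
import pytest

from bretpharm import bret, synthetic
from bretpharm.synthetic import NoiseModel, SensorTruth, gen_bret_plate


def _series(values, time=None, treatment="ligand", conc=1.0, replicate=1):
    time = time if time is not None else list(range(-3, len(values) - 3))
    return pd.DataFrame(
        {
            "receptor": "b2AR",
            "grk_condition": "Control",
            "arrestin": "beta-arrestin2",
            "sensor": "F5",
            "treatment": treatment,
            "conc_uM": conc,
            "time_min": time,
            "replicate": replicate,
            "bret_ratio": values,
        }
    )


class TestCorrectLabeling:
    def test_identical_labeled_and_mock_cancel(self):
        labeled = _series([1.0, 1.0, 1.0])
        out = bret.correct_labeling(labeled, labeled.copy())
        assert (out["corrected"] == 0).all()

    def test_constant_offset_is_recovered(self):
        labeled = _series([1.2, 1.2, 1.2])
        mock = _series([1.0, 1.0, 1.0])
        out = bret.correct_labeling(labeled, mock)
        assert np.allclose(out["corrected"], 0.2)

    def test_triplicates_are_averaged_before_subtraction(self):
        labeled = pd.concat(
            [_series([v], time=[0.0], replicate=r) for r, v in enumerate((1.0, 1.1, 1.2))]
        )
        mock = pd.concat(
            [_series([0.5], time=[0.0], replicate=r) for r in range(3)]
        )
        out = bret.correct_labeling(labeled, mock)
        assert out["corrected"].iloc[0] == pytest.approx(0.6)

    def test_missing_mock_wells_error(self):
        labeled = _series([1.0, 1.0, 1.0])
        mock = _series([1.0, 1.0, 1.0], conc=2.0)
        with pytest.raises(ValueError, match="mock"):
            bret.correct_labeling(labeled, mock)

    def test_averaging_order_commutes_for_equal_replicate_counts(self):
        rng = np.random.default_rng(5)
        labeled = pd.concat(
            [_series(rng.normal(1.0, 0.1, 4), time=[0, 1, 2, 3], replicate=r)
             for r in range(3)]
        )
        mock = pd.concat(
            [_series(rng.normal(0.3, 0.1, 4), time=[0, 1, 2, 3], replicate=r)
             for r in range(3)]
        )
        averaged_first = bret.correct_labeling(labeled, mock)
        # subtraction per replicate, then averaging
        merged = labeled.merge(
            mock,
            on=["receptor", "grk_condition", "arrestin", "sensor", "treatment",
                "conc_uM", "time_min", "replicate"],
            suffixes=("_l", "_m"),
        )
        merged["diff"] = merged["bret_ratio_l"] - merged["bret_ratio_m"]
        by_time = merged.groupby("time_min")["diff"].mean()
        assert np.allclose(averaged_first["corrected"].to_numpy(), by_time.to_numpy())


class TestBaselineNormalize:
    def _corrected(self, values, time):
        frame = _series(values, time=time)
        frame = frame.rename(columns={"bret_ratio": "corrected"})
        return frame[
            ["receptor", "grk_condition", "arrestin", "sensor", "treatment",
             "conc_uM", "time_min", "corrected"]
        ]

    def test_constant_series_gives_unit_fold(self):
        out = bret.baseline_normalize(
            self._corrected([0.5] * 6, time=[-3, -2, -1, 0, 1, 2])
        )
        assert np.allclose(out["fold"], 1.0)

    def test_hand_arithmetic(self):
        out = bret.baseline_normalize(
            self._corrected([0.5, 0.5, 0.6], time=[-2, -1, 2])
        )
        assert out["fold"].iloc[-1] == pytest.approx(1.2)

    def test_zero_baseline_is_an_error(self):
        with pytest.raises(ValueError, match="baseline"):
            bret.baseline_normalize(
                self._corrected([0.0, 0.0, 0.5], time=[-2, -1, 2])
            )


class TestVehicleNormalize:
    def _folds(self, stim, veh, time):
        frames = [
            _series(stim, time=time).rename(columns={"bret_ratio": "fold"}),
            _series(veh, time=time, treatment="vehicle", conc=0.0).rename(
                columns={"bret_ratio": "fold"}
            ),
        ]
        out = pd.concat(frames, ignore_index=True)
        return out[
            ["receptor", "grk_condition", "arrestin", "sensor", "treatment",
             "conc_uM", "time_min", "fold"]
        ]

    def test_stim_equal_vehicle_gives_unity_and_zero(self):
        folds = self._folds([1.1, 1.2], [1.1, 1.2], time=[1, 2])
        as_fold = bret.vehicle_normalize(folds, convention="fold")
        as_pct = bret.vehicle_normalize(folds, convention="percent")
        stim_fold = as_fold[as_fold["treatment"] == "ligand"]["delta_net"]
        stim_pct = as_pct[as_pct["treatment"] == "ligand"]["delta_net"]
        assert np.allclose(stim_fold, 1.0)
        assert np.allclose(stim_pct, 0.0)

    @pytest.mark.parametrize("stim,veh", [(1.10, 1.00), (1.21, 1.10)])
    def test_ten_percent_change(self, stim, veh):
        folds = self._folds([stim], [veh], time=[2])
        out = bret.vehicle_normalize(folds, convention="percent")
        value = out[out["treatment"] == "ligand"]["delta_net"].iloc[0]
        assert value == pytest.approx(10.0)

    def test_nonpositive_vehicle_errors(self):
        folds = self._folds([1.1], [0.0], time=[2])
        with pytest.raises(ValueError, match="vehicle"):
            bret.vehicle_normalize(folds)


class TestWindowAverage:
    def _tc(self, values, time):
        frame = _series(values, time=time).rename(columns={"bret_ratio": "delta_net"})
        return frame[
            ["receptor", "grk_condition", "arrestin", "sensor", "treatment",
             "conc_uM", "time_min", "delta_net"]
        ]

    def test_mean_of_window_points(self):
        out = bret.window_average(self._tc([4.0, 5.0, 6.0], time=[2, 3, 4]))
        assert out["response"].iloc[0] == pytest.approx(5.0)

    def test_single_point_window(self):
        out = bret.window_average(self._tc([1.0, 7.0], time=[0, 2]))
        assert out["response"].iloc[0] == pytest.approx(7.0)

    def test_empty_window_errors(self):
        with pytest.raises(ValueError, match="window"):
            bret.window_average(self._tc([1.0], time=[5.0]))


class TestAssemble:
    def _responses(self, mapping):
        return pd.DataFrame(
            {
                "receptor": "b2AR",
                "grk_condition": "Control",
                "arrestin": "beta-arrestin2",
                "sensor": "F5",
                "treatment": "ligand",
                "conc_uM": list(mapping),
                "response": list(mapping.values()),
            }
        )

    def test_anchor_subtraction(self):
        out = bret.assemble_concentration_response(
            self._responses({0.1: 1.0, 1.0: 4.0, 10.0: 6.0, 100.0: 7.0})
        )
        assert np.allclose(out["response"], [0.0, 3.0, 5.0, 6.0])

    def test_equal_responses_map_to_zero(self):
        out = bret.assemble_concentration_response(
            self._responses({0.1: 2.0, 1.0: 2.0, 10.0: 2.0, 100.0: 2.0})
        )
        assert (out["response"] == 0).all()

    def test_too_few_concentrations_flagged(self):
        with pytest.raises(ValueError, match="unfittable"):
            bret.assemble_concentration_response(
                self._responses({0.1: 1.0, 1.0: 2.0, 10.0: 3.0})
            )


class TestRoundTrip:
    def test_noiseless_plate_reproduces_truth_curves(self, small_design):
        truths = {
            ("b2AR", "F5"): SensorTruth("b2AR", "F5", 0.0, 0.2, -1.0, 1.0, True)
        }
        wells = gen_bret_plate(small_design, truths, NoiseModel(seed=0))
        out = bret.process_wells(wells, convention="percent")
        truth = truths[("b2AR", "F5")]
        cr = out["concresp"].sort_values("log10_conc_uM")
        expected = np.array(
            [100.0 * truth.response(10.0**x) for x in cr["log10_conc_uM"]]
        )
        expected -= expected[0]
        assert np.allclose(cr["response"], expected, atol=1e-9)

    def test_vehicle_drift_cancels_exactly(self, responder_truth):
        design = synthetic.PlateDesign(
            receptors=("b2AR",),
            sensors=("F5",),
            concentrations_uM=(0.001, 0.01, 0.1, 1.0, 10.0),
            timepoints_min=(-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
            drift_per_min=0.01,
        )
        wells = gen_bret_plate(
            design, {("b2AR", "F5"): responder_truth}, NoiseModel(seed=0)
        )
        out = bret.process_wells(wells, convention="percent")
        vehicle_tc = out["timecourse"]
        vehicle_rows = vehicle_tc[vehicle_tc["treatment"] == "vehicle"]
        assert np.allclose(vehicle_rows["delta_net"], 0.0, atol=1e-12)
        cr = out["concresp"].sort_values("log10_conc_uM")
        truth_pct = np.array(
            [100.0 * responder_truth.response(10.0**x) for x in cr["log10_conc_uM"]]
        )
        truth_pct -= truth_pct[0]
        assert np.allclose(cr["response"], truth_pct, atol=1e-9)
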