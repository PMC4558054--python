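"""Calibration: windowing, objective, normalisation, fitting, CIs."""

import numpy as np
import pandas as pd
import pytest

from choflux.calibrate import (
    CalibrationConfig,
    CalibrationResult,
    confidence_intervals,
    denormalize_params,
    fit,
    intervals_overlap,
    natural_covariance,
    normalize_params,
    objective,
    select_experiments,
    subset_comparison,
    window_measurements,
)
from choflux.measurements import MeasurementSet
from choflux.synth import NoiseModel, SamplingSchedule, generate_dataset


def _measurements(times, culture="c1", viability=None):
    rec = pd.DataFrame(
        {"culture": culture, "output": "S", "time_h": times,
         "value": 1.0, "sd": 0.1}
    )
    via = viability if viability is not None else pd.DataFrame(
        {"culture": [culture], "time_h": [0.0], "viability_pct": [100.0]}
    )
    return MeasurementSet(records=rec, viability=via)


class TestWindowing:
    def test_early_samples_dropped(self):
        ms = _measurements([12.0, 24.0, 48.0])
        out = window_measurements(ms)
        assert sorted(out.records["time_h"]) == [24.0, 48.0]

    def test_viability_cutoff_drops_late_records(self):
        via = pd.DataFrame(
            {"culture": "c1", "time_h": [0, 96, 120, 132],
             "viability_pct": [100, 97, 94, 80]}
        )
        ms = _measurements([24.0, 96.0, 120.0, 132.0], viability=via)
        out = window_measurements(ms)
        assert sorted(out.records["time_h"]) == [24.0, 96.0, 120.0]

    def test_high_viability_keeps_everything(self):
        ms = _measurements([24.0, 72.0, 144.0])
        assert len(window_measurements(ms)) == 3

    def test_phase_schemes_split_at_72h(self):
        ms = _measurements([24.0, 48.0, 96.0])
        p1 = window_measurements(ms, CalibrationConfig(scheme="phase1"))
        p2 = window_measurements(ms, CalibrationConfig(scheme="phase2"))
        assert sorted(p1.records["time_h"]) == [24.0, 48.0]
        assert sorted(p2.records["time_h"]) == [96.0]

    def test_missing_viability_is_an_error(self):
        rec = pd.DataFrame(
            {"culture": "c1", "output": "S", "time_h": [24.0],
             "value": [1.0], "sd": [0.1]}
        )
        ms = MeasurementSet(records=rec, viability=None)
        with pytest.raises(ValueError):
            window_measurements(ms)


class TestObjective:
    def test_weighted_ssr_examples(self, toy):
        net, params, exp = toy
        ms, _ = generate_dataset(net, params, exp, schedule=SamplingSchedule(12.0),
                                 noise=NoiseModel(0, 0, 0), seed=0,
                                 outputs=["S", "P"])
        assert objective(params, net, [exp], ms) == pytest.approx(0.0, abs=1e-10)
        # shift one record by one sd -> SSR contribution 1
        rec = ms.records.copy()
        rec.loc[0, "value"] += rec.loc[0, "sd"]
        shifted = MeasurementSet(records=rec, viability=ms.viability)
        assert objective(params, net, [exp], shifted) == pytest.approx(1.0, abs=1e-6)
        # halving sd quadruples that contribution
        rec2 = rec.copy()
        rec2.loc[0, "sd"] = rec.loc[0, "sd"] / 2
        rec2.loc[0, "value"] = rec.loc[0, "value"]
        shifted2 = MeasurementSet(records=rec2, viability=ms.viability)
        assert objective(params, net, [exp], shifted2) == pytest.approx(4.0, abs=1e-5)


def test_normalization_round_trip(rng):
    values = rng.uniform(1e-9, 1e3, size=20)
    exps = np.floor(np.log10(values)).astype(int)
    scaled = normalize_params(values, exps)
    assert np.all((scaled >= 1.0 - 1e-9) & (scaled < 10.0 + 1e-9))
    assert denormalize_params(scaled, exps) == pytest.approx(values, rel=1e-15)
    assert normalize_params(2.9e-8, -8) == pytest.approx(2.9)
    assert normalize_params(0.0, 5) == 0.0


class TestFit:
    free = ["VmaxU", "VmaxC", "KdP_C"]

    def _noiseless(self, toy):
        net, params, exp = toy
        ms, _ = generate_dataset(net, params, exp, schedule=SamplingSchedule(12.0),
                                 noise=NoiseModel(0, 0, 0), seed=0,
                                 outputs=["S", "P", "M"])
        return net, params, exp, ms

    def test_zero_noise_recovery_within_one_percent(self, toy):
        net, params, exp, ms = self._noiseless(toy)
        start = params.copy()
        for n in self.free:
            start[n] = params[n] * 1.1
        res = fit(net, [exp], ms,
                  CalibrationConfig(free_names=self.free, window=False),
                  params=start)
        assert res.success
        for n in self.free:
            assert res.params[n] == pytest.approx(params[n], rel=0.01)

    def test_descent_and_bounds(self, toy):
        net, params, exp, ms = self._noiseless(toy)
        start = params.copy()
        for n in self.free:
            start[n] = params[n] * 1.3
        res = fit(net, [exp], ms,
                  CalibrationConfig(free_names=self.free, window=False),
                  params=start)
        assert res.ssr <= objective(start, net, [exp], ms) + 1e-12
        assert np.all(res.estimates >= 0.0)


class TestConfidenceIntervals:
    def _linear_result(self, sigma=1.0):
        """Weighted linear model y = a*t oracle, 5 points, known closed form."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        a_true = 2.0
        noise = np.array([0.3, -0.2, 0.1, -0.4, 0.25])
        y = a_true * t + noise
        a_hat = (t @ y) / (t @ t)
        resid = (a_hat * t - y) / sigma
        jac = (t / sigma)[:, None]
        from choflux.parameters import ParameterSet

        p = ParameterSet(names=["a"], values=np.array([a_hat]))
        return CalibrationResult(
            params=p, free_names=["a"], estimates=np.array([a_hat]),
            exponents=np.array([0]), ssr=float(resid @ resid), residuals=resid,
            jacobian=jac, n_obs=5, success=True,
        ), t, y, a_hat, sigma

    def test_matches_textbook_closed_form(self):
        res, t, y, a_hat, sigma = self._linear_result()
        ci = confidence_intervals(res).iloc[0]
        s2 = np.sum((y - a_hat * t) ** 2) / 4
        se = np.sqrt(s2 / (t @ t))
        from scipy import stats

        half = stats.t.ppf(0.975, 4) * se
        assert ci["estimate"] == pytest.approx(a_hat)
        assert ci["ci_low"] == pytest.approx(a_hat - half)
        assert ci["ci_high"] == pytest.approx(a_hat + half)
        assert ci["ci_low"] <= ci["estimate"] <= ci["ci_high"]

    def test_zero_residuals_give_zero_width(self):
        res, *_ = self._linear_result()
        res.residuals = np.zeros(5)
        res.ssr = 0.0
        ci = confidence_intervals(res).iloc[0]
        assert ci["ci_low"] == ci["ci_high"] == ci["estimate"]

    def test_doubling_sigma_doubles_width(self):
        # fixed weighted residuals, Jacobian halves -> CI half-width doubles
        res1, *_ = self._linear_result(sigma=1.0)
        res2, *_ = self._linear_result(sigma=1.0)
        res2.jacobian = res1.jacobian / 2.0
        w1 = confidence_intervals(res1).iloc[0]
        w2 = confidence_intervals(res2).iloc[0]
        assert (w2["ci_high"] - w2["ci_low"]) == pytest.approx(
            2.0 * (w1["ci_high"] - w1["ci_low"])
        )

    def test_rank_deficiency_flags_non_identifiable(self):
        res, *_ = self._linear_result()
        res.free_names = ["a", "b"]
        res.estimates = np.array([2.0, 1.0])
        res.exponents = np.array([0, 0])
        res.jacobian = np.column_stack([res.jacobian, res.jacobian])  # collinear
        ci = confidence_intervals(res)
        assert not ci["identifiable"].any()

    def test_natural_covariance_rescales_by_magnitude(self):
        res, *_ = self._linear_result()
        res.exponents = np.array([-3])
        nat = natural_covariance(res)
        res.exponents = np.array([0])
        scaled = natural_covariance(res)
        assert nat[0, 0] == pytest.approx(scaled[0, 0] * 1e-6)


class TestSubsetComparison:
    def test_interval_overlap_logic(self):
        assert intervals_overlap(1, 2, 1.5, 3)
        assert not intervals_overlap(1, 2, 2.1, 3)
        assert intervals_overlap(1, 2, 2.0, 3)

    def test_scheme_selection(self, ref_exps):
        assert len(select_experiments(ref_exps, "batch")) == 2
        assert len(select_experiments(ref_exps, "Biogro")) == 2
        assert len(select_experiments(ref_exps, "all")) == 4
        assert {e.mode for e in select_experiments(ref_exps, "fed-batch")} == {"fed-batch"}

    def test_identical_subsets_agree(self, toy):
        """Duplicated cultures in the two media give identical estimates and
        full CI overlap."""
        from choflux.simulator import CultureExperiment

        net, params, exp = toy
        exp_a = CultureExperiment(name="a", initial_state=dict(exp.initial_state),
                                  mode="batch", duration_h=exp.duration_h)
        exp_a.medium = "Biogro"
        exp_b = CultureExperiment(name="b", initial_state=dict(exp.initial_state),
                                  mode="batch", duration_h=exp.duration_h)
        exp_b.medium = "PowerCHO"
        sets = []
        for e in (exp_a, exp_b):
            ms, _ = generate_dataset(net, params, e, schedule=SamplingSchedule(12.0),
                                     noise=NoiseModel(0.05, 0.05, 0.05), seed=11,
                                     outputs=["S", "P", "M"])
            sets.append(ms)
        ms = sets[0].concat(sets[1])
        start = params.copy()
        start["VmaxU"] = params["VmaxU"] * 1.1
        table, overlaps = subset_comparison(
            net, [exp_a, exp_b], ms, ["Biogro", "PowerCHO"], start,
            CalibrationConfig(free_names=["VmaxU", "VmaxC"], window=False),
        )
        a = table[table["scheme"] == "Biogro"].set_index("parameter")
        b = table[table["scheme"] == "PowerCHO"].set_index("parameter")
        for n in ["VmaxU", "VmaxC"]:
            assert a.loc[n, "estimate"] == pytest.approx(b.loc[n, "estimate"], rel=1e-6)
        assert all(overlaps[("Biogro", "PowerCHO")].values())
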