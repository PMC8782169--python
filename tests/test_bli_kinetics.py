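"""Sensorgram alignment, kobs fitting and the kobs-vs-concentration analysis."""

import dataclasses

import numpy as np
import pytest

from nmrbind import (
    BLIGroundTruth,
    BLIStage,
    BLITrace,
    KobsFit,
    align_baseline,
    analyze_sensors,
    fit_dissociation,
    fit_kobs,
    kinetic_analysis,
    simulate_bli,
)


def make_trace(baseline_level=0.3, drift=0.0, kobs=0.05, req=0.8, koff=0.04, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    tb = np.arange(0.0, 60.0, 0.2)
    ta = np.arange(0.0, 120.0, 0.2)
    td = np.arange(0.0, 120.0, 0.2)
    assoc = req * (1 - np.exp(-kobs * ta))
    stages = [
        BLIStage("baseline", tb, baseline_level + drift * tb + rng.normal(0, noise, tb.size)),
        BLIStage("association", 60 + ta, baseline_level + assoc + rng.normal(0, noise, ta.size)),
        BLIStage("dissociation", 180 + td, baseline_level + assoc[-1] * np.exp(-koff * td) + rng.normal(0, noise, td.size)),
    ]
    return BLITrace("s1", 4e-6, stages)


class TestAlignBaseline:
    def test_flat_baseline_subtracted(self):
        aligned = align_baseline(make_trace(baseline_level=0.3))
        assert np.allclose(aligned.stage("baseline").response, 0.0)
        assert aligned.stage("association").response[0] == pytest.approx(0.0, abs=1e-12)

    def test_already_zero_is_identity(self):
        tr = make_trace(baseline_level=0.0)
        aligned = align_baseline(tr)
        for s0, s1 in zip(tr.stages, aligned.stages):
            assert np.allclose(s0.response, s1.response)

    def test_drifting_baseline_offset_equals_tail_mean(self):
        tr = make_trace(baseline_level=0.3, drift=0.001)
        base = tr.stage("baseline")
        n_tail = max(1, int(round(0.2 * base.time.size)))
        expected_offset = float(np.mean(base.response[-n_tail:]))
        aligned = align_baseline(tr)
        shift = tr.stage("association").response - aligned.stage("association").response
        assert np.allclose(shift, expected_offset)

    def test_missing_baseline_warns_and_passes_through(self):
        tr = make_trace()
        no_base = dataclasses.replace(tr, stages=tr.stages[1:])
        with pytest.warns(UserWarning, match="baseline"):
            aligned = align_baseline(no_base)
        assert np.allclose(aligned.stage("association").response, no_base.stage("association").response)

    def test_association_clock_rezeroed(self):
        aligned = align_baseline(make_trace())
        assert aligned.stage("association").time[0] == 0.0
        assert aligned.stage("dissociation").time[0] == 0.0


class TestFitKobs:
    def test_noiseless_exact_recovery(self):
        aligned = align_baseline(make_trace(kobs=0.05, req=0.8))
        fit = fit_kobs(aligned)
        assert fit.usable
        assert fit.kobs == pytest.approx(0.05, rel=1e-6)
        assert fit.req == pytest.approx(0.8, rel=1e-6)

    def test_linear_ramp_flagged_unusable(self):
        ta = np.arange(0.0, 120.0, 0.2)
        tr = BLITrace(
            "ramp", 4e-6,
            [BLIStage("baseline", np.arange(0, 60, 0.2), np.zeros(300)),
             BLIStage("association", 60 + ta, 0.001 * ta)],
        )
        fit = fit_kobs(align_baseline(tr))
        assert not fit.usable

    def test_median_kobs_within_5pct_at_instrument_noise(self):
        recovered = []
        for seed in range(100):
            aligned = align_baseline(make_trace(kobs=0.05, req=0.8, noise=0.01, seed=seed))
            fit = fit_kobs(aligned)
            if fit.usable:
                recovered.append(fit.kobs)
        assert abs(np.median(recovered) - 0.05) / 0.05 < 0.05


class TestKineticAnalysis:
    def test_exact_linear_inputs_recovered_exactly(self):
        concs = np.array([1e-6, 2e-6, 4e-6, 8e-6])
        fits = [KobsFit(c, kobs=1e4 * c + 0.01, kobs_err=0.0, usable=True) for c in concs]
        kin = kinetic_analysis(fits)
        assert kin.kon == pytest.approx(1e4, rel=1e-10)
        assert kin.koff == pytest.approx(0.01, rel=1e-10)
        assert kin.kd == pytest.approx(1e-6, rel=1e-10)
        assert kin.r_squared == pytest.approx(1.0)

    def test_matches_closed_form_weighted_regression_with_duplicates(self):
        concs = [1e-6, 2e-6, 2e-6, 4e-6, 8e-6]
        kobs = [0.051, 0.059, 0.062, 0.081, 0.121]
        errs = [0.002, 0.001, 0.003, 0.002, 0.004]
        fits = [KobsFit(c, kobs=k, kobs_err=e, usable=True) for c, k, e in zip(concs, kobs, errs)]
        kin = kinetic_analysis(fits)
        # independent oracle: solve the weighted normal equations directly
        x, y, w = np.array(concs), np.array(kobs), 1.0 / np.array(errs) ** 2
        A = np.array([[np.sum(w * x * x), np.sum(w * x)], [np.sum(w * x), np.sum(w)]])
        b = np.array([np.sum(w * x * y), np.sum(w * y)])
        slope, intercept = np.linalg.solve(A, b)
        assert kin.kon == pytest.approx(slope, rel=1e-9)
        assert kin.koff == pytest.approx(intercept, rel=1e-9)

    def test_fewer_than_three_concentrations_is_error(self):
        fits = [KobsFit(c, kobs=1e4 * c + 0.01, usable=True) for c in (1e-6, 2e-6)]
        with pytest.raises(ValueError, match="3 distinct"):
            kinetic_analysis(fits)

    def test_negative_intercept_flags_unreliable(self):
        fits = [KobsFit(c, kobs=1e4 * c - 0.005, kobs_err=0.0, usable=True) for c in (1e-6, 2e-6, 4e-6, 8e-6)]
        kin = kinetic_analysis(fits)
        assert not kin.reliable
        assert np.isnan(kin.kd)


class TestDissociation:
    def test_noiseless_koff_recovery(self):
        aligned = align_baseline(make_trace(koff=0.04))
        fit = fit_dissociation(aligned)
        assert fit.usable
        assert fit.koff == pytest.approx(0.04, rel=1e-4)

    def test_flat_zero_trace_unusable(self):
        td = np.arange(0.0, 120.0, 0.2)
        tr = BLITrace(
            "flat", 4e-6,
            [BLIStage("baseline", np.arange(0, 60, 0.2), np.zeros(300)),
             BLIStage("association", np.arange(60, 180, 0.2), np.zeros(600)),
             BLIStage("dissociation", 180 + td, np.zeros(td.size))],
        )
        assert not fit_dissociation(align_baseline(tr)).usable


class TestSimulatorRecovery:
    def test_noiseless_full_set_recovers_rates_sharply(self):
        gt = BLIGroundTruth(kon=1e4, koff=0.04, noise_sd=0.0, seed=0)
        _, kin, _ = analyze_sensors(simulate_bli(gt))
        assert kin.kon == pytest.approx(1e4, rel=5e-3)
        assert kin.koff == pytest.approx(0.04, rel=5e-3)
        assert kin.kd == pytest.approx(4e-6, rel=5e-3)

    @pytest.mark.parametrize("kon, koff", [(1e3, 1e-3), (1e4, 0.04), (1e6, 1.0)])
    def test_noiseless_recovery_across_rate_regimes(self, kon, koff):
        gt = BLIGroundTruth(kon=kon, koff=koff, noise_sd=0.0, offset=0.0, seed=0)
        _, kin, _ = analyze_sensors(simulate_bli(gt))
        assert kin.kon == pytest.approx(kon, rel=5e-3)
        assert kin.koff == pytest.approx(koff, rel=5e-3)

    def test_kobs_monotonic_in_concentration(self):
        gt = BLIGroundTruth(seed=2)
        kfits, _, _ = analyze_sensors(simulate_bli(gt))
        kobs = [f.kobs for f in sorted(kfits, key=lambda f: f.conc)]
        assert all(b > a for a, b in zip(kobs, kobs[1:]))

    def test_dissociation_koff_consistent_with_intercept(self):
        gt = BLIGroundTruth(seed=3)
        _, kin, dfits = analyze_sensors(simulate_bli(gt))
        for d in dfits:
            if d.usable:
                joint_sigma = 2 * np.hypot(kin.koff_err, d.koff_err)
                assert abs(d.koff - kin.koff) <= max(joint_sigma, 0.2 * kin.koff)
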