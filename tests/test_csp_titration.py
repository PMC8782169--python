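"""CSP computation, two-state bound fraction, peak tracking and Kd fitting."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from nmrbind import (
    BindingFit,
    Peak,
    PeakList,
    TitrationGroundTruth,
    analyze_titration,
    bound_fraction,
    combined_csp,
    compare_saturation,
    fit_residue_kd,
    global_kd,
    interaction_surface,
    match_peaks,
    simulate_titration,
    track_trajectories,
)


def bound_fraction_bisection(p0: float, l0: float, kd: float) -> float:
    """Independent oracle: root of Kd·[PL] = (P0−[PL])·(L0−[PL]) by bisection."""
    if l0 == 0:
        return 0.0

    def mass_balance(pl):
        return kd * pl - (p0 - pl) * (l0 - pl)

    upper = min(p0, l0)
    if mass_balance(upper) < 0:  # kd == 0, stoichiometric limit
        return upper / p0
    return brentq(mass_balance, 0.0, upper, xtol=1e-30, rtol=1e-15) / p0


class TestCombinedCsp:
    @pytest.mark.parametrize(
        "dh, dn, expected",
        [(0.0, 0.0, 0.0), (0.10, 0.0, 0.10), (0.0, 1.00, 0.152)],
    )
    def test_reference_values(self, dh, dn, expected):
        assert combined_csp(dh, dn) == pytest.approx(expected, abs=1e-12)

    @given(
        dh=st.floats(-5, 5, allow_nan=False),
        dn=st.floats(-30, 30, allow_nan=False),
    )
    @settings(max_examples=50, derandomize=True)
    def test_sign_invariance(self, dh, dn):
        v = combined_csp(dh, dn)
        assert v >= 0
        assert combined_csp(-dh, dn) == v
        assert combined_csp(dh, -dn) == v


class TestBoundFraction:
    def test_no_ligand_gives_zero(self):
        assert bound_fraction(50e-6, 0.0, 3.7e-6) == 0.0

    def test_stoichiometric_limit(self):
        assert bound_fraction(50e-6, 60e-6, 0.0) == 1.0

    def test_matches_bisection_oracle_at_titration_midpoint(self):
        f = bound_fraction(50e-6, 200e-6, 3.7e-6)
        oracle = bound_fraction_bisection(50e-6, 200e-6, 3.7e-6)
        assert f == pytest.approx(oracle, rel=1e-10)
        assert f == pytest.approx(0.976, abs=0.001)

    def test_matches_bisection_oracle_on_grid(self):
        p0s = np.geomspace(1e-6, 1e-3, 6)
        ratios = np.linspace(0.25, 12, 6)
        kds = np.geomspace(1e-7, 1e-3, 6)
        for p0 in p0s:
            for r in ratios:
                for kd in kds:
                    f = bound_fraction(p0, r * p0, kd)
                    assert f == pytest.approx(bound_fraction_bisection(p0, r * p0, kd), rel=1e-10)

    @given(
        p0=st.floats(1e-6, 1e-3),
        ratio=st.floats(0.0, 12.0),
        kd=st.floats(1e-7, 1e-3),
    )
    @settings(max_examples=100, derandomize=True)
    def test_bounded_and_monotonic(self, p0, ratio, kd):
        f = bound_fraction(p0, ratio * p0, kd)
        assert 0.0 <= f <= 1.0
        assert bound_fraction(p0, (ratio + 0.5) * p0, kd) >= f  # more ligand binds more
        assert bound_fraction(p0, ratio * p0, kd * 2) <= f  # weaker binds less

    def test_dilute_limit_approaches_langmuir(self):
        # as P0 -> 0 the fraction tends to L/(L+Kd)
        kd = 5e-6
        p0 = kd / 1000
        for l0 in (1e-6, 5e-6, 2e-5):
            assert bound_fraction(p0, l0, kd) == pytest.approx(l0 / (l0 + kd), rel=5e-3)


class TestMatchPeaks:
    def test_identical_lists_identity_mapping(self, small_peak_list):
        matches = match_peaks(small_peak_list, small_peak_list)
        for rid, m in matches.items():
            assert m.status == "matched"
            assert m.target.residue_id == rid
            assert m.distance == 0.0

    def test_small_uniform_shift_recovered(self, small_peak_list):
        shifted = PeakList(
            "shifted",
            [Peak(p.residue_id, p.delta_H + 0.01, p.delta_N + 0.05, p.intensity) for p in small_peak_list],
        )
        matches = match_peaks(small_peak_list, shifted)
        assert all(m.status == "matched" and m.target.residue_id == rid for rid, m in matches.items())

    def test_jump_beyond_limit_unmatched(self):
        ref = PeakList("ref", [Peak("A1", 8.0, 120.0)])
        tgt = PeakList("tgt", [Peak("A1", 9.0, 120.0)])
        matches = match_peaks(ref, tgt, max_jump=0.2)
        assert matches["A1"].status == "unmatched"

    def test_crossing_trajectories_flag_ambiguity_not_swap(self):
        # two reference peaks nearly equidistant from a single nearby target:
        # neither may silently claim it
        ref = PeakList("ref", [Peak("A1", 8.00, 120.0), Peak("B2", 8.04, 120.0)])
        tgt = PeakList("tgt", [Peak("x", 8.02, 120.0), Peak("y", 9.5, 130.0)])
        matches = match_peaks(ref, tgt, max_jump=0.2)
        assert matches["A1"].status == "ambiguous"
        assert matches["B2"].status == "ambiguous"


class TestKdFitting:
    def test_noiseless_recovery_is_exact(self):
        gt = TitrationGroundTruth.default(kd=3.7e-6, seed=7, noise_h=0.0, noise_n=0.0)
        series = simulate_titration(gt)
        result = analyze_titration(series)
        assert result.verdict == "binding detected"
        assert result.global_kd.mean == pytest.approx(3.7e-6, rel=1e-3)

    @pytest.mark.parametrize("kd_true", [1e-7, 1e-6, 1e-5, 1e-4])
    def test_noiseless_recovery_sweep(self, kd_true):
        gt = TitrationGroundTruth.default(kd=kd_true, n_residues=4, seed=11, noise_h=0.0, noise_n=0.0)
        trajs = track_trajectories(simulate_titration(gt))
        for traj in trajs.values():
            fit = fit_residue_kd(traj, gt.p0, gt.ratios)
            assert fit.converged
            assert fit.kd == pytest.approx(kd_true, rel=1e-3)

    def test_error_bars_have_nominal_coverage(self):
        """1-sigma intervals from the fit covariance cover the truth roughly 68% of the time."""
        kd_true = 3.7e-6
        covered = 0
        n_fits = 0
        for seed in range(100):
            gt = TitrationGroundTruth.default(kd=kd_true, n_residues=1, seed=seed)
            trajs = track_trajectories(simulate_titration(gt))
            for traj in trajs.values():
                fit = fit_residue_kd(traj, gt.p0, gt.ratios)
                if fit.converged:
                    n_fits += 1
                    covered += abs(fit.kd - kd_true) <= fit.kd_err
        assert n_fits >= 80
        assert 0.45 <= covered / n_fits <= 0.90  # nominal 0.68

    def test_all_zero_trajectory_flagged_not_raised(self):
        from nmrbind import ShiftTrajectory

        traj = ShiftTrajectory("dead", np.full(9, 8.0), np.full(9, 120.0), np.zeros(9))
        fit = fit_residue_kd(traj, 50e-6, (0, 0.5, 1, 2, 4, 6, 8, 10, 12))
        assert not fit.converged
        assert "no significant shift" in fit.message


class TestGlobalKd:
    def test_single_fit(self):
        fits = [BindingFit("a", kd=2e-6, kd_err=1e-7, converged=True)]
        g = global_kd(fits)
        assert (g.mean, g.sd, g.n_residues) == (2e-6, 0.0, 1)

    def test_mean_and_sd_across_residues(self):
        fits = [
            BindingFit(r, kd=k, kd_err=1e-7, converged=True)
            for r, k in zip("abc", (3e-6, 4e-6, 5e-6))
        ]
        g = global_kd(fits)
        assert g.mean == pytest.approx(4e-6)
        assert g.sd == pytest.approx(1e-6)

    def test_non_converged_fits_never_contribute(self):
        fits = [
            BindingFit("a", kd=2e-6, kd_err=1e-7, converged=True),
            BindingFit("b", kd=9e-3, kd_err=1e-2, converged=False),
        ]
        assert global_kd(fits).n_residues == 1

    def test_zero_converged_is_error(self):
        with pytest.raises(ValueError, match="no converged"):
            global_kd([BindingFit("a", converged=False)])

    def test_shared_truth_recovered_within_dispersion(self):
        gt = TitrationGroundTruth.default(kd=5e-6, n_residues=12, seed=3)
        result = analyze_titration(simulate_titration(gt))
        g = result.global_kd
        assert abs(g.mean - 5e-6) < max(3 * g.sd / np.sqrt(g.n_residues), 5e-7)


class TestCompareSaturation:
    def test_identical_series_indistinguishable(self):
        gt = TitrationGroundTruth.default(kd=4e-6, seed=5, noise_h=0.0, noise_n=0.0)
        s = simulate_titration(gt)
        cmp = compare_saturation(s, s, ratio=4.0)
        assert cmp.verdict == "indistinguishable"
        assert all(r == pytest.approx(1.0) for r in cmp.per_residue.values())

    def test_tighter_binder_called_stronger(self):
        gt_a = TitrationGroundTruth.default(kd=4e-6, seed=5)
        gt_b = dataclasses.replace(gt_a, kd=40e-6)
        cmp = compare_saturation(simulate_titration(gt_a), simulate_titration(gt_b), ratio=4.0)
        # oracle: f_b at ratio 4 is higher for the tighter Kd
        fa = bound_fraction_bisection(50e-6, 200e-6, 4e-6)
        fb = bound_fraction_bisection(50e-6, 200e-6, 40e-6)
        assert fa > fb
        assert cmp.verdict == "A stronger"
        assert cmp.median_ratio == pytest.approx(fa / fb, rel=0.15)

    def test_absent_ratio_lists_available(self):
        gt = TitrationGroundTruth.default(kd=4e-6, seed=5)
        s = simulate_titration(gt)
        with pytest.raises(ValueError, match="available"):
            compare_saturation(s, s, ratio=3.0)


class TestInteractionSurface:
    def test_flat_profile_empty_surface(self):
        csps = {f"r{i}": 0.1 for i in range(6)}
        assert interaction_surface(csps).surface == []

    def test_constructed_hotspots_returned_exactly(self):
        csps = {f"r{i}": 0.02 for i in range(10)}
        for hot in ("C2", "C3", "M13", "K14"):
            csps[hot] = 0.10
        surf = interaction_surface(csps)
        assert sorted(surf.surface) == ["C2", "C3", "K14", "M13"]
        assert sorted(surf.top(4)) == ["C2", "C3", "K14", "M13"]

    def test_requires_five_residues(self):
        with pytest.raises(ValueError, match="5"):
            interaction_surface({"a": 0.1, "b": 0.2})
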