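"""Superposition, fluctuations, equilibration, compressibility, dG stats."""

import numpy as np
import pytest

from capsidkit.analysis import (AnalysisError, classify_variant,
                                compressibility, detect_equilibration,
                                ensemble_dg_stats, radius_series, rmsf,
                                superpose_frames, superpose_rmsd)
from capsidkit.ensemble_synth import EnsembleParams, generate_ensemble
from capsidkit.geometry import kabsch, rotation_about_axis
from capsidkit.structure_io import StructureError, StructureModel


def quaternion_rmsd(reference, mobile):
    """Independent optimal-superposition RMSD via the quaternion method."""
    p = mobile - mobile.mean(axis=0)
    q = reference - reference.mean(axis=0)
    m = p.T @ q
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    lam = np.linalg.eigvalsh(k).max()
    e0 = (p ** 2).sum() + (q ** 2).sum()
    msd = max(0.0, (e0 - 2.0 * lam)) / len(p)
    return np.sqrt(msd)


class TestSuperposition:
    def test_identical_structures_have_zero_rmsd(self, toy_asu):
        assert superpose_rmsd(toy_asu, toy_asu) == pytest.approx(0.0,
                                                                 abs=1e-9)

    def test_rigid_motion_gives_zero_rmsd(self, toy_asu):
        rot = rotation_about_axis(np.array([0.2, 0.5, 1.0]), 1.7)
        moved = toy_asu.copy()
        for a in moved.atoms():
            a.coords = rot @ a.coords + np.array([4.0, 5.0, 6.0])
        assert superpose_rmsd(toy_asu, moved) <= 1e-6

    def test_kabsch_matches_quaternion_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            ref = rng.normal(size=(20, 3)) * 5.0
            mob = rng.normal(size=(20, 3)) * 5.0
            _, _, mine = kabsch(ref, mob)
            assert abs(mine - quaternion_rmsd(ref, mob)) <= 1e-9

    def test_rmsd_is_symmetric(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(15, 3))
        b = rng.normal(size=(15, 3))
        assert kabsch(a, b)[2] == pytest.approx(kabsch(b, a)[2], abs=1e-12)

    def test_selection_size_mismatch(self, toy_asu):
        smaller = StructureModel([toy_asu.chains[0].copy()])
        with pytest.raises(AnalysisError):
            superpose_rmsd(toy_asu, smaller)


class TestRmsf:
    def test_constant_trajectory_is_all_zero(self, toy_asu):
        frames = generate_ensemble(toy_asu, EnsembleParams(
            n_frames=5, breathing_amplitude=0.0, atomic_noise_sd=0.0,
            seed=0))
        assert np.allclose(rmsf(frames), 0.0)

    def test_single_frame_is_an_error(self, toy_asu):
        frames = generate_ensemble(toy_asu, EnsembleParams(n_frames=1,
                                                           seed=0))
        with pytest.raises(AnalysisError):
            rmsf(frames)

    def test_isotropic_noise_gives_sigma_root3(self, toy_asu):
        sigma, n = 0.25, 2000
        frames = generate_ensemble(toy_asu, EnsembleParams(
            n_frames=n, breathing_amplitude=0.0, atomic_noise_sd=sigma,
            cell_coupling=True, seed=5))
        values = rmsf(frames)   # no superposition: noise is about the mean
        expected = sigma * np.sqrt(3.0)
        se = expected / np.sqrt(2 * n)
        assert abs(values.mean() - expected) <= 4 * se

    def test_mobile_segment_ranks_first(self, toy_asu):
        profile = [1.0, 1.0, 1.0, 4.0, 1.0]
        frames = generate_ensemble(toy_asu, EnsembleParams(
            n_frames=250, breathing_amplitude=0.0, atomic_noise_sd=0.15,
            rmsf_profile=profile, seed=13))
        sup = superpose_frames(frames)
        per_res = rmsf(sup).reshape(5, 5)
        assert np.all(per_res.argmax(axis=1) == 3)


class TestEquilibration:
    def test_constant_series_starts_at_zero(self):
        assert detect_equilibration([1.0] * 50) == 0

    def test_ramp_then_flat_finds_the_knee(self):
        knee = 60
        series = np.concatenate([np.linspace(0.0, 2.0, knee),
                                 np.full(140, 2.0)])
        idx = detect_equilibration(series, slope_tol=1e-3)
        window = 0.25 * len(series)
        assert abs(idx - knee) <= window / 2

    def test_strictly_rising_series_has_no_plateau(self):
        with pytest.raises(AnalysisError):
            detect_equilibration(np.linspace(0, 5, 100), slope_tol=1e-3)

    def test_short_series_rejected(self):
        with pytest.raises(AnalysisError):
            detect_equilibration([1.0] * 10)


class TestRadiusSeries:
    def test_unperturbed_toy_equals_construction_radius(self, toy_asu,
                                                        toy_params):
        frames = generate_ensemble(toy_asu, EnsembleParams(
            n_frames=2, breathing_amplitude=0.0, atomic_noise_sd=0.0,
            seed=0))
        rs = radius_series(frames)
        np.testing.assert_allclose(rs, toy_params.inradius, rtol=1e-9)

    def test_breathing_cv_matches_injected_amplitude(self, toy_asu):
        n = 60
        frames = generate_ensemble(toy_asu, EnsembleParams(
            n_frames=n, breathing_amplitude=0.02, atomic_noise_sd=0.0,
            seed=19))
        rs = radius_series(frames)
        cv = rs.std(ddof=1) / rs.mean()
        se = 0.02 / np.sqrt(2 * (n - 1))
        assert abs(cv - 0.02) <= 3 * se

    def test_single_pentamer_frame_is_an_error(self, toy_capsid):
        from capsidkit.structure_io import TrajectoryFrame, UnitCell
        lone = toy_capsid.subset([c.id for c in toy_capsid.chains[:5]])
        lone.unit_cell = UnitCell(150, 150, 150)
        frame = TrajectoryFrame(0, lone, lone.unit_cell)
        with pytest.raises((StructureError, AnalysisError)):
            radius_series([frame])


class TestCompressibility:
    def test_constant_volumes_give_zero(self):
        res = compressibility([1e6] * 50, 300.0)
        assert res.chi_T == 0.0
        assert res.mean_volume == 1e6

    def test_variance_scaling_is_quadratic(self):
        rng = np.random.default_rng(23)
        v0 = 5.0e6
        dv = rng.normal(0, 2000.0, 400)
        dv -= dv.mean()          # same mean volume in both series
        a = compressibility(v0 + dv, 300.0).chi_T
        b = compressibility(v0 + 2 * dv, 300.0).chi_T
        assert b / a == pytest.approx(4.0, rel=1e-9)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(AnalysisError):
            compressibility([1.0, -1.0], 300.0)
        with pytest.raises(AnalysisError):
            compressibility([1.0, 2.0], 0.0)


class TestDgStats:
    def test_constant_series(self):
        st = ensemble_dg_stats([-7.5] * 20)
        assert st.sd == 0.0
        assert st.modal_bin_center == pytest.approx(-7.5)
        assert st.counts.sum() == 20

    def test_empty_series_is_an_error(self):
        with pytest.raises(AnalysisError):
            ensemble_dg_stats([])

    def test_gaussian_mixture_mean_matches_closed_form(self):
        rng = np.random.default_rng(29)
        n = 4000
        comp = rng.random(n) < 0.3
        x = np.where(comp, rng.normal(-400.0, 20.0, n),
                     rng.normal(-300.0, 20.0, n))
        st = ensemble_dg_stats(x)
        true_mean = 0.3 * -400.0 + 0.7 * -300.0
        true_sd = np.sqrt(20 ** 2 + 0.3 * 0.7 * 100 ** 2)
        assert abs(st.mean - true_mean) <= 3 * true_sd / np.sqrt(n)
        assert st.counts.sum() == n
        assert st.min <= st.modal_bin_center <= st.max

    def test_modal_bin_prefers_leftmost_on_ties(self):
        st = ensemble_dg_stats([0.0, 10.0], n_bins=2)
        assert st.modal_bin_center == pytest.approx(2.5)


class TestClassification:
    @pytest.mark.parametrize("ddg,threshold,expected", [
        (80.0, 100.0, "capsid"),        # marginal destabilisation
        (201.0, 100.0, "pentamer"),     # strong destabilisation
        (100.0, 100.0, "capsid"),       # tie is inclusive
        (-50.0, 100.0, "capsid"),
    ])
    def test_threshold_rule(self, ddg, threshold, expected):
        assert classify_variant(ddg, threshold) == expected

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            classify_variant(10.0, 0.0)
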