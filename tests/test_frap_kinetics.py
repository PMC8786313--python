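import math

import numpy as np
import pytest

from synapdyn import frap_kinetics as fk
from synapdyn import synthetic_data as sd
from synapdyn.curves import CurveEnsemble, CurveError, RecoveryCurve
from synapdyn.frap_kinetics import FRAPFitError
from synapdyn.synthetic_data import frap_model


def _noiseless(**kwargs):
    kwargs.setdefault("noise_sd", 0.0)
    bleach, controls, truth = sd.make_frap_series(**kwargs)
    return bleach[0], controls, truth


class TestBleachCorrect:
    def test_constant_controls_identity(self):
        target, controls, _ = _noiseless(k_b=0.0)
        corrected = fk.bleach_correct(target, controls)
        assert np.allclose(corrected.intensity, target.intensity)
        assert corrected.stage == "bleach_corrected"

    @pytest.mark.parametrize("k_b", [0.001, 0.002, 0.005, 0.01])
    def test_correction_removes_imaging_bleach(self, k_b):
        target, controls, _ = _noiseless(k_b=k_b)
        reference, _, _ = _noiseless(k_b=0.0)
        corrected = fk.bleach_correct(target, controls)
        assert np.max(np.abs(corrected.intensity - reference.intensity)) < 1e-9

    def test_mismatched_grids_rejected(self):
        target, _, _ = _noiseless()
        bad = RecoveryCurve(np.arange(5, dtype=float), np.ones(5))
        with pytest.raises(CurveError, match="grid"):
            fk.bleach_correct(target, [bad])

    def test_nonpositive_control_rejected(self):
        target, controls, _ = _noiseless()
        controls[0].intensity[3] = 0.0
        with pytest.raises(CurveError, match="non-positive"):
            fk.bleach_correct(target, controls)

    def test_no_controls_rejected(self):
        target, _, _ = _noiseless()
        with pytest.raises(CurveError, match="control"):
            fk.bleach_correct(target, [])


class TestNormalize:
    def test_matches_closed_form_recovery(self):
        target, controls, truth = _noiseless(
            w=(0.6, 0.4), tau=(20.0, 200.0), f_inf=0.7
        )
        norm = fk.normalize_recovery(fk.bleach_correct(target, controls), 10)
        post = norm.postbleach_mask
        expected = frap_model(norm.time[post], (0.6, 0.4), (20.0, 200.0), 0.7)
        assert np.allclose(norm.intensity[post], expected, atol=1e-12)

    def test_value_zero_at_t0(self):
        target, _, _ = _noiseless()
        norm = fk.normalize_recovery(target, 10)
        assert norm.value_at(0.0) == 0.0

    def test_full_recovery_reaches_one(self):
        t = np.arange(-3, 50, dtype=float)
        intensity = np.where(t < 0, 1.0, 1 - np.exp(-np.clip(t, 0, None) / 4))
        norm = fk.normalize_recovery(RecoveryCurve(t, intensity), 3)
        assert norm.intensity[-1] == pytest.approx(1.0, abs=1e-4)

    def test_flat_curve_has_no_bleach(self):
        t = np.arange(-3, 20, dtype=float)
        curve = RecoveryCurve(t, np.ones_like(t))
        with pytest.raises(CurveError, match="no bleach"):
            fk.normalize_recovery(curve, 3)

    def test_no_recovery_stays_zero(self):
        t = np.arange(-3, 20, dtype=float)
        intensity = np.where(t < 0, 1.0, 0.2)
        norm = fk.normalize_recovery(RecoveryCurve(t, intensity), 3)
        assert np.allclose(norm.intensity[norm.postbleach_mask], 0.0)

    def test_idempotence(self):
        target, controls, _ = _noiseless()
        once = fk.normalize_recovery(fk.bleach_correct(target, controls), 10)
        twice = fk.normalize_recovery(once, 10)
        assert np.allclose(once.intensity, twice.intensity, atol=1e-12)


class TestMeanCurve:
    def test_identical_members_zero_sem(self):
        t = np.arange(10, dtype=float)
        ens = CurveEnsemble(t, np.tile(np.sin(t / 3) + 2, (4, 1)))
        mean, sem = fk.mean_curve(ens)
        assert np.allclose(sem, 0.0)

    def test_two_member_mean(self):
        t = np.arange(4, dtype=float)
        a, b = np.array([1.0, 2, 3, 4]), np.array([3.0, 4, 5, 6])
        ens = CurveEnsemble(t, np.stack([a, b]))
        mean, _ = fk.mean_curve(ens)
        assert np.allclose(mean, (a + b) / 2)

    def test_single_member_rejected(self):
        with pytest.raises(CurveError, match=">= 2"):
            CurveEnsemble(np.arange(4, dtype=float), np.ones((1, 4)))

    def test_simulated_replicates_cover_truth(self):
        curves = []
        for s in range(20):
            bleach, controls, truth = sd.make_frap_series(noise_sd=0.02, seed=s)
            curves.append(fk.process_frap(bleach[0], controls, 10))
        ens = CurveEnsemble.from_curves(curves)
        mean, sem = fk.mean_curve(ens)
        post = ens.time >= 0
        expected = frap_model(ens.time[post], (0.6, 0.4), (20.0, 200.0), 0.7)
        covered = np.abs(mean[post] - expected) <= 2 * np.maximum(sem[post], 1e-12)
        assert covered.mean() >= 0.95


class TestFitRecovery:
    def test_noiseless_mono_exponential_exact(self):
        target, controls, _ = _noiseless(w=(1.0,), tau=(50.0,), f_inf=0.8)
        norm = fk.process_frap(target, controls, 10)
        fit = fk.fit_recovery(norm, 1, seed=0)
        assert abs(fit.tau[0] - 50.0) / 50.0 < 1e-3
        assert fit.f_inf == pytest.approx(0.8, rel=1e-3)

    def test_noiseless_bi_exponential_exact(self):
        target, controls, _ = _noiseless(w=(0.6, 0.4), tau=(20.0, 200.0), f_inf=0.7)
        norm = fk.process_frap(target, controls, 10)
        fit = fk.fit_recovery(norm, 2, seed=0)
        assert abs(fit.tau[0] - 20.0) / 20.0 < 0.01
        assert abs(fit.tau[1] - 200.0) / 200.0 < 0.01
        assert fit.weights[0] == pytest.approx(0.6, abs=0.01)

    def test_taus_sorted_ascending(self):
        target, controls, _ = _noiseless(w=(0.4, 0.6), tau=(150.0, 15.0), f_inf=0.7)
        norm = fk.process_frap(target, controls, 10)
        fit = fk.fit_recovery(norm, 2, seed=0)
        assert fit.tau[0] < fit.tau[1]

    def test_flat_zero_curve_rejected(self):
        t = np.arange(-5, 100, dtype=float)
        curve = RecoveryCurve(t, np.zeros_like(t), stage="normalized")
        with pytest.raises(FRAPFitError, match="no recovery"):
            fk.fit_recovery(curve, 1)

    def test_unnormalized_curve_rejected(self):
        target, _, _ = _noiseless()
        with pytest.raises(FRAPFitError, match="normalized"):
            fk.fit_recovery(target, 1)

    def test_too_few_points_rejected(self):
        t = np.arange(-2, 8, dtype=float)
        curve = RecoveryCurve(t, np.clip(t / 10, 0, None), stage="normalized")
        with pytest.raises(FRAPFitError, match="too few"):
            fk.fit_recovery(curve, 2)


class TestSelectModel:
    def test_ssr_nesting_never_increases(self):
        bleach, controls, _ = sd.make_frap_series(noise_sd=0.02, seed=7)
        norm = fk.process_frap(bleach[0], controls, 10)
        _, fits = fk.select_model(norm, seed=7)
        assert fits[2].ssr <= fits[1].ssr + 1e-12
        assert fits[3].ssr <= fits[2].ssr + 1e-12

    def test_parsimony_rule_prefers_fewer_components(self):
        # SSR(3) within 5% of SSR(2) must yield n=2
        bleach, controls, _ = sd.make_frap_series(
            postbleach_frames=300, noise_sd=0.02, seed=3
        )
        norm = fk.process_frap(bleach[0], controls, 10)
        chosen, fits = fk.select_model(norm, seed=3)
        if fits[3].ssr >= 0.95 * fits[2].ssr and fits[2].ssr < 0.95 * fits[1].ssr:
            assert chosen.n_components == 2

    def test_true_mono_selects_one(self):
        bleach, controls, _ = sd.make_frap_series(
            postbleach_frames=300, w=(1.0,), tau=(50.0,), f_inf=0.8,
            noise_sd=0.02, seed=11,
        )
        norm = fk.process_frap(bleach[0], controls, 10)
        chosen, _ = fk.select_model(norm, seed=11)
        assert chosen.n_components == 1

    def test_true_bi_selects_two(self):
        bleach, controls, _ = sd.make_frap_series(
            postbleach_frames=300, noise_sd=0.02, seed=5
        )
        norm = fk.process_frap(bleach[0], controls, 10)
        chosen, _ = fk.select_model(norm, seed=5)
        assert chosen.n_components == 2


class TestRecoveryAtTime:
    def test_closed_form_at_380s(self):
        target, controls, _ = _noiseless(w=(0.6, 0.4), tau=(20.0, 200.0), f_inf=0.7)
        norm = fk.process_frap(target, controls, 10)
        expected = 100 * 0.7 * (
            1 - 0.6 * math.exp(-380 / 20) - 0.4 * math.exp(-380 / 200)
        )
        assert fk.recovery_at_time(norm, 380.0) == pytest.approx(expected, rel=1e-9)

    def test_anchored_at_zero(self):
        target, controls, _ = _noiseless()
        norm = fk.process_frap(target, controls, 10)
        assert fk.recovery_at_time(norm, 0.0) == 0.0

    def test_fully_recovered_reads_100(self):
        t = np.arange(-3, 40, dtype=float)
        intensity = np.where(t < 0, 1.0, 1 - np.exp(-np.clip(t, 0, None) / 2))
        norm = fk.normalize_recovery(RecoveryCurve(t, intensity), 3)
        assert fk.recovery_at_time(norm, 39.0) == pytest.approx(100.0, abs=0.1)

    def test_beyond_range_rejected(self):
        target, controls, _ = _noiseless()
        norm = fk.process_frap(target, controls, 10)
        with pytest.raises(CurveError, match="no frame"):
            fk.recovery_at_time(norm, 10_000.0)
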