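"""Maximal force, enslaving recovery, variability, and trial exclusion."""

import numpy as np
import pytest

from polyhand import forces
from polyhand.errors import CoverageError, InsufficientDataError, LengthError
from polyhand.synthetic import ForceModelSpec, simulate_force_session

from conftest import make_force_recording, make_force_trial

RATE = 128.0


def constant_trial(instructed, level, values, n=2000, fingers=("T", "I")):
    force = np.tile(np.asarray(values, dtype=float), (n, 1))
    assert force.shape[1] == len(fingers)
    return make_force_trial(instructed, level, force)


class TestMaximalForce:
    def test_constant_and_two_trial_max(self):
        rec = make_force_recording(["T", "I"], [
            constant_trial("T", "MF", [10.0, 0.0]),
            constant_trial("T", "MF", [8.0, 0.0]),
            constant_trial("I", "MF", [0.0, 11.0]),
        ])
        mf = forces.maximal_force(rec)
        assert mf["T"] == pytest.approx(10.0)
        assert mf["I"] == pytest.approx(11.0)

    def test_single_sample_spike_suppressed_by_boxcar(self):
        trial = constant_trial("T", "MF", [10.0, 0.0])
        trial.force[900, 0] = 100.0
        rec = make_force_recording(["T", "I"], [trial,
                                                constant_trial("I", "MF", [0.0, 5.0])])
        mf = forces.maximal_force(rec)
        # oracle: explicit 250 ms boxcar then max
        width = int(round(0.25 * RATE))
        kernel = np.ones(width) / width
        oracle = np.convolve(trial.force[:, 0], kernel, mode="same").max()
        assert mf["T"] == pytest.approx(oracle)
        assert mf["T"] < 10.0 + 100.0 / width * 2  # nowhere near the spike

    def test_missing_finger_coverage_error(self):
        rec = make_force_recording(["T", "I"], [constant_trial("T", "MF", [10.0, 0.0])])
        with pytest.raises(CoverageError, match="I"):
            forces.maximal_force(rec)


class TestEnslavingMatrix:
    def test_direct_ratio_example(self):
        # F_I(T) = 2 N with MF_I = 10 N -> e_TI = 0.2
        rec = make_force_recording(["T", "I"], [
            constant_trial("T", "MF", [10.0, 2.0]),
            constant_trial("I", "MF", [0.0, 10.0]),
        ])
        mf = forces.maximal_force(rec)
        ens = forces.enslaving_matrix(rec, mf, level="MF")
        assert ens.values[0, 1] == pytest.approx(0.2)
        np.testing.assert_allclose(np.diag(ens.values), 1.0)

    def test_silent_uninstructed_fingers_zero_row(self):
        rec = make_force_recording(["T", "I"], [
            constant_trial("T", "MF", [10.0, 0.0]),
            constant_trial("I", "MF", [0.0, 10.0]),
        ])
        ens = forces.enslaving_matrix(rec, forces.maximal_force(rec), level="MF")
        assert ens.values[0, 1] == 0.0
        assert ens.values[1, 0] == 0.0

    def test_noiseless_generator_recovery_exact(self):
        spec = ForceModelSpec(noise_coeff=0.0, seed=0)
        session = simulate_force_session(spec)
        mf = forces.maximal_force(session)
        np.testing.assert_allclose(mf.mf, spec.mf, rtol=1e-12)
        for level in ("MF", "10", "20", "30"):
            ens = forces.enslaving_matrix(session, mf, level=level)
            np.testing.assert_allclose(ens.values, spec.coupling, atol=1e-12)

    def test_missing_level_coverage_error(self):
        rec = make_force_recording(["T", "I"], [
            constant_trial("T", "MF", [10.0, 0.0]),
            constant_trial("I", "MF", [0.0, 10.0]),
        ])
        with pytest.raises(CoverageError):
            forces.enslaving_matrix(rec, forces.maximal_force(rec), level="10")


class TestForceVariability:
    def test_constant_is_zero(self):
        trial = constant_trial("T", "10", [3.0, 0.0])
        assert forces.force_variability(trial, finger_index=0) == 0.0

    def test_white_noise_sd_recovered(self, rng):
        force = np.zeros((2000, 2))
        force[:, 0] = 10.0 + rng.standard_normal(2000)
        trial = make_force_trial("T", "10", force)
        assert forces.force_variability(trial, finger_index=0) == pytest.approx(1.0, rel=0.10)

    def test_linear_ramp_closed_form(self):
        n = 2000
        ramp = np.linspace(0, 15, n)
        trial = make_force_trial("T", "10", np.column_stack([ramp, np.zeros(n)]))
        lo, hi = forces.VARIABILITY_WINDOW
        # SD of an arithmetic sequence of m terms with step d: d * sqrt(m (m+1) / 12)
        m = hi - lo + 1
        step = 15.0 / (n - 1)
        closed_form = step * np.sqrt(m * (m + 1) / 12.0)
        assert forces.force_variability(trial, finger_index=0) == pytest.approx(closed_form)

    def test_translation_invariant_and_scale_linear(self, rng):
        force = np.zeros((2000, 1))
        force[:, 0] = rng.standard_normal(2000)
        base = forces.force_variability(make_force_trial("T", "10", force), 0)
        shifted = forces.force_variability(make_force_trial("T", "10", force + 5.0), 0)
        scaled = forces.force_variability(make_force_trial("T", "10", force * 3.0), 0)
        assert shifted == pytest.approx(base)
        assert scaled == pytest.approx(3.0 * base)

    def test_short_trial_length_error(self):
        trial = constant_trial("T", "10", [1.0, 0.0], n=1000)
        with pytest.raises(LengthError):
            forces.force_variability(trial, finger_index=0)


class TestExclusion:
    def test_identical_trials_keep_all(self):
        trials = [constant_trial("T", "10", [3.0, 0.0]) for _ in range(3)]
        kept, excluded = forces.exclude_unstable_trials(trials, ["T", "I"])
        assert len(kept) == 3 and excluded == []

    def test_single_outlier_excluded(self, rng):
        quiet = []
        for _ in range(3):
            f = np.zeros((2000, 2))
            f[:, 0] = 5.0 + 0.1 * rng.standard_normal(2000)
            quiet.append(make_force_trial("T", "10", f))
        wild = np.zeros((2000, 2))
        wild[:, 0] = 5.0 + 3.0 * rng.standard_normal(2000)
        trials = quiet + [make_force_trial("T", "10", wild)]
        kept, excluded = forces.exclude_unstable_trials(trials, ["T", "I"])
        assert len(excluded) == 1 and excluded[0] is trials[-1]

    def test_matches_independent_reimplementation(self, rng):
        fingers = ["T", "I"]
        trials = []
        for finger in fingers:
            for level in ("10", "20"):
                for _ in range(4):
                    f = np.zeros((2000, 2))
                    fi = fingers.index(finger)
                    f[:, fi] = 5.0 + rng.uniform(0.05, 2.0) * rng.standard_normal(2000)
                    trials.append(make_force_trial(finger, level, f))
        kept, excluded = forces.exclude_unstable_trials(trials, fingers)

        # brute-force re-implementation of the 3x-cell-median rule
        lo, hi = forces.VARIABILITY_WINDOW
        sds = [np.std(t.force[lo:hi + 1, fingers.index(t.instructed_finger)], ddof=1)
               for t in trials]
        expect_excluded = set()
        for key in {(t.instructed_finger, t.level) for t in trials}:
            idx = [i for i, t in enumerate(trials)
                   if (t.instructed_finger, t.level) == key]
            med = np.median([sds[i] for i in idx])
            expect_excluded |= {i for i in idx if sds[i] > 3 * med}
        assert {id(t) for t in excluded} == {id(trials[i]) for i in expect_excluded}


class TestEnslavingCorrelation:
    def _matrix(self, values, fingers):
        return forces.EnslavingMatrix(fingers=list(fingers), values=np.asarray(values))

    def test_identity_and_affine_invariance(self, rng, five_fingers):
        a = rng.uniform(0.0, 0.5, size=(5, 5))
        np.fill_diagonal(a, 1.0)
        ma = self._matrix(a, five_fingers)
        assert forces.enslaving_correlation(ma, ma, five_fingers) == pytest.approx(1.0)
        b = 2.0 * a + 0.1
        np.fill_diagonal(b, 1.0)
        mb = self._matrix(b, five_fingers)
        assert forces.enslaving_correlation(ma, mb, five_fingers) == pytest.approx(1.0)

    def test_matches_flattened_offdiagonal_correlation(self, rng, five_fingers):
        a = rng.uniform(size=(5, 5))
        b = rng.uniform(size=(5, 5))
        ma, mb = self._matrix(a, five_fingers), self._matrix(b, five_fingers)
        r = forces.enslaving_correlation(ma, mb, five_fingers)
        mask = ~np.eye(5, dtype=bool)
        assert r == pytest.approx(np.corrcoef(a[mask], b[mask])[0, 1])
        assert len(ma.off_diagonal(five_fingers)) == 20  # N = 20 ordered pairs

    def test_too_few_pairs(self, rng):
        a = self._matrix(rng.uniform(size=(5, 5)), ["T", "I", "M", "R", "L"])
        with pytest.raises(InsufficientDataError):
            forces.enslaving_correlation(a, a, ["T"])
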