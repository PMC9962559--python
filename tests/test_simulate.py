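"""Synthetic CPMG / PFGSE generator behavior and invariants."""

import json

import numpy as np
import pytest

from oxirelax import (AcquisitionConfig, ComponentSpec, OxidationClass,
                      PfgseConfig, classify_oxidation, generate_dataset,
                      simulate_cpmg_curve, simulate_pfgse,
                      sample_oxidation_state)
from oxirelax.errors import InvalidInputError
from oxirelax.simulate import DEFAULT_STATE_PARAMS, write_dataset


class TestCpmgCurve:
    def test_monoexponential_analytic_values(self, small_acq):
        curve = simulate_cpmg_curve([ComponentSpec(1.0, 0.1)], small_acq, seed=0)
        # extrapolating to t=0 gives the total amplitude; at t = T2 the
        # noiseless decay equals exp(-1)
        assert curve.amplitudes[0] == pytest.approx(np.exp(-curve.times[0] / 0.1))
        val = np.interp(0.1, curve.times, curve.amplitudes)
        assert val == pytest.approx(np.exp(-1.0), rel=1e-3)

    def test_biexponential_bounded_by_pure_decays(self, small_acq):
        comps = [ComponentSpec(0.5, 0.05), ComponentSpec(0.5, 0.2)]
        curve = simulate_cpmg_curve(comps, small_acq, seed=0)
        t = curve.times
        fast = np.exp(-t / 0.05)
        slow = np.exp(-t / 0.2)
        assert np.all(curve.amplitudes >= fast - 1e-12)
        assert np.all(curve.amplitudes <= slow + 1e-12)

    def test_noiseless_curve_strictly_decreasing_and_positive(self, small_acq):
        comps = [ComponentSpec(0.4, 0.05), ComponentSpec(0.6, 0.15)]
        curve = simulate_cpmg_curve(comps, small_acq, seed=3)
        assert np.all(curve.amplitudes > 0)
        assert np.all(np.diff(curve.amplitudes) < 0)
        assert curve.amplitudes[0] <= 1.0  # first echo below total amplitude

    def test_scan_averaging_shrinks_noise(self):
        sigma, reps = 0.05, 200
        comps = [ComponentSpec(1.0, 0.1)]
        t2_model = lambda acq, s: simulate_cpmg_curve(comps, acq, seed=s)
        acq1 = AcquisitionConfig(n_echoes=64, noise_sigma=sigma, n_scans=1)
        acq25 = AcquisitionConfig(n_echoes=64, noise_sigma=sigma, n_scans=25)
        clean = simulate_cpmg_curve(comps, AcquisitionConfig(n_echoes=64, noise_sigma=0)).amplitudes
        sd1 = np.std([t2_model(acq1, s).amplitudes - clean for s in range(reps)])
        sd25 = np.std([t2_model(acq25, s).amplitudes - clean for s in range(reps)])
        assert sd1 / sd25 == pytest.approx(5.0, rel=0.15)

    def test_deterministic_given_seed(self):
        acq = AcquisitionConfig(n_echoes=128, noise_sigma=0.02)
        a = simulate_cpmg_curve([ComponentSpec(1, 0.1)], acq, seed=42).amplitudes
        b = simulate_cpmg_curve([ComponentSpec(1, 0.1)], acq, seed=42).amplitudes
        np.testing.assert_array_equal(a, b)

    def test_invalid_inputs(self, small_acq):
        with pytest.raises(InvalidInputError):
            simulate_cpmg_curve([], small_acq)
        with pytest.raises(InvalidInputError):
            AcquisitionConfig(tau=-1e-4)
        with pytest.raises(InvalidInputError):
            ComponentSpec(1.0, t2=0.0)


class TestPfgse:
    def test_zero_gradient_gives_unit_signal(self):
        series = simulate_pfgse(3e-11, PfgseConfig(), noise_sigma=0.0)
        assert series[0, 0] == 0.0
        assert series[0, 1] == 1.0

    def test_log_attenuation_is_minus_b_d(self):
        d = 3e-11
        series = simulate_pfgse(d, PfgseConfig(), noise_sigma=0.0)
        b, s = series[:, 0], series[:, 1]
        np.testing.assert_allclose(np.log(s), -b * d, atol=1e-12)

    def test_doubling_d_doubles_log_attenuation(self):
        cfg = PfgseConfig()
        s1 = simulate_pfgse(2e-11, cfg, noise_sigma=0.0)[:, 1]
        s2 = simulate_pfgse(4e-11, cfg, noise_sigma=0.0)[:, 1]
        np.testing.assert_allclose(np.log(s2), 2 * np.log(s1), atol=1e-12)

    def test_invalid_d(self):
        with pytest.raises(InvalidInputError):
            simulate_pfgse(0.0, PfgseConfig())


class TestOxidationState:
    @pytest.mark.parametrize("cls,check", [
        (OxidationClass.BAD, lambda chem: chem.d <= 0.02e-9 and chem.pv >= 50),
        (OxidationClass.GOOD, lambda chem: chem.d > 0.03e-9 and chem.pv < 20),
    ])
    def test_chemistry_lands_in_class_bin(self, cls, check):
        for seed in range(20):
            _, chem = sample_oxidation_state(cls, DEFAULT_STATE_PARAMS[cls], seed=seed)
            assert check(chem)

    def test_zero_jitter_returns_exact_means(self):
        import dataclasses
        params = dataclasses.replace(DEFAULT_STATE_PARAMS[OxidationClass.FAIR],
                                     component_jitter=0.0)
        comps, _ = sample_oxidation_state(OxidationClass.FAIR, params, seed=5)
        assert comps == params.component_means

    def test_mean_t2_strictly_ordered_across_classes(self):
        def mean_t2(cls):
            comps = DEFAULT_STATE_PARAMS[cls].component_means
            amps = np.array([c.amplitude for c in comps])
            t2s = np.array([c.t2 for c in comps])
            return np.sum(amps * t2s) / amps.sum()
        assert mean_t2(OxidationClass.GOOD) > mean_t2(OxidationClass.FAIR) \
            > mean_t2(OxidationClass.BAD)

    def test_bad_has_extra_short_t2_component(self):
        t2s_bad = sorted(c.t2 for c in DEFAULT_STATE_PARAMS[OxidationClass.BAD].component_means)
        t2s_good = [c.t2 for c in DEFAULT_STATE_PARAMS[OxidationClass.GOOD].component_means]
        assert len(t2s_bad) == len(t2s_good) + 1
        assert t2s_bad[0] < 0.5 * min(t2s_good)

    def test_boundary_blur_crowds_edges_without_crossing_bins(self):
        import dataclasses
        params = dataclasses.replace(DEFAULT_STATE_PARAMS[OxidationClass.FAIR],
                                     boundary_blur=0.1)
        lo, hi = params.pv_range
        for seed in range(30):
            _, chem = sample_oxidation_state(OxidationClass.FAIR, params, seed=seed)
            assert classify_oxidation(chem.d, chem.pv) == OxidationClass.FAIR
            # pv lands in the outer 10% of its range, near a threshold
            assert chem.pv <= lo + 0.1 * (hi - lo) or chem.pv >= hi - 0.1 * (hi - lo)

    def test_class_mismatch_raises(self):
        with pytest.raises(InvalidInputError):
            sample_oxidation_state(OxidationClass.GOOD,
                                   DEFAULT_STATE_PARAMS[OxidationClass.BAD], seed=0)


class TestGenerateDataset:
    def test_reference_mix_reproduces_supports(self, small_acq):
        recs = generate_dataset(390, (126, 77, 187), small_acq, seed=1)
        counts = {c: 0 for c in OxidationClass}
        for r in recs:
            counts[r.true_class] += 1
        assert counts[OxidationClass.GOOD] == 126
        assert counts[OxidationClass.FAIR] == 77
        assert counts[OxidationClass.BAD] == 187

    def test_minimal_dataset_one_per_class(self, small_acq):
        recs = generate_dataset(3, (1 / 3, 1 / 3, 1 / 3), small_acq, seed=1)
        assert sorted(r.true_class for r in recs) == list(OxidationClass)

    def test_labels_rederive_from_chemistry(self, tiny_records):
        for r in tiny_records:
            assert classify_oxidation(r.chem.d, r.chem.pv) == r.true_class

    def test_same_seed_byte_identical_manifest(self, small_acq, tmp_path):
        texts = []
        for sub in ("a", "b"):
            recs = generate_dataset(9, (1 / 3, 1 / 3, 1 / 3), small_acq, seed=77)
            path = write_dataset(recs, tmp_path / sub)
            texts.append(path.read_text())
        assert texts[0] == texts[1]
        json.loads(texts[0])  # well-formed JSON

    def test_mean_bad_curve_below_mean_good_curve(self):
        acq = AcquisitionConfig(n_echoes=512, noise_sigma=0.0)
        def mean_curve(cls):
            curves = []
            for seed in range(12):
                comps, _ = sample_oxidation_state(cls, DEFAULT_STATE_PARAMS[cls], seed=seed)
                curves.append(simulate_cpmg_curve(comps, acq).amplitudes)
            return np.mean(curves, axis=0)
        good, bad = mean_curve(OxidationClass.GOOD), mean_curve(OxidationClass.BAD)
        t = acq.times
        late = t > 10 * t[0]
        assert np.all(bad[late] < good[late])

    def test_too_small_n_raises(self, small_acq):
        with pytest.raises(InvalidInputError):
            generate_dataset(2, (1 / 3, 1 / 3, 1 / 3), small_acq, seed=0)
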