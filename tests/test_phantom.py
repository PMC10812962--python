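"""Phantom generator: geometry, determinism, signal model, domain shift."""

import dataclasses

import numpy as np
import pytest

import qmapsynth as q
from qmapsynth.phantom import CARTILAGE_COMPARTMENTS, make_labels


class TestLabels:
    def test_every_voxel_has_exactly_one_label(self, small_phantom):
        lab = small_phantom.labels.label_volume
        assert set(np.unique(lab)) <= set(q.LABEL_TABLE.values())

    def test_cartilage_mask_is_union_of_six_compartments(self, small_phantom):
        labels = small_phantom.labels
        total = sum(int(labels.mask(c).sum()) for c in CARTILAGE_COMPARTMENTS)
        assert int(labels.cartilage_mask.sum()) == total

    def test_compartments_disjoint_and_nonempty(self, small_phantom):
        labels = small_phantom.labels
        for c in CARTILAGE_COMPARTMENTS:
            assert labels.mask(c).any()
        # disjoint by construction of a single integer volume
        assert labels.label_volume.ndim == 3

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            q.PhantomSpec(matrix_size=(2, 16, 16))

    def test_unknown_label_rejected(self, small_phantom):
        with pytest.raises(KeyError):
            small_phantom.labels.mask("SYNOVIUM")


class TestGeneratePhantom:
    def test_deterministic_for_fixed_seed_and_id(self, small_spec):
        a = q.generate_phantom(small_spec, "S001")
        b = q.generate_phantom(small_spec, "S001")
        assert np.array_equal(a.t1rho_truth.values_ms, b.t1rho_truth.values_ms)
        assert np.array_equal(a.t2_truth.values_ms, b.t2_truth.values_ms)
        assert np.array_equal(a.s0, b.s0)

    def test_different_subjects_differ(self, small_spec):
        a = q.generate_phantom(small_spec, "S001")
        b = q.generate_phantom(small_spec, "S002")
        assert not np.array_equal(a.t1rho_truth.values_ms, b.t1rho_truth.values_ms)

    def test_t1rho_exceeds_t2_in_cartilage_on_average(self, small_phantom):
        cart = small_phantom.labels.cartilage_mask
        assert small_phantom.t1rho_truth.values_ms[cart].mean() > \
            small_phantom.t2_truth.values_ms[cart].mean()

    def test_lesion_free_phantom_is_exact_affine_of_t2(self):
        """Without lesions T1rho is exactly the stated compartment-wise
        affine function of T2 (slope = spread ratio, plus the systematic
        compartment offset), i.e. no voxel exceeds the smooth field +
        jitter construction."""
        spec = q.PhantomSpec(matrix_size=(4, 48, 48), seed=3, lesion_rate=0.0)
        ph = q.generate_phantom(spec, "S001")
        p = spec.tissue_params["cartilage"]
        slope = p.t1rho_spread_ms / p.t2_spread_ms
        for i, c in enumerate(CARTILAGE_COMPARTMENTS):
            m = ph.labels.mask(c)
            expected = p.t1rho_ms + spec.compartment_t1rho_offset_ms[i] \
                + slope * (ph.t2_truth.values_ms[m] - p.t2_ms)
            np.testing.assert_allclose(ph.t1rho_truth.values_ms[m], expected,
                                       atol=1e-9)

    def test_lesions_break_the_affine_coupling(self):
        spec = q.PhantomSpec(matrix_size=(4, 48, 48), seed=3, lesion_rate=8.0)
        ph = q.generate_phantom(spec, "S001")
        p = spec.tissue_params["cartilage"]
        slope = p.t1rho_spread_ms / p.t2_spread_ms
        deviations = []
        for i, c in enumerate(CARTILAGE_COMPARTMENTS):
            m = ph.labels.mask(c)
            affine = p.t1rho_ms + spec.compartment_t1rho_offset_ms[i] \
                + slope * (ph.t2_truth.values_ms[m] - p.t2_ms)
            deviations.append((ph.t1rho_truth.values_ms[m] - affine).max())
        assert max(deviations) > 1.0

    def test_sampled_cartilage_mean_within_3_se(self):
        """Empirical mean T1rho over cartilage voxels from many subjects
        stays within 3 SE of the spec mean, where the SE follows from the
        generator's sampling model (between-subject compartment baselines
        dominate)."""
        spec = q.PhantomSpec(matrix_size=(2, 48, 48), n_subjects=12, seed=9,
                             lesion_rate=0.0)
        p = spec.tissue_params["cartilage"]
        slope = p.t1rho_spread_ms / p.t2_spread_ms
        cluster_means = []
        for i in range(12):
            ph = q.generate_phantom(spec, f"S{i:03d}")
            for j, c in enumerate(CARTILAGE_COMPARTMENTS):
                m = ph.labels.mask(c)
                # remove the known systematic compartment offset so the
                # clusters share one mean
                cluster_means.append(ph.t1rho_truth.values_ms[m].mean()
                                     - spec.compartment_t1rho_offset_ms[j])
        k = len(cluster_means)
        se = slope * p.t2_spread_ms / np.sqrt(k)
        assert abs(np.mean(cluster_means) - p.t1rho_ms) < 3 * se


class TestSimulateEchoes:
    def test_zero_time_echo_equals_s0(self, flat_truth, acq):
        es = q.simulate_echoes(flat_truth, acq, "T1rho", noise_sigma=0.0)
        np.testing.assert_array_equal(es.data[0], flat_truth.s0)

    def test_analytic_decay_at_one_time_constant(self, flat_truth):
        acq = q.AcquisitionSpec(tsl_times_ms=(0.0, 40.0), te_times_ms=(0.0, 30.0))
        es = q.simulate_echoes(flat_truth, acq, "T1rho", noise_sigma=0.0)
        inside = flat_truth.s0 > 0
        ratio = es.data[1][inside] / es.data[0][inside]
        np.testing.assert_allclose(ratio, np.exp(-1.0), rtol=1e-12)

    def test_noise_is_seed_deterministic(self, small_phantom, acq):
        a = q.simulate_echoes(small_phantom, acq, "T2", noise_sigma=0.02, seed=5)
        b = q.simulate_echoes(small_phantom, acq, "T2", noise_sigma=0.02, seed=5)
        c = q.simulate_echoes(small_phantom, acq, "T2", noise_sigma=0.02, seed=6)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_noiseless_decay_strictly_monotonic(self, small_phantom, acq):
        es = q.simulate_echoes(small_phantom, acq, "T1rho", noise_sigma=0.0)
        tissue = small_phantom.s0 > 0
        diffs = np.diff(es.data, axis=0)
        assert (diffs[:, tissue] < 0).all()

    def test_noiseless_signal_positive_where_s0_positive(self, small_phantom, acq):
        es = q.simulate_echoes(small_phantom, acq, "T2", noise_sigma=0.0)
        tissue = small_phantom.s0 > 0
        assert (es.data[:, tissue] > 0).all()

    def test_bad_kind_rejected(self, small_phantom, acq):
        with pytest.raises(ValueError, match="kind"):
            q.simulate_echoes(small_phantom, acq, "T1", noise_sigma=0.0)


class TestDomainShift:
    def test_identity_shift_returns_input(self, small_phantom, acq):
        es = q.simulate_echoes(small_phantom, acq, "T2", noise_sigma=0.01, seed=1)
        shift = q.DomainShiftSpec(bias_field_amplitude=0.0, snr_scale=1.0,
                                  global_offset_ms=0.0)
        out = q.apply_domain_shift(es, shift)
        np.testing.assert_array_equal(out.data, es.data)

    def test_bias_field_shared_across_echoes(self, small_phantom, acq):
        es = q.simulate_echoes(small_phantom, acq, "T2", noise_sigma=0.0)
        shift = q.DomainShiftSpec(bias_field_amplitude=0.2, snr_scale=1.0, seed=3)
        out = q.apply_domain_shift(es, shift)
        tissue = small_phantom.s0 > 0
        ratios = out.data[:, tissue] / es.data[:, tissue]
        for e in range(1, ratios.shape[0]):
            np.testing.assert_allclose(ratios[e], ratios[0], rtol=1e-12)

    def test_bias_field_cancels_in_fit(self, small_phantom, acq):
        """A multiplicative sensitivity field changes S0 only: the fitted
        relaxation time of a noiseless biased series equals the truth."""
        es = q.simulate_echoes(small_phantom, acq, "T1rho", noise_sigma=0.0)
        shift = q.DomainShiftSpec(bias_field_amplitude=0.15, snr_scale=1.0, seed=3)
        out = q.apply_domain_shift(es, shift)
        cart = small_phantom.labels.cartilage_mask
        fit = q.fit_monoexponential(out, mask=cart)
        np.testing.assert_allclose(
            fit.map.values_ms[cart],
            small_phantom.t1rho_truth.values_ms[cart],
            rtol=1e-6,
        )

    def test_global_offset_shifts_recovered_time(self, small_phantom, acq):
        es = q.simulate_echoes(small_phantom, acq, "T2", noise_sigma=0.0)
        shift = q.DomainShiftSpec(bias_field_amplitude=0.0, snr_scale=1.0,
                                  global_offset_ms=3.0)
        out = q.apply_domain_shift(es, shift, truth_map=small_phantom.t2_truth)
        cart = small_phantom.labels.cartilage_mask
        fit = q.fit_monoexponential(out, mask=cart)
        np.testing.assert_allclose(
            fit.map.values_ms[cart],
            small_phantom.t2_truth.values_ms[cart] + 3.0,
            rtol=1e-6,
        )

    def test_offset_requires_truth_map(self, small_phantom, acq):
        es = q.simulate_echoes(small_phantom, acq, "T2", noise_sigma=0.0)
        shift = q.DomainShiftSpec(global_offset_ms=2.0)
        with pytest.raises(ValueError, match="truth map"):
            q.apply_domain_shift(es, shift)

    def test_shift_deterministic_under_seed(self, small_phantom, acq):
        es = q.simulate_echoes(small_phantom, acq, "T2", noise_sigma=0.01, seed=1)
        shift = q.DomainShiftSpec(bias_field_amplitude=0.1, snr_scale=2.0, seed=9)
        a = q.apply_domain_shift(es, shift)
        b = q.apply_domain_shift(es, shift)
        assert np.array_equal(a.data, b.data)


class TestCohort:
    def test_cohort_size_and_unique_ids(self):
        spec = q.PhantomSpec(matrix_size=(2, 32, 32), n_subjects=5, seed=1)
        cohort = q.make_cohort(spec)
        ids = [s.truth.subject_id for s in cohort]
        assert len(cohort) == 5 and len(set(ids)) == 5

    def test_same_spec_regenerates_identical_cohort(self):
        spec = q.PhantomSpec(matrix_size=(2, 32, 32), n_subjects=2, seed=1)
        a = q.make_cohort(spec)
        b = q.make_cohort(spec)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.truth.t1rho_truth.values_ms,
                                  sb.truth.t1rho_truth.values_ms)
            assert np.array_equal(sa.echoes_t2.data, sb.echoes_t2.data)

    def test_duplicate_ids_rejected(self):
        spec = q.PhantomSpec(matrix_size=(2, 32, 32), n_subjects=2, seed=1)
        with pytest.raises(ValueError, match="duplicate"):
            q.make_cohort(spec, subject_ids=["A", "A"])

    def test_cohort_roundtrip_through_config_serialization(self, tmp_path):
        spec = q.PhantomSpec(matrix_size=(2, 32, 32), n_subjects=2, seed=12)
        cfg = q.RunConfig(phantom=spec)
        path = q.save_config(cfg, tmp_path / "cfg.yaml")
        cfg2 = q.load_config(path)
        assert cfg2.phantom == spec
        a = q.make_cohort(spec)
        b = q.make_cohort(cfg2.phantom)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.truth.t2_truth.values_ms,
                                  sb.truth.t2_truth.values_ms)
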