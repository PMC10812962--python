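"""Similarity metrics, agreement statistics and cohort reports."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.ndimage import gaussian_filter

import qmapsynth as q
from qmapsynth.evaluation import (
    bland_altman,
    compartment_means,
    evaluate_cohort,
    nmse,
    pearson_corr,
    psnr,
    quantification_error,
    ssim_volume,
)


class TestNMSE:
    def test_zero_iff_equal(self):
        x = np.random.default_rng(0).random((2, 4, 4))
        assert nmse(x, x) == 0.0

    def test_hand_computed_two_voxel_example(self):
        truth = np.array([3.0, 4.0]).reshape(1, 1, 2)
        pred = np.array([4.0, 4.0]).reshape(1, 1, 2)
        assert nmse(pred, truth) == pytest.approx(4.0)

    def test_matches_brute_force_on_random_volumes(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            t = rng.random((4, 16, 16)) * 100
            p = t + rng.normal(0, 5, t.shape)
            m = rng.random(t.shape) > 0.5
            expected = 100.0 * np.sum((p[m] - t[m]) ** 2) / np.sum(t[m] ** 2)
            assert nmse(p, t, m) == pytest.approx(expected, abs=1e-9)

    def test_all_zero_truth_returns_nan_sentinel(self):
        assert np.isnan(nmse(np.ones((1, 2, 2)), np.zeros((1, 2, 2))))

    def test_rms_variant_is_sqrt_of_ratio(self):
        rng = np.random.default_rng(2)
        t = rng.random((2, 8, 8)) * 50
        p = t + rng.normal(0, 2, t.shape)
        assert nmse(p, t, rms=True) == pytest.approx(
            100.0 * np.sqrt(nmse(p, t) / 100.0))


class TestPSNR:
    def test_zero_db_when_mse_equals_range_squared(self):
        truth = np.zeros((1, 2, 2))
        pred = np.full((1, 2, 2), 150.0)
        assert psnr(pred, truth) == pytest.approx(0.0)

    def test_quartering_mse_adds_6dB(self):
        truth = np.zeros((1, 4, 4))
        pred = np.full((1, 4, 4), 8.0)
        assert psnr(pred / 2, truth) - psnr(pred, truth) == pytest.approx(
            10 * np.log10(4), abs=1e-9)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        t = rng.random((2, 8, 8)) * 100
        p = t + rng.normal(0, 3, t.shape)
        m = rng.random(t.shape) > 0.3
        expected = 10 * np.log10(150.0**2 / np.mean((p[m] - t[m]) ** 2))
        assert psnr(p, t, m) == pytest.approx(expected, abs=1e-9)

    def test_identical_images_give_inf_sentinel(self):
        x = np.ones((1, 2, 2))
        assert np.isinf(psnr(x, x))


class TestSSIM:
    def test_identical_volumes_score_one(self):
        x = np.random.default_rng(0).random((2, 16, 16)) * 150
        assert ssim_volume(x, x) == pytest.approx(1.0)

    def test_large_constant_shift_penalized(self):
        x = np.random.default_rng(1).random((2, 16, 16)) * 100
        assert ssim_volume(x + 50.0, x) < 0.9

    def test_matches_independent_windowed_formula(self):
        """Cross-implementation oracle: direct Gaussian-window SSIM
        recomputation (local moments via gaussian_filter, interior crop)."""
        def oracle_2d(truth, pred, data_range=150.0):
            C1, C2 = (0.01 * data_range) ** 2, (0.03 * data_range) ** 2
            f = lambda a: gaussian_filter(a, 1.5, truncate=3.5)
            ux, uy = f(truth), f(pred)
            vx = f(truth * truth) - ux * ux
            vy = f(pred * pred) - uy * uy
            cxy = f(truth * pred) - ux * uy
            S = ((2 * ux * uy + C1) * (2 * cxy + C2)) / (
                (ux**2 + uy**2 + C1) * (vx + vy + C2))
            r = int(3.5 * 1.5 + 0.5)
            return S[r:-r, r:-r].mean()

        rng = np.random.default_rng(4)
        t = rng.random((3, 24, 24)) * 150
        p = np.clip(t + rng.normal(0, 10, t.shape), 0, 150)
        expected = np.mean([oracle_2d(t[k], p[k]) for k in range(3)])
        assert ssim_volume(p, t) == pytest.approx(expected, abs=1e-6)


@st.composite
def _paired_volumes(draw):
    shape = (2, 6, 6)
    finite = st.floats(1.0, 140.0, allow_nan=False)
    t = draw(hnp.arrays(np.float64, shape, elements=finite))
    p = draw(hnp.arrays(np.float64, shape, elements=st.floats(0.0, 150.0)))
    return p, t


class TestMetricProperties:
    """Invariants that must hold for any admissible volume pair."""

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(_paired_volumes())
    def test_nmse_nonnegative_and_zero_only_for_equality(self, pair):
        p, t = pair
        v = nmse(p, t)
        assert v >= 0.0
        assert nmse(t, t) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(_paired_volumes(), st.floats(-20.0, 20.0))
    def test_bland_altman_translation_equivariance(self, pair, c):
        p, t = pair
        tm = t.mean(axis=(1, 2))
        pm = p.mean(axis=(1, 2))
        a = bland_altman(tm, pm)
        b = bland_altman(tm, pm + c)
        assert b.bias == pytest.approx(a.bias + c, abs=1e-9)
        assert (b.loa[1] - b.loa[0]) == pytest.approx(a.loa[1] - a.loa[0], abs=1e-9)


class TestPearson:
    def test_affine_gives_unit_correlation(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        r, dof, p = pearson_corr(2 * t + 1, t)
        assert r == pytest.approx(1.0)
        assert dof == 2

    def test_negation_gives_minus_one(self):
        t = np.array([1.0, 2.0, 5.0])
        r, _, _ = pearson_corr(-t, t)
        assert r == pytest.approx(-1.0)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(5)
        t = rng.normal(size=200)
        p = 0.6 * t + rng.normal(size=200)
        r, dof, _ = pearson_corr(p, t)
        expected = np.sum((p - p.mean()) * (t - t.mean())) / np.sqrt(
            np.sum((p - p.mean()) ** 2) * np.sum((t - t.mean()) ** 2))
        assert r == pytest.approx(expected, abs=1e-12)
        assert dof == 198

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_corr(np.ones(5), np.arange(5.0))


class TestCompartmentMeans:
    def test_constant_map(self, small_phantom):
        means = compartment_means(np.full(small_phantom.s0.shape, 7.0),
                                  small_phantom.labels)
        assert set(means) == set(q.CARTILAGE_COMPARTMENTS)
        assert all(v == pytest.approx(7.0) for v in means.values())

    def test_hand_built_two_compartment_toy(self):
        lab = np.zeros((1, 1, 3), dtype=np.int16)
        lab[0, 0] = [1, 1, 3]  # MF, MF, MT
        labels = q.CompartmentLabels(lab)
        vol = np.array([[[10.0, 20.0, 30.0]]])
        means = compartment_means(vol, labels, compartments=("MF", "MT"))
        assert means == {"MF": pytest.approx(15.0), "MT": pytest.approx(30.0)}

    def test_count_weighted_means_conserve_cartilage_sum(self, small_phantom):
        vol = small_phantom.t1rho_truth.values_ms
        labels = small_phantom.labels
        means = compartment_means(vol, labels)
        total = sum(means[c] * labels.mask(c).sum() for c in means)
        assert total == pytest.approx(vol[labels.cartilage_mask].sum(), rel=1e-12)


class TestBlandAltman:
    def test_perfect_agreement(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba.bias == 0.0 and ba.loa == (0.0, 0.0)

    def test_hand_computed_two_pair_example(self):
        """d = (+2, -2): bias 0, sample SD 2.828, LoA half-width 5.543."""
        ba = bland_altman([10.0, 20.0], [12.0, 18.0])
        assert ba.bias == pytest.approx(0.0)
        assert ba.sd == pytest.approx(2.8284, abs=1e-4)
        assert ba.loa[1] == pytest.approx(5.543, abs=1e-3)
        assert ba.loa[0] == pytest.approx(-5.543, abs=1e-3)

    def test_translation_shifts_bias_not_width(self):
        rng = np.random.default_rng(6)
        t = rng.normal(40, 3, 20)
        p = t + rng.normal(0, 1, 20)
        a = bland_altman(t, p)
        b = bland_altman(t, p + 5.0)
        assert b.bias == pytest.approx(a.bias + 5.0)
        assert (b.loa[1] - b.loa[0]) == pytest.approx(a.loa[1] - a.loa[0])

    def test_loa_contains_bias_and_table_emitted(self):
        ba = bland_altman([30.0, 40.0, 50.0], [31.0, 39.0, 52.0])
        assert ba.loa[0] <= ba.bias <= ba.loa[1]
        assert list(ba.table.columns) == ["mean", "difference"]
        assert len(ba.table) == 3

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestQuantificationError:
    def test_perfect_prediction(self, small_phantom):
        vol = small_phantom.t1rho_truth.values_ms
        value, ok = quantification_error(vol, vol, small_phantom.labels)
        assert value == 0.0 and ok

    def test_five_percent_inflation_flagged_ok(self, small_phantom):
        vol = small_phantom.t1rho_truth.values_ms
        value, ok = quantification_error(1.05 * vol, vol, small_phantom.labels)
        assert value == pytest.approx(5.0, rel=1e-9)
        assert ok

    def test_ten_percent_inflation_exceeds_threshold(self, small_phantom):
        vol = small_phantom.t1rho_truth.values_ms
        value, ok = quantification_error(1.10 * vol, vol, small_phantom.labels)
        assert value == pytest.approx(10.0, rel=1e-9)
        assert not ok


class TestEvaluateCohort:
    def _one_subject(self, seed=0):
        spec = q.PhantomSpec(matrix_size=(2, 48, 48), seed=seed)
        ph = q.generate_phantom(spec, f"S{seed:03d}")
        return ph

    def test_perfect_prediction_report(self):
        ph = self._one_subject()
        vol = ph.t1rho_truth.values_ms
        rng = np.random.default_rng(0)
        other = self._one_subject(seed=1)
        preds = {"A": vol, "B": other.t1rho_truth.values_ms}
        metrics, agreement = evaluate_cohort(
            preds, preds, {"A": ph.labels, "B": other.labels})
        vals = metrics.per_subject
        assert (vals.loc[vals["metric"] == "nmse_pct", "value"] == 0).all()
        assert (vals.loc[vals["metric"] == "ssim", "value"] == 1).all()
        assert agreement["all"].bias_ms == pytest.approx(0.0)
        assert agreement["all"].quantification_error_pct == 0.0

    def test_aggregation_matches_per_subject_rows(self):
        a, b = self._one_subject(0), self._one_subject(1)
        rng = np.random.default_rng(2)
        truths = {"A": a.t1rho_truth.values_ms, "B": b.t1rho_truth.values_ms}
        preds = {k: v + rng.normal(0, 1, v.shape) for k, v in truths.items()}
        metrics, _ = evaluate_cohort(preds, truths, {"A": a.labels, "B": b.labels})
        df = metrics.per_subject
        sel = df[(df["region"] == "cartilage") & (df["metric"] == "nmse_pct")]
        agg = metrics.summary.loc[("all", "cartilage", "nmse_pct")]
        assert agg["mean"] == pytest.approx(sel["value"].mean())
        assert agg["n"] == 2

    def test_mismatched_subject_sets_rejected(self):
        a = self._one_subject()
        with pytest.raises(ValueError, match="same subjects"):
            evaluate_cohort({"A": a.s0}, {"B": a.s0}, {"A": a.labels})

    def test_noise_ladder_never_improves_cartilage_nmse(self, acq):
        """Degradation direction: fitted-vs-truth cartilage NMSE is
        non-decreasing along a seeded noise ladder."""
        spec = q.PhantomSpec(matrix_size=(2, 48, 48), seed=13)
        ph = q.generate_phantom(spec, "S001")
        cart = ph.labels.cartilage_mask
        values = []
        for sigma in (0.005, 0.01, 0.02, 0.05):
            es = q.simulate_echoes(ph, acq, "T1rho", noise_sigma=sigma, seed=4)
            fit = q.fit_monoexponential(es, mask=cart)
            values.append(nmse(fit.map.values_ms, ph.t1rho_truth.values_ms, cart))
        assert all(b >= a for a, b in zip(values, values[1:]))
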