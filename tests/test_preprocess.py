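"""Preprocessing operators against independent oracles, plus pipeline contracts."""

import math

import numpy as np
import pytest

import ramanpipe as rp
from ramanpipe.preprocess import PRESETS, PipelineSpec, StageSpec, apply_pipeline, get_preset
from ramanpipe.simulate import lorentzian


def snip_oracle(y, iterations, lls=False):
    """Literal scalar clipping loop; optional LLS compress/decompress."""
    n = len(y)
    if lls:
        v = [math.log(math.log(math.sqrt(yi + 1.0) + 1.0) + 1.0) for yi in y]
    else:
        v = list(map(float, y))
    for m in range(1, iterations + 1):
        new = list(v)
        for i in range(m, n - m):  # edge points without a full window stay put
            new[i] = min(v[i], 0.5 * (v[i - m] + v[i + m]))
        v = new
    if lls:
        v = [(math.exp(math.exp(vi) - 1.0) - 1.0) ** 2 - 1.0 for vi in v]
    return np.minimum(np.array(v), np.asarray(y, dtype=float))


class TestSnip:
    def test_flat_spectrum_untouched(self):
        y = np.full(200, 7.0)
        corrected, baseline = rp.snip_baseline(y, 30)
        np.testing.assert_allclose(baseline, 7.0, atol=1e-6)
        np.testing.assert_allclose(corrected, 0.0, atol=1e-6)

    @pytest.mark.parametrize("lls", [False, True])
    def test_matches_literal_loop_oracle(self, lls):
        """Vectorized SNIP equals the scalar reference on random spectra."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = rng.integers(64, 512)
            iters = int(rng.integers(1, 60))
            y = rng.gamma(2.0, 2.0, size=n)
            _, baseline = rp.snip_baseline(y, iters, lls=lls)
            np.testing.assert_allclose(baseline, snip_oracle(y, iters, lls=lls), atol=1e-9)

    def test_ramp_plus_peak_recovery(self):
        """A Lorentzian on a linear ramp: the ramp goes, the peak stays."""
        x = np.arange(500)
        y = x * (100.0 / 499.0) + 50.0 * lorentzian(x.astype(float), 250.0, 10.0)
        corrected, _ = rp.snip_baseline(y, 80)
        assert corrected[250] == pytest.approx(50.0, rel=0.05)
        far = np.abs(x - 250) > 50
        assert np.abs(corrected[far]).max() < 1.0

    def test_baseline_never_exceeds_input(self, small_cohort):
        _, baseline = rp.snip_baseline(small_cohort.matrix, 80)
        assert np.all(baseline <= small_cohort.matrix + 1e-9)

    def test_default_iterations_is_80(self):
        y = np.random.default_rng(0).gamma(2.0, 2.0, 300)
        np.testing.assert_array_equal(rp.snip_baseline(y)[1], rp.snip_baseline(y, 80)[1])

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            rp.snip_baseline(np.ones(10), 0)
        with pytest.raises(ValueError):
            rp.snip_baseline(np.array([]))


class TestNormalization:
    def test_l2_three_four_five(self):
        np.testing.assert_allclose(rp.l2_normalize(np.array([3.0, 4.0])), [0.6, 0.8])

    def test_l2_idempotent_on_unit_sphere(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        u = rp.l2_normalize(x)
        assert np.linalg.norm(u) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(rp.l2_normalize(u), u, atol=1e-12)

    def test_l2_scale_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        for c in (1e-6, 0.5, 3.0, 1e6):
            np.testing.assert_allclose(rp.l2_normalize(c * x), rp.l2_normalize(x), atol=1e-9)

    def test_l2_zero_vector_raises(self):
        with pytest.raises(ValueError, match="zero-norm"):
            rp.l2_normalize(np.zeros(3))

    def test_snv_hand_computed(self):
        # population sd of [1,2,3] is sqrt(2/3)
        expected = (np.array([1.0, 2.0, 3.0]) - 2.0) / np.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(rp.snv_normalize(np.array([1.0, 2.0, 3.0])), expected)
        assert expected[2] == pytest.approx(1.224744871, abs=1e-9)

    def test_snv_moments(self):
        x = np.random.default_rng(3).gamma(2.0, 1.5, 200)
        z = rp.snv_normalize(x)
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std() == pytest.approx(1.0, abs=1e-9)

    def test_snv_constant_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            rp.snv_normalize(np.full(5, 5.0))


class TestFilters:
    def test_median_constant_unchanged(self):
        np.testing.assert_array_equal(rp.median_filter(np.full(20, 4.5)), np.full(20, 4.5))

    def test_median_hand_enumerated_windows(self):
        """Mirror padding of [1,2,100,3,4] gives medians [2,2,3,3,4]."""
        out = rp.median_filter(np.array([1.0, 2.0, 100.0, 3.0, 4.0]), window=5)
        np.testing.assert_array_equal(out, [2, 2, 3, 3, 4])

    def test_median_removes_isolated_spike(self):
        rng = np.random.default_rng(4)
        y = rng.normal(0, 0.1, 101)
        y[50] += 50.0
        out = rp.median_filter(y, window=5)
        assert abs(out[50]) < 1.0

    def test_median_rejects_bad_window(self):
        with pytest.raises(ValueError):
            rp.median_filter(np.ones(10), window=4)
        with pytest.raises(ValueError):
            rp.median_filter(np.ones(10), window=11)

    def test_savgol_preserves_cubic(self):
        x = np.linspace(-1, 1, 50)
        y = 2 * x**3 - x**2 + 0.5 * x + 1
        out = rp.smooth(y, "savgol", window=11, polyorder=3)
        np.testing.assert_allclose(out[8:-8], y[8:-8], atol=1e-8)

    def test_gaussian_impulse_gives_kernel(self):
        y = np.zeros(41)
        y[20] = 1.0
        out = rp.smooth(y, "gaussian", sigma=2.0)
        offsets = np.arange(-8, 9)
        kernel = np.exp(-0.5 * (offsets / 2.0) ** 2)
        kernel /= kernel.sum()
        np.testing.assert_allclose(out[20 + offsets], kernel, atol=1e-9)

    def test_constants_unchanged_by_smoothing(self):
        c = np.full(60, 3.0)
        np.testing.assert_allclose(rp.smooth(c, "savgol"), c, atol=1e-10)
        np.testing.assert_allclose(rp.smooth(c, "gaussian"), c, atol=1e-10)

    def test_invalid_savgol_params(self):
        with pytest.raises(ValueError):
            rp.smooth(np.ones(30), "savgol", window=5, polyorder=5)


class TestPipelines:
    def test_presets_match_study_recipes(self):
        ml = get_preset("suggested_ml")
        assert [s.kind for s in ml.stages] == [
            "snip_baseline", "l2_normalize", "median_filter", "pca"]
        assert ml.stages[0].params["iterations"] == 80
        assert ml.stages[2].params["window"] == 5
        assert ml.pca_components == 30
        assert ml.region == "low_plus_high"
        dl = get_preset("suggested_dl")
        assert [s.kind for s in dl.stages] == ["snip_baseline", "l2_normalize"]
        assert dl.pca_components is None
        assert [s.kind for s in get_preset("pipeline_a").stages] == [
            "savgol_smooth", "snip_baseline", "snv_normalize", "pca"]
        assert [s.kind for s in get_preset("pipeline_b").stages] == [
            "gaussian_smooth", "snip_baseline", "snv_normalize", "pca"]
        assert [s.kind for s in get_preset("pipeline_c").stages] == [
            "snip_baseline", "snv_normalize", "savgol_smooth"]

    def test_empty_pipeline_is_identity(self, tiny_cohort):
        spec = PipelineSpec("noop", (), region="full")
        out, state = apply_pipeline(tiny_cohort, spec)
        assert state is None
        np.testing.assert_array_equal(out.matrix, tiny_cohort.matrix)

    def test_pipeline_deterministic(self, small_cohort):
        spec = get_preset("suggested_ml")
        a, _ = apply_pipeline(small_cohort, spec)
        b, _ = apply_pipeline(small_cohort, spec)
        np.testing.assert_array_equal(a, b)

    def test_fitted_state_reused_on_heldout(self, small_cohort):
        """Transform-only application uses the training fit, not a refit."""
        spec = get_preset("suggested_ml")
        scores_fit, state = apply_pipeline(small_cohort, spec)
        scores_tx, state2 = apply_pipeline(small_cohort, spec, fitted_state=state)
        assert state2 is state
        np.testing.assert_allclose(scores_tx, scores_fit, atol=1e-9)

    def test_pca_must_be_last_and_unique(self):
        with pytest.raises(ValueError):
            PipelineSpec("bad", (StageSpec("pca"), StageSpec("l2_normalize")))
        with pytest.raises(ValueError):
            PipelineSpec("bad", (StageSpec("pca"), StageSpec("pca")))

    def test_unknown_preset_and_stage(self):
        with pytest.raises(ValueError, match="unknown pipeline preset"):
            get_preset("nope")
        with pytest.raises(ValueError, match="unknown stage kind"):
            StageSpec("fourier")

    def test_preset_names_complete(self):
        assert set(PRESETS) == {
            "suggested_ml", "suggested_dl", "pipeline_a", "pipeline_b", "pipeline_c"}

    def test_pipeline_dict_roundtrip(self):
        for name in PRESETS:
            spec = get_preset(name)
            assert rp.pipeline_from_dict(rp.pipeline_to_dict(spec)) == spec
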