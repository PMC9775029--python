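"""Core estimator: normalization, two-threshold trough detection against a
brute-force oracle, spline baseline synthesis, moving-average detrending,
and dominant-frequency RR estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from nirsrr import DegenerateInputError, SimConfig, ValidationError, synthesize_o2hb
from nirsrr.preprocess import main_bandpass
from nirsrr.rr import (
    TroughParams,
    detect_troughs,
    estimate_rr,
    estimate_rr_pipeline,
    ma_detrend,
    normalize_minmax,
    spectral_grid_bpm,
    synthesize_baseline,
)
from nirsrr.simulate import inject_artifacts


def brute_force_troughs(x, a=1.0, b=3.0):
    """Independent exhaustive implementation of the two-threshold rule."""
    th1 = a * np.mean(x)
    candidates = [
        i for i in range(1, len(x) - 1)
        if x[i] < x[i - 1] and x[i] < x[i + 1] and x[i] < th1
    ]
    z = [x[i] for i in candidates]
    if len(z) < 2:
        return candidates, candidates, []
    mu = sum(z) / len(z)
    sd = (sum((v - mu) ** 2 for v in z) / (len(z) - 1)) ** 0.5
    retained = [i for i in candidates if x[i] >= mu - b * sd]
    rejected = [i for i in candidates if x[i] < mu - b * sd]
    return candidates, retained, rejected


class TestNormalize:
    @pytest.mark.parametrize(
        "x,expected",
        [
            ([0, 5, 10], [-1, 0, 1]),
            ([2, 4, 8], [-1, -1 / 3, 1]),
        ],
    )
    def test_affine_map_examples(self, x, expected):
        assert np.allclose(normalize_minmax(np.asarray(x, float)), expected)

    @given(
        hnp.arrays(
            np.float64,
            st.integers(3, 50),
            elements=st.floats(-1e6, 1e6, allow_nan=False),
        ).filter(lambda a: a.max() > a.min())
    )
    @settings(deadline=None, derandomize=True)
    def test_output_extrema_are_exactly_plus_minus_one(self, x):
        out = normalize_minmax(x)
        assert out.min() == -1.0 and out.max() == 1.0

    def test_constant_input_is_degenerate(self):
        with pytest.raises(DegenerateInputError, match="degenerate amplitude"):
            normalize_minmax(np.full(10, 3.0))


class TestTroughDetection:
    def test_sine_troughs_at_known_samples(self):
        # 0.5 Hz unit sine at 50 Hz over 10 s: minima every 100 samples
        n = np.arange(500)
        x = np.sin(np.pi * n / 50)
        ts = detect_troughs(x)
        assert ts.candidates.tolist() == [75, 175, 275, 375, 475]
        assert ts.retained.tolist() == [75, 175, 275, 375, 475]
        assert ts.rejected.size == 0

    def test_monotone_ramp_has_no_troughs(self):
        ts = detect_troughs(normalize_minmax(np.arange(100.0)))
        assert ts.candidates.size == 0 and ts.retained.size == 0

    def test_deep_excursion_rejected_periodic_troughs_kept(self):
        fs, t = 50.0, np.arange(0, 60, 1 / 50.0)
        x = np.sin(2 * np.pi * 0.5 * t)
        bump, _ = inject_artifacts(x.size, fs, [30.0], [0.8], [-6.0])
        xn = normalize_minmax(x + bump)
        ts = detect_troughs(xn)
        cand, ret, rej = brute_force_troughs(xn)
        assert ts.retained.tolist() == ret
        assert ts.rejected.tolist() == rej
        deep = int(np.argmin(xn))
        assert deep in ts.candidates and deep not in ts.retained
        assert ts.retained.size >= 25  # the periodic troughs survive

    def test_matches_brute_force_on_random_signals(self, rng):
        for _ in range(300):
            n = int(rng.integers(10, 200))
            raw = rng.standard_normal(n).cumsum() + rng.standard_normal(n)
            if raw.max() <= raw.min():
                continue
            x = normalize_minmax(raw)
            a = float(rng.uniform(0.25, 1.5))
            b = float(rng.uniform(1.0, 6.0))
            ts = detect_troughs(x, TroughParams(a=a, b=b))
            cand, ret, rej = brute_force_troughs(x, a, b)
            assert ts.candidates.tolist() == cand
            assert ts.retained.tolist() == ret
            assert ts.rejected.tolist() == rej

    def test_offset_before_normalization_leaves_indices_unchanged(self):
        rng = np.random.default_rng(8)
        raw = rng.standard_normal(400).cumsum()
        a = detect_troughs(normalize_minmax(raw))
        b = detect_troughs(normalize_minmax(raw + 123.456))
        assert a.retained.tolist() == b.retained.tolist()

    def test_single_candidate_retained_without_std(self):
        x = normalize_minmax(np.array([1.0, -1.0, 1.0, 2.0, 3.0]))
        ts = detect_troughs(x)
        assert ts.retained.tolist() == ts.candidates.tolist()
        assert np.isnan(ts.th2_value)

    def test_literal_th2_convention_discards_nearly_everything(self):
        # the literal textual rule keeps only z above mean+B*std, which for
        # trough values rejects essentially all of them
        t = np.arange(0, 30, 0.02)
        x = normalize_minmax(np.sin(2 * np.pi * 1.0 * t) + 0.2 * np.sin(2 * np.pi * 0.25 * t))
        literal = detect_troughs(x, TroughParams(th2_convention="literal"))
        corrected = detect_troughs(x, TroughParams())
        assert corrected.retained.size > 20
        assert literal.retained.size < corrected.retained.size / 2

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValidationError, match="normalized"):
            detect_troughs(np.array([0.0, -5.0, 3.0, 1.0]))


class TestBaselineSpline:
    def test_two_knots_degenerate_to_line(self):
        x = np.zeros(11)
        x[10] = 1.0
        from nirsrr.rr import TroughSet

        troughs = TroughSet(
            candidates=np.array([0, 10]), retained=np.array([0, 10]),
            rejected=np.array([], dtype=int), th1_value=0.0, th2_value=0.0,
        )
        m = synthesize_baseline(troughs, x)
        assert m[5] == pytest.approx(0.5)

    def test_spline_interpolates_knots_exactly(self, clean_trial):
        filt, _, cfg = clean_trial
        x = normalize_minmax(filt)
        ts = detect_troughs(x)
        m = synthesize_baseline(ts, x)
        assert m.size == x.size
        assert np.max(np.abs(m[ts.retained] - x[ts.retained])) < 1e-12

    def test_spline_recovers_slow_sine_between_knots(self):
        # knots sampled from sin(2*pi*t/10) every 1.25 s
        from nirsrr.rr import TroughSet

        fs = 50.0
        t = np.arange(0, 40, 1 / fs)
        target = np.sin(2 * np.pi * t / 10.0)
        knots = np.arange(0, t.size, int(1.25 * fs))
        troughs = TroughSet(
            candidates=knots, retained=knots, rejected=np.array([], dtype=int),
            th1_value=0.0, th2_value=0.0,
        )
        m = synthesize_baseline(troughs, target)
        inside = slice(knots[0], knots[-1] + 1)
        assert np.max(np.abs(m[inside] - target[inside])) < 0.01

    def test_fewer_than_two_knots_is_degenerate(self):
        from nirsrr.rr import TroughSet

        troughs = TroughSet(
            candidates=np.array([5]), retained=np.array([5]),
            rejected=np.array([], dtype=int), th1_value=0.0, th2_value=0.0,
        )
        with pytest.raises(DegenerateInputError, match="insufficient troughs"):
            synthesize_baseline(troughs, np.zeros(20))


class TestMovingAverageDetrend:
    def test_constant_maps_to_zero(self):
        s, g = ma_detrend(np.full(1000, 4.2), fs=50.0)
        assert np.allclose(g, 0.0, atol=1e-12)

    def test_ramp_interior_maps_to_zero(self):
        m = np.linspace(0, 10, 2000)
        _, g = ma_detrend(m, fs=50.0)
        k = 150  # kernel length at 3 s, 50 Hz
        assert np.max(np.abs(g[3 * k : -3 * k])) < 1e-8

    def test_kernel_longer_than_signal_rejected(self):
        with pytest.raises(ValidationError):
            ma_detrend(np.zeros(100), fs=50.0, ma_seconds=3.0)


class TestSpectralEstimate:
    @pytest.mark.parametrize("freq,expected", [(0.2, 12.0), (0.4, 24.0)])
    def test_pure_tone_rate(self, freq, expected):
        fs, t = 50.0, np.arange(0, 50, 1 / 50.0)
        res = estimate_rr(np.sin(2 * np.pi * freq * t), fs)
        grid = spectral_grid_bpm(t.size, fs)
        assert abs(res.rr_bpm - expected) <= grid
        assert res.rr_bpm == pytest.approx(60.0 * res.dominant_frequency)

    def test_two_tone_argmax_picks_larger(self):
        fs, t = 50.0, np.arange(0, 50, 1 / 50.0)
        g = np.sin(2 * np.pi * 0.15 * t) + 0.4 * np.sin(2 * np.pi * 0.35 * t)
        res = estimate_rr(g, fs)
        assert abs(res.rr_bpm - 9.0) <= spectral_grid_bpm(t.size, fs)

    def test_constant_signal_has_no_spectral_content(self):
        with pytest.raises(DegenerateInputError, match="no spectral content"):
            estimate_rr(np.full(1000, 2.0), fs=50.0)

    def test_search_band_validation(self):
        with pytest.raises(ValidationError):
            estimate_rr(np.random.default_rng(0).standard_normal(1000), 50.0,
                        band=(3.0, 1.0))


class TestFullPipeline:
    def test_clean_trial_recovers_commanded_rate(self, clean_trial):
        filt, _, cfg = clean_trial
        res = estimate_rr_pipeline(filt, cfg.sampling_rate)
        grid = spectral_grid_bpm(filt.size, cfg.sampling_rate)
        assert abs(res.rr_bpm - 18.0) <= grid
        assert res.baseline is not None and res.detrended is not None
        assert res.baseline.size == filt.size

    def test_artifact_twin_estimates_match(self):
        fs = 50.0
        cfg = SimConfig(resp_rate=0.3, seed=23)
        sig, _ = synthesize_o2hb(cfg)
        bump, _ = inject_artifacts(
            sig.size, fs, [17.0, 33.0], [0.8, 0.6],
            [-12.0 * cfg.resp_amplitude] * 2,
        )
        r0 = estimate_rr_pipeline(main_bandpass(sig, fs), fs)
        r1 = estimate_rr_pipeline(main_bandpass(sig + bump, fs), fs)
        assert r1.troughs.rejected.size >= 2
        assert abs(r0.rr_bpm - r1.rr_bpm) <= spectral_grid_bpm(sig.size, fs)

    def test_flat_signal_propagates_degenerate_error(self):
        with pytest.raises(DegenerateInputError):
            estimate_rr_pipeline(np.zeros(2500), 50.0)
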