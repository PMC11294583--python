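"""Tests of the trace quantification pipeline."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from meientry import synth
from meientry.traces import (
    TraceError,
    align_and_summarize,
    bleed_correct,
    call_mi,
    detect_peak,
    half_decay_time,
    kmeans_correlation,
    ks_compare,
    nc_ratio,
    peak_mi_correlation,
)


# ---------------------------------------------------------------- MI calling

class TestCallMi:
    def test_clean_step(self):
        trace = np.zeros(80)
        trace[40:] = 100.0
        assert call_mi(trace, min_rise=10.0) == 40

    def test_flat_trace_is_non_meiotic(self):
        assert call_mi(np.full(50, 7.0), min_rise=1.0) is None

    def test_short_trace_rejected(self):
        with pytest.raises(TraceError):
            call_mi([1.0, 2.0], min_rise=1.0)

    def test_non_uniform_grid_rejected(self):
        with pytest.raises(TraceError):
            call_mi(np.arange(10.0), min_rise=0.1,
                    times=np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 10.0]))

    def test_recovers_generator_truth(self, small_cohort):
        """Called MI within ±2 frames of truth for ≥95% of meiotic cells."""
        cfg, table, truths = small_cohort
        marker = table[(table.channel == "mi_marker")].pivot(
            index="cell_id", columns="time_h", values="intensity")
        hits, total = 0, 0
        for t in truths:
            if t.cell_class != "meiotic":
                continue
            total += 1
            idx = call_mi(marker.loc[t.cell_id].values, min_rise=10.0)
            if idx is None:
                continue
            err = abs(idx * cfg.sampling_interval - t.mi_time)
            hits += err <= 2 * cfg.sampling_interval + 1e-9
        assert total > 10
        assert hits / total >= 0.95

    def test_non_meiotic_cells_not_called(self, small_cohort):
        cfg, table, truths = small_cohort
        marker = table[(table.channel == "mi_marker")].pivot(
            index="cell_id", columns="time_h", values="intensity")
        non = [t.cell_id for t in truths if t.cell_class == "non_meiotic"]
        called = [call_mi(marker.loc[c].values, min_rise=10.0) for c in non]
        assert all(c is None for c in called)


# ---------------------------------------------------------------- peaks

class TestDetectPeak:
    def test_exhaustive_max(self):
        call = detect_peak([1, 5, 2, 9, 3], mi_index=4, window=60)
        assert (call.peak_index, call.peak_value) == (3, 9.0)

    def test_window_clipping(self):
        call = detect_peak([1, 5, 2, 9, 3], mi_index=4, window=1)
        assert call.peak_index == 3 and call.window_used == 1

    def test_tie_breaks_to_earlier_frame(self):
        call = detect_peak([1, 9, 9, 1], mi_index=3, window=3)
        assert call.peak_index == 1

    def test_never_returns_frame_at_or_after_mi(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            trace = rng.random(40)
            mi = int(rng.integers(1, 40))
            w = int(rng.integers(1, 70))
            assert detect_peak(trace, mi, w).peak_index < mi

    def test_invalid_inputs(self):
        with pytest.raises(TraceError):
            detect_peak([1, 2, 3], mi_index=0, window=5)
        with pytest.raises(TraceError):
            detect_peak([1, 2, 3], mi_index=2, window=0)

    def test_recovers_rim11_peaks(self, small_cohort):
        """Median peak-time error ≤1 frame on the synthetic cohort."""
        cfg, table, truths = small_cohort
        rim = table[(table.channel == "rim11")
                    & (table.compartment == "nuclear")].pivot(
            index="cell_id", columns="time_h", values="intensity")
        errors = []
        for t in truths:
            if t.cell_class != "meiotic" or t.peak_time_rim11 is None:
                continue
            mi_idx = int(round(t.mi_time / cfg.sampling_interval))
            call = detect_peak(rim.loc[t.cell_id].values, mi_idx, 60,
                               dt=cfg.sampling_interval)
            errors.append(
                round(abs(call.peak_time - t.peak_time_rim11)
                      / cfg.sampling_interval))
        assert np.median(errors) <= 1.0


# ---------------------------------------------------------------- alignment

class TestAlign:
    def test_identical_traces_zero_ci(self):
        tr = np.sin(np.linspace(0, 3, 50))
        out = align_and_summarize([tr, tr, tr], [25, 25, 25], half_width=10)
        assert np.allclose(out.mean, tr[15:36])
        assert np.allclose(out.ci_upper - out.ci_lower, 0.0)

    def test_offset_traces_register_exactly(self):
        base = np.exp(-0.5 * (np.arange(60.0) - 20) ** 2 / 25)
        shifted = np.roll(base, 5)
        out = align_and_summarize([base, shifted], [20, 25], half_width=8)
        assert np.allclose(out.mean, base[12:29])

    def test_zero_anchor_alignment_is_identity(self):
        tr = np.arange(30.0)
        out = align_and_summarize([tr, tr], [0, 0], half_width=29)
        covered = out.rel_frames >= 0
        assert np.allclose(out.mean[covered], tr)

    def test_uncovered_frames_omitted(self):
        out = align_and_summarize(
            [np.arange(10.0), np.arange(10.0)], [5, 5], half_width=20)
        assert out.rel_frames.min() == -5 and out.rel_frames.max() == 4

    def test_single_trace_rejected(self):
        with pytest.raises(TraceError):
            align_and_summarize([np.arange(5.0)], [2], half_width=2)

    def test_cohort_alignment_recovers_model_mean(self, small_cohort,
                                                  resolved_params):
        """Aligned noisy cohort mean covers the noiseless trace at ≥90% of
        frames (cells share one MI anchor scale, so the aligned mean should
        track the model observable)."""
        from meientry import model

        cfg, table, truths = small_cohort
        ume = table[(table.channel == "ume6")].pivot(
            index="cell_id", columns="time_h", values="intensity")
        meiotic = [t for t in truths if t.cell_class == "meiotic"]
        anchors = [int(round(t.mi_time / cfg.sampling_interval))
                   for t in meiotic]
        out = align_and_summarize(
            [ume.loc[t.cell_id].values for t in meiotic], anchors,
            half_width=20)
        traj = model.simulate(resolved_params, t_end=cfg.duration,
                              dt=cfg.sampling_interval)
        noiseless = traj.observable("ume6") + cfg.background
        anchor_ref = int(round(np.median([t.mi_time for t in meiotic])
                               / cfg.sampling_interval))
        inside = 0
        for rel, lo, hi in zip(out.rel_frames, out.ci_lower, out.ci_upper):
            ref_idx = anchor_ref + rel
            if not (0 <= ref_idx < noiseless.size):
                continue
            margin = 0.3 * abs(noiseless[ref_idx]) + 1.0
            inside += (lo - margin) <= noiseless[ref_idx] <= (hi + margin)
        assert inside / out.rel_frames.size >= 0.9


# ---------------------------------------------------------------- clustering

class TestKmeansCorrelation:
    def _two_group_data(self):
        rng = np.random.default_rng(1)
        a = rng.random(40)
        b = -a + rng.normal(0, 0.05, 40)     # anticorrelated template
        X = np.vstack([a] * 6 + [b] * 6)
        labels = np.array([0] * 6 + [1] * 6)
        return X, labels

    def test_exact_copies_separate_perfectly(self):
        X, labels = self._two_group_data()
        res = kmeans_correlation(X, k=2, replicates=5, seed=0)
        assert adjusted_rand_score(labels, res.assignments) == 1.0
        assert res.inertia == pytest.approx(0.0, abs=1e-9)

    def test_affine_invariance(self):
        X, _ = self._two_group_data()
        res1 = kmeans_correlation(X, k=2, replicates=5, seed=0)
        X2 = X.copy()
        X2[3] = 7.0 + 3.5 * X2[3]            # positive affine rescale
        res2 = kmeans_correlation(X2, k=2, replicates=5, seed=0)
        same = res1.assignments == res1.assignments[3]
        same2 = res2.assignments == res2.assignments[3]
        assert np.array_equal(same, same2)

    def test_planted_six_groups_recovered(self, resolved_params):
        """ARI ≥ 0.9 on six timing groups staggered 1 h apart, 5% noise."""
        traces, labels = synth.planted_timing_cohort(
            n_per_group=25, n_groups=6, stagger_h=1.0, noise_sd=2.0,
            params=resolved_params, seed=12)
        res = kmeans_correlation(traces[:, :80], k=6, replicates=10,
                                 max_iter=10000, seed=0)
        assert adjusted_rand_score(labels, res.assignments) >= 0.9

    def test_deterministic_under_seed(self):
        X, _ = self._two_group_data()
        X = X + np.random.default_rng(3).normal(0, 0.1, X.shape)
        r1 = kmeans_correlation(X, k=3, replicates=4, seed=42)
        r2 = kmeans_correlation(X, k=3, replicates=4, seed=42)
        assert np.array_equal(r1.assignments, r2.assignments)
        assert r1.inertia == r2.inertia

    def test_inertia_definition(self):
        X, _ = self._two_group_data()
        res = kmeans_correlation(X, k=2, replicates=3, seed=1)
        z = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        c = res.centroids
        zc = (c - c.mean(1, keepdims=True)) / c.std(1, keepdims=True)
        manual = sum(
            1 - (z[i] @ zc[res.assignments[i] - 1]) / X.shape[1]
            for i in range(X.shape[0]))
        assert res.inertia == pytest.approx(manual, abs=1e-9)

    def test_errors(self):
        X, _ = self._two_group_data()
        with pytest.raises(TraceError, match="constant"):
            bad = X.copy()
            bad[2] = 5.0
            kmeans_correlation(bad, k=2)
        with pytest.raises(TraceError):
            kmeans_correlation(X, k=100)
        with pytest.raises(TraceError):
            kmeans_correlation(X, k=1)


# ---------------------------------------------------------------- statistics

class TestStatistics:
    def test_perfect_linear_relation(self):
        peaks = np.array([1.0, 2.0, 3.5, 6.0])
        assert peak_mi_correlation(peaks, peaks + 5.0) == pytest.approx(1.0)

    def test_population_r2_recovered(self):
        """ρ = 0.8 bivariate normal, n = 10⁴ → r² = 0.64 ± 0.02."""
        rng = np.random.default_rng(2)
        cov = [[1.0, 0.8], [0.8, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=10_000)
        assert peak_mi_correlation(xy[:, 0], xy[:, 1]) == pytest.approx(
            0.64, abs=0.02)

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(3)
        r2 = peak_mi_correlation(rng.random(5000), rng.random(5000))
        assert r2 < 0.01

    def test_degenerate_inputs(self):
        with pytest.raises(TraceError):
            peak_mi_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(TraceError):
            peak_mi_correlation([1.0, 2.0], [1.0, 2.0])

    def test_ks_identical_samples(self):
        a = np.arange(20.0)
        p, sig = ks_compare(a, a)
        assert p == pytest.approx(1.0) and not sig

    def test_ks_separated_samples(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 200)
        b = rng.normal(5, 1, 200)
        p, sig = ks_compare(a, b)
        assert p < 1e-6 and sig

    def test_ks_type_one_error_calibrated(self):
        """Rejection rate 0.05 ± 0.01 over 2000 same-distribution draws."""
        rng = np.random.default_rng(5)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            _, sig = ks_compare(rng.normal(0, 1, 100), rng.normal(0, 1, 100))
            rejections += sig
        assert rejections / n_rep == pytest.approx(0.05, abs=0.01)

    def test_ks_small_sample_rejected(self):
        with pytest.raises(TraceError):
            ks_compare([1.0, 2.0], [3.0, 4.0, 5.0, 6.0, 7.0])


# ---------------------------------------------------------------- decays & ratios

class TestHalfDecay:
    def test_noiseless_exponential(self):
        lam = np.log(2.0) / 0.5                 # 30-min half-time
        t = np.arange(0, 8, 0.2)
        trace = np.where(t < 2.0, 20.0, 20.0 * np.exp(-lam * (t - 2.0)))
        est = half_decay_time(trace, switch_index=10)
        assert not est.censored
        assert est.t50 == pytest.approx(30.0, abs=12.0)

    def test_non_decaying_trace_censored(self):
        est = half_decay_time(np.full(40, 10.0), switch_index=10)
        assert est.censored and est.t50 is None

    def test_single_frame_dip_ignored(self):
        trace = np.full(40, 10.0)
        trace[20] = 1.0                          # fluke frame
        est = half_decay_time(trace, switch_index=10)
        assert est.censored

    def test_errors(self):
        with pytest.raises(TraceError):
            half_decay_time(np.ones(10), switch_index=0)
        with pytest.raises(TraceError):
            half_decay_time(np.zeros(10), switch_index=5)


class TestRatioAndBleed:
    @pytest.mark.parametrize("nuc,whole,expected",
                             [(10.0, 10.0, 1.0), (0.0, 7.0, 0.0),
                              (15.0, 10.0, 1.5)])
    def test_nc_ratio(self, nuc, whole, expected):
        assert nc_ratio(nuc, whole) == expected

    def test_nc_ratio_invalid(self):
        with pytest.raises(TraceError):
            nc_ratio(1.0, 0.0)

    def test_bleed_arithmetic(self):
        out = bleed_correct([100.0], [50.0], 0.51)
        assert out[0] == pytest.approx(74.5)

    def test_bleed_zero_coeff_identity(self):
        orange = np.array([3.0, 4.0, 5.0])
        assert np.array_equal(bleed_correct(orange, np.ones(3), 0.0), orange)

    def test_bleed_floors_at_zero(self):
        assert bleed_correct([10.0], [100.0], 0.51)[0] == 0.0

    def test_bleed_length_mismatch(self):
        with pytest.raises(TraceError):
            bleed_correct([1.0, 2.0], [1.0], 0.51)
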