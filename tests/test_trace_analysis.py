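"""Change-point detection, screening, step counting and lifetime fitting."""

import dataclasses

import numpy as np
import pytest

from smlight import synthetic as syn, trace_analysis as ta

from oracles import exhaustive_segmentation


def steps(levels, lengths):
    return np.concatenate([np.full(n, float(l)) for l, n in zip(levels, lengths)])


class TestChangePointDetection:
    def test_noiseless_two_steps_found_exactly(self):
        cp = ta.detect_change_points(steps([100, 50, 0], [5, 5, 5]))
        assert list(cp.boundaries) == [5, 10]
        assert cp.directions == ["down", "down"]
        np.testing.assert_allclose(cp.segment_means, [100, 50, 0])

    def test_constant_input_has_no_boundaries(self):
        cp = ta.detect_change_points(np.full(50, 100.0))
        assert cp.boundaries.size == 0
        assert cp.segment_means[0] == 100.0

    def test_nan_input_rejected(self):
        x = np.full(50, 1.0)
        x[3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            ta.detect_change_points(x)

    def test_segment_summary_reconstructs_means(self, fast_bleach_config, rng):
        """Segment means recomputed from boundaries equal the reported ones."""
        tr = syn.generate_bleach_trace(2, fast_bleach_config, rng=rng)
        cp = ta.detect_change_points(tr.donor)
        edges = [0, *cp.boundaries, tr.n_frames]
        means = [tr.donor[a:b].mean() for a, b in zip(edges, edges[1:])]
        np.testing.assert_allclose(means, cp.segment_means, rtol=1e-12)

    @pytest.mark.parametrize("case_seed", range(5))
    def test_matches_exhaustive_oracle_on_noiseless_traces(self, case_seed):
        """Binary segmentation equals brute-force least squares, <=2 steps, <=60 frames."""
        case_rng = np.random.default_rng(1000 + case_seed)
        for n in (20, 40, 60):
            for _ in range(30):
                k = case_rng.integers(0, 3)
                while True:
                    bs = sorted(case_rng.integers(5, n - 4, size=k).tolist())
                    if all(b2 - b1 >= 5 for b1, b2 in zip(bs, bs[1:])):
                        break
                levels = case_rng.choice(np.arange(0, 1001, 50), size=k + 1,
                                         replace=False)
                edges = [0, *bs, n]
                x = np.concatenate([
                    np.full(b - a, float(l))
                    for (a, b), l in zip(zip(edges, edges[1:]), levels)
                ])
                expected = exhaustive_segmentation(x)
                got = tuple(ta.detect_change_points(x).boundaries)
                assert got == tuple(expected), (n, bs, levels)

    def test_lower_alpha_never_adds_boundaries(self, fast_bleach_config):
        gen = np.random.default_rng(42)
        for _ in range(25):
            tr = syn.generate_bleach_trace(2, fast_bleach_config, rng=gen)
            n_prev = None
            for alpha in (0.0005, 0.01, 0.1, 0.3):
                nb = ta.detect_change_points(tr.donor, alpha=alpha).boundaries.size
                if n_prev is not None:
                    assert nb >= n_prev
                n_prev = nb

    def test_two_step_recovery_rate_at_screening_snr(self):
        """>=95% of two-step traces yield both bleach frames within +-2 frames."""
        ds = syn.generate_condition_dataset("lit-dimer", 500, seed=9, kind="bleach")
        ok = total = 0
        for i, tr in enumerate(ds.traces):
            truth = sorted(ds.truth.bleach_frames.iloc[i])
            if len(truth) != 2:
                continue
            down = sorted(ta.detect_change_points(tr.donor).down_boundaries())
            total += 1
            if len(down) == 2 and all(abs(d - t) <= 2 for d, t in zip(down, truth)):
                ok += 1
        assert ok / total >= 0.95


class TestScreening:
    def test_snr_is_signal_drop_over_pooled_noise(self):
        """Alternating +-c noise around a 300->0 step gives SNR 3 exactly."""
        n_half = 40
        c = 100.0 * np.sqrt((2 * n_half - 1) / (2 * n_half))
        wiggle = np.tile([c, -c], n_half)
        x = np.concatenate([300.0 + wiggle, 0.0 + wiggle])
        tr = syn.Trace(time=np.arange(x.size) * 0.1, donor=x)
        rep = ta.compute_snr(tr)
        assert rep.snr == pytest.approx(3.0, abs=0.01)
        assert rep.accepted

    def test_noiseless_positive_signal_is_infinite_snr(self):
        x = steps([300, 0], [30, 30])
        tr = syn.Trace(time=np.arange(60) * 0.1, donor=x)
        rep = ta.compute_snr(tr)
        assert np.isinf(rep.snr)
        assert rep.accepted

    def test_no_bleach_reason_reported(self):
        rng = np.random.default_rng(0)
        x = 300.0 + rng.normal(0, 30, size=100)
        tr = syn.Trace(time=np.arange(100) * 0.1, donor=x)
        rep = ta.compute_snr(tr)
        assert "no bleach" in rep.reason

    def test_low_snr_presets_mostly_rejected(self):
        """Traces generated at SNR 2 fail the 2.5 screen more often than not."""
        cfg = syn.TraceConfig(n_frames=300, donor_brightness=200.0, noise_sd=100.0,
                              donor_bleach_rate=0.2, acceptor_bleach_rate=0.0)
        gen = np.random.default_rng(7)
        rejected = 0
        for _ in range(200):
            tr = syn.generate_bleach_trace(1, cfg, rng=gen)
            if not ta.compute_snr(tr).accepted:
                rejected += 1
        assert rejected > 100


class TestStepCounting:
    def test_two_equal_down_steps_is_dimer(self):
        cp = ta.detect_change_points(steps([600, 300, 0], [10, 10, 10]))
        sc = ta.count_bleach_steps(cp)
        assert sc.classification == "dimer"
        assert sc.n_down_steps == 2

    def test_blink_up_step_not_counted(self):
        """down-up-down counts two bleaches; the up recovery is ignored."""
        cp = ta.detect_change_points(steps([600, 300, 600, 300], [10, 10, 10, 10]))
        sc = ta.count_bleach_steps(cp)
        assert sc.classification == "dimer"

    def test_no_bleach_is_rejected(self):
        cp = ta.detect_change_points(np.full(50, 200.0))
        sc = ta.count_bleach_steps(cp)
        assert sc.classification == "rejected"
        assert sc.reason == "no bleaching"

    def test_small_shoulder_steps_dropped(self):
        """A down-step below a quarter of the largest one is residual drift."""
        cp = ta.detect_change_points(steps([600, 580, 0], [10, 10, 10]))
        sc = ta.count_bleach_steps(cp)
        assert sc.classification == "monomer"

    def test_classification_invariant_under_intensity_scaling(self, fast_bleach_config):
        gen = np.random.default_rng(3)
        for _ in range(20):
            n_fl = int(gen.integers(1, 3))
            tr = syn.generate_bleach_trace(n_fl, fast_bleach_config, rng=gen)
            a = ta.count_bleach_steps(ta.detect_change_points(tr.donor))
            b = ta.count_bleach_steps(ta.detect_change_points(tr.donor * 7.31))
            assert a.classification == b.classification

    def test_dimer_fraction_recovered_from_preset(self):
        """1000 traces at two-step probability 0.25 classify near 25%."""
        preset = dataclasses.replace(syn.get_preset("lit-monomer"),
                                     two_step_probability=0.25)
        ds = syn.generate_condition_dataset(preset, 1000, seed=13, kind="bleach")
        cls = [ta.count_bleach_steps(ta.detect_change_points(tr.donor)).classification
               for tr in ds.traces]
        n_counted = sum(c in ("monomer", "dimer") for c in cls)
        frac = sum(c == "dimer" for c in cls) / n_counted
        assert frac == pytest.approx(0.25, abs=0.03)


class TestTruncation:
    def test_first_bleach_of_either_dye_ends_window(self):
        donor = steps([500, 0], [80, 40])
        acceptor = steps([500, 0], [40, 80])
        tr = syn.Trace(time=np.arange(120) * 0.1, donor=donor, acceptor=acceptor)
        cp_d = ta.detect_change_points(donor)
        cp_a = ta.detect_change_points(acceptor)
        assert ta.truncate_at_bleach(tr, cp_d, cp_a) == (0, 40)

    def test_no_bleach_keeps_full_range(self):
        donor = np.full(60, 400.0)
        acceptor = np.full(60, 300.0)
        tr = syn.Trace(time=np.arange(60) * 0.1, donor=donor, acceptor=acceptor)
        cp_d = ta.detect_change_points(donor)
        cp_a = ta.detect_change_points(acceptor)
        assert ta.truncate_at_bleach(tr, cp_d, cp_a) == (0, 60)

    def test_truncation_matches_generator_truth(self):
        """Recovered window end within +-2 frames of the true first bleach."""
        ds = syn.generate_condition_dataset("dark-monomer", 100, seed=17, kind="fret")
        ok = total = 0
        for i, tr in enumerate(ds.traces):
            row = ds.truth.iloc[i]
            truths = [f for f in (row.donor_bleach_frame, row.acceptor_bleach_frame)
                      if f is not None and not np.isnan(f)]
            cp_d = ta.detect_change_points(tr.donor)
            cp_a = ta.detect_change_points(tr.acceptor)
            _, hi = ta.truncate_at_bleach(tr, cp_d, cp_a)
            expected = min(truths) if truths else tr.n_frames
            total += 1
            if abs(hi - expected) <= 2:
                ok += 1
        assert ok / total >= 0.95


class TestLifetimeFit:
    @staticmethod
    def _exact_histogram(tau, n_photons=1_000_000, bin_width=0.05, window=50.0):
        edges = np.arange(0, window + bin_width / 2, bin_width)
        norm = 1.0 - np.exp(-window / tau)
        p = (np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau)) / norm
        return syn.TcspcHistogram(bin_edges=edges, counts=p * n_photons)

    def test_exact_counts_recover_tau(self):
        fit = ta.fit_lifetime(self._exact_histogram(2.0))
        assert fit.tau_hat == pytest.approx(2.0, abs=1e-6)

    def test_doubling_counts_scales_se_only(self):
        h1 = self._exact_histogram(3.0, n_photons=10_000)
        h2 = syn.TcspcHistogram(bin_edges=h1.bin_edges, counts=h1.counts * 2)
        f1, f2 = ta.fit_lifetime(h1), ta.fit_lifetime(h2)
        assert f2.tau_hat == pytest.approx(f1.tau_hat, rel=1e-9)
        assert f2.tau_se == pytest.approx(f1.tau_se / np.sqrt(2), rel=1e-3)

    def test_recovery_from_photon_noise(self):
        h = syn.generate_tcspc(3.09, 100_000, seed=29)
        fit = ta.fit_lifetime(h)
        assert abs(fit.tau_hat - 3.09) < 3 * fit.tau_se
        assert fit.tau_se == pytest.approx(3.09 / np.sqrt(100_000), rel=0.2)

    def test_tail_fit_start_respected(self):
        h = syn.generate_tcspc(3.0, 200_000, seed=30)
        fit = ta.fit_lifetime(h, fit_start=2.0)
        assert abs(fit.tau_hat - 3.0) < 4 * fit.tau_se

    def test_degenerate_inputs_rejected(self):
        edges = np.arange(0, 10.5, 0.5)
        counts = np.zeros(20)
        counts[0] = 5000
        with pytest.raises(ValueError, match="single bin"):
            ta.fit_lifetime(syn.TcspcHistogram(bin_edges=edges, counts=counts))
        with pytest.raises(ValueError, match="100 photons"):
            ta.fit_lifetime(syn.TcspcHistogram(bin_edges=edges,
                                               counts=np.full(20, 2.0)))
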