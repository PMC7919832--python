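"""Generators: click waveforms, train processes, renders, spectra, counts."""

import numpy as np
import pandas as pd
import pytest

from finclick.simulate import (ScenarioConfig, TrainProcess, augment_spectra,
                               generate_click_times, generate_click_waveform,
                               generate_minute_counts,
                               generate_spectra_dataset, render_recording,
                               study_mimic_scenario)
from finclick.types import SyntheticClick

FS = 576_000


class TestClickWaveform:
    def test_length_and_spectral_peak(self):
        w = generate_click_waveform(125_000, 100e-6, FS, 1.0)
        assert len(w) == round(100e-6 * FS) == 58
        spec = np.abs(np.fft.rfft(w, n=8192))
        freqs = np.fft.rfftfreq(8192, 1 / FS)
        peak = freqs[np.argmax(spec)]
        assert 118_750 <= peak <= 131_250  # within 5% of 125 kHz

    def test_narrowband_quality_factor(self):
        w = generate_click_waveform(125_000, 100e-6, FS)
        spec = np.abs(np.fft.rfft(w, n=16384))
        freqs = np.fft.rfftfreq(16384, 1 / FS)
        peak = spec.max()
        above = freqs[spec >= peak / np.sqrt(2)]
        bw = above.max() - above.min()
        assert 125_000 / bw >= 5

    def test_zero_amplitude(self):
        w = generate_click_waveform(125_000, 100e-6, FS, amplitude=0.0)
        assert len(w) == 58 and not w.any()

    @pytest.mark.parametrize("f", [87_000, 145_000])
    def test_species_band_edges_pass(self, f):
        w = generate_click_waveform(f, 100e-6, FS)
        spec = np.abs(np.fft.rfft(w, n=16384))
        freqs = np.fft.rfftfreq(16384, 1 / FS)
        assert abs(freqs[np.argmax(spec)] - f) / f < 0.05

    def test_rejects_peak_at_or_above_nyquist(self):
        with pytest.raises(ValueError):
            generate_click_waveform(FS / 2, 100e-6, FS)


class TestClickTimes:
    def test_monte_carlo_mean_count(self):
        # 10 trains/min of exactly 20 clicks over 60 s -> E[clicks] = 200
        proc = TrainProcess(trains_per_minute=10, clicks_per_train=(20, 20))
        counts = [len(generate_click_times(proc, 60.0, seed=s))
                  for s in range(100)]
        # edge-truncation drops a few clicks from trains starting near 60 s
        assert abs(np.mean(counts) - 200) < 15

    def test_zero_rate_empty(self):
        proc = TrainProcess(trains_per_minute=0.0)
        assert generate_click_times(proc, 60.0, seed=1) == []

    def test_times_strictly_increasing_and_icis_capped(self):
        proc = TrainProcess(trains_per_minute=30)
        for seed in range(20):
            clicks = generate_click_times(proc, 10.0, seed=seed)
            t = np.array([c.center_time for c in clicks])
            assert np.all(np.diff(t) > 0)

    def test_within_train_gaps_never_exceed_200ms(self):
        # isolate single trains so consecutive gaps are within-train ICIs
        proc = TrainProcess(trains_per_minute=1.0, clicks_per_train=(40, 40))
        for seed in range(30):
            clicks = generate_click_times(proc, 5.0, seed=seed)
            if len(clicks) < 40:
                continue
            icis = np.diff([c.center_time for c in clicks[:40]])
            assert np.all(icis <= 0.200)


class TestRender:
    def test_truth_returned_unchanged(self):
        proc = TrainProcess(trains_per_minute=60, clicks_per_train=(5, 8))
        clicks = generate_click_times(proc, 2.0, seed=3)
        clip, truth = render_recording(clicks, 2.0, seed=4)
        assert truth == clicks
        assert len(clip.samples) == round(2.0 * FS)
        assert np.all(np.isfinite(clip.samples))
        assert np.all(np.abs(clip.samples) <= 1.0)

    def test_noise_only_rms_matches_request(self):
        clip, _ = render_recording([], 1.0, noise_level_db=-30.0, seed=5)
        rms_db = 20 * np.log10(np.sqrt(np.mean(clip.samples**2)))
        assert abs(rms_db - (-30.0)) < 0.5

    def test_click_snr_within_1db(self):
        c = SyntheticClick(center_time=0.05, peak_frequency=120_000,
                           duration=100e-6, snr_db=18.0)
        clip, _ = render_recording([c], 0.1, seed=6)
        # brick-wall band filter via FFT
        spec = np.fft.rfft(clip.samples)
        freqs = np.fft.rfftfreq(len(clip.samples), 1 / FS)
        spec[(freqs < 87_000) | (freqs > 145_000)] = 0
        xb = np.fft.irfft(spec, n=len(clip.samples))
        i0, i1 = int(0.05 * FS - 29), int(0.05 * FS + 29)
        click_rms = np.sqrt(np.mean(xb[i0:i1] ** 2))
        noise_rms = np.sqrt(np.mean(xb[: i0 - 5000] ** 2))
        achieved = 20 * np.log10(click_rms / noise_rms)
        assert abs(achieved - 18.0) < 1.0

    def test_click_outside_clip_rejected(self):
        c = SyntheticClick(center_time=3.0, peak_frequency=120_000,
                           duration=100e-6, snr_db=15.0)
        with pytest.raises(ValueError):
            render_recording([c], 2.0)


class TestSpectraDataset:
    def test_counts_and_bins(self, spectra_small):
        labels = [s.label for s in spectra_small]
        assert labels.count("click") == labels.count("noise") == 300
        assert all(s.magnitude.shape == (257,) for s in spectra_small)
        assert all(np.all(s.magnitude >= 0) for s in spectra_small)

    def test_minimal_dataset_one_of_each(self):
        ds = generate_spectra_dataset(2, 0.5, seed=0)
        assert sorted(s.label for s in ds) == ["click", "noise"]

    def test_class_separability_in_band(self, spectra_small):
        freqs = np.arange(257) * FS / 512
        band = (freqs >= 87_000) & (freqs <= 128_000)
        click_e = np.mean([s.magnitude[band].sum()
                           for s in spectra_small if s.label == "click"])
        noise_e = np.mean([s.magnitude[band].sum()
                           for s in spectra_small if s.label == "noise"])
        assert click_e > noise_e

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_spectra_dataset(1, 0.5, seed=0)
        with pytest.raises(ValueError):
            generate_spectra_dataset(10, 0.0, seed=0)


class TestAugment:
    def test_perturbation_bounded_by_max_db(self, spectra_small):
        src = spectra_small[:50]
        out = augment_spectra(src, 3.0, 1, seed=2)
        for orig, aug in zip(src, out[50:]):
            ratio_db = 20 * np.log10(aug.magnitude / orig.magnitude)
            assert np.max(np.abs(ratio_db)) <= 3.0 + 1e-9
            assert aug.label == orig.label

    def test_zero_db_copies_identical(self, spectra_small):
        src = spectra_small[:10]
        out = augment_spectra(src, 0.0, 1, seed=2)
        for orig, aug in zip(src, out[10:]):
            np.testing.assert_allclose(aug.magnitude, orig.magnitude)

    def test_output_size(self, spectra_small):
        assert len(augment_spectra(spectra_small[:100], 3.0, 1, seed=0)) == 200
        assert len(augment_spectra(spectra_small[:100], 3.0, 3, seed=0)) == 400

    def test_negative_db_rejected(self, spectra_small):
        with pytest.raises(ValueError):
            augment_spectra(spectra_small[:10], -1.0, 1, seed=0)


class TestMinuteCounts:
    def test_mean_converges_without_random_effects(self):
        # multipliers 1, SDs 0, baseline 100, 5 individuals -> mean 500
        sc = ScenarioConfig(
            baseline_rate=100.0, effect_multipliers={},
            re_sd_date=0, re_sd_session=0, re_sd_obs=0,
            n_days=100, sessions_per_day=10, minutes_per_session=10,
            individuals_probs=(0, 0, 0, 0, 1),
            prob_training=0, prob_separated=0,
            enrichment_probs=(1, 0, 0, 0, 0, 0), event_probs=(1, 0, 0, 0, 0),
            visitor_probs=(1, 0, 0), seed=9)
        counts, _ = generate_minute_counts(sc)
        assert len(counts) == 10_000
        assert abs(counts.click_count.mean() - 500) / 500 < 0.01

    def test_determinism(self):
        sc = ScenarioConfig(n_days=4, seed=21)
        a = generate_minute_counts(sc)
        b = generate_minute_counts(sc)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_empty_schedule(self):
        counts, annot = generate_minute_counts(ScenarioConfig(n_days=0))
        assert len(counts) == 0 and len(annot) == 0
        assert "click_count" in counts.columns

    def test_separation_ratio_matches_planted_multiplier(self):
        # isolate the grouping effect: no other factors, no random effects
        sc = study_mimic_scenario(seed=13).replace(
            re_sd_date=0, re_sd_session=0, re_sd_obs=0,
            n_days=150, prob_training=0,
            enrichment_probs=(1, 0, 0, 0, 0, 0), event_probs=(1, 0, 0, 0, 0),
            visitor_probs=(1, 0, 0), individuals_probs=(0, 0, 0, 0, 1))
        counts, annot = generate_minute_counts(sc)
        df = annot.assign(count=counts.click_count)
        # match covariates: compare within season via per-minute rate ratio
        ratios = []
        for season, g in df.groupby("season"):
            sep = g.loc[g.grouping == "separated", "count"].mean()
            tog = g.loc[g.grouping == "together", "count"].mean()
            if sep > 0 and tog > 0:
                ratios.append(sep / tog)
        assert abs(np.mean(ratios) - 2.36) / 2.36 < 0.05

    def test_annotations_cover_table_vocabulary(self):
        _, annot = generate_minute_counts(study_mimic_scenario(seed=2))
        assert set(annot.season) <= {"spring", "summer", "fall", "winter"}
        assert set(annot.visitors) <= {"none", "few", "many"}
        assert annot.live_fish.isin([0, 1]).all()
        assert (annot.n_individuals >= 1).all()
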