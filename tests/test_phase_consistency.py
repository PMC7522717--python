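"""PPC estimator, onset-window phase extraction and group averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iurhythm import (
    ConsistencySpectrum,
    EnvelopeSignal,
    IUAnnotation,
    IURecord,
    SynthConfig,
    extract_windows,
    generate_envelope,
    group_spectrum,
    ppc,
    speaker_spectra,
    speaker_spectrum,
    window_phases,
)
from iurhythm.phase_consistency import ppc_from_phasors


def ppc_bruteforce(angles):
    """Independent O(N^2) oracle: mean cosine over all distinct pairs."""
    angles = np.asarray(angles, dtype=float)
    n = len(angles)
    total = 0.0
    for j in range(n):
        for k in range(j + 1, n):
            total += np.cos(angles[j] - angles[k])
    return 2.0 * total / (n * (n - 1))


def dft_phase_oracle(window, window_s, f_hz):
    """Direct DFT of the demeaned, Hann-tapered window at one bin."""
    x = np.asarray(window, dtype=float)
    n = len(x)
    x = x - x.mean()
    # symmetric Hann taper written out explicitly
    taper = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / (n - 1)))
    x = x * taper
    k = int(round(f_hz * window_s))
    coeff = np.sum(x * np.exp(-2j * np.pi * k * np.arange(n) / n))
    return np.angle(coeff)


class TestPPC:
    def test_identical_phases_give_one(self):
        assert ppc(np.full(10, 1.234)) == pytest.approx(1.0)

    def test_three_spread_angles(self):
        # pairs: cos(pi/2) + cos(pi) + cos(pi/2) = -1, times 2/6
        assert ppc(np.array([0.0, np.pi / 2, np.pi])) \
            == pytest.approx(-1.0 / 3.0)

    def test_matches_bruteforce_on_random_angles(self, rng):
        for n in (2, 3, 17, 200):
            angles = rng.uniform(-np.pi, np.pi, size=n)
            assert ppc(angles) == pytest.approx(ppc_bruteforce(angles),
                                                abs=1e-10)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-np.pi, np.pi), min_size=2, max_size=40))
    def test_identity_equals_pairwise_sum(self, angles):
        assert ppc(np.array(angles)) == pytest.approx(
            ppc_bruteforce(angles), abs=1e-10)

    def test_uniform_phases_average_to_zero(self, rng):
        means = [ppc(rng.uniform(-np.pi, np.pi, size=10000))
                 for _ in range(100)]
        assert abs(np.mean(means)) < 0.01

    def test_unbiased_by_event_count(self, rng):
        # phases from a fixed von Mises distribution: the expected PPC
        # is the squared population phase-locking, independent of N
        mean10 = np.mean([ppc(rng.vonmises(0.0, 1.0, size=10))
                          for _ in range(3000)])
        mean100 = np.mean([ppc(rng.vonmises(0.0, 1.0, size=100))
                           for _ in range(3000)])
        assert mean10 == pytest.approx(mean100, abs=0.02)

    def test_too_few_angles(self):
        with pytest.raises(ValueError):
            ppc(np.array([0.1]))

    def test_phasor_matrix_agrees_with_scalar_ppc(self, rng):
        angles = rng.uniform(-np.pi, np.pi, size=(30, 4))
        mat = ppc_from_phasors(np.exp(1j * angles))
        expected = [ppc(angles[:, k]) for k in range(4)]
        np.testing.assert_allclose(mat, expected, atol=1e-10)


class TestExtractWindows:
    def _env(self, duration_s=10.0, fs=100.0):
        values = np.abs(np.sin(np.arange(int(duration_s * fs)) / fs))
        return EnvelopeSignal(values, fs, normalization="none")

    def test_window_centered_on_onset(self):
        env = self._env()
        wins, kept = extract_windows(env, np.array([5.0]), window_s=2.0)
        assert wins.shape == (1, 200)
        assert kept.all()
        np.testing.assert_array_equal(wins[0], env.values[400:600])

    def test_boundary_onset_dropped(self):
        env = self._env()
        wins, kept = extract_windows(env, np.array([0.5, 5.0]), window_s=2.0)
        assert kept.tolist() == [False, True]
        assert wins.shape == (1, 200)

    def test_no_window_fits(self):
        env = self._env(duration_s=1.0)
        with pytest.raises(ValueError):
            extract_windows(env, np.array([0.5]), window_s=2.0)

    @pytest.mark.parametrize("window_s,spacing", [(2.0, 0.5), (4.0, 0.25)])
    def test_bin_spacing_exact(self, window_s, spacing):
        env = self._env(duration_s=20.0)
        wins, _ = extract_windows(env, np.array([10.0]), window_s)
        assert wins.shape[1] == round(window_s * 100)
        freqs, _ = window_phases(wins, window_s)
        assert freqs[0] == spacing
        assert np.all(np.diff(freqs) == spacing)


class TestWindowPhases:
    FS = 100.0

    def _phases_of(self, x, window_s=2.0):
        return window_phases(x[None, :], window_s)

    def test_cosine_phase_zero_at_its_bin(self):
        t = np.arange(200) / self.FS
        freqs, phases = self._phases_of(np.cos(2 * np.pi * 1.0 * t))
        assert abs(phases[0, freqs == 1.0][0]) < 0.01

    def test_sine_phase_minus_half_pi(self):
        t = np.arange(200) / self.FS
        freqs, phases = self._phases_of(np.sin(2 * np.pi * 1.0 * t))
        assert phases[0, freqs == 1.0][0] == pytest.approx(-np.pi / 2,
                                                           abs=0.01)

    def test_matches_direct_dft_oracle(self, rng):
        x = rng.uniform(0, 1, size=200)
        freqs, phases = self._phases_of(x)
        for f in (0.5, 1.0, 2.5, 7.0):
            assert phases[0, freqs == f][0] == pytest.approx(
                dft_phase_oracle(x, 2.0, f), abs=1e-9)

    def test_constant_window_phases_undefined(self, caplog):
        with caplog.at_level("WARNING", logger="iurhythm.phase_consistency"):
            freqs, phases = self._phases_of(np.full(200, 0.3))
        assert np.all(np.isnan(phases))
        assert any("undefined" in r.message for r in caplog.records)

    def test_phases_in_principal_range(self, rng):
        x = rng.uniform(0, 1, size=(5, 200))
        _, phases = window_phases(x, 2.0)
        assert np.all(phases > -np.pi - 1e-12)
        assert np.all(phases <= np.pi + 1e-12)


class TestSpeakerSpectrum:
    def _periodic_case(self, n_onsets, period=1.0, fs=100.0, noise=0.0):
        duration = (n_onsets + 3) * period
        t = np.arange(int(duration * fs)) / fs
        values = 0.5 * (1.0 + np.cos(2 * np.pi * t / period))
        if noise:
            values += noise * np.random.default_rng(11).uniform(
                0, 1, size=len(values))
        env = EnvelopeSignal(values, fs, normalization="none")
        onsets = period * np.arange(2, 2 + n_onsets)
        records = tuple(IURecord(o, o + 0.5 * period, "A") for o in onsets)
        return env, IUAnnotation(records)

    def test_five_onsets_excluded(self):
        env, ann = self._periodic_case(5)
        with pytest.raises(ValueError, match="more than 5"):
            speaker_spectrum(env, ann, "A")
        assert speaker_spectra(env, ann) == []

    def test_six_onsets_included(self):
        env, ann = self._periodic_case(6)
        spec = speaker_spectrum(env, ann, "A")
        assert spec.n_events == 6
        assert np.all(np.abs(spec.ppc) <= 1 + 1e-12)

    def test_periodic_onsets_peak_at_fundamental(self):
        # noise gives the non-harmonic bins inconsistent phases; the 1 Hz
        # component is locked to the strictly periodic onsets
        env, ann = self._periodic_case(40, noise=0.3)
        spec = speaker_spectrum(env, ann, "A")
        f = spec.frequencies_hz
        at_1hz = spec.ppc[f == 1.0][0]
        competitors = (f >= 2.5) & (f <= 5.0) & (f % 1.0 != 0)
        assert np.all(at_1hz > spec.ppc[competitors])


class TestGroupSpectrum:
    def _spec(self, values, speaker="A"):
        values = np.asarray(values, dtype=float)
        freqs = 0.5 * np.arange(1, len(values) + 1)
        return ConsistencySpectrum(freqs, values, n_events=10,
                                   speaker_id=speaker)

    def test_single_speaker_degenerate_ci(self):
        g = group_spectrum([self._spec([0.2, 0.4])], seed=0)
        np.testing.assert_allclose(g.mean_ppc, [0.2, 0.4])
        np.testing.assert_allclose(g.ci_low, g.mean_ppc)
        np.testing.assert_allclose(g.ci_high, g.mean_ppc)

    def test_identical_speakers_zero_width_ci(self):
        g = group_spectrum([self._spec([0.3, 0.1], "A"),
                            self._spec([0.3, 0.1], "B")], seed=0)
        np.testing.assert_allclose(g.ci_high - g.ci_low, 0.0)

    def test_mismatched_grids_rejected(self):
        a = self._spec([0.1, 0.2], "A")
        b = ConsistencySpectrum(np.array([0.25, 0.5]), np.array([0.1, 0.2]),
                                n_events=10, speaker_id="B")
        with pytest.raises(ValueError, match="B"):
            group_spectrum([a, b], seed=0)

    def test_bootstrap_ci_covers_true_mean(self, rng):
        # 20 speakers per replicate with PPC scattered around a known mean
        true_mean = 0.30
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            spectra = [
                self._spec(np.clip(
                    true_mean + 0.08 * rng.standard_normal(3), -1, 1),
                    speaker=f"S{i}")
                for i in range(20)
            ]
            g = group_spectrum(spectra, n_boot=500, seed=rng)
            hits += int(np.sum((g.ci_low <= true_mean)
                               & (true_mean <= g.ci_high)))
        # percentile bootstrap at n=20 speakers: near-nominal per-bin coverage
        assert hits / (3 * n_rep) >= 0.90

    def test_multispeaker_windows_keep_overlapping_speech(self, short_synth):
        # windows are extracted from the shared envelope, so speech by the
        # other participant inside a window is retained by construction
        env, ann = short_synth
        spectra = speaker_spectra(env, ann)
        assert len(spectra) == 2
        g = group_spectrum(spectra, seed=0)
        assert g.n_speakers == 2
        assert np.all(g.ci_low <= g.mean_ppc + 1e-12)
        assert np.all(g.mean_ppc <= g.ci_high + 1e-12)
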