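"""State-wise multitaper spectra and NNMF frequency modes."""

import numpy as np
import pytest

from tdehmm import (BAND_ANCHORS, MultitaperConfig, SubjectTimeSeries,
                    cohort_spectra, collapse_to_bands, nnmf_frequency_modes,
                    state_multitaper)
from tdehmm.spectral import FrequencyModes, StateSpectra, \
    _count_local_maxima


def _sinusoid_subject(freq, fs=100.0, T=3000, n_ch=2, noise=0.0, seed=0,
                      lag_quarter=False):
    rng = np.random.default_rng(seed)
    t = np.arange(T) / fs
    x = np.sin(2 * np.pi * freq * t)
    data = np.tile(x, (n_ch, 1))
    if lag_quarter:
        data[1] = np.sin(2 * np.pi * freq * t + np.pi / 2)
    data += noise * rng.normal(size=data.shape)
    return SubjectTimeSeries(data, fs=fs, subject_id="s0")


class TestStateMultitaper:
    def test_psd_peak_at_oscillation(self):
        ts = _sinusoid_subject(10.0)
        gamma = np.ones((ts.n_samples, 1))
        freqs, psd, coh, _ = state_multitaper(ts, gamma)
        assert freqs[np.argmax(psd[0, :, 0])] == pytest.approx(10.0,
                                                               abs=0.6)

    def test_self_coherence_is_one(self):
        ts = _sinusoid_subject(10.0, noise=0.3)
        gamma = np.ones((ts.n_samples, 1))
        _, _, coh, _ = state_multitaper(ts, gamma)
        assert np.allclose(coh[0, :, 0, 0], 1.0)
        assert np.allclose(coh[0, :, 1, 1], 1.0)

    def test_lagged_copy_coherent_at_oscillation_only(self):
        """A 90-degree lagged copy plus independent noise is highly
        coherent at the oscillation bin and weakly elsewhere."""
        ts = _sinusoid_subject(10.0, T=6000, noise=0.1, lag_quarter=True,
                               seed=1)
        gamma = np.ones((ts.n_samples, 1))
        freqs, _, coh, _ = state_multitaper(ts, gamma)
        at = np.argmin(np.abs(freqs - 10.0))
        c = coh[0, :, 0, 1]
        assert c[at] >= 0.9
        away = np.abs(freqs - 10.0) > 3.0
        assert np.median(c[away]) <= 0.3

    def test_cross_spectra_hermitian(self):
        ts = _sinusoid_subject(8.0, noise=0.2, lag_quarter=True)
        gamma = np.ones((ts.n_samples, 1))
        _, _, _, csd = state_multitaper(ts, gamma, return_csd=True)
        assert np.allclose(csd[0], np.conj(np.swapaxes(csd[0], 1, 2)))

    def test_never_active_state_flagged_missing(self):
        ts = _sinusoid_subject(10.0)
        gamma = np.zeros((ts.n_samples, 2))
        gamma[:, 0] = 1.0
        _, psd, coh, _ = state_multitaper(ts, gamma)
        assert np.isnan(psd[1]).all() and np.isnan(coh[1]).all()
        assert np.isfinite(psd[0]).all()

    def test_misaligned_gamma_rejected(self):
        ts = _sinusoid_subject(10.0)
        with pytest.raises(ValueError, match="align"):
            state_multitaper(ts, np.ones((ts.n_samples - 14, 1)))

    def test_parseval_on_bandlimited_signal(self):
        """Gamma-weighted variance matches the integrated PSD within 15%
        on an in-band signal."""
        ts = _sinusoid_subject(12.0, T=6000, noise=0.15, seed=2)
        gamma = np.ones((ts.n_samples, 1))
        freqs, psd, _, _ = state_multitaper(ts, gamma)
        df = freqs[1] - freqs[0]
        integ = psd[0, :, 0].sum() * df
        assert integ == pytest.approx(ts.data[0].var(), rel=0.15)

    def test_state_conditional_separation(self):
        """With a hard gamma, each state's spectrum peaks at its own
        frequency even though the recording interleaves both."""
        fs, T = 100.0, 6000
        rng = np.random.default_rng(3)
        t = np.arange(T) / fs
        state = (np.sin(2 * np.pi * t / 12.0) > 0).astype(int)  # slow alt
        x = np.where(state == 0, np.sin(2 * np.pi * 7 * t),
                     np.sin(2 * np.pi * 23 * t))
        ts = SubjectTimeSeries(np.vstack([x, x + 0.
                                          + 0.1 * rng.normal(size=T)]),
                               fs=fs)
        gamma = np.eye(2)[state]
        freqs, psd, _, _ = state_multitaper(ts, gamma)
        assert freqs[np.argmax(psd[0, :, 0])] == pytest.approx(7.0, abs=1.0)
        assert freqs[np.argmax(psd[1, :, 0])] == pytest.approx(23.0,
                                                               abs=1.0)


def _band_templates(F=90):
    freqs = np.linspace(1, 45, F)
    bands = [(2, 8), (8, 14), (14, 30), (30, 45)]
    H = np.zeros((4, F))
    for m, (lo, hi) in enumerate(bands):
        c, w = (lo + hi) / 2, (hi - lo) / 2
        H[m] = np.exp(-0.5 * ((freqs - c) / (w / 2.5)) ** 2)
        H[m, np.abs(freqs - c) > w] = 0.0
    return freqs, H


class TestNnmfModes:
    def test_exact_factorization_recovered(self, rng):
        freqs, H = _band_templates()
        A = rng.uniform(0.2, 2.0, size=(300, 4))
        # sparse coefficients make the factorization identifiable
        A[rng.random(A.shape) < 0.4] = 0.0
        A = A[A.sum(axis=1) > 0]
        V = A @ H
        spectra = _as_spectra(V, freqs)
        modes = nnmf_frequency_modes(spectra, n_modes=4, n_restarts=8,
                                     seed=0)
        Hn = H / H.sum(axis=1, keepdims=True)
        for m in range(4):
            cos = (modes.mode_profiles[m] @ Hn[m]) / (
                np.linalg.norm(modes.mode_profiles[m])
                * np.linalg.norm(Hn[m]))
            assert cos >= 0.99
        assert modes.labels == ["delta/theta", "alpha", "beta", "low-gamma"]

    def test_single_mode_flat_spectra(self, rng):
        V = np.ones((40, 30)) * rng.uniform(0.5, 2.0, size=(40, 1))
        spectra = _as_spectra(V, np.linspace(1, 45, 30))
        modes = nnmf_frequency_modes(spectra, n_modes=1, n_restarts=3,
                                     seed=0)
        assert modes.reconstruction_error < 1e-3 * np.linalg.norm(V)
        assert np.ptp(modes.mode_profiles[0]) < 0.2 / 30

    def test_reconstruction_error_nested_in_modes(self, rng):
        freqs, H = _band_templates()
        V = rng.uniform(0.2, 2.0, size=(100, 4)) @ H \
            + 0.01 * rng.uniform(size=(100, 90))
        errs = []
        for m in range(1, 5):
            modes = nnmf_frequency_modes(_as_spectra(V, freqs), n_modes=m,
                                         n_restarts=4, seed=0)
            errs.append(modes.reconstruction_error)
        assert np.all(np.diff(errs) <= 1e-8)

    def test_profiles_nonnegative_and_normalized(self, rng):
        freqs, H = _band_templates()
        V = rng.uniform(0.2, 2.0, size=(60, 4)) @ H
        modes = nnmf_frequency_modes(_as_spectra(V, freqs), n_modes=4,
                                     n_restarts=4, seed=1)
        assert np.all(modes.mode_profiles >= 0)
        assert np.allclose(modes.mode_profiles.sum(axis=1), 1.0)

    def test_unimodality_counter(self):
        assert _count_local_maxima(np.exp(-np.linspace(-3, 3, 50) ** 2)) == 1
        bimodal = np.concatenate([np.exp(-np.linspace(-3, 3, 25) ** 2),
                                  np.exp(-np.linspace(-3, 3, 25) ** 2)])
        assert _count_local_maxima(bimodal) == 2


def _as_spectra(V, freqs):
    """Wrap a (samples x F) matrix as single-channel StateSpectra."""
    psd = V[:, None, :, None]
    coh = np.ones((V.shape[0], 1, freqs.size, 1, 1))
    return StateSpectra(frequencies=freqs, psd=psd, coherence=coh)


class TestCollapseToBands:
    def _modes(self, freqs, profiles, labels):
        return FrequencyModes(frequencies=freqs,
                              mode_profiles=np.asarray(profiles),
                              labels=labels,
                              peak_frequencies=np.zeros(len(labels)),
                              n_local_maxima=np.ones(len(labels)),
                              reconstruction_error=0.0)

    def test_indicator_profile_picks_single_bin(self, rng):
        freqs = np.linspace(1, 45, 20)
        psd = rng.uniform(size=(2, 3, 20, 4))
        coh = rng.uniform(size=(2, 3, 20, 4, 4))
        spectra = StateSpectra(frequencies=freqs, psd=psd, coherence=coh)
        prof = np.zeros((1, 20))
        prof[0, 7] = 1.0
        bp, bc = collapse_to_bands(spectra, self._modes(freqs, prof,
                                                        ["alpha"]))
        assert np.allclose(bp[:, :, 0, :], psd[:, :, 7, :])
        assert np.allclose(bc[:, :, 0], coh[:, :, 7])

    def test_zero_psd_gives_zero_band_power(self):
        freqs = np.linspace(1, 45, 10)
        spectra = StateSpectra(frequencies=freqs,
                               psd=np.zeros((1, 2, 10, 3)),
                               coherence=np.zeros((1, 2, 10, 3, 3)))
        prof = np.full((2, 10), 0.1)
        bp, _ = collapse_to_bands(spectra, self._modes(
            freqs, prof, ["alpha", "beta"]))
        assert np.all(bp == 0)

    def test_band_coherence_stays_bounded(self, rng):
        freqs = np.linspace(1, 45, 15)
        coh = rng.uniform(size=(2, 2, 15, 3, 3))
        spectra = StateSpectra(frequencies=freqs,
                               psd=rng.uniform(size=(2, 2, 15, 3)),
                               coherence=coh)
        prof = rng.dirichlet(np.ones(15), size=2)
        _, bc = collapse_to_bands(spectra, self._modes(
            freqs, prof, ["alpha", "beta"]))
        assert np.all(bc >= 0) and np.all(bc <= 1)

    def test_gamma_band_flagged_out_of_statistics(self):
        freqs = np.linspace(1, 45, 10)
        modes = self._modes(freqs, np.full((4, 10), 0.1),
                            ["delta/theta", "alpha", "beta", "low-gamma"])
        assert modes.statistics_mask().tolist() == [True, True, True,
                                                    False]

    def test_mismatched_grids_rejected(self, rng):
        freqs = np.linspace(1, 45, 10)
        spectra = StateSpectra(frequencies=freqs,
                               psd=rng.uniform(size=(1, 1, 10, 2)),
                               coherence=rng.uniform(size=(1, 1, 10, 2, 2)))
        modes = self._modes(np.linspace(1, 45, 11), np.full((1, 11), 1 / 11),
                            ["alpha"])
        with pytest.raises(ValueError):
            collapse_to_bands(spectra, modes)
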