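"""Filtering, instantaneous phase, and PLI against independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mstnet.connectivity import (
    BANDS,
    BandDefinition,
    ConnectivityMatrix,
    bandpass_array,
    condition_matrix,
    instantaneous_phase,
    mean_pli,
    pli_from_phases,
    pli_matrix,
    read_matrix_csv,
    write_matrix_csv,
)

FS = 128.0


def _tone(freq: float, duration: float = 20.0) -> np.ndarray:
    t = np.arange(0, duration, 1 / FS)
    return np.cos(2 * np.pi * freq * t)


class TestBandpass:
    def test_band_edges_match_canonical_definition(self):
        assert {b.name: (b.lo, b.hi) for b in BANDS.values()} == {
            "theta": (4.0, 7.0), "alpha": (7.0, 13.0), "beta1": (13.0, 20.0),
            "beta2": (20.0, 30.0), "gamma": (31.0, 45.0),
        }

    def test_in_band_tone_amplitude_preserved(self):
        x = _tone(10.0)
        y = bandpass_array(x, "alpha", FS)
        core = slice(256, -256)
        assert y[core].std() / x[core].std() == pytest.approx(1.0, rel=0.05)

    def test_out_of_band_tone_attenuated_20db(self):
        x = _tone(10.0)
        y = bandpass_array(x, "gamma", FS)
        core = slice(256, -256)
        atten_db = -20 * np.log10(y[core].std() / x[core].std())
        assert atten_db >= 20

    def test_zero_signal_passes_through_as_zero(self):
        y = bandpass_array(np.zeros((3, 1024)), "beta1", FS)
        np.testing.assert_allclose(y, 0.0, atol=1e-12)

    def test_band_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_array(np.zeros(1024), BandDefinition("wide", 31.0, 70.0), FS)


class TestInstantaneousPhase:
    def test_tone_phase_advances_at_carrier_rate(self):
        y = bandpass_array(_tone(10.0), "alpha", FS)
        ph = instantaneous_phase(y[None, :], fs=FS, edge_trim=0.5)
        slope = np.polyfit(np.arange(ph.shape[1]) / FS, np.unwrap(ph[0]), 1)[0]
        assert slope == pytest.approx(2 * np.pi * 10, rel=1e-3)

    def test_quarter_cycle_shift_gives_constant_difference(self):
        t = np.arange(0, 20, 1 / FS)
        x = np.vstack([np.cos(2 * np.pi * 10 * t), np.cos(2 * np.pi * 10 * t - np.pi / 2)])
        ph = instantaneous_phase(bandpass_array(x, "alpha", FS), fs=FS, edge_trim=0.5)
        d = np.angle(np.exp(1j * (ph[0] - ph[1])))
        assert np.abs(d - np.pi / 2).max() < 0.05

    def test_silent_channel_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_phase(np.zeros((2, 1024)), fs=FS)

    def test_trial_shorter_than_trim_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_phase(np.ones((1, 100)), fs=FS, edge_trim=0.5)


class TestPli:
    def test_constant_positive_difference_gives_one(self):
        ph = np.vstack([np.zeros(600), np.full(600, -np.pi / 3)])
        assert pli_from_phases(ph)[0, 1] == 1.0

    def test_symmetric_alternating_difference_gives_zero(self):
        d = np.tile([np.pi / 6, -np.pi / 6], 300)
        ph = np.vstack([np.zeros(600), d])
        assert pli_from_phases(ph)[0, 1] == 0.0

    def test_hand_counted_eight_sample_series(self):
        # five positive-sign samples, three negative: |5 - 3| / 8 = 0.25
        ph = np.vstack([np.zeros(8), np.array([-0.1] * 5 + [0.1] * 3)])
        assert pli_from_phases(ph)[0, 1] == pytest.approx(0.25)

    def test_exact_zero_and_pi_differences_contribute_nothing(self):
        ph = np.vstack([np.zeros(4), np.array([0.0, np.pi, 0.0, np.pi])])
        assert pli_from_phases(ph)[0, 1] == 0.0

    @settings(derandomize=True, max_examples=30)
    @given(shift=st.floats(-10, 10), seed=st.integers(0, 10_000))
    def test_global_phase_shift_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        ph = rng.uniform(-np.pi, np.pi, size=(3, 200))
        np.testing.assert_allclose(
            pli_from_phases(ph), pli_from_phases(ph + shift), atol=1e-12
        )

    def test_matrix_is_symmetric_in_zero_one_with_zero_diagonal(self, rng):
        ph = rng.uniform(-np.pi, np.pi, size=(6, 800))
        m = pli_from_phases(ph)
        np.testing.assert_array_equal(m, m.T)
        assert np.all(np.diag(m) == 0)
        assert m.min() >= 0 and m.max() <= 1

    def test_independent_noise_pli_near_zero(self, rng):
        n = 4096
        vals = [
            pli_from_phases(rng.uniform(-np.pi, np.pi, size=(2, n)))[0, 1]
            for _ in range(10)
        ]
        assert np.mean(vals) < 3 / np.sqrt(n)

    def test_nan_phases_rejected(self):
        ph = np.zeros((2, 600))
        ph[1, 0] = np.nan
        with pytest.raises(ValueError):
            pli_from_phases(ph)

    def test_short_series_rejected_by_matrix_wrapper(self):
        with pytest.raises(ValueError):
            pli_matrix(np.zeros((2, 100)), ["a", "b"])


class TestMeanPli:
    def test_constant_offdiagonal(self):
        m = np.full((5, 5), 0.3)
        np.fill_diagonal(m, 0)
        assert mean_pli(m) == pytest.approx(0.3)

    def test_single_nonzero_pair_on_32_nodes(self):
        m = np.zeros((32, 32))
        m[0, 1] = m[1, 0] = 1.0
        assert mean_pli(m) == pytest.approx(1 / 496)

    def test_zero_matrix(self):
        assert mean_pli(np.zeros((8, 8))) == 0.0


def _random_cm(rng, subject="s1", band="gamma"):
    a = rng.uniform(0, 1, size=(5, 5))
    m = (a + a.T) / 2
    np.fill_diagonal(m, 0)
    return ConnectivityMatrix(m, band=band, channel_names=list("abcde"),
                              subject_id=subject)


class TestConditionMatrix:
    def test_single_trial_passthrough(self, rng):
        m = _random_cm(rng)
        avg = condition_matrix([m])
        np.testing.assert_array_equal(avg.values, m.values)
        assert avg.n_trials_averaged == 1

    def test_three_trials_equal_elementwise_mean(self, rng):
        mats = [_random_cm(rng) for _ in range(3)]
        avg = condition_matrix(mats)
        np.testing.assert_allclose(
            avg.values, np.mean([m.values for m in mats], axis=0)
        )
        assert avg.n_trials_averaged == 3

    def test_mixed_band_or_subject_rejected(self, rng):
        with pytest.raises(ValueError):
            condition_matrix([_random_cm(rng), _random_cm(rng, band="theta")])
        with pytest.raises(ValueError):
            condition_matrix([_random_cm(rng), _random_cm(rng, subject="s2")])


class TestMatrixContainer:
    def test_invalid_matrices_rejected(self):
        bad = np.array([[0.0, 0.4], [0.5, 0.0]])
        with pytest.raises(ValueError):
            ConnectivityMatrix(bad, band="gamma", channel_names=["a", "b"])
        with pytest.raises(ValueError):
            ConnectivityMatrix(
                np.array([[0.1, 0.4], [0.4, 0.0]]), band="gamma",
                channel_names=["a", "b"],
            )
        with pytest.raises(ValueError):
            ConnectivityMatrix(
                np.array([[0.0, 1.4], [1.4, 0.0]]), band="gamma",
                channel_names=["a", "b"],
            )

    def test_csv_roundtrip(self, rng, tmp_path):
        m = _random_cm(rng)
        path = write_matrix_csv(m, tmp_path / "m.csv")
        back = read_matrix_csv(path, band="gamma", subject_id="s1")
        np.testing.assert_allclose(back.values, m.values, atol=1e-9)
        assert list(back.channel_names) == list(m.channel_names)
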