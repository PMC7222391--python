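"""Band-pass filtering, instantaneous phase, and phase lag index (PLI) matrices.

The PLI between two signals quantifies the asymmetry of their phase-difference
distribution:

    PLI(i, j) = | < sign(delta_phi_ij(t)) >_t |,   delta_phi wrapped to (-pi, pi]

where samples with a phase difference of exactly 0 or pi contribute 0. A PLI
of 0 means no consistent lead/lag relation — in particular, zero-lag signal
spread from a common source (volume conduction) produces symmetric phase
differences and is rejected by construction. A PLI of 1 means one channel's
phase always leads the other's.

Phases are taken from the analytic signal (Hilbert transform) of the
band-pass-filtered trial; a short stretch at each end is trimmed before the
PLI is computed to suppress filter and transform edge effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.fft import next_fast_len

from .trial_io import TrialRecording

__all__ = [
    "BandDefinition",
    "BANDS",
    "ConnectivityMatrix",
    "bandpass",
    "bandpass_array",
    "instantaneous_phase",
    "pli_matrix",
    "pli_from_phases",
    "mean_pli",
    "condition_matrix",
    "trial_connectivity",
    "write_matrix_csv",
    "read_matrix_csv",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with edges in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"invalid band edges ({self.lo}, {self.hi})")


#: The five canonical analysis bands.
BANDS: dict[str, BandDefinition] = {
    "theta": BandDefinition("theta", 4.0, 7.0),
    "alpha": BandDefinition("alpha", 7.0, 13.0),
    "beta1": BandDefinition("beta1", 13.0, 20.0),
    "beta2": BandDefinition("beta2", 20.0, 30.0),
    "gamma": BandDefinition("gamma", 31.0, 45.0),
}


def get_band(band: str | BandDefinition) -> BandDefinition:
    if isinstance(band, BandDefinition):
        return band
    try:
        return BANDS[band]
    except KeyError:
        raise KeyError(f"unknown band {band!r}; known: {sorted(BANDS)}") from None


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel PLI matrix for one subject/condition/band.

    Invariants: symmetric, zero diagonal, entries in [0, 1].
    """

    values: np.ndarray
    band: str
    channel_names: Sequence[str]
    subject_id: str | None = None
    condition: str | None = None
    n_trials_averaged: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"matrix must be square, got {v.shape}")
        if len(self.channel_names) != v.shape[0]:
            raise ValueError("channel name count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("PLI matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("PLI matrix diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("PLI entries must lie in [0, 1]")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# Filtering and phase extraction
# ---------------------------------------------------------------------------

def _design_fir(band: BandDefinition, fs: float) -> np.ndarray:
    """Zero-phase band-pass FIR (Hamming window design).

    Transition width is 25% of the band width; the Hamming window's empirical
    transition-width constant (~3.3 cycles) sets the tap count.
    """
    if band.hi >= fs / 2:
        raise ValueError(
            f"band {band.name} upper edge {band.hi} Hz at/above Nyquist ({fs / 2} Hz)"
        )
    width = 0.25 * (band.hi - band.lo)
    numtaps = int(np.ceil(3.3 * fs / width))
    numtaps += 1 - numtaps % 2  # odd for a type-I linear-phase filter
    return sp_signal.firwin(
        numtaps, [band.lo, band.hi], pass_zero=False, fs=fs, window="hamming"
    )


def bandpass_array(data: np.ndarray, band: str | BandDefinition, fs: float) -> np.ndarray:
    """Zero-phase band-pass of a (..., samples) array.

    The symmetric (linear-phase) FIR is applied in a single FFT-based pass
    with centred alignment, which is exactly zero-phase; edges are
    reflect-padded by half the filter length to avoid boundary droop.
    """
    band = get_band(band)
    taps = _design_fir(band, fs)
    data = np.asarray(data, dtype=float)
    squeeze = data.ndim == 1
    data = np.atleast_2d(data)
    pad = len(taps) // 2
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(pad, pad)], mode="reflect")
    out = sp_signal.fftconvolve(padded, taps[None, :], mode="same", axes=-1)
    out = out[..., pad:-pad]
    return out[0] if squeeze else out


def bandpass(trial: TrialRecording, band: str | BandDefinition) -> TrialRecording:
    """Band-pass filter a trial; same shape, zero phase distortion."""
    out = bandpass_array(trial.data, band, trial.fs)
    return TrialRecording(
        subject_id=trial.subject_id,
        trial_id=trial.trial_id,
        data=out,
        fs=trial.fs,
        channel_names=trial.channel_names,
    )


def instantaneous_phase(
    filtered: TrialRecording | np.ndarray,
    fs: float | None = None,
    edge_trim: float = 0.5,
) -> np.ndarray:
    """Per-channel instantaneous phase (radians) of a narrowband signal.

    The analytic signal is built with the Hilbert transform; ``edge_trim``
    seconds are removed from both ends to discard filter/transform edge
    artefacts. Channels that are (numerically) silent have no defined phase
    and raise a ValueError.
    """
    if isinstance(filtered, TrialRecording):
        data, fs = filtered.data, filtered.fs
    else:
        data = np.asarray(filtered, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    n = data.shape[-1]
    trim = int(round(edge_trim * fs))
    if n <= 2 * trim:
        raise ValueError(
            f"trial of {n} samples too short for edge_trim={edge_trim} s at {fs} Hz"
        )
    rms = np.sqrt(np.mean(data**2, axis=-1))
    if np.any(rms < 1e-12 * max(1.0, float(np.max(rms)))) or np.all(rms == 0):
        raise ValueError("degenerate (silent) channel: instantaneous phase undefined")
    nfft = next_fast_len(n)
    analytic = sp_signal.hilbert(data, N=nfft, axis=-1)[..., :n]
    phases = np.angle(analytic)
    return phases[..., trim : n - trim] if trim else phases


# ---------------------------------------------------------------------------
# PLI
# ---------------------------------------------------------------------------

def pli_from_phases(phases: np.ndarray) -> np.ndarray:
    """PLI matrix from a channels x samples phase array.

    Uses sign(sin(delta_phi)), which equals the sign of the wrapped phase
    difference on (-pi, pi] and maps differences of exactly 0 or pi to 0.
    """
    phases = np.asarray(phases, dtype=float)
    if not np.isfinite(phases).all():
        raise ValueError("phase array contains NaN/Inf")
    n_ch = phases.shape[0]
    out = np.zeros((n_ch, n_ch))
    # pairwise loop over the upper triangle keeps peak memory at O(samples)
    for i in range(n_ch):
        d = np.sin(phases[i + 1 :, :] - phases[i, :])
        s = np.sign(d)
        s[np.abs(d) < 1e-9] = 0.0
        out[i, i + 1 :] = np.abs(s.mean(axis=-1))
    return out + out.T


def pli_matrix(
    phases: np.ndarray,
    channel_names: Sequence[str],
    band: str = "",
    subject_id: str | None = None,
    condition: str | None = None,
) -> ConnectivityMatrix:
    """Wrap :func:`pli_from_phases` in a :class:`ConnectivityMatrix`."""
    if phases.shape[-1] < 512:
        raise ValueError(
            f"need >= 512 usable samples for a stable PLI, got {phases.shape[-1]}"
        )
    return ConnectivityMatrix(
        values=pli_from_phases(phases),
        band=band,
        channel_names=channel_names,
        subject_id=subject_id,
        condition=condition,
    )


def mean_pli(matrix: ConnectivityMatrix | np.ndarray) -> float:
    """Whole-network mean PLI: average over all off-diagonal upper-triangle pairs."""
    v = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    iu = np.triu_indices(v.shape[0], k=1)
    return float(v[iu].mean())


def trial_connectivity(
    trial: TrialRecording, band: str | BandDefinition, edge_trim: float = 0.5
) -> ConnectivityMatrix:
    """Full per-trial chain: band-pass -> analytic phase -> PLI matrix."""
    band = get_band(band)
    filt = bandpass_array(trial.data, band, trial.fs)
    phases = instantaneous_phase(filt, fs=trial.fs, edge_trim=edge_trim)
    return pli_matrix(
        phases,
        channel_names=trial.channel_names,
        band=band.name,
        subject_id=trial.subject_id,
    )


def condition_matrix(matrices: Iterable[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of per-trial PLI matrices for one subject x condition.

    All inputs must share band, subject and shape; the trial count is recorded
    in ``n_trials_averaged``.
    """
    mats = list(matrices)
    if not mats:
        raise ValueError("need at least one trial matrix")
    first = mats[0]
    for m in mats[1:]:
        if m.band != first.band:
            raise ValueError(f"mixed bands: {m.band} vs {first.band}")
        if m.subject_id != first.subject_id:
            raise ValueError(f"mixed subjects: {m.subject_id} vs {first.subject_id}")
        if m.values.shape != first.values.shape:
            raise ValueError("mixed matrix sizes")
    mean = np.mean([m.values for m in mats], axis=0)
    return ConnectivityMatrix(
        values=mean,
        band=first.band,
        channel_names=first.channel_names,
        subject_id=first.subject_id,
        condition=first.condition,
        n_trials_averaged=len(mats),
    )


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def write_matrix_csv(matrix: ConnectivityMatrix, path: str | Path) -> Path:
    """Square CSV with a channel-name header row/index."""
    path = Path(path)
    df = pd.DataFrame(
        matrix.values, index=matrix.channel_names, columns=matrix.channel_names
    )
    df.to_csv(path, float_format="%.10g")
    return path


def read_matrix_csv(
    path: str | Path,
    band: str = "",
    subject_id: str | None = None,
    condition: str | None = None,
    n_trials_averaged: int = 1,
) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConnectivityMatrix(
        values=df.to_numpy(dtype=float),
        band=band,
        channel_names=list(df.columns),
        subject_id=subject_id,
        condition=condition,
        n_trials_averaged=n_trials_averaged,
    )
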