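"""Synthetic multi-channel studies with known phase-coupling ground truth.

The generator produces trials whose phase-lag structure is planted, so every
downstream stage (PLI, spanning trees, group statistics) can be validated
against a known answer. The signal model, per trial:

* every coupled pair (i, j) shares a narrowband Gaussian-noise carrier inside
  a chosen frequency band; channel j receives a phase-shifted copy of the
  carrier (shift = the pair's phase lag plus slowly varying wrapped-Gaussian
  jitter) mixed with independent narrowband noise at level
  ``1 - coupling_strength``. The mixing weight gives a closed, monotone link
  between coupling strength and the expected PLI without integrating an ODE;
* channels in no pair carry independent narrowband noise in the coupling
  band, so their pairwise PLI is null but their phase stays defined;
* a single zero-lag narrowband source is added to *all* channels scaled by
  ``common_source_gain`` — a volume-conduction-like confound that the PLI is
  designed to reject;
* background narrowband noise fills the remaining canonical bands, and white
  measurement noise of standard deviation ``noise_sd`` is added throughout.

Group studies follow a 2 (arousal) x 2 (valence) within-subject design:
condition coupling = baseline + arousal_effect for high arousal
+ valence_effect for low valence + interaction_effect when both apply, plus
a Gaussian per-subject intercept. The sign conventions mirror the direction
in which emotional arousal and negative valence strengthen gamma-band
phase coupling; both are configurable. The default planted topology is a
hub-and-spokes (star) graph, so stronger coupling pulls the spanning tree
toward a star shape (higher leaf fraction and maximum degree, lower diameter
and eccentricity).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import BANDS, BandDefinition, get_band
from .trial_io import (
    CHANNELS_32,
    CONDITIONS,
    Study,
    SubjectBundle,
    TrialLabels,
    TrialRecording,
)

__all__ = [
    "GroundTruthGraph",
    "CoupledPair",
    "GroupSimConfig",
    "SyntheticStudy",
    "ConfigurationError",
    "generate_trial",
    "generate_group",
    "star_pairs",
    "write_truth_csv",
]


class ConfigurationError(ValueError):
    """Raised when simulation parameters violate their contracts."""


@dataclass(frozen=True)
class CoupledPair:
    """One planted coupling: channel ``i`` leads channel ``j`` by ``lag`` radians.

    ``strength`` in [0, 1] is the mixing weight of the leader's oscillation in
    the follower. The lag must be nonzero modulo pi — a lag of exactly 0 or pi
    yields a symmetric sign distribution that the PLI cannot see, by
    construction.
    """

    i: int
    j: int
    strength: float
    lag: float

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ConfigurationError(f"self-pair ({self.i}, {self.j})")
        if not (0.0 <= self.strength <= 1.0):
            raise ConfigurationError(f"coupling strength {self.strength} outside [0, 1]")
        if abs(np.sin(self.lag)) < 1e-9:
            raise ConfigurationError(
                f"phase lag {self.lag} is 0 mod pi; the PLI is blind to it"
            )


@dataclass(frozen=True)
class GroundTruthGraph:
    """The planted coupling graph for one subject x condition."""

    n_channels: int
    pairs: tuple[CoupledPair, ...]
    common_source_gain: float = 0.0

    def __post_init__(self) -> None:
        if self.common_source_gain < 0:
            raise ConfigurationError("common_source_gain must be >= 0")
        for p in self.pairs:
            if not (0 <= p.i < self.n_channels and 0 <= p.j < self.n_channels):
                raise ConfigurationError(
                    f"pair ({p.i}, {p.j}) outside 0..{self.n_channels - 1}"
                )


def star_pairs(
    n_channels: int, hub: int, strength: float, lag: float = np.pi / 4
) -> tuple[CoupledPair, ...]:
    """Hub-and-spokes coupling: the hub leads every other channel by ``lag``."""
    return tuple(
        CoupledPair(i=hub, j=k, strength=strength, lag=lag)
        for k in range(n_channels)
        if k != hub
    )


# ---------------------------------------------------------------------------
# Single-trial synthesis
# ---------------------------------------------------------------------------

def _analytic_noise(
    rng: np.random.Generator, m: int, n: int, band: BandDefinition, fs: float
) -> np.ndarray:
    """``m`` independent analytic narrowband Gaussian-noise series of length ``n``.

    Synthesized spectrally: i.i.d. complex Gaussian coefficients on the
    positive frequencies inside the band, zero elsewhere, inverse FFT. The
    one-sided spectrum makes the series analytic by construction; each row's
    real part is scaled to unit variance.
    """
    freqs = np.fft.fftfreq(n, d=1.0 / fs)
    mask = (freqs >= band.lo) & (freqs <= band.hi)
    k = int(mask.sum())
    if k == 0:
        raise ConfigurationError(
            f"band {band.name} contains no FFT bins at n={n}, fs={fs}"
        )
    spectrum = np.zeros((m, n), dtype=complex)
    spectrum[:, mask] = rng.standard_normal((m, k)) + 1j * rng.standard_normal((m, k))
    z = np.fft.ifft(spectrum, axis=-1)
    z /= z.real.std(axis=-1, keepdims=True)
    return z


def _slow_jitter(
    rng: np.random.Generator, m: int, n: int, fs: float, sds: np.ndarray
) -> np.ndarray:
    """``m`` slowly varying Gaussian phase-jitter series with pointwise SDs ``sds``."""
    from scipy.ndimage import uniform_filter1d

    win = max(3, int(round(0.5 * fs)))  # ~0.5 s smoothing: slow relative to the carrier
    z = uniform_filter1d(rng.standard_normal((m, n + win)), win, axis=-1)
    z = z[:, win // 2 : win // 2 + n]
    z_sd = z.std(axis=-1, keepdims=True)
    z_sd[z_sd == 0] = 1.0
    return z / z_sd * np.asarray(sds)[:, None]


def generate_trial(
    truth: GroundTruthGraph,
    band: str | BandDefinition,
    fs: float = 128.0,
    duration: float = 60.0,
    noise_sd: float = 0.5,
    seed: int | np.random.Generator = 0,
    subject_id: str = "sim",
    trial_id: int = 0,
    channel_names: Sequence[str] | None = None,
    background: bool = True,
    return_phases: bool = False,
):
    """Synthesize one trial with the planted coupling of ``truth``.

    Every channel owns a latent analytic narrowband oscillation. A coupled
    pair mixes the leader's oscillation, rotated by the pair's phase lag plus
    slow wrapped-Gaussian jitter of SD ``(1 - strength) * pi/2``, into the
    follower at weight ``strength``; the follower keeps its own oscillation
    at weight ``1 - strength``. Channels in no pair keep their own
    oscillation untouched.

    Returns a :class:`~mstnet.trial_io.TrialRecording`; with
    ``return_phases=True`` also returns the generator's own phase series per
    channel (the angle of the in-band analytic component), a filter-free
    reference for the downstream PLI.
    """
    band = get_band(band)
    n = int(round(fs * duration))
    if n < 512:
        raise ConfigurationError(
            f"duration*fs = {n} samples < 512; PLI needs longer trials"
        )
    if band.lo < 4.0 or band.hi > 45.0:
        raise ConfigurationError(f"band {band.name} outside the 4-45 Hz analysis range")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_ch = truth.n_channels
    if channel_names is None:
        channel_names = (
            CHANNELS_32 if n_ch == 32 else tuple(f"ch{k:02d}" for k in range(n_ch))
        )

    latents = _analytic_noise(rng, n_ch, n, band, fs)
    pairs = truth.pairs
    inband = latents.copy()
    if pairs:
        jitter = _slow_jitter(
            rng, len(pairs), n, fs,
            np.array([(1.0 - p.strength) * np.pi / 2.0 for p in pairs]),
        )
        incoming = np.zeros((n_ch, n), dtype=complex)
        incoming_power = np.zeros(n_ch)
        own_weight = np.ones(n_ch)
        for p, eta in zip(pairs, jitter):
            incoming[p.j] += p.strength * latents[p.i] * np.exp(-1j * (p.lag + eta))
            incoming_power[p.j] += p.strength**2
            own_weight[p.j] = min(own_weight[p.j], 1.0 - p.strength)
        inband = own_weight[:, None] * latents + incoming
        norm = np.sqrt(own_weight**2 + incoming_power)
        norm[norm == 0] = 1.0
        inband /= norm[:, None]

    data = inband.real.copy()

    if truth.common_source_gain > 0:
        common = _analytic_noise(rng, 1, n, band, fs).real[0]
        data += truth.common_source_gain * common

    if background:
        for other in BANDS.values():
            if other.hi <= band.lo or other.lo >= band.hi:
                data += 0.5 * _analytic_noise(rng, n_ch, n, other, fs).real

    if noise_sd > 0:
        data += noise_sd * rng.standard_normal((n_ch, n))

    trial = TrialRecording(
        subject_id=subject_id,
        trial_id=trial_id,
        data=data,
        fs=fs,
        channel_names=channel_names,
    )
    if return_phases:
        return trial, np.angle(inband)
    return trial


# ---------------------------------------------------------------------------
# Group studies (2 x 2 within-subject design)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSimConfig:
    """Parameters of a simulated 2x2 within-subject study.

    Condition coupling is ``baseline_coupling`` plus ``arousal_effect`` for
    high-arousal conditions, ``valence_effect`` for low-valence conditions and
    ``interaction_effect`` when both hold; the resulting strengths must stay
    in [0, 1]. Each subject adds a Gaussian intercept (``subject_sd``) to the
    baseline, making the within-subject design meaningful.
    """

    n_subjects: int = 32
    trials_per_condition: int = 10
    band_of_effect: str = "gamma"
    baseline_coupling: float = 0.4
    arousal_effect: float = 0.0
    valence_effect: float = 0.0
    interaction_effect: float = 0.0
    noise_sd: float = 0.5
    fs: float = 128.0
    duration: float = 60.0
    seed: int = 0
    subject_sd: float = 0.05
    common_source_gain: float = 0.5
    hub_channel: int = 7  # T7 in the 32-channel montage
    phase_lag: float = np.pi / 4
    n_channels: int = 32

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("need n_subjects >= 2")
        if self.trials_per_condition < 1:
            raise ConfigurationError("need trials_per_condition >= 1")
        if self.fs <= 0 or self.duration <= 0:
            raise ConfigurationError("fs and duration must be positive")
        for cond in CONDITIONS:
            c = self.condition_coupling(cond)
            if not (0.0 <= c <= 1.0):
                raise ConfigurationError(
                    f"condition {cond} coupling {c:.3f} outside [0, 1]; "
                    "shrink the effects or move the baseline"
                )

    def condition_coupling(self, condition: str) -> float:
        """Planted coupling strength for a condition, before subject intercepts."""
        high_arousal = condition.startswith("HA")
        low_valence = condition.endswith("LV")
        c = self.baseline_coupling
        if high_arousal:
            c += self.arousal_effect
        if low_valence:
            c += self.valence_effect
        if high_arousal and low_valence:
            c += self.interaction_effect
        return c


@dataclass
class SyntheticStudy:
    """A generated study: subject bundles plus the planted ground truth."""

    study: Study
    truth: dict[tuple[str, str], GroundTruthGraph]  # (subject_id, condition) -> graph
    config: GroupSimConfig


def _condition_labels(rng: np.random.Generator, condition: str) -> TrialLabels:
    """Ratings drawn uniformly inside the condition's high/low intervals."""
    high_arousal = condition.startswith("HA")
    high_valence = condition.endswith("HV")
    arousal = rng.uniform(6.0, 9.0) if high_arousal else rng.uniform(1.0, 4.0)
    valence = rng.uniform(6.0, 9.0) if high_valence else rng.uniform(1.0, 4.0)
    return TrialLabels(valence=float(valence), arousal=float(arousal))


def generate_group(config: GroupSimConfig) -> SyntheticStudy:
    """Generate a full 2x2 within-subject study. Deterministic per seed."""
    root = np.random.SeedSequence(config.seed)
    subj_seqs = root.spawn(config.n_subjects)
    subjects: list[SubjectBundle] = []
    truth: dict[tuple[str, str], GroundTruthGraph] = {}

    for s_idx, seq in enumerate(subj_seqs):
        subject_id = f"sub{s_idx + 1:02d}"
        rng = np.random.default_rng(seq)
        intercept = rng.normal(0.0, config.subject_sd)
        trials: list[TrialRecording] = []
        labels: list[TrialLabels] = []
        trial_id = 0
        for condition in CONDITIONS:
            strength = float(
                np.clip(config.condition_coupling(condition) + intercept, 0.0, 1.0)
            )
            graph = GroundTruthGraph(
                n_channels=config.n_channels,
                pairs=star_pairs(
                    config.n_channels, config.hub_channel, strength, config.phase_lag
                ),
                common_source_gain=config.common_source_gain,
            )
            truth[(subject_id, condition)] = graph
            for _ in range(config.trials_per_condition):
                trial = generate_trial(
                    graph,
                    band=config.band_of_effect,
                    fs=config.fs,
                    duration=config.duration,
                    noise_sd=config.noise_sd,
                    seed=rng,
                    subject_id=subject_id,
                    trial_id=trial_id,
                )
                trials.append(trial)
                labels.append(_condition_labels(rng, condition))
                trial_id += 1
        subjects.append(SubjectBundle(subject_id=subject_id, trials=trials, labels=labels))

    return SyntheticStudy(study=Study(subjects), truth=truth, config=config)


def write_truth_csv(synth: SyntheticStudy, path: str | Path) -> Path:
    """Planted coupling graphs as an edge-list CSV (subject, condition, i, j, strength, lag)."""
    rows = [
        {
            "subject_id": sid,
            "condition": cond,
            "i": p.i,
            "j": p.j,
            "strength": p.strength,
            "lag": p.lag,
            "common_source_gain": g.common_source_gain,
        }
        for (sid, cond), g in synth.truth.items()
        for p in g.pairs
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
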