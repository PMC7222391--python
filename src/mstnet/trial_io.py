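"""Study input/output: trial containers, emotion-condition labelling, exclusions.

A study is a collection of subjects; each subject contributes a stack of
multi-channel trials (channels x samples) recorded at 128 Hz together with
per-trial self-assessment ratings of valence and arousal on a 1-9 scale.
Trials are classified into the four quadrant conditions (HAHV, HALV, LAHV,
LALV) by thresholding the two ratings: 1-4 is "low", 6-9 is "high", and the
middle band (4, 6) is left unclassified so that ambiguous trials never enter
a condition. Subjects that do not cover all four conditions are excluded.

Two on-disk layouts are supported:

* the package's native container — per subject, a ``<id>_data.npy`` array of
  shape (trials, channels, samples) plus a ``<id>_labels.csv`` sidecar with
  columns ``trial_id, valence, arousal``;
* optionally, arrays shaped like the DEAP preprocessed release — per subject
  an array of shape (trials, 40, 8064) at 128 Hz, where the first 32 rows are
  EEG channels and the first 3 s of each trial are a pre-stimulus baseline.
  The reader keeps the 32 EEG rows and drops the 3-s baseline, leaving the
  60-s viewing window (7680 samples).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS_32",
    "CONDITIONS",
    "TrialRecording",
    "TrialLabels",
    "SubjectBundle",
    "Study",
    "classify_trial",
    "classify_rating",
    "exclude_subjects",
    "read_subject",
    "read_study",
    "write_subject",
    "write_study",
]

#: Standard 32-channel 10-20 montage in DEAP channel order; these names are
#: the network's node labels throughout the package.
CHANNELS_32: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "C4",
    "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2", "Cz",
)

#: The four quadrant conditions (arousal level x valence level).
CONDITIONS: tuple[str, ...] = ("HAHV", "HALV", "LAHV", "LALV")

UNCLASSIFIED = "UNCLASSIFIED"

DEAP_N_ROWS = 40          # 32 EEG + 8 peripheral channels
DEAP_N_SAMPLES = 8064     # 63 s at 128 Hz
DEAP_BASELINE_S = 3.0     # pre-stimulus baseline dropped on load
DEFAULT_FS = 128.0


class FormatError(ValueError):
    """Raised when an input file violates the study layout contract."""


@dataclass
class TrialRecording:
    """One trial's multi-channel time series.

    ``data`` is channels x samples (microvolts; unitless synthetic signals are
    accepted), ``fs`` the sampling rate in Hz, ``channel_names`` the ordered
    node labels. Values must be finite.
    """

    subject_id: str
    trial_id: int
    data: np.ndarray
    fs: float
    channel_names: Sequence[str] = CHANNELS_32

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError(f"trial data must be 2-D, got shape {self.data.shape}")
        if len(self.channel_names) != self.data.shape[0]:
            raise FormatError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if not np.isfinite(self.data).all():
            raise FormatError("trial data contains NaN/Inf")
        if self.fs <= 0:
            raise FormatError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class TrialLabels:
    """Self-assessment ratings for one trial, each on the 1-9 scale."""

    valence: float
    arousal: float

    def __post_init__(self) -> None:
        for name in ("valence", "arousal"):
            v = getattr(self, name)
            if not (1.0 <= v <= 9.0):
                raise ValueError(f"{name} rating {v} outside [1, 9]")


def classify_rating(score: float) -> str | None:
    """Map one 1-9 rating to 'low' ([1, 4]), 'high' ([6, 9]) or None (middle band).

    The endpoints 4 and 6 are included in their interval, so boundary ratings
    are classified rather than dropped.
    """
    if 1.0 <= score <= 4.0:
        return "low"
    if 6.0 <= score <= 9.0:
        return "high"
    return None


def classify_trial(labels: TrialLabels) -> str:
    """Assign a trial to HAHV/HALV/LAHV/LALV, or UNCLASSIFIED.

    Both axes must fall outside the ambiguous middle band (4, 6) for the trial
    to receive a named condition.
    """
    v = classify_rating(labels.valence)
    a = classify_rating(labels.arousal)
    if v is None or a is None:
        return UNCLASSIFIED
    return ("H" if a == "high" else "L") + "A" + ("H" if v == "high" else "L") + "V"


@dataclass
class SubjectBundle:
    """All trials and labels of one subject, with lazily derived conditions."""

    subject_id: str
    trials: list[TrialRecording]
    labels: list[TrialLabels]

    def __post_init__(self) -> None:
        if len(self.trials) != len(self.labels):
            raise FormatError(
                f"subject {self.subject_id}: {len(self.trials)} trials but "
                f"{len(self.labels)} label rows"
            )

    @property
    def conditions(self) -> list[str]:
        return [classify_trial(lab) for lab in self.labels]

    def trials_in(self, condition: str) -> list[TrialRecording]:
        return [t for t, c in zip(self.trials, self.conditions) if c == condition]

    def missing_conditions(self) -> list[str]:
        present = set(self.conditions)
        return [c for c in CONDITIONS if c not in present]


@dataclass
class Study:
    subjects: list[SubjectBundle] = field(default_factory=list)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


def exclude_subjects(study: Study) -> tuple[Study, pd.DataFrame]:
    """Drop subjects lacking trials in any of the four conditions.

    Mirrors the exclusion of participants whose ratings cover only part of
    the 2x2 design. Returns the filtered study and a log table with columns
    ``subject_id, reason``.
    """
    if not study.subjects:
        raise ValueError("empty study: no subjects to filter")
    kept: list[SubjectBundle] = []
    log_rows: list[dict] = []
    for subj in study.subjects:
        missing = subj.missing_conditions()
        if missing:
            log_rows.append(
                {
                    "subject_id": subj.subject_id,
                    "reason": "missing conditions: " + ",".join(missing),
                }
            )
        else:
            kept.append(subj)
    if not kept:
        raise ValueError("all subjects excluded: no subject covers all four conditions")
    return Study(kept), pd.DataFrame(log_rows, columns=["subject_id", "reason"])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _load_array(path: Path) -> np.ndarray:
    return np.load(path, allow_pickle=False)


def read_subject(
    path: str | Path,
    format_tag: str = "native",
    subject_id: str | None = None,
) -> SubjectBundle:
    """Read one subject's trials.

    ``format_tag='native'``: ``path`` is the ``<id>_data.npy`` file of the
    native container; the label sidecar ``<id>_labels.csv`` must sit next to
    it.

    ``format_tag='deap-preprocessed'``: ``path`` is an ``.npy`` array shaped
    (trials, 40, 8064); the label sidecar ``<id>_labels.csv`` holds the
    ratings. Only the first 32 rows (EEG) are kept and the first 3 s of each
    trial are discarded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if subject_id is None:
        subject_id = path.stem.replace("_data", "")
    label_path = path.with_name(f"{subject_id}_labels.csv")
    if not label_path.exists():
        raise FormatError(f"missing label sidecar {label_path}")
    labels_df = pd.read_csv(label_path, float_precision="round_trip")
    data = _load_array(path)
    if data.ndim != 3:
        raise FormatError(f"expected trials x channels x samples, got {data.shape}")

    if format_tag == "deap-preprocessed":
        if data.shape[1] < 32:
            raise FormatError(
                f"deap-preprocessed array has {data.shape[1]} channels, need >= 32"
            )
        n_drop = int(round(DEAP_BASELINE_S * DEFAULT_FS))
        data = data[:, :32, n_drop:]
        fs = DEFAULT_FS
    elif format_tag == "native":
        if data.shape[1] != 32:
            raise FormatError(
                f"native array has {data.shape[1]} channels, need exactly 32"
            )
        meta_path = path.with_name(f"{subject_id}_meta.json")
        fs = DEFAULT_FS
        if meta_path.exists():
            fs = float(json.loads(meta_path.read_text()).get("fs", DEFAULT_FS))
        if fs != DEFAULT_FS:
            raise FormatError(
                f"sampling rate {fs} Hz != {DEFAULT_FS} Hz; resampling is out of "
                "scope — supply 128 Hz data"
            )
    else:
        raise ValueError(f"unknown format_tag {format_tag!r}")

    trials = [
        TrialRecording(
            subject_id=subject_id,
            trial_id=int(labels_df.iloc[k].get("trial_id", k)),
            data=data[k],
            fs=fs,
            channel_names=CHANNELS_32,
        )
        for k in range(data.shape[0])
    ]
    labels = [
        TrialLabels(valence=float(r.valence), arousal=float(r.arousal))
        for r in labels_df.itertuples()
    ]
    return SubjectBundle(subject_id=subject_id, trials=trials, labels=labels)


def read_study(directory: str | Path, format_tag: str = "native") -> Study:
    """Read every ``*_data.npy`` subject in a directory."""
    directory = Path(directory)
    paths = sorted(directory.glob("*_data.npy"))
    if not paths:
        raise FileNotFoundError(f"no *_data.npy subjects under {directory}")
    return Study([read_subject(p, format_tag=format_tag) for p in paths])


def write_subject(bundle: SubjectBundle, directory: str | Path) -> Path:
    """Write one subject in the native container layout; returns the data path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = np.stack([t.data for t in bundle.trials])
    data_path = directory / f"{bundle.subject_id}_data.npy"
    np.save(data_path, stack)
    fs = bundle.trials[0].fs
    (directory / f"{bundle.subject_id}_meta.json").write_text(
        json.dumps({"fs": fs, "channel_names": list(bundle.trials[0].channel_names)})
    )
    pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in bundle.trials],
            "valence": [lab.valence for lab in bundle.labels],
            "arousal": [lab.arousal for lab in bundle.labels],
        }
    ).to_csv(
        directory / f"{bundle.subject_id}_labels.csv",
        index=False,
        float_format="%.17g",  # lossless float round-trip
    )
    return data_path


def write_study(study: Study, directory: str | Path) -> Path:
    directory = Path(directory)
    for subj in study.subjects:
        write_subject(subj, directory)
    return directory
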