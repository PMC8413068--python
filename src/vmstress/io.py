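"""Recordings, labels and channel-montage groups.

Reads multichannel EDF recordings in the layout of the PhysioNet
"EEG During Mental Arithmetic Tasks" dataset (per subject: one 180 s
baseline trial and one 60 s task trial, 20 EEG channels in microvolts plus
one ECG channel in millivolts) together with the subject-info table that
carries the performance label: ``G`` (good count quality, non-stressed) or
``B`` (bad, stressed).

Channels are assigned to anatomical groups by their 10-20 electrode-name
prefix: frontal (Fp*/F*), temporal (T*), central (C*), parietal (P*),
occipital (O*), behind-ear (A*/M*), plus the ECG channel.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .edf import write_edf

TRIALS = ("baseline", "task")

GROUP_NAMES = (
    "frontal",
    "temporal",
    "central",
    "parietal",
    "occipital",
    "behind_ear",
    "ecg",
    "all",
)

#: Default 21-channel montage: the 10-20 subset covering the full scalp —
#: frontal 6+1, temporal 4, central 2+1, parietal 2+1, occipital 2,
#: behind-ear 1, plus one ECG lead.
EEGMAT_MONTAGE = (
    "EEG Fp1", "EEG Fp2", "EEG F3", "EEG F4", "EEG F7", "EEG F8", "EEG Fz",
    "EEG T3", "EEG T4", "EEG T5", "EEG T6",
    "EEG C3", "EEG C4", "EEG Cz",
    "EEG P3", "EEG P4", "EEG Pz",
    "EEG O1", "EEG O2",
    "EEG A2",
    "ECG ECG",
)


class FormatError(ValueError):
    """A file was readable but structurally inconsistent with the layout."""


@dataclass
class Recording:
    """One subject-trial multichannel recording.

    ``samples`` is channels x time in the channel's native physical units
    (microvolts for EEG, millivolts for ECG).  The sampling rate always
    comes from the file header, never from documentation.
    """

    subject_id: str
    trial: str
    channel_names: list[str]
    samples: np.ndarray
    fs: float
    duration_s: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.trial not in TRIALS:
            raise ValueError(f"trial must be one of {TRIALS}, got {self.trial!r}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_names):
            raise ValueError("samples must be (n_channels, n_samples)")
        expected = round(self.fs * self.duration_s)
        if self.samples.shape[1] != expected:
            raise ValueError(
                f"sample count {self.samples.shape[1]} != round(fs*duration)={expected}"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.samples[self.channel_names.index(name)]


@dataclass
class SubjectLabel:
    subject_id: str
    quality: str          # "G" (good / non-stressed) or "B" (bad / stressed)
    n_subtractions: int = 0
    age: float = float("nan")
    gender: str = ""

    def __post_init__(self):
        if self.quality not in ("G", "B"):
            raise ValueError(f"quality must be G or B, got {self.quality!r}")
        if self.n_subtractions < 0:
            raise ValueError("n_subtractions must be nonnegative")


@dataclass
class ChannelGroup:
    name: str
    members: list[str] = field(default_factory=list)


def _strip_modality(name: str) -> str:
    for prefix in ("EEG ", "ECG "):
        if name.startswith(prefix):
            return name[len(prefix):]
    return name


def _classify_channel(name: str) -> str | None:
    """Map a single channel name to its group by 10-20 prefix convention."""
    bare = _strip_modality(name).strip()
    if bare.upper() == "ECG":
        return "ecg"
    first = bare[:1].upper()
    if first == "F":           # covers Fp*, F*, Fz
        return "frontal"
    if first == "T":
        return "temporal"
    if first == "C":
        return "central"
    if first == "P":
        return "parietal"
    if first == "O":
        return "occipital"
    if first in ("A", "M"):    # earlobe / mastoid references
        return "behind_ear"
    return None


def channel_group(
    montage: list[str] | tuple[str, ...],
    name: str,
    overrides: dict[str, list[str]] | None = None,
) -> ChannelGroup:
    """Return the channels of ``montage`` belonging to anatomical group ``name``.

    ``overrides`` (e.g. parsed from a config file's ``groups:`` section) maps a
    group name to an explicit channel list and takes precedence over the
    prefix convention.
    """
    if name not in GROUP_NAMES:
        raise ValueError(f"unknown channel group {name!r}; choose from {GROUP_NAMES}")
    montage = list(montage)
    if overrides and name in overrides:
        members = [ch for ch in overrides[name] if ch in montage]
        return ChannelGroup(name=name, members=members)
    if name == "all":
        return ChannelGroup(name="all", members=montage)
    members = [ch for ch in montage if _classify_channel(ch) == name]
    return ChannelGroup(name=name, members=members)


def load_group_overrides(path) -> dict[str, list[str]]:
    """Read montage-group overrides from a YAML config (keys ``groups.<name>``)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    groups = cfg.get("groups", {})
    bad = set(groups) - set(GROUP_NAMES)
    if bad:
        raise ValueError(f"unknown group names in config: {sorted(bad)}")
    return {k: list(v) for k, v in groups.items()}


# Physical-dimension multipliers from SI (what mne returns) back to the
# header's native unit.
_SI_TO_NATIVE = {"uV": 1e6, "µV": 1e6, "mV": 1e3, "V": 1.0}


def read_recording(path, trial: str, subject_id: str | None = None) -> Recording:
    """Read one EDF file into a :class:`Recording`.

    Samples are returned as stored in the file (the header's physical units);
    no resampling, filtering or re-referencing is applied.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read EDF file: {path}")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises a zoo of types for malformed files
        raise FormatError(f"not a readable EDF file: {path} ({exc})") from exc
    if len(raw.ch_names) < 1:
        raise FormatError(f"EDF file has no signals: {path}")
    data = raw.get_data()  # SI units
    orig_units = getattr(raw, "_orig_units", {}) or {}
    for i, ch in enumerate(raw.ch_names):
        unit = orig_units.get(ch, "uV")
        data[i] *= _SI_TO_NATIVE.get(unit, 1.0)
    fs = float(raw.info["sfreq"])
    if subject_id is None:
        subject_id = path.stem
    return Recording(
        subject_id=subject_id,
        trial=trial,
        channel_names=list(raw.ch_names),
        samples=data,
        fs=fs,
        duration_s=raw.n_times / fs,
    )


def write_recording(rec: Recording, path) -> None:
    """Write a :class:`Recording` to EDF (EEG channels tagged uV, ECG mV)."""
    dims = [
        "mV" if _classify_channel(ch) == "ecg" else "uV"
        for ch in rec.channel_names
    ]
    write_edf(path, rec.samples, rec.channel_names, int(round(rec.fs)), dims)


_QUALITY_TOKENS = {
    "G": "G", "B": "B", "GOOD": "G", "BAD": "B", "1": "G", "0": "B",
}

_SUBJECT_COLS = ("subject_id", "subject")
_QUALITY_COLS = ("quality", "count quality", "count_quality")


def read_labels(path) -> list[SubjectLabel]:
    """Parse a subject-info table (CSV or TSV) into :class:`SubjectLabel` rows.

    The table must carry a subject-id column and a quality column; quality
    tokens G/B, good/bad and the dataset's 1/0 coding are all normalized to
    G/B.  Optional columns (age, gender, number of subtractions) are carried
    through when present.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read label table: {path}")
    text = path.read_text()
    if not text.strip():
        return []
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.DictReader(text.splitlines(), delimiter=delim)
    fields = {f.strip().lower(): f for f in reader.fieldnames or []}

    def col(candidates):
        for c in candidates:
            if c in fields:
                return fields[c]
        return None

    subj_col = col(_SUBJECT_COLS)
    qual_col = col(_QUALITY_COLS)
    if subj_col is None or qual_col is None:
        raise FormatError(
            f"label table {path} must have subject and quality columns; "
            f"found {list(fields)}"
        )
    age_col = col(("age",))
    gender_col = col(("gender",))
    nsub_col = col(("n_subtractions", "number of subtractions"))

    labels = []
    for row in reader:
        token = str(row[qual_col]).strip().upper()
        if token not in _QUALITY_TOKENS:
            raise ValueError(
                f"unknown quality token {row[qual_col]!r} for subject "
                f"{row[subj_col]!r} (expected G/B, good/bad or 1/0)"
            )
        labels.append(
            SubjectLabel(
                subject_id=str(row[subj_col]).strip(),
                quality=_QUALITY_TOKENS[token],
                n_subtractions=int(float(row[nsub_col])) if nsub_col and row[nsub_col] else 0,
                age=float(row[age_col]) if age_col and row[age_col] else float("nan"),
                gender=str(row[gender_col]).strip() if gender_col and row[gender_col] else "",
            )
        )
    return labels
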