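"""Synthetic two-class EEG+ECG recordings.

Emulates the layout of the mental-arithmetic stress dataset the pipeline
targets: per subject one long baseline trial and one shorter task trial,
recorded over a 21-channel montage (20 EEG + 1 ECG) at a fixed sampling
rate, with a binary performance label (G = non-stressed, B = stressed).

Each EEG channel is a sum of amplitude-modulated narrowband oscillations
(default band centers 4, 8, 12, 20 and 30 Hz, spanning the classical
theta-alpha-beta rhythms) plus white noise.  The class difference is
placed where the downstream Poincaré descriptors look for it: stressed
(B) subjects draw their slow band-amplitude modulation with variance
multiplied by ``1 + effect_size`` relative to non-stressed subjects, so
the two classes differ in mode-wise variability, not in mean amplitude.
The ECG channel is a ~1.1 Hz periodic spike train (millivolt scale) with
the same class-dependent amplitude modulation.  ``effect_size = 0`` makes
the classes statistically indistinguishable.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import EEGMAT_MONTAGE, Recording, SubjectLabel, write_recording

__all__ = ["SynthConfig", "generate", "write_fixture"]

#: (center Hz, bandwidth Hz, base amplitude) per oscillatory band.
DEFAULT_BANDS = (
    (4.0, 1.0, 20.0),
    (8.0, 1.5, 15.0),
    (12.0, 2.0, 12.0),
    (20.0, 3.0, 8.0),
    (30.0, 4.0, 5.0),
)


@dataclass
class SynthConfig:
    """Study conditions for the generator.

    Subject counts default to the emulated cohort (26 non-stressed, 10
    stressed); trial durations to 180 s baseline / 60 s task.  ``fs``
    defaults to 128 Hz, a desk-scale rate that keeps every default band
    below Nyquist.  ``effect_size`` scales the between-class difference in
    band-amplitude-modulation *variance*; 0 removes it entirely.
    """

    n_good: int = 26
    n_bad: int = 10
    fs: float = 128.0
    duration_task_s: float = 60.0
    duration_baseline_s: float = 180.0
    channels: tuple = EEGMAT_MONTAGE
    bands: tuple = DEFAULT_BANDS
    effect_size: float = 1.0
    noise_sd: float = 2.0          # white-noise floor, microvolts
    modulation_sd: float = 0.35    # base relative SD of the slow envelope
    seed: int = 0

    def __post_init__(self):
        if self.n_good < 1 or self.n_bad < 1:
            raise ValueError("subject counts must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if len(self.channels) == 0 or len(set(self.channels)) != len(self.channels):
            raise ValueError("channel montage must be nonempty with unique names")
        for c, bw, amp in self.bands:
            if c >= self.fs / 2:
                raise ValueError(f"band center {c} Hz at or above Nyquist ({self.fs/2})")


def _slow_envelope(rng, n, fs, cutoff_hz=1.0):
    """Unit-variance slow random envelope: white noise smoothed to ~cutoff_hz."""
    from scipy.ndimage import gaussian_filter1d

    w = rng.standard_normal(n)
    sigma = fs / (2.0 * np.pi * cutoff_hz)   # Gaussian kernel width in samples
    env = gaussian_filter1d(w, sigma, mode="wrap")
    sd = env.std()
    return env / sd if sd > 0 else env


def _ecg_wave(rng, n, fs, rate_hz=1.1):
    """Periodic R-peak spike train with slight beat jitter, millivolt scale."""
    t = np.arange(n) / fs
    total_s = n / fs
    beat_times = []
    tcur = rng.uniform(0, 1.0 / rate_hz)
    while tcur < total_s:
        beat_times.append(tcur)
        tcur += (1.0 / rate_hz) * (1.0 + 0.05 * rng.standard_normal())
    sig = np.zeros(n)
    width = 0.02  # R-wave width in seconds
    for bt in beat_times:
        sig += np.exp(-0.5 * ((t - bt) / width) ** 2)
    return sig  # ~unit peak amplitude


def generate(cfg: SynthConfig):
    """Generate recordings and labels for the configured cohort.

    Returns ``(recordings, labels)`` where recordings holds two trials
    (baseline then task) for every subject, stressed and non-stressed
    interleaved deterministically by subject index.
    """
    rng = np.random.default_rng(cfg.seed)
    recordings: list[Recording] = []
    labels: list[SubjectLabel] = []
    qualities = ["G"] * cfg.n_good + ["B"] * cfg.n_bad
    n_total = len(qualities)
    for idx, quality in enumerate(qualities):
        sid = f"Subject{idx:02d}"
        sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        # stressed subjects: modulation variance x (1 + effect_size)
        var_scale = (1.0 + cfg.effect_size) if quality == "B" else 1.0
        mod_sd = cfg.modulation_sd * np.sqrt(var_scale)
        gender = "F" if idx % 2 == 0 else "M"
        labels.append(
            SubjectLabel(
                subject_id=sid,
                quality=quality,
                n_subtractions=int(sub_rng.poisson(21 if quality == "G" else 7)),
                age=float(sub_rng.integers(16, 27)),
                gender=gender,
            )
        )
        for trial, dur in (
            ("baseline", cfg.duration_baseline_s),
            ("task", cfg.duration_task_s),
        ):
            n = round(cfg.fs * dur)
            t = np.arange(n) / cfg.fs
            samples = np.empty((len(cfg.channels), n))
            for ci, ch in enumerate(cfg.channels):
                if ch.startswith("ECG"):
                    env = 1.0 + mod_sd * _slow_envelope(sub_rng, n, cfg.fs)
                    sig = 1.0 * _ecg_wave(sub_rng, n, cfg.fs) * env
                    sig += 0.02 * sub_rng.standard_normal(n)  # mV noise floor
                else:
                    sig = np.zeros(n)
                    for center, bw, amp in cfg.bands:
                        phase = sub_rng.uniform(0, 2 * np.pi)
                        env = 1.0 + mod_sd * _slow_envelope(
                            sub_rng, n, cfg.fs, cutoff_hz=max(bw / 2.0, 0.25)
                        )
                        sig += amp * env * np.cos(2 * np.pi * center * t + phase)
                    sig += cfg.noise_sd * sub_rng.standard_normal(n)
                samples[ci] = sig
            recordings.append(
                Recording(
                    subject_id=sid,
                    trial=trial,
                    channel_names=list(cfg.channels),
                    samples=samples,
                    fs=cfg.fs,
                    duration_s=dur,
                )
            )
    return recordings, labels


def write_fixture(recordings, labels, out_dir) -> list[Path]:
    """Write EDF files plus a subject-info CSV in the layout `vmstress.io` reads.

    Baseline trials are written as ``<subject>_1.edf`` and task trials as
    ``<subject>_2.edf``, mirroring the numbering of the emulated dataset.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for rec in recordings:
        n = 1 if rec.trial == "baseline" else 2
        path = out_dir / f"{rec.subject_id}_{n}.edf"
        write_recording(rec, path)
        written.append(path)
    info = out_dir / "subject-info.csv"
    with open(info, "w") as fh:
        fh.write("subject_id,age,gender,n_subtractions,quality\n")
        for lab in labels:
            fh.write(
                f"{lab.subject_id},{lab.age:.0f},{lab.gender},"
                f"{lab.n_subtractions},{lab.quality}\n"
            )
    written.append(info)
    return written


def make_subject_info_table(path, n_good: int = 26, n_bad: int = 10, seed: int = 0):
    """Write a synthetic stand-in subject-info table (no signal files).

    Mirrors the published cohort composition — ``n_good`` non-stressed and
    ``n_bad`` stressed subjects — in the CSV layout ``read_labels`` parses.
    """
    rng = np.random.default_rng(seed)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("subject_id,age,gender,n_subtractions,quality\n")
        for idx, q in enumerate(["G"] * n_good + ["B"] * n_bad):
            age = rng.integers(16, 27)
            gender = "F" if idx % 2 == 0 else "M"
            nsub = rng.poisson(21 if q == "G" else 7)
            fh.write(f"Subject{idx:02d},{age},{gender},{nsub},{q}\n")
    return path
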