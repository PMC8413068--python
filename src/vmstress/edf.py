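"""Minimal EDF (European Data Format) writer.

EDF stores a fixed-width ASCII header followed by interleaved 16-bit
little-endian data records.  This writer emits one data record per second
(so the sampling rate must be an integer) and maps each channel's physical
range onto the full digital range [-32768, 32767], which keeps the
quantization error at its 16-bit floor.

Reading is delegated to :mod:`mne` (see :mod:`vmstress.io`); this module
exists only because the environment provides no EDF export path.
"""

from __future__ import annotations

import numpy as np

DIG_MIN = -32768
DIG_MAX = 32767

__all__ = ["write_edf"]


def _field(value, width: int) -> bytes:
    """Render one fixed-width ASCII header field, space padded."""
    raw = str(value).encode("ascii")
    if len(raw) > width:
        raw = raw[:width]
    return raw + b" " * (width - len(raw))


def _fmt_phys(v: float, direction: int) -> str:
    """Render a physical bound in <= 8 ASCII chars.

    ``direction`` is -1 for a lower bound and +1 for an upper bound: the
    rendered value must bracket ``v`` from that side so no sample falls
    outside the serialized physical range.
    """
    import math

    if v == 0:
        return "0"
    for prec in (6, 5, 4, 3, 2, 1):
        s = f"{v:.{prec}g}"
        if len(s) > 8:
            continue
        if direction * (float(s) - v) >= 0:
            return s
        # rounded the wrong way: nudge one unit in the last rendered digit
        mag = math.floor(math.log10(abs(v)))
        nudged = v + direction * 10.0 ** (mag - prec + 1)
        s = f"{nudged:.{prec}g}"
        if len(s) <= 8 and direction * (float(s) - v) >= 0:
            return s
    raise ValueError(f"cannot render physical bound {v!r} in 8 characters")


def write_edf(
    path,
    samples: np.ndarray,
    channel_names: list[str],
    fs: int,
    physical_dims: list[str],
) -> None:
    """Write a channels x time matrix of physical values to an EDF file.

    Parameters
    ----------
    path
        Output file path.
    samples
        Array of shape ``(n_channels, n_samples)`` in the physical units
        named by ``physical_dims`` (e.g. ``"uV"`` for EEG, ``"mV"`` for ECG).
    channel_names
        One label per channel, at most 16 ASCII characters each.
    fs
        Sampling rate in Hz; must be a positive integer and divide the
        sample count (one data record per second).
    physical_dims
        Physical dimension label per channel.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be a 2-D channels x time array")
    n_sig, n_samp = samples.shape
    if len(channel_names) != n_sig or len(physical_dims) != n_sig:
        raise ValueError("channel_names/physical_dims must match channel count")
    fs = int(fs)
    if fs <= 0:
        raise ValueError("fs must be a positive integer")
    if n_samp % fs != 0:
        raise ValueError(
            f"sample count {n_samp} is not a whole number of 1 s records at fs={fs}"
        )
    n_rec = n_samp // fs

    phys_min = samples.min(axis=1).astype(float)
    phys_max = samples.max(axis=1).astype(float)
    flat = phys_max <= phys_min
    phys_max[flat] = phys_min[flat] + 1.0

    # Serialize ranges first, then quantize against the *serialized* values so
    # that a reader recovers exactly the gain we used.
    pmin_s = [_fmt_phys(v, -1) for v in phys_min]
    pmax_s = [_fmt_phys(v, +1) for v in phys_max]
    pmin = np.array([float(s) for s in pmin_s])
    pmax = np.array([float(s) for s in pmax_s])
    gain = (pmax - pmin) / (DIG_MAX - DIG_MIN)

    hdr = bytearray()
    hdr += _field("0", 8)                       # version
    hdr += _field("X X X X", 80)                # patient id (anonymous)
    hdr += _field("Startdate X X X X", 80)      # recording id
    hdr += _field("01.01.00", 8)                # start date
    hdr += _field("00.00.00", 8)                # start time
    hdr += _field(256 * (n_sig + 1), 8)         # header bytes
    hdr += _field("", 44)                       # reserved
    hdr += _field(n_rec, 8)                     # number of records
    hdr += _field(1, 8)                         # record duration (s)
    hdr += _field(n_sig, 4)                     # number of signals
    for name in channel_names:
        hdr += _field(name, 16)
    hdr += b" " * (80 * n_sig)                  # transducer type
    for dim in physical_dims:
        hdr += _field(dim, 8)
    for s in pmin_s:
        hdr += _field(s, 8)
    for s in pmax_s:
        hdr += _field(s, 8)
    hdr += _field(DIG_MIN, 8) * n_sig
    hdr += _field(DIG_MAX, 8) * n_sig
    hdr += b" " * (80 * n_sig)                  # prefiltering
    hdr += _field(fs, 8) * n_sig                # samples per record
    hdr += b" " * (32 * n_sig)                  # reserved per signal
    assert len(hdr) == 256 * (n_sig + 1)

    digital = np.round(
        (samples - pmin[:, None]) / gain[:, None] + DIG_MIN
    )
    digital = np.clip(digital, DIG_MIN, DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        for r in range(n_rec):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())
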