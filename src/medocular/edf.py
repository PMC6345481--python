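"""European Data Format (EDF) input/output.

Writing is a self-contained implementation of the plain EDF container
(256-byte fixed header, 256 bytes per signal, 16-bit little-endian samples
in 1-second data records) — sufficient for continuous multichannel
recordings with per-channel physical scaling.  Reading goes through MNE's
EDF reader, which also serves as an independent check on the writer.

EDF stores samples as 16-bit integers, so a round trip quantizes each
channel to (phys_max - phys_min) / 65535 of its range.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

from .preprocess import Recording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    rec: Recording,
    path,
    patient_id: str = "X",
    recording_id: str = "synthetic",
    start: _dt.datetime | None = None,
) -> None:
    """Write a recording as 16-bit EDF with 1-second data records.

    The sampling rate must be an integer (samples per 1-s record); the
    trailing partial second, if any, is dropped.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_sig = rec.n_channels
    n_records = rec.n_samples // fs
    if n_records == 0:
        raise ValueError("recording shorter than one EDF data record")
    data = rec.data[:, : n_records * fs]

    phys_min = np.floor(data.min(axis=1))
    phys_max = np.ceil(data.max(axis=1))
    flat = phys_max - phys_min < 1e-9
    phys_max[flat] = phys_min[flat] + 1.0

    start = start or _dt.datetime(2000, 1, 1, 0, 0, 0)
    header_bytes = 256 * (1 + n_sig)

    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field(patient_id, 80))
        fh.write(_field(recording_id, 80))
        fh.write(_field(start.strftime("%d.%m.%y"), 8))
        fh.write(_field(start.strftime("%H.%M.%S"), 8))
        fh.write(_field(str(header_bytes), 8))
        fh.write(_field("", 44))
        fh.write(_field(str(n_records), 8))
        fh.write(_field("1", 8))          # record duration, seconds
        fh.write(_field(str(n_sig), 4))

        labels = []
        for name in rec.channel_names:
            prefix = "EOG" if name in rec.eog_channels else "EEG"
            labels.append(f"{prefix} {name}")
        for lab in labels:
            fh.write(_field(lab, 16))
        for _ in labels:
            fh.write(_field("AgAgCl electrode", 80))
        for _ in labels:
            fh.write(_field("uV", 8))
        for v in phys_min:
            fh.write(_field(f"{v:g}", 8))
        for v in phys_max:
            fh.write(_field(f"{v:g}", 8))
        for _ in labels:
            fh.write(_field(str(_DIG_MIN), 8))
        for _ in labels:
            fh.write(_field(str(_DIG_MAX), 8))
        for _ in labels:
            fh.write(_field("", 80))
        for _ in labels:
            fh.write(_field(str(fs), 8))
        for _ in labels:
            fh.write(_field("", 32))

        gain = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
        digital = np.empty((n_sig, n_records * fs), dtype="<i2")
        for i in range(n_sig):
            d = (data[i] - phys_min[i]) / gain[i] + _DIG_MIN
            digital[i] = np.clip(np.round(d), _DIG_MIN, _DIG_MAX).astype("<i2")
        for r in range(n_records):
            for i in range(n_sig):
                fh.write(digital[i, r * fs : (r + 1) * fs].tobytes())


def read_edf(path) -> Recording:
    """Read an EDF file into a :class:`Recording` (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = []
    eog = []
    for ch in raw.ch_names:
        # strip the "EEG "/"EOG " type prefix the writer adds
        name = ch.split(" ", 1)[1] if " " in ch else ch
        names.append(name)
        if ch.startswith("EOG") or name.upper().startswith("EOG"):
            eog.append(name)
    data_uv = raw.get_data() * 1e6
    return Recording(
        channel_names=names,
        fs=float(raw.info["sfreq"]),
        data=data_uv,
        annotations=[],
        reference="recording",
        eog_channels=tuple(eog) if eog else ("EOG",),
    )
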