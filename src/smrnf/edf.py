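"""EDF serialization of recordings.

Writing: a minimal single-purpose EDF writer (16-bit, one data record per
second, physical unit uV) so generated sessions can be opened by standard
EEG software.  No installed package writes EDF, hence the direct
implementation of the fixed-layout header.  Reading goes through mne's EDF
reader when available, with a built-in fallback parser for the same subset
this module writes.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .core import EEGRecording, Montage

__all__ = ["write_edf", "read_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: EEGRecording, path) -> Path:
    """Write one run as EDF (16-bit), one data record per second.

    Requires an integer number of seconds and an integer sample rate; each
    channel gets a symmetric physical range wide enough for its data, so
    quantization error is below range/65536 uV.
    """
    path = Path(path)
    fs = rec.sample_rate
    if fs != int(fs):
        raise ValueError("EDF export needs an integer sample rate")
    fs = int(fs)
    n_records, rem = divmod(rec.n_samples, fs)
    if rem:
        raise ValueError("EDF export needs a whole number of seconds")
    ns = rec.n_channels
    labels = rec.montage.all_labels

    phys_max = np.maximum(np.abs(rec.data).max(axis=1), 1e-6)
    phys_max = phys_max * 1.0000001  # keep extremes inside the digital range

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad(f"subject {rec.subject_id}", 80))
        fh.write(_pad(f"run {rec.run_label}", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(256 * (ns + 1)), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(ns), 4))
        for label in labels:
            fh.write(_pad(label, 16))
        for _ in labels:
            fh.write(_pad("AgAgCl electrode", 80))
        for _ in labels:
            fh.write(_pad("uV", 8))
        for pm in phys_max:
            fh.write(_pad(f"{-pm:.6g}"[:8], 8))
        for pm in phys_max:
            fh.write(_pad(f"{pm:.6g}"[:8], 8))
        for _ in labels:
            fh.write(_pad(str(_DIG_MIN), 8))
        for _ in labels:
            fh.write(_pad(str(_DIG_MAX), 8))
        for _ in labels:
            fh.write(_pad("", 80))
        for _ in labels:
            fh.write(_pad(str(fs), 8))
        for _ in labels:
            fh.write(_pad("", 32))

        # re-read the physical extremes as the ascii header stores them, so
        # the scaling used for the samples matches what a reader recovers
        pmins = np.array([float(f"{-pm:.6g}"[:8]) for pm in phys_max])
        pmaxs = np.array([float(f"{pm:.6g}"[:8]) for pm in phys_max])
        scale = (_DIG_MAX - _DIG_MIN) / (pmaxs - pmins)
        for k in range(n_records):
            chunk = rec.data[:, k * fs:(k + 1) * fs]
            digital = np.rint((chunk - pmins[:, None]) * scale[:, None] + _DIG_MIN)
            digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")
            fh.write(digital.tobytes())
    return path


def _read_edf_fallback(path) -> tuple[np.ndarray, list, float]:
    with open(path, "rb") as fh:
        header = fh.read(256)
        n_records = int(header[236:244])
        ns = int(header[252:256])
        sig = fh.read(256 * ns)
        pos = 0
        labels = [sig[pos + i * 16: pos + (i + 1) * 16].decode().strip() for i in range(ns)]
        pos = ns * (16 + 80)
        pos += ns * 8  # physical dimension
        pmin = np.array([float(sig[pos + i * 8: pos + (i + 1) * 8]) for i in range(ns)])
        pos += ns * 8
        pmax = np.array([float(sig[pos + i * 8: pos + (i + 1) * 8]) for i in range(ns)])
        pos += ns * 8
        dmin = np.array([float(sig[pos + i * 8: pos + (i + 1) * 8]) for i in range(ns)])
        pos += ns * 8
        dmax = np.array([float(sig[pos + i * 8: pos + (i + 1) * 8]) for i in range(ns)])
        pos += ns * (8 + 80)
        spr = [int(sig[pos + i * 8: pos + (i + 1) * 8]) for i in range(ns)]
        if len(set(spr)) != 1:
            raise ValueError("mixed sampling rates not supported")
        fs = spr[0]  # 1-s records
        raw = np.frombuffer(fh.read(), dtype="<i2")
    raw = raw.reshape(n_records, ns, fs)
    data = raw.transpose(1, 0, 2).reshape(ns, n_records * fs).astype(float)
    gain = (pmax - pmin) / (dmax - dmin)
    data = (data - dmin[:, None]) * gain[:, None] + pmin[:, None]
    return data, labels, float(fs)


def read_edf(path, montage: Montage | None = None,
             run_label: str = "baseline", subject_id: str = "S00") -> EEGRecording:
    """Read an EDF run back into an EEGRecording (uV).

    Channel order must match the montage.  Uses mne when installed, else
    the built-in parser (sufficient for files written by `write_edf`).
    """
    montage = montage or Montage()
    try:
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne loads volts
        labels = list(raw.ch_names)
        fs = float(raw.info["sfreq"])
    except ImportError:
        data, labels, fs = _read_edf_fallback(path)
    order = [labels.index(l) for l in montage.all_labels]
    return EEGRecording(data=data[order], sample_rate=fs, montage=montage,
                        run_label=run_label, subject_id=subject_id)
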