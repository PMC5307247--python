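"""Reading and writing :class:`~entrofatigue.synth.Recording` objects.

Two on-disk dialects are supported:

* **TSV** — a plain-text table, one column per channel, one row per sample,
  preceded by a small ``#``-prefixed key/value header (``fs``, ``subject``,
  ``state``).  Lossless to the printed precision.
* **EDF** — European Data Format, 16-bit, one signal per channel, physical
  range fixed at +/-200 microvolts (a standard clinical EEG dialect).
  Written by a minimal EDF encoder in this module; read back through
  :mod:`mne`.  The subject id and state label travel in the EDF patient and
  recording identification fields.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import Recording, STATES

logger = logging.getLogger(__name__)

#: EDF physical range in microvolts (16-bit digital range)
EDF_PHYS_MIN = -200.0
EDF_PHYS_MAX = 200.0
_DIG_MIN, _DIG_MAX = -32768, 32767


class RecordingFormatError(ValueError):
    """Malformed recording file or unsupported format."""


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "txt"):
        return "tsv"
    if suffix == "edf":
        return "edf"
    raise RecordingFormatError(f"cannot infer format from suffix {path.suffix!r}; "
                               "pass format='tsv' or 'edf'")


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> Path:
    """Write a recording to ``path`` as TSV or EDF (inferred from the suffix)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        _write_tsv(rec, path)
    elif fmt == "edf":
        _write_edf(rec, path)
    else:
        raise RecordingFormatError(f"unknown format {fmt!r}; expected 'tsv' or 'edf'")
    return path


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording previously written by :func:`write_recording`."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        return _read_tsv(path)
    if fmt == "edf":
        return _read_edf(path)
    raise RecordingFormatError(f"unknown format {fmt!r}; expected 'tsv' or 'edf'")


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def _write_tsv(rec: Recording, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:.10g}\n")
        fh.write(f"# subject={rec.subject_id}\n")
        fh.write(f"# state={rec.state}\n")
        fh.write("\t".join(rec.channels) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.9g", delimiter="\t")


def _read_tsv(path: Path) -> Recording:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    for key in ("fs", "subject", "state"):
        if key not in meta:
            raise RecordingFormatError(f"{path}: missing '# {key}=...' header line")
    if meta["state"] not in STATES:
        raise RecordingFormatError(f"{path}: unknown state {meta['state']!r}")
    try:
        table = pd.read_csv(path, sep="\t", comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise RecordingFormatError(f"{path}: malformed table ({exc})") from exc
    values = table.to_numpy()
    if values.dtype.kind not in "fi":
        bad = [c for c in table.columns if table[c].dtype.kind not in "fi"]
        raise RecordingFormatError(f"{path}: non-numeric samples in column(s) {bad}")
    return Recording(subject_id=int(meta["subject"]), state=meta["state"],
                     channels=tuple(table.columns), data=values.T,
                     fs=float(meta["fs"]))


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw + b" " * (width - len(raw))


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF writer: 1-second data records, 16-bit samples, 'uV' units.

    Requires an integer sampling rate and a whole number of seconds.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise RecordingFormatError("EDF export requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record, per signal
    n_samples = rec.n_samples
    if n_samples % spr != 0:
        raise RecordingFormatError("EDF export requires a whole number of seconds")
    n_records = n_samples // spr
    n_sig = len(rec.channels)

    lo, hi = rec.data.min(), rec.data.max()
    if lo < EDF_PHYS_MIN or hi > EDF_PHYS_MAX:
        warnings.warn(f"EDF export clips samples outside [{EDF_PHYS_MIN}, {EDF_PHYS_MAX}] uV "
                      f"(observed range [{lo:.1f}, {hi:.1f}])", stacklevel=3)
    clipped = np.clip(rec.data, EDF_PHYS_MIN, EDF_PHYS_MAX)
    scale = (_DIG_MAX - _DIG_MIN) / (EDF_PHYS_MAX - EDF_PHYS_MIN)
    digital = np.rint((clipped - EDF_PHYS_MIN) * scale + _DIG_MIN).astype("<i2")

    header = b"".join([
        _pad("0", 8),
        _pad(f"subject={rec.subject_id}", 80),
        _pad(f"state={rec.state}", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (n_sig + 1)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(n_sig), 4),
    ])
    sig_header = b"".join([
        b"".join(_pad(ch, 16) for ch in rec.channels),          # label
        b"".join(_pad("", 80) for _ in rec.channels),           # transducer
        b"".join(_pad("uV", 8) for _ in rec.channels),          # dimension
        b"".join(_pad(f"{EDF_PHYS_MIN:.0f}", 8) for _ in rec.channels),
        b"".join(_pad(f"{EDF_PHYS_MAX:.0f}", 8) for _ in rec.channels),
        b"".join(_pad(str(_DIG_MIN), 8) for _ in rec.channels),
        b"".join(_pad(str(_DIG_MAX), 8) for _ in rec.channels),
        b"".join(_pad("", 80) for _ in rec.channels),           # prefiltering
        b"".join(_pad(str(spr), 8) for _ in rec.channels),
        b"".join(_pad("", 32) for _ in rec.channels),           # reserved
    ])

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        # data: records x signals x samples, little-endian int16
        reshaped = digital.reshape(n_sig, n_records, spr)
        for r in range(n_records):
            fh.write(reshaped[:, r, :].tobytes())


def _read_edf(path: Path) -> Recording:
    import mne

    with open(path, "rb") as fh:
        head = fh.read(256)
    if len(head) < 256:
        raise RecordingFormatError(f"{path}: truncated EDF header")
    patient = head[8:88].decode("ascii", errors="replace").strip()
    recording_id = head[88:168].decode("ascii", errors="replace").strip()
    meta = {}
    for blob in (patient, recording_id):
        for token in blob.split():
            if "=" in token:
                k, _, v = token.partition("=")
                meta[k] = v
    if "subject" not in meta or meta.get("state") not in STATES:
        raise RecordingFormatError(
            f"{path}: EDF id fields lack 'subject=<int>'/'state=<normal|fatigue>' metadata")

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne rescales 'uV' channels to volts
    return Recording(subject_id=int(meta["subject"]), state=meta["state"],
                     channels=tuple(raw.ch_names), data=data_uv,
                     fs=float(raw.info["sfreq"]))
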