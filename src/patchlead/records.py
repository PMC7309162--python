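"""Multi-lead ECG record container and plain-text I/O.

The canonical on-disk format is a commented-header CSV: lines starting with
``#`` carry metadata (``fs``, ``units``, ``leads``, optional ``subject``),
followed by one comma-separated row per sample.  Canonical units are
microvolts; a header declaring ``mV`` is converted on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

#: Standard 12-lead order used everywhere in this package.
STANDARD_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF",
                  "V1", "V2", "V3", "V4", "V5", "V6")

#: Names of the three bipolar patch channels.
PATCH_LEADS = ("P1", "P2", "P3")


class RecordFormatError(ValueError):
    """Raised for malformed record files (bad header, ragged rows, units)."""


@dataclass
class MultiLeadRecord:
    """A sampled multi-channel ECG.

    Parameters
    ----------
    lead_names : tuple of str
        One name per channel, e.g. ``("I", "II", ...)``.
    fs : float
        Sampling rate in Hz.
    data : ndarray, shape (n_samples, n_leads)
        Sample values in microvolts.
    subject : str, optional
        Free-form subject identifier carried through serialization.
    """

    lead_names: tuple
    fs: float
    data: np.ndarray
    subject: str = ""

    def __post_init__(self):
        self.lead_names = tuple(self.lead_names)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_samples, n_leads)")
        if self.data.shape[1] != len(self.lead_names):
            raise ValueError(
                f"{len(self.lead_names)} lead names but "
                f"{self.data.shape[1]} data columns")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_leads(self) -> int:
        return len(self.lead_names)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return one lead's samples (μV) by name."""
        try:
            j = self.lead_names.index(name)
        except ValueError:
            raise KeyError(f"lead {name!r} not in record "
                           f"(has {', '.join(self.lead_names)})") from None
        return self.data[:, j]

    def slice(self, start: int, stop: int) -> "MultiLeadRecord":
        """Sample-index slice ``[start, stop)`` as a new record."""
        return replace(self, data=self.data[start:stop].copy())

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.fs


def write_record(record: MultiLeadRecord, path) -> None:
    """Write a record to canonical CSV (deterministic byte output)."""
    if record.n_samples == 0:
        raise ValueError("refusing to write an empty record (zero samples)")
    buf = io.StringIO()
    buf.write(f"# fs: {record.fs!r}\n")
    buf.write("# units: uV\n")
    buf.write(f"# leads: {','.join(record.lead_names)}\n")
    if record.subject:
        buf.write(f"# subject: {record.subject}\n")
    for row in record.data:
        buf.write(",".join(repr(float(v)) for v in row))
        buf.write("\n")
    with open(path, "w", newline="\n") as fh:
        fh.write(buf.getvalue())


def read_record(path) -> MultiLeadRecord:
    """Read a record written by :func:`write_record`.

    Values are returned in μV; a header declaring ``mV`` is scaled by 1000.
    """
    meta = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" not in body:
                    raise RecordFormatError(
                        f"line {lineno}: malformed header line {line!r}")
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            else:
                rows.append(line.split(","))
    for required in ("fs", "leads", "units"):
        if required not in meta:
            raise RecordFormatError(f"missing required header field {required!r}")
    leads = tuple(s.strip() for s in meta["leads"].split(","))
    units = meta["units"].lower()
    if units in ("uv", "µv", "μv"):
        scale = 1.0
    elif units == "mv":
        scale = 1000.0
    else:
        raise RecordFormatError(f"unknown units {meta['units']!r}")
    try:
        fs = float(meta["fs"])
    except ValueError:
        raise RecordFormatError(f"bad fs value {meta['fs']!r}") from None
    n_cols = len(leads)
    data = np.empty((len(rows), n_cols))
    for i, row in enumerate(rows):
        if len(row) != n_cols:
            raise RecordFormatError(
                f"ragged row {i}: {len(row)} values, expected {n_cols}")
        data[i] = [float(v) for v in row]
    return MultiLeadRecord(lead_names=leads, fs=fs, data=data * scale,
                           subject=meta.get("subject", ""))
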