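"""Loading, validation and windowing of multi-channel sEMG recordings.

A :class:`Recording` is one labelled trial (samples x channels) at a known
sampling rate.  Recordings are segmented into fixed-length analysis
:class:`Window` objects; every window carries its source (subject, trial)
group key so that downstream cross-validation can keep all windows of one
trial in the same fold and avoid train/test leakage at the window level.

Supported on-disk formats: delimited text (comma, tab or whitespace; one
row per sample, one column per channel) and the MATLAB v5 container
layout used by the public "sEMG for Basic Hand Movements" archive
(per-class trial matrices, two channels, 500 Hz, 6 s trials).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io

__all__ = [
    "MOVEMENT_CLASSES",
    "Recording",
    "Window",
    "read_delimited",
    "write_delimited",
    "read_dataset_archive",
    "segment",
    "windows_to_csv",
    "windows_from_csv",
]

#: The six grasp classes: cylindrical, tip, hook, palmar, spherical, lateral.
MOVEMENT_CLASSES = ("CY", "TI", "HO", "PA", "SP", "LA")

# archive variable stems -> class codes
_ARCHIVE_CLASS_MAP = {
    "cyl": "CY",
    "tip": "TI",
    "hook": "HO",
    "palm": "PA",
    "spher": "SP",
    "lat": "LA",
}


@dataclass
class Recording:
    """One labelled multi-channel sEMG trial."""

    samples: np.ndarray  # (n_samples, n_channels)
    rate: float
    label: str
    subject: str = "s1"
    trial: int = 0
    channel_names: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 2-D array (samples x channels)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(
                f"recording (subject={self.subject}, trial={self.trial}, "
                f"label={self.label}) contains non-finite samples"
            )
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channel_names is None:
            self.channel_names = tuple(f"ch{i + 1}" for i in range(self.n_channels))

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def group(self) -> tuple[str, int]:
        return (self.subject, self.trial)


@dataclass
class Window:
    """A fixed-length slice of a Recording, inheriting its label and group."""

    samples: np.ndarray  # (window_length, n_channels)
    label: str
    subject: str
    trial: int
    start_index: int
    rate: float

    @property
    def group(self) -> tuple[str, int]:
        return (self.subject, self.trial)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


def read_delimited(
    path: str | Path,
    rate: float,
    label: str = "",
    subject: str = "s1",
    trial: int = 0,
) -> Recording:
    """Read a delimited-text recording (one row per sample, one column per channel).

    The delimiter (comma, tab or whitespace) is sniffed from the first
    data line.  Malformed rows raise a parse error naming the line.
    """
    path = Path(path)
    rows: list[list[float]] = []
    delim = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if delim is None:
                delim = "," if "," in line else ("\t" if "\t" in line else None)
            parts = line.split(delim) if delim else line.split()
            try:
                values = [float(p) for p in parts]
            except ValueError:
                raise ValueError(f"{path}: non-numeric value at line {lineno}: {line!r}") from None
            if rows and len(values) != len(rows[0]):
                raise ValueError(
                    f"{path}: line {lineno} has {len(values)} columns, expected {len(rows[0])}"
                )
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: empty input file")
    return Recording(samples=np.array(rows), rate=rate, label=label, subject=subject, trial=trial)


def write_delimited(rec: Recording, path: str | Path, delimiter: str = ",") -> None:
    """Write a Recording as delimited text, one row per sample."""
    np.savetxt(path, rec.samples, delimiter=delimiter, fmt="%.12g")


def read_dataset_archive(path: str | Path) -> list[Recording]:
    """Read a MATLAB v5 container in the public hand-movement archive layout.

    The container holds, per movement class and channel, a matrix of
    shape (n_trials, n_samples) in variables named ``<class>_ch1`` /
    ``<class>_ch2`` (e.g. ``cyl_ch1``); the sampling rate is fixed at
    500 Hz.  Returns one two-channel Recording per trial.
    """
    path = Path(path)
    mat = scipy.io.loadmat(path)
    found = [k for k in mat if not k.startswith("__")]
    recordings: list[Recording] = []
    subject = path.stem
    for stem, code in _ARCHIVE_CLASS_MAP.items():
        keys = [f"{stem}_ch1", f"{stem}_ch2"]
        if not all(k in mat for k in keys):
            raise ValueError(
                f"{path}: missing expected variables {keys}; found {sorted(found)}"
            )
        ch1, ch2 = (np.asarray(mat[k], dtype=float) for k in keys)
        if ch1.shape != ch2.shape:
            raise ValueError(f"{path}: channel shape mismatch for class {code}")
        for t in range(ch1.shape[0]):
            samples = np.column_stack([ch1[t], ch2[t]])
            if not np.all(np.isfinite(samples)):
                raise ValueError(f"{path}: non-finite samples in class {code} trial {t}")
            recordings.append(
                Recording(samples=samples, rate=500.0, label=code, subject=subject, trial=t)
            )
    return recordings


def segment(rec: Recording, window_length: int, overlap: float = 0.0) -> list[Window]:
    """Slice a recording into fixed-length windows.

    The stride is ``round(window_length * (1 - overlap))``; trailing
    samples that cannot fill a complete window are discarded.  Windows
    use half-open 0-based intervals ``[start, start + window_length)``.
    """
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    if window_length > rec.n_samples:
        raise ValueError(
            f"window_length {window_length} exceeds recording length {rec.n_samples}"
        )
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    stride = round(window_length * (1.0 - overlap))
    if stride < 1:
        raise ValueError("stride rounds to zero; decrease overlap")
    starts = range(0, rec.n_samples - window_length + 1, stride)
    return [
        Window(
            samples=rec.samples[s : s + window_length],
            label=rec.label,
            subject=rec.subject,
            trial=rec.trial,
            start_index=s,
            rate=rec.rate,
        )
        for s in starts
    ]


def windows_to_csv(windows: list[Window], path: str | Path) -> None:
    """Serialize windows to one CSV: metadata columns then flattened samples.

    Sample columns are named ``<channel>_<offset>`` in channel-major order.
    """
    if not windows:
        raise ValueError("no windows to write")
    length, n_ch = windows[0].samples.shape
    header = ["start_index", "subject", "trial", "label", "rate"] + [
        f"ch{c + 1}_{i}" for c in range(n_ch) for i in range(length)
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for w in windows:
            if w.samples.shape != (length, n_ch):
                raise ValueError("all windows must share the same shape")
            row = [w.start_index, w.subject, w.trial, w.label, repr(float(w.rate))]
            row.extend(repr(float(v)) for v in w.samples.T.ravel())
            writer.writerow(row)


def windows_from_csv(path: str | Path) -> list[Window]:
    """Inverse of :func:`windows_to_csv`."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        sample_cols = header[5:]
        n_ch = len({c.split("_")[0] for c in sample_cols})
        length = len(sample_cols) // n_ch
        windows = []
        for row in reader:
            samples = np.array([float(v) for v in row[5:]]).reshape(n_ch, length).T
            windows.append(
                Window(
                    samples=samples,
                    label=row[3],
                    subject=row[1],
                    trial=int(row[2]),
                    start_index=int(row[0]),
                    rate=float(row[4]),
                )
            )
    return windows
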