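"""Time- and frequency-domain features of wavelet-packet sub-bands.

For every terminal sub-band of every channel of a window, four features
are computed:

* MAV, mean absolute value: ``(1/N) sum |x_i|``
* RMS, root mean square: ``sqrt((1/N) sum x_i^2)``
* MNF, mean (power-weighted) frequency: ``sum f_j P_j / sum P_j``
* MDF, median frequency: the first bin at which cumulative spectral
  power reaches half the total

MNF and MDF are computed from a one-sided, unwindowed periodogram of the
sub-band coefficient sequence, whose effective sampling rate is
``rate / 2**level`` because each decomposition level decimates by two.
A window with ``C`` channels decomposed to level ``L`` therefore yields
``C * 2**L * 4`` features (64 for the standard 2-channel, level-3
configuration), in frozen channel-major, band-minor, feature-last order.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass

import numpy as np

from .signal_io import Window
from .wpt import wp_decompose, wp_reconstruct, SubbandSet

__all__ = [
    "Spectrum",
    "FeatureMatrix",
    "FEATURE_KINDS",
    "mav",
    "rms",
    "power_spectrum",
    "mnf",
    "mdf",
    "extract_features",
    "feature_names",
    "build_feature_matrix",
]

FEATURE_KINDS = ("MAV", "RMS", "MNF", "MDF")


@dataclass
class Spectrum:
    """One-sided power spectrum: bin centre frequencies and powers."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape or self.freqs.ndim != 1:
            raise ValueError("freqs and power must be 1-D arrays of equal length")
        if self.freqs.size and (self.freqs[0] != 0.0 or np.any(np.diff(self.freqs) <= 0)):
            raise ValueError("freqs must start at 0 and be strictly increasing")
        if np.any(~np.isfinite(self.power)) or np.any(self.power < 0):
            raise ValueError("power values must be finite and non-negative")

    @property
    def n_bins(self) -> int:
        return self.freqs.size


@dataclass
class FeatureMatrix:
    """Per-window feature rows with labels and (subject, trial) groups."""

    values: np.ndarray  # (n_windows, n_features)
    feature_names: list[str]
    labels: np.ndarray  # (n_windows,) str
    subjects: np.ndarray  # (n_windows,) str
    trials: np.ndarray  # (n_windows,) int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.subjects = np.asarray(self.subjects)
        self.trials = np.asarray(self.trials, dtype=int)
        n = self.values.shape[0]
        if not (len(self.labels) == len(self.subjects) == len(self.trials) == n):
            raise ValueError("labels/subjects/trials must match the number of rows")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match the number of columns")

    @property
    def groups(self) -> list[tuple[str, int]]:
        return list(zip(self.subjects.tolist(), self.trials.tolist()))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["label", "subject", "trial"] + self.feature_names)
            for i in range(self.values.shape[0]):
                writer.writerow(
                    [self.labels[i], self.subjects[i], self.trials[i]]
                    + [repr(float(v)) for v in self.values[i]]
                )

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            names = header[3:]
            labels, subjects, trials, rows = [], [], [], []
            for row in reader:
                labels.append(row[0])
                subjects.append(row[1])
                trials.append(int(row[2]))
                rows.append([float(v) for v in row[3:]])
        return cls(np.array(rows), names, np.array(labels), np.array(subjects), np.array(trials))


def mav(x: np.ndarray) -> float:
    """Mean absolute value of a sequence."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("mav of an empty sequence")
    return float(np.mean(np.abs(x)))


def rms(x: np.ndarray) -> float:
    """Root-mean-square amplitude of a sequence."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("rms of an empty sequence")
    return float(np.sqrt(np.mean(x * x)))


def power_spectrum(x: np.ndarray, rate: float) -> Spectrum:
    """One-sided unwindowed periodogram, ``P_j = |DFT(x)_j|^2``.

    Bin centres are ``f_j = j * rate / N`` for ``j = 0 .. floor(N/2)``.
    No detrending or tapering is applied: the estimator is deterministic
    and exact for sinusoids that sit on a bin.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("power_spectrum needs at least 2 samples")
    if rate <= 0:
        raise ValueError("rate must be positive")
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / rate)
    return Spectrum(freqs=freqs, power=spec)


def mnf(s: Spectrum) -> float:
    """Mean frequency: power-weighted average of bin frequencies.

    A zero-power spectrum yields 0.0 with a warning (legitimately occurs
    for all-zero sub-bands of narrowband signals).
    """
    total = float(np.sum(s.power))
    if total == 0.0:
        warnings.warn("mnf of a zero-power spectrum; returning 0", stacklevel=2)
        return 0.0
    return float(np.sum(s.freqs * s.power) / total)


def mdf(s: Spectrum) -> float:
    """Median frequency: first bin where cumulative power reaches half the total.

    Reported as the bin frequency without interpolation; ties resolve to
    the smallest index.  Zero total power yields 0.0 with a warning.
    """
    total = float(np.sum(s.power))
    if total == 0.0:
        warnings.warn("mdf of a zero-power spectrum; returning 0", stacklevel=2)
        return 0.0
    cum = np.cumsum(s.power)
    j = int(np.searchsorted(cum, 0.5 * total))
    return float(s.freqs[j])


def feature_names(n_channels: int, level: int) -> list[str]:
    """Frozen column order: channel-major, then band, then feature kind."""
    return [
        f"ch{c + 1}_band{b}_{kind}"
        for c in range(n_channels)
        for b in range(2 ** level)
        for kind in FEATURE_KINDS
    ]


def extract_features(
    w: Window,
    basis: str = "dmey",
    level: int = 3,
    rate: float | None = None,
    on_reconstructed: bool = False,
) -> np.ndarray:
    """Feature row for one window: 4 features per channel per sub-band.

    With ``on_reconstructed=True`` the spectral features are computed on
    the band-limited signal reconstructed from each single sub-band (at
    the full rate) instead of on the decimated coefficient sequence.
    """
    rate = w.rate if rate is None else rate
    sub_rate = rate / 2 ** level
    row: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-power sub-bands are expected
        for c in range(w.n_channels):
            s = wp_decompose(w.samples[:, c], basis=basis, level=level)
            for b in range(s.n_subbands):
                coeffs = s.coeffs[b]
                if on_reconstructed:
                    lone = SubbandSet(
                        coeffs=[coeffs if i == b else np.zeros_like(coeffs)
                                for i in range(s.n_subbands)],
                        level=s.level, basis=s.basis, mode=s.mode,
                        original_length=s.original_length,
                    )
                    seq, seq_rate = wp_reconstruct(lone), rate
                else:
                    seq, seq_rate = coeffs, sub_rate
                spec = power_spectrum(seq, seq_rate)
                row.extend([mav(coeffs), rms(coeffs), mnf(spec), mdf(spec)])
    return np.array(row)


def build_feature_matrix(
    windows: list[Window],
    basis: str = "dmey",
    level: int = 3,
    on_reconstructed: bool = False,
) -> FeatureMatrix:
    """Stack per-window feature rows into a FeatureMatrix."""
    if not windows:
        raise ValueError("no windows given")
    n_ch = windows[0].n_channels
    rows = np.array([
        extract_features(w, basis=basis, level=level, on_reconstructed=on_reconstructed)
        for w in windows
    ])
    return FeatureMatrix(
        values=rows,
        feature_names=feature_names(n_ch, level),
        labels=np.array([w.label for w in windows]),
        subjects=np.array([w.subject for w in windows]),
        trials=np.array([w.trial for w in windows]),
    )
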