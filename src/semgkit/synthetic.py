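"""Synthetic 2-channel sEMG-like trials with a controllable class structure.

Real surface-EMG interference patterns are well approximated by
amplitude-modulated coloured Gaussian noise, so each trial is generated
as white Gaussian noise shaped in the frequency domain by a per-class
weight profile over the eight level-3 frequency bands of ``[0, rate/2]``
(exact spectral masking via the DFT — no filter transition bands),
scaled per channel by a class-specific gain pair, multiplied by a
trapezoidal activation envelope with per-trial amplitude jitter, and
topped with a white sensor-noise floor.

Class structure.  All six classes share a common sEMG-like base spectrum
(energy concentrated roughly in the 30–150 Hz bands).  Class ``c``
perturbs it multiplicatively: ``w_c = w_base * (1 + 0.3 * d * p_c)``
where ``p_c`` is a fixed sign pattern over the 8 bands and ``d`` is the
``separation`` dial; channel gains are perturbed the same way with a
smaller factor.  At ``separation = 0`` every class is generatively
identical (classification accuracy must sit at chance); at
``separation = 1`` classes are separable but overlapping; at
``separation = 2`` they are well separated.

The default amplitude scale is 1e-2 signal units, matching the raw-data
magnitude of the recordings the generator emulates, so absolute additive
noise levels such as 1e-2 .. 8e-1 are directly meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import Recording, MOVEMENT_CLASSES

__all__ = ["SyntheticSpec", "generate", "expected_band_energy"]

N_BANDS = 8

# per-class sign patterns over the 8 level-3 bands (rows) and the
# 2 channel gains; every pair of classes differs in several positions
_BAND_PATTERNS = np.array(
    [
        [+1, +1, 0, 0, -1, -1, 0, 0],   # CY: low-band dominant
        [0, 0, +1, +1, 0, 0, -1, -1],   # TI: mid-band dominant
        [-1, 0, +1, 0, -1, 0, +1, 0],   # HO: alternating even bands
        [0, -1, 0, +1, 0, -1, 0, +1],   # PA: alternating odd bands
        [+1, 0, -1, -1, 0, +1, 0, -1],  # SP
        [0, +1, +1, 0, -1, 0, -1, -1],   # LA
    ],
    dtype=float,
)
_CHANNEL_PATTERNS = np.array(
    [[+1, -1], [-1, +1], [+1, +1], [-1, -1], [+1, 0], [0, +1]], dtype=float
)
_BAND_FACTOR = 0.3
_CHANNEL_FACTOR = 0.25
# class-dependent spectral tilt inside each band: shifts the band's mean
# frequency without changing its energy, so classes differ in their
# frequency-domain features as well as their energy distribution
_TILT_FACTOR = 0.8


@dataclass
class SyntheticSpec:
    """Generative parameters; the defaults mirror the emulated recordings
    (5 subjects, 6 movement classes, 30 trials each, 2 channels, 500 Hz,
    6-second trials)."""

    n_subjects: int = 5
    n_trials_per_class: int = 30
    rate: float = 500.0
    duration: float = 6.0
    classes: tuple[str, ...] = MOVEMENT_CLASSES
    n_channels: int = 2
    separation: float = 1.0
    amplitude: float = 1e-2          # plateau RMS, signal units
    noise_floor: float = 5e-4        # sensor-noise std, signal units
    ramp: float = 0.5                # envelope ramp length, seconds
    plateau_jitter: float = 0.1      # relative per-trial amplitude jitter
    seed: int = 0
    band_weights: np.ndarray | None = None    # (n_classes, 8) override
    channel_ratio: np.ndarray | None = None   # (n_classes, n_channels) override

    def __post_init__(self) -> None:
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not 1 <= len(self.classes) <= len(_BAND_PATTERNS):
            raise ValueError(f"1..{len(_BAND_PATTERNS)} classes supported")
        if self.rate <= 0 or self.duration <= 0:
            raise ValueError("rate and duration must be positive")
        if self.n_channels != 2 and self.channel_ratio is None:
            raise ValueError("channel_ratio override required for n_channels != 2")
        if self.band_weights is not None:
            self.band_weights = np.asarray(self.band_weights, dtype=float)
            if self.band_weights.shape != (len(self.classes), N_BANDS):
                raise ValueError("band_weights must be (n_classes, 8)")
            if np.any(self.band_weights < 0) or np.any(self.band_weights.max(axis=1) <= 0):
                raise ValueError("band weights must be nonnegative with a positive entry per class")

    @property
    def n_samples(self) -> int:
        return int(round(self.rate * self.duration))

    def class_band_weights(self) -> np.ndarray:
        """(n_classes, 8) spectral amplitude weights implied by the spec."""
        if self.band_weights is not None:
            return self.band_weights
        base = np.array([0.72, 1.0, 0.9, 0.78, 0.68, 0.52, 0.4, 0.3])
        w = base[None, :] * (
            1.0 + _BAND_FACTOR * self.separation * _BAND_PATTERNS[: len(self.classes)]
        )
        return np.clip(w, 0.02 * base.max(), None)

    def class_channel_gains(self) -> np.ndarray:
        """(n_classes, n_channels) per-channel amplitude gains."""
        if self.channel_ratio is not None:
            return np.asarray(self.channel_ratio, dtype=float)
        g = 1.0 + _CHANNEL_FACTOR * self.separation * _CHANNEL_PATTERNS[: len(self.classes)]
        return np.clip(g, 0.05, None)


def _envelope(spec: SyntheticSpec) -> np.ndarray:
    n = spec.n_samples
    t = np.arange(n) / spec.rate
    env = np.ones(n)
    r = spec.ramp
    if r > 0:
        env = np.minimum(env, t / r)
        env = np.minimum(env, (spec.duration - 1 / spec.rate - t) / r)
    return np.clip(env, 0.0, 1.0)


def _band_index(freqs: np.ndarray, rate: float) -> np.ndarray:
    """Map rFFT bin frequencies to the 8 equal bands of [0, rate/2]."""
    idx = np.floor(freqs / (rate / 2.0 / N_BANDS)).astype(int)
    return np.clip(idx, 0, N_BANDS - 1)


def _band_power_profile(spec: SyntheticSpec, class_index: int) -> np.ndarray:
    """Target power-spectral profile per rFFT bin for one class.

    The piecewise-constant band-weight profile is smoothed across band
    edges with a Laplacian (two-sided exponential) kernel of scale 1/3
    band width.  A brick-wall profile would make measured sub-band
    energies deviate from the target whenever adjacent bands differ
    strongly, because the analysing wavelet filters have finite
    transition bands (with roughly exponential tails) that exchange
    energy across each edge; a transition with matched tails makes that
    exchange close to symmetric, so the per-band energy budget is
    preserved.  DC is zeroed so every trial is zero-mean in expectation.

    An explicit ``band_weights`` override is taken literally: no tilt
    and no edge smoothing, giving exact brick-wall band control.
    """
    n = spec.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.rate)
    band_of_bin = _band_index(freqs, spec.rate)
    weights = spec.class_band_weights()[class_index]
    profile = weights[band_of_bin].astype(float) ** 2
    # linear within-band tilt: P(f) *= 1 + tilt * x, x in [-1/2, 1/2] across
    # the band; integrates to 1, so per-band energy is unchanged while the
    # band's spectral centroid moves with the class pattern
    if spec.band_weights is None:
        band_width = spec.rate / 2.0 / N_BANDS
        x = freqs / band_width - band_of_bin - 0.5
        tilt = np.clip(_TILT_FACTOR * spec.separation, 0.0, 1.8)
        profile = profile * (
            1.0 + tilt * _BAND_PATTERNS[class_index][band_of_bin] * x
        )
        band_width_bins = (spec.rate / 2.0 / N_BANDS) / (spec.rate / n)
        m = profile.size
        kernel = np.exp(-np.abs(np.arange(-m + 1, m)) / (band_width_bins / 3.0))
        kernel /= kernel.sum()
        ext = np.concatenate(
            [np.full(m - 1, profile[0]), profile, np.full(m - 1, profile[-1])]
        )
        profile = np.convolve(ext, kernel, mode="valid")
    profile[0] = 0.0
    return profile


def generate(spec: SyntheticSpec) -> list[Recording]:
    """Generate the full labelled trial set described by ``spec``.

    Fully deterministic given ``spec.seed``.  Returns
    ``n_subjects * n_classes * n_trials_per_class`` recordings.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    gains = spec.class_channel_gains()
    env = _envelope(spec)

    # normalise each class mask so the shaped noise has unit variance
    # before the amplitude scale is applied (DC is zeroed: zero-mean signal)
    recordings: list[Recording] = []
    for s in range(spec.n_subjects):
        subject = f"synth{s + 1}"
        for ci, label in enumerate(spec.classes):
            mask = np.sqrt(_band_power_profile(spec, ci))
            # E[x^2] of masked unit white noise = sum(mask^2 over full DFT)/N^2
            full_sq = 2.0 * np.sum(mask**2) - mask[0] ** 2
            if n % 2 == 0:
                full_sq -= mask[-1] ** 2
            norm = np.sqrt(full_sq / n)
            for t in range(spec.n_trials_per_class):
                amp = spec.amplitude * (
                    1.0 + spec.plateau_jitter * rng.uniform(-1.0, 1.0)
                )
                chans = []
                for c in range(spec.n_channels):
                    white = rng.standard_normal(n)
                    shaped = np.fft.irfft(np.fft.rfft(white) * mask, n=n) / norm
                    chans.append(amp * gains[ci, c] * env * shaped)
                samples = np.column_stack(chans)
                samples += spec.noise_floor * rng.standard_normal(samples.shape)
                recordings.append(
                    Recording(samples=samples, rate=spec.rate, label=label,
                              subject=subject, trial=t)
                )
    return recordings


def expected_band_energy(spec: SyntheticSpec, class_index: int) -> np.ndarray:
    """Closed-form expected per-sample power in each level-3 band.

    Averaged over channels and over the whole trial (envelope mean-square
    gain and plateau-jitter second moment included), for comparison with
    measured sub-band coefficient energy ``sum c^2 / n_samples``.
    """
    gains = spec.class_channel_gains()[class_index]
    n = spec.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.rate)
    band_of_bin = _band_index(freqs, spec.rate)
    # full two-sided squared-mask sum, and its per-band split
    two_sided = 2.0 * np.ones(freqs.size)
    two_sided[0] = 1.0
    if n % 2 == 0:
        two_sided[-1] = 1.0
    sq = two_sided * _band_power_profile(spec, class_index)
    total = np.sum(sq)
    band_frac = np.array([np.sum(sq[band_of_bin == b]) for b in range(N_BANDS)]) / total
    env_ms = float(np.mean(_envelope(spec) ** 2))
    jitter_ms = 1.0 + spec.plateau_jitter**2 / 3.0  # E[(1+jU)^2], U ~ Unif(-1,1)
    signal_power = spec.amplitude**2 * float(np.mean(gains**2)) * env_ms * jitter_ms
    noise_bins = np.bincount(band_of_bin, weights=two_sided, minlength=N_BANDS)
    noise_frac = noise_bins / noise_bins.sum()
    return signal_power * band_frac + spec.noise_floor**2 * noise_frac
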