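"""Wavelet packet transform (WPT) filter bank.

A level-``L`` wavelet packet decomposition splits a 1-D signal into
``2**L`` terminal sub-bands by recursively filtering every node with an
orthonormal low-pass/high-pass pair ``h``/``g`` and downsampling by two,
expanding *both* branches at every level (unlike the plain discrete
wavelet transform, which only recurses on the low-pass branch).

Conventions, fixed so results are reproducible across implementations:

* Boundary handling defaults to **periodization**: the signal is treated
  as circular, which makes the transform exactly orthogonal, so Parseval
  energy conservation and perfect reconstruction hold to machine
  precision.  Signals whose length is not a multiple of ``2**level`` are
  zero-padded at the tail first and truncated again on reconstruction.
* One analysis stage computes, for a length-``N`` (even) node signal,

      a[i] = sum_j h[j] x[(2 i + 1 - L/2 + j) mod N],   i = 0..N/2-1

  and likewise ``d[i]`` with ``g``; this phase matches the decimated
  circular convolution used by standard wavelet toolboxes, so terminal
  coefficients are directly comparable.
* The high-pass filter is derived from the stored low-pass table by the
  quadrature-mirror rule ``g[k] = (-1)**k h[L-1-k]``.
* Terminal sub-bands are returned in **frequency (sequency) order**:
  index 0 is the lowest band and index ``2**level - 1`` the highest, the
  bands partitioning ``[0, rate/2]`` evenly.  Internally the recursion
  produces natural (Paley) order; the reordering is the Gray-code-style
  permutation that accounts for the spectral inversion a decimator
  applies to every high-pass branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._filter_tables import SCALING_FILTERS

__all__ = [
    "WaveletFilterPair",
    "SubbandSet",
    "get_filters",
    "wp_decompose",
    "wp_reconstruct",
    "subband_frequency_range",
    "natural_to_frequency_order",
]


@dataclass(frozen=True)
class WaveletFilterPair:
    """Orthonormal decomposition filter pair for one named wavelet basis."""

    name: str
    h: np.ndarray  # low-pass scaling filter
    g: np.ndarray  # high-pass wavelet filter, g[k] = (-1)^k h[L-1-k]

    def __post_init__(self) -> None:
        object.__setattr__(self, "h", np.asarray(self.h, dtype=float))
        object.__setattr__(self, "g", np.asarray(self.g, dtype=float))
        if self.h.shape != self.g.shape or self.h.ndim != 1:
            raise ValueError("h and g must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return self.h.size


@dataclass
class SubbandSet:
    """Terminal coefficients of one window's WPT, in frequency order."""

    coeffs: list[np.ndarray]
    level: int
    basis: str
    mode: str
    original_length: int

    def __post_init__(self) -> None:
        if len(self.coeffs) != 2 ** self.level:
            raise ValueError(
                f"expected {2 ** self.level} sub-bands, got {len(self.coeffs)}"
            )

    @property
    def n_subbands(self) -> int:
        return len(self.coeffs)

    def energy(self) -> float:
        """Total coefficient energy, sum over bands of sum of squares."""
        return float(sum(np.sum(c * c) for c in self.coeffs))


def get_filters(name: str) -> WaveletFilterPair:
    """Return the embedded filter pair for one of the supported bases.

    Supported: ``sym3``, ``fk8``, ``dmey``, ``db4``, ``coif2``.
    """
    try:
        h = np.asarray(SCALING_FILTERS[name], dtype=float)
    except KeyError:
        supported = ", ".join(sorted(SCALING_FILTERS))
        raise ValueError(f"unknown wavelet basis {name!r}; supported: {supported}") from None
    L = h.size
    g = ((-1.0) ** np.arange(L)) * h[::-1]
    return WaveletFilterPair(name=name, h=h, g=g)


def _analysis_stage(x: np.ndarray, f: np.ndarray) -> np.ndarray:
    """One filter-and-downsample-by-2 stage under periodic extension."""
    N = x.size
    L = f.size
    idx = (2 * np.arange(N // 2)[:, None] + 1 - L // 2 + np.arange(L)[None, :]) % N
    return x[idx] @ f


def _analysis_stage_symmetric(x: np.ndarray, f: np.ndarray) -> np.ndarray:
    N = x.size
    L = f.size
    # half-point symmetric extension, as used for non-circular boundaries
    ext = np.concatenate([x[L - 1 :: -1], x, x[: -L - 1 : -1]])
    full = np.convolve(ext, f[::-1], mode="valid")
    start = (full.size - N) // 2
    return full[start : start + N : 2]


def _synthesis_stage(a: np.ndarray, d: np.ndarray, h: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Invert one periodized analysis stage (adjoint of the orthogonal map)."""
    N = 2 * a.size
    L = h.size
    x = np.zeros(N)
    idx = (2 * np.arange(a.size)[:, None] + 1 - L // 2 + np.arange(L)[None, :]) % N
    np.add.at(x, idx, a[:, None] * h[None, :])
    np.add.at(x, idx, d[:, None] * g[None, :])
    return x


def natural_to_frequency_order(level: int) -> np.ndarray:
    """Permutation p with p[f] = natural-order index of frequency band f.

    At every decimation the high-pass branch's spectrum is mirrored, so
    frequency order interleaves branches in a Gray-code pattern: going
    one level down, band f expands into (low, high) when f is even and
    (high, low) when f is odd.
    """
    order = [""]
    for _ in range(level):
        nxt = []
        for f, path in enumerate(order):
            nxt.extend([path + "a", path + "d"] if f % 2 == 0 else [path + "d", path + "a"])
        order = nxt
    return np.array([int(p.replace("a", "0").replace("d", "1"), 2) for p in order])


def wp_decompose(
    x: np.ndarray,
    basis: str = "dmey",
    level: int = 3,
    mode: str = "periodization",
) -> SubbandSet:
    """Decompose ``x`` into its ``2**level`` terminal WPT sub-bands.

    Parameters
    ----------
    x
        1-D real signal; must be at least as long as the filter.
    basis
        Wavelet basis name (see :func:`get_filters`).
    level
        Tree depth; yields ``2**level`` sub-bands.
    mode
        ``"periodization"`` (default; orthogonal, invertible) or
        ``"symmetric"`` (half-point symmetric extension, analysis only).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("x must be a non-empty 1-D sequence")
    if level < 1:
        raise ValueError("level must be >= 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    fp = get_filters(basis)
    if x.size < len(fp):
        raise ValueError(f"signal length {x.size} shorter than filter length {len(fp)}")
    if mode not in ("periodization", "symmetric"):
        raise ValueError(f"unknown boundary mode {mode!r}")

    original_length = x.size
    if mode == "periodization":
        block = 2 ** level
        pad = (-x.size) % block
        if pad:
            x = np.concatenate([x, np.zeros(pad)])
        stage = _analysis_stage
    else:
        stage = _analysis_stage_symmetric

    nodes = [x]
    for _ in range(level):
        nxt = []
        for node in nodes:
            nxt.append(stage(node, fp.h))
            nxt.append(stage(node, fp.g))
        nodes = nxt

    perm = natural_to_frequency_order(level)
    coeffs = [nodes[i] for i in perm]
    return SubbandSet(
        coeffs=coeffs, level=level, basis=basis, mode=mode,
        original_length=original_length,
    )


def wp_reconstruct(s: SubbandSet) -> np.ndarray:
    """Invert :func:`wp_decompose`, returning the original-length signal.

    Only defined for periodization mode, where the transform is orthogonal.
    """
    if s.mode != "periodization":
        raise ValueError("reconstruction is only supported for periodization mode")
    lengths = {c.size for c in s.coeffs}
    if len(lengths) != 1:
        raise ValueError("inconsistent sub-band lengths")
    fp = get_filters(s.basis)
    perm = natural_to_frequency_order(s.level)
    nodes: list[np.ndarray] = [None] * len(s.coeffs)  # type: ignore[list-item]
    for f, nat in enumerate(perm):
        nodes[nat] = np.asarray(s.coeffs[f], dtype=float)
    for _ in range(s.level):
        nodes = [
            _synthesis_stage(nodes[2 * i], nodes[2 * i + 1], fp.h, fp.g)
            for i in range(len(nodes) // 2)
        ]
    return nodes[0][: s.original_length]


def subband_frequency_range(s: SubbandSet, index: int, rate: float) -> tuple[float, float]:
    """Frequency band (low, high) in Hz covered by sub-band ``index``.

    The ``2**level`` frequency-ordered bands partition ``[0, rate/2]``.
    """
    n = s.n_subbands
    if not 0 <= index < n:
        raise IndexError(f"sub-band index {index} out of range [0, {n})")
    width = rate / 2.0 / n
    return (index * width, (index + 1) * width)
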