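"""Wavelet correlation networks from regional BOLD time series.

Each subject's regional BOLD matrix (regions x timepoints) is decomposed
with a maximum-overlap (undecimated) discrete wavelet transform, MODWT,
using the Daubechies least-asymmetric length-8 filter, LA(8).  Level k of a
J-level MODWT isolates the frequency band [1/(2^(k+1) TR), 1/(2^k TR)]; at
TR = 2.5 s the four levels cover 0.1-0.2, 0.05-0.1, 0.025-0.05 and
0.0125-0.025 Hz, and level 3 (0.025-0.05 Hz) is the conventional
resting-state band.  Functional connectivity between two regions is the
Pearson correlation of their level-k wavelet coefficients, and the weighted
network applies the soft threshold w = |r|^2, which emphasises strong and
penalises weak correlations without binarising.

The MODWT is implemented directly (circular filtering with 1/sqrt(2)-scaled
filters): it is shift-covariant, defined for any series length, and
satisfies the energy identity sum_j ||W_j||^2 + ||V_J||^2 = ||X||^2 under
the periodic boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "WaveletDecomposition",
    "CorrelationMatrix",
    "WeightedNetwork",
    "band_bounds",
    "boundary_coefficient_count",
    "modwt",
    "wavelet_correlation",
    "build_connectivity",
    "regional_mean_timeseries",
]

#: PyWavelets name of the Daubechies least-asymmetric length-8 filter.
LA8 = "sym4"


@dataclass
class WaveletDecomposition:
    """Per-level MODWT detail coefficients of one time series.

    ``details`` has shape (levels, n_timepoints) — the undecimated transform
    keeps every level at the input length.  ``smooth`` is the level-J
    scaling (approximation) sequence.
    """

    details: np.ndarray
    smooth: np.ndarray
    levels: int
    family: str = LA8
    tr: float | None = None

    def level(self, k: int) -> np.ndarray:
        """Detail coefficients of level k (1-based)."""
        if not 1 <= k <= self.levels:
            raise ValueError(f"level must be in 1..{self.levels}, got {k}")
        return self.details[k - 1]


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of band-restricted wavelet correlations r_ij."""

    r: np.ndarray
    band_index: int
    region_names: list[str] | None = field(default=None)


@dataclass
class WeightedNetwork:
    """Zero-diagonal symmetric soft-thresholded weight matrix, w_ij in [0,1]."""

    w: np.ndarray
    region_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight matrix must have a zero diagonal")
        if w.min() < 0 or w.max() > 1:
            raise ValueError("weights must lie in [0, 1]")
        self.w = w

    @property
    def n_nodes(self) -> int:
        return self.w.shape[0]


def band_bounds(tr: float, k: int) -> tuple[float, float]:
    """Frequency band (low_hz, high_hz) of MODWT level k at repetition time tr.

    Level k covers [1/(2^(k+1) tr), 1/(2^k tr)]; successive levels halve the
    band, and level 1 ends at the Nyquist frequency 1/(2 tr).
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if k < 1:
        raise ValueError("level index must be >= 1")
    return 1.0 / (2 ** (k + 1) * tr), 1.0 / (2**k * tr)


def _filters(family: str) -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(family)
    g = np.asarray(w.dec_lo, dtype=float) / np.sqrt(2.0)
    h = np.asarray(w.dec_hi, dtype=float) / np.sqrt(2.0)
    return g, h


def _min_length(levels: int, filter_len: int) -> int:
    """Support of the level-J equivalent filter: (2^J - 1)(L - 1) + 1."""
    return (2**levels - 1) * (filter_len - 1) + 1


def boundary_coefficient_count(level: int, family: str = LA8) -> int:
    """Number of circularly wrapped (boundary-affected) coefficients at a level."""
    filter_len = len(pywt.Wavelet(family).dec_lo)
    return _min_length(level, filter_len) - 1


def _modwt_matrix(x: np.ndarray, levels: int, family: str) -> tuple[np.ndarray, np.ndarray]:
    """MODWT of each row of ``x``; returns (details[J, R, T], smooth[R, T])."""
    g, h = _filters(family)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[-1]
    need = _min_length(levels, len(g))
    if n < need:
        raise ValueError(
            f"series length {n} is shorter than the level-{levels} filter "
            f"support; at least {need} samples are required"
        )
    v = x.copy()
    details = np.empty((levels,) + x.shape)
    for j in range(1, levels + 1):
        up = 2 ** (j - 1)
        wj = np.zeros_like(v)
        vj = np.zeros_like(v)
        for tap in range(len(g)):
            shifted = np.roll(v, up * tap, axis=-1)
            wj += h[tap] * shifted
            vj += g[tap] * shifted
        details[j - 1] = wj
        v = vj
    return details, v


def modwt(series, levels: int = 4, family: str = LA8, tr: float | None = None) -> WaveletDecomposition:
    """J-level maximum-overlap DWT of a single time series."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("modwt expects a 1-D series; see build_connectivity for matrices")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    details, smooth = _modwt_matrix(series, levels, family)
    return WaveletDecomposition(
        details=details[:, 0, :], smooth=smooth[0], levels=levels, family=family, tr=tr
    )


def wavelet_correlation(
    dec_a: WaveletDecomposition,
    dec_b: WaveletDecomposition,
    k: int,
    exclude_boundary: bool = False,
) -> float:
    """Pearson correlation of two series' level-k MODWT coefficients."""
    if dec_a.levels != dec_b.levels or dec_a.family != dec_b.family:
        raise ValueError("decompositions must share levels and wavelet family")
    wa, wb = dec_a.level(k), dec_b.level(k)
    if wa.shape != wb.shape:
        raise ValueError("decompositions must share series length")
    if exclude_boundary:
        nb = boundary_coefficient_count(k, dec_a.family)
        if wa.size - nb < 3:
            raise ValueError("too few interior coefficients after boundary exclusion")
        wa, wb = wa[nb:], wb[nb:]
    return float(np.corrcoef(wa, wb)[0, 1])


def build_connectivity(
    bold: np.ndarray,
    tr: float = 2.5,
    level: int = 3,
    levels: int = 4,
    family: str = LA8,
    region_names: list[str] | None = None,
    exclude_boundary: bool = False,
) -> tuple[CorrelationMatrix, WeightedNetwork]:
    """Wavelet correlation matrix and soft-thresholded weights of one subject.

    ``bold`` is a regions x timepoints matrix.  Returns the symmetric
    level-``level`` correlation matrix r and the weighted network
    w = |r|^2 with zero diagonal.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 2 or bold.shape[0] < 2:
        raise ValueError("bold must be a (regions >= 2) x timepoints matrix")
    if not 1 <= level <= levels:
        raise ValueError(f"analysis level {level} outside 1..{levels}")
    sd = bold.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = region_names or [f"region {i}" for i in range(bold.shape[0])]
        bad = ", ".join(names[i] for i in flat[:5])
        raise ValueError(
            f"constant BOLD signal leaves the wavelet correlation undefined for: {bad}"
        )
    details, _ = _modwt_matrix(bold, levels, family)
    coeffs = details[level - 1]
    if exclude_boundary:
        coeffs = coeffs[:, boundary_coefficient_count(level, family):]
    r = np.corrcoef(coeffs)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    w = np.abs(r) ** 2
    np.fill_diagonal(w, 0.0)
    return (
        CorrelationMatrix(r=r, band_index=level, region_names=region_names),
        WeightedNetwork(w=w, region_names=region_names),
    )


def regional_mean_timeseries(volume_series, labels) -> np.ndarray:
    """Probability-weighted mean BOLD series per region.

    ``volume_series`` is a 4-D array (x, y, z, t) or a NIfTI-style image;
    ``labels`` is a LabelVolumeSet whose probabilities are thresholded at
    p > 0.25 with overlap resolution before weighting.  Raises if a region
    retains no voxels.
    """
    if hasattr(volume_series, "get_fdata"):
        volume_series = volume_series.get_fdata()
    vol = np.asarray(volume_series, dtype=float)
    if vol.ndim != 4:
        raise ValueError("volume_series must be 4-D (x, y, z, t)")
    weights = labels.effective_weights()
    if weights.shape[1:] != vol.shape[:3]:
        raise ValueError(
            f"label grid {weights.shape[1:]} does not match volume grid {vol.shape[:3]}"
        )
    totals = weights.reshape(weights.shape[0], -1).sum(axis=1)
    empty = np.flatnonzero(totals == 0)
    if empty.size:
        bad = ", ".join(labels.region_names[i] for i in empty[:5])
        raise ValueError(
            f"no voxels survive the p > {labels.threshold} threshold for region(s): {bad}"
        )
    flat_w = weights.reshape(weights.shape[0], -1)
    flat_v = vol.reshape(-1, vol.shape[3])
    return (flat_w @ flat_v) / totals[:, None]
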