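"""Spectral preprocessing chain for 1D NMR metabolomics.

The chain applied to every sample (and to every library standard) before
quantification:

1. baseline subtraction — the pooled mean intensity in the two signal-free
   edge regions (up-field of -3 ppm, down-field of 12.5 ppm) is subtracted;
2. reference normalization — intensities are divided by the trapezoidal
   integral of the 0-ppm reference (DSS) peak window, so spectra share a
   common relative scale;
3. global FFT cross-correlation alignment of each spectrum to a reference
   spectrum (a single whole-spectrum shift; segment-wise alignment is out of
   scope);
4. window selection 0.5-9.5 ppm with the water region 4.5-5.2 ppm removed;
5. binning: mean intensity over half-open 0.0008-ppm bins anchored at the
   window start.

Steps are exposed individually so the order can be changed; the default
order above is what :func:`preprocess` applies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spectra import Spectrum

__all__ = [
    "PreprocessConfig",
    "baseline_correct",
    "normalize_to_reference",
    "mask_regions",
    "bin_spectrum",
    "n_bins_in_window",
    "align_fft",
    "preprocess",
]

DEFAULT_ORDER = ("baseline", "normalize", "align", "mask", "bin")


@dataclass
class PreprocessConfig:
    """Constants of the preprocessing chain (all in ppm)."""

    window: tuple[float, float] = (0.5, 9.5)
    water_region: tuple[float, float] = (4.5, 5.2)
    bin_width: float = 0.0008
    baseline_edges: tuple[float, float] = (-3.0, 12.5)  # up-field of lo, down-field of hi
    reference_ppm: float = 0.0
    reference_halfwindow: float = 0.05

    def __post_init__(self) -> None:
        if self.window[0] >= self.window[1]:
            raise ValueError("window must be (low, high) with low < high")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.reference_halfwindow <= 0:
            raise ValueError("reference_halfwindow must be positive")


def baseline_correct(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Subtract the pooled mean intensity of the two signal-free edge regions."""
    cfg = cfg or PreprocessConfig()
    lo, hi = cfg.baseline_edges
    mask = (s.ppm < lo) | (s.ppm > hi)
    if not mask.any():
        raise ValueError(
            f"no points up-field of {lo} ppm or down-field of {hi} ppm; "
            "skip the baseline step for this axis"
        )
    baseline = float(s.intensity[mask].mean())
    return s.copy(intensity=s.intensity - baseline)


def normalize_to_reference(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Divide by the trapezoidal integral of the reference-peak window.

    The reference window is ``reference_ppm +/- reference_halfwindow``; after
    normalization the reference integral is exactly 1.  Area rather than peak
    height is integrated for robustness to noise on the peak maximum.
    """
    cfg = cfg or PreprocessConfig()
    lo = cfg.reference_ppm - cfg.reference_halfwindow
    hi = cfg.reference_ppm + cfg.reference_halfwindow
    mask = (s.ppm >= lo) & (s.ppm <= hi)
    if mask.sum() < 2:
        raise ValueError(f"reference window [{lo}, {hi}] ppm contains fewer than 2 points")
    area = float(np.trapezoid(s.intensity[mask], s.ppm[mask]))
    if area <= 0:
        raise ValueError(
            f"no reference peak detected: integral over [{lo}, {hi}] ppm is {area:g} <= 0"
        )
    return s.copy(intensity=s.intensity / area)


def mask_regions(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Keep the analysis window and drop the water region.

    Points outside ``window`` (inclusive) are removed, then points strictly
    inside the closed ``water_region`` are removed.
    """
    cfg = cfg or PreprocessConfig()
    wlo, whi = cfg.window
    alo, ahi = cfg.water_region
    keep = (s.ppm >= wlo) & (s.ppm <= whi) & ~((s.ppm >= alo) & (s.ppm <= ahi))
    if not keep.any():
        raise ValueError("masking removed every point; check window/water settings")
    return s.copy(ppm=s.ppm[keep], intensity=s.intensity[keep])


def bin_spectrum(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Average intensities over half-open ppm bins of width ``bin_width``.

    Bins are ``[left, left + w)`` anchored at the first retained ppm value
    (the window start once :func:`mask_regions` has run).  Output ppm values
    are bin centers; empty bins (e.g. across the removed water region) are
    dropped.  A partial trailing bin is kept if it contains at least one
    point; a point falling exactly on the final right edge is assigned to the
    last bin.
    """
    cfg = cfg or PreprocessConfig()
    w = cfg.bin_width
    step = s.step
    if w < step * (1 - 1e-9):
        raise ValueError(f"bin_width {w} ppm is below the native grid step {step:.3g} ppm")
    start = float(s.ppm[0])
    q = (s.ppm - start) / w
    # points within 1e-6 bin-widths of a boundary from below belong to the next bin
    idx = np.floor(q + 1e-6).astype(np.int64)
    # histogram convention: the final bin is closed on the right, so a point
    # landing exactly on the span's right edge joins the last bin
    n_bins = max(int(np.ceil(q[-1] - 1e-6)), 1)
    np.clip(idx, 0, n_bins - 1, out=idx)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=s.intensity, minlength=n_bins)
    nonempty = counts > 0
    centers = start + (np.arange(n_bins) + 0.5) * w
    return s.copy(ppm=centers[nonempty], intensity=sums[nonempty] / counts[nonempty])


def n_bins_in_window(cfg: PreprocessConfig | None = None) -> int:
    """Number of half-open bins tiling the analysis window (before water removal)."""
    cfg = cfg or PreprocessConfig()
    span = cfg.window[1] - cfg.window[0]
    return int(np.ceil(span / cfg.bin_width - 1e-9))


def align_fft(
    s: Spectrum, reference: Spectrum, max_shift: float
) -> tuple[Spectrum, float]:
    """Align ``s`` to ``reference`` by circular FFT cross-correlation.

    The circular lag (restricted to ``+/- max_shift`` ppm) maximizing the
    cross-correlation between the two intensity vectors is found, and ``s``
    is rolled by that many grid points.  Returns the aligned spectrum and the
    estimated displacement of ``s`` relative to the reference, in ppm
    (positive: features of ``s`` sat at higher ppm than the reference's).
    Ties are broken toward the smallest absolute lag.
    """
    if not s.same_grid(reference):
        raise ValueError("spectra must share the same ppm grid for alignment")
    n = len(s)
    step = s.step
    max_lag = int(np.floor(max_shift / step + 1e-9))
    if max_lag <= 0:
        return s.copy(), 0.0
    max_lag = min(max_lag, n // 2)
    fa = np.fft.rfft(s.intensity)
    fb = np.fft.rfft(reference.intensity)
    xcorr = np.fft.irfft(fa * np.conj(fb), n=n)  # xcorr[k] = sum_i s[i] ref[i-k]
    lags = np.concatenate([np.arange(0, max_lag + 1), np.arange(-max_lag, 0)])
    vals = xcorr[lags % n]
    order = np.lexsort((np.abs(lags), -vals))  # best correlation, then smallest |lag|
    best = int(lags[order[0]])
    aligned = np.roll(s.intensity, -best)
    return s.copy(intensity=aligned), best * step


def preprocess(
    s: Spectrum,
    cfg: PreprocessConfig | None = None,
    reference: Spectrum | None = None,
    max_shift: float = 0.02,
    order: Sequence[str] = DEFAULT_ORDER,
    skip: Sequence[str] = (),
) -> Spectrum:
    """Run the preprocessing chain in the given order.

    ``reference`` is the alignment target; when omitted the ``align`` step is
    skipped.  Steps named in ``skip`` are omitted.
    """
    cfg = cfg or PreprocessConfig()
    steps = {
        "baseline": lambda x: baseline_correct(x, cfg),
        "normalize": lambda x: normalize_to_reference(x, cfg),
        "align": lambda x: align_fft(x, reference, max_shift)[0] if reference is not None else x,
        "mask": lambda x: mask_regions(x, cfg),
        "bin": lambda x: bin_spectrum(x, cfg),
    }
    unknown = set(order) - set(steps)
    if unknown:
        raise ValueError(f"unknown preprocessing steps: {sorted(unknown)}")
    out = s
    for name in order:
        if name in skip:
            continue
        out = steps[name](out)
    return out
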