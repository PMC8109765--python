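"""Spectrum container and plain-text spectrum I/O.

A 1D NMR spectrum is a chemical-shift axis (ppm) plus an intensity vector.
Files are two-column whitespace-delimited text (ppm, intensity), one file per
sample.  By NMR convention files are often written with the ppm axis
descending; internally the axis is always stored ascending, and descending
files are reversed on read so that shift arithmetic has a single sign
convention throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

__all__ = ["Spectrum", "SpectrumParseError", "read_spectrum", "write_spectrum"]


class SpectrumParseError(ValueError):
    """Raised when a spectrum text file cannot be parsed."""


@dataclass
class Spectrum:
    """One 1D spectrum: ppm axis, intensity vector, free-form metadata.

    Parameters
    ----------
    ppm
        Strictly monotone chemical-shift grid in ppm. Stored ascending; a
        descending input is reversed (together with ``intensity``).
    intensity
        Real intensity values, same length as ``ppm``, all finite.
    metadata
        Sample annotations (sample_id, fluid, pulse_sequence, group labels...).
    """

    ppm: np.ndarray
    intensity: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D arrays")
        if self.ppm.size != self.intensity.size:
            raise ValueError(
                f"ppm and intensity lengths differ: {self.ppm.size} vs {self.intensity.size}"
            )
        if self.ppm.size == 0:
            raise ValueError("empty spectrum")
        d = np.diff(self.ppm)
        if np.all(d < 0):  # descending file, NMR convention: store ascending
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d > 0):
            raise ValueError("ppm axis must be strictly monotone")
        if not np.all(np.isfinite(self.ppm)) or not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite values in spectrum")

    def __len__(self) -> int:
        return int(self.ppm.size)

    @property
    def step(self) -> float:
        """Median grid step in ppm."""
        return float(np.median(np.diff(self.ppm)))

    def copy(self, intensity: np.ndarray | None = None, ppm: np.ndarray | None = None) -> "Spectrum":
        return Spectrum(
            ppm=self.ppm.copy() if ppm is None else np.asarray(ppm, dtype=float),
            intensity=self.intensity.copy() if intensity is None else np.asarray(intensity, dtype=float),
            metadata=dict(self.metadata),
        )

    def same_grid(self, other: "Spectrum", rtol: float = 1e-9, atol: float = 1e-12) -> bool:
        return self.ppm.shape == other.ppm.shape and np.allclose(
            self.ppm, other.ppm, rtol=rtol, atol=atol
        )


def read_spectrum(path: str | Path, metadata: dict[str, Any] | None = None) -> Spectrum:
    """Read a two-column (ppm, intensity) text spectrum.

    Blank lines and lines starting with ``#`` are ignored.  A ragged or
    non-numeric row raises :class:`SpectrumParseError` naming the line number.
    """
    path = Path(path)
    ppm: list[float] = []
    intensity: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 2:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                ppm.append(float(parts[0]))
                intensity.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: non-numeric value in {stripped!r}"
                ) from exc
    if not ppm:
        raise SpectrumParseError(f"{path}: no data rows")
    meta = dict(metadata or {})
    meta.setdefault("sample_id", path.stem)
    return Spectrum(np.array(ppm), np.array(intensity), meta)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column text at full double precision."""
    data = np.column_stack([spectrum.ppm, spectrum.intensity])
    np.savetxt(path, data, fmt="%.17g")
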