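"""Relative metabolite quantification by constrained full-spectrum fitting.

A sample spectrum is modeled as a nonnegative linear combination of
unit-normalized standard spectra on a shared ppm grid:

    minimize ||y - S^T c||_2   subject to  c >= 0

where the rows of S are the standards (each summing to 1 over the grid) and
y is the preprocessed, reference-normalized sample.  Because both sides share
the reference-peak scale, the fitted coefficients c are relative
concentrations comparable across samples.  The fit uses the full spectral
region, so metabolites without fully resolved isolated peaks still
contribute through their complete multiplet pattern.

The convex problem is solved by active-set nonnegative least squares
(``scipy.optimize.nnls``); an iterative two-stage mode (unconstrained start,
bounded trust-region refinement) and a per-standard independent mode are
provided for comparison.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .spectra import Spectrum, read_spectrum
from .tables import META_COLUMNS

__all__ = [
    "StandardLibrary",
    "QuantResult",
    "interpolate_library",
    "fit_concentrations",
    "quantify_cohort",
    "read_library",
    "write_library",
]

COLLINEARITY_WARN_CONDITION = 1e6


@dataclass
class StandardLibrary:
    """Named standard spectra on a common ppm axis, rows normalized to unit total intensity."""

    names: list[str]
    matrix: np.ndarray  # standards x grid points
    axis: np.ndarray  # ppm grid, ascending

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        self.names = list(self.names)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (standards x grid)")
        if self.matrix.shape != (len(self.names), self.axis.size):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.names)} names and axis of {self.axis.size} points"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("standard names must be unique")
        if not np.all(np.diff(self.axis) > 0):
            raise ValueError("library axis must be strictly ascending")

    def __len__(self) -> int:
        return len(self.names)

    def normalized(self) -> "StandardLibrary":
        """Return a copy with each row rescaled to total intensity 1."""
        totals = self.matrix.sum(axis=1)
        if np.any(totals <= 0):
            bad = [self.names[i] for i in np.flatnonzero(totals <= 0)]
            raise ValueError(f"standards with nonpositive total intensity: {bad}")
        return StandardLibrary(self.names, self.matrix / totals[:, None], self.axis.copy())


@dataclass
class QuantResult:
    """Fitted relative concentrations for one sample."""

    names: list[str]
    concentrations: np.ndarray  # >= 0, one per standard
    residual_norm: float
    r_squared: float
    mode: str = "nnls"
    warnings: list[str] = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return pd.Series(self.concentrations, index=self.names)


def interpolate_library(lib: StandardLibrary, target_axis: np.ndarray) -> StandardLibrary:
    """Linearly interpolate every standard onto ``target_axis`` and re-normalize.

    Raises if the target axis extends beyond the library's span (extrapolation
    of standard spectra is never meaningful).
    """
    target_axis = np.asarray(target_axis, dtype=float)
    if target_axis[0] < lib.axis[0] - 1e-12 or target_axis[-1] > lib.axis[-1] + 1e-12:
        raise ValueError(
            f"target axis [{target_axis[0]:g}, {target_axis[-1]:g}] ppm extends beyond "
            f"library span [{lib.axis[0]:g}, {lib.axis[-1]:g}] ppm"
        )
    rows = np.vstack([np.interp(target_axis, lib.axis, row) for row in lib.matrix])
    return StandardLibrary(list(lib.names), rows, target_axis).normalized()


def _solve_two_stage(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Unconstrained least-squares start, then bounded trust-region refinement."""
    c0, *_ = np.linalg.lstsq(A, y, rcond=None)
    c0 = np.clip(c0, 0.0, None)
    res = optimize.least_squares(
        lambda c: A @ c - y, c0, bounds=(0.0, np.inf), method="trf", xtol=1e-12, ftol=1e-12
    )
    return res.x


def fit_concentrations(
    sample: Spectrum, lib: StandardLibrary, mode: str = "nnls"
) -> QuantResult:
    """Fit nonnegative relative concentrations of all standards to one sample.

    Modes
    -----
    ``"nnls"`` (default)
        Active-set nonnegative least squares; deterministic global optimum of
        the convex problem.
    ``"two_stage"``
        Unconstrained linear fit as starting point, refined by a bounded
        least-squares solver.  Converges to the same optimum; kept for
        parity with iterative curve-fitting workflows.
    ``"independent"``
        Each standard fit alone against the sample (clipped at zero),
        ignoring all other standards.
    """
    if len(lib) == 0:
        raise ValueError("empty standard library")
    if sample.ppm.shape != lib.axis.shape or not np.allclose(sample.ppm, lib.axis):
        raise ValueError("sample is not on the library axis; interpolate the library first")
    recorded: list[str] = []
    y = sample.intensity
    A = lib.matrix.T  # grid x standards
    if not y.any():
        msg = "all-zero sample spectrum; returning all-zero concentrations"
        warnings.warn(msg, stacklevel=2)
        return QuantResult(list(lib.names), np.zeros(len(lib)), 0.0, 1.0, mode, [msg])
    cond = np.linalg.cond(A)
    if cond > COLLINEARITY_WARN_CONDITION:
        msg = f"library condition number {cond:.3g} exceeds {COLLINEARITY_WARN_CONDITION:g}; near-duplicate standards?"
        warnings.warn(msg, stacklevel=2)
        recorded.append(msg)
    if mode == "nnls":
        c, _ = optimize.nnls(A, y)
    elif mode == "two_stage":
        c = _solve_two_stage(A, y)
    elif mode == "independent":
        norms = np.einsum("ij,ij->i", lib.matrix, lib.matrix)
        c = np.clip(lib.matrix @ y / norms, 0.0, None)
    else:
        raise ValueError(f"unknown fit mode {mode!r}")
    resid = y - A @ c
    rnorm = float(np.linalg.norm(resid))
    ss_tot = float(np.dot(y, y))
    r2 = 1.0 - rnorm**2 / ss_tot if ss_tot > 0 else 1.0
    return QuantResult(list(lib.names), c, rnorm, r2, mode, recorded)


def quantify_cohort(
    samples: Sequence[Spectrum], lib: StandardLibrary, mode: str = "nnls"
) -> pd.DataFrame:
    """Quantify a list of identically preprocessed samples.

    Returns a table with the standard metadata columns (sample_id, sex,
    genotype, age_point, fluid) followed by one relative-concentration column
    per metabolite.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample list")
    ref = samples[0]
    offending = [
        s.metadata.get("sample_id", f"#{i}")
        for i, s in enumerate(samples)
        if not s.same_grid(ref)
    ]
    if offending:
        raise ValueError(f"samples not on a common grid: {offending}")
    rows: list[dict[str, Any]] = []
    for s in samples:
        result = fit_concentrations(s, lib, mode=mode)
        row = {col: s.metadata.get(col) for col in META_COLUMNS}
        row.update(zip(result.names, result.concentrations))
        rows.append(row)
    return pd.DataFrame(rows)


def write_library(lib: StandardLibrary, directory: str | Path) -> None:
    """Write a library as one two-column text file per standard plus a manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "file"])
        for name, row in zip(lib.names, lib.matrix):
            fname = f"{name}.txt"
            np.savetxt(directory / fname, np.column_stack([lib.axis, row]), fmt="%.17g")
            writer.writerow([name, fname])


def read_library(directory: str | Path) -> StandardLibrary:
    """Read a library written by :func:`write_library` (manifest.csv + text spectra)."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    names, rows, axis = [], [], None
    for _, rec in manifest.iterrows():
        s = read_spectrum(directory / rec["file"])
        if axis is None:
            axis = s.ppm
        elif not np.allclose(axis, s.ppm):
            raise ValueError(f"standard {rec['name']!r} is not on the common library axis")
        names.append(str(rec["name"]))
        rows.append(s.intensity)
    if axis is None:
        raise ValueError(f"empty manifest in {directory}")
    return StandardLibrary(names, np.vstack(rows), axis)
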