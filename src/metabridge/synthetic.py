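"""Synthetic data generation emulating a two-biofluid NMR metabolomics study.

Three generators, each with a ground-truth record, stand in for data that a
real study would measure:

* **standard spectra** — sums of Lorentzian lines on a ppm grid, normalized
  to unit total intensity, a synthetic substitute for database standards;
* **mixture spectra** — known nonnegative combinations of standards plus
  baseline, global shift, noise and a 0-ppm reference peak, exercising the
  preprocessing and quantification chain;
* **concentration tables** — a Gaussian copula imposes a prescribed
  cross-fluid Spearman correlation structure on log-normal marginals, with
  genotype/age mean offsets applied on the log scale, emulating the study
  design: 2 fluids x 2 sexes x 2 genotypes x 2 age points with a few pooled
  replicates per cell and ~51 shared metabolites.

The copula uses the exact Gaussian relation rho_pearson = 2 sin(pi rho_S/6),
so target rank correlations are achieved exactly in the large-sample limit;
monotone (exp) marginal transforms and additive log-scale group offsets
leave Spearman correlations untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .quantify import StandardLibrary
from .spectra import Spectrum
from .tables import AGE_POINTS, GENOTYPES, SEXES

__all__ = [
    "SyntheticStandardSpec",
    "StudyDesign",
    "CopulaSpec",
    "lorentzian",
    "make_standard_library",
    "default_standard_specs",
    "synthesize_mixture_spectrum",
    "simulate_concentration_table",
    "spearman_to_pearson",
    "pearson_to_spearman",
    "default_group_effects",
]

PPM_MIN, PPM_MAX = 0.5, 9.5  # metabolite signal region


def lorentzian(x: np.ndarray, center: float, height: float, hwhm: float) -> np.ndarray:
    """Lorentzian line: height * hwhm^2 / ((x-center)^2 + hwhm^2)."""
    return height * hwhm**2 / ((x - center) ** 2 + hwhm**2)


def spearman_to_pearson(rho_s: np.ndarray | float) -> np.ndarray | float:
    """Latent Pearson correlation achieving a target Spearman under a Gaussian copula."""
    return 2.0 * np.sin(np.pi * np.asarray(rho_s, dtype=float) / 6.0)


def pearson_to_spearman(r: np.ndarray | float) -> np.ndarray | float:
    """Population Spearman correlation of a bivariate Gaussian with Pearson r."""
    return (6.0 / np.pi) * np.arcsin(np.asarray(r, dtype=float) / 2.0)


@dataclass
class SyntheticStandardSpec:
    """Peak list defining one synthetic standard spectrum.

    ``peaks`` is a list of (center ppm, height >= 0, half-width-at-half-max
    ppm > 0); all centers must lie in the metabolite signal region
    [0.5, 9.5] ppm.
    """

    name: str
    peaks: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"standard {self.name!r} has no peaks")
        for center, height, hwhm in self.peaks:
            if not (PPM_MIN <= center <= PPM_MAX):
                raise ValueError(
                    f"standard {self.name!r}: peak center {center} ppm outside "
                    f"[{PPM_MIN}, {PPM_MAX}] ppm"
                )
            if height < 0:
                raise ValueError(f"standard {self.name!r}: negative peak height {height}")
            if hwhm <= 0:
                raise ValueError(f"standard {self.name!r}: nonpositive peak width {hwhm}")


def make_standard_library(
    specs: list[SyntheticStandardSpec], axis: np.ndarray
) -> StandardLibrary:
    """Evaluate Lorentzian peak lists on ``axis`` and normalize to unit total intensity."""
    axis = np.asarray(axis, dtype=float)
    if not specs:
        raise ValueError("no standard specs given")
    if not np.all(np.diff(axis) > 0):
        raise ValueError("axis must be strictly ascending")
    rows = []
    for spec in specs:
        for center, _, _ in spec.peaks:
            if not (axis[0] <= center <= axis[-1]):
                raise ValueError(
                    f"standard {spec.name!r}: peak at {center} ppm outside the "
                    f"axis range [{axis[0]:g}, {axis[-1]:g}] ppm"
                )
        rows.append(sum(lorentzian(axis, c, h, w) for c, h, w in spec.peaks))
    names = [s.name for s in specs]
    return StandardLibrary(names, np.vstack(rows), axis).normalized()


def default_standard_specs(
    n: int,
    rng: np.random.Generator,
    names: list[str] | None = None,
    peaks_per_standard: tuple[int, int] = (2, 5),
    width: float = 0.002,
) -> list[SyntheticStandardSpec]:
    """Reproducible random peak lists: a few Lorentzians per standard.

    Peak centers avoid the water region margins only implicitly (uniform over
    [0.7, 9.3] ppm); heights U[0.3, 1]; widths ``width`` scaled by U[0.5, 2].
    """
    if names is None:
        names = [f"met{i + 1:02d}" for i in range(n)]
    if len(names) != n:
        raise ValueError("names length must equal n")
    specs = []
    for name in names:
        k = int(rng.integers(peaks_per_standard[0], peaks_per_standard[1] + 1))
        centers = rng.uniform(0.7, 9.3, size=k)
        heights = rng.uniform(0.3, 1.0, size=k)
        widths = width * rng.uniform(0.5, 2.0, size=k)
        specs.append(SyntheticStandardSpec(name, list(zip(centers, heights, widths))))
    return specs


def synthesize_mixture_spectrum(
    library: StandardLibrary,
    concentrations: np.ndarray,
    baseline_offset: float = 0.0,
    shift: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    reference_height: float = 50.0,
    reference_hwhm: float = 0.002,
    metadata: dict[str, Any] | None = None,
) -> tuple[Spectrum, dict[str, Any]]:
    """Known mixture of library standards plus baseline, shift, noise and reference peak.

    The metabolite signal ``sum_i c_i * standard_i`` is circularly shifted by
    ``shift`` ppm (rounded to the nearest grid point), then a constant
    ``baseline_offset``, i.i.d. Gaussian noise of ``noise_sd``, and a tall
    Lorentzian reference peak at 0 ppm are added.  The returned ground-truth
    record stores every parameter, including the on-grid reference area, so
    recovery after preprocessing and quantification can be checked.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    if concentrations.shape != (len(library),):
        raise ValueError(
            f"need {len(library)} concentrations, got shape {concentrations.shape}"
        )
    if np.any(concentrations < 0):
        bad = np.flatnonzero(concentrations < 0)
        raise ValueError(f"negative concentrations at indices {bad.tolist()}")
    axis = library.axis
    signal = concentrations @ library.matrix
    step = float(np.median(np.diff(axis)))
    shift_points = int(round(shift / step))
    signal = np.roll(signal, shift_points)
    reference = np.zeros_like(axis)
    reference_area = 0.0
    if reference_height > 0:
        if not (axis[0] <= 0.0 <= axis[-1]):
            raise ValueError("axis must cover 0 ppm to place the reference peak")
        reference = lorentzian(axis, 0.0, reference_height, reference_hwhm)
        reference_area = float(np.trapezoid(reference, axis))
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=axis.size) if noise_sd > 0 else 0.0
    intensity = signal + reference + baseline_offset + noise
    truth = {
        "concentrations": concentrations.copy(),
        "names": list(library.names),
        "baseline_offset": baseline_offset,
        "shift_requested": shift,
        "shift_applied": shift_points * step,
        "noise_sd": noise_sd,
        "seed": seed,
        "reference_area": reference_area,
        "reference_height": reference_height,
    }
    return Spectrum(axis.copy(), intensity, dict(metadata or {})), truth


def default_groups() -> list[tuple[str, str, str]]:
    """All sex x genotype x age-point combinations of the study design."""
    return list(product(SEXES, GENOTYPES, AGE_POINTS))


@dataclass
class StudyDesign:
    """Layout of the emulated study.

    Defaults follow the study conditions: 51 metabolites shared between blood
    and CSF, every sex x genotype x age-point cell present, and a small
    number of pooled replicates per cell (each pool treated as one
    replicate).
    """

    n_metabolites_blood: int = 51
    n_metabolites_csf: int = 51
    n_shared: int = 51
    groups: list[tuple[str, str, str]] = field(default_factory=default_groups)
    replicates_per_group: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shared > min(self.n_metabolites_blood, self.n_metabolites_csf):
            raise ValueError("n_shared exceeds a fluid's metabolite count")
        if self.n_shared < 1:
            raise ValueError("need at least one shared metabolite")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("duplicate group label combinations")
        if self.replicates_per_group < 3:
            raise ValueError("replicates_per_group must be >= 3")

    @property
    def shared_names(self) -> list[str]:
        return [f"met{i + 1:02d}" for i in range(self.n_shared)]

    @property
    def blood_names(self) -> list[str]:
        extra = [
            f"blood_only{i + 1:02d}" for i in range(self.n_metabolites_blood - self.n_shared)
        ]
        return self.shared_names + extra

    @property
    def csf_names(self) -> list[str]:
        extra = [f"csf_only{i + 1:02d}" for i in range(self.n_metabolites_csf - self.n_shared)]
        return self.shared_names + extra


@dataclass
class CopulaSpec:
    """Gaussian-copula specification for the cross-fluid dependence.

    ``target_spearman[i, j]`` is the desired Spearman correlation between
    shared metabolite i in blood and shared metabolite j in CSF.  Marginals
    are log-normal per metabolite (blood metabolites first, then CSF);
    ``noise_sd`` adds independent Gaussian measurement noise on the log
    scale, which attenuates the realized correlations (default 0).
    """

    target_spearman: np.ndarray
    marginal_mu: np.ndarray | float = 0.0
    marginal_sigma: np.ndarray | float = 0.5
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.target_spearman = np.atleast_2d(np.asarray(self.target_spearman, dtype=float))
        if np.any(np.abs(self.target_spearman) > 1):
            raise ValueError("target Spearman correlations must lie in [-1, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def joint_correlation(self, design: StudyDesign) -> np.ndarray:
        """Latent correlation matrix over (blood metabolites, CSF metabolites).

        Within-fluid latent correlations are zero; the cross block between
        the shared metabolites carries the converted Pearson targets.
        Raises if the assembled matrix is not positive semi-definite.
        """
        ns = design.n_shared
        if self.target_spearman.shape != (ns, ns):
            raise ValueError(
                f"target_spearman shape {self.target_spearman.shape} does not match "
                f"n_shared={ns}"
            )
        nb, nc = design.n_metabolites_blood, design.n_metabolites_csf
        d = nb + nc
        corr = np.eye(d)
        cross = spearman_to_pearson(self.target_spearman)
        corr[:ns, nb : nb + ns] = cross
        corr[nb : nb + ns, :ns] = cross.T
        eigmin = float(np.linalg.eigvalsh(corr).min())
        if eigmin < -1e-8:
            raise ValueError(
                f"joint latent correlation is not positive semi-definite "
                f"(smallest eigenvalue {eigmin:.3e}); weaken the targets"
            )
        return corr


def default_copula_spec(design: StudyDesign, rho_shared: float = 0.5) -> CopulaSpec:
    """Diagonal cross-fluid structure: each shared metabolite tracks itself at ``rho_shared``."""
    return CopulaSpec(target_spearman=np.eye(design.n_shared) * rho_shared)


def default_group_effects(design: StudyDesign) -> dict[tuple[str, str], np.ndarray]:
    """Mean offsets on the log scale per (genotype, age_point).

    Genotype affects the first half of the metabolites with alternating sign
    (+/-0.3), age the first two thirds with alternating sign (+/-0.2), so the
    emulated cohort shows both increases and decreases over time and between
    genotypes, as real metabolite panels do.
    """
    d = design.n_metabolites_blood + design.n_metabolites_csf
    idx = np.arange(d)
    genotype_effect = np.where(idx < d // 2, 0.3 * (-1.0) ** idx, 0.0)
    age_effect = np.where(idx < 2 * d // 3, 0.2 * (-1.0) ** (idx // 2), 0.0)
    return {
        (g, a): (genotype_effect if g == "APP" else 0.0) + (age_effect if a == "late" else 0.0)
        for g, a in product(GENOTYPES, AGE_POINTS)
    }


def simulate_concentration_table(
    design: StudyDesign,
    copula: CopulaSpec | None = None,
    group_effects: Mapping[tuple[str, str], np.ndarray | float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, Any]]:
    """Draw matched blood and CSF concentration tables from the copula model.

    Each replicate of each group draws one joint latent Gaussian vector; its
    blood and CSF halves are pushed through log-normal marginals (so the
    blood and CSF rows of one pool are dependent exactly as prescribed).
    Returns (blood table, CSF table, ground truth).
    """
    copula = copula if copula is not None else default_copula_spec(design)
    if group_effects is None:
        group_effects = default_group_effects(design)
    nb, nc = design.n_metabolites_blood, design.n_metabolites_csf
    d = nb + nc
    corr = copula.joint_correlation(design)
    evals, evecs = np.linalg.eigh(corr)
    factor = evecs * np.sqrt(np.clip(evals, 0.0, None))
    mu = np.broadcast_to(np.asarray(copula.marginal_mu, dtype=float), (d,))
    sigma = np.broadcast_to(np.asarray(copula.marginal_sigma, dtype=float), (d,))
    rng = np.random.default_rng(design.seed)
    blood_rows, csf_rows = [], []
    for sex, genotype, age_point in design.groups:
        offset = np.broadcast_to(
            np.asarray(group_effects.get((genotype, age_point), 0.0), dtype=float), (d,)
        )
        for rep in range(design.replicates_per_group):
            z = factor @ rng.standard_normal(d)
            log_value = mu + sigma * z + offset
            if copula.noise_sd > 0:
                log_value = log_value + rng.normal(0.0, copula.noise_sd, size=d)
            value = np.exp(log_value)
            sample_id = f"{sex}_{genotype}_{age_point}_r{rep + 1}"
            meta = {
                "sample_id": sample_id,
                "sex": sex,
                "genotype": genotype,
                "age_point": age_point,
            }
            blood_rows.append(
                {**meta, "fluid": "blood", **dict(zip(design.blood_names, value[:nb]))}
            )
            csf_rows.append(
                {**meta, "fluid": "csf", **dict(zip(design.csf_names, value[nb:]))}
            )
    truth = {
        "target_spearman": copula.target_spearman.copy(),
        "latent_correlation": corr,
        "marginal_mu": np.array(mu),
        "marginal_sigma": np.array(sigma),
        "group_effects": {k: np.broadcast_to(np.asarray(v, dtype=float), (d,)).copy()
                          for k, v in group_effects.items()},
        "noise_sd": copula.noise_sd,
        "seed": design.seed,
    }
    return pd.DataFrame(blood_rows), pd.DataFrame(csf_rows), truth
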