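"""End-to-end orchestration: simulate -> preprocess -> quantify -> network -> rank -> summarize.

The pipeline is driven by a plain-text YAML config (see DEFAULT_CONFIG for
the schema and defaults).  Two modes:

* ``concentrations`` — simulate concentration tables directly and run the
  statistical stages;
* ``spectra`` — additionally render every sample as a synthetic NMR mixture
  spectrum, run the full preprocessing chain, and quantify by constrained
  fitting before the statistical stages (requires all metabolites shared
  between fluids so one standard library serves both).

Every stage writes CSV artifacts into the output directory; a run log
records the seed, package versions and stages executed.  All randomness
derives from the single config seed, so a rerun is byte-identical.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .corrnet import differential_correlations, harmonize_pairs, significance_filter, spearman_matrix
from .preprocess import PreprocessConfig, bin_spectrum, mask_regions, preprocess
from .quantify import StandardLibrary, quantify_cohort, write_library
from .ranking import build_block_matrix, connectedness_scores, rank_and_diff, ranking_table
from .spectra import Spectrum
from .summarize import anova_rank, log_ratio_table, ridge_consensus
from .synthetic import (
    CopulaSpec,
    StudyDesign,
    default_copula_spec,
    default_standard_specs,
    make_standard_library,
    simulate_concentration_table,
    synthesize_mixture_spectrum,
)
from .tables import GENOTYPES, SEXES, metabolite_columns, select_group, write_table

__all__ = ["DEFAULT_CONFIG", "PipelineError", "load_config", "run_pipeline"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "outdir": "metabridge_run",
    "mode": "concentrations",  # or "spectra"
    "design": {
        "n_metabolites_blood": 12,
        "n_metabolites_csf": 12,
        "n_shared": 12,
        "replicates_per_group": 4,
    },
    "copula": {"rho_shared": 0.6, "marginal_mu": 0.0, "marginal_sigma": 0.5, "noise_sd": 0.0},
    "spectra": {
        "ppm_min": -3.5,
        "ppm_max": 13.0,
        "step": 0.0008,
        "noise_sd": 0.001,
        "baseline_offset": 0.05,
        "max_shift": 0.01,
        "shift_sd": 0.002,
    },
    "network": {"alpha": 0.05},
    "summarize": {"top_k": 5, "ridge_lambda": 1.0},
}

REQUIRED_KEYS = ("seed", "outdir", "mode")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML config and merge it over the documented defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError("config must be a mapping")
    return validate_config(user)


def validate_config(user: dict[str, Any]) -> dict[str, Any]:
    """Check required keys, reject unknown ones, and fill in defaults."""
    for key in REQUIRED_KEYS:
        if key not in user:
            raise ValueError(f"config missing required key: {key!r}")
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            sub_unknown = set(value) - set(cfg[key])
            if sub_unknown:
                raise ValueError(f"unknown config keys under {key!r}: {sorted(sub_unknown)}")
            cfg[key].update(value)
        else:
            cfg[key] = value
    if cfg["mode"] not in ("concentrations", "spectra"):
        raise ValueError(f"mode must be 'concentrations' or 'spectra', got {cfg['mode']!r}")
    return cfg


def _preprocess_library(lib: StandardLibrary, pp: PreprocessConfig) -> StandardLibrary:
    """Mask and bin every standard exactly like the samples, then re-normalize."""
    rows, axis = [], None
    for name, row in zip(lib.names, lib.matrix):
        s = bin_spectrum(mask_regions(Spectrum(lib.axis, row), pp), pp)
        if axis is None:
            axis = s.ppm
        rows.append(s.intensity)
    return StandardLibrary(list(lib.names), np.vstack(rows), axis).normalized()


def _spectra_stage(
    cfg: dict[str, Any],
    design: StudyDesign,
    tables: dict[str, pd.DataFrame],
    outdir: Path,
    log: list[str],
) -> dict[str, pd.DataFrame]:
    """Render, preprocess and quantify synthetic spectra for every sample."""
    sp = cfg["spectra"]
    if not (design.n_metabolites_blood == design.n_metabolites_csf == design.n_shared):
        raise ValueError("spectra mode requires all metabolites shared between fluids")
    axis = np.arange(sp["ppm_min"], sp["ppm_max"] + sp["step"] / 2, sp["step"])
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg["seed"]), 1]))
    specs = default_standard_specs(design.n_shared, rng, names=design.shared_names)
    lib = make_standard_library(specs, axis)
    write_library(lib, outdir / "library")
    pp = PreprocessConfig()
    binned_lib = _preprocess_library(lib, pp)
    quantified: dict[str, pd.DataFrame] = {}
    reference_spectrum = None
    for fluid, table in tables.items():
        mets = metabolite_columns(table)
        processed = []
        for i, row in table.iterrows():
            spectrum, _ = synthesize_mixture_spectrum(
                lib,
                row[mets].to_numpy(dtype=float),
                baseline_offset=sp["baseline_offset"],
                shift=float(rng.normal(0.0, sp["shift_sd"])),
                noise_sd=sp["noise_sd"],
                seed=int(rng.integers(2**31)),
                metadata={c: row[c] for c in table.columns if c not in mets},
            )
            partial = preprocess(spectrum, pp, order=("baseline", "normalize"))
            if reference_spectrum is None:
                reference_spectrum = partial
            processed.append(
                preprocess(
                    partial,
                    pp,
                    reference=reference_spectrum,
                    max_shift=sp["max_shift"],
                    order=("align", "mask", "bin"),
                )
            )
        quantified[fluid] = quantify_cohort(processed, binned_lib)
        log.append(f"quantified {len(processed)} {fluid} spectra on {len(binned_lib.axis)} bins")
    return quantified


def run_pipeline(config: dict[str, Any], base_dir: str | Path = ".") -> Path:
    """Run every stage of the analysis; returns the output directory.

    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    cfg = validate_config(config)
    outdir = Path(base_dir) / cfg["outdir"]
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"metabridge {__version__}",
        f"numpy {np.__version__}, pandas {pd.__version__}",
        f"seed {cfg['seed']}",
        f"mode {cfg['mode']}",
    ]
    stage = "simulate"
    try:
        design = StudyDesign(seed=int(cfg["seed"]), **cfg["design"])
        cop = cfg["copula"]
        copula = default_copula_spec(design, rho_shared=cop["rho_shared"])
        copula = CopulaSpec(
            target_spearman=copula.target_spearman,
            marginal_mu=cop["marginal_mu"],
            marginal_sigma=cop["marginal_sigma"],
            noise_sd=cop["noise_sd"],
        )
        blood, csf, _truth = simulate_concentration_table(design, copula)
        tables = {"blood": blood, "csf": csf}
        for fluid, table in tables.items():
            write_table(table, outdir / f"simulated_{fluid}.csv")
        log.append(f"simulated {len(blood)} pools per fluid, {design.n_shared} shared metabolites")

        if cfg["mode"] == "spectra":
            stage = "preprocess+quantify"
            tables = _spectra_stage(cfg, design, tables, outdir, log)
            for fluid, table in tables.items():
                write_table(table, outdir / f"quantified_{fluid}.csv")

        stage = "corrnet"
        alpha = float(cfg["network"]["alpha"])
        nets: dict[tuple[str, str], Any] = {}
        for sex in SEXES:
            for genotype in GENOTYPES:
                b = select_group(tables["blood"], sex=sex, genotype=genotype)
                c = select_group(tables["csf"], sex=sex, genotype=genotype)
                net = significance_filter(spearman_matrix(b, c), alpha=alpha)
                nets[(sex, genotype)] = net
                tag = f"{sex}_{genotype}"
                for name, mat in (("rho", net.rho), ("pvals", net.pvals), ("adjacency", net.A)):
                    pd.DataFrame(mat, index=net.blood_names, columns=net.csf_names).to_csv(
                        outdir / f"{name}_{tag}.csv"
                    )
                log.append(
                    f"network {tag}: n={net.n_samples}, "
                    f"{int(np.count_nonzero(net.A))} significant pairs"
                )

        stage = "differential"
        for sex in SEXES:
            wt, app = nets[(sex, "WT")], nets[(sex, "APP")]
            pairs_app, pairs_wt = harmonize_pairs(app, wt)
            diff = differential_correlations(
                pairs_app, pairs_wt, app.n_samples, wt.n_samples, alpha=alpha
            )
            diff = diff.rename(columns={"r_group1": "r_APP", "r_group2": "r_WT"})
            diff.to_csv(outdir / f"differential_correlations_{sex}.csv", index=False)
            log.append(f"differential {sex}: {int(diff['significant'].sum())} of {len(diff)} pairs")

        stage = "rank"
        score_tables: dict[tuple[str, str, str], pd.Series] = {}
        for (sex, genotype), net in nets.items():
            block = build_block_matrix(net.A)
            ranking = connectedness_scores(block)
            for fluid, scores, names in (
                ("blood", ranking.scores_blood, net.blood_names),
                ("csf", ranking.scores_csf, net.csf_names),
            ):
                tab = ranking_table(scores, names, fluid=fluid)
                tab.to_csv(outdir / f"ranking_{fluid}_{sex}_{genotype}.csv", index=False)
                score_tables[(sex, genotype, fluid)] = pd.Series(
                    scores, index=names, dtype=float
                )
        for sex in SEXES:
            for fluid in ("blood", "csf"):
                diff = rank_and_diff(
                    score_tables[(sex, "WT", fluid)],
                    score_tables[(sex, "APP", fluid)],
                    labels=("WT", "APP"),
                )
                diff.to_csv(outdir / f"ranking_diff_{fluid}_{sex}.csv", index=False)
        log.append("rankings written per sex/genotype/fluid")

        stage = "summarize"
        summ = cfg["summarize"]
        for fluid, table in tables.items():
            log_ratio_table(table).to_csv(outdir / f"log_ratios_{fluid}.csv", index=False)
            anova_rank(table, grouping="genotype").to_csv(
                outdir / f"anova_{fluid}.csv", index=False
            )
            consensus = ridge_consensus(
                table,
                grouping="genotype",
                ridge_lambda=float(summ["ridge_lambda"]),
                k=int(summ["top_k"]),
            )
            pd.DataFrame(
                {
                    "method": ["anova"] * len(consensus["anova_top"])
                    + ["ridge"] * len(consensus["ridge_top"])
                    + ["consensus"] * len(consensus["consensus"]),
                    "metabolite": consensus["anova_top"]
                    + consensus["ridge_top"]
                    + consensus["consensus"],
                }
            ).to_csv(outdir / f"feature_selection_{fluid}.csv", index=False)
            log.append(
                f"summaries for {fluid}: consensus features {consensus['consensus']}"
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    with open(outdir / "config_used.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    (outdir / "report.txt").write_text(
        "metabridge pipeline report\n"
        + "\n".join(f"  {line}" for line in log)
        + "\n"
    )
    return outdir
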