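"""Pipeline drivers: full-trial analysis and simulation reports as CSV bundles.

Two entry points:

* :func:`run_analysis` -- plot-level CSV (or the bundled example trial) in,
  a directory of tables out: ANOVA per trait, cross means with trial
  statistics, GCA/SCA effect tables, variance components and the trait
  correlation matrix, plus ``run.log`` recording every design decision in
  force (heritability definition, SS type, testing denominator,
  parameterization) so no default is silent.
* :func:`run_simulation` -- parameter-recovery experiment out of the
  synthetic-trial generator: per-replicate estimates and a bias/RMSE
  summary.

All CSVs carry full precision; display rounding belongs to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets
from .anova import (
    Ncd2Anova,
    anova_to_frame,
    factorial_partition,
    rcbd_anova,
    trial_stats,
    trial_stats_from_ms,
)
from .combining import combining_ability_table, gca_sca_reference_ls
from .correlation import correlation_frame
from .simulate import RecoveryReport, SimulationConfig, recovery_experiment
from .trial import CrossMeanTable, TrialDataset, cross_mean_table, read_trial_table
from .varcomp import EmsDesign, genetic_summary, heritability_se, solve_ems

__all__ = ["PipelineConfig", "run_analysis", "run_simulation", "run_example_analysis"]


@dataclass
class PipelineConfig:
    input_path: str | None = None  # None -> bundled example trial
    output_dir: str = "ncd2_out"
    traits: tuple[str, ...] | None = None
    parameterization: str = "sum_to_zero"  # or "reference_level"
    reference_female: str | None = None
    reference_male: str | None = None
    alpha: float = 0.05
    denominator: str = "ems"  # F-test denominators: "ems" | "error"
    coeff_additive: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.parameterization not in ("sum_to_zero", "reference_level"):
            raise ValueError("unknown parameterization")


def _log_lines(config: PipelineConfig) -> list[str]:
    return [
        "ncd2 analysis log",
        f"input: {config.input_path or 'bundled example trial'}",
        f"parameterization: {config.parameterization}",
        f"F-test denominators: {config.denominator} "
        "(ems = female/male over interaction, interaction over error)",
        "sums of squares: sequential (type-I), order block -> female -> male -> interaction",
        "error stratum: RCBD residual (block x genotype pooled into error)",
        f"additive-variance coefficient: {config.coeff_additive} * (s2_F + s2_M)",
        "heritability: narrow-sense = s2_A / s2_P (broad-sense s2_G / s2_P also reported)",
        "negative variance components truncated to 0 and flagged",
        f"alpha: {config.alpha}",
    ]


def _combining_frames(
    means: CrossMeanTable,
    traits,
    config: PipelineConfig,
    ms_error: dict[str, float] | None,
    df_error: dict[str, int] | None,
    r: int,
):
    gca_f_rows: dict[str, dict] = {}
    gca_m_rows: dict[str, dict] = {}
    sca_rows: dict[tuple[str, str], dict] = {}
    for trait in traits:
        if config.parameterization == "reference_level":
            table = gca_sca_reference_ls(
                means, trait, config.reference_female, config.reference_male
            )
        else:
            kw = {}
            if ms_error is not None:
                kw = dict(
                    ms_error=ms_error[trait],
                    r=r,
                    df_error=None if df_error is None else df_error[trait],
                    alpha=config.alpha,
                )
            table = combining_ability_table(means, trait, **kw)
        for g in table.gca_female:
            gca_f_rows.setdefault(g.parent, {"parent": g.parent})[trait] = g.effect
        for g in table.gca_male:
            gca_m_rows.setdefault(g.parent, {"parent": g.parent})[trait] = g.effect
        for s in table.sca:
            key = (s.cross.female, s.cross.male)
            sca_rows.setdefault(
                key, {"female": key[0], "male": key[1]}
            )[trait] = s.effect
    return (
        pd.DataFrame(list(gca_f_rows.values())),
        pd.DataFrame(list(gca_m_rows.values())),
        pd.DataFrame(list(sca_rows.values())),
    )


def run_analysis(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run the full pipeline; write the table bundle; return it keyed by name."""
    outdir = Path(config.output_dir)
    if config.input_path is None:
        return run_example_analysis(config)

    dataset = read_trial_table(config.input_path)
    traits = list(config.traits) if config.traits else list(dataset.traits)
    outdir.mkdir(parents=True, exist_ok=True)

    anova_frames = []
    stats_rows = []
    ms_error: dict[str, float] = {}
    df_error: dict[str, int] = {}
    genetic_rows = []
    for trait in traits:
        rcbd = rcbd_anova(dataset, trait)
        part = factorial_partition(dataset, trait, denominator=config.denominator)
        frame = anova_to_frame(part.rows())
        frame.insert(0, "trait", trait)
        anova_frames.append(frame)
        ms_error[trait] = part.error.ms
        df_error[trait] = part.error.df
        st = trial_stats(dataset, trait, rcbd, alpha=config.alpha)
        stats_rows.append(
            {
                "trait": trait,
                "grand_mean": st.grand_mean,
                "se_mean": st.se_mean,
                "lsd_5": st.lsd_5,
                "cv_pct": st.cv_pct,
                "f_prob": st.f_prob,
            }
        )
        components = solve_ems(part)
        summary = genetic_summary(
            components[:4], components[4], coeff_additive=config.coeff_additive
        )
        h2 = summary.h2_narrow
        se = (
            heritability_se(min(max(h2, 0.0), 1.0), part, coeff_additive=config.coeff_additive)
            if np.isfinite(h2)
            else np.nan
        )
        genetic_rows.append(_genetic_row(trait, summary, se))

    means = cross_mean_table(dataset)
    gca_f, gca_m, sca = _combining_frames(
        means, traits, config, ms_error, df_error, dataset.r
    )
    tables = {
        "anova": pd.concat(anova_frames, ignore_index=True),
        "cross_means": means.data[["female", "male", *traits]],
        "trial_stats": pd.DataFrame(stats_rows),
        "gca_female": gca_f,
        "gca_male": gca_m,
        "sca": sca,
        "variance_components": pd.DataFrame(genetic_rows),
        "correlations": correlation_frame(means),
    }
    _write_bundle(tables, outdir, config)
    return tables


def _genetic_row(trait: str, summary, h2_se: float) -> dict:
    return {
        "trait": trait,
        "h2_narrow": summary.h2_narrow,
        "h2_se": h2_se,
        "h2_broad": summary.h2_broad,
        "sigma2_p": summary.sigma2_p,
        "sigma2_a": summary.sigma2_a,
        "sigma2_d": summary.sigma2_d,
        "sigma2_e": summary.sigma2_e,
        "sigma2_g": summary.sigma2_g,
        "dominance_degree": summary.dominance_degree,
        "truncated": ";".join(summary.truncated),
    }


def run_example_analysis(config: PipelineConfig | None = None) -> dict[str, pd.DataFrame]:
    """Mean-only pipeline on the bundled trial (published cross means + mean
    squares): combining ability, variance components, trial statistics and
    correlations.  Plot-level strata cannot be recomputed because replicate
    data were never published; the published mean squares stand in."""
    config = config or PipelineConfig()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    means = datasets.load_example_cross_means()
    ms = datasets.load_example_mean_squares()
    traits = list(config.traits) if config.traits else list(means.traits)
    r = datasets.EXAMPLE_BLOCKS
    design = EmsDesign(p=4, q=3, r=r)

    ms_error = {t: float(ms.loc["error", t]) for t in traits}
    df_error = {t: int(ms.loc["error", "df"]) for t in traits}

    stats_rows = []
    genetic_rows = []
    for trait in traits:
        st = trial_stats_from_ms(
            ms_error=ms_error[trait],
            df_error=df_error[trait],
            r=r,
            grand_mean=means.grand_mean(trait),
            alpha=config.alpha,
        )
        stats_rows.append(
            {
                "trait": trait,
                "grand_mean": st.grand_mean,
                "se_mean": st.se_mean,
                "lsd_5": st.lsd_5,
                "cv_pct": st.cv_pct,
            }
        )
        anova = _anova_from_ms(ms, trait, design)
        components = solve_ems(anova, design)
        summary = genetic_summary(
            components[:4], components[4], coeff_additive=config.coeff_additive
        )
        h2 = summary.h2_narrow
        se = (
            heritability_se(
                min(max(h2, 0.0), 1.0), anova, design, coeff_additive=config.coeff_additive
            )
            if np.isfinite(h2)
            else np.nan
        )
        genetic_rows.append(_genetic_row(trait, summary, se))

    gca_f, gca_m, sca = _combining_frames(means, traits, config, ms_error, df_error, r)
    tables = {
        "cross_means": means.data[["female", "male", *traits]],
        "trial_stats": pd.DataFrame(stats_rows),
        "gca_female": gca_f,
        "gca_male": gca_m,
        "sca": sca,
        "variance_components": pd.DataFrame(genetic_rows),
        "correlations": correlation_frame(means),
    }
    _write_bundle(tables, outdir, config)
    return tables


def _anova_from_ms(ms: pd.DataFrame, trait: str, design: EmsDesign) -> Ncd2Anova:
    """Wrap published mean squares in an ANOVA object for the EMS solver."""
    from .anova import AnovaRow

    def row(source: str) -> AnovaRow:
        df_ = int(ms.loc[source, "df"])
        m = float(ms.loc[source, trait])
        return AnovaRow(source, df_, ss=m * df_, ms=m)

    return Ncd2Anova(
        female=row("female"),
        male=row("male"),
        interaction=row("interaction"),
        error=row("error"),
        p=design.p,
        q=design.q,
        r=design.r,
        n_cells=8,
    )


def _write_bundle(
    tables: dict[str, pd.DataFrame], outdir: Path, config: PipelineConfig
) -> None:
    for name, frame in tables.items():
        index = name == "correlations"
        frame.to_csv(outdir / f"{name}.csv", index=index)
    (outdir / "run.log").write_text("\n".join(_log_lines(config)) + "\n")


def run_simulation(
    config: PipelineConfig, sim: SimulationConfig, n_replicates: int
) -> RecoveryReport:
    """Run a recovery experiment and write recovery.csv + summary.csv."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = recovery_experiment(sim, n_replicates, coeff_additive=config.coeff_additive)
    report.estimates.to_csv(outdir / "recovery.csv", index=False)
    report.summary().to_csv(outdir / "summary.csv", index=False)
    return report
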