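"""RCBD ANOVA and the NCD II factorial partition of the cross sum of squares.

Two stages:

1. :func:`rcbd_anova` -- the randomized-complete-block decomposition
   ``Y_ij = mu + genotype_i + block_j + e_ij`` where each realized cross is
   one genotype.  Block x genotype interaction is pooled into error (the
   model has no interaction term).
2. :func:`factorial_partition` -- the cross (genotype) sum of squares split
   into female, male and female x male strata.  For complete balanced
   designs this is the closed-form marginal-contrast decomposition; for
   incomplete grids (not every female x male cell realized) sequential
   (type-I) least-squares sums of squares are computed in the fixed order
   block -> female -> male -> interaction, with degrees of freedom from
   realized-cell rank.

The expected mean squares of the design are::

    female       MS_F  = s2_e + r*s2_FM + r*q*s2_F
    male         MS_M  = s2_e + r*s2_FM + r*p*s2_M
    female x male MS_FM = s2_e + r*s2_FM
    error        MS_E  = s2_e

so by default female and male mean squares are F-tested against the
interaction mean square and the interaction against error
(``denominator="ems"``); ``denominator="error"`` tests every stratum
against error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trial import TrialDataset

__all__ = [
    "AnovaRow",
    "Ncd2Anova",
    "TrialStats",
    "rcbd_anova",
    "factorial_partition",
    "trial_stats",
    "trial_stats_from_ms",
    "anova_to_frame",
    "significance_stars",
]


def significance_stars(p_value: float) -> str:
    """Footnote convention: ``**`` p<0.01, ``*`` p<0.05, ``ns`` otherwise."""
    if not np.isfinite(p_value):
        return ""
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


@dataclass
class AnovaRow:
    source: str
    df: int
    ss: float
    ms: float = np.nan
    f_value: float = np.nan
    p_value: float = np.nan

    def __post_init__(self) -> None:
        if self.df > 0 and not np.isfinite(self.ms):
            self.ms = self.ss / self.df

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


@dataclass
class Ncd2Anova:
    """Factorial ANOVA of an NCD II trial (female / male / interaction / error)."""

    female: AnovaRow
    male: AnovaRow
    interaction: AnovaRow
    error: AnovaRow
    p: int
    q: int
    r: int
    n_cells: int
    block: AnovaRow | None = None
    denominator: str = "ems"

    def rows(self) -> list[AnovaRow]:
        out = [self.female, self.male, self.interaction, self.error]
        if self.block is not None:
            out = [self.block, *out]
        return out


@dataclass
class TrialStats:
    """Per-trait summary statistics of a replicated trial."""

    grand_mean: float
    se_mean: float       # sqrt(MS_error / r)
    lsd_5: float         # t_(1-alpha/2, df_error) * sqrt(2 * MS_error / r)
    cv_pct: float        # 100 * sqrt(MS_error) / grand mean
    f_prob: float        # p-value of the genotype (cross) F test


def _safe_f(ms_num: float, df_num: int, ms_den: float, df_den: int) -> tuple[float, float]:
    if df_num <= 0 or df_den <= 0 or not np.isfinite(ms_den) or ms_den <= 0:
        return np.nan, np.nan
    f = ms_num / ms_den
    return f, float(stats.f.sf(f, df_num, df_den))


def rcbd_anova(dataset: TrialDataset, trait: str) -> list[AnovaRow]:
    """Two-way (genotype + block) decomposition treating each cross as a genotype.

    Returns rows ``genotype, block, error, total``.  Requires at least two
    blocks and a balanced layout (each realized cross once per block).
    """
    if dataset.r < 2:
        raise ValueError("RCBD ANOVA needs at least 2 blocks")
    if dataset.n_cells < 2:
        raise ValueError("RCBD ANOVA needs at least 2 genotypes (crosses)")
    df = dataset.data
    y = df[trait].to_numpy(dtype=float)
    grand = y.mean()
    n = y.size
    g = dataset.n_cells
    r = dataset.r

    geno_means = df.groupby(["female", "male"], sort=False)[trait].mean().to_numpy()
    block_means = df.groupby("block", sort=False)[trait].mean().to_numpy()

    ss_total = float(((y - grand) ** 2).sum())
    ss_geno = float(r * ((geno_means - grand) ** 2).sum())
    ss_block = float(g * ((block_means - grand) ** 2).sum())
    ss_error = max(ss_total - ss_geno - ss_block, 0.0)

    df_geno, df_block = g - 1, r - 1
    df_error = n - 1 - df_geno - df_block

    error = AnovaRow("error", df_error, ss_error)
    f_g, p_g = _safe_f(ss_geno / df_geno, df_geno, error.ms, df_error)
    f_b, p_b = _safe_f(ss_block / df_block, df_block, error.ms, df_error)
    return [
        AnovaRow("genotype", df_geno, ss_geno, f_value=f_g, p_value=p_g),
        AnovaRow("block", df_block, ss_block, f_value=f_b, p_value=p_b),
        error,
        AnovaRow("total", n - 1, ss_total, ms=np.nan),
    ]


def _dummies(labels: pd.Series) -> np.ndarray:
    return pd.get_dummies(labels, dtype=float).to_numpy()


def _rss_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), int(rank)


def _sequential_partition(dataset: TrialDataset, trait: str) -> dict[str, tuple[float, int]]:
    """Type-I sums of squares in the order block -> female -> male -> cells."""
    df = dataset.data
    y = df[trait].to_numpy(dtype=float)
    n = y.size
    blocks = [np.ones((n, 1))]
    rss_prev, rank_prev = _rss_rank(np.hstack(blocks), y)
    out: dict[str, tuple[float, int]] = {}
    cell = df["female"].astype(str) + "\x1f" + df["male"].astype(str)
    for name, labels in (
        ("block", df["block"]),
        ("female", df["female"]),
        ("male", df["male"]),
        ("interaction", cell),
    ):
        blocks.append(_dummies(labels))
        rss, rank = _rss_rank(np.hstack(blocks), y)
        out[name] = (max(rss_prev - rss, 0.0), rank - rank_prev)
        rss_prev, rank_prev = rss, rank
    out["error"] = (rss_prev, n - rank_prev)
    return out


def _balanced_partition(dataset: TrialDataset, trait: str) -> dict[str, tuple[float, int]]:
    """Closed-form marginal decomposition for a complete balanced p x q x r grid."""
    df = dataset.data
    y = df[trait].to_numpy(dtype=float)
    grand = y.mean()
    p, q, r = dataset.p, dataset.q, dataset.r

    fmeans = (
        df.groupby("female")[trait].mean().reindex(dataset.females).to_numpy()
    )
    mmeans = df.groupby("male")[trait].mean().reindex(dataset.males).to_numpy()
    bmeans = df.groupby("block", sort=False)[trait].mean().to_numpy()
    cmeans = (
        df.pivot_table(index="female", columns="male", values=trait)
        .reindex(index=dataset.females, columns=dataset.males)
        .to_numpy()
    )

    ss_f = float(r * q * ((fmeans - grand) ** 2).sum())
    ss_m = float(r * p * ((mmeans - grand) ** 2).sum())
    ss_block = float(p * q * ((bmeans - grand) ** 2).sum())
    inter = cmeans - fmeans[:, None] - mmeans[None, :] + grand
    ss_fm = float(r * (inter**2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_cells = float(r * ((cmeans - grand) ** 2).sum())
    ss_err = max(ss_total - ss_block - ss_cells, 0.0)
    df_err = (p * q - 1) * (r - 1)
    return {
        "block": (ss_block, r - 1),
        "female": (ss_f, p - 1),
        "male": (ss_m, q - 1),
        "interaction": (ss_fm, (p - 1) * (q - 1)),
        "error": (ss_err, df_err),
    }


def factorial_partition(
    dataset: TrialDataset, trait: str, denominator: str = "ems"
) -> Ncd2Anova:
    """Partition the cross variation into female, male and female x male strata.

    ``denominator`` selects the F-test denominators: ``"ems"`` follows the
    expected-mean-squares ordering (female and male over interaction,
    interaction over error); ``"error"`` tests every stratum over error.
    """
    if denominator not in ("ems", "error"):
        raise ValueError("denominator must be 'ems' or 'error'")
    realized_f = set(dataset.data["female"])
    realized_m = set(dataset.data["male"])
    for role, declared, realized in (
        ("female", dataset.females, realized_f),
        ("male", dataset.males, realized_m),
    ):
        orphans = [x for x in declared if x not in realized]
        if orphans:
            warnings.warn(
                f"{role} parent(s) with no realized crosses dropped: {orphans}",
                stacklevel=2,
            )
    if len(realized_f) < 2 or len(realized_m) < 2:
        raise ValueError("factorial partition needs >=2 females and >=2 males")

    if dataset.is_complete:
        parts = _balanced_partition(dataset, trait)
    else:
        parts = _sequential_partition(dataset, trait)

    def row(name: str) -> AnovaRow:
        ss, df_ = parts[name]
        return AnovaRow(name, df_, ss)

    female, male = row("female"), row("male")
    interaction, error, block = row("interaction"), row("error"), row("block")

    main_den = interaction if denominator == "ems" else error
    female.f_value, female.p_value = _safe_f(female.ms, female.df, main_den.ms, main_den.df)
    male.f_value, male.p_value = _safe_f(male.ms, male.df, main_den.ms, main_den.df)
    interaction.f_value, interaction.p_value = _safe_f(
        interaction.ms, interaction.df, error.ms, error.df
    )
    return Ncd2Anova(
        female=female,
        male=male,
        interaction=interaction,
        error=error,
        p=len(realized_f),
        q=len(realized_m),
        r=dataset.r,
        n_cells=dataset.n_cells,
        block=block,
        denominator=denominator,
    )


def trial_stats(
    dataset: TrialDataset, trait: str, anova: list[AnovaRow], alpha: float = 0.05
) -> TrialStats:
    """Summary statistics (SE of a cross mean, LSD, CV%) from an RCBD ANOVA."""
    by_source = {r.source: r for r in anova}
    error = by_source["error"]
    if error.df < 1:
        raise ValueError("error stratum needs df >= 1")
    f_prob = by_source.get("genotype", AnovaRow("genotype", 0, 0.0)).p_value
    return trial_stats_from_ms(
        ms_error=error.ms,
        df_error=error.df,
        r=dataset.r,
        grand_mean=float(dataset.data[trait].mean()),
        f_prob=f_prob,
        alpha=alpha,
    )


def trial_stats_from_ms(
    ms_error: float,
    df_error: int,
    r: int,
    grand_mean: float,
    f_prob: float = np.nan,
    alpha: float = 0.05,
) -> TrialStats:
    """Summary statistics when only the error mean square is available."""
    se = float(np.sqrt(ms_error / r))
    if ms_error == 0:
        lsd = 0.0
    else:
        t_crit = float(stats.t.ppf(1 - alpha / 2, df_error))
        lsd = t_crit * float(np.sqrt(2 * ms_error / r))
    cv = 100 * float(np.sqrt(ms_error)) / grand_mean if grand_mean != 0 else np.nan
    return TrialStats(
        grand_mean=grand_mean, se_mean=se, lsd_5=lsd, cv_pct=cv, f_prob=f_prob
    )


def anova_to_frame(rows: list[AnovaRow]) -> pd.DataFrame:
    """Export ANOVA rows as a table with a significance-star column."""
    return pd.DataFrame(
        [
            {
                "source": r.source,
                "df": r.df,
                "ss": r.ss,
                "ms": r.ms,
                "f_value": r.f_value,
                "p_value": r.p_value,
                "signif": r.stars,
            }
            for r in rows
        ]
    )
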