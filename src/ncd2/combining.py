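"""General and specific combining ability from cross means.

The genetic model for the mean of cross (i, j) is

    y_ij = mu + g_i + g_j + s_ij

where g_i, g_j are the general combining abilities (GCA) of the female and
male parent -- their average deviations from the grand mean across all their
realized crosses -- and s_ij is the specific combining ability (SCA) of the
cross, the residual after both GCAs are removed.  Two estimators are
provided:

* the simple-means (sum-to-zero) estimator
  ``g_i = mean(crosses of parent i) - grand mean`` and
  ``s_ij = y_ij - grand mean - g_i - g_j``, and
* a reference-level least-squares fit in which one female and one male act
  as the baseline (their effects constrained to 0) and interaction terms
  are estimated only for cells identifiable after the main effects;
  unidentifiable cells are reported as structural zeros.

On complete balanced designs the two parameterizations are algebraic
re-expressions of the same fit.  Effects are declared significant by the
t ratio effect / SE against the two-sided critical value at the chosen
alpha, with degrees of freedom taken from the trial's error stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .trial import CrossIdentity, CrossMeanTable

__all__ = [
    "GcaEffect",
    "ScaEffect",
    "CombiningAbilityTable",
    "gca_simple",
    "sca_simple",
    "gca_sca_reference_ls",
    "combining_ability_table",
    "effect_t_test",
    "gca_standard_error",
    "sca_standard_error",
]


@dataclass
class GcaEffect:
    parent: str
    role: str  # "female" | "male"
    effect: float
    se: float = np.nan
    t_value: float = np.nan
    significant: bool | None = None


@dataclass
class ScaEffect:
    cross: CrossIdentity
    effect: float
    se: float = np.nan
    t_value: float = np.nan
    significant: bool | None = None
    structural_zero: bool = False


@dataclass
class CombiningAbilityTable:
    gca_female: list[GcaEffect]
    gca_male: list[GcaEffect]
    sca: list[ScaEffect]
    parameterization: str  # "sum_to_zero" | "reference_level"
    grand_mean: float
    trait: str = ""

    def fitted_value(self, female: str, male: str) -> float:
        gf = {g.parent: g.effect for g in self.gca_female}[female]
        gm = {g.parent: g.effect for g in self.gca_male}[male]
        s = {(s.cross.female, s.cross.male): s.effect for s in self.sca}[(female, male)]
        return self.grand_mean + gf + gm + s


def effect_t_test(
    effect: float, se: float, df: int, alpha: float = 0.05
) -> tuple[float, bool]:
    """t = effect / SE; significant iff |t| exceeds the two-sided critical value."""
    if se <= 0 or not np.isfinite(se):
        raise ValueError("standard error must be positive")
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    t = effect / se
    critical = float(stats.t.ppf(1 - alpha / 2, df))
    return t, bool(abs(t) > critical)


def gca_standard_error(ms_error: float, n_crosses: int, r: int) -> float:
    """SE of a parent's GCA: sqrt(MS_error / (n_i * r)).

    ``n_crosses`` is the number of realized crosses of that parent, so a
    parent appearing in more cells is estimated more precisely.
    """
    return float(np.sqrt(ms_error / (n_crosses * r)))


def sca_standard_error(ms_error: float, p: int, q: int, r: int) -> float:
    """SE of an SCA effect: sqrt(MS_error * (p-1)(q-1) / (p*q*r)).

    The (p-1)(q-1)/(p*q) coefficient is the standard factorial-design
    shrinkage of the interaction contrast on a complete grid; for incomplete
    grids p and q are the realized margin counts (approximation, documented).
    """
    return float(np.sqrt(ms_error * (p - 1) * (q - 1) / (p * q * r)))


def _attach_test(
    eff, se: float, df_error: int | None, alpha: float
) -> None:
    eff.se = se
    if df_error is not None and se > 0:
        eff.t_value, eff.significant = effect_t_test(eff.effect, se, df_error, alpha)


def gca_simple(
    means: CrossMeanTable,
    role: str,
    trait: str,
    ms_error: float | None = None,
    r: int | None = None,
    df_error: int | None = None,
    alpha: float = 0.05,
) -> list[GcaEffect]:
    """Simple-means GCA: parent's average cross mean minus the grand mean."""
    if role not in ("female", "male"):
        raise ValueError("role must be 'female' or 'male'")
    grand = means.grand_mean(trait)
    parents = means.females if role == "female" else means.males
    grouped = means.data.groupby(role)[trait].agg(["mean", "size"])
    counts = means.data.groupby(role)[trait].size()
    out: list[GcaEffect] = []
    for parent in parents:
        if parent not in grouped.index or counts[parent] == 0:
            warnings.warn(f"{role} parent {parent!r} has no realized crosses; excluded")
            continue
        eff = GcaEffect(
            parent=parent, role=role, effect=float(grouped.loc[parent, "mean"] - grand)
        )
        if ms_error is not None and r is not None:
            se = gca_standard_error(ms_error, int(grouped.loc[parent, "size"]), r)
            _attach_test(eff, se, df_error, alpha)
        out.append(eff)
    if len(out) < 2:
        raise ValueError(f"need >=2 {role} parents with realized crosses")
    return out


def sca_simple(
    means: CrossMeanTable,
    gca_f: list[GcaEffect],
    gca_m: list[GcaEffect],
    trait: str,
    ms_error: float | None = None,
    r: int | None = None,
    df_error: int | None = None,
    alpha: float = 0.05,
) -> list[ScaEffect]:
    """SCA residuals: s_ij = y_ij - grand mean - g_i - g_j per realized cross."""
    grand = means.grand_mean(trait)
    gf = {g.parent: g.effect for g in gca_f}
    gm = {g.parent: g.effect for g in gca_m}
    out: list[ScaEffect] = []
    p, q = len(gf), len(gm)
    for _, row in means.data.iterrows():
        f, m = row["female"], row["male"]
        if f not in gf or m not in gm:
            raise ValueError(f"GCA lists do not cover cross ({f}, {m})")
        eff = ScaEffect(
            cross=CrossIdentity(f, m),
            effect=float(row[trait] - grand - gf[f] - gm[m]),
        )
        if ms_error is not None and r is not None:
            se = sca_standard_error(ms_error, p, q, r)
            _attach_test(eff, se, df_error, alpha)
        out.append(eff)
    return out


def combining_ability_table(
    means: CrossMeanTable,
    trait: str,
    ms_error: float | None = None,
    r: int | None = None,
    df_error: int | None = None,
    alpha: float = 0.05,
) -> CombiningAbilityTable:
    """Convenience wrapper: sum-to-zero GCA (both roles) plus SCA for one trait."""
    kw = dict(ms_error=ms_error, r=r, df_error=df_error, alpha=alpha)
    gca_f = gca_simple(means, "female", trait, **kw)
    gca_m = gca_simple(means, "male", trait, **kw)
    sca = sca_simple(means, gca_f, gca_m, trait, **kw)
    return CombiningAbilityTable(
        gca_female=gca_f,
        gca_male=gca_m,
        sca=sca,
        parameterization="sum_to_zero",
        grand_mean=means.grand_mean(trait),
        trait=trait,
    )


def gca_sca_reference_ls(
    means: CrossMeanTable,
    trait: str,
    reference_female: str | None = None,
    reference_male: str | None = None,
) -> CombiningAbilityTable:
    """Least-squares fit with one female and one male constrained to effect 0.

    The intercept is the fitted value of the reference x reference cell;
    every other parent's effect is its contrast against the reference.
    Interaction terms are added sequentially (row-major cell order) only
    where they increase the design rank after the main effects; the
    remaining cells' SCA values are structural zeros -- their interaction is
    not identifiable from the realized grid.
    """
    females, males = means.females, means.males
    reference_female = reference_female or females[0]
    reference_male = reference_male or males[0]
    if reference_female not in females:
        raise ValueError(f"unknown reference female {reference_female!r}")
    if reference_male not in males:
        raise ValueError(f"unknown reference male {reference_male!r}")

    y = means.trait_vector(trait)
    n = y.size
    f_levels = [f for f in females if f != reference_female]
    m_levels = [m for m in males if m != reference_male]

    cols: list[np.ndarray] = [np.ones(n)]
    names: list[tuple[str, str]] = [("intercept", "")]
    for f in f_levels:
        cols.append((means.data["female"] == f).to_numpy(dtype=float))
        names.append(("female", f))
    for m in m_levels:
        cols.append((means.data["male"] == m).to_numpy(dtype=float))
        names.append(("male", m))
    x_main = np.column_stack(cols)
    rank_main = np.linalg.matrix_rank(x_main)
    if rank_main < x_main.shape[1]:
        raise ValueError(
            "rank-deficient main-effect design: some parents are aliased "
            f"(females {f_levels}, males {m_levels})"
        )

    # greedy sequential inclusion of identifiable interaction cells
    inter_cols: list[np.ndarray] = []
    inter_cells: list[tuple[str, str]] = []
    x_cur = x_main
    rank_cur = rank_main
    for f in f_levels:
        for m in m_levels:
            col = (
                (means.data["female"] == f) & (means.data["male"] == m)
            ).to_numpy(dtype=float)
            if not col.any():
                continue
            cand = np.column_stack([x_cur, col])
            rank_new = np.linalg.matrix_rank(cand)
            if rank_new > rank_cur:
                inter_cols.append(col)
                inter_cells.append((f, m))
                x_cur, rank_cur = cand, rank_new

    beta, *_ = np.linalg.lstsq(x_cur, y, rcond=None)
    k_main = x_main.shape[1]
    coef = dict(zip(names, beta[:k_main]))
    inter = dict(zip(inter_cells, beta[k_main:]))

    gca_female = [GcaEffect(reference_female, "female", 0.0)]
    gca_female += [GcaEffect(f, "female", float(coef[("female", f)])) for f in f_levels]
    gca_male = [GcaEffect(reference_male, "male", 0.0)]
    gca_male += [GcaEffect(m, "male", float(coef[("male", m)])) for m in m_levels]

    sca: list[ScaEffect] = []
    for c in means.crosses:
        key = (c.female, c.male)
        if key in inter:
            sca.append(ScaEffect(cross=c, effect=float(inter[key])))
        else:
            sca.append(ScaEffect(cross=c, effect=0.0, structural_zero=True))

    return CombiningAbilityTable(
        gca_female=gca_female,
        gca_male=gca_male,
        sca=sca,
        parameterization="reference_level",
        grand_mean=float(coef[("intercept", "")]),
        trait=trait,
    )
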