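"""Method-of-moments variance components and derived genetic parameters.

Solving the expected mean squares of the factorial design::

    s2_e  = MS_error
    s2_FM = (MS_FM - MS_error) / r
    s2_F  = (MS_F - MS_FM) / (r * q)
    s2_M  = (MS_M - MS_FM) / (r * p)

negative solutions (sampling noise can push the moment estimator below
zero) are truncated to 0 and flagged, never silently.

The genetic interpretation maps the design components onto gene-action
variances::

    additive   s2_A = 2 * (s2_M + s2_F)        (default; the textbook
                                                half-sib coefficient
                                                4 * s2_GCA is available
                                                as coeff_additive=4.0)
    dominance  s2_D = 4 * s2_FM
    genotypic  s2_G = s2_A + s2_D
    phenotypic s2_P = s2_G + s2_e
    narrow-sense heritability  h2 = s2_A / s2_P
    broad-sense heritability   H2 = s2_G / s2_P
    degree of dominance        d  = sqrt(s2_D / s2_A)

with d = 1 indicating complete dominance, d > 1 overdominance and d < 1
partial dominance.  The heritability standard error is a delta-method
approximation using the chi-square sampling variance of each mean square,
var(MS) = 2 MS^2 / df.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anova import Ncd2Anova

__all__ = [
    "EmsDesign",
    "VarianceDecomposition",
    "solve_ems",
    "genetic_summary",
    "heritability_se",
]


@dataclass(frozen=True)
class EmsDesign:
    """Design dimensions entering the expected-mean-squares coefficients."""

    p: int  # female parents
    q: int  # male parents
    r: int  # blocks

    def __post_init__(self) -> None:
        if self.p < 2 or self.q < 2:
            raise ValueError("need p >= 2 females and q >= 2 males")
        if self.r < 1:
            raise ValueError("need r >= 1 blocks")


@dataclass
class VarianceDecomposition:
    sigma2_f: float
    sigma2_m: float
    sigma2_fm: float
    sigma2_e: float
    sigma2_a: float
    sigma2_d: float
    sigma2_g: float
    sigma2_p: float
    h2_narrow: float
    h2_broad: float
    dominance_degree: float
    truncated: tuple[str, ...] = ()


def solve_ems(
    anova: Ncd2Anova, design: EmsDesign | None = None
) -> tuple[float, float, float, float, tuple[str, ...]]:
    """Solve the EMS equations for (s2_f, s2_m, s2_fm, s2_e).

    Returns the four components plus the names of any truncated (negative
    -> 0) components.
    """
    if design is None:
        design = EmsDesign(p=anova.p, q=anova.q, r=anova.r)
    if design.r == 0:
        raise ValueError("design with r = 0 blocks")
    for row in (anova.female, anova.male, anova.interaction, anova.error):
        if row.df < 1:
            raise ValueError(f"stratum {row.source!r} has df < 1")
    r, p, q = design.r, design.p, design.q
    ms_f, ms_m = anova.female.ms, anova.male.ms
    ms_fm, ms_e = anova.interaction.ms, anova.error.ms

    raw = {
        "sigma2_e": ms_e,
        "sigma2_fm": (ms_fm - ms_e) / r,
        "sigma2_f": (ms_f - ms_fm) / (r * q),
        "sigma2_m": (ms_m - ms_fm) / (r * p),
    }
    truncated = tuple(k for k, v in raw.items() if v < 0)
    clipped = {k: max(v, 0.0) for k, v in raw.items()}
    return (
        clipped["sigma2_f"],
        clipped["sigma2_m"],
        clipped["sigma2_fm"],
        clipped["sigma2_e"],
        truncated,
    )


def genetic_summary(
    components: tuple[float, float, float, float],
    truncated: tuple[str, ...] = (),
    coeff_additive: float = 2.0,
) -> VarianceDecomposition:
    """Derive gene-action variances, heritabilities and degree of dominance.

    ``components`` is (s2_f, s2_m, s2_fm, s2_e), all non-negative.
    ``coeff_additive`` scales s2_F + s2_M into additive variance; the
    default 2.0 matches the published convention for this design, 4.0 is
    the textbook half-sib covariance coefficient.
    """
    s2f, s2m, s2fm, s2e = components
    if min(s2f, s2m, s2fm, s2e) < 0:
        raise ValueError("variance components must be non-negative")
    s2a = coeff_additive * (s2m + s2f)
    s2d = 4.0 * s2fm
    s2g = s2a + s2d
    s2p = s2g + s2e
    h2 = s2a / s2p if s2p > 0 else np.nan
    h2b = s2g / s2p if s2p > 0 else np.nan
    if s2a == 0:
        d = 0.0 if s2d == 0 else np.nan
    else:
        d = float(np.sqrt(s2d / s2a))
    return VarianceDecomposition(
        sigma2_f=s2f,
        sigma2_m=s2m,
        sigma2_fm=s2fm,
        sigma2_e=s2e,
        sigma2_a=s2a,
        sigma2_d=s2d,
        sigma2_g=s2g,
        sigma2_p=s2p,
        h2_narrow=h2,
        h2_broad=h2b,
        dominance_degree=d,
        truncated=truncated,
    )


def _h2_from_ms(ms: np.ndarray, design: EmsDesign, coeff_additive: float) -> float:
    """Narrow-sense h2 as a smooth function of the four mean squares.

    Truncation is deliberately ignored here so the delta-method gradient is
    well defined; the approximation degrades near the zero boundary.
    """
    ms_f, ms_m, ms_fm, ms_e = ms
    r, p, q = design.r, design.p, design.q
    s2f = (ms_f - ms_fm) / (r * q)
    s2m = (ms_m - ms_fm) / (r * p)
    s2fm = (ms_fm - ms_e) / r
    s2a = coeff_additive * (s2f + s2m)
    s2p = s2a + 4.0 * s2fm + ms_e
    return s2a / s2p if s2p != 0 else np.nan


def heritability_se(
    h2: float,
    anova: Ncd2Anova,
    design: EmsDesign | None = None,
    coeff_additive: float = 2.0,
) -> float:
    """Delta-method SE of narrow-sense heritability (approximate).

    Each mean square MS_i is treated as (EMS_i / df_i) * chi2(df_i), so
    var(MS_i) = 2 MS_i^2 / df_i; the gradient of h2 with respect to the
    mean squares is taken numerically and the variances are propagated
    assuming independent strata.  Boundary convention: h2 = 0 with zero
    additive variance returns SE 0.
    """
    if not (0 <= h2 <= 1):
        raise ValueError("h2 must lie in [0, 1]")
    if design is None:
        design = EmsDesign(p=anova.p, q=anova.q, r=anova.r)
    rows = [anova.female, anova.male, anova.interaction, anova.error]
    if any(row.df == 0 for row in rows):
        return np.nan
    if h2 == 0:
        return 0.0
    ms = np.array([row.ms for row in rows], dtype=float)
    dfs = np.array([row.df for row in rows], dtype=float)
    grad = np.empty(4)
    for i in range(4):
        h = max(abs(ms[i]), 1.0) * 1e-6
        up, down = ms.copy(), ms.copy()
        up[i] += h
        down[i] -= h
        grad[i] = (
            _h2_from_ms(up, design, coeff_additive)
            - _h2_from_ms(down, design, coeff_additive)
        ) / (2 * h)
    var = float((grad**2 * 2 * ms**2 / dfs).sum())
    return float(np.sqrt(var))
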