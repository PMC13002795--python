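"""Bundled example trial: a published rice NCD II advancement trial.

Eight F2 progenies from a 4-female x 3-male factorial (8 of the 12 cells
realized), grown in 3 complete blocks.  Only the replicate-averaged cross
means and the per-stratum ANOVA mean squares were published, so the bundle
carries:

* the cross-mean table (8 crosses x 8 traits),
* the mean squares and degrees of freedom per ANOVA stratum and trait,
* the printed trial summary statistics (SE, LSD, F-probability, CV),
* the printed genetic summary (heritability, variance components, degree
  of dominance) and the printed trait correlation matrix,

which together drive the mean-only analyses and serve as the package's
internal-consistency test surface.  Printed values are stored exactly as
published and are never overwritten by recomputation.
"""

from __future__ import annotations

import pandas as pd

from .trial import CrossMeanTable, TraitCatalog, TrialDataset, dataset_from_observations

__all__ = [
    "EXAMPLE_FEMALES",
    "EXAMPLE_MALES",
    "load_example_cross_means",
    "load_example_mean_squares",
    "load_example_trial_summary",
    "load_example_genetic_summary",
    "load_example_correlations",
    "expand_means_to_plots",
]

EXAMPLE_FEMALES = ("NERICA 4", "Uwemi", "Kudya", "Makafaci")
EXAMPLE_MALES = ("Kayanjamalo", "Kilombero", "Mtupatupa")
EXAMPLE_BLOCKS = 3

_TRAITS = TraitCatalog()

# One row per realized cross; traits in catalog order
# (DTF50, PH_cm, PL_cm, NPP, GL_mm, GW_mm, GS, GYPP_g).
_CROSS_MEANS = [
    ("NERICA 4", "Kilombero", 117, 80, 26.3, 10, 9.3, 2.4, 3.9, 14.5),
    ("NERICA 4", "Mtupatupa", 112, 77, 23.8, 12, 9.1, 2.6, 3.5, 13.9),
    ("Uwemi", "Mtupatupa", 114, 89, 22.8, 9, 9.2, 2.6, 3.6, 14.9),
    ("Uwemi", "Kilombero", 118, 73, 22.9, 8, 8.8, 2.8, 3.2, 10.3),
    ("Kudya", "Kayanjamalo", 112, 96, 23.4, 9, 9.7, 2.5, 3.9, 19.0),
    ("Kudya", "Mtupatupa", 111, 78, 23.7, 10, 9.2, 2.5, 3.6, 12.1),
    ("Makafaci", "Kilombero", 114, 93, 24.6, 10, 9.4, 2.4, 3.9, 14.8),
    ("Makafaci", "Mtupatupa", 117, 90, 28.1, 13, 9.3, 2.2, 4.3, 11.4),
]

# Published ANOVA mean squares per stratum (rows) and trait (columns), with
# the published degrees of freedom.  The error stratum is the RCBD residual.
_MEAN_SQUARES = {
    "df": {"female": 3, "male": 2, "interaction": 7, "error": 14},
    "female": {
        "DTF50": 21.44, "PH_cm": 192.38, "PL_cm": 14.729, "NPP": 11.704,
        "GL_mm": 0.215, "GW_mm": 0.148, "GS": 0.553, "GYPP_g": 9.94,
    },
    "male": {
        "DTF50": 32.06, "PH_cm": 240.09, "PL_cm": 1.938, "NPP": 6.838,
        "GL_mm": 0.341, "GW_mm": 0.005, "GS": 0.063, "GYPP_g": 44.49,
    },
    "interaction": {
        "DTF50": 23.33, "PH_cm": 214.34, "PL_cm": 10.156, "NPP": 8.042,
        "GL_mm": 0.210, "GW_mm": 0.089, "GS": 0.355, "GYPP_g": 21.54,
    },
    "error": {
        "DTF50": 12.14, "PH_cm": 42.45, "PL_cm": 1.814, "NPP": 6.485,
        "GL_mm": 0.375, "GW_mm": 0.027, "GS": 0.167, "GYPP_g": 12.84,
    },
}

# Published trial summary rows.  Note: the published SE row equals
# sqrt(MS_error/r) only for GYPP (2.07); the basis of the other printed SEs
# is unstated, so both printed and recomputed values are exposed.
_TRIAL_SUMMARY = {
    "mean": {
        "DTF50": 115, "PH_cm": 85, "PL_cm": 24.4, "NPP": 10,
        "GL_mm": 9.2, "GW_mm": 2.5, "GS": 3.7, "GYPP_g": 13.9,
    },
    "se": {
        "DTF50": 2.011, "PH_cm": 6.5, "PL_cm": 1.35, "NPP": 2.5,
        "GL_mm": 0.35, "GW_mm": 0.10, "GS": 0.24, "GYPP_g": 2.07,
    },
    "lsd": {
        "DTF50": 6.101, "PH_cm": 11.4, "PL_cm": 2.36, "NPP": 4.5,
        "GL_mm": 1.07, "GW_mm": 0.29, "GS": 0.72, "GYPP_g": 6.27,
    },
    "f_prob": {
        "DTF50": 0.141, "PH_cm": 0.005, "PL_cm": 0.003, "NPP": 0.345,
        "GL_mm": 0.700, "GW_mm": 0.028, "GS": 0.109, "GYPP_g": 0.19,
    },
    "cv_pct": {
        "DTF50": 3.0, "PH_cm": 7.7, "PL_cm": 5.5, "NPP": 25.1,
        "GL_mm": 6.7, "GW_mm": 6.6, "GS": 10.9, "GYPP_g": 25.8,
    },
}

# Published genetic summary: narrow-sense heritability with its SE, then
# phenotypic/additive/dominance/environmental/genotypic variance and the
# degree of dominance, per trait.  GS was not reported in this table.
_GENETIC_SUMMARY = {
    "DTF50": {"h2": 0.24, "h2_se": 0.16, "s2p": 23.26, "s2a": 5.58,
              "s2d": 5.58, "s2e": 12.1, "s2g": 11.2, "d2": 1.00},
    "PH_cm": {"h2": 0.03, "h2_se": 0.12, "s2p": 280.20, "s2a": 8.57,
              "s2d": 229.18, "s2e": 42.45, "s2g": 237.76, "d2": 5.15},
    "PL_cm": {"h2": 0.14, "h2_se": 0.10, "s2p": 14.97, "s2a": 2.02,
              "s2d": 11.11, "s2e": 1.84, "s2g": 13.15, "d2": 2.33},
    "NPP": {"h2": 0.07, "h2_se": 0.11, "s2p": 9.175, "s2a": 0.614,
            "s2d": 2.075, "s2e": 6.48, "s2g": 2.687, "d2": 1.82},
    "GL_mm": {"h2": 0.40, "h2_se": 0.51, "s2p": 0.82, "s2a": 0.33,
              "s2d": 0.28, "s2e": 0.21, "s2g": 0.61, "d2": 0.94},
    "GW_mm": {"h2": 0.00, "h2_se": None, "s2p": 0.12, "s2a": 0.00,
              "s2d": 0.08, "s2e": 0.03, "s2g": 0.08, "d2": 0.00},
    "GYPP_g": {"h2": 0.39, "h2_se": 0.23, "s2p": 78.25, "s2a": 30.61,
               "s2d": 34.80, "s2e": 12.84, "s2g": 65.41, "d2": 1.05},
}

# Published lower-triangular phenotypic correlation matrix (coefficient,
# printed significance stars).  Trait order as in the catalog.
_CORRELATIONS = {
    ("PH_cm", "DTF50"): (-0.198, ""),
    ("PL_cm", "DTF50"): (0.461, "*"),
    ("PL_cm", "PH_cm"): (0.191, ""),
    ("NPP", "DTF50"): (-0.044, ""),
    ("NPP", "PH_cm"): (0.087, ""),
    ("NPP", "PL_cm"): (0.726, "***"),
    ("GL_mm", "DTF50"): (-0.407, "**"),
    ("GL_mm", "PH_cm"): (0.845, "***"),
    ("GL_mm", "PL_cm"): (0.222, ""),
    ("GL_mm", "NPP"): (0.118, ""),
    ("GW_mm", "DTF50"): (-0.060, ""),
    ("GW_mm", "PH_cm"): (-0.549, "**"),
    ("GW_mm", "PL_cm"): (-0.866, "***"),
    ("GW_mm", "NPP"): (-0.687, "***"),
    ("GW_mm", "GL_mm"): (-0.597, "**"),
    ("GS", "DTF50"): (0.094, ""),
    ("GS", "PH_cm"): (0.697, "***"),
    ("GS", "PL_cm"): (0.815, "***"),
    ("GS", "NPP"): (0.590, "**"),
    ("GS", "GL_mm"): (0.710, "***"),
    ("GS", "GW_mm"): (-0.966, "***"),
    ("GYPP_g", "DTF50"): (-0.493, "**"),
    ("GYPP_g", "PH_cm"): (0.675, "**"),
    ("GYPP_g", "PL_cm"): (-0.227, ""),
    ("GYPP_g", "NPP"): (-0.205, ""),
    ("GYPP_g", "GL_mm"): (0.829, "***"),
    ("GYPP_g", "GW_mm"): (-0.116, ""),
    ("GYPP_g", "GS"): (0.274, ""),
}


def load_example_cross_means() -> CrossMeanTable:
    """The bundled 8-cross x 8-trait replicate-mean table."""
    rows = []
    for female, male, dtf, ph, pl, npp, gl, gw, gs, gypp in _CROSS_MEANS:
        rows.append(
            {
                "female": female, "male": male,
                "DTF50": float(dtf), "PH_cm": float(ph), "PL_cm": pl,
                "NPP": float(npp), "GL_mm": gl, "GW_mm": gw, "GS": gs,
                "GYPP_g": gypp,
            }
        )
    return CrossMeanTable(
        data=pd.DataFrame(rows), traits=_TRAITS, n_blocks=EXAMPLE_BLOCKS
    )


def load_example_mean_squares() -> pd.DataFrame:
    """Published ANOVA mean squares: rows female/male/interaction/error.

    Columns: ``df`` then one column per trait.
    """
    strata = ["female", "male", "interaction", "error"]
    records = []
    for s in strata:
        rec = {"source": s, "df": _MEAN_SQUARES["df"][s]}
        rec.update(_MEAN_SQUARES[s])
        records.append(rec)
    return pd.DataFrame(records).set_index("source")


def load_example_trial_summary() -> pd.DataFrame:
    """Published per-trait summary rows (mean, SE, LSD, F-prob, CV%)."""
    return pd.DataFrame(_TRIAL_SUMMARY).T[list(_TRAITS)]


def load_example_genetic_summary() -> pd.DataFrame:
    """Published variance components, heritability and degree of dominance."""
    return pd.DataFrame(_GENETIC_SUMMARY).T


def load_example_correlations() -> pd.DataFrame:
    """Published lower-triangular correlations with their printed stars."""
    records = [
        {"trait_a": a, "trait_b": b, "r": r, "stars": stars}
        for (a, b), (r, stars) in _CORRELATIONS.items()
    ]
    return pd.DataFrame(records)


def expand_means_to_plots(means: CrossMeanTable, n_blocks: int = 3) -> TrialDataset:
    """Expand a cross-mean table to constant-within-cross plot data.

    Every block repeats the cross mean exactly, so ``cross_mean_table`` of
    the result returns the input unchanged.  Useful for pushing mean-only
    tables through plot-level code paths (the within-cell error is zero by
    construction).
    """
    from .trial import CrossIdentity, PlotObservation

    obs = []
    for _, row in means.data.iterrows():
        for k in range(n_blocks):
            obs.append(
                PlotObservation(
                    cross=CrossIdentity(row["female"], row["male"]),
                    block=f"B{k + 1}",
                    values={t: float(row[t]) for t in means.traits},
                )
            )
    return dataset_from_observations(obs, means.traits)
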