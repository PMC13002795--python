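"""Pairwise Pearson correlations among traits with t-based significance.

Correlations are computed over realized crosses (the replicate-mean table),
which is the published convention for this kind of trial; a plot-level
variant over all crosses x blocks is available by passing a
:class:`~ncd2.trial.TrialDataset`.  Significance stars follow the
three-level convention * p<0.05, ** p<0.01, *** p<0.001 from a two-sided t
test with n - 2 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trial import CrossMeanTable, TraitCatalog, TrialDataset

__all__ = [
    "CorrelationEntry",
    "pearson_matrix",
    "correlation_frame",
    "correlation_stars",
]


def correlation_stars(p_value: float) -> str:
    if not np.isfinite(p_value):
        return ""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


@dataclass
class CorrelationEntry:
    trait_a: str
    trait_b: str
    r: float
    n: int
    t_value: float
    p_value: float
    stars: str


def _trait_frame(source: CrossMeanTable | TrialDataset) -> tuple[pd.DataFrame, TraitCatalog]:
    if isinstance(source, TrialDataset):
        return source.data[list(source.traits)], source.traits
    return source.data[list(source.traits)], source.traits


def pearson_matrix(
    source: CrossMeanTable | TrialDataset, traits: TraitCatalog | None = None
) -> list[CorrelationEntry]:
    """All pairwise product-moment correlations (lower triangle, a after b).

    Zero-variance traits yield NaN entries with a warning rather than an
    error, so one degenerate trait does not abort the full matrix.
    """
    frame, catalog = _trait_frame(source)
    names = list(traits) if traits is not None else list(catalog)
    n = len(frame)
    if n < 3:
        raise ValueError("need at least 3 crosses for a correlation")
    degenerate = [t for t in names if float(frame[t].std(ddof=1)) == 0.0]
    if degenerate:
        warnings.warn(f"zero-variance trait(s), correlations undefined: {degenerate}")
    out: list[CorrelationEntry] = []
    for i, a in enumerate(names):
        for b in names[:i]:
            if a in degenerate or b in degenerate:
                out.append(CorrelationEntry(a, b, np.nan, n, np.nan, np.nan, ""))
                continue
            r, p = stats.pearsonr(frame[a], frame[b])
            r = float(r)
            denom = 1 - r**2
            t = r * np.sqrt((n - 2) / denom) if denom > 0 else np.inf * np.sign(r)
            out.append(
                CorrelationEntry(a, b, r, n, float(t), float(p), correlation_stars(p))
            )
    return out


def correlation_frame(
    source: CrossMeanTable | TrialDataset,
    traits: TraitCatalog | None = None,
    with_stars: bool = True,
) -> pd.DataFrame:
    """Lower-triangular matrix layout; cells are ``r`` or ``r + stars`` strings."""
    entries = pearson_matrix(source, traits)
    frame, catalog = _trait_frame(source)
    names = list(traits) if traits is not None else list(catalog)
    mat = pd.DataFrame("", index=names, columns=names, dtype=object)
    for t in names:
        mat.loc[t, t] = "1" if with_stars else 1.0
    for e in entries:
        cell = f"{e.r:.3f}{e.stars}" if with_stars else e.r
        mat.loc[e.trait_a, e.trait_b] = cell
    return mat
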