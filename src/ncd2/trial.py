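"""Phenotype data model for factorial (female x male) mating-design trials.

A trial is a set of plot observations keyed by (female parent, male parent,
block), with one numeric column per trait.  The design is a North Carolina
Design II factorial: every realized cross is one cell of the p x q grid of
female x male combinations, replicated in r complete blocks.  Incomplete
grids (not every cell realized) are first-class; completeness is a flag,
never an error.

Two table shapes are supported:

* long plot-level CSV -- columns ``female, male, block`` plus one column per
  trait, one row per plot; the canonical input.
* wide cross-mean CSV -- one row per cross with replicate-averaged trait
  values; sufficient for mean-only analyses (combining-ability arithmetic,
  correlations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_TRAITS",
    "TraitCatalog",
    "CrossIdentity",
    "PlotObservation",
    "TrialDataset",
    "CrossMeanTable",
    "TrialSchemaError",
    "DuplicatePlotError",
    "TrialParseError",
    "read_trial_table",
    "write_trial_table",
    "cross_mean_table",
    "derive_grain_shape",
    "round_half_up",
]

#: Default trait order: days to 50% flowering, plant height (cm), panicle
#: length (cm), panicles per plant, grain length (mm), grain width (mm),
#: grain shape (length/width ratio, unitless), grain yield per plant (g).
DEFAULT_TRAITS = (
    "DTF50",
    "PH_cm",
    "PL_cm",
    "NPP",
    "GL_mm",
    "GW_mm",
    "GS",
    "GYPP_g",
)

_KEY_COLUMNS = ("female", "male", "block")


class TrialSchemaError(ValueError):
    """A mandatory column is missing or the file layout is invalid."""


class DuplicatePlotError(ValueError):
    """Two rows share the same (female, male, block) key."""


class TrialParseError(ValueError):
    """A trait cell could not be parsed as a number."""


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero, the convention of printed trial tables.

    Python's built-in ``round`` is banker's rounding; published agronomy
    tables round 3.88 -> 3.9, 0.235 -> 0.24.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TraitCatalog:
    """Ordered list of trait identifiers carried by a trial."""

    names: tuple[str, ...] = DEFAULT_TRAITS

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise ValueError("trait catalog must name at least one trait")
        if len(set(self.names)) != len(self.names):
            raise ValueError("trait names must be unique")
        if any(not n for n in self.names):
            raise ValueError("trait names must be non-empty")

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True, order=True)
class CrossIdentity:
    """One female x male combination of the mating design."""

    female: str
    male: str

    def __post_init__(self) -> None:
        if not self.female or not self.male:
            raise ValueError("parent labels must be non-empty")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.female} x {self.male}"


@dataclass(frozen=True)
class PlotObservation:
    """One plot: a cross grown in one block, with its trait values."""

    cross: CrossIdentity
    block: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        for trait, value in self.values.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite value for trait {trait!r}")


@dataclass
class TrialDataset:
    """Plot-level observations of a (possibly incomplete) p x q x r factorial.

    ``data`` is a DataFrame with columns ``female, male, block`` followed by
    one column per trait in catalog order.  Parent and block lists are kept
    in first-appearance order so that output tables are reproducible.
    """

    data: pd.DataFrame
    traits: TraitCatalog
    females: list[str] = field(default_factory=list)
    males: list[str] = field(default_factory=list)
    blocks: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in _KEY_COLUMNS if c not in self.data.columns]
        if missing:
            raise TrialSchemaError(f"missing mandatory column(s): {missing}")
        for trait in self.traits:
            if trait not in self.data.columns:
                raise TrialSchemaError(f"missing trait column: {trait!r}")
        if not self.females:
            self.females = list(dict.fromkeys(self.data["female"]))
        if not self.males:
            self.males = list(dict.fromkeys(self.data["male"]))
        if not self.blocks:
            self.blocks = list(dict.fromkeys(self.data["block"]))
        dup = self.data.duplicated(subset=list(_KEY_COLUMNS))
        if dup.any():
            row = self.data.loc[dup.idxmax(), list(_KEY_COLUMNS)]
            raise DuplicatePlotError(
                f"duplicate plot for ({row['female']}, {row['male']}, {row['block']})"
            )
        values = self.data[list(self.traits)].to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise TrialParseError("trial contains non-finite trait values")
        counts = self.data.groupby(["female", "male"], sort=False).size()
        if counts.nunique() > 1:
            raise TrialSchemaError(
                "unbalanced design: realized crosses have unequal replicate counts"
            )

    # -- design geometry -------------------------------------------------

    @property
    def p(self) -> int:
        return len(self.females)

    @property
    def q(self) -> int:
        return len(self.males)

    @property
    def r(self) -> int:
        return len(self.blocks)

    @property
    def crosses(self) -> list[CrossIdentity]:
        """Realized crosses in first-appearance order."""
        seen = dict.fromkeys(
            CrossIdentity(f, m) for f, m in zip(self.data["female"], self.data["male"])
        )
        return list(seen)

    @property
    def n_cells(self) -> int:
        return len(self.crosses)

    @property
    def is_complete(self) -> bool:
        """True iff every cell of the p x q grid is realized."""
        return self.n_cells == self.p * self.q

    @property
    def observations(self) -> list[PlotObservation]:
        out = []
        for _, row in self.data.iterrows():
            out.append(
                PlotObservation(
                    cross=CrossIdentity(row["female"], row["male"]),
                    block=str(row["block"]),
                    values={t: float(row[t]) for t in self.traits},
                )
            )
        return out


@dataclass
class CrossMeanTable:
    """Replicate-averaged trait values, one row per realized cross."""

    data: pd.DataFrame  # columns: female, male, then traits
    traits: TraitCatalog
    n_blocks: int = 1

    def __post_init__(self) -> None:
        for col in ("female", "male"):
            if col not in self.data.columns:
                raise TrialSchemaError(f"missing mandatory column: {col!r}")
        for trait in self.traits:
            if trait not in self.data.columns:
                raise TrialSchemaError(f"missing trait column: {trait!r}")
        self.data = self.data.reset_index(drop=True)

    @property
    def crosses(self) -> list[CrossIdentity]:
        return [
            CrossIdentity(f, m) for f, m in zip(self.data["female"], self.data["male"])
        ]

    @property
    def females(self) -> list[str]:
        return list(dict.fromkeys(self.data["female"]))

    @property
    def males(self) -> list[str]:
        return list(dict.fromkeys(self.data["male"]))

    def value(self, female: str, male: str, trait: str) -> float:
        mask = (self.data["female"] == female) & (self.data["male"] == male)
        if not mask.any():
            raise KeyError(f"no realized cross ({female}, {male})")
        return float(self.data.loc[mask, trait].iloc[0])

    def grand_mean(self, trait: str) -> float:
        return float(self.data[trait].mean())

    def trait_vector(self, trait: str) -> np.ndarray:
        return self.data[trait].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        cols = ["female", "male", *self.traits]
        self.data[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, traits: TraitCatalog | None = None, n_blocks: int = 1
    ) -> "CrossMeanTable":
        df = pd.read_csv(path)
        if traits is None:
            trait_cols = [c for c in df.columns if c not in ("female", "male", "genotype")]
            traits = TraitCatalog(tuple(trait_cols))
        return cls(data=df, traits=traits, n_blocks=n_blocks)


# -- operations -----------------------------------------------------------


def read_trial_table(
    path: str | Path, trait_catalog: TraitCatalog | None = None
) -> TrialDataset:
    """Read a long-format plot-level CSV into a validated :class:`TrialDataset`.

    Parent and block lists are inferred in first-appearance order.  Rows with
    unparseable numerics are rejected with the offending row number, never
    silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if df.empty:
        raise TrialSchemaError(f"{path} contains no data rows")
    missing = [c for c in _KEY_COLUMNS if c not in df.columns]
    if missing:
        raise TrialSchemaError(f"{path}: missing mandatory column(s): {missing}")
    if trait_catalog is None:
        trait_cols = [c for c in df.columns if c not in (*_KEY_COLUMNS, "genotype")]
        if not trait_cols:
            raise TrialSchemaError(f"{path}: no trait columns found")
        trait_catalog = TraitCatalog(tuple(trait_cols))
    for trait in trait_catalog:
        if trait not in df.columns:
            raise TrialSchemaError(f"{path}: missing trait column: {trait!r}")
        detect = pd.to_numeric(df[trait], errors="coerce")
        bad = detect.isna() & df[trait].notna() | df[trait].isna()
        if bad.any():
            # +2: one for the header line, one for 0-based indexing
            rownum = int(bad.idxmax()) + 2
            raise TrialParseError(
                f"{path}: non-numeric value for trait {trait!r} at file row {rownum}"
            )
        # astype, not to_numeric: the latter's parser is not correctly rounded
        df[trait] = df[trait].astype(float)
    keep = [*_KEY_COLUMNS, *trait_catalog]
    return TrialDataset(data=df[keep].copy(), traits=trait_catalog)


def write_trial_table(dataset: TrialDataset, path: str | Path) -> None:
    """Write the canonical long-format CSV (round-trips through the reader)."""
    cols = [*_KEY_COLUMNS, *dataset.traits]
    # %.17g preserves every float bit-for-bit across a write/read cycle
    dataset.data[cols].to_csv(path, index=False, float_format="%.17g")


def cross_mean_table(dataset: TrialDataset) -> CrossMeanTable:
    """Average each realized cross over its blocks, one row per cross."""
    if dataset.data.empty:
        raise TrialSchemaError("empty dataset: nothing to average")
    grouped = (
        dataset.data.groupby(["female", "male"], sort=False)[list(dataset.traits)]
        .mean()
        .reset_index()
    )
    return CrossMeanTable(data=grouped, traits=dataset.traits, n_blocks=dataset.r)


def derive_grain_shape(gl: float, gw: float) -> float:
    """Grain shape = grain length / grain width (both mm; result unitless)."""
    if gw <= 0:
        raise ValueError("grain width must be positive")
    return gl / gw


def dataset_from_observations(
    observations: Iterable[PlotObservation],
    traits: TraitCatalog,
    females: Sequence[str] | None = None,
    males: Sequence[str] | None = None,
    blocks: Sequence[str] | None = None,
) -> TrialDataset:
    """Assemble a :class:`TrialDataset` from individual plot observations."""
    rows = []
    for obs in observations:
        row = {"female": obs.cross.female, "male": obs.cross.male, "block": obs.block}
        row.update({t: obs.values[t] for t in traits})
        rows.append(row)
    df = pd.DataFrame(rows)
    return TrialDataset(
        data=df,
        traits=traits,
        females=list(females) if females else [],
        males=list(males) if males else [],
        blocks=list(blocks) if blocks else [],
    )
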