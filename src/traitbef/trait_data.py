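"""Species x trait tables: loading, validation, transformation, standardization.

The trait table is the raw material of every downstream analysis: the
per-species trait values ``t_i`` entering community-weighted means, and the
standardized values whose pairwise squared differences define the trait
distances of Rao's quadratic diversity.  Traits are mixed continuous/ordinal;
ordinal traits (e.g. rooting depth classes 1-5) are carried as their numeric
codes throughout, so means and distances operate on the codes.

Right-skewed traits (seed mass, seedling counts, shoot length, leaf N,
inflorescence mass fraction, foliar d15N) are log-transformed before any
standardization.  Foliar d15N can be negative (legumes sit near the
atmospheric 0 permil), so a flagged trait containing values <= 0 receives a
shifted log, ``log(x - min(x) + 1)``, with the shift recorded in the trait
metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FUNCTIONAL_GROUPS",
    "TraitMeta",
    "TraitTable",
    "load_trait_table",
    "transform_traits",
    "standardize_traits",
]

#: The a-priori functional groups of the experimental design.
FUNCTIONAL_GROUPS = ("grass", "small_herb", "tall_herb", "legume")

_VALUE_KINDS = ("continuous", "ordinal", "binary")


@dataclass(frozen=True)
class TraitMeta:
    """Per-trait metadata: kind, transform flag, level set, provenance."""

    name: str
    abbreviation: str
    value_kind: str
    log_transform: bool = False
    source: str = "measurement"
    levels: tuple[float, ...] | None = None
    log_shift: float | None = None  # set when a shifted log was applied

    def __post_init__(self) -> None:
        if self.value_kind not in _VALUE_KINDS:
            raise ValueError(
                f"trait {self.abbreviation!r}: value_kind must be one of "
                f"{_VALUE_KINDS}, got {self.value_kind!r}"
            )
        if self.value_kind in ("ordinal", "binary") and not self.levels:
            raise ValueError(
                f"trait {self.abbreviation!r}: ordinal/binary traits require "
                "an explicit ordered level set"
            )
        if self.source not in ("measurement", "literature"):
            raise ValueError(
                f"trait {self.abbreviation!r}: source must be 'measurement' "
                f"or 'literature', got {self.source!r}"
            )


@dataclass
class TraitTable:
    """A validated species x trait matrix with per-trait metadata.

    ``values`` is a DataFrame indexed by species id with one column per trait
    abbreviation; ``groups`` maps species id to functional group.  The
    ``transformed`` / ``standardized`` flags record the processing state and
    guard against double application.
    """

    species_ids: list[str]
    groups: pd.Series
    values: pd.DataFrame
    meta: list[TraitMeta]
    standardized: bool = False
    transformed: bool = False

    def __post_init__(self) -> None:
        abbrevs = [m.abbreviation for m in self.meta]
        if len(set(abbrevs)) != len(abbrevs):
            dupes = {a for a in abbrevs if abbrevs.count(a) > 1}
            raise ValueError(f"duplicate trait abbreviations: {sorted(dupes)}")
        if list(self.values.columns) != abbrevs:
            raise ValueError("trait value columns do not match metadata order")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("duplicate species ids")
        if list(self.values.index) != list(self.species_ids):
            raise ValueError("value rows do not match species_ids order")
        unknown = set(self.groups.unique()) - set(FUNCTIONAL_GROUPS)
        if unknown:
            raise ValueError(f"unknown functional group(s): {sorted(unknown)}")
        self.values.index.name = "species_id"
        self.groups.index.name = "species_id"
        if self.values.isna().any().any():
            cell = next(
                (sp, tr)
                for sp in self.values.index
                for tr in self.values.columns
                if pd.isna(self.values.at[sp, tr])
            )
            raise ValueError(
                f"missing trait value for species {cell[0]!r}, trait {cell[1]!r}"
            )

    @property
    def trait_abbrevs(self) -> list[str]:
        return [m.abbreviation for m in self.meta]

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def meta_for(self, abbreviation: str) -> TraitMeta:
        for m in self.meta:
            if m.abbreviation == abbreviation:
                return m
        raise KeyError(abbreviation)

    def group_sizes(self) -> dict[str, int]:
        counts = self.groups.value_counts()
        return {g: int(counts.get(g, 0)) for g in FUNCTIONAL_GROUPS}

    def copy(self) -> "TraitTable":
        return TraitTable(
            species_ids=list(self.species_ids),
            groups=self.groups.copy(),
            values=self.values.copy(),
            meta=list(self.meta),
            standardized=self.standardized,
            transformed=self.transformed,
        )

    # -- persistence -------------------------------------------------------

    def to_csv(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        """Write the table (and optionally its metadata) back to disk."""
        path = Path(path)
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        out = self.values.copy()
        out.insert(0, "group", self.groups.reindex(out.index))
        out.to_csv(path, sep=sep, index_label="species_id")
        if meta_path is not None:
            write_trait_meta(self.meta, meta_path)


def write_trait_meta(meta: Sequence[TraitMeta], path: str | Path) -> None:
    records = []
    for m in meta:
        rec: dict = {
            "name": m.name,
            "abbreviation": m.abbreviation,
            "value_kind": m.value_kind,
            "log_transform": m.log_transform,
            "source": m.source,
        }
        if m.levels is not None:
            rec["levels"] = [float(v) for v in m.levels]
        if m.log_shift is not None:
            rec["log_shift"] = float(m.log_shift)
        records.append(rec)
    Path(path).write_text(yaml.safe_dump({"traits": records}, sort_keys=False))


def read_trait_meta(path: str | Path) -> list[TraitMeta]:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "traits" not in raw:
        raise ValueError(f"{path}: expected a mapping with a 'traits' list")
    metas = []
    for rec in raw["traits"]:
        metas.append(
            TraitMeta(
                name=rec["name"],
                abbreviation=rec["abbreviation"],
                value_kind=rec["value_kind"],
                log_transform=bool(rec.get("log_transform", False)),
                source=rec.get("source", "measurement"),
                levels=tuple(rec["levels"]) if rec.get("levels") else None,
                log_shift=rec.get("log_shift"),
            )
        )
    return metas


def load_trait_table(path: str | Path, meta_path: str | Path) -> TraitTable:
    """Load and validate a species x trait table.

    ``path`` is a CSV/TSV (autodetected by extension) with species rows, a
    ``species_id`` first column, a ``group`` column of functional groups, and
    one column per trait abbreviation.  ``meta_path`` is a YAML file declaring
    every trait column (kind, log-transform flag, level set, source).

    A species with any missing trait value is rejected (named in the error),
    never imputed.
    """
    path = Path(path)
    meta_path = Path(meta_path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not meta_path.exists():
        raise FileNotFoundError(meta_path)

    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    first = df.columns[0]
    df = df.rename(columns={first: "species_id"})
    if df["species_id"].duplicated().any():
        dupes = df.loc[df["species_id"].duplicated(), "species_id"].tolist()
        raise ValueError(f"duplicate species id(s): {dupes}")
    if "group" not in df.columns:
        raise ValueError("trait table must contain a 'group' column")
    df = df.set_index("species_id")

    meta = read_trait_meta(meta_path)
    declared = [m.abbreviation for m in meta]
    table_cols = [c for c in df.columns if c != "group"]
    undeclared = sorted(set(table_cols) - set(declared))
    if undeclared:
        raise ValueError(f"trait column(s) not declared in metadata: {undeclared}")
    absent = sorted(set(declared) - set(table_cols))
    if absent:
        raise ValueError(f"declared trait(s) missing from table: {absent}")

    groups = df["group"].astype(str)
    unknown = sorted(set(groups.unique()) - set(FUNCTIONAL_GROUPS))
    if unknown:
        bad = groups[groups.isin(unknown)]
        raise ValueError(
            f"unknown functional group(s) {unknown} for species "
            f"{bad.index.tolist()}"
        )

    values = df[declared].apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        for sp in values.index:
            for tr in declared:
                if pd.isna(values.at[sp, tr]):
                    raise ValueError(
                        f"missing or non-numeric trait value: species {sp!r}, "
                        f"trait {tr!r}"
                    )

    for m in meta:
        if m.levels is not None:
            col = values[m.abbreviation]
            allowed = set(float(v) for v in m.levels)
            bad = col[~col.astype(float).isin(allowed)]
            if len(bad):
                raise ValueError(
                    f"trait {m.abbreviation!r}: value(s) outside declared "
                    f"level set {sorted(allowed)} for species "
                    f"{bad.index.tolist()}"
                )

    return TraitTable(
        species_ids=list(values.index),
        groups=groups,
        values=values.astype(float),
        meta=list(meta),
        standardized=False,
        transformed=False,
    )


def transform_traits(table: TraitTable) -> TraitTable:
    """Apply the flagged natural-log transforms, returning a new table.

    Traits flagged ``log_transform`` get ``log(x)`` when strictly positive;
    when a flagged column contains values <= 0 the strictly monotone shifted
    log ``log(x - min(x) + 1)`` is applied and the shift recorded in that
    trait's metadata.  Unflagged traits pass through unchanged.  Applying the
    transform twice is an error.
    """
    if table.transformed:
        raise ValueError("transform_traits applied twice (table already transformed)")
    if table.standardized:
        raise ValueError("cannot transform a standardized table")
    values = table.values.copy()
    meta: list[TraitMeta] = []
    for m in table.meta:
        if not m.log_transform:
            meta.append(m)
            continue
        col = values[m.abbreviation].to_numpy(dtype=float)
        lo = col.min()
        if lo > 0:
            values[m.abbreviation] = np.log(col)
            meta.append(m)
        else:
            shift = -lo + 1.0
            values[m.abbreviation] = np.log(col + shift)
            meta.append(replace(m, log_shift=float(shift)))
    return TraitTable(
        species_ids=list(table.species_ids),
        groups=table.groups.copy(),
        values=values,
        meta=meta,
        standardized=False,
        transformed=True,
    )


def standardize_traits(table: TraitTable) -> TraitTable:
    """Center each trait to mean 0 and scale to unit sample variance (n-1).

    Standardization makes single-trait Rao diversities comparable across
    traits, so that multi-trait weights read as relative importances.
    Requires transforms to have been applied first; a zero-variance trait is
    an error (it carries no information and would divide by zero).
    """
    if not table.transformed:
        raise ValueError("standardize_traits requires transform_traits first")
    if table.standardized:
        raise ValueError("standardize_traits applied twice")
    values = table.values.copy()
    for m in table.meta:
        col = values[m.abbreviation].to_numpy(dtype=float)
        sd = col.std(ddof=1)
        if not math.isfinite(sd) or sd <= 0:
            raise ValueError(f"trait {m.abbreviation!r} has zero variance")
        values[m.abbreviation] = (col - col.mean()) / sd
    return TraitTable(
        species_ids=list(table.species_ids),
        groups=table.groups.copy(),
        values=values,
        meta=list(table.meta),
        standardized=True,
        transformed=True,
    )
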