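"""Readers for trait tables and IUCN status lists.

The in-memory trait table is a plain pandas DataFrame indexed by species,
with one column per schema trait: floats (NaN = missing) for quantitative
traits, strings (NA = missing) for qualitative ones.  Validation happens at
read time and never partially constructs a table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .schema import QUALITATIVE, QUANTITATIVE, SchemaError, TraitSchema

#: IUCN Red List categories, in erosion-scenario removal order.
IUCN_ORDER: tuple[str, ...] = ("CR", "EN", "VU", "NT", "LC", "DD")


class DataError(ValueError):
    """Raised for malformed input tables."""


def validate_trait_table(df: pd.DataFrame, schema: TraitSchema) -> pd.DataFrame:
    """Validate and coerce a species x trait DataFrame against ``schema``.

    Returns a clean copy: quantitative columns as float (NaN missing),
    qualitative columns as object dtype with modalities checked against the
    trait's rank map.
    """
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise DataError(f"duplicate species identifiers: {dupes[:5]}")
    missing_cols = [t.name for t in schema if t.name not in df.columns]
    if missing_cols:
        raise DataError(f"trait table missing schema columns: {missing_cols}")
    out = pd.DataFrame(index=df.index.astype(str))
    out.index.name = "species"
    for trait in schema:
        col = df[trait.name]
        if trait.kind == QUANTITATIVE:
            try:
                out[trait.name] = pd.to_numeric(col, errors="raise").astype(float)
            except (ValueError, TypeError) as exc:
                raise DataError(
                    f"non-numeric value in quantitative trait {trait.name!r}: {exc}"
                ) from exc
        else:
            vals = col.astype(object).where(col.notna(), other=pd.NA)
            known = set(trait.rank_map)
            bad = sorted({v for v in vals.dropna().unique() if v not in known})
            if bad:
                raise SchemaError(
                    f"trait {trait.name!r}: modalities {bad} not in rank_map "
                    f"{sorted(known)}"
                )
            out[trait.name] = vals
    return out


def read_trait_table(path: str | Path, schema: TraitSchema) -> pd.DataFrame:
    """Read a species x trait CSV (first column = species id) and validate."""
    df = pd.read_csv(path, index_col=0)
    return validate_trait_table(df, schema)


def write_trait_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path)


def validate_iucn(status: pd.Series, species: list[str] | None = None) -> pd.Series:
    """Check that every species carries exactly one known IUCN category."""
    bad = sorted(set(status.dropna().unique()) - set(IUCN_ORDER))
    if bad:
        raise DataError(f"unknown IUCN categories: {bad}")
    if status.isna().any():
        raise DataError(
            f"species without IUCN status: {list(status.index[status.isna()])[:5]}")
    if species is not None:
        missing = sorted(set(species) - set(status.index))
        if missing:
            raise DataError(f"no IUCN status for species: {missing[:5]}")
    return status.astype(object)


def read_iucn(path: str | Path, species: list[str] | None = None) -> pd.Series:
    df = pd.read_csv(path)
    if not {"species", "status"}.issubset(df.columns):
        raise DataError("IUCN CSV must have columns species,status")
    s = df.set_index("species")["status"]
    return validate_iucn(s, species)


def write_iucn(status: pd.Series, path: str | Path) -> None:
    status.rename("status").rename_axis("species").to_csv(path)
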