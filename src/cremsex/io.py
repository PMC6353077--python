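"""Measurement and observer tables: validation and delimited-text I/O.

Measurement files are wide CSV — one row per individual with columns
``individual_id, site, gender, <trait codes...>`` — where gender is the
archaeologically assigned label (M/F) used as the truth proxy for sex.
Observer files are long CSV with columns
``individual_id, trait, observer, value_mm``. Missing cells may be empty
or ``NA`` on read and are written as empty fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import FEMALE, MALE, SexSpecificSummary, TraitRegistry, load_trait_registry

__all__ = [
    "ValidationError",
    "MeasurementTable",
    "ObserverTable",
    "read_measurement_table",
    "write_measurement_table",
    "read_observer_table",
    "write_observer_table",
    "summarize_trait",
]

META_COLUMNS = ["individual_id", "site", "gender"]
NA_STRINGS = ["", "NA"]


class ValidationError(ValueError):
    """An input table violates the data model."""


def _as_registry(registry: TraitRegistry | None) -> TraitRegistry:
    return registry if registry is not None else load_trait_registry()


@dataclass(frozen=True)
class MeasurementTable:
    """Individuals × traits matrix with id/site/gender metadata.

    ``df`` holds one row per individual; trait columns are float mm with
    NaN for missing. Column order is stable: metadata first, then traits
    in registry order.
    """

    df: pd.DataFrame

    @property
    def trait_codes(self) -> list[str]:
        return [c for c in self.df.columns if c not in META_COLUMNS]

    @property
    def n_individuals(self) -> int:
        return len(self.df)

    def sex_values(self, trait: str) -> tuple[np.ndarray, np.ndarray]:
        """Complete-case measurement vectors (male, female) for one trait."""
        if trait not in self.trait_codes:
            raise KeyError(f"trait {trait!r} not present in table")
        col = self.df[trait]
        male = col[(self.df["gender"] == MALE) & col.notna()].to_numpy(float)
        female = col[(self.df["gender"] == FEMALE) & col.notna()].to_numpy(float)
        return male, female

    def restrict(self, index) -> "MeasurementTable":
        return MeasurementTable(self.df.loc[index].reset_index(drop=True))


@dataclass(frozen=True)
class ObserverTable:
    """Long-format dual-observer replicate measurements."""

    df: pd.DataFrame

    @property
    def trait_codes(self) -> list[str]:
        return list(dict.fromkeys(self.df["trait"]))

    def pairs(self, trait: str) -> pd.DataFrame:
        """Wide per-individual pairs for one trait, columns obs1/obs2.

        Raises :class:`ValidationError` if any individual lacks exactly one
        value per observer.
        """
        sub = self.df[self.df["trait"] == trait]
        if sub.empty:
            raise ValidationError(f"no observer data for trait {trait!r}")
        counts = sub.groupby(["individual_id", "observer"]).size()
        bad = counts[counts != 1]
        wide = sub.pivot_table(
            index="individual_id", columns="observer", values="value_mm", aggfunc="first"
        ).reindex(columns=[1, 2])
        incomplete = wide.index[wide.isna().any(axis=1)].tolist()
        if len(bad) or incomplete:
            offenders = sorted(set([i for i, _ in bad.index] + incomplete))
            raise ValidationError(
                f"trait {trait!r}: unpaired observer values for individuals {offenders}"
            )
        wide.columns = [f"obs{int(o)}" for o in wide.columns]
        return wide


def _validate_measurement_frame(df: pd.DataFrame, registry: TraitRegistry) -> pd.DataFrame:
    for col in META_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r}")
    trait_cols = [c for c in df.columns if c not in META_COLUMNS]
    unknown = [c for c in trait_cols if c not in registry]
    if unknown:
        raise ValidationError(f"unknown trait columns: {unknown}")

    ids = df["individual_id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValidationError(f"duplicate individual_id values: {dupes}")

    bad_gender = ~df["gender"].isin([MALE, FEMALE])
    if bad_gender.any():
        row = df.index[bad_gender][0]
        raise ValidationError(
            f"row {row} (individual {df.loc[row, 'individual_id']!r}): "
            f"gender must be 'M' or 'F', got {df.loc[row, 'gender']!r}"
        )

    out = df.copy()
    out["individual_id"] = ids
    out["site"] = out["site"].astype(str)
    for col in trait_cols:
        # parse with Python's correctly-rounded float() so shortest-repr
        # serialization round-trips exactly (pandas' fast parser can be 1 ULP off)
        values = np.full(len(out), np.nan)
        for i, v in enumerate(out[col]):
            if not isinstance(v, str) and pd.isna(v):
                continue
            if isinstance(v, str):
                s = v.strip()
                if s in NA_STRINGS:
                    continue
                try:
                    x = float(s)
                except ValueError:
                    raise ValidationError(
                        f"row {i}, column {col!r}: cannot parse value {v!r} as mm"
                    ) from None
            else:
                x = float(v)
            if not np.isfinite(x) or x <= 0:
                raise ValidationError(
                    f"row {i} (individual {out.iloc[i]['individual_id']!r}), "
                    f"column {col!r}: value {x} is not a positive finite length"
                )
            values[i] = x
        out[col] = values
    # stable order: metadata, then traits in registry order
    ordered = [c for c in registry.codes if c in trait_cols]
    return out[META_COLUMNS + ordered].reset_index(drop=True)


def make_measurement_table(df: pd.DataFrame, registry: TraitRegistry | None = None) -> MeasurementTable:
    """Validate a raw frame against the registry and wrap it."""
    return MeasurementTable(_validate_measurement_frame(df, _as_registry(registry)))


def read_measurement_table(path, registry: TraitRegistry | None = None) -> MeasurementTable:
    """Read and validate a wide measurement CSV."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace({s: None for s in NA_STRINGS})
    return make_measurement_table(df, registry)


def write_measurement_table(table: MeasurementTable, path) -> None:
    """Write a measurement table as CSV; missing values become empty fields.

    Trait values are serialized with shortest round-trip float repr, so
    write∘read is the identity and repeated writes are byte-identical.
    """
    out = table.df.copy()
    for col in table.trait_codes:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, index=False)


def read_observer_table(path) -> ObserverTable:
    """Read and validate a long dual-observer CSV."""
    df = pd.read_csv(path, dtype={"individual_id": str, "trait": str})
    required = ["individual_id", "trait", "observer", "value_mm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"observer file missing columns: {missing}")
    if not df["observer"].isin([1, 2]).all():
        raise ValidationError("observer must be 1 or 2")
    values = pd.to_numeric(df["value_mm"], errors="coerce")
    if values.isna().any() or not (values > 0).all():
        row = df.index[values.isna() | ~(values > 0)][0]
        raise ValidationError(f"row {row}: observer value must be a positive length in mm")
    df["value_mm"] = values.astype(float)
    return ObserverTable(df[required].reset_index(drop=True))


def write_observer_table(table: ObserverTable, path) -> None:
    table.df.to_csv(path, index=False)


def summarize_trait(table: MeasurementTable, trait: str) -> tuple[SexSpecificSummary, SexSpecificSummary]:
    """Complete-case per-sex (n, mean, sample SD) for one trait.

    Returns the (male, female) pair. Raises :class:`ValidationError` when a
    sex has no observations for the trait.
    """
    male, female = table.sex_values(trait)
    out = []
    for sex, vals in ((MALE, male), (FEMALE, female)):
        if len(vals) == 0:
            raise ValidationError(f"trait {trait!r}: insufficient data for sex {sex}")
        sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else float("nan")
        out.append(
            SexSpecificSummary(trait=trait, sex=sex, n=len(vals), mean=float(np.mean(vals)), sd=sd)
        )
    return out[0], out[1]
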