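"""Trait registry and bundled osteometric reference standards.

The package ships two small JSON resources: a registry of the 24 metric
traits measurable on calcined adult skeletons (with the published
inter-observer error statistics used to screen them), and a set of
reference standards — per-trait, per-sex sample size, mean and sample SD
in millimetres — for the ancient Italian cremated series and two
contemporary cremated comparison series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

__all__ = [
    "TraitDescriptor",
    "TraitRegistry",
    "SexSpecificSummary",
    "TraitStandard",
    "ReferenceStandard",
    "load_trait_registry",
    "load_reference_registry",
    "available_standards",
]

MALE = "M"
FEMALE = "F"
SEXES = (MALE, FEMALE)


@dataclass(frozen=True)
class TraitDescriptor:
    """One metric trait: a caliper measurement on a named skeletal element."""

    code: str
    bone: str
    description: str
    unit: str = "mm"
    retained: bool = True
    #: published grand mean over the two observers (mm), if known
    observer_mean_mm: float | None = None
    #: published absolute technical error of measurement (mm), if known
    observer_tem_mm: float | None = None

    def __post_init__(self) -> None:
        if self.unit != "mm":
            raise ValueError(f"trait {self.code!r}: unit must be 'mm', got {self.unit!r}")


class TraitRegistry(Mapping[str, TraitDescriptor]):
    """Ordered, code-unique collection of trait descriptors."""

    def __init__(self, traits: list[TraitDescriptor]):
        codes = [t.code for t in traits]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ValueError(f"duplicate trait codes in registry: {dupes}")
        self._traits = {t.code: t for t in traits}

    def __getitem__(self, code: str) -> TraitDescriptor:
        return self._traits[code]

    def __iter__(self) -> Iterator[str]:
        return iter(self._traits)

    def __len__(self) -> int:
        return len(self._traits)

    @property
    def codes(self) -> list[str]:
        return list(self._traits)

    @property
    def retained_codes(self) -> list[str]:
        return [c for c, t in self._traits.items() if t.retained]

    def __repr__(self) -> str:  # pragma: no cover
        return f"TraitRegistry({len(self)} traits, {len(self.retained_codes)} retained)"


@dataclass(frozen=True)
class SexSpecificSummary:
    """Complete-case (n, mean, sd) for one trait in one sex.

    ``sd`` is the sample standard deviation (n−1 denominator), in mm.
    """

    trait: str
    sex: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        if self.n >= 2 and not self.sd >= 0:
            raise ValueError("sd must be nonnegative")


@dataclass(frozen=True)
class TraitStandard:
    """Per-sex reference parameters for one trait, with optional published extras."""

    code: str
    male: SexSpecificSummary
    female: SexSpecificSummary
    cutoff: float | None = None
    published: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ReferenceStandard:
    """A named set of per-trait, per-sex reference summaries."""

    label: str
    traits: dict[str, TraitStandard]
    description: str = ""

    def __contains__(self, code: str) -> bool:
        return code in self.traits

    def __getitem__(self, code: str) -> TraitStandard:
        try:
            return self.traits[code]
        except KeyError:
            raise KeyError(
                f"standard {self.label!r} does not cover trait {code!r}"
            ) from None

    @property
    def codes(self) -> list[str]:
        return list(self.traits)


def _data(name: str) -> dict:
    with resources.files("cremsex.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return json.load(fh)


def load_trait_registry() -> TraitRegistry:
    """Load the bundled registry of 24 traits (21 retained after the RTEM screen)."""
    raw = _data("traits.json")
    return TraitRegistry(
        [
            TraitDescriptor(
                code=t["code"],
                bone=t["bone"],
                description=t["description"],
                unit=raw.get("unit", "mm"),
                retained=t["retained"],
                observer_mean_mm=t.get("observer_mean_mm"),
                observer_tem_mm=t.get("observer_tem_mm"),
            )
            for t in raw["traits"]
        ]
    )


def _summary(code: str, sex: str, block: dict) -> SexSpecificSummary:
    return SexSpecificSummary(
        trait=code, sex=sex, n=int(block["n"]), mean=float(block["mean"]), sd=float(block["sd"])
    )


def available_standards() -> list[str]:
    """Names of the bundled reference standards."""
    return list(_data("standards.json")["standards"])


def load_reference_registry(name: str) -> ReferenceStandard:
    """Load a bundled reference standard by name.

    Bundled names: ``present-study`` (the ancient Italian cremated series),
    ``external-modern-1`` and ``external-modern-2`` (two contemporary
    cremated series of known sex).
    """
    standards = _data("standards.json")["standards"]
    if name not in standards:
        raise KeyError(
            f"unknown reference standard {name!r}; available: {sorted(standards)}"
        )
    raw = standards[name]
    traits = {}
    for t in raw["traits"]:
        code = t["code"]
        traits[code] = TraitStandard(
            code=code,
            male=_summary(code, MALE, t["male"]),
            female=_summary(code, FEMALE, t["female"]),
            cutoff=t.get("cutoff"),
            published=t.get("published", {}),
        )
    return ReferenceStandard(label=raw["label"], traits=traits, description=raw.get("description", ""))
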