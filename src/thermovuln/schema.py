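"""Trait schema: the declarative description of species traits.

A :class:`TraitSchema` drives both halves of the analysis.  The sensitivity
index reads each trait's kind (quantitative traits are binned into thirds of
their observed range, qualitative traits carry an explicit modality->rank
map on the 0/1/2 scale), while the functional-diversity side reads the trait
categories so that each of the five ecological functions (feeding, habitat,
reproduction, social behaviour, intrinsic biology) receives equal weight in
the Gower distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

#: The five ecological functions a marine-mammal trait can describe.
CATEGORIES: tuple[str, ...] = (
    "feeding",
    "habitat",
    "reproduction",
    "social_behavior",
    "biology",
)

QUANTITATIVE = "quantitative"
QUALITATIVE = "qualitative"
_KINDS = (QUANTITATIVE, QUALITATIVE)
_VALID_RANKS = (0, 1, 2)


class SchemaError(ValueError):
    """Raised when a trait schema (or data against it) is inconsistent."""


@dataclass(frozen=True)
class Trait:
    """One trait: its ecological category, kind, and sensitivity ranking rule.

    Parameters
    ----------
    name:
        Column identifier in the trait table.
    category:
        One of :data:`CATEGORIES`.
    kind:
        ``"quantitative"`` (numeric; ranked by thirds of the observed range)
        or ``"qualitative"`` (categorical; ranked via ``rank_map``).
    rank_map:
        For qualitative traits, a total map modality -> rank in {0, 1, 2}.
        Ignored (must be ``None``) for quantitative traits.
    use_sensitivity, use_functional:
        Whether the trait enters the sensitivity index and/or the functional
        (Gower) distance.
    """

    name: str
    category: str
    kind: str
    rank_map: Mapping[str, int] | None = None
    use_sensitivity: bool = True
    use_functional: bool = True

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise SchemaError(
                f"trait {self.name!r}: unknown category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )
        if self.kind not in _KINDS:
            raise SchemaError(
                f"trait {self.name!r}: kind must be one of {_KINDS}, got {self.kind!r}"
            )
        if self.kind == QUALITATIVE:
            if not self.rank_map:
                raise SchemaError(
                    f"qualitative trait {self.name!r} needs a non-empty rank_map"
                )
            bad = {m: r for m, r in self.rank_map.items() if r not in _VALID_RANKS}
            if bad:
                raise SchemaError(
                    f"trait {self.name!r}: ranks must be in {_VALID_RANKS}, got {bad}"
                )
            object.__setattr__(self, "rank_map", dict(self.rank_map))
        elif self.rank_map is not None:
            raise SchemaError(
                f"quantitative trait {self.name!r} must not declare a rank_map"
            )


@dataclass(frozen=True)
class TraitSchema:
    """An ordered collection of :class:`Trait` definitions."""

    traits: tuple[Trait, ...]

    def __post_init__(self) -> None:
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate trait names: {dupes}")
        object.__setattr__(self, "traits", tuple(self.traits))

    def __iter__(self):
        return iter(self.traits)

    def __len__(self) -> int:
        return len(self.traits)

    def __getitem__(self, name: str) -> Trait:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.traits]

    @property
    def sensitivity_traits(self) -> list[Trait]:
        return [t for t in self.traits if t.use_sensitivity]

    @property
    def functional_traits(self) -> list[Trait]:
        return [t for t in self.traits if t.use_functional]

    def require_functional_coverage(self) -> None:
        """Check that every category has at least one functional trait.

        Equal weighting of the five functions is only defined when every
        function is represented; called by the weight builder.
        """
        present = {t.category for t in self.functional_traits}
        missing = [c for c in CATEGORIES if c not in present]
        if missing:
            raise SchemaError(
                f"no functional trait in categor{'y' if len(missing) == 1 else 'ies'}: "
                f"{missing}"
            )

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        out = []
        for t in self.traits:
            d: dict = {"name": t.name, "category": t.category, "kind": t.kind}
            if t.rank_map is not None:
                d["rank_map"] = dict(t.rank_map)
            d["use_sensitivity"] = t.use_sensitivity
            d["use_functional"] = t.use_functional
            out.append(d)
        return {"traits": out}

    @classmethod
    def from_dict(cls, data: Mapping) -> "TraitSchema":
        try:
            entries: Iterable[Mapping] = data["traits"]
        except (KeyError, TypeError) as exc:
            raise SchemaError("schema document must contain a 'traits' list") from exc
        traits = [
            Trait(
                name=e["name"],
                category=e["category"],
                kind=e["kind"],
                rank_map=e.get("rank_map"),
                use_sensitivity=bool(e.get("use_sensitivity", True)),
                use_functional=bool(e.get("use_functional", True)),
            )
            for e in entries
        ]
        return cls(traits=tuple(traits))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TraitSchema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_schema() -> TraitSchema:
    """The built-in marine-mammal trait schema.

    Sixteen traits across the five functions.  Fifteen enter the sensitivity
    index; thirteen (diet through sexual dimorphism) enter the functional
    space.  Rank maps encode the expected influence of each modality on
    sensitivity to surface-ocean warming, e.g. epipelagic habitat use is most
    exposed to warming of the upper mixed layer (rank 2) while depth- or
    habitat-generalists are least (rank 0).
    """
    t = Trait
    return TraitSchema(
        traits=(
            # feeding
            t("main_diet", "feeding", QUALITATIVE,
              {"specialist": 2, "mixed": 1, "generalist": 0}),
            t("foraging_depth_range", "feeding", QUANTITATIVE),
            t("fasting_strategy", "feeding", QUALITATIVE,
              {"capital": 2, "intermediate": 1, "income": 0}),
            # habitat
            t("foraging_location", "habitat", QUALITATIVE,
              {"coastal": 2, "shelf": 1, "oceanic": 0}),
            t("habitat_vertical_specialization", "habitat", QUALITATIVE,
              {"epipelagic": 2, "benthic": 1, "mesopelagic": 1, "generalist": 0},
              use_functional=False),
            t("ice_reliance", "habitat", QUALITATIVE,
              {"obligate": 2, "seasonal": 1, "none": 0},
              use_functional=False),
            # stored as restriction (inverse range size): higher = more sensitive,
            # matching the upward direction of the thirds-of-range ranking
            t("geographic_range_restriction", "habitat", QUANTITATIVE,
              use_functional=False),
            # reproduction
            t("female_sexual_maturity", "reproduction", QUANTITATIVE),
            t("weaning", "reproduction", QUANTITATIVE),
            t("gestation_length", "reproduction", QUANTITATIVE),
            t("interlitter_interval", "reproduction", QUANTITATIVE),
            t("breeding_sites", "reproduction", QUALITATIVE,
              {"ice": 2, "land": 1, "water": 0}),
            # social behaviour
            t("social_group_size", "social_behavior", QUANTITATIVE),
            t("social_behavior", "social_behavior", QUALITATIVE,
              {"solitary": 2, "small_groups": 1, "gregarious": 0}),
            # intrinsic biology
            t("adult_max_body_mass", "biology", QUANTITATIVE),
            t("sexual_dimorphism", "biology", QUANTITATIVE,
              use_sensitivity=False),
        )
    )
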