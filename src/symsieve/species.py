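"""Species tags and the trait-based A/B/C species partition.

The subtraction logic compares three groups of plant species: trait-positive
dicots (group A), trait-positive monocots (group B), and trait-negative
species (group C).  Orthology clustering runs over a subset of these (the
*clustered species*), while homology-search hit tables may cover all of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml


class SpeciesResolutionError(ValueError):
    """A sequence label could not be assigned to a registered species."""


@dataclass(frozen=True)
class SpeciesTag:
    """A short species code (e.g. ``Mtr``) with an optional display name."""

    code: str
    display_name: str = ""

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("species code must be non-empty")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


def _as_tags(items: Iterable[SpeciesTag | str]) -> tuple[SpeciesTag, ...]:
    return tuple(s if isinstance(s, SpeciesTag) else SpeciesTag(s) for s in items)


@dataclass
class SpeciesGroups:
    """The A/B/C partition plus the ordered clustered-species set.

    ``group_a``: trait-positive dicots; ``group_b``: trait-positive monocots;
    ``group_c``: trait-negative species.  ``clustered_species`` is the ordered
    subset whose proteomes entered orthology clustering (in the reference
    configuration A ∪ C, but any partition is accepted).
    """

    group_a: tuple[SpeciesTag, ...]
    group_b: tuple[SpeciesTag, ...]
    group_c: tuple[SpeciesTag, ...]
    clustered_species: tuple[SpeciesTag, ...] = field(default_factory=tuple)
    guide_tree: str | None = None

    def __post_init__(self) -> None:
        self.group_a = _as_tags(self.group_a)
        self.group_b = _as_tags(self.group_b)
        self.group_c = _as_tags(self.group_c)
        self.clustered_species = _as_tags(self.clustered_species)
        if not self.clustered_species:
            self.clustered_species = self.group_a + self.group_c
        codes = [t.code for t in self.group_a + self.group_b + self.group_c]
        dupes = {c for c in codes if codes.count(c) > 1}
        if dupes:
            raise ValueError(f"species groups overlap or repeat codes: {sorted(dupes)}")
        unknown = [t.code for t in self.clustered_species if t.code not in set(codes)]
        if unknown:
            raise ValueError(f"clustered species not in any group: {unknown}")

    # -- membership helpers -------------------------------------------------

    @property
    def all_species(self) -> tuple[SpeciesTag, ...]:
        return self.group_a + self.group_b + self.group_c

    def codes(self, which: str = "all") -> set[str]:
        grp = {
            "A": self.group_a,
            "B": self.group_b,
            "C": self.group_c,
            "all": self.all_species,
            "clustered": self.clustered_species,
        }[which]
        return {t.code for t in grp}

    @property
    def positive_clustered(self) -> tuple[SpeciesTag, ...]:
        """Trait-positive species that are part of the clustered set."""
        pos = self.codes("A") | self.codes("B")
        return tuple(t for t in self.clustered_species if t.code in pos)

    # -- label resolution ---------------------------------------------------

    def resolve_label(self, label: str) -> tuple[SpeciesTag, str]:
        """Split ``<code>_<protein_id>`` by the longest registered code prefix.

        Protein ids may themselves contain underscores, so the longest code
        that prefixes the label (followed by an underscore) wins.
        """
        best: SpeciesTag | None = None
        for tag in self.all_species:
            if label.startswith(tag.code + "_"):
                if best is None or len(tag.code) > len(best.code):
                    best = tag
        if best is None:
            raise SpeciesResolutionError(
                f"label {label!r} matches no registered species code "
                f"(known: {sorted(self.codes('all'))})"
            )
        return best, label[len(best.code) + 1 :]

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SpeciesGroups":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "SpeciesGroups":
        return cls(
            group_a=tuple(data["group_a"]),
            group_b=tuple(data.get("group_b", ())),
            group_c=tuple(data["group_c"]),
            clustered_species=tuple(data.get("clustered_species", ())),
            guide_tree=data.get("guide_tree"),
        )

    def to_dict(self) -> dict:
        out = {
            "group_a": [t.code for t in self.group_a],
            "group_b": [t.code for t in self.group_b],
            "group_c": [t.code for t in self.group_c],
            "clustered_species": [t.code for t in self.clustered_species],
        }
        if self.guide_tree:
            out["guide_tree"] = self.guide_tree
        return out

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


#: The reference 16-species configuration: six trait-positive dicots, seven
#: trait-positive monocots, three trait-negative Brassicaceae; the nine
#: clustered species are the dicots of groups A and C.
DEFAULT_GROUPS = SpeciesGroups(
    group_a=(
        SpeciesTag("Mtr", "Medicago truncatula"),
        SpeciesTag("Gma", "Glycine max"),
        SpeciesTag("Sly", "Solanum lycopersicum"),
        SpeciesTag("Stu", "Solanum tuberosum"),
        SpeciesTag("Vvi", "Vitis vinifera"),
        SpeciesTag("Ptr", "Populus trichocarpa"),
    ),
    group_b=(
        SpeciesTag("Osa", "Oryza sativa"),
        SpeciesTag("Zma", "Zea mays"),
        SpeciesTag("Tur", "Triticum urartu"),
        SpeciesTag("Sbi", "Sorghum bicolor"),
        SpeciesTag("Hvu", "Hordeum vulgare"),
        SpeciesTag("Bdi", "Brachypodium distachyon"),
        SpeciesTag("Ata", "Aegilops tauschii"),
    ),
    group_c=(
        SpeciesTag("Ath", "Arabidopsis thaliana"),
        SpeciesTag("Aly", "Arabidopsis lyrata"),
        SpeciesTag("Bra", "Brassica rapa"),
    ),
)


def make_groups(
    group_a: Sequence[str],
    group_b: Sequence[str] = (),
    group_c: Sequence[str] = (),
    clustered: Sequence[str] = (),
) -> SpeciesGroups:
    """Convenience constructor from bare code strings."""
    return SpeciesGroups(
        group_a=tuple(group_a),
        group_b=tuple(group_b),
        group_c=tuple(group_c),
        clustered_species=tuple(clustered),
    )
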