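"""Crop classification and sequential-combination rules.

The crop table follows the MIRCA2000 classification: 26 crop classes, up
to five sub-crops each (sub-crops encode varieties such as spring/winter
cereals or the multiple seasons of paddy rice). For reporting, crops
aggregate to four groups: rice; the C3 cereals wheat, barley and rye; the
C4 cereals maize, millet and sorghum; everything else as "other".

Which crop combinations may form a sequential system is config-driven
(``data/combination_rules.yaml``); the shipped defaults are a documented
reconstruction, see that file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .core import InvalidCropError

GROUP_LABELS = ("rice", "C3_cereal", "C4_cereal", "other")
#: display names used in report tables
GROUP_DISPLAY = {
    "rice": "Rice",
    "C3_cereal": "C3 cereal",
    "C4_cereal": "C4 cereal",
    "other": "Other",
}


@dataclass(frozen=True)
class CropClass:
    crop_id: int
    name: str
    group: str
    is_perennial: bool
    max_subcrops: int

    def __post_init__(self) -> None:
        if not 1 <= self.crop_id <= 26:
            raise InvalidCropError(f"crop_id must be 1..26, got {self.crop_id}")
        if self.group not in GROUP_LABELS:
            raise InvalidCropError(f"unknown group {self.group!r}")
        if not 1 <= self.max_subcrops <= 5:
            raise InvalidCropError("max_subcrops must be 1..5")


class Taxonomy:
    """The 26-crop table with name/group lookups."""

    def __init__(self, crops: list[CropClass]):
        self._by_id = {c.crop_id: c for c in crops}
        self._by_name = {c.name: c for c in crops}
        if len(self._by_id) != len(crops):
            raise InvalidCropError("duplicate crop_id in taxonomy")

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(sorted(self._by_id.values(), key=lambda c: c.crop_id))

    def crop(self, crop_id: int) -> CropClass:
        try:
            return self._by_id[crop_id]
        except KeyError:
            raise InvalidCropError(f"unknown crop_id {crop_id}") from None

    def id_of(self, name: str) -> int:
        try:
            return self._by_name[name].crop_id
        except KeyError:
            raise InvalidCropError(f"unknown crop name {name!r}") from None

    def crop_group(self, crop_id: int) -> str:
        """Crop group label: rice / C3_cereal / C4_cereal / other."""
        return self.crop(crop_id).group

    def is_perennial(self, crop_id: int) -> bool:
        return self.crop(crop_id).is_perennial

    @property
    def annual_crop_ids(self) -> tuple[int, ...]:
        return tuple(c.crop_id for c in self if not c.is_perennial)

    @property
    def perennial_crop_ids(self) -> tuple[int, ...]:
        return tuple(c.crop_id for c in self if c.is_perennial)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "crop_id": c.crop_id,
                    "name": c.name,
                    "group": c.group,
                    "is_perennial": c.is_perennial,
                    "max_subcrops": c.max_subcrops,
                }
                for c in self
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


Pair = tuple[tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class CombinationRules:
    """Which crop combinations may form one sequential system.

    ``forbidden_pairs`` holds unordered (crop_id, subcrop) pairs that may
    never co-occur; ``same_crop_sequences_allowed`` lists crops whose
    sub-crops encode true multiple seasons and may therefore follow
    themselves (paddy rice by default); perennials (from the taxonomy)
    never enter multi-crop sequences.
    """

    forbidden_pairs: frozenset[frozenset[tuple[int, int]]]
    same_crop_sequences_allowed: frozenset[int]
    max_frequency: int = 3
    perennial_crops: frozenset[int] = field(default_factory=frozenset)

    def pair_forbidden(self, a: tuple[int, int], b: tuple[int, int]) -> bool:
        return frozenset((a, b)) in self.forbidden_pairs

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "version": 1,
            "max_frequency": self.max_frequency,
            "same_crop_sequences_allowed": sorted(self.same_crop_sequences_allowed),
            "forbidden_pairs": sorted(
                [sorted(list(p)) for p in self.forbidden_pairs]
            ),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _data_text(name: str) -> str:
    return (resources.files("multicrop") / "data" / name).read_text()


def load_taxonomy(path: str | Path | None = None) -> Taxonomy:
    """Load the crop table (shipped default, or a user YAML override)."""
    text = Path(path).read_text() if path is not None else _data_text("crops.yaml")
    raw = yaml.safe_load(text)
    crops = [
        CropClass(
            crop_id=int(r["crop_id"]),
            name=str(r["name"]),
            group=str(r["group"]),
            is_perennial=bool(r["perennial"]),
            max_subcrops=int(r["max_subcrops"]),
        )
        for r in raw["crops"]
    ]
    return Taxonomy(crops)


def load_rules(
    path: str | Path | None = None, taxonomy: Taxonomy | None = None
) -> CombinationRules:
    """Load combination rules; perennial exclusions come from the taxonomy."""
    text = (
        Path(path).read_text()
        if path is not None
        else _data_text("combination_rules.yaml")
    )
    raw = yaml.safe_load(text)
    taxonomy = taxonomy if taxonomy is not None else load_taxonomy()
    pairs = frozenset(
        frozenset(((int(a), int(b)), (int(c), int(d))))
        for (a, b), (c, d) in raw.get("forbidden_pairs", [])
    )
    return CombinationRules(
        forbidden_pairs=pairs,
        same_crop_sequences_allowed=frozenset(
            int(c) for c in raw.get("same_crop_sequences_allowed", [])
        ),
        max_frequency=int(raw.get("max_frequency", 3)),
        perennial_crops=frozenset(taxonomy.perennial_crop_ids),
    )


def is_permitted_combination(
    members: list[tuple[int, int]], rules: CombinationRules
) -> bool:
    """Whether 1-3 (crop_id, subcrop) members may form one system.

    Invariant under member permutation. Single members are always
    permitted; multi-crop sequences are rejected when they contain a
    perennial, a forbidden pair, or a same-crop repeat outside the
    allowed multi-season crops.
    """
    if not 1 <= len(members) <= rules.max_frequency:
        return False
    if len(members) == 1:
        return True
    if any(crop in rules.perennial_crops for crop, _ in members):
        return False
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            if a == b:
                return False  # identical sub-crop twice is never a sequence
            if rules.pair_forbidden(a, b):
                return False
            if a[0] == b[0] and a[0] not in rules.same_crop_sequences_allowed:
                return False
    return True
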