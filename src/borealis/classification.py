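"""Biogeographic species classification from Arctic subzone occurrence data.

Each vascular species is scored by its reported frequency in the five Arctic
bioclimatic subzones (A coldest … E warmest) and the boreal zone, and assigned
one of four range classes:

* **Boreal** — boreal zone only, absent from the tundra biome;
* **Boreal-Tundra** — boreal zone and Low Arctic (subzones D–E) but not the
  High Arctic (A–C);
* **Arctic** — tundra biome but not the boreal zone;
* **Ubiquitous** — boreal zone, Low Arctic and High Arctic.

"boreal" in lowercase (the borealisation indices' focal set) covers the
Boreal and Boreal-Tundra classes: species whose ranges cross the biome
boundary without extending into the High Arctic. Occurrence combinations
matching none of the four definitions (e.g. High Arctic presence without
Low Arctic presence) are surfaced as ``UNCLASSIFIED`` and must be resolved
through a manual-override table before indices are computed.
"""

from __future__ import annotations

import enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

ZONES = ("A", "B", "C", "D", "E", "Boreal")
HIGH_ARCTIC = ("A", "B", "C")
LOW_ARCTIC = ("D", "E")

#: Frequency categories ordered from most to least abundant. ``uncertain``
#: and ``introduced`` sit below ``rare`` since all three count as absence.
CATEGORY_ORDER = ("frequent", "scattered", "rare", "uncertain", "introduced", "absent")
_RANK = {c: i for i, c in enumerate(CATEGORY_ORDER)}


class SpeciesClass(str, enum.Enum):
    BOREAL = "Boreal"
    BOREAL_TUNDRA = "BorealTundra"
    ARCTIC = "Arctic"
    UBIQUITOUS = "Ubiquitous"
    UNCLASSIFIED = "Unclassified"

    def __str__(self) -> str:  # keeps CSV output plain
        return self.value


class ClassificationError(ValueError):
    pass


def zone_present(category: str) -> bool:
    """Whether a frequency category counts as presence in a zone.

    Only ``frequent`` and ``scattered`` count; ``rare``, ``uncertain`` and
    ``introduced`` are treated as absence.
    """
    if category not in _RANK:
        raise ClassificationError(
            f"unknown frequency category {category!r}; valid: {CATEGORY_ORDER}"
        )
    return category in ("frequent", "scattered")


def classify_species(occurrence: Mapping[str, str]) -> SpeciesClass:
    """Assign a range class from a zone → frequency-category mapping.

    The rule set reduces to three presence predicates — boreal zone (B),
    Low Arctic D∪E (L), High Arctic A∪B∪C (H):

    ====  ====  ====  =================
    B     L     H     class
    ====  ====  ====  =================
    yes   no    no    Boreal
    yes   yes   no    Boreal-Tundra
    no    any presence  Arctic
    yes   yes   yes   Ubiquitous
    ====  ====  ====  =================

    Anything else (B∧H without L, or no presence at all) is UNCLASSIFIED.
    """
    missing = [z for z in ZONES if z not in occurrence]
    if missing:
        raise ClassificationError(f"occurrence table missing zones: {missing}")
    boreal = zone_present(occurrence["Boreal"])
    low = any(zone_present(occurrence[z]) for z in LOW_ARCTIC)
    high = any(zone_present(occurrence[z]) for z in HIGH_ARCTIC)

    if boreal and not low and not high:
        return SpeciesClass.BOREAL
    if boreal and low and not high:
        return SpeciesClass.BOREAL_TUNDRA
    if not boreal and (low or high):
        return SpeciesClass.ARCTIC
    if boreal and low and high:
        return SpeciesClass.UBIQUITOUS
    return SpeciesClass.UNCLASSIFIED


def merge_infraspecific_occurrences(
    entries: Sequence[Mapping[str, str]]
) -> dict[str, str]:
    """Merge several infraspecific occurrence rows into one species row.

    Per zone, the most abundant reported category wins (frequent > scattered
    > rare > uncertain > introduced > absent). Associative and commutative.
    """
    if not entries:
        raise ClassificationError("merge requires at least one occurrence entry")
    merged: dict[str, str] = {}
    for zone in ZONES:
        cats = []
        for entry in entries:
            cat = entry.get(zone, "absent")
            if cat not in _RANK:
                raise ClassificationError(f"unknown frequency category {cat!r}")
            cats.append(cat)
        merged[zone] = min(cats, key=_RANK.__getitem__)
    return merged


def is_boreal_class(cls: SpeciesClass | str) -> bool:
    """Whether a class belongs to the lowercase-'boreal' focal set.

    True for Boreal and Boreal-Tundra; False for Arctic and Ubiquitous.
    Unclassified species must be resolved first and raise.
    """
    cls = SpeciesClass(cls)
    if cls is SpeciesClass.UNCLASSIFIED:
        raise ClassificationError(
            "unclassified species must be resolved (manual override) before "
            "index computation"
        )
    return cls in (SpeciesClass.BOREAL, SpeciesClass.BOREAL_TUNDRA)


def classify_table(
    occurrences: pd.DataFrame,
    overrides: Mapping[str, SpeciesClass | str] | None = None,
) -> pd.DataFrame:
    """Classify every taxon in a zone-occurrence table.

    Parameters
    ----------
    occurrences
        One row per taxon row with columns ``taxon, A, B, C, D, E, Boreal``;
        multiple rows per taxon (infraspecifics) are merged first.
    overrides
        taxon → class manual assignments, applied last (``source='manual'``).

    Returns
    -------
    DataFrame with columns ``taxon, cls, source``.
    """
    rows = []
    for taxon, group in occurrences.groupby("taxon", sort=True):
        entries = [
            {z: str(r[z]) for z in ZONES} for _, r in group.iterrows()
        ]
        merged = merge_infraspecific_occurrences(entries)
        rows.append(
            {"taxon": taxon, "cls": classify_species(merged).value, "source": "rules"}
        )
    table = pd.DataFrame(rows, columns=["taxon", "cls", "source"])
    if overrides:
        ov = {t: SpeciesClass(c).value for t, c in overrides.items()}
        known = table["taxon"].isin(ov)
        table.loc[known, "cls"] = table.loc[known, "taxon"].map(ov)
        table.loc[known, "source"] = "manual"
        new = [t for t in ov if t not in set(table["taxon"])]
        if new:
            table = pd.concat(
                [
                    table,
                    pd.DataFrame(
                        {"taxon": new, "cls": [ov[t] for t in new], "source": "manual"}
                    ),
                ],
                ignore_index=True,
            )
    return table


def class_lookup(table: pd.DataFrame) -> dict[str, SpeciesClass]:
    """taxon → SpeciesClass dict from a ``classify_table`` output frame."""
    return {r.taxon: SpeciesClass(r.cls) for r in table.itertuples()}


def boreal_set(class_table: Mapping[str, SpeciesClass] | pd.DataFrame) -> frozenset[str]:
    """Set of taxa in the lowercase-'boreal' focal classes."""
    if isinstance(class_table, pd.DataFrame):
        class_table = class_lookup(class_table)
    return frozenset(t for t, c in class_table.items() if is_boreal_class(c))
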