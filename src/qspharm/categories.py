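"""Target membership across the five pathway categories: Venn overlaps,
pleiotropy rankings, and category-unique targets.

Each identified target is profiled by the set of pathway categories
(NT, SG, ANS, NP, DS) whose pathways contain it. Targets appearing in at
least four of the five categories are called pleiotropic; targets confined
to a single category are candidates for selective intervention. Pathways in
the 'other' bucket do not enter the five-way Venn but are flagged on the
profile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .enrichment import PATHWAY_CATEGORIES, PathwayCollection


@dataclass(frozen=True)
class CategoryProfile:
    target_id: str
    categories: frozenset[str]  # subset of the five Venn categories
    pathway_count: int  # distinct pathways (any category) containing the target
    in_other: bool = False  # appears in >=1 'other'-category pathway
    provenance: str = "known"  # known | predicted

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", frozenset(self.categories))


def build_profiles(
    targets: Iterable[str],
    collection: PathwayCollection,
    provenance: Mapping[str, str] | None = None,
) -> list[CategoryProfile]:
    """One profile per target with at least one pathway membership.

    ``provenance`` optionally maps target ids to 'known' or 'predicted' so
    that known-vs-predicted splits stay reproducible downstream.
    """
    provenance = provenance or {}
    profiles = []
    for tid in sorted(set(targets)):
        cats: set[str] = set()
        count = 0
        in_other = False
        for pid, members in collection.pathways.items():
            if tid not in members:
                continue
            count += 1
            cat = collection.category(pid)
            if cat in PATHWAY_CATEGORIES:
                cats.add(cat)
            else:
                in_other = True
        if count == 0:
            continue
        profiles.append(
            CategoryProfile(
                target_id=tid,
                categories=frozenset(cats),
                pathway_count=count,
                in_other=in_other,
                provenance=provenance.get(tid, "known"),
            )
        )
    return profiles


def overlap_counts(profiles: Iterable[CategoryProfile]) -> dict[frozenset[str], int]:
    """Counts over the 31 nonempty subsets of the five categories.

    Each profiled target with at least one Venn category contributes to
    exactly one subset (its full category set), so the counts partition
    those profiles. Targets confined to 'other' pathways are not counted.
    """
    counts: dict[frozenset[str], int] = {}
    for size in range(1, len(PATHWAY_CATEGORIES) + 1):
        from itertools import combinations

        for combo in combinations(PATHWAY_CATEGORIES, size):
            counts[frozenset(combo)] = 0
    for profile in profiles:
        if profile.categories:
            counts[profile.categories] += 1
    return counts


def overlap_counts_json(counts: Mapping[frozenset[str], int]) -> dict[str, int]:
    """JSON-friendly view keyed by '+'-joined category names in canonical order."""
    order = {c: i for i, c in enumerate(PATHWAY_CATEGORIES)}
    return {
        "+".join(sorted(subset, key=order.get)): n
        for subset, n in sorted(
            counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0], key=order.get))
        )
    }


def pleiotropic(
    profiles: Iterable[CategoryProfile], min_categories: int = 4
) -> list[CategoryProfile]:
    """Targets shared by at least ``min_categories`` of the five categories,
    sorted by descending category count then target id."""
    kept = [p for p in profiles if len(p.categories) >= min_categories]
    kept.sort(key=lambda p: (-len(p.categories), p.target_id))
    return kept


def category_unique(
    profiles: Iterable[CategoryProfile],
) -> dict[str, list[str]]:
    """Per category, the targets appearing in that category only."""
    out: dict[str, list[str]] = {c: [] for c in PATHWAY_CATEGORIES}
    for p in profiles:
        if len(p.categories) == 1:
            (cat,) = p.categories
            out[cat].append(p.target_id)
    for cat in out:
        out[cat].sort()
    return out


def write_profiles_tsv(profiles: Iterable[CategoryProfile], path: str | Path) -> None:
    order = {c: i for i, c in enumerate(PATHWAY_CATEGORIES)}
    with Path(path).open("w") as fh:
        fh.write("target_id\tcategories\tn_categories\tpathway_count\tin_other\tprovenance\n")
        for p in sorted(profiles, key=lambda p: p.target_id):
            cats = "+".join(sorted(p.categories, key=order.get))
            fh.write(
                f"{p.target_id}\t{cats}\t{len(p.categories)}\t{p.pathway_count}\t"
                f"{int(p.in_other)}\t{p.provenance}\n"
            )


def write_overlap_json(counts: Mapping[frozenset[str], int], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(overlap_counts_json(counts), fh, indent=1)
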