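#!/usr/bin/env python
"""Category overlap and pleiotropy of the identified targets.

Profiles every target by the pathway categories (NT/SG/ANS/NP/DS) whose
pathways contain it, tabulates the 31 Venn overlap counts, ranks pleiotropic
targets (in >= 4 categories), and lists the targets unique to a single
category — candidates for selective intervention.
"""

from pathlib import Path

from qspharm.categories import (
    build_profiles,
    category_unique,
    overlap_counts,
    pleiotropic,
    write_overlap_json,
    write_profiles_tsv,
)
from qspharm.enrichment import PathwayCollection
from qspharm.interactions import InteractionMatrix

DATA = Path("results/data")
OUT = Path("results/tables")


def main() -> None:
    matrix = InteractionMatrix.read(OUT / "matrix_edgelist.tsv")
    known = sorted(t for t, deg in matrix.target_degrees().items() if deg)
    predicted = set()
    with (OUT / "predictions.tsv").open() as fh:
        next(fh)
        for line in fh:
            predicted.add(line.split("\t")[1])
    provenance = {t: "known" for t in known}
    provenance.update({t: "predicted" for t in predicted if t not in provenance})

    collection = PathwayCollection.from_gmt(DATA / "pathways.gmt")
    profiles = build_profiles(sorted(set(known) | predicted), collection, provenance)
    write_profiles_tsv(profiles, OUT / "category_profiles.tsv")
    counts = overlap_counts(profiles)
    write_overlap_json(counts, OUT / "category_overlaps.json")
    print(f"{len(profiles)} targets profiled across the five categories")

    for k in (5, 4):
        hits = [p for p in pleiotropic(profiles, k) if len(p.categories) == k]
        print(f"targets in exactly {k} categories: {len(hits)}")
    pleio = pleiotropic(profiles, 4)
    print(f"pleiotropic targets (>= 4 of 5 categories): {len(pleio)}")

    unique = category_unique(profiles)
    for cat, targets in unique.items():
        print(f"  unique to {cat}: {len(targets)}")


if __name__ == "__main__":
    main()
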