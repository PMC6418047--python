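#!/usr/bin/env python
"""Curate the drug-target interaction table into the binary matrix R.

Parses the STITCH-dialect table produced by 01_simulate_study.py, applies
the experimental-evidence filter (score >= 0.4), builds the sparse binary
matrix, and summarises promiscuity (per-drug/per-target degrees).
"""

from pathlib import Path

from qspharm.interactions import (
    build_matrix,
    filter_by_evidence,
    parse_interaction_table,
    promiscuity_summary,
    write_degree_summary,
)

DATA = Path("results/data")
OUT = Path("results/tables")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = parse_interaction_table(DATA / "interactions_stitch.tsv", "stitch")
    kept = filter_by_evidence(records, 0.4)
    print(f"parsed {len(records)} records, {len(kept)} pass the evidence filter")

    drug_ids = sorted({r.drug_id for r in kept})
    target_ids = sorted({r.target_id for r in kept})
    matrix, dropped = build_matrix(kept, drug_ids, target_ids)
    matrix.write(OUT / "matrix_edgelist.tsv")
    print(f"matrix: {matrix.shape[0]} drugs x {matrix.shape[1]} targets, "
          f"{matrix.n_entries} interactions ({dropped} unresolvable dropped)")

    summary = promiscuity_summary(matrix, threshold=10)
    write_degree_summary(summary, OUT / "degrees.tsv")
    print(f"mean interactions per drug:   {summary.mean_per_drug_rounded}")
    print(f"mean interactions per target: {summary.mean_per_target_rounded}")
    print(f"promiscuous drugs (>=10 targets): {len(summary.promiscuous_drugs)}")


if __name__ == "__main__":
    main()
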