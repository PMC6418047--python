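#!/usr/bin/env python
"""Generate the synthetic study that every downstream step analyses.

Writes a study_like study (50 drugs in six abuse categories x 150 candidate
targets, rank-5 latent structure, ~9 interactions per drug, 50 pathways with
3 planted enriched) to results/data/ in the pipeline's input formats, plus
the ground-truth JSON used to score recovery.
"""

from pathlib import Path

from qspharm.synthetic import make_study, write_study

SEED = 42
OUT = Path("results/data")


def main() -> None:
    study = make_study("study_like", seed=SEED)
    paths = write_study(study, OUT)
    print(f"study 'study_like' (seed {SEED})")
    print(f"  drugs:        {len(study.matrix.drug_ids)}")
    print(f"  targets:      {len(study.matrix.target_ids)}")
    print(f"  interactions: {study.full_matrix.n_entries} "
          f"({study.matrix.n_entries} train / {len(study.heldout_positives)} held out)")
    print(f"  pathways:     {len(study.collection.pathways)} "
          f"({len(study.planted_enriched)} planted enriched)")
    for name, path in paths.items():
        print(f"  wrote {name}: {path}")


if __name__ == "__main__":
    main()
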