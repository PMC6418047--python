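# qspharm

Quantitative systems pharmacology (QSP) analysis of drug–target interaction
networks, built around the study design used for drugs of abuse: curate
evidence-scored drug–target interactions from database exports, predict
novel interactions with probabilistic matrix factorization, compare drugs
and targets by structural and pharmacological similarity, and map the
identified targets onto cellular pathways with enrichment and pleiotropy
analysis. It is written for computational pharmacologists who want each of
those steps as a tested, composable library (plus a CLI), exercisable
end-to-end on synthetic studies with known ground truth.

## What it computes

**Interaction curation.** Interaction tables in two TSV dialects (a
DrugBank-like edge list and a STITCH-like table with five confidence
channels) are parsed, validated, and filtered: curated records are kept
unconditionally, text-mined/experimental records only when their
experimental confidence is ≥ 0.4. The union induces a sparse binary matrix
*R* (N drugs × M targets) and the promiscuity summary (per-drug and
per-target degrees).

**PMF prediction.** *R* is factorized as *R ≈ UᵀV* with D latent factors
per drug and target, fit by gradient descent on the squared error over
observed positives and a seeded sample of unobserved pairs treated as
negatives, with L2 regularization. The reconstructed value for an
unobserved pair, clamped to [0, 1], is its confidence score; per drug, the
candidates with confidence > 0.7 within the top 10 ranks are reported as
novel interactions.

**Similarity and clustering.** Drugs are compared by the Tanimoto distance
1 − |a∩b|/|a∪b| between structure fingerprints and by the cosine distance
1 − (dᵢ·dⱼ)/(|dᵢ||dⱼ|) between their binary target vectors (rows of *R*);
targets by the cosine distance between ligand vectors (columns of *R*).
Dendrograms use agglomerative clustering (UPGMA by default) with a
deterministic lexicographic tie-break, exportable as Newick.

**Pathway enrichment.** For a pathway *A* with *K* members in a universe of
*M* proteins and *m* identified targets of which *k₀* fall in *A*, the
enrichment p-value is the upper hypergeometric tail
P(A) = Σ_{k≥k₀} C(K,k)·C(M−K,m−k)/C(M,m), adjusted across pathways with the
Benjamini–Hochberg step-up procedure; pathways with adjusted p < 0.05 are
called enriched.

**Category analysis.** Each target is profiled by the pathway categories
(NT, SG, ANS, NP, DS) containing it; the package tabulates the 31-way Venn
overlap counts, pleiotropic targets (≥ 4 of 5 categories), and targets
unique to one category.

## Worked example

The `analysis/` scripts run the whole study on a synthetic dataset shaped
like the curated one (50 drugs in six categories × 150 candidate targets,
~9 interactions per drug, 50 pathways of which 3 are planted enriched):

```bash
python analysis/01_simulate_study.py
python analysis/02_curate_interactions.py
python analysis/03_predict_targets.py
python analysis/04_similarity_clusters.py
python analysis/05_pathway_enrichment.py
python analysis/06_target_pleiotropy.py
```

which prints, among other things:

```
parsed 409 records, 409 pass the evidence filter
matrix: 50 drugs x 87 targets, 409 interactions (0 unresolvable dropped)
mean interactions per drug:   8.2
...
43 novel interactions selected for 31 drugs
held-out AUC 0.942, hit rate@10 0.84 (45 positives)
...
category recovery (ARI at k=6): interaction patterns 0.776, structure fingerprints 0.007
...
planted enriched pathways recovered: 3/3 (pw001, pw002, pw003)
  pw001 [NT] K=60 k0=32 p_adj=3.51e-10
```

Reading these numbers: the evidence filter and matrix construction
reproduce the study's promiscuity regime (~8–9 interactions per drug); the
PMF model ranks 84% of masked interactions into each drug's top 10 and
separates held-out positives from negatives with AUC 0.94; drugs cluster by
category when compared through their interaction patterns but not through
their 2D structures; and all three planted pathways are recovered as the
most significant enrichments. Tables land under `results/tables/`.

The same pipeline is scriptable over your own files:

```bash
qspharm run --stitch interactions.tsv --pathways pathways.gmt --out-dir results/run
qspharm report --run-dir results/run --format tsv
```

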