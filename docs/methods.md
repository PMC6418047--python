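# Methods

This note documents the models, procedures, parameter choices, and known
limitations behind `qspharm`.

## Interaction curation

Two table dialects are supported. The DrugBank-like dialect is a plain
(drug, target) edge list: such records come from manual curation and are
kept unconditionally. The STITCH-like dialect carries five confidence
channels (experimental, database, text-mining, prediction, combined); only
the experimental channel gates inclusion, with an inclusive threshold of
0.4 on the unit scale — the conventional "medium confidence" cutoff for
that resource. Raw exports score channels as integers on 0–1000; the parser
detects this (any score > 1 in the file) and rescales by 1/1000, so both
conventions are accepted. Scores still outside [0, 1] after rescaling are
reported as errors naming the offending line.

Records from both sources are merged by set union: the binary matrix *R*
records whether any retained source reports the pair. Conflict resolution
beyond the union (e.g. preferring one source) is not attempted; provenance
stays on the record list. Identifiers that cannot be resolved against the
supplied drug/target orderings are dropped with a logged count (strict mode
turns this into an error), keeping partial fixtures usable.

Promiscuity is the degree of a node in the bipartite network. Means are
reported unrounded and at one decimal; the promiscuous-drug list uses an
inclusive threshold (default ≥ 10 targets).

## Probabilistic matrix factorization

*R* (N × M) is modelled as *UᵀV* with D-dimensional factors. Because only
positive interactions are recorded, this is the implicit-feedback setting:
each training epoch pairs the observed positives (value 1) with
`neg_ratio` × as many unobserved pairs sampled as provisional negatives
(value 0), resampled every epoch so no single unobserved pair is
persistently treated as negative. The objective is the summed squared
reconstruction error over those cells plus L2 penalties on U and V,
minimized by full-batch gradient descent (a per-sample SGD variant is
available behind `optimizer="sgd"`).

Defaults: D = 50, reg_u = reg_v = 0.01, learn_rate = 0.01, epochs = 200
with early stop when the relative loss change drops below 1e-5,
neg_ratio = 5, seed 0. All randomness (initialization at scale 0.1,
negative resampling) derives from the config seed, so training is
bit-reproducible. A non-finite loss aborts with an error advising a smaller
learning rate. With negative resampling disabled the objective is fixed and
the loss trace is non-increasing; with resampling the trace is noisy by
construction and only monitored for divergence.

Confidence scores are the factor products clamped to [0, 1] (`clamp`,
default) or passed through a logistic (`logistic`). Clamping is the default
because reconstructed values are presented directly as confidences.
Selection: per drug, unobserved targets are ranked by confidence descending
with ties broken by target id ascending; a candidate is reported iff its
rank is ≤ 10 and its confidence is strictly greater than 0.7. Drugs with no
training interaction are skipped (cold-start predictions are undefined for
this model). Model checkpoints store U, V, the config, and a fingerprint
(dimensions + entry hash) of the training matrix; predictions against a
different matrix are refused.

Held-out evaluation reports ROC AUC of held-out positives vs sampled
negatives and the hit rate at top-10. In masking experiments the held-out
positives are excluded from negative sampling
(`train_pmf(..., exclude_from_negatives=...)`): a masked entry is missing,
not an observed zero. On noise-free rank-5 synthetic data at the package's
evaluation scale (80 × 60, density 0.10, 10% of positives masked), held-out
AUC is typically 0.88–0.97 across seeds (mean ≈ 0.92); the Bayes-optimal
ranking given the generating probabilities reaches ≈ 0.99, so a gap of a
few points is inherent to the squared-loss implicit-feedback fit at this
sample size, not an optimization failure.

## Similarity and clustering

Cosine distance 1 − (u·v)/(|u||v|) is applied to binary target vectors
(drug rows) and ligand vectors (target columns). Zero vectors are a domain
error rather than silently distance 1 — the curation rule that every study
drug has ≥ 1 target guarantees they cannot occur in a valid study. Tanimoto
distance 1 − |a∩b|/|a∪b| applies to fingerprint on-bit sets; two empty
fingerprints are a domain error. Fingerprints are consumed as precomputed
bit vectors so the core builds without a cheminformatics dependency; any
2048-bit circular fingerprint generator can feed the same interface.

Dendrograms are built by hand-rolled agglomerative clustering
(Lance–Williams updates; single, complete, and average linkage, default
average/UPGMA — the common default for profile similarity, and the figures
such trees produce are balanced). Among pairs at the minimal current
distance, the pair whose sorted leaf-label tuples compare lexicographically
smallest merges first, making merge order fully deterministic even on
degenerate (all-equal) distance data; scipy's linkage does not expose such
a tie-break, which is why the step is implemented here (it is cross-checked
against scipy on tie-free inputs in the test suite). Trees export to Newick
with branch lengths equal to merge-height differences, and a cut-at-k
utility returns partitions (clusters are split in reverse merge order).
Partition agreement uses the adjusted Rand index.

## Pathway enrichment

The universe M is the union of all pathway member sets. The draw size m
counts only identified targets inside that universe (the hypergeometric urn
is defined over the universe); targets outside every pathway are logged and
excluded, with `count_unmapped_in_m=True` available for the alternative
reading. The upper tail P(X ≥ k₀) is computed through the log-space
survival function of the hypergeometric distribution, exact to floating
precision (the test oracle enumerates draws with rational arithmetic).

Benjamini–Hochberg adjustment is the standard step-up: with p-values sorted
ascending, adjusted value at rank i = min over k ≥ i of min(p₍ₖ₎·n/k, 1),
mapped back to input order. A literal variant that divides by the outer
rank i instead of k (`method="printed"`) is kept behind a switch for
comparison; it lacks the step-up envelope and is not the default because
the procedure intended is Benjamini–Hochberg. Pathways with zero overlap
are excluded from the BH family by default (only mapped pathways are
listed), which changes the family size; `include_zero_overlap=True` keeps
them at p = 1. Significance is strict: adjusted p < α (default 0.05).

Category labels (NT = synaptic neurotransmission, SG = signal transduction,
ANS = autonomic-nervous-system innervation, NP = neuroplasticity,
DS = disease-associated, plus `other`) are an input annotation carried in
the GMT description field, never computed. Pathways labelled `other` do not
enter the five-way Venn analysis; targets confined to them still receive
profiles with an `in_other` flag, and the 31 subset counts partition the
profiles that touch at least one of the five categories.

## Synthetic studies

The generator produces the study conditions every stage is tested under.

*Interactions.* Drug and target factors are standard normal (D = rank);
the interaction probability is sigmoid(gain · uᵢ·vⱼ/√D + b) with the
intercept b calibrated by bisection so the expected density matches the
request (the realized Bernoulli density is checked to ±20% relative before
any post-processing). Entries are Bernoulli draws, optionally flipped with
probability `noise`; any empty drug row receives one forced entry at its
highest-probability target, mirroring the inclusion criterion that every
study drug has a known target. The default gain of 8 makes probabilities
nearly saturated, so `noise=0` data is genuinely noise-free (at gain 1 the
Bernoulli sampling itself dominates: the Bayes-optimal held-out AUC is only
≈ 0.66, and no recovery method could meet the package's evaluation bar).
When drug categories are supplied, drug factors are drawn around
per-category templates placed at the vertices of a regular simplex in
latent space (deterministic and maximally spread — random templates
frequently collide when categories outnumber latent dimensions) with
mixing weight `category_strength`.

*Pathways.* Background pathways sample members uniformly from the universe;
planted pathways multiply the odds of each identified target by
`enrichment_factor`. Categories cycle through NT/SG/ANS/NP/DS. The
`study_like` universe appends 350 background proteins to the 150 simulated
targets so that identified targets are a small fraction of the universe, as
they are against a genome-scale pathway database; without this the planting
signal is diluted to near-invisibility.

*Fingerprints.* Each category owns a template (~15% of bits); drugs keep
template bits with probability `category_signal` and add background bits at
rate 0.1. The study_like default signal is 0.2 — weak on purpose, because
functional categories of abused drugs do not imply structural similarity,
and the structure-vs-interaction clustering comparison is meant to show
exactly that contrast.

*Profiles.* `study_like`: 50 drugs (six categories) × 150 targets, rank 5,
density 0.06 (≈ 9 interactions/drug, matching the curated study's ≈ 8.9),
noise 0, category_strength 0.95, 50 pathways sized 20–80 with 3 planted at
factor 10, 10% held-out split. `pmf_recovery`: 80 × 60, density 0.10, no
category structure — the factor-recovery evaluation scale. All generators
are pure functions of (parameters, seed); written studies round-trip
bit-identically through the package's own readers. Problem sizes throughout
(and in the analysis scripts) are chosen so the full suite and the
acceptance script each run in well under a minute.

What the generator does **not** emulate: real chemistry (no valid SMILES,
no fingerprint–structure consistency), identifier namespaces, correlated
evidence channels, pathway topology or overlap structure beyond random
membership, and database-scale sparsity (hundreds of thousands of
chemicals). Passing tests therefore demonstrate correctness of the
algorithms under a low-rank generative model and calibrated nulls — not
that the predictions would validate against a live database snapshot.

## Null calibration of enrichment p-values

Hypergeometric p-values are discrete, so their null distribution is only
uniform "up to discreteness": P(P ≤ t) ≤ t with equality at achievable
points. Two consequences shape the calibration experiment. First, a
two-sided KS test of raw discrete p-values against the continuous uniform
rejects for any correct implementation once the sample is large (the
largest atom carries ≈ 0.2 mass at the experiment's scale). The experiment
therefore applies the standard randomized probability-integral transform
p′ = P(X > k₀) + u·P(X = k₀), which is exactly Uniform(0,1) under the null,
and KS-tests p′; the raw p-values are additionally checked one-sided
(empirical CDF never above the uniform's). Second, p-values of different
pathways within one replicate share the identified-target draw and are
correlated, which inflates the KS statistic regardless of calibration; the
experiment records one fixed pathway's p-value per replicate (200
independent replicates). Zero-overlap pathways are included here, since
excluding them conditions the null.

## Error handling and exit codes

Domain errors (zero vectors, invalid hypergeometric bounds, empty target
lists) are distinct from validation errors (malformed input) and
configuration errors (unknown dialects, profiles, parameters). The CLI maps
these to exit codes 3, 2, and 2 respectively, with 4 for missing files and
0 on success. Pipeline stages run in a fixed order, each writing its
artifact before the next begins; a failure aborts with the stage name.

## Known limitations

- The PMF model offers point estimates only — no posterior over factors,
  no uncertainty on confidence scores.
- The 0.7/top-10 selection rule and the 0.4 evidence threshold are study
  conventions, not optimized quantities; both are exposed as parameters.
- Cold-start drugs (no known interaction) cannot be scored.
- Pathway enrichment is membership-based; pathway topology is ignored.
- The cut-at-k utility assumes monotone merge heights, which holds for the
  supported linkages but not for (unimplemented) centroid-style linkages.
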