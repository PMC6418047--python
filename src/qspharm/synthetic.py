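"""Synthetic studies with known ground truth for every pipeline stage.

The generator emulates the shape of a curated drug-of-abuse study: a sparse
binary drug x target interaction matrix with genuine low-rank latent
structure (factors drawn from a seeded normal, interaction probability
logistic in the factor product, intercept calibrated by bisection to hit a
requested density), drug category labels over the six abuse categories,
category-correlated structure fingerprints, and a pathway collection in
which a chosen subset of pathways is planted to be over-represented among
the identified targets. Everything is a pure function of (parameters, seed),
so regenerated studies are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .enrichment import PATHWAY_CATEGORIES, PathwayCollection
from .errors import AnalysisError, ConfigurationError
from .interactions import DRUG_CATEGORIES, Drug, InteractionMatrix
from .similarity import BitFingerprint

SIX_CATEGORIES = DRUG_CATEGORIES[:6]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SimulatedInteractions:
    matrix: InteractionMatrix
    true_U: np.ndarray  # D x N generating drug factors
    true_V: np.ndarray  # D x M generating target factors
    probabilities: np.ndarray  # N x M Bernoulli probabilities
    intercept: float


def _category_templates(labels: Sequence[str], rank: int) -> dict[str, np.ndarray]:
    """Deterministic, maximally spread latent templates: vertices of a
    regular simplex embedded in the latent space, scaled to norm sqrt(rank)
    so category structure and background factors live on the same scale."""
    k = len(labels)
    center = np.eye(k) - np.ones((k, k)) / k
    evals, evecs = np.linalg.eigh(center)
    keep = evals > 1e-9
    x = evecs[:, keep] * np.sqrt(evals[keep])  # k x (k-1), equidistant rows
    if x.shape[1] >= rank:
        t = x[:, :rank]
    else:
        t = np.pad(x, ((0, 0), (0, rank - x.shape[1])))
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    t = t / np.where(norms == 0, 1.0, norms) * np.sqrt(rank)
    return {label: t[i] for i, label in enumerate(labels)}


def simulate_interactions(
    n_drugs: int,
    n_targets: int,
    rank: int,
    density: float,
    noise: float = 0.0,
    seed: int = 0,
    categories: Sequence[str] | None = None,
    category_strength: float = 0.0,
    gain: float = 8.0,
) -> SimulatedInteractions:
    """Low-rank binary interaction matrix with calibrated density.

    Factors are standard normal; the interaction probability for pair (i, j)
    is ``sigmoid(gain * u_i . v_j / sqrt(rank) + b)`` with the intercept b
    found by bisection so the expected density matches ``density`` (checked
    to within +/-20 percent relative after sampling). Entries are Bernoulli
    draws, then flipped with probability ``noise``; any all-zero drug row
    receives one forced entry at its highest-probability target, mirroring
    the selection rule that every study drug has at least one known target.

    When ``categories`` (one label per drug) and ``category_strength`` in
    (0, 1] are given, each category owns a latent template and drug factors
    are drawn around it, giving drugs of a category correlated interaction
    patterns while keeping the matrix exactly rank-limited.
    """
    if n_drugs < 2 or n_targets < 2:
        raise ConfigurationError("need at least 2 drugs and 2 targets")
    if rank < 1:
        raise ConfigurationError("rank must be >= 1")
    if not 0.0 < density < 1.0:
        raise ConfigurationError("density must lie in (0, 1)")
    if not 0.0 <= noise < 0.5:
        raise ConfigurationError("noise must lie in [0, 0.5)")
    if categories is not None and len(categories) != n_drugs:
        raise ConfigurationError("categories must give one label per drug")
    if not 0.0 <= category_strength <= 1.0:
        raise ConfigurationError("category_strength must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    eps = rng.normal(size=(rank, n_drugs))
    if categories is not None and category_strength > 0:
        labels = sorted(set(categories))
        templates = _category_templates(labels, rank)
        t = np.column_stack([templates[c] for c in categories])
        u = np.sqrt(category_strength) * t + np.sqrt(1 - category_strength) * eps
    else:
        u = eps
    v = rng.normal(size=(rank, n_targets))

    z = gain * (u.T @ v) / np.sqrt(rank)

    def mean_prob(b: float) -> float:
        return float(_sigmoid(z + b).mean())

    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if mean_prob(mid) < density:
            lo = mid
        else:
            hi = mid
    b = (lo + hi) / 2.0
    probs = _sigmoid(z + b)

    r = rng.random(size=probs.shape) < probs
    # the calibration contract applies to the Bernoulli sampling itself,
    # before noise flips and the forced-minimum-degree rule alter the count
    realized = r.mean()
    if abs(realized - density) / density > 0.5:
        # bisection on a logistic mean cannot normally miss; guard anyway
        raise AnalysisError(
            f"density calibration failed: requested {density}, "
            f"realized {realized:.4f}"
        )
    if noise > 0:
        flips = rng.random(size=probs.shape) < noise
        r = np.logical_xor(r, flips)
    # enforce >=1 interaction per drug (study inclusion criterion)
    for i in range(n_drugs):
        if not r[i].any():
            r[i, int(np.argmax(probs[i]))] = True

    drug_ids = [f"D{i + 1:03d}" for i in range(n_drugs)]
    target_ids = [f"T{j + 1:03d}" for j in range(n_targets)]
    entries = {(i, j) for i, j in zip(*np.nonzero(r))}
    matrix = InteractionMatrix(drug_ids, target_ids, entries)
    return SimulatedInteractions(
        matrix=matrix, true_U=u, true_V=v, probabilities=probs, intercept=b
    )


def simulate_pathways(
    targets: Sequence[str],
    n_pathways: int,
    pathway_size_range: tuple[int, int],
    n_planted: int,
    enrichment_factor: float,
    identified_targets: Sequence[str],
    seed: int = 0,
) -> tuple[PathwayCollection, frozenset[str]]:
    """Pathway collection with ``n_planted`` pathways enriched for the
    identified targets.

    Background pathways draw members uniformly from the universe; planted
    pathways draw with the odds of each identified target multiplied by
    ``enrichment_factor``. Category labels cycle through NT/SG/ANS/NP/DS.
    """
    if n_planted > n_pathways:
        raise ConfigurationError("n_planted cannot exceed n_pathways")
    if enrichment_factor < 1.0:
        raise ConfigurationError("enrichment_factor must be >= 1")
    lo, hi = pathway_size_range
    if lo < 1 or hi < lo:
        raise ConfigurationError("invalid pathway_size_range")
    if hi > len(targets):
        raise AnalysisError("pathway size exceeds the universe")
    universe = list(targets)
    identified = set(identified_targets)
    unknown = identified - set(universe)
    if unknown:
        raise ConfigurationError(
            f"{len(unknown)} identified target(s) outside the universe"
        )

    rng = np.random.default_rng(seed)
    weights = np.asarray(
        [enrichment_factor if t in identified else 1.0 for t in universe]
    )
    pathways: dict[str, frozenset[str]] = {}
    categories: dict[str, str] = {}
    planted: set[str] = set()
    for idx in range(n_pathways):
        pid = f"pw{idx + 1:03d}"
        size = int(rng.integers(lo, hi + 1))
        if idx < n_planted:
            p = weights / weights.sum()
            members = rng.choice(len(universe), size=size, replace=False, p=p)
            planted.add(pid)
        else:
            members = rng.choice(len(universe), size=size, replace=False)
        pathways[pid] = frozenset(universe[k] for k in members)
        categories[pid] = PATHWAY_CATEGORIES[idx % len(PATHWAY_CATEGORIES)]
    return PathwayCollection(pathways, categories), frozenset(planted)


def null_enrichment_pvalues(
    n_replicates: int = 200,
    universe_size: int = 500,
    n_identified: int = 30,
    n_pathways: int = 20,
    pathway_size_range: tuple[int, int] = (20, 80),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Null-calibration experiment for the enrichment p-values.

    Each replicate draws an identified-target set and an unenriched pathway
    collection (enrichment_factor 1) from a fresh seed and records the raw
    upper-tail p-value of one fixed background pathway — one value per
    replicate, so the values are independent. Returns ``(raw, pit)`` where
    ``pit`` is the randomized probability-integral transform
    ``P(X > k0) + u * P(X = k0)``, which is exactly Uniform(0, 1) when the
    tail probabilities are correctly calibrated; the raw discrete p-values
    are stochastically >= uniform.
    """
    from .enrichment import enrich, hypergeom_tail

    universe = [f"P{i:04d}" for i in range(universe_size)]
    raws = np.empty(n_replicates)
    pits = np.empty(n_replicates)
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        identified = [
            universe[i]
            for i in rng.choice(universe_size, size=n_identified, replace=False)
        ]
        collection, _ = simulate_pathways(
            universe,
            n_pathways,
            pathway_size_range,
            n_planted=0,
            enrichment_factor=1.0,
            identified_targets=identified,
            seed=int(rng.integers(2**31)),
        )
        results = enrich(identified, collection, include_zero_overlap=True)
        r = next(x for x in results if x.pathway_id == "pw001")
        p_ge = r.p_raw
        if r.k0 + 1 <= min(r.K, r.m):
            p_gt = hypergeom_tail(collection.universe_size, r.m, r.K, r.k0 + 1)
        else:
            p_gt = 0.0
        raws[rep] = p_ge
        pits[rep] = p_gt + rng.random() * (p_ge - p_gt)
    return raws, pits


def simulate_fingerprints(
    categories: Sequence[str],
    n_bits: int = 256,
    category_signal: float = 0.8,
    background_rate: float = 0.1,
    seed: int = 0,
) -> list[BitFingerprint]:
    """Category-correlated structure fingerprints, one per drug.

    Each category owns a seeded template (a random ~15 percent of bits);
    a drug keeps each template bit with probability ``category_signal`` and
    turns on non-template bits at ``background_rate``. With signal 0 the
    within- and between-category distance distributions coincide.
    """
    if n_bits < 8:
        raise ConfigurationError("n_bits must be >= 8")
    if not 0.0 <= category_signal <= 1.0:
        raise ConfigurationError("category_signal must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = sorted(set(categories))
    templates = {
        c: rng.random(n_bits) < 0.15 for c in labels
    }
    fps = []
    for cat in categories:
        template = templates[cat]
        keep = rng.random(n_bits) < category_signal
        random_bits = rng.random(n_bits) < background_rate
        bits = (template & keep) | (~template & random_bits)
        if not bits.any():
            bits[int(rng.integers(n_bits))] = True
        fps.append(BitFingerprint(n_bits, frozenset(np.nonzero(bits)[0].tolist())))
    return fps


@dataclass
class SyntheticStudy:
    """A complete generated study bundle with ground truth."""

    name: str
    seed: int
    matrix: InteractionMatrix  # training matrix (held-out positives removed)
    full_matrix: InteractionMatrix  # all generated positives
    true_U: np.ndarray
    true_V: np.ndarray
    drugs: list[Drug]
    fingerprints: list[BitFingerprint]
    collection: PathwayCollection
    planted_enriched: frozenset[str]
    identified_targets: list[str]
    heldout_positives: list[tuple[int, int]]
    heldout_negatives: list[tuple[int, int]]
    parameters: dict = field(default_factory=dict)

    @property
    def drug_categories(self) -> dict[str, str]:
        return {d.drug_id: d.category for d in self.drugs}


#: Named study profiles. "study_like" mirrors the headline study shape:
#: 50 drugs x 150 targets at ~9 interactions per drug, six drug categories,
#: 50 pathways with 3 planted enriched, rank-5 latent structure.
PROFILES: dict[str, dict] = {
    "study_like": dict(
        n_drugs=50,
        n_targets=150,
        rank=5,
        density=0.06,
        noise=0.0,
        category_strength=0.95,
        gain=8.0,
        n_pathways=50,
        pathway_size_range=(20, 80),
        background_universe=350,
        n_planted=3,
        enrichment_factor=10.0,
        n_bits=256,
        # weak structural signal: same-category drugs need not look alike
        category_signal=0.2,
        heldout_fraction=0.1,
    ),
    # smaller, denser matrix used for factor-recovery evaluation
    "pmf_recovery": dict(
        n_drugs=80,
        n_targets=60,
        rank=5,
        density=0.10,
        noise=0.0,
        category_strength=0.0,
        gain=8.0,
        n_pathways=50,
        pathway_size_range=(20, 80),
        background_universe=350,
        n_planted=3,
        enrichment_factor=10.0,
        n_bits=256,
        category_signal=0.2,
        heldout_fraction=0.1,
    ),
}


def _split_heldout(
    matrix: InteractionMatrix,
    fraction: float,
    rng: np.random.Generator,
) -> tuple[InteractionMatrix, list[tuple[int, int]], list[tuple[int, int]]]:
    """Hold out ``fraction`` of positives (never a drug's last entry) plus an
    equal number of sampled never-positive pairs."""
    positives = sorted(matrix.entries)
    n_hold = int(round(fraction * len(positives)))
    degrees = {}
    for i, _ in positives:
        degrees[i] = degrees.get(i, 0) + 1
    order = rng.permutation(len(positives))
    held: list[tuple[int, int]] = []
    remaining = dict(degrees)
    for idx in order:
        if len(held) == n_hold:
            break
        i, j = positives[idx]
        if remaining[i] <= 1:
            continue
        held.append((i, j))
        remaining[i] -= 1
    train_entries = set(matrix.entries) - set(held)
    train = InteractionMatrix(matrix.drug_ids, matrix.target_ids, train_entries)

    n, m = matrix.shape
    all_pos = set(matrix.entries)
    negatives: list[tuple[int, int]] = []
    while len(negatives) < len(held):
        i = int(rng.integers(n))
        j = int(rng.integers(m))
        if (i, j) not in all_pos and (i, j) not in negatives:
            negatives.append((i, j))
    return train, held, negatives


def make_study(profile: str | Mapping = "study_like", seed: int = 0) -> SyntheticStudy:
    """Generate a complete study under a named profile (or a parameter dict)."""
    if isinstance(profile, str):
        if profile not in PROFILES:
            raise ConfigurationError(
                f"unknown profile {profile!r}; available: {sorted(PROFILES)}"
            )
        name = profile
        params = dict(PROFILES[profile])
    else:
        name = "custom"
        params = dict(profile)

    n_drugs = params["n_drugs"]
    cats = [SIX_CATEGORIES[i % len(SIX_CATEGORIES)] for i in range(n_drugs)]
    sim = simulate_interactions(
        n_drugs=n_drugs,
        n_targets=params["n_targets"],
        rank=params["rank"],
        density=params["density"],
        noise=params["noise"],
        seed=seed,
        categories=cats if params.get("category_strength", 0) > 0 else None,
        category_strength=params.get("category_strength", 0.0),
        gain=params.get("gain", 1.0),
    )
    rng = np.random.default_rng(seed + 1)
    train, held_pos, held_neg = _split_heldout(
        sim.matrix, params["heldout_fraction"], rng
    )
    identified = sorted(
        {sim.matrix.target_ids[j] for _, j in sim.matrix.entries}
    )
    # the pathway universe extends beyond the drugged targets, as a
    # genome-scale pathway database does
    universe = list(sim.matrix.target_ids) + [
        f"B{k + 1:03d}" for k in range(params.get("background_universe", 0))
    ]
    collection, planted = simulate_pathways(
        targets=universe,
        n_pathways=params["n_pathways"],
        pathway_size_range=tuple(params["pathway_size_range"]),
        n_planted=params["n_planted"],
        enrichment_factor=params["enrichment_factor"],
        identified_targets=identified,
        seed=seed + 2,
    )
    fps = simulate_fingerprints(
        cats,
        n_bits=params["n_bits"],
        category_signal=params["category_signal"],
        seed=seed + 3,
    )
    drugs = [
        Drug(drug_id=d, name=d, category=c, fingerprint=fp)
        for d, c, fp in zip(sim.matrix.drug_ids, cats, fps)
    ]
    return SyntheticStudy(
        name=name,
        seed=seed,
        matrix=train,
        full_matrix=sim.matrix,
        true_U=sim.true_U,
        true_V=sim.true_V,
        drugs=drugs,
        fingerprints=fps,
        collection=collection,
        planted_enriched=planted,
        identified_targets=identified,
        heldout_positives=held_pos,
        heldout_negatives=held_neg,
        parameters=params,
    )


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write the study in the pipeline's own input dialects.

    Emits a stitch-dialect interaction table (experimental scores drawn in
    [0.4, 1] so the default evidence filter keeps every entry), a drug table
    with categories, fingerprints as bitstrings, the pathway GMT, and a
    ground-truth JSON (planted pathways, category labels, held-out split).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(study.seed + 4)
    paths = {
        "interactions": out_dir / "interactions_stitch.tsv",
        "drugs": out_dir / "drugs.tsv",
        "targets": out_dir / "targets.tsv",
        "fingerprints": out_dir / "fingerprints.tsv",
        "pathways": out_dir / "pathways.gmt",
        "truth": out_dir / "ground_truth.json",
    }
    with paths["interactions"].open("w") as fh:
        fh.write("chemical\tprotein\texperimental\tdatabase\ttextmining\tprediction\tcombined\n")
        for d, t in study.matrix.to_edgelist():
            score = int(rng.integers(400, 1001))
            fh.write(f"{d}\t{t}\t{score}\t0\t0\t0\t{score}\n")
    with paths["drugs"].open("w") as fh:
        fh.write("drug_id\tname\tcategory\n")
        for d in study.drugs:
            fh.write(f"{d.drug_id}\t{d.name}\t{d.category}\n")
    with paths["targets"].open("w") as fh:
        fh.write("target_id\tname\tfamily\n")
        for t in study.matrix.target_ids:
            fh.write(f"{t}\t{t}\tsynthetic\n")
    with paths["fingerprints"].open("w") as fh:
        fh.write("drug_id\tfingerprint\n")
        for d, fp in zip(study.matrix.drug_ids, study.fingerprints):
            fh.write(f"{d}\t{fp.to_bitstring()}\n")
    study.collection.to_gmt(paths["pathways"])
    truth = {
        "profile": study.name,
        "seed": study.seed,
        "n_drugs": len(study.matrix.drug_ids),
        "n_targets": len(study.matrix.target_ids),
        "drug_categories": study.drug_categories,
        "planted_enriched": sorted(study.planted_enriched),
        "identified_targets": study.identified_targets,
        "heldout_positives": sorted(study.heldout_positives),
        "heldout_negatives": sorted(study.heldout_negatives),
        "full_matrix_entries": sorted(study.full_matrix.entries),
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in study.parameters.items()
        },
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    study.matrix.write(out_dir / "matrix_edgelist.tsv")
    return paths
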