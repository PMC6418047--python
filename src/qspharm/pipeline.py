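"""End-to-end orchestration: parse -> filter -> matrix -> PMF -> predict ->
similarity/cluster -> enrichment -> category analysis.

A :class:`RunConfig` bundles input paths and the thresholds of the analysis
(evidence cutoff 0.4, confidence cutoff 0.7, top-10 selection, alpha 0.05 —
the study defaults). ``run_full_pipeline`` executes every stage in order,
writes each stage's artifact under the output directory, and returns a
machine-readable report of the headline tallies. Runs are deterministic for
a fixed config and seed, so reports are byte-identical across reruns.
"""

from __future__ import annotations

import configparser
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from . import categories as cat
from . import enrichment as enr
from . import interactions as ia
from . import pmf as pmf_mod
from . import similarity as sim
from .errors import AnalysisError, ConfigurationError, InputOutputError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, thresholds and output location for one pipeline run."""

    interactions_drugbank: Path | None = None
    interactions_stitch: Path | None = None
    pathways: Path | None = None
    drugs: Path | None = None
    fingerprints: Path | None = None
    out_dir: Path = Path("results/run")
    min_experimental: float = 0.4
    top_k: int = 10
    min_conf: float = 0.7
    alpha: float = 0.05
    linkage: str = "average"
    cut_k: int = 6
    seed: int = 0
    pmf: pmf_mod.PMFConfig = field(default_factory=pmf_mod.PMFConfig)

    def __post_init__(self) -> None:
        for name in ("interactions_drugbank", "interactions_stitch", "pathways",
                     "drugs", "fingerprints"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        self.out_dir = Path(self.out_dir)

    def validate(self) -> None:
        if self.interactions_drugbank is None and self.interactions_stitch is None:
            raise ConfigurationError("at least one interaction table is required")
        for name in ("interactions_drugbank", "interactions_stitch", "pathways",
                     "drugs", "fingerprints"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise InputOutputError(f"{name} path does not exist: {value}")
        if not (0 <= self.min_experimental <= 1):
            raise ConfigurationError("min_experimental must lie in [0, 1]")
        if not (0 <= self.min_conf <= 1):
            raise ConfigurationError("min_conf must lie in [0, 1]")
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.linkage not in sim.LINKAGES:
            raise ConfigurationError(f"unknown linkage {self.linkage!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a flat INI-style config with [inputs], [analysis], [pmf],
        [output] sections; missing keys keep their defaults."""
        parser = configparser.ConfigParser()
        read = parser.read(path)
        if not read:
            raise InputOutputError(f"config file not found: {path}")
        kwargs: dict = {}
        inputs = parser["inputs"] if parser.has_section("inputs") else {}
        for key in ("interactions_drugbank", "interactions_stitch", "pathways",
                    "drugs", "fingerprints"):
            if key in inputs:
                kwargs[key] = Path(inputs[key])
        analysis = parser["analysis"] if parser.has_section("analysis") else {}
        for key, cast in (
            ("min_experimental", float), ("top_k", int), ("min_conf", float),
            ("alpha", float), ("linkage", str), ("cut_k", int), ("seed", int),
        ):
            if key in analysis:
                kwargs[key] = cast(analysis[key])
        if parser.has_section("pmf"):
            pmf_kwargs: dict = {}
            casts = {
                "n_factors": int, "reg_u": float, "reg_v": float,
                "learn_rate": float, "epochs": int, "tol": float,
                "neg_ratio": float, "seed": int, "score_map": str,
                "optimizer": str, "init_scale": float,
            }
            for key, value in parser["pmf"].items():
                if key not in casts:
                    raise ConfigurationError(f"unknown pmf option {key!r}")
                pmf_kwargs[key] = casts[key](value)
            kwargs["pmf"] = pmf_mod.PMFConfig(**pmf_kwargs)
        if parser.has_section("output") and "out_dir" in parser["output"]:
            kwargs["out_dir"] = Path(parser["output"]["out_dir"])
        return cls(**kwargs)


def _read_drug_table(path: Path) -> dict[str, ia.Drug]:
    drugs = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            drug_id = fields[idx["drug_id"]]
            drugs[drug_id] = ia.Drug(
                drug_id=drug_id,
                name=fields[idx["name"]] if "name" in idx else drug_id,
                category=fields[idx["category"]] if "category" in idx else "other",
            )
    return drugs


def _read_fingerprints(path: Path) -> dict[str, sim.BitFingerprint]:
    fps = {}
    with path.open() as fh:
        fh.readline()
        for line in fh:
            drug_id, bits = line.rstrip("\n").split("\t")
            fps[drug_id] = sim.BitFingerprint.from_bitstring(bits)
    return fps


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the aggregated report dictionary."""
    config.validate()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    stage = "parse"
    try:
        records: list[ia.InteractionRecord] = []
        if config.interactions_drugbank is not None:
            records += ia.parse_interaction_table(
                config.interactions_drugbank, "drugbank"
            )
        if config.interactions_stitch is not None:
            records += ia.parse_interaction_table(config.interactions_stitch, "stitch")

        stage = "filter"
        kept = ia.filter_by_evidence(records, config.min_experimental)
        if not kept:
            raise AnalysisError("no interaction records survive the evidence filter")

        stage = "matrix"
        drug_ids = sorted({r.drug_id for r in kept})
        target_ids = sorted({r.target_id for r in kept})
        matrix, dropped = ia.build_matrix(kept, drug_ids, target_ids)
        matrix.write(out / "matrix_edgelist.tsv")
        summary = ia.promiscuity_summary(matrix)
        ia.write_degree_summary(summary, out / "degrees.tsv")

        stage = "pmf"
        pmf_config = replace(config.pmf, seed=config.seed)
        model = pmf_mod.train_pmf(matrix, pmf_config)
        model.save(out / "pmf_model.json")

        stage = "predict"
        predictions = pmf_mod.select_novel_predictions(
            model, matrix, top_k=config.top_k, min_conf=config.min_conf
        )
        pmf_mod.write_predictions_tsv(predictions, out / "predictions.tsv")

        stage = "similarity"
        drug_labels, dvecs = sim.target_vectors(matrix)
        drug_dm = sim.pairwise_distances(list(dvecs), "cosine", labels=drug_labels)
        drug_dm.write_tsv(out / "drug_distances.tsv")
        drug_tree = sim.hierarchical_cluster(drug_dm, config.linkage)
        (out / "drug_tree.nwk").write_text(drug_tree.to_newick() + "\n")

        target_labels, tvecs = sim.ligand_vectors(matrix)
        target_dm = sim.pairwise_distances(list(tvecs), "cosine", labels=target_labels)
        target_dm.write_tsv(out / "target_distances.tsv")
        target_tree = sim.hierarchical_cluster(target_dm, config.linkage)
        (out / "target_tree.nwk").write_text(target_tree.to_newick() + "\n")

        structure_clustered = False
        if config.fingerprints is not None:
            fps = _read_fingerprints(config.fingerprints)
            fp_labels = [d for d in drug_labels if d in fps]
            if len(fp_labels) >= 2:
                fp_dm = sim.pairwise_distances(
                    [fps[d] for d in fp_labels], "tanimoto", labels=fp_labels
                )
                fp_dm.write_tsv(out / "structure_distances.tsv")
                fp_tree = sim.hierarchical_cluster(fp_dm, config.linkage)
                (out / "structure_tree.nwk").write_text(fp_tree.to_newick() + "\n")
                structure_clustered = True

        stage = "enrich"
        known_targets = sorted(t for t, deg in matrix.target_degrees().items() if deg)
        predicted_targets = sorted({p.target_id for p in predictions})
        all_targets = sorted(set(known_targets) | set(predicted_targets))
        enriched_known: list[enr.EnrichmentResult] = []
        enriched_all: list[enr.EnrichmentResult] = []
        if config.pathways is not None:
            collection = enr.PathwayCollection.from_gmt(config.pathways)
            enriched_known = enr.enrich(known_targets, collection)
            enriched_all = enr.enrich(all_targets, collection)
            enr.write_results_tsv(enriched_known, out / "enrichment_known.tsv")
            enr.write_results_tsv(enriched_all, out / "enrichment_all.tsv")

        stage = "categories"
        report_categories: dict = {}
        if config.pathways is not None:
            provenance = {t: "known" for t in known_targets}
            provenance.update(
                {t: "predicted" for t in predicted_targets if t not in provenance}
            )
            profiles = cat.build_profiles(all_targets, collection, provenance)
            cat.write_profiles_tsv(profiles, out / "category_profiles.tsv")
            counts = cat.overlap_counts(profiles)
            cat.write_overlap_json(counts, out / "category_overlaps.json")
            pleio = cat.pleiotropic(profiles)
            sig_all = enr.significant(enriched_all, config.alpha)
            per_category: dict[str, int] = {}
            for r in sig_all:
                per_category[r.category] = per_category.get(r.category, 0) + 1
            report_categories = {
                "n_profiled_targets": len(profiles),
                "n_pleiotropic_targets": len(pleio),
                "pleiotropic_targets": [p.target_id for p in pleio],
                "enriched_pathways_per_category": dict(sorted(per_category.items())),
                "n_significant_pathways": len(sig_all),
            }

        stage = "report"
        report = {
            "config": {
                "min_experimental": config.min_experimental,
                "top_k": config.top_k,
                "min_conf": config.min_conf,
                "alpha": config.alpha,
                "linkage": config.linkage,
                "seed": config.seed,
            },
            "records": {
                "parsed": len(records),
                "kept_after_filter": len(kept),
                "dropped_unresolvable": dropped,
            },
            "matrix": {
                "n_drugs": matrix.shape[0],
                "n_targets": matrix.shape[1],
                "n_interactions": matrix.n_entries,
                "mean_interactions_per_drug": summary.mean_per_drug_rounded,
                "mean_interactions_per_target": summary.mean_per_target_rounded,
                "n_promiscuous_drugs": len(summary.promiscuous_drugs),
            },
            "predictions": {
                "n_novel_interactions": len(predictions),
                "n_drugs_with_predictions": len({p.drug_id for p in predictions}),
                "n_predicted_targets": len(predicted_targets),
                "n_new_targets": len(
                    {p.target_id for p in predictions if p.novelty == "new_target"}
                ),
            },
            "similarity": {
                "structure_clustered": structure_clustered,
                "drug_tree_leaves": len(drug_tree.labels),
                "target_tree_leaves": len(target_tree.labels),
            },
            "enrichment": report_categories,
        }
        report_path = out / "report.json"
        report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
        return report
    except Exception as exc:
        from .errors import ValidationError

        if isinstance(exc, (ConfigurationError, InputOutputError, ValidationError)):
            raise
        raise AnalysisError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def report_as_tsv(report: dict) -> str:
    """Flatten the report into key<TAB>value lines (stable ordering)."""

    lines: list[str] = []

    def walk(prefix: str, obj) -> None:
        if isinstance(obj, dict):
            for key in sorted(obj):
                walk(f"{prefix}.{key}" if prefix else key, obj[key])
        elif isinstance(obj, list):
            lines.append(f"{prefix}\t{','.join(str(x) for x in obj)}")
        else:
            lines.append(f"{prefix}\t{obj}")

    walk("", report)
    return "\n".join(lines) + "\n"
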