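"""Drug-target interaction tables, evidence filtering, and the binary matrix.

Two tab-separated dialects are supported:

``drugbank``
    Columns ``drug_id`` and ``target_id`` (extra columns ignored). Records
    carry no evidence scores; curated interactions from this source are kept
    unconditionally by the evidence filter.

``stitch``
    Columns ``chemical``, ``protein`` and five confidence channels
    ``experimental``, ``database``, ``textmining``, ``prediction``,
    ``combined``. Raw exports score channels as integers on a 0-1000 scale
    while the analysis operates on the unit interval; when any score in a
    file exceeds 1 the whole file is rescaled by 1/1000. Only records whose
    experimental score clears a threshold (default 0.4, inclusive) survive
    the evidence filter.

The union of filtered records induces a sparse binary drug x target matrix
``R`` whose entries mark known interactions; per-drug and per-target degrees
("promiscuity") summarise the bipartite network.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from .errors import ConfigurationError, InputOutputError, ValidationError

logger = logging.getLogger(__name__)

#: Closed vocabulary of drug-of-abuse categories.
DRUG_CATEGORIES = (
    "CNS stimulant",
    "CNS depressant",
    "opioid",
    "cannabinoid",
    "anabolic steroid",
    "hallucinogen",
    "other",
)

EVIDENCE_CHANNELS = ("experimental", "database", "textmining", "prediction", "combined")

_DIALECT_COLUMNS = {
    "drugbank": ("drug_id", "target_id"),
    "stitch": ("chemical", "protein") + EVIDENCE_CHANNELS,
}


@dataclass(frozen=True)
class Drug:
    drug_id: str
    name: str = ""
    category: str = "other"
    fingerprint: "object | None" = None

    def __post_init__(self) -> None:
        if self.category not in DRUG_CATEGORIES:
            raise ValidationError(
                f"unknown drug category {self.category!r} for {self.drug_id}; "
                f"expected one of {DRUG_CATEGORIES}"
            )


@dataclass(frozen=True)
class Target:
    target_id: str
    name: str = ""
    family: str = ""


@dataclass(frozen=True)
class InteractionRecord:
    """One drug-target pair from one source, with optional evidence scores."""

    drug_id: str
    target_id: str
    source: str  # drugbank | stitch | predicted
    evidence: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for channel, score in self.evidence.items():
            if channel not in EVIDENCE_CHANNELS:
                raise ValidationError(f"unknown evidence channel {channel!r}")
            if not (0.0 <= score <= 1.0):
                raise ValidationError(
                    f"evidence score {channel}={score} outside [0, 1] for "
                    f"({self.drug_id}, {self.target_id})"
                )

    @property
    def experimental(self) -> float | None:
        return self.evidence.get("experimental")


class InteractionMatrix:
    """Sparse binary interaction matrix R over ordered drug and target ids."""

    def __init__(
        self,
        drug_ids: Sequence[str],
        target_ids: Sequence[str],
        entries: Iterable[tuple[int, int]],
    ) -> None:
        if not drug_ids or not target_ids:
            raise ConfigurationError("drug and target lists must be non-empty")
        if len(set(drug_ids)) != len(drug_ids):
            raise ValidationError("duplicate drug ids in matrix ordering")
        if len(set(target_ids)) != len(target_ids):
            raise ValidationError("duplicate target ids in matrix ordering")
        self.drug_ids = list(drug_ids)
        self.target_ids = list(target_ids)
        self.entries = frozenset((int(i), int(j)) for i, j in entries)
        n, m = self.shape
        for i, j in self.entries:
            if not (0 <= i < n and 0 <= j < m):
                raise ValidationError(f"entry ({i}, {j}) outside {n}x{m} matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.drug_ids), len(self.target_ids)

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    def to_dense(self) -> np.ndarray:
        r = np.zeros(self.shape, dtype=float)
        for i, j in self.entries:
            r[i, j] = 1.0
        return r

    def to_sparse(self) -> sparse.coo_matrix:
        if not self.entries:
            return sparse.coo_matrix(self.shape)
        rows, cols = zip(*sorted(self.entries))
        return sparse.coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=self.shape
        )

    def drug_degrees(self) -> dict[str, int]:
        deg = dict.fromkeys(self.drug_ids, 0)
        for i, _ in self.entries:
            deg[self.drug_ids[i]] += 1
        return deg

    def target_degrees(self) -> dict[str, int]:
        deg = dict.fromkeys(self.target_ids, 0)
        for _, j in self.entries:
            deg[self.target_ids[j]] += 1
        return deg

    def entry_hash(self) -> str:
        """Stable fingerprint of dimensions and edge set (checkpoint guard)."""
        payload = json.dumps(
            [self.shape, sorted(self.entries)], separators=(",", ":")
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_edgelist(self) -> list[tuple[str, str]]:
        return sorted(
            (self.drug_ids[i], self.target_ids[j]) for i, j in self.entries
        )

    def write(self, edgelist_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Write the edge list as TSV plus a JSON sidecar with the ordering."""
        edgelist_path = Path(edgelist_path)
        with edgelist_path.open("w") as fh:
            fh.write("drug_id\ttarget_id\n")
            for d, t in self.to_edgelist():
                fh.write(f"{d}\t{t}\n")
        if sidecar_path is None:
            sidecar_path = edgelist_path.with_suffix(".json")
        with Path(sidecar_path).open("w") as fh:
            json.dump(
                {
                    "n_drugs": len(self.drug_ids),
                    "n_targets": len(self.target_ids),
                    "drug_ids": self.drug_ids,
                    "target_ids": self.target_ids,
                },
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def read(cls, edgelist_path: str | Path, sidecar_path: str | Path | None = None) -> "InteractionMatrix":
        edgelist_path = Path(edgelist_path)
        if sidecar_path is None:
            sidecar_path = edgelist_path.with_suffix(".json")
        try:
            meta = json.loads(Path(sidecar_path).read_text())
        except FileNotFoundError as exc:
            raise InputOutputError(f"matrix sidecar not found: {sidecar_path}") from exc
        drug_index = {d: i for i, d in enumerate(meta["drug_ids"])}
        target_index = {t: j for j, t in enumerate(meta["target_ids"])}
        entries = []
        with edgelist_path.open() as fh:
            next(fh)  # header
            for line in fh:
                d, t = line.rstrip("\n").split("\t")
                entries.append((drug_index[d], target_index[t]))
        return cls(meta["drug_ids"], meta["target_ids"], entries)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, InteractionMatrix)
            and self.drug_ids == other.drug_ids
            and self.target_ids == other.target_ids
            and self.entries == other.entries
        )


def parse_interaction_table(path: str | Path, dialect: str) -> list[InteractionRecord]:
    """Parse a TSV interaction table in the ``drugbank`` or ``stitch`` dialect.

    Comment lines starting with ``#`` are skipped. STITCH-style integer scores
    on a 0-1000 scale are detected (any raw score > 1) and rescaled to [0, 1].
    Malformed rows raise :class:`ValidationError` naming the line number.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ConfigurationError(
            f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECT_COLUMNS)}"
        )
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"interaction table not found: {path}")

    with path.open(newline="") as fh:
        rows: list[tuple[int, dict[str, str]]] = []
        header: list[str] | None = None
        reader = csv.reader(fh, delimiter="\t")
        for lineno, raw in enumerate(reader, start=1):
            if not raw or (raw[0].startswith("#")):
                continue
            if header is None:
                header = [c.strip() for c in raw]
                missing = [c for c in _DIALECT_COLUMNS[dialect] if c not in header]
                if missing:
                    raise ValidationError(
                        f"{path}: header missing column(s) {missing} for "
                        f"dialect {dialect!r}"
                    )
                continue
            if len(raw) != len(header):
                raise ValidationError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(raw)}"
                )
            rows.append((lineno, dict(zip(header, (c.strip() for c in raw)))))

    if header is None:
        raise ValidationError(f"{path}: empty table (no header)")

    if dialect == "drugbank":
        records = [
            InteractionRecord(row["drug_id"], row["target_id"], source="drugbank")
            for _, row in rows
        ]
    else:
        parsed: list[tuple[int, str, str, dict[str, float]]] = []
        max_score = 0.0
        for lineno, row in rows:
            scores: dict[str, float] = {}
            for channel in EVIDENCE_CHANNELS:
                cell = row[channel]
                if cell == "":
                    continue
                try:
                    scores[channel] = float(cell)
                except ValueError as exc:
                    raise ValidationError(
                        f"{path}:{lineno}: non-numeric {channel} score {cell!r}"
                    ) from exc
            if scores:
                max_score = max(max_score, max(scores.values()))
            parsed.append((lineno, row["chemical"], row["protein"], scores))
        scale = 1000.0 if max_score > 1.0 else 1.0
        records = []
        for lineno, drug, target, scores in parsed:
            rescaled = {k: v / scale for k, v in scores.items()}
            bad = {k: v for k, v in rescaled.items() if not 0.0 <= v <= 1.0}
            if bad:
                raise ValidationError(
                    f"{path}:{lineno}: score(s) outside [0, 1] after rescaling: {bad}"
                )
            records.append(
                InteractionRecord(drug, target, source="stitch", evidence=rescaled)
            )

    seen: set[tuple[str, str, str]] = set()
    for rec in records:
        key = (rec.drug_id, rec.target_id, rec.source)
        if key in seen:
            raise ValidationError(f"{path}: duplicate record {key}")
        seen.add(key)
    return records


def filter_by_evidence(
    records: Iterable[InteractionRecord], min_experimental: float = 0.4
) -> list[InteractionRecord]:
    """Keep curated (drugbank) records unconditionally and stitch records with
    experimental evidence >= ``min_experimental`` (boundary inclusive)."""
    if not (0.0 <= min_experimental <= 1.0):
        raise ConfigurationError(
            f"min_experimental must lie in [0, 1], got {min_experimental}"
        )
    kept = []
    for rec in records:
        if rec.source != "stitch":
            kept.append(rec)
        elif rec.experimental is not None and rec.experimental >= min_experimental:
            kept.append(rec)
    return kept


def build_matrix(
    records: Iterable[InteractionRecord],
    drugs: Sequence[Drug | str],
    targets: Sequence[Target | str],
    strict: bool = False,
) -> tuple[InteractionMatrix, int]:
    """Build the binary matrix R; returns (matrix, n_dropped_records).

    Records naming a drug or target absent from the supplied orderings are
    dropped with a logged count (or raise in ``strict`` mode). Duplicate
    (drug, target) pairs across sources collapse to one binary entry.
    """
    drug_ids = [d.drug_id if isinstance(d, Drug) else d for d in drugs]
    target_ids = [t.target_id if isinstance(t, Target) else t for t in targets]
    if not drug_ids or not target_ids:
        raise ConfigurationError("drug and target lists must be non-empty")
    drug_index = {d: i for i, d in enumerate(drug_ids)}
    target_index = {t: j for j, t in enumerate(target_ids)}
    entries: set[tuple[int, int]] = set()
    dropped = 0
    for rec in records:
        i = drug_index.get(rec.drug_id)
        j = target_index.get(rec.target_id)
        if i is None or j is None:
            if strict:
                raise ValidationError(
                    f"unresolvable interaction ({rec.drug_id}, {rec.target_id})"
                )
            dropped += 1
            continue
        entries.add((i, j))
    if dropped:
        logger.warning("dropped %d records with unresolvable identifiers", dropped)
    return InteractionMatrix(drug_ids, target_ids, entries), dropped


@dataclass(frozen=True)
class PromiscuitySummary:
    drug_degrees: Mapping[str, int]
    target_degrees: Mapping[str, int]
    mean_per_drug: float
    mean_per_target: float
    mean_per_drug_rounded: float
    mean_per_target_rounded: float
    promiscuous_drugs: tuple[str, ...]
    threshold: int


def promiscuity_summary(
    matrix: InteractionMatrix, threshold: int = 10
) -> PromiscuitySummary:
    """Per-drug/per-target degrees and their means.

    ``promiscuous_drugs`` lists drugs hitting at least ``threshold`` targets
    (inclusive), sorted by descending degree then id. Means are reported both
    unrounded and at 1-decimal rounding.
    """
    if matrix.n_entries == 0:
        raise AnalysisErrorEmpty()
    n, m = matrix.shape
    drug_deg = matrix.drug_degrees()
    target_deg = matrix.target_degrees()
    mean_drug = matrix.n_entries / n
    mean_target = matrix.n_entries / m
    promiscuous = tuple(
        d for d, _ in sorted(drug_deg.items(), key=lambda kv: (-kv[1], kv[0]))
        if drug_deg[d] >= threshold
    )
    return PromiscuitySummary(
        drug_degrees=drug_deg,
        target_degrees=target_deg,
        mean_per_drug=mean_drug,
        mean_per_target=mean_target,
        mean_per_drug_rounded=round(mean_drug, 1),
        mean_per_target_rounded=round(mean_target, 1),
        promiscuous_drugs=promiscuous,
        threshold=threshold,
    )


class AnalysisErrorEmpty(ValidationError):
    def __init__(self) -> None:
        super().__init__("promiscuity summary requires a non-empty matrix")


def write_degree_summary(summary: PromiscuitySummary, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("kind\tid\tdegree\n")
        for d, deg in sorted(summary.drug_degrees.items()):
            fh.write(f"drug\t{d}\t{deg}\n")
        for t, deg in sorted(summary.target_degrees.items()):
            fh.write(f"target\t{t}\t{deg}\n")
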