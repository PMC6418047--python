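"""Hypergeometric pathway over-representation with Benjamini-Hochberg FDR.

For a pathway A of size K inside a universe of M proteins, and a query list
of m identified targets of which k0 fall in A, the enrichment p-value is the
upper hypergeometric tail

    P(A) = sum_{k0 <= k <= min(K, m)} C(K, k) C(M-K, m-k) / C(M, m),

i.e. the probability of drawing k0 or more pathway members by chance. Raw
p-values across the pathway family are adjusted with the Benjamini-Hochberg
step-up procedure; pathways with adjusted p below 0.05 (strict) are called
significantly enriched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import AnalysisError, InputOutputError, ValidationError

logger = logging.getLogger(__name__)

#: The five pathway categories used in the Venn/pleiotropy analysis.
PATHWAY_CATEGORIES = ("NT", "SG", "ANS", "NP", "DS")
CATEGORY_VOCAB = PATHWAY_CATEGORIES + ("other",)


@dataclass(frozen=True)
class PathwayCollection:
    """Pathway membership sets plus a category label per pathway."""

    pathways: Mapping[str, frozenset[str]]
    categories: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.pathways:
            raise ValidationError("pathway collection is empty")
        for pid, members in self.pathways.items():
            if not members:
                raise ValidationError(f"pathway {pid!r} has no members")
        for pid in self.pathways:
            if self.categories.get(pid, "other") not in CATEGORY_VOCAB:
                raise ValidationError(
                    f"pathway {pid!r} has unknown category "
                    f"{self.categories.get(pid)!r}"
                )

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.pathways.values():
            out |= members
        return frozenset(out)

    @property
    def universe_size(self) -> int:
        return len(self.universe)

    def category(self, pathway_id: str) -> str:
        return self.categories.get(pathway_id, "other")

    @classmethod
    def from_gmt(cls, path: str | Path) -> "PathwayCollection":
        """Read GMT: pathway_id <TAB> category/description <TAB> member ids.

        The description field is taken as the category when it is one of
        NT/SG/ANS/NP/DS (or contains a ``category=X`` token); otherwise the
        pathway is labelled ``other``.
        """
        path = Path(path)
        if not path.exists():
            raise InputOutputError(f"GMT file not found: {path}")
        pathways: dict[str, frozenset[str]] = {}
        categories: dict[str, str] = {}
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValidationError(
                        f"{path}:{lineno}: GMT line needs id, description and "
                        f">=1 member"
                    )
                pid, desc, *members = fields
                if pid in pathways:
                    raise ValidationError(f"{path}:{lineno}: duplicate pathway {pid!r}")
                category = "other"
                for token in desc.replace(";", " ").split():
                    if token in CATEGORY_VOCAB:
                        category = token
                    elif token.startswith("category="):
                        category = token.split("=", 1)[1]
                pathways[pid] = frozenset(m for m in members if m)
                categories[pid] = category
        return cls(pathways, categories)

    def to_gmt(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for pid in sorted(self.pathways):
                members = "\t".join(sorted(self.pathways[pid]))
                fh.write(f"{pid}\t{self.category(pid)}\t{members}\n")


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    category: str
    K: int
    k0: int
    m: int
    p_raw: float
    p_adjusted: float = float("nan")


def hypergeom_tail(M: int, m: int, K: int, k0: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k0).

    X counts pathway members among m draws without replacement from a
    universe of M proteins of which K are in the pathway. Computed via the
    log-space survival function, exact to floating precision.
    """
    if not (0 <= K <= M and 0 <= m <= M and 0 <= k0 <= min(K, m)):
        raise AnalysisError(
            f"invalid hypergeometric arguments M={M}, m={m}, K={K}, k0={k0}"
        )
    if k0 == 0:
        return 1.0
    return float(stats.hypergeom.sf(k0 - 1, M, K, m))


def bh_adjust(p_values: Sequence[float], method: str = "bh") -> list[float]:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    With p-values sorted ascending, the adjusted value at sorted rank i is
    ``min_{k >= i} min(p_(k) * n / k, 1)``. ``method='printed'`` instead uses
    the divisor i in place of k (no step-up envelope), a literal variant kept
    for comparison.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise AnalysisError("p-values must be a flat sequence")
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise AnalysisError("p-values must lie in [0, 1]")
    if method not in ("bh", "printed"):
        raise AnalysisError(f"unknown adjustment method {method!r}")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    ranks = np.arange(1, n + 1)
    if method == "bh":
        stepped = np.minimum(ranked * n / ranks, 1.0)
        adjusted_sorted = np.minimum.accumulate(stepped[::-1])[::-1]
    else:
        adjusted_sorted = np.minimum(ranked * n / ranks, 1.0)
    adjusted = np.empty(n)
    adjusted[order] = adjusted_sorted
    return [float(x) for x in adjusted]


def enrich(
    targets: Iterable[str],
    collection: PathwayCollection,
    include_zero_overlap: bool = False,
    count_unmapped_in_m: bool = False,
    method: str = "bh",
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of a target list against a pathway collection.

    By default ``m`` counts only identified targets inside the pathway
    universe (the hypergeometric urn), and pathways with zero overlap are
    excluded from the BH family; both choices can be flipped. Results are
    sorted by (p_adjusted, pathway_id).
    """
    target_set = set(targets)
    if not target_set:
        raise AnalysisError("enrichment requires a non-empty target set")
    universe = collection.universe
    mapped = target_set & universe
    unmapped = sorted(target_set - universe)
    if not mapped:
        raise AnalysisError(
            "no target maps into the pathway universe; unmapped ids: "
            + ", ".join(unmapped[:20])
        )
    if unmapped:
        logger.info(
            "%d identified target(s) outside the pathway universe", len(unmapped)
        )
    m = len(target_set) if count_unmapped_in_m else len(mapped)
    M = collection.universe_size

    results: list[EnrichmentResult] = []
    for pid in sorted(collection.pathways):
        members = collection.pathways[pid]
        K = len(members)
        k0 = len(mapped & members)
        if k0 == 0 and not include_zero_overlap:
            continue
        p_raw = hypergeom_tail(M, m, K, k0)
        results.append(
            EnrichmentResult(
                pathway_id=pid,
                category=collection.category(pid),
                K=K,
                k0=k0,
                m=m,
                p_raw=p_raw,
            )
        )
    if not results:
        return []
    adjusted = bh_adjust([r.p_raw for r in results], method=method)
    results = [replace(r, p_adjusted=adj) for r, adj in zip(results, adjusted)]
    results.sort(key=lambda r: (r.p_adjusted, r.pathway_id))
    return results


def significant(
    results: Iterable[EnrichmentResult], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Keep results with adjusted p strictly below ``alpha``, sorted."""
    kept = [r for r in results if r.p_adjusted < alpha]
    kept.sort(key=lambda r: (r.p_adjusted, r.pathway_id))
    return kept


def write_results_tsv(results: Iterable[EnrichmentResult], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("pathway_id\tcategory\tK\tk0\tm\tp_raw\tp_adjusted\n")
        for r in sorted(results, key=lambda r: (r.p_adjusted, r.pathway_id)):
            fh.write(
                f"{r.pathway_id}\t{r.category}\t{r.K}\t{r.k0}\t{r.m}\t"
                f"{r.p_raw:.6g}\t{r.p_adjusted:.6g}\n"
            )
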