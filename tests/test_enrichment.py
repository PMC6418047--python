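"""Hypergeometric tail, BH adjustment, and enrichment analysis."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from qspharm.enrichment import (
    PathwayCollection,
    bh_adjust,
    enrich,
    hypergeom_tail,
    significant,
)
from qspharm.errors import AnalysisError, ValidationError


def enumeration_tail(M: int, m: int, K: int, k0: int) -> Fraction:
    """Exact upper tail by enumerating every m-subset of the universe."""
    pathway = set(range(K))
    hits = sum(
        1
        for draw in itertools.combinations(range(M), m)
        if len(pathway.intersection(draw)) >= k0
    )
    return Fraction(hits, comb(M, m))


class TestHypergeomTail:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_tail(100, 10, 5, 0) == 1.0

    def test_pathway_equals_universe(self):
        assert hypergeom_tail(10, 3, 10, 3) == pytest.approx(1.0)

    def test_matches_full_enumeration_example(self):
        expected = enumeration_tail(20, 5, 4, 2)  # over all C(20,5)=15504 draws
        assert hypergeom_tail(20, 5, 4, 2) == pytest.approx(float(expected), abs=1e-12)

    def test_non_increasing_in_overlap(self):
        values = [hypergeom_tail(50, 10, 8, k0) for k0 in range(9)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_invalid_bounds_raise(self):
        with pytest.raises(AnalysisError):
            hypergeom_tail(10, 11, 5, 0)
        with pytest.raises(AnalysisError):
            hypergeom_tail(10, 3, 5, 4)


class TestBHAdjust:
    def test_single_value_is_identity(self):
        assert bh_adjust([0.05]) == [0.05]

    def test_hand_applied_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_equal_values_are_a_fixed_point(self):
        assert bh_adjust([0.2] * 7) == pytest.approx([0.2] * 7)

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 200))
            p = rng.random(n)
            ours = bh_adjust(list(p))
            theirs = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, theirs, atol=1e-12)

    def test_matches_direct_quadratic_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(1, 60))
            p = list(rng.random(n))
            # independent O(n^2) application of the step-up definition
            order = sorted(range(n), key=lambda i: p[i])
            expected = [None] * n
            for pos, idx in enumerate(order, start=1):
                candidates = [
                    min(p[order[k - 1]] * n / k, 1.0) for k in range(pos, n + 1)
                ]
                expected[idx] = min(candidates)
            assert np.allclose(bh_adjust(p), expected, atol=1e-12)

    def test_output_dominates_input_and_preserves_order(self):
        rng = np.random.default_rng(2)
        p = list(rng.random(100))
        adj = bh_adjust(p)
        assert all(a >= r for a, r in zip(adj, p))
        order_p = np.argsort(p, kind="stable")
        assert np.all(np.diff(np.asarray(adj)[order_p]) >= -1e-15)

    def test_printed_variant_lacks_the_envelope(self):
        p = [0.04, 0.01, 0.03]
        printed = bh_adjust(p, method="printed")
        assert printed == pytest.approx([0.04 * 3 / 3, 0.01 * 3 / 1, 0.03 * 3 / 2])

    def test_out_of_range_input_raises(self):
        with pytest.raises(AnalysisError):
            bh_adjust([0.5, 1.5])


@pytest.fixture()
def disjoint_collection() -> PathwayCollection:
    """Universe of 20 proteins in 4 disjoint pathways of 5."""
    pathways = {
        f"pw{k}": frozenset(f"P{5 * k + i}" for i in range(5)) for k in range(4)
    }
    return PathwayCollection(pathways, {f"pw{k}": "NT" for k in range(4)})


class TestEnrich:
    def test_full_pathway_hit_has_closed_form_p(self, disjoint_collection):
        results = enrich({f"P{i}" for i in range(5)}, disjoint_collection)
        (hit,) = [r for r in results if r.pathway_id == "pw0"]
        assert hit.k0 == 5
        assert hit.p_raw == pytest.approx(1 / comb(20, 5), rel=1e-9)

    def test_targets_equal_to_universe_give_p_one(self, disjoint_collection):
        results = enrich(
            {f"P{i}" for i in range(20)}, disjoint_collection, include_zero_overlap=True
        )
        assert all(r.p_raw == pytest.approx(1.0) for r in results)

    def test_unmapped_targets_raise_with_diagnostic(self, disjoint_collection):
        with pytest.raises(AnalysisError, match="XX1"):
            enrich({"XX1", "XX2"}, disjoint_collection)

    def test_invariant_to_input_ordering(self, disjoint_collection):
        t = ["P0", "P1", "P7", "P13"]
        a = enrich(t, disjoint_collection)
        b = enrich(list(reversed(t)), disjoint_collection)
        assert a == b

    def test_planted_pathways_attain_smallest_adjusted_p(self):
        from qspharm.synthetic import simulate_pathways

        universe = [f"P{i:04d}" for i in range(500)]
        rng = np.random.default_rng(42)
        identified = [universe[i] for i in rng.choice(500, 30, replace=False)]
        collection, planted = simulate_pathways(
            universe, 50, (20, 80), 3, 10.0, identified, seed=42
        )
        results = enrich(identified, collection)
        top3 = {r.pathway_id for r in results[:3]}
        assert top3 == set(planted)
        assert all(r.p_adjusted < 0.05 for r in results[:3])


class TestSignificant:
    def test_strict_alpha_boundary(self):
        results = enrich({"P0", "P1"}, PathwayCollection(
            {"pw0": frozenset({"P0", "P1"}), "pw1": frozenset({"P2", "P3"})},
            {"pw0": "NT", "pw1": "SG"},
        ), include_zero_overlap=True)
        by_id = {r.pathway_id: r for r in results}
        from dataclasses import replace

        fake = [
            replace(by_id["pw0"], p_adjusted=0.049),
            replace(by_id["pw0"], pathway_id="x", p_adjusted=0.05),
            replace(by_id["pw0"], pathway_id="y", p_adjusted=0.2),
        ]
        assert [r.p_adjusted for r in significant(fake)] == [0.049]

    def test_empty_results(self):
        assert significant([]) == []


class TestGMT:
    def test_round_trip(self, tmp_path, disjoint_collection):
        path = tmp_path / "c.gmt"
        disjoint_collection.to_gmt(path)
        again = PathwayCollection.from_gmt(path)
        assert again.pathways == dict(disjoint_collection.pathways)
        assert {p: again.category(p) for p in again.pathways} == {
            p: disjoint_collection.category(p) for p in disjoint_collection.pathways
        }

    def test_malformed_line_raises(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("pw1\tonly_description\n")
        with pytest.raises(ValidationError):
            PathwayCollection.from_gmt(path)
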