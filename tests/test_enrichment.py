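"""Enrichment score, expected overlap, permutation null and significance calls."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirsig import (UNDEFINED, EnrichmentRecord, GeneSet, PermutationConfig,
                    SignificanceRule, TargetDatabase, call_significance,
                    enrich_signature, enrichment_score, expected_count,
                    observed_overlap, permutation_pvalue)
from mirsig.enrichment import _family_scores
from mirsig.errors import ConfigurationError, ValidationError
from mirsig.synthetic import MirnaSpec, SyntheticDbSpec, simulate_target_db


class TestObservedOverlap:
    def test_partial_disjoint_and_subset(self, toy_db):
        risk = GeneSet.from_symbols("R", ["B", "C", "E"])
        assert observed_overlap(toy_db, "famX", risk) == (2, ["B", "C"])
        assert observed_overlap(toy_db, "famZ", risk) == (0, [])
        everything = GeneSet.from_symbols("R", ["A", "B", "C", "D"])
        count, _ = observed_overlap(toy_db, "famX", everything)
        assert count == toy_db.target_count("famX")

    def test_risk_outside_universe_ignored(self, toy_db):
        risk = GeneSet.from_symbols("R", ["C", "NOT_IN_DB"])
        assert observed_overlap(toy_db, "famY", risk) == (1, ["C"])

    def test_unknown_family(self, toy_db):
        with pytest.raises(KeyError):
            observed_overlap(toy_db, "famQ", GeneSet.from_symbols("R", ["A"]))


class TestExpectedCount:
    @pytest.mark.parametrize("m,K,N,expected", [
        (50, 100, 1000, 5.0), (0, 100, 1000, 0.0), (30, 20, 200, 3.0)])
    def test_formula(self, m, K, N, expected):
        assert expected_count(m, K, N) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            expected_count(10, 5, 0)
        with pytest.raises(ValidationError):
            expected_count(10, 50, 20)

    def test_equals_mean_uniform_overlap(self):
        # E[|targets ∩ risk|] under uniform size-m draws is (K/N)*m
        rng = np.random.default_rng(11)
        N, K, m, reps = 300, 60, 40, 10_000
        overlaps = np.array([
            np.count_nonzero(rng.choice(N, size=m, replace=False) < K)
            for _ in range(reps)])
        se = overlaps.std(ddof=1) / math.sqrt(reps)
        assert abs(overlaps.mean() - expected_count(m, K, N)) < 3 * se


class TestEnrichmentScore:
    def test_examples(self):
        assert enrichment_score(20, 5.0) == pytest.approx(2.0)
        assert enrichment_score(7, 7.0) == pytest.approx(0.0)
        assert enrichment_score(0, 5.0) == UNDEFINED

    def test_undefined_orders_below_everything(self):
        assert UNDEFINED < -1e12

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            enrichment_score(3, 0.0)
        with pytest.raises(ValidationError):
            enrichment_score(-1, 2.0)

    def test_gene_duplication_leaves_scores_unchanged(self, toy_db, toy_risk):
        # doubling the universe, every target set and the risk set doubles O,
        # E, K, N and m alike: every score is invariant
        def doubled(names):
            return frozenset(g for n in names for g in (n, n + "_COPY"))
        db2 = TargetDatabase(genes=doubled(toy_db.genes),
                             targets={f: doubled(t) for f, t in toy_db.targets.items()})
        risk2 = GeneSet("R", doubled(toy_risk.genes))
        assert _family_scores(db2, risk2) == pytest.approx(_family_scores(toy_db, toy_risk))


def _degenerate_db(n_fam=5):
    """Every family shares one identical target set."""
    genes = frozenset({"A", "B", "C"})
    return TargetDatabase(genes=genes,
                          targets={f"f{i}": genes for i in range(n_fam)})


class TestPermutationPvalue:
    def test_all_ties_strict_vs_conservative(self):
        db = _degenerate_db()
        risk = GeneSet.from_symbols("R", ["A", "B"])
        true = _family_scores(db, risk)["f0"]
        strict, _ = permutation_pvalue(db, risk, true,
                                       PermutationConfig(n_perm=50, draw_size=2, seed=1))
        conservative, _ = permutation_pvalue(
            db, risk, true, PermutationConfig(n_perm=50, draw_size=2, seed=1,
                                              tie_mode="greater-or-equal-plus-one"))
        assert strict == 0.0
        assert conservative == 1.0

    def test_undefined_nulls_never_count_as_higher(self):
        # the query family overlaps risk; every other family misses it entirely
        genes = frozenset({"A", "B", "C", "D"})
        db = TargetDatabase(genes=genes, targets={
            "hit": frozenset({"A", "B"}),
            "miss1": frozenset({"C"}), "miss2": frozenset({"D"}),
            "miss3": frozenset({"C", "D"})})
        risk = GeneSet.from_symbols("R", ["A", "B"])
        true = _family_scores(db, risk)["hit"]
        p, _ = permutation_pvalue(db, risk, true,
                                  PermutationConfig(n_perm=100, draw_size=2, seed=0))
        assert p == 0.0

    def test_matches_exhaustive_enumeration(self):
        fams = tuple(MirnaSpec(f"f{i}", 100 + 37 * i, (1, 1, 2, 1, 3, 1, 1, 2)[i])
                     for i in range(8))
        sim = simulate_target_db(SyntheticDbSpec(1000, 80, fams, seed=7))
        scores = _family_scores(sim.db, sim.risk)
        for query in ("f0", "f2", "f4"):
            true = scores[query]
            pooled = [scores[f] for subset in combinations(sorted(scores), 2)
                      for f in subset]
            exact = sum(s > true for s in pooled) / len(pooled)
            mc, _ = permutation_pvalue(sim.db, sim.risk, true,
                                       PermutationConfig(n_perm=4000, draw_size=2, seed=3))
            assert abs(mc - exact) < 0.02

    def test_per_replicate_pool_uses_means(self):
        db = _degenerate_db()
        risk = GeneSet.from_symbols("R", ["A"])
        cfg = PermutationConfig(n_perm=10, draw_size=3, seed=5,
                                null_pool="per-replicate")
        _, null = permutation_pvalue(db, risk, _family_scores(db, risk)["f0"], cfg)
        assert null.shape == (10,)

    def test_deterministic_given_seed(self, toy_db, toy_risk):
        cfg = PermutationConfig(n_perm=200, draw_size=2, seed=9)
        p1, null1 = permutation_pvalue(toy_db, toy_risk, 0.1, cfg)
        p2, null2 = permutation_pvalue(toy_db, toy_risk, 0.1, cfg)
        assert p1 == p2 and np.array_equal(null1, null2)

    def test_draw_size_exceeding_families(self, toy_db, toy_risk):
        with pytest.raises(ConfigurationError):
            permutation_pvalue(toy_db, toy_risk, 0.0,
                               PermutationConfig(n_perm=10, draw_size=4, seed=0))


class TestCallSignificance:
    def _record(self, score, p):
        return EnrichmentRecord("m", 1, 1.0, score, p, False)

    @pytest.mark.parametrize("score,p,expected", [
        (1.20, 0.05, True),    # boundary p is inclusive
        (0.9, 0.001, False),   # score below the cut
        (1.68, 0.2, False),    # p too large
        (1.0, 0.01, False),    # score must strictly exceed the cut
        (UNDEFINED, 0.0, False),
    ])
    def test_rule(self, score, p, expected):
        assert call_significance(self._record(score, p), SignificanceRule()) is expected

    @given(score=st.floats(min_value=-5, max_value=5, allow_nan=False),
           p=st.floats(min_value=0, max_value=1, allow_nan=False),
           d_score=st.floats(min_value=0, max_value=3),
           d_p=st.floats(min_value=0, max_value=1))
    def test_monotone(self, score, p, d_score, d_p):
        rule = SignificanceRule()
        base = call_significance(self._record(score, p), rule)
        better = call_significance(self._record(score + d_score, max(p - d_p, 0.0)), rule)
        assert better or not base  # improving either margin never loses the call


class TestEnrichSignature:
    def test_zero_overlap_family_is_undefined_not_significant(self):
        genes = frozenset({"A", "B", "C"})
        db = TargetDatabase(genes=genes, targets={"solo": frozenset({"A"}),
                                                  "other": frozenset({"B"})})
        risk = GeneSet.from_symbols("R", ["C"])
        result = enrich_signature(db, risk, ["solo"],
                                  PermutationConfig(n_perm=20, seed=0))
        record = result.records[0]
        assert record.observed == 0
        assert record.score == UNDEFINED
        assert not record.significant

    def test_planted_family_top_ranked_and_significant(self):
        fams = (MirnaSpec("planted", 400, 4.0),) + tuple(
            MirnaSpec(f"null-{i}", 400, 1.0) for i in range(20))
        sim = simulate_target_db(SyntheticDbSpec(2000, 100, fams, seed=3))
        result = enrich_signature(sim.db, sim.risk, [f.name for f in fams],
                                  PermutationConfig(n_perm=200, draw_size=11, seed=3))
        assert result.records[0].mirna == "planted"
        assert result.records[0].significant

    def test_union_risk_genes_is_union_of_overlaps(self, toy_db, toy_risk):
        result = enrich_signature(toy_db, toy_risk, ["famX", "famY"],
                                  PermutationConfig(n_perm=20, seed=1))
        union = set()
        for record in result.records:
            union.update(record.overlap_genes)
        assert set(result.union_risk_genes) == union
        assert result.n_union_risk_genes == len(union)

    def test_empty_signature_rejected(self, toy_db, toy_risk):
        with pytest.raises(ConfigurationError):
            enrich_signature(toy_db, toy_risk, [])

    def test_sorted_by_descending_score(self, toy_db, toy_risk):
        result = enrich_signature(toy_db, toy_risk, list(toy_db.families),
                                  PermutationConfig(n_perm=20, seed=1))
        scores = [r.score for r in result.records]
        assert scores == sorted(scores, reverse=True)
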