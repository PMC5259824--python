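import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pathcontext as pc

UNIVERSE = ["P1", "P2", "P3", "P4", "P5", "P6"]


class TestLikelihood:
    def test_log_base_is_smax_plus_two(self):
        tbl = pc.EntityScoreTable(keyword="k", scores={"P1": 8, "P2": 0, "P3": 3})
        lik = pc.likelihood_from_entity_scores(tbl, ["P1", "P2", "P3"])
        assert lik.base_used == 10
        assert lik.values["P1"] == pytest.approx(math.log10(9), abs=1e-5)
        assert lik.values["P2"] == 0.0
        assert lik.values["P3"] == pytest.approx(math.log10(4), abs=1e-5)

    def test_all_zero_scores_give_zero_likelihoods(self):
        tbl = pc.EntityScoreTable(keyword="k", scores={})
        lik = pc.likelihood_from_entity_scores(tbl, UNIVERSE)
        assert lik.base_used == 2
        assert all(v == 0.0 for v in lik.values.values())

    def test_top_score_maps_just_below_one(self):
        tbl = pc.EntityScoreTable(keyword="k", scores={"P1": 8})
        lik = pc.likelihood_from_entity_scores(tbl, ["P1"])
        assert lik.values["P1"] == pytest.approx(math.log10(9), abs=1e-4)
        assert lik.values["P1"] < 1.0

    @given(
        st.lists(
            st.one_of(st.just(0.0), st.floats(min_value=1e-9, max_value=1e6)),
            min_size=1,
            max_size=20,
        ),
    )
    def test_values_in_unit_interval_and_zero_iff_score_zero(self, scores):
        ids = [f"P{i}" for i in range(len(scores))]
        tbl = pc.EntityScoreTable(keyword="k", scores=dict(zip(ids, scores)))
        lik = pc.likelihood_from_entity_scores(tbl, ids)
        for pid, s in zip(ids, scores):
            v = lik.values[pid]
            assert 0.0 <= v < 1.0
            assert (v == 0.0) == (s == 0.0)


class TestPrior:
    def test_uniform_totals_give_uniform_prior(self):
        prior = pc.prior_from_evidence(
            pc.PriorEvidenceTable(totals={pid: 5.0 for pid in UNIVERSE}), UNIVERSE
        )
        expected = math.log(6) / math.log(7)
        assert all(v == pytest.approx(expected, abs=1e-5) for v in prior.values.values())
        assert expected == pytest.approx(0.92078, abs=1e-5)

    def test_missing_ids_treated_as_zero(self):
        prior = pc.prior_from_evidence(pc.PriorEvidenceTable(totals={"P1": 10}), ["P1", "P2"])
        assert prior.values["P1"] == pytest.approx(math.log(11) / math.log(12), abs=1e-5)
        assert prior.values["P2"] == 0.0


class TestPosterior:
    def test_bayes_arithmetic(self):
        prior = pc.context.PriorVector(values={"A": 0.5, "B": 0.5}, base_used=2)
        lik = pc.context.LikelihoodVector(values={"A": 0.2, "B": 0.6}, base_used=2)
        cs = pc.posterior_context_scores(lik, prior)
        assert cs.values == pytest.approx({"A": 0.25, "B": 0.75})

    def test_zero_denominator_gives_all_zero(self):
        prior = pc.context.PriorVector(values={"A": 0.5, "B": 0.5}, base_used=2)
        lik = pc.context.LikelihoodVector(values={"A": 0.0, "B": 0.0}, base_used=2)
        cs = pc.posterior_context_scores(lik, prior)
        assert all(v == 0.0 for v in cs.values.values())

    def test_universe_mismatch_rejected(self):
        prior = pc.context.PriorVector(values={"A": 0.5}, base_used=2)
        lik = pc.context.LikelihoodVector(values={"B": 0.5}, base_used=2)
        with pytest.raises(ValueError):
            pc.posterior_context_scores(lik, prior)

    def test_worked_toy_context_scores(self, toy):
        cs = pc.context_scores(toy.entity_tables, toy.prior, toy.pvalues.pathway_ids)
        expected = {"P1": 0.39737, "P2": 0.0, "P3": 0.25071, "P4": 0.35192, "P5": 0.0, "P6": 0.0}
        for pid, v in expected.items():
            assert cs.values[pid] == pytest.approx(v, abs=1e-4)

    def test_single_keyword_posterior_sums_to_one(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 30))
            ids = [f"P{i}" for i in range(n)]
            tbl = pc.EntityScoreTable(
                keyword="k",
                scores={pid: float(s) for pid, s in zip(ids, rng.uniform(0.5, 100, n))},
            )
            prior = pc.prior_from_evidence(
                pc.PriorEvidenceTable(
                    totals={pid: float(t) for pid, t in zip(ids, rng.uniform(0.5, 100, n))}
                ),
                ids,
            )
            cs = pc.posterior_context_scores(pc.likelihood_from_entity_scores(tbl, ids), prior)
            assert sum(cs.values.values()) == pytest.approx(1.0, abs=1e-12)

    def test_posterior_monotone_in_own_entity_score(self, rng):
        """Raising s_i raises CS_i and weakly lowers every other CS_j."""
        for _ in range(20):
            n = int(rng.integers(3, 10))
            ids = [f"P{i}" for i in range(n)]
            base = {pid: float(s) for pid, s in zip(ids, rng.uniform(1, 50, n))}
            totals = pc.PriorEvidenceTable(
                totals={pid: float(t) for pid, t in zip(ids, rng.uniform(1, 50, n))}
            )
            target = ids[int(rng.integers(0, n))]
            bumped = dict(base)
            bumped[target] = base[target] + float(rng.uniform(0.5, 5))
            # keep s_max fixed so only the target's likelihood moves
            anchor = max(base.values()) + 10
            base["anchor_cap"] = bumped["anchor_cap"] = anchor
            ids_ext = ids + ["anchor_cap"]
            prior = pc.prior_from_evidence(totals, ids_ext)

            def cs_ext(scores):
                tbl = pc.EntityScoreTable(keyword="k", scores=scores)
                return pc.posterior_context_scores(
                    pc.likelihood_from_entity_scores(tbl, ids_ext), prior
                ).values

            before, after = cs_ext(base), cs_ext(bumped)
            assert after[target] > before[target]
            for pid in ids:
                if pid != target:
                    assert after[pid] <= before[pid] + 1e-15

    def test_uniform_prior_preserves_entity_score_order(self, rng):
        n = 20
        ids = [f"P{i}" for i in range(n)]
        scores = {pid: float(s) for pid, s in zip(ids, rng.uniform(0, 100, n))}
        tbl = pc.EntityScoreTable(keyword="k", scores=scores)
        prior = pc.prior_from_evidence(pc.PriorEvidenceTable(totals={p: 5.0 for p in ids}), ids)
        cs = pc.posterior_context_scores(pc.likelihood_from_entity_scores(tbl, ids), prior)
        by_score = sorted(ids, key=lambda p: (-scores[p], p))
        by_cs = sorted(ids, key=lambda p: (-cs.values[p], p))
        assert by_score == by_cs


class TestAveraging:
    def test_arithmetic_mean(self):
        a = pc.ContextScoreVector(values={"A": 0.2, "B": 0.8})
        b = pc.ContextScoreVector(values={"A": 0.4, "B": 0.6})
        avg = pc.average_context_scores([a, b])
        assert avg.values == pytest.approx({"A": 0.3, "B": 0.7})

    def test_single_keyword_is_identity(self):
        a = pc.ContextScoreVector(values={"A": 0.2, "B": 0.8})
        assert pc.average_context_scores([a]).values == a.values

    def test_identical_vectors_unchanged(self):
        a = pc.ContextScoreVector(values={"A": 0.25, "B": 0.75})
        avg = pc.average_context_scores([a, a, a])
        assert avg.values == pytest.approx(a.values)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            pc.average_context_scores([])

    def test_universe_mismatch_rejected(self):
        a = pc.ContextScoreVector(values={"A": 1.0})
        b = pc.ContextScoreVector(values={"B": 1.0})
        with pytest.raises(ValueError):
            pc.average_context_scores([a, b])
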