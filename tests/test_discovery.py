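import itertools

import numpy as np
import pandas as pd
import pytest

import oracles
from reosig import (
    DataError,
    ExpressionMatrix,
    GeneratorConfig,
    OrientedGenePair,
    SurvivalData,
    concordance_index,
    enumerate_candidate_pairs,
    forward_select_signature,
    generate_cohort,
    reo_indicator,
    select_de_genes,
    select_prognostic_genes,
    select_prognostic_pairs,
    signature_cindex,
    vote_classify,
)
from reosig.classify import NON_RESPONDER
from reosig.data import truncate_followup


def _expr_from_array(values, genes=None, samples=None):
    g, n = values.shape
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=genes or [f"g{i}" for i in range(g)],
            columns=samples or [f"s{j}" for j in range(n)],
        )
    )


class TestDEGeneScreen:
    def test_planted_shift_detected_and_null_behaviour(self):
        rng = np.random.default_rng(2)
        n = 100
        labels = np.array(["CR"] * 50 + ["nonCR"] * 50)
        values = rng.normal(8, 1, size=(30, n))
        values[0, :50] += 2.0  # planted 2-sigma shift
        expr = _expr_from_array(values)
        selected = select_de_genes(expr, labels, alpha=0.05)
        assert "g0" in selected
        # verify every selection against an independent t computation
        from scipy.stats import t as tdist

        for gene in expr.gene_ids:
            x = values[expr.gene_ids.index(gene), :50]
            y = values[expr.gene_ids.index(gene), 50:]
            t = oracles.pooled_t_stat(x, y)
            p = 2 * tdist.sf(abs(t), n - 2)
            assert (gene in selected) == (p < 0.05)

    def test_constant_gene_skipped_not_fatal(self):
        values = np.vstack([np.full(10, 5.0), np.arange(10, dtype=float)])
        labels = ["CR"] * 5 + ["nonCR"] * 5
        out = select_de_genes(_expr_from_array(values), labels)
        assert "g0" not in out  # degenerate, skipped quietly

    def test_alpha_zero_empty(self):
        rng = np.random.default_rng(0)
        expr = _expr_from_array(rng.normal(size=(5, 20)))
        assert select_de_genes(expr, ["CR"] * 10 + ["nonCR"] * 10, alpha=0.0) == []

    def test_missing_states_excluded_and_empty_group_error(self):
        rng = np.random.default_rng(1)
        expr = _expr_from_array(rng.normal(size=(3, 6)))
        with pytest.raises(DataError):
            select_de_genes(expr, ["CR", "CR", "CR", None, None, None])


class TestPrognosticGeneScreen:
    def test_strong_hazard_gene_included_noise_mostly_not(self):
        rng = np.random.default_rng(4)
        n = 200
        x = rng.normal(size=n)
        times = rng.exponential(np.exp(-1.0 * x) * 20)  # beta = 1
        surv = SurvivalData(times, np.ones(n, dtype=int))
        values = rng.normal(8, 1, size=(10, n))
        values[0] = x
        expr = _expr_from_array(values)
        selected = select_prognostic_genes(expr, surv, expr.gene_ids, alpha=0.05)
        assert "g0" in selected
        # pure-noise genes pass only at the nominal rate; 9 noise genes
        # should essentially never all be selected
        assert len(selected) < 6

    def test_empty_candidates(self):
        rng = np.random.default_rng(0)
        expr = _expr_from_array(rng.normal(size=(3, 10)))
        surv = SurvivalData(np.arange(1, 11, dtype=float), np.ones(10, dtype=int))
        assert select_prognostic_genes(expr, surv, []) == []


class TestPairEnumeration:
    def test_counts(self):
        genes = [f"G{i:03d}" for i in range(70)]
        pairs = enumerate_candidate_pairs(genes)
        assert len(pairs) == 2415
        assert pairs == sorted(pairs)
        assert enumerate_candidate_pairs(["a", "b"]) == [("a", "b")]

    def test_errors(self):
        with pytest.raises(DataError):
            enumerate_candidate_pairs(["only"])
        with pytest.raises(DataError):
            enumerate_candidate_pairs(["x", "x", "y"])


class TestReoIndicator:
    def test_definition_and_tie(self, small_expr):
        pair = OrientedGenePair("gA", "gB")
        np.testing.assert_array_equal(
            reo_indicator(small_expr, pair), [1, 0, 0]
        )  # 5>3, 2<4, 3==3 -> tie counts 0

    def test_missing_gene_named(self, small_expr):
        with pytest.raises(DataError, match="gZ"):
            reo_indicator(small_expr, OrientedGenePair("gA", "gZ"))

    def test_monotone_invariance(self):
        rng = np.random.default_rng(9)
        values = rng.normal(8, 2, size=(6, 40))
        expr = _expr_from_array(values)
        pair = OrientedGenePair("g0", "g3")
        base = reo_indicator(expr, pair)
        for _ in range(20):
            a = rng.uniform(0.1, 3.0, size=40)
            b = rng.uniform(-5, 5, size=40)
            transformed = _expr_from_array(values * a + b)
            np.testing.assert_array_equal(reo_indicator(transformed, pair), base)


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(12)
    n = 200
    state = rng.random(n) < 0.5  # True = low risk
    d = np.where(state, 1.0, -1.0) * np.abs(rng.normal(1, 0.3, n))
    values = rng.normal(8, 1, size=(6, n))
    values[0] = 8 + d / 2
    values[1] = 8 - d / 2
    times = rng.exponential(np.where(state, 50.0, 15.0))
    surv = SurvivalData(times, np.ones(n, dtype=int))
    return _expr_from_array(values), surv, state


class TestPrognosticPairScreen:

    def test_planted_pair_selected_with_hr_below_one(self, planted):
        expr, surv, _ = planted
        pairs = select_prognostic_pairs(expr, [("g0", "g1")], surv, fdr=0.05)
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.gene_a, p.gene_b) == ("g0", "g1")
        assert p.pair_hr < 1
        assert p.pair_q is not None and p.pair_cindex > 0.5

    def test_unfavorable_orientation_flipped(self, planted):
        expr, surv, _ = planted
        # submit reversed: favorable pattern should come back re-oriented
        pairs = select_prognostic_pairs(expr, [("g1", "g0")], surv, fdr=0.05)
        assert (pairs[0].gene_a, pairs[0].gene_b) == ("g0", "g1")
        assert pairs[0].pair_hr < 1

    def test_fdr_zero_empty(self, planted):
        expr, surv, _ = planted
        assert select_prognostic_pairs(expr, [("g0", "g1")], surv, fdr=0.0) == []


class TestSignatureCindex:
    def test_perfect_single_pair(self):
        # within-group times tied so every comparable pair is between
        # groups; the favorable ordering then separates them perfectly
        values = np.array([[2.0, 2.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0]])
        expr = _expr_from_array(values)
        surv = SurvivalData([10, 10, 1, 1], [1, 1, 1, 1])
        pair = OrientedGenePair("g0", "g1")
        assert signature_cindex(expr, [pair], surv) == 1.0

    def test_compositional_identity_with_vote_labels(self, default_cohort):
        expr = default_cohort.expression
        clin = truncate_followup(default_cohort.clinical)
        surv = SurvivalData.from_clinical(clin)
        pairs = default_cohort.planted
        from reosig import GenePairSignature

        labels = vote_classify(expr, GenePairSignature(pairs=tuple(pairs))).labels
        risk = (labels == NON_RESPONDER).astype(float)
        assert signature_cindex(expr, pairs, surv) == pytest.approx(
            concordance_index(risk, surv)
        )


class TestForwardSelection:
    def _survival(self, rng, state):
        times = rng.exponential(np.where(state, 50.0, 15.0))
        return SurvivalData(times, np.ones(len(state), dtype=int))

    def test_single_candidate_returned_as_is(self):
        rng = np.random.default_rng(21)
        n = 150
        state = rng.random(n) < 0.5
        d = np.where(state, 1.0, -1.0)
        values = rng.normal(8, 1, size=(4, n))
        values[0], values[1] = 8 + d / 2, 8 - d / 2
        expr = _expr_from_array(values)
        surv = self._survival(rng, state)
        pool = select_prognostic_pairs(expr, [("g0", "g1")], surv)
        sig, trace = forward_select_signature(expr, pool, surv)
        assert len(sig) == 1
        assert sig.training_cindex == pytest.approx(pool[0].pair_cindex)
        assert trace.chosen_seed == 0

    def test_pairs_come_from_pool_and_trace_tolerance(self, default_cohort):
        from reosig.discovery import CINDEX_TOL

        expr = default_cohort.expression
        clin = truncate_followup(default_cohort.clinical)
        surv = SurvivalData.from_clinical(clin)
        genes = sorted({g for p in default_cohort.planted for g in (p.gene_a, p.gene_b)})
        pool = select_prognostic_pairs(expr, enumerate_candidate_pairs(genes), surv)
        sig, trace = forward_select_signature(expr, pool, surv)
        pool_keys = {p.unordered for p in pool}
        assert all(p.unordered in pool_keys for p in sig.pairs)
        # along every growth path the C-index never drops by more than
        # the selection tolerance between consecutive steps
        for path in trace.paths:
            cs = [c for _, c in path]
            assert all(b >= a - CINDEX_TOL - 1e-12 for a, b in zip(cs, cs[1:]))
        # returned C-index within tolerance-per-step of best single pair
        best_single = max(p.pair_cindex for p in pool)
        assert sig.training_cindex >= best_single - CINDEX_TOL * len(sig)

    def test_empty_pool_error(self, default_cohort):
        surv = SurvivalData.from_clinical(default_cohort.clinical)
        with pytest.raises(DataError):
            forward_select_signature(default_cohort.expression, [], surv)

    def test_recovers_planted_pairs_on_reference_cohort(self):
        cohort = generate_cohort(GeneratorConfig(seed=3))
        clin = truncate_followup(cohort.clinical)
        surv = SurvivalData.from_clinical(clin)
        genes = sorted({g for p in cohort.planted for g in (p.gene_a, p.gene_b)})
        pool = select_prognostic_pairs(
            cohort.expression, enumerate_candidate_pairs(genes), surv
        )
        sig, _ = forward_select_signature(cohort.expression, pool, surv)
        planted = {p.unordered for p in cohort.planted}
        assert sum(p.unordered in planted for p in sig.pairs) >= 3


class TestMonotoneInvarianceOfRankStages:
    def test_steps_two_and_three_unchanged_by_per_sample_distortion(self, default_cohort):
        """Pair screening and forward selection consume only order
        information, so a strictly increasing per-sample transform leaves
        their outputs identical."""
        from reosig import apply_monotone_distortion

        expr = default_cohort.expression
        clin = truncate_followup(default_cohort.clinical)
        surv = SurvivalData.from_clinical(clin)
        genes = sorted({g for p in default_cohort.planted for g in (p.gene_a, p.gene_b)})
        candidates = enumerate_candidate_pairs(genes)

        distorted = apply_monotone_distortion(expr, family="power", seed=99)
        pool_a = select_prognostic_pairs(expr, candidates, surv)
        pool_b = select_prognostic_pairs(distorted, candidates, surv)
        assert [(p.gene_a, p.gene_b) for p in pool_a] == [
            (p.gene_a, p.gene_b) for p in pool_b
        ]
        sig_a, _ = forward_select_signature(expr, pool_a, surv)
        sig_b, _ = forward_select_signature(distorted, pool_b, surv)
        assert [p.name for p in sig_a.pairs] == [p.name for p in sig_b.pairs]
        assert sig_a.training_cindex == pytest.approx(sig_b.training_cindex)
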