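"""Discovery statistics: enrichment, collapsing, ranking, KS, network test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from popscale.cohort import (
    bh_adjust,
    collapse_genes,
    enrichment_test,
    expected_dnm_count,
    gene_collapsing_test,
    ks_compare,
    min_score_per_gene,
    network_degree_test,
    rank_patient_variants,
)
from popscale.errors import ConsistencyError, ParameterError
from popscale.simulate import simulate_scores
from popscale.types import (
    CohortObservation,
    GeneSet,
    Group,
    Inheritance,
    InteractionGraph,
    MutationRate,
    VariantKey,
)


def _keys(gene, n):
    return [VariantKey(gene, i + 1, "M", "R") for i in range(n)]


class TestExpectedCount:
    def test_single_variant_arithmetic(self):
        rates = [MutationRate(_keys("A", 1)[0], 1e-8)]
        assert expected_dnm_count(rates, 31_000) == pytest.approx(6.2e-4)

    def test_empty_band_is_zero(self):
        rates = [MutationRate(k, 1e-8) for k in _keys("A", 5)]
        assert expected_dnm_count(rates, 100, band_filter=lambda k: False) == 0.0

    def test_matches_per_variant_loop(self, rng):
        keys = _keys("A", 1000)
        mus = rng.uniform(1e-9, 1e-7, size=1000)
        rates = [MutationRate(k, float(m)) for k, m in zip(keys, mus)]
        brute = 0.0
        for r in rates:
            brute += 2 * 500 * r.mu
        assert expected_dnm_count(rates, 500) == pytest.approx(brute, abs=1e-12)


class TestEnrichment:
    def test_null_case(self):
        res = enrichment_test(10, 10.0)
        assert res.fold == 1.0 and res.poisson_p > 0.3

    def test_zero_observed_boundary(self):
        res = enrichment_test(0, 5.0)
        assert res.fold == 0.0 and res.poisson_p == 1.0

    def test_ci_contains_point_estimate(self, rng):
        for _ in range(20):
            obs, exp = int(rng.integers(0, 50)), float(rng.uniform(0.5, 20))
            res = enrichment_test(obs, exp)
            assert res.ci95[0] <= res.fold <= res.ci95[1]

    def test_expected_must_be_positive(self):
        with pytest.raises(ParameterError):
            enrichment_test(3, 0.0)


class TestCollapsing:
    def test_zero_dnms_gives_unit_p(self):
        keys = _keys("A", 3)
        scores = {k: -1.0 for k in keys}
        rates = [MutationRate(k, 1e-6) for k in keys]
        res = gene_collapsing_test(scores, rates, [], 100, n_sims=1000, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0, abs=2e-3)

    def test_monte_carlo_matches_enumeration(self):
        """3-variant gene: exact null by enumerating Poisson-count outcomes."""
        keys = _keys("A", 3)
        scores = {keys[0]: -5.0, keys[1]: -2.0, keys[2]: -0.5}
        mus = np.array([2e-5, 1e-5, 3e-5])
        rates = [MutationRate(k, float(m)) for k, m in zip(keys, mus)]
        n_prob = 2000
        lam = 2 * n_prob * mus.sum()
        probs = mus / mus.sum()
        observed = [keys[0]]  # T_obs = 5.0
        t_obs = 5.0

        # exact P(T_null >= T_obs): enumerate counts 0..12 and all draws
        p_exact = 0.0
        for c in range(0, 13):
            pc = stats.poisson.pmf(c, lam)
            if c == 0:
                continue
            for combo in itertools.product(range(3), repeat=c):
                t = sum(-scores[keys[i]] for i in combo)
                if t >= t_obs:
                    p_exact += pc * np.prod([probs[i] for i in combo])
        res = gene_collapsing_test(scores, rates, observed, n_prob,
                                   n_sims=100_000, seed=1)
        assert abs(res.p_value - p_exact) < 0.01

    def test_null_pvalues_uniform(self):
        """Type-I calibration: 300 null genes, rates rich enough that the
        statistic is effectively continuous."""
        rng = np.random.default_rng(2)
        ps = []
        for g in range(300):
            keys = _keys(f"G{g}", 10)
            w = rng.lognormal(0, 1, 10)
            mus = 2e-3 * w / w.sum()
            scores = {k: float(rng.normal(0, 1)) for k in keys}
            rates = [MutationRate(k, float(m)) for k, m in zip(keys, mus)]
            lam = 2 * 2000 * mus.sum()
            n = rng.poisson(lam)
            obs = [keys[i] for i in rng.choice(10, size=n, p=mus / mus.sum())]
            ps.append(
                gene_collapsing_test(scores, rates, obs, 2000,
                                     n_sims=1000, seed=100 + g).p_value
            )
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_missing_score_is_consistency_error(self):
        keys = _keys("A", 2)
        scores = {keys[0]: -1.0, keys[1]: -1.0}
        rates = [MutationRate(k, 1e-6) for k in keys]
        stranger = VariantKey("B", 9, "A", "C")
        with pytest.raises(ConsistencyError, match="B:A9C"):
            gene_collapsing_test(scores, rates, [stranger], 100, n_sims=1000, seed=0)

    def test_bit_reproducible(self):
        keys = _keys("A", 5)
        scores = {k: float(-i) for i, k in enumerate(keys)}
        rates = [MutationRate(k, 1e-5) for k in keys]
        a = gene_collapsing_test(scores, rates, keys[:2], 1000, n_sims=2000, seed=7)
        b = gene_collapsing_test(scores, rates, keys[:2], 1000, n_sims=2000, seed=7)
        assert a.p_value == b.p_value and a.statistic == b.statistic


class TestBH:
    def test_three_value_closed_form(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert bh_adjust([0.2]) == [0.2]

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.1, 0.0])

    @given(
        st.lists(st.floats(min_value=1e-9, max_value=1.0, exclude_min=False),
                 min_size=1, max_size=100)
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_statsmodels_stepup(self, ps):
        ours = bh_adjust(ps)
        _, ref, _, _ = multipletests(ps, method="fdr_bh")
        assert np.allclose(ours, ref, atol=1e-12)


class TestRanking:
    @staticmethod
    def _obs(patient, key, inh=Inheritance.DNM, grp=Group.CASE):
        return CohortObservation(patient_id=patient, key=key, inheritance=inh, group=grp)

    def test_singleton_ranks_first(self):
        k = VariantKey("A", 1, "M", "R")
        df, summary = rank_patient_variants([self._obs("p1", k)], {k: -3.0})
        assert df["rank"].tolist() == [1]
        assert summary["top_is_dnm"] == 1.0

    def test_tie_break_is_lexicographic(self):
        ka = VariantKey("A", 5, "M", "R")
        kb = VariantKey("B", 2, "M", "R")
        obs = [self._obs("p1", kb), self._obs("p1", ka)]
        df, _ = rank_patient_variants(obs, {ka: -1.0, kb: -1.0})
        assert df.loc[df["rank"] == 1, "gene"].item() == "A"

    def test_unscored_variant_rejected(self):
        k = VariantKey("A", 1, "M", "R")
        with pytest.raises(ConsistencyError):
            rank_patient_variants([self._obs("p1", k)], {})

    def test_severe_cutoff_restricts_summary(self):
        k1, k2 = VariantKey("A", 1, "M", "R"), VariantKey("B", 1, "M", "R")
        obs = [self._obs("p1", k1), self._obs("p2", k2)]
        _, summary = rank_patient_variants(obs, {k1: -6.0, k2: -0.5},
                                           severe_cutoff=-5.0)
        assert summary["n_eligible"] == 1


class TestGeneMetrics:
    def test_min_score_examples(self):
        scores, _ = simulate_scores(1, 1, 0.5, seed=0)
        scores[0].popeve_score = -3.2
        assert min_score_per_gene(scores) == {scores[0].key.gene_id: -3.2}

    def test_matches_groupby_min(self):
        import pandas as pd

        scores, _ = simulate_scores(100, 100, 0.5, seed=1)
        got = min_score_per_gene(scores)
        df = pd.DataFrame(
            {"gene": [v.key.gene_id for v in scores],
             "s": [v.mean_base_score() for v in scores]}
        )
        ref = df.groupby("gene")["s"].min().to_dict()
        assert got == pytest.approx(ref)

    def test_ks_identical_and_disjoint(self):
        a = list(np.linspace(0, 1, 50))
        d, _ = ks_compare(a, a)
        assert d == pytest.approx(0.0, abs=1e-12)
        d, p = ks_compare(a, [x + 10 for x in a])
        assert d == 1.0 and p < 1e-10

    def test_ks_against_analytic_gap(self, rng):
        """N(0,1) vs N(1,1): population sup gap = 2*Phi(1/2) - 1 ~ 0.383."""
        a, b = rng.normal(0, 1, 500), rng.normal(1, 1, 500)
        d, _ = ks_compare(a, b)
        assert abs(d - (2 * stats.norm.cdf(0.5) - 1)) < 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            ks_compare([], [1.0])


class TestNetwork:
    @staticmethod
    def _planted(seed=0):
        rng = np.random.default_rng(seed)
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(f"N{i}" for i in range(400))
        base = {f"N{i}" for i in range(20)}
        added = {f"N{i}" for i in range(20, 30)}
        for u in sorted(base):
            for v in sorted(base):
                if u < v and rng.random() < 0.8:
                    g.add_edge(u, v)
        for u in sorted(added):
            for v in sorted(base):
                if rng.random() < 0.5:
                    g.add_edge(u, v)
        for i in range(30, 400):
            for j in range(i + 1, 400):
                if rng.random() < 0.005:
                    g.add_edge(f"N{i}", f"N{j}")
        return InteractionGraph(graph=g), GeneSet("base", frozenset(base)), added

    def test_planted_clique_detected(self):
        graph, base, added = self._planted()
        res = network_degree_test(graph, base, GeneSet("added", frozenset(added)),
                                  n_random=999, seed=1)
        assert res.permutation_p <= 0.01
        assert res.mean_degree_augmented > res.mean_degree_base

    def test_empty_graph_degenerate(self):
        graph = InteractionGraph.from_edges([], nodes=[f"N{i}" for i in range(30)])
        res = network_degree_test(
            graph,
            GeneSet("b", frozenset({"N0", "N1"})),
            GeneSet("a", frozenset({"N2"})),
            n_random=99,
            seed=0,
        )
        assert res.mean_degree_base == 0.0
        assert res.mean_degree_augmented == 0.0
        assert res.permutation_p == 1.0

    def test_overlap_rejected(self):
        graph, base, added = self._planted()
        with pytest.raises(ParameterError, match="disjoint"):
            network_degree_test(graph, base,
                                GeneSet("a", frozenset(list(base.genes)[:2])), 99, 0)


def test_collapse_genes_routes_and_bh(small_table, small_rates):
    """End-to-end gene table: planted severe gene flagged by both routes."""
    from popscale.mixture import Thresholds
    from popscale.simulate import simulate_cohort

    scores, _ = small_table
    cohort, _ = simulate_cohort(scores, small_rates, 100, 0,
                                causal_fraction=1.0, severe_shift=2.5, seed=21)
    smap = {v.key: v.mean_base_score() for v in scores}
    th = Thresholds(severe_cutoff=np.quantile(list(smap.values()), 0.01),
                    moderate_cutoff=np.quantile(list(smap.values()), 0.05))
    results = collapse_genes(cohort, smap, small_rates, 100,
                             n_sims=2000, seed=3, thresholds=th)
    assert all(r.q_value >= r.p_value - 1e-12 for r in results)
    best = min(results, key=lambda r: r.p_value)
    assert best.q_value < 0.05
    assert best.discovery_route.value in ("both", "variant_threshold", "gene_collapsing")
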