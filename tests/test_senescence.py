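"""Rank-AUC enrichment scoring, QC, classification, annotation, gating."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from neurovasc import DegenerateInputError, ParameterError
from neurovasc import senescence as sen


def brute_force_score(ranking, members, top_fraction, n_genes):
    """Independent recovery-curve walk: cumulative hits summed stepwise."""
    window = int(np.ceil(top_fraction * n_genes))
    hits = 0
    area = 0
    for pos in range(window):
        if ranking[pos] in members:
            hits += 1
        area += hits
    s = min(len(members), window)
    max_area = s * (s + 1) / 2 + s * (window - s)
    return area / max_area


@pytest.fixture(scope="module")
def planted_matrix():
    return sen.generate_expression_matrix(
        n_cells=600, n_genes=3000, senescent_fraction=0.2, log2_effect=2.0, seed=1
    )


class TestGenerator:
    def test_zero_fraction_means_no_positives(self):
        adata = sen.generate_expression_matrix(
            n_cells=50, n_genes=500, senescent_fraction=0.0, seed=0
        )
        assert not adata.obs["senescent_truth"].any()

    def test_deterministic_per_seed(self):
        kw = dict(n_cells=40, n_genes=400, senescent_fraction=0.25, seed=5)
        a = sen.generate_expression_matrix(**kw)
        b = sen.generate_expression_matrix(**kw)
        np.testing.assert_array_equal(np.asarray(a.X), np.asarray(b.X))

    def test_unknown_gene_set_member_rejected(self):
        gs = sen.GeneSet("bad", ("not_a_gene",))
        with pytest.raises(ParameterError):
            sen.generate_expression_matrix(n_cells=10, n_genes=100, gene_set=gs)

    def test_null_effect_scores_indistinguishable(self):
        """log2_effect=0: planted cells' scores match the others (KS test)."""
        pvals = []
        for seed in range(10):
            adata = sen.generate_expression_matrix(
                n_cells=300,
                n_genes=2000,
                senescent_fraction=0.2,
                log2_effect=0.0,
                seed=seed,
            )
            gs = sen.default_senescence_set(2000)
            scores = sen.score_cells(adata, gs, seed=seed)
            truth = adata.obs["senescent_truth"].to_numpy()
            pvals.append(ks_2samp(scores[truth], scores[~truth]).pvalue)
        assert max(pvals) > 0.01


class TestQc:
    def test_mito_rule_strict_boundary(self):
        x = np.zeros((12, 10), dtype=np.int32)
        x[:, :] = 10  # every gene expressed: unique-gene bounds never trigger
        x[0, 0] = 90   # mito gene share: 90 / (90 + 9*10) = 0.5 -> removed
        x[1, 0] = 18   # 18 / (18 + 9*10 + 12) is not 0.15; construct exactly:
        # cell 1: mito 18, others 9 genes with 102 total -> 18/120 = 0.15 kept
        x[1, 1:] = np.array([12, 10, 10, 10, 10, 10, 10, 10, 20])
        import anndata as ad

        adata = ad.AnnData(
            X=x,
            obs=pd.DataFrame(index=[f"c{i}" for i in range(12)]),
            var=pd.DataFrame(
                {"mito": [True] + [False] * 9}, index=[f"g{i}" for i in range(10)]
            ),
        )
        filtered, log = sen.qc_filter_cells(adata, gene_count_bounds=(0, 10**9))
        assert "c0" in set(log["cell_id"])
        assert "c1" not in set(log["cell_id"])
        assert filtered.n_obs == 11

    def test_removed_set_matches_brute_force_rules(self):
        adata = sen.generate_expression_matrix(
            n_cells=1000,
            n_genes=1000,
            senescent_fraction=0.0,
            mito_fraction_high_cells=0.05,
            seed=3,
        )
        filtered, log = sen.qc_filter_cells(adata)
        x = np.asarray(adata.X)
        mito = adata.var["mito"].to_numpy()
        frac = x[:, mito].sum(axis=1) / x.sum(axis=1)
        unique = (x > 0).sum(axis=1)
        lo, hi = np.percentile(unique, [1, 99])
        expected = (frac > 0.15) | (unique < lo) | (unique > hi)
        assert set(log["cell_id"]) == set(adata.obs_names[expected])
        assert filtered.n_obs == (~expected).sum()
        # the planted high-mito cells are among the removals
        assert set(adata.obs_names[adata.obs["high_mito_truth"]]) <= set(log["cell_id"])

    def test_all_cells_removed_raises(self):
        adata = sen.generate_expression_matrix(n_cells=20, n_genes=100, seed=0)
        with pytest.raises(DegenerateInputError):
            sen.qc_filter_cells(adata, gene_count_bounds=(10**9, 10**9 + 1))


class TestRanking:
    def test_single_expressed_gene_ranks_first(self):
        import anndata as ad

        x = np.zeros((1, 50), dtype=np.int32)
        x[0, 33] = 5
        adata = ad.AnnData(
            X=x,
            obs=pd.DataFrame(index=["c0"]),
            var=pd.DataFrame(index=[f"g{i}" for i in range(50)]),
        )
        order = sen.rank_genes(adata)
        assert order[0, 0] == 33

    def test_all_zero_cell_gets_seeded_permutation(self):
        import anndata as ad

        adata = ad.AnnData(
            X=np.zeros((1, 30), dtype=np.int32),
            obs=pd.DataFrame(index=["cellX"]),
            var=pd.DataFrame(index=[f"g{i}" for i in range(30)]),
        )
        a = sen.rank_genes(adata, seed=7)
        b = sen.rank_genes(adata, seed=7)
        np.testing.assert_array_equal(a, b)
        assert sorted(a[0]) == list(range(30))

    def test_rankings_deterministic(self, planted_matrix):
        a = sen.rank_genes(planted_matrix[:50], seed=2)
        b = sen.rank_genes(planted_matrix[:50], seed=2)
        np.testing.assert_array_equal(a, b)


class TestEnrichmentScore:
    def test_maximal_enrichment_scores_one(self):
        ranking = list(range(100))
        members = set(range(10))
        assert sen.enrichment_score(ranking, members, top_fraction=0.2) == 1.0

    def test_no_member_in_window_scores_zero(self):
        ranking = list(range(100))
        members = {95, 96}
        assert sen.enrichment_score(ranking, members, top_fraction=0.05) == 0.0

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ParameterError):
            sen.enrichment_score(list(range(10)), set())

    def test_scores_match_brute_force_on_random_rankings(self):
        rng = np.random.default_rng(0)
        n_genes = 1000
        members = set(rng.choice(n_genes, 40, replace=False).tolist())
        for _ in range(50):
            ranking = rng.permutation(n_genes).tolist()
            fast = sen.enrichment_score(ranking, members, top_fraction=0.05)
            brute = brute_force_score(ranking, members, 0.05, n_genes)
            assert fast == pytest.approx(brute, abs=1e-12)

    def test_null_mean_matches_monte_carlo(self):
        """Mean score of random rankings agrees with an independent MC walk."""
        rng = np.random.default_rng(1)
        n_genes, set_size = 10000, 100
        members = set(rng.choice(n_genes, set_size, replace=False).tolist())
        ours = []
        brute = []
        rng_a = np.random.default_rng(10)
        rng_b = np.random.default_rng(20)
        for _ in range(1000):
            ours.append(
                sen.enrichment_score(rng_a.permutation(n_genes), members, 0.05)
            )
        for _ in range(1000):
            brute.append(
                brute_force_score(rng_b.permutation(n_genes), members, 0.05, n_genes)
            )
        assert np.mean(ours) == pytest.approx(np.mean(brute), abs=0.005)

    def test_score_invariant_outside_window_and_monotone(self):
        rng = np.random.default_rng(2)
        n_genes = 500
        members = set(range(0, 50))
        ranking = rng.permutation(n_genes)
        base = sen.enrichment_score(ranking, members, top_fraction=0.1)
        window = int(np.ceil(0.1 * n_genes))
        shuffled = ranking.copy()
        shuffled[window:] = rng.permutation(shuffled[window:])
        assert sen.enrichment_score(shuffled, members, 0.1) == base
        # promoting a member to rank 1 never decreases the score
        member_pos = next(i for i, g in enumerate(ranking) if g in members and i > 0)
        promoted = np.concatenate(
            ([ranking[member_pos]], np.delete(ranking, member_pos))
        )
        assert sen.enrichment_score(promoted, members, 0.1) >= base

    def test_vectorized_scorer_equals_per_cell_scorer(self, planted_matrix):
        gs = sen.default_senescence_set(3000)
        sub = planted_matrix[:40].copy()
        rankings = sen.rank_genes(sub, seed=0)
        fast = sen.score_cells(sub, gs, seed=0, rankings=rankings)
        gene_names = sub.var_names.to_numpy()
        members = set(gs.members)
        for i in range(sub.n_obs):
            slow = sen.enrichment_score(gene_names[rankings[i]], members, 0.05)
            assert fast[i] == pytest.approx(slow, abs=1e-12)

    def test_scores_bounded(self, planted_matrix):
        gs = sen.default_senescence_set(3000)
        scores = sen.score_cells(planted_matrix, gs, seed=1)
        assert np.all((scores >= 0) & (scores <= 1))


class TestClassification:
    def test_bimodal_scores_recover_planted_fraction(self):
        fractions = []
        for seed in range(3):
            adata = sen.generate_expression_matrix(
                n_cells=2000, n_genes=10000, senescent_fraction=0.2,
                log2_effect=2.0, seed=seed,
            )
            gs = sen.default_senescence_set(10000)
            scores = sen.score_cells(adata, gs, seed=seed)
            calls, _, _ = sen.classify_senescent(scores)
            fractions.append(calls.mean())
        assert np.mean(fractions) == pytest.approx(0.2, abs=0.02)

    def test_null_positive_rate_low(self):
        rates = []
        for seed in range(3):
            adata = sen.generate_expression_matrix(
                n_cells=1000, n_genes=5000, senescent_fraction=0.2,
                log2_effect=0.0, seed=40 + seed,
            )
            gs = sen.default_senescence_set(5000)
            scores = sen.score_cells(adata, gs, seed=seed)
            calls, _, _ = sen.classify_senescent(scores)
            rates.append(calls.mean())
        assert max(rates) <= 0.05

    def test_explicit_threshold_is_exact(self):
        rng = np.random.default_rng(0)
        scores = rng.random(100)
        calls, thr, used = sen.classify_senescent(scores, strategy=0.6)
        assert used == "explicit"
        np.testing.assert_array_equal(calls, scores >= 0.6)

    def test_constant_scores_raise(self):
        with pytest.raises(DegenerateInputError):
            sen.classify_senescent(np.full(50, 0.3))

    def test_too_few_cells_raise(self):
        with pytest.raises(ParameterError):
            sen.classify_senescent(np.arange(5) / 5)


class TestAnnotation:
    def _three_type_matrix(self):
        # 3 cell types, each overexpressing its own 20-gene signature
        rng = np.random.default_rng(0)
        n_per = 60
        n_genes = 2000
        genes = [f"g{i:04d}" for i in range(n_genes)]
        sig_idx = {"astro": range(0, 20), "endo": range(20, 40), "microglia": range(40, 60)}
        base = rng.lognormal(0, 1, n_genes)
        rows = []
        truth = []
        for name, idx in sig_idx.items():
            mu = np.tile(base, (n_per, 1))
            mu[:, list(idx)] *= 16
            lam = rng.gamma(2, mu / 2)
            rows.append(rng.poisson(lam))
            truth += [name] * n_per
        import anndata as ad

        adata = ad.AnnData(
            X=np.vstack(rows).astype(np.int32),
            obs=pd.DataFrame({"truth": truth}, index=[f"c{i}" for i in range(3 * n_per)]),
            var=pd.DataFrame(index=genes),
        )
        sigs = {
            name: sen.GeneSet(name, tuple(genes[i] for i in idx))
            for name, idx in sig_idx.items()
        }
        return adata, sigs

    def test_strong_mixture_annotated_accurately(self):
        adata, sigs = self._three_type_matrix()
        out = sen.annotate_cell_types(adata, sigs, top_n=20, top_fraction=0.05)
        accuracy = (out["label"] == adata.obs["truth"]).mean()
        assert accuracy >= 0.95

    def test_low_scores_unassigned(self):
        adata, sigs = self._three_type_matrix()
        out = sen.annotate_cell_types(adata, sigs, auc_cutoff=1.01)
        assert (out["label"] == "unassigned").all()


class TestGating:
    def test_double_positive_fraction(self):
        table = pd.DataFrame(
            {
                "RFP": [True] * 10 + [False] * 90,
                "CD31": [True] * 100,
            }
        )
        res = sen.gating_fraction(table, ["RFP", "CD31"], ["CD31"])
        assert res.fraction == pytest.approx(0.10)
        assert (res.n_numerator, res.n_denominator) == (10, 100)

    def test_identity_population_is_one(self):
        table = pd.DataFrame({"CD31": [True, True, False]})
        res = sen.gating_fraction(table, ["CD31"], ["CD31"])
        assert res.fraction == 1.0

    def test_matches_brute_force_row_filtering(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {m: rng.random(500) < p for m, p in
             [("RFP", 0.2), ("CD31", 0.4), ("CD11b", 0.3)]}
        )
        res = sen.gating_fraction(table, ["RFP", "CD31"], ["CD31"])
        brute_num = sum(r.RFP and r.CD31 for r in table.itertuples())
        brute_den = sum(r.CD31 for r in table.itertuples())
        assert res.fraction == pytest.approx(brute_num / brute_den)
        assert 0 <= res.fraction <= 1

    def test_non_nested_populations_rejected(self):
        table = pd.DataFrame({"RFP": [True], "CD31": [True]})
        with pytest.raises(ParameterError):
            sen.gating_fraction(table, ["RFP"], ["CD31"])

    def test_empty_denominator_raises(self):
        table = pd.DataFrame({"RFP": [False], "CD31": [False]})
        with pytest.raises(DegenerateInputError):
            sen.gating_fraction(table, ["RFP", "CD31"], ["CD31"])
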