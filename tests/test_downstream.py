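"""Clustering, enrichment statistics, PCA and reproducibility QC."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fiberlfq.downstream import (
    annotate_fraction,
    bh_fdr,
    fisher_enrichment,
    group_median_zscores,
    hierarchical_cluster,
    pca,
    reproducibility_correlation,
)
from fiberlfq.io import AnnotationMap

from conftest import make_design, make_log_matrix


def annotation(entries):
    return AnnotationMap(
        pd.DataFrame(entries, columns=["accession", "namespace", "term"])
    )


def complete_matrix(design, seed=0, n=20):
    rng = np.random.default_rng(seed)
    vals = pd.DataFrame(
        rng.normal(20, 2, size=(n, len(design.sample_ids))),
        index=[f"P{i}" for i in range(n)],
        columns=design.sample_ids,
    )
    return make_log_matrix(vals, design)


class TestGroupMedianZscores:
    def test_rows_are_standardised_before_medians(self, design5):
        m = complete_matrix(design5, seed=1)
        sub = m.values
        mu, sd = sub.mean(axis=1), sub.std(axis=1, ddof=0)
        z = sub.sub(mu, axis=0).div(sd, axis=0)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-12)
        out = group_median_zscores(m, list(m.values.index))
        for f, t in design5.groups:
            np.testing.assert_allclose(
                out[f"{f}_{t}"].to_numpy(),
                z[design5.samples_in(f, t)].median(axis=1).to_numpy(),
                rtol=1e-12,
            )

    def test_constant_rows_dropped_with_warning(self, design5):
        m = complete_matrix(design5, seed=2, n=3)
        vals = m.values.copy()
        vals.loc["P0"] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            out = group_median_zscores(make_log_matrix(vals, design5), ["P0", "P1"])
        assert list(out.index) == ["P1"]


class TestHierarchicalCluster:
    def _two_blocks(self, design, n_each=5, seed=3):
        rng = np.random.default_rng(seed)
        groups = [f"{f}_{t}" for f, t in design.groups]
        v = np.array([1.0, 1.0, -1.0, -1.0])
        rows = {}
        for i in range(n_each):
            rows[f"up{i}"] = v + rng.normal(0, 0.05, 4)
            rows[f"dn{i}"] = -v + rng.normal(0, 0.05, 4)
        return pd.DataFrame(rows, index=groups).T

    def test_opposite_profiles_split_perfectly(self, design5):
        z = self._two_blocks(design5)
        out = hierarchical_cluster(z, 2)
        ups = {out.labels[f"up{i}"] for i in range(5)}
        dns = {out.labels[f"dn{i}"] for i in range(5)}
        assert len(ups) == 1 and len(dns) == 1 and ups != dns
        assert set(out.labels) == {1, 2}

    def test_duplicated_rows_share_a_cluster(self, design5):
        z = self._two_blocks(design5)
        z.loc["up_copy"] = z.loc["up0"]
        out = hierarchical_cluster(z, 2)
        assert out.labels["up_copy"] == out.labels["up0"]

    def test_row_order_invariance(self, design5):
        z = self._two_blocks(design5)
        a = hierarchical_cluster(z, 2)
        b = hierarchical_cluster(z.iloc[::-1], 2)
        for pid in z.index:
            same_a = {q for q in z.index if a.labels[q] == a.labels[pid]}
            same_b = {q for q in z.index if b.labels[q] == b.labels[pid]}
            assert same_a == same_b

    def test_linkage_heights_match_bruteforce_average_linkage(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(6, 4))
        z = pd.DataFrame(x, index=[f"r{i}" for i in range(6)])
        out = hierarchical_cluster(z, 2)
        # brute-force average linkage on the Euclidean distance matrix
        clusters = {i: [i] for i in range(6)}
        dist = {
            (i, j): np.linalg.norm(x[i] - x[j])
            for i in range(6) for j in range(i + 1, 6)
        }

        def d(ca, cb):
            return np.mean([
                dist[(min(a, b), max(a, b))] for a in clusters[ca] for b in clusters[cb]
            ])

        heights = []
        nxt = 6
        while len(clusters) > 1:
            pairs = list(itertools.combinations(clusters, 2))
            ca, cb = min(pairs, key=lambda p: d(*p))
            heights.append(d(ca, cb))
            clusters[nxt] = clusters.pop(ca) + clusters.pop(cb)
            nxt += 1
        np.testing.assert_allclose(out.linkage[:, 2], heights, rtol=1e-10)

    def test_fewer_rows_than_clusters_rejected(self, design5):
        z = self._two_blocks(design5).iloc[:1]
        with pytest.raises(ValueError):
            hierarchical_cluster(z, 2)


def enum_two_sided(k, m, K, N):
    """Exhaustive hypergeometric enumeration of the two-sided Fisher p."""
    rv = stats.hypergeom(N, K, m)
    js = np.arange(max(0, m + K - N), min(m, K) + 1)
    pj = rv.pmf(js)
    return float(pj[pj <= rv.pmf(k) * (1 + 1e-10)].sum())


class TestFisherEnrichment:
    def _setup(self, n_bg=100, n_term=10, n_query=10, k=5):
        background = [f"P{i}" for i in range(n_bg)]
        term_members = background[:n_term]
        query = background[:k] + background[n_term:n_term + (n_query - k)]
        ann = annotation([(p, "GOBP", "path") for p in term_members])
        return query, background, ann

    def test_worked_example_matches_tail_enumeration(self):
        query, background, ann = self._setup()
        res = fisher_enrichment(query, background, ann).iloc[0]
        assert (res["k"], res["m"], res["K"], res["N"]) == (5, 10, 10, 100)
        one_sided = stats.hypergeom.sf(4, 100, 10, 10)
        assert one_sided == pytest.approx(6.716277482650502e-4, rel=1e-10)
        assert res["direction"] == "enriched"
        # two-sided p can be no smaller than the enrichment tail
        assert res["p"] >= one_sided
        assert res["p"] == pytest.approx(enum_two_sided(5, 10, 10, 100), abs=1e-12)

    def test_query_equals_background_is_never_enriched(self):
        _, background, ann = self._setup()
        res = fisher_enrichment(background, background, ann)
        assert (res["p"] == 1.0).all()

    def test_term_absent_from_background_not_tested(self):
        query, background, ann = self._setup()
        ann2 = annotation(
            list(ann.entries.itertuples(index=False))
            + [("ELSEWHERE", "KEGG", "ghost")]
        )
        res = fisher_enrichment(query, background, ann2)
        assert "ghost" not in set(res["term"])

    def test_query_outside_background_rejected(self):
        query, background, ann = self._setup()
        with pytest.raises(ValueError, match="subset"):
            fisher_enrichment(query + ["NOT_THERE"], background, ann)

    def test_matches_enumeration_on_exhaustive_small_tables(self):
        worst = 0.0
        for N in range(1, 31):
            for K in range(0, N + 1, 3):
                for m in range(0, N + 1, 2):
                    for k in range(max(0, m + K - N), min(m, K) + 1):
                        table = [[k, m - k], [K - k, N - m - K + k]]
                        p = stats.fisher_exact(table)[1]
                        worst = max(worst, abs(p - enum_two_sided(k, m, K, N)))
        assert worst < 1e-10


class TestBhFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.03]), [0.03])

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 5), [0.2] * 5)

    def test_hand_stepup_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_monotone_in_rank_and_never_below_p(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= p - 1e-15).all()
        assert (q <= 1.0).all()

    def test_against_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(6)
        p = rng.uniform(size=100)
        np.testing.assert_allclose(bh_fdr(p), sm.multipletests(p, method="fdr_bh")[1],
                                   rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestAnnotateFraction:
    def test_half_annotated(self):
        ann = annotation([("a", "GOCC", "mito"), ("b", "GOCC", "mito")])
        frac, empty = annotate_fraction({"a", "b", "c", "d"}, ann, "GOCC", "mito")
        assert frac == 0.5 and not empty

    def test_empty_set_flagged(self):
        ann = annotation([("a", "GOCC", "mito")])
        frac, empty = annotate_fraction(set(), ann, "GOCC", "mito")
        assert frac == 0.0 and empty

    def test_matches_manual_count(self):
        ids = [f"P{i}" for i in range(10)]
        ann = annotation([(p, "Keyword", "tag") for p in ids[::3]])
        frac, _ = annotate_fraction(ids, ann, "Keyword", "tag")
        assert frac == pytest.approx(len(ids[::3]) / 10)


class TestPca:
    def test_collinear_samples_put_all_variance_on_pc1(self, design5):
        base = np.linspace(0, 1, 20)
        vals = pd.DataFrame(
            np.outer(np.arange(1, 6), base) + 10.0,
            index=[f"P{i}" for i in range(5)],
            columns=design5.sample_ids,
        )
        res = pca(make_log_matrix(vals, design5))
        assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_variance_fractions_sum_to_one(self, design5):
        res = pca(complete_matrix(design5, seed=7))
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)
        assert ((res.variance_explained >= 0) & (res.variance_explained <= 1)).all()

    def test_matches_covariance_eigendecomposition(self):
        design = make_design(1, fibers=("slow", "fast"), times=("PRE", "POST"))
        rng = np.random.default_rng(8)
        vals = pd.DataFrame(
            rng.normal(size=(3, 4)), index=list("abc"), columns=design.sample_ids
        )
        res = pca(make_log_matrix(vals, design))
        x = vals.to_numpy()
        xc = (x - x.mean(axis=1, keepdims=True)).T
        evals = np.sort(np.linalg.eigvalsh(xc.T @ xc))[::-1]
        np.testing.assert_allclose(
            res.variance_explained, evals[: len(res.variance_explained)] / evals.sum(),
            atol=1e-12,
        )
        # scores reproduce the centred data through the loadings
        np.testing.assert_allclose(
            res.scores.to_numpy() @ res.loadings.to_numpy().T, xc, atol=1e-10
        )

    def test_missing_cells_rejected(self, design5):
        m = complete_matrix(design5, seed=9)
        vals = m.values.copy()
        vals.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="imput"):
            pca(make_log_matrix(vals, design5))


class TestReproducibility:
    def test_duplicated_and_negated_samples(self):
        design = make_design(3, fibers=("slow",), times=("PRE",))
        rng = np.random.default_rng(10)
        base = rng.normal(20, 2, size=50)
        vals = pd.DataFrame(
            {
                design.sample_ids[0]: base,
                design.sample_ids[1]: base,
                design.sample_ids[2]: -base,
            },
            index=[f"P{i}" for i in range(50)],
        )
        res = reproducibility_correlation(make_log_matrix(vals, design))
        r = res.r_matrix
        assert r.iloc[0, 1] == pytest.approx(1.0)
        assert r.iloc[0, 2] == pytest.approx(-1.0)

    def test_median_is_middle_pairwise_r(self):
        design = make_design(3, fibers=("slow",), times=("PRE",))
        rng = np.random.default_rng(11)
        vals = pd.DataFrame(
            rng.normal(20, 2, size=(100, 3)),
            index=[f"P{i}" for i in range(100)],
            columns=design.sample_ids,
        )
        m = make_log_matrix(vals, design)
        res = reproducibility_correlation(m)
        pairs = [
            m.values.iloc[:, a].corr(m.values.iloc[:, b])
            for a, b in [(0, 1), (0, 2), (1, 2)]
        ]
        assert res.median_overall == pytest.approx(sorted(pairs)[1], rel=1e-12)

    def test_insufficient_shared_observations_give_nan(self):
        design = make_design(2, fibers=("slow",), times=("PRE",))
        vals = pd.DataFrame(
            {
                design.sample_ids[0]: [1.0, 2.0, np.nan, np.nan, 5.0],
                design.sample_ids[1]: [np.nan, 2.5, 3.0, 4.0, np.nan],
            },
            index=[f"P{i}" for i in range(5)],
        )
        res = reproducibility_correlation(make_log_matrix(vals, design))
        assert np.isnan(res.r_matrix.iloc[0, 1])
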