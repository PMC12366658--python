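import numpy as np
import pandas as pd
import pytest
from scipy import stats

import chimeradecomp as cd
from chimeradecomp.enrichment import (
    _running_sum_es,
    log2_fold_enrichment,
    preranked_enrichment,
    rank_list,
    read_gmt,
    symmetric_rank_transform,
    write_gmt,
)


def brute_force_es(scores, in_set, weight):
    """Independent oracle: literal position-by-position running sum."""
    n = len(scores)
    k = int(np.sum(in_set))
    wts = [abs(s) ** weight if h else 0.0 for s, h in zip(scores, in_set)]
    nr = sum(wts)
    cum, trace = 0.0, []
    for i in range(n):
        cum += wts[i] / nr if in_set[i] else -1.0 / (n - k)
        trace.append(cum)
    best = max(range(n), key=lambda i: abs(trace[i]))
    return trace[best], best


class TestRunningSum:
    def test_matches_brute_force_on_small_lists(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            n = int(rng.integers(4, 13))
            scores = np.sort(rng.normal(0, 2, n))[::-1]
            k = int(rng.integers(1, n))
            in_set = np.zeros(n, dtype=bool)
            in_set[rng.choice(n, k, replace=False)] = True
            for weight in (0.0, 1.0, 1.5):
                es_bf, pos_bf = brute_force_es(scores, in_set, weight)
                es, pos = _running_sum_es(scores, in_set, weight)
                assert abs(es) == pytest.approx(abs(es_bf), abs=1e-9)
                # sign and position are only defined when the extremum is
                # unique; skip float-level ties between +/- peaks
                if abs(abs(es) - abs(es_bf)) < 1e-9 and np.sign(es) == np.sign(es_bf):
                    assert pos == pos_bf

    def test_unweighted_top_k_set_reaches_one(self):
        scores = np.linspace(5, -5, 50)
        in_set = np.zeros(50, dtype=bool)
        in_set[:7] = True
        es, pos = _running_sum_es(scores, in_set, weight=0.0)
        assert es == pytest.approx(1.0)
        assert pos == 6  # peak right after the k-th gene

    def test_complement_antisymmetry_unweighted(self):
        # on score-free ranks, the complement's deviation mirrors the set's
        scores = np.ones(12)
        in_set = np.zeros(12, dtype=bool)
        in_set[[0, 3, 4, 7]] = True
        es_set, _ = _running_sum_es(scores, in_set, weight=0.0)
        # P_hit(set) - P_miss(set) = -(P_hit(complement) - P_miss(complement))
        es_comp, _ = _running_sum_es(scores, ~in_set, weight=0.0)
        assert es_set == pytest.approx(-es_comp, abs=1e-12)


class TestPreranked:
    def test_planted_set_detected(self, rng):
        vals = pd.Series(rng.normal(0, 1, 1000), index=[f"g{i}" for i in range(1000)])
        hot = list(vals.nlargest(30).index)
        res = preranked_enrichment(rank_list(vals), {"hot": hot}, n_perm=500, seed=6)
        assert res.loc["hot", "es"] > 0.9
        assert res.loc["hot", "p"] < 0.01
        assert res.loc["hot", "fdr"] < 0.05

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(123)
        vals = pd.Series(rng.normal(0, 1, 400), index=[f"g{i}" for i in range(400)])
        sets = {
            f"null{i}": [f"g{j}" for j in rng.choice(400, 20, replace=False)]
            for i in range(200)
        }
        res = preranked_enrichment(rank_list(vals), sets, n_perm=1000, seed=6)
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_size_window_filters_sets(self, rng):
        vals = pd.Series(rng.normal(0, 1, 100), index=[f"g{i}" for i in range(100)])
        sets = {"tiny": ["g1", "g2"], "ok": [f"g{i}" for i in range(20)],
                "huge": [f"g{i}" for i in range(90)]}
        res = preranked_enrichment(rank_list(vals), sets, n_perm=50, min_size=10, max_size=50)
        assert list(res.index) == ["ok"]

    def test_matches_external_preranked_es(self):
        """The in-house ES agrees exactly with an independent preranked
        implementation (gseapy) on a random instance."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(3)
        vals = pd.Series(rng.normal(0, 1, 300), index=[f"G{i}" for i in range(300)])
        sets = {
            "S1": [f"G{i}" for i in rng.choice(300, 25, replace=False)],
            "S2": list(vals.nlargest(20).index),
        }
        ranked = rank_list(vals)
        mine = preranked_enrichment(ranked, sets, n_perm=10, seed=6)
        ext = gseapy.prerank(
            rnk=pd.DataFrame({"gene": ranked.index, "score": ranked.to_numpy()}),
            gene_sets=sets, permutation_num=10, seed=6, min_size=5, max_size=500,
            outdir=None, no_plot=True, threads=1,
        ).res2d.set_index("Term")
        for name in sets:
            assert mine.loc[name, "es"] == pytest.approx(float(ext.loc[name, "ES"]), abs=1e-9)

    def test_errors(self, rng):
        vals = pd.Series(rng.normal(0, 1, 50), index=[f"g{i}" for i in range(50)])
        with pytest.raises(ValueError, match="n_perm"):
            preranked_enrichment(rank_list(vals), {"s": ["g1"]}, n_perm=0)
        with pytest.raises(ValueError, match="empty"):
            preranked_enrichment(pd.Series(dtype=float), {"s": ["g1"]})


class TestSymmetricRankTransform:
    def test_worked_example_5000_genes(self, rng):
        vals = pd.Series(rng.permutation(np.arange(5000, dtype=float)),
                         index=[f"g{i:05d}" for i in range(5000)])
        t = symmetric_rank_transform(vals)
        assert t.iloc[0] == 2500 and t.iloc[1] == 2499
        assert t.iloc[-1] == -2500 and t.iloc[-2] == -2499
        # the top value belongs to the gene with the largest input
        assert t.index[0] == vals.idxmax()

    def test_four_genes_mirror_skipping_zero(self):
        t = symmetric_rank_transform(pd.Series([10.0, 7, 3, 1], index=list("abcd")))
        assert t.tolist() == [2.0, 1.0, -1.0, -2.0]

    def test_odd_function_of_rank_position(self):
        t = symmetric_rank_transform(
            pd.Series(np.arange(20, dtype=float), index=[f"g{i}" for i in range(20)])
        ).to_numpy()
        n = len(t)
        for i in range(n // 2):
            assert t[i] == -t[n - 1 - i]

    def test_tie_break_is_lexicographic_and_deterministic(self):
        vals = pd.Series([1.0, 1.0, 1.0, 0.0], index=["b", "a", "c", "d"])
        t1 = symmetric_rank_transform(vals)
        t2 = symmetric_rank_transform(vals)
        assert list(t1.index[:3]) == ["a", "b", "c"]
        pd.testing.assert_series_equal(t1, t2)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            symmetric_rank_transform(pd.Series([1.0, -0.1], index=["a", "b"]))


class TestLog2FoldEnrichment:
    def _ranked(self, n=5000):
        return pd.Series(np.linspace(10, -10, n), index=[f"g{i}" for i in range(n)])

    def test_worked_example(self):
        ranked = self._ranked()
        hits = [f"g{i}" for i in range(15)]  # 15 in top 500, none in bottom
        assert log2_fold_enrichment(ranked, hits, 500) == pytest.approx(4.0)

    def test_absent_and_balanced_sets_give_zero(self):
        ranked = self._ranked(100)
        assert log2_fold_enrichment(ranked, ["nope"], 20) == 0.0
        balanced = ["g0", "g1", "g98", "g99"]
        assert log2_fold_enrichment(ranked, balanced, 20) == 0.0

    def test_negative_direction_swaps_tails(self):
        ranked = self._ranked(100)
        bottom_set = [f"g{i}" for i in range(90, 100)]
        assert log2_fold_enrichment(ranked, bottom_set, 10, direction="negative") > 0

    def test_cutoff_validation(self):
        ranked = self._ranked(100)
        with pytest.raises(ValueError, match="cutoff_rank"):
            log2_fold_enrichment(ranked, ["g0"], 0)
        with pytest.raises(ValueError, match="half"):
            log2_fold_enrichment(ranked, ["g0"], 51)


class TestTFPropagation:
    def test_perfect_and_reversed(self):
        ct = {f"ct{i}": float(i) for i in range(10)}
        rho, p, n = cd.tf_propagation_correlation(ct, ct)
        assert rho == pytest.approx(1.0) and n == 10
        rev = {k: -v for k, v in ct.items()}
        rho, _, _ = cd.tf_propagation_correlation(ct, rev)
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_correlation_oracle(self, rng):
        tf = {f"ct{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 10))}
        enr = {k: 2 * v + rng.normal(0, 0.5) for k, v in tf.items()}
        rho, p, n = cd.tf_propagation_correlation(tf, enr)
        # oracle: Pearson correlation of the rank vectors
        a = pd.Series(tf).rank().to_numpy()
        b = pd.Series(enr).rank().to_numpy()
        oracle = np.corrcoef(a, b)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_too_few_shared_cell_types(self):
        with pytest.raises(ValueError, match="3 shared"):
            cd.tf_propagation_correlation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})


class TestImprintedInteraction:
    def _decomp_with_planted_n(self, seed=0, n_genes=600, n_imprinted=40, n_mag=1.5):
        rng = np.random.default_rng(seed)
        # null genes: small noise-driven N; imprinted genes: planted mismatch effect
        n_vals = rng.normal(0, 0.05, n_genes)
        signed = np.zeros(n_genes)
        n_vals[-n_imprinted:] = -n_mag  # mismatch-higher => framework N negative
        genes = [f"g{i:04d}" for i in range(n_genes)]
        df = pd.DataFrame({"N": n_vals}, index=genes)
        mags = np.abs(n_vals) + 0.3  # pretend |I|+|E| ~ 0.3
        df["signed_Np"] = np.sign(n_vals) * np.abs(n_vals) / mags
        return df, genes[-n_imprinted:]

    def test_absolute_mode_detects_planted_interaction(self):
        df, imprinted = self._decomp_with_planted_n()
        res = cd.imprinted_interaction_test(df, imprinted, mode="absolute", n_perm=500)
        assert res.fdr < 0.05 and res.es > 0

    def test_signed_mode_orientation(self):
        # mismatch-upregulated genes enrich at the positive (mismatched) end
        df, imprinted = self._decomp_with_planted_n()
        res = cd.imprinted_interaction_test(df, imprinted, mode="signed", n_perm=500)
        assert res.es > 0 and res.p < 0.01

    def test_null_interaction_is_not_enriched(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(500)]
        df = pd.DataFrame({"N": rng.normal(0, 0.05, 500)}, index=genes)
        df["signed_Np"] = np.sign(df["N"]) * 0.1
        imprinted = [genes[i] for i in rng.choice(500, 30, replace=False)]
        res = cd.imprinted_interaction_test(df, imprinted, mode="absolute", n_perm=500)
        assert res.p > 0.05 and abs(res.es) < 0.5

    def test_empty_intersection_error(self):
        df = pd.DataFrame({"N": [1.0], "signed_Np": [0.5]}, index=["g1"])
        with pytest.raises(ValueError, match="intersect"):
            cd.imprinted_interaction_test(df, ["absent"], mode="absolute")


def test_rank_list_rejects_duplicates_and_nan():
    with pytest.raises(ValueError, match="duplicate"):
        rank_list(pd.Series([1.0, 2.0], index=["a", "a"]))
    with pytest.raises(ValueError, match="NaN"):
        rank_list(pd.Series([1.0, np.nan], index=["a", "b"]))


def test_gmt_roundtrip(tmp_path):
    sets = {"setA": ["g1", "g2", "g3"], "setB": ["g9"]}
    path = tmp_path / "sets.gmt"
    write_gmt(sets, path)
    assert read_gmt(path) == sets
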