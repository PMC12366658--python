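import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import chimeradecomp as cd


class TestRatioDecompose:
    def test_equal_ratios_no_divergence(self):
        res = cd.ratio_decompose({c: (40, 20) for c in ("HM", "HR", "DM", "DR")})
        assert res.I == res.E == res.N == 0

    def test_pure_intrinsic_tempo_difference(self):
        # mouse cells make more neurons than progenitors in either environment
        res = cd.ratio_decompose(
            {"HM": (80, 20), "DM": (80, 20), "HR": (20, 20), "DR": (20, 20)}
        )
        assert res.Ip == pytest.approx(1.0)
        assert res.I == pytest.approx(-2.0)  # rat-minus-mouse convention

    def test_mixed_equals_plain_decompose(self):
        counts = {"HM": (40, 10), "DM": (10, 10), "HR": (10, 10), "DR": (40, 10)}
        res = cd.ratio_decompose(counts)
        oracle = cd.decompose({"HM": 4.0, "DM": 1.0, "HR": 1.0, "DR": 4.0})
        for col in ("I1", "I2", "E1", "E2", "I", "E", "N", "Ip", "Ep", "Np"):
            assert getattr(res, col) == pytest.approx(getattr(oracle, col), abs=1e-12)

    def test_zero_denominator_names_combination(self):
        with pytest.raises(ValueError, match="DM"):
            cd.ratio_decompose({"HM": (1, 1), "HR": (1, 1), "DM": (1, 0), "DR": (1, 1)})

    def test_inherits_proportion_identity(self):
        res = cd.ratio_decompose({"HM": (30, 10), "HR": (10, 15), "DM": (22, 9), "DR": (40, 13)})
        assert res.Ip + res.Ep + res.Np == pytest.approx(1.0)


class TestTau:
    @pytest.mark.parametrize(
        "x, expected",
        [((5, 0, 0, 0), 1.0), ((3, 3, 3), 0.0), ((1, 0.5, 0), 0.75)],
    )
    def test_known_values(self, x, expected):
        assert cd.tau(x) == pytest.approx(expected)

    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=2, max_size=12),
           st.floats(min_value=0.01, max_value=100))
    def test_scale_invariance(self, x, c):
        if max(x) <= 0:
            return
        assert cd.tau([c * v for v in x]) == pytest.approx(cd.tau(x), abs=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            cd.tau([0, 0, 0])
        with pytest.raises(ValueError, match="2 cell types"):
            cd.tau([1.0])
        with pytest.raises(ValueError, match="non-negative"):
            cd.tau([1.0, -1.0])


class TestPredictorCorrelations:
    def _decomp(self, rng, n=200):
        vals = 2.0 ** rng.normal(0, 2, (n, 4))
        df = pd.DataFrame(vals, columns=["HM", "HR", "DM", "DR"],
                          index=[f"g{i}" for i in range(n)])
        return cd.decompose_table(df)

    def test_self_covariate_gives_rho_one(self, rng):
        dec = self._decomp(rng)
        cov = pd.DataFrame({"self": dec["Ip"] - dec["Ep"]})
        res = cd.predictor_correlations(dec, cov)
        assert res.loc["self", "rho"] == pytest.approx(1.0)

    def test_constant_covariate_is_nan(self, rng):
        dec = self._decomp(rng)
        cov = pd.DataFrame({"const": 1.0}, index=dec.index)
        res = cd.predictor_correlations(dec, cov)
        assert np.isnan(res.loc["const", "rho"])

    def test_independent_covariate_null_p_uniform(self):
        rng = np.random.default_rng(31)
        pvals = []
        for rep in range(60):
            dec = self._decomp(rng, n=150)
            cov = pd.DataFrame({"noise": rng.normal(0, 1, len(dec))}, index=dec.index)
            pvals.append(cd.predictor_correlations(dec, cov).loc["noise", "p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_join_policies_and_errors(self, rng):
        dec = self._decomp(rng, n=60)
        cov = pd.DataFrame(
            {"a": np.arange(60, dtype=float), "b": np.arange(60, dtype=float)},
            index=dec.index,
        )
        cov.loc[cov.index[:30], "b"] = np.nan
        complete = cd.predictor_correlations(dec, cov, join="complete")
        pairwise = cd.predictor_correlations(dec, cov, join="pairwise")
        assert complete.loc["a", "n"] <= pairwise.loc["a", "n"]
        with pytest.raises(ValueError, match="overlap"):
            cd.predictor_correlations(dec, pd.DataFrame({"x": [1.0]}, index=["absent"]))


class TestClassifyDynamics:
    def test_threshold_reading_product_between_cutoffs(self):
        # correlation product ~0.5 sits between -0.25 and 0.7 -> unclassified
        tc = pd.DataFrame(
            {
                "mouse_t0": [1.0], "mouse_t1": [2.0], "mouse_t2": [4.0],
                "rat_t0": [1.0], "rat_t1": [3.0], "rat_t2": [1.5],
            },
            index=["g"],
        )
        res = cd.classify_dynamics(tc, timepoints=("t0", "t1", "t2"))
        prod = res.loc["g", "r_mouse"] * res.loc["g", "r_rat"]
        assert -0.25 <= prod <= 0.7
        assert res.loc["g", "dynamics_class"] == "unclassified"

    def test_classes_mutually_exclusive_and_shift_subset_of_similar(self):
        table, _ = cd.generate_timecourse_table(300, seed=5)
        res = cd.classify_dynamics(table)
        shift = res["dynamics_class"] == "temporal_shift"
        assert res.loc[shift, "is_similar"].all()
        assert set(res["dynamics_class"]) <= {
            "similar", "opposite", "temporal_shift", "unclassified"
        }

    def test_direction_flags(self):
        tc = pd.DataFrame(
            {
                "mouse_t0": [1.0, 4.0], "mouse_t1": [2.0, 2.0], "mouse_t2": [4.0, 1.0],
                "rat_t0": [2.0, 8.0], "rat_t1": [4.0, 4.0], "rat_t2": [8.0, 2.0],
            },
            index=["up", "down"],
        )
        res = cd.classify_dynamics(tc, timepoints=("t0", "t1", "t2"))
        assert res.loc["up", "direction"] == "increasing"
        assert res.loc["down", "direction"] == "decreasing"
        assert res.loc["up", "higher_in_rat"].item() and not res.loc["up", "higher_in_mouse"].item()

    def test_too_few_stages(self):
        tc = pd.DataFrame({"mouse_t0": [1.0], "mouse_t1": [2.0],
                           "rat_t0": [1.0], "rat_t1": [2.0]})
        with pytest.raises(ValueError, match="3 timepoints"):
            cd.classify_dynamics(tc, timepoints=("t0", "t1"))


class TestImprintedBulkWorkflow:
    def _table(self, rng, n_genes=30, planted=("g0", "g1", "g2")):
        genes = [f"g{i}" for i in range(n_genes)]
        samples = [f"mm{i}" for i in range(3)] + [f"m{i}" for i in range(3)] + [f"wt{i}" for i in range(3)]
        conditions = {s: ("mismatched" if s.startswith("mm") else
                          "matched" if s.startswith("m") else "wildtype")
                      for s in samples}
        base = rng.uniform(10, 100, n_genes)
        tpm = pd.DataFrame(
            base + rng.normal(0, 1, (9, n_genes)), index=samples, columns=genes
        ).clip(lower=0.1)
        for g in planted:  # imprinting collapse in mismatched samples
            tpm.loc[[s for s in samples if s.startswith("mm")], g] = 0.5
        return tpm, conditions

    def test_floor_removes_low_genes_in_all_conditions(self, rng):
        tpm, cond = self._table(rng)
        tpm["low"] = 4.0
        res = cd.imprinted_bulk_workflow(tpm, cond, imprinted=list(tpm.columns))
        assert "low" not in res.medians.index

    def test_flagging_by_median_ratio(self, rng):
        tpm, cond = self._table(rng, planted=())
        tpm["hit"] = 10.0
        tpm.loc[[s for s in tpm.index if s.startswith("mm")], "hit"] = 2.4
        res = cd.imprinted_bulk_workflow(tpm, cond, imprinted=["hit", "g5"])
        assert "hit" in res.flagged_genes  # |log2(2.4/10)| ~ 2.06 > 1
        assert "g5" not in res.flagged_genes

    def test_mismatched_samples_cluster_together(self, rng):
        tpm, cond = self._table(rng, planted=tuple(f"g{i}" for i in range(10)))
        res = cd.imprinted_bulk_workflow(tpm, cond, imprinted=[f"g{i}" for i in range(10)])
        order = res.sample_order
        pos = [i for i, s in enumerate(order) if s.startswith("mm")]
        assert max(pos) - min(pos) == len(pos) - 1  # contiguous block

    def test_sample_order_permutation_invariant(self, rng):
        tpm, cond = self._table(rng, planted=tuple(f"g{i}" for i in range(10)))
        res1 = cd.imprinted_bulk_workflow(tpm, cond, imprinted=list(tpm.columns))
        shuffled = tpm.sample(frac=1, random_state=1)
        res2 = cd.imprinted_bulk_workflow(shuffled, cond, imprinted=list(tpm.columns))
        assert res1.sample_order == res2.sample_order

    def test_empty_condition_error(self, rng):
        tpm, cond = self._table(rng)
        cond = {s: ("matched" if c == "mismatched" else c) for s, c in cond.items()}
        with pytest.raises(ValueError, match="mismatched"):
            cd.imprinted_bulk_workflow(tpm, cond, imprinted=list(tpm.columns))


class TestMarkerGate:
    def test_boundary_is_strict(self):
        cell = pd.Series({"NANOG": 1.0, "SOX2": 1.0, "POU5F1": 1.0})
        assert not cd.marker_gate(cell, ["NANOG", "SOX2", "POU5F1"])

    def test_single_marker_above(self):
        cell = pd.Series({"NANOG": 0.0, "SOX2": 2.0, "POU5F1": 0.5})
        assert cd.marker_gate(cell, ["NANOG", "SOX2", "POU5F1"])

    def test_empty_marker_list_error(self):
        with pytest.raises(ValueError, match="empty"):
            cd.marker_gate(pd.Series({"NANOG": 2.0}), [])

    def test_pseudo_tpm_log2fc(self):
        tpm = pd.DataFrame(
            {"a": [99.0, 0.5], "b": [9.0, 0.2]}, index=["expressed", "silent"]
        )
        from chimeradecomp.traits import pseudo_tpm_log2fc

        lfc = pseudo_tpm_log2fc(tpm, "a", "b")
        assert lfc.loc["expressed"] == pytest.approx(np.log2(100 / 10))
        assert "silent" not in lfc.index  # below 1 TPM in all categories
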