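"""Shift statistics, rank-sum inference, ECDFs, set derivation, Z-scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oracles import brute_force_ranksum_p
from sarcoquant.errors import GeneSetError, ValidationError
from sarcoquant.geneset import (
    GeneSet, LfcTable, compute_ecdf, compute_shift, derive_invivo_sets,
    filter_expressed, run_shift_panel, wilcoxon_shift_test, zscore_vs_group,
)
from sarcoquant.synthetic import LfcSimConfig, simulate_lfc_table


def _table(lfcs, label="t", prefix="g"):
    n = len(lfcs)
    return LfcTable(
        pd.DataFrame({"gene_id": [f"{prefix}{i}" for i in range(n)],
                      "lfc": lfcs, "qval": [0.5] * n}),
        comparison_label=label,
    )


class TestComputeShift:
    def test_explicit_medians_all_genes_background(self):
        table = _table([-0.1, 0.0, 0.1, 0.2, 0.3, 0.4, 0.5])
        gs = GeneSet("top", frozenset(["g4", "g5", "g6"]))  # lfc .3, .4, .5
        res = compute_shift(table, gs, "all_genes")
        assert res.statistic == pytest.approx(0.4 - 0.2)
        assert res.n_set == 3 and res.n_background == 7

    def test_set_equal_to_table_is_zero(self):
        table = _table([0.1, 0.9, -0.3, 0.4])
        gs = GeneSet("all", frozenset(table.data["gene_id"]))
        res = compute_shift(table, gs, "all_genes")
        assert res.statistic == 0.0

    def test_complement_background(self):
        table = _table([-0.1, 0.0, 0.1, 0.2, 0.3, 0.4, 0.5])
        gs = GeneSet("top", frozenset(["g4", "g5", "g6"]))
        res = compute_shift(table, gs, "complement")
        assert res.statistic == pytest.approx(0.4 - 0.05)
        assert res.n_background == 4

    def test_absent_set_genes_dropped_and_counted(self):
        table = _table([0.1, 0.2, 0.3])
        gs = GeneSet("s", frozenset(["g0", "g1", "missing1", "missing2"]))
        res = compute_shift(table, gs)
        assert res.n_set == 2 and res.n_dropped == 2

    def test_no_set_genes_in_table_rejected(self):
        with pytest.raises(GeneSetError):
            compute_shift(_table([0.1, 0.2]), GeneSet("s", frozenset(["x"])))

    def test_shift_invariance_global_constant(self):
        table = _table(list(np.linspace(-1, 1, 101)))
        gs = GeneSet("s", frozenset([f"g{i}" for i in range(80, 101)]))
        base = compute_shift(table, gs).statistic
        shifted = _table(list(np.linspace(-1, 1, 101) + 5.0))
        assert compute_shift(shifted, gs).statistic == pytest.approx(base)

    def test_shift_of_set_only_moves_statistic_by_c(self):
        rng = np.random.default_rng(0)
        lfcs = rng.normal(0, 0.3, 2000)
        table = _table(list(lfcs))
        set_ids = [f"g{i}" for i in range(100)]
        gs = GeneSet("s", frozenset(set_ids))
        c = 0.7
        lfcs2 = lfcs.copy()
        lfcs2[:100] += c
        shifted = _table(list(lfcs2))
        # exact under the complement background; near-exact for all-genes
        d_comp = (compute_shift(shifted, gs, "complement").statistic
                  - compute_shift(table, gs, "complement").statistic)
        assert d_comp == pytest.approx(c)
        d_all = (compute_shift(shifted, gs, "all_genes").statistic
                 - compute_shift(table, gs, "all_genes").statistic)
        assert d_all == pytest.approx(c, abs=0.05)

    def test_background_modes_agree_for_small_sets(self):
        # at 1% set fraction the two background definitions nearly coincide
        table, sets = simulate_lfc_table(
            LfcSimConfig(9900, {"s": 100}, 0.3, 0.3, seed=4))
        a = compute_shift(table, sets["s"], "all_genes").statistic
        b = compute_shift(table, sets["s"], "complement").statistic
        assert abs(a - b) < 0.01


class TestWilcoxon:
    def test_exact_small_sample(self):
        assert wilcoxon_shift_test([4, 5, 6], [1, 2, 3]) == pytest.approx(0.1)

    def test_single_pair_p_one(self):
        assert wilcoxon_shift_test([1], [2]) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_shift_test([], [1.0])

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(20):
            n, m = rng.integers(2, 5, 2)
            x = rng.normal(0, 1, n)
            y = rng.normal(0.5, 1, m)
            assert wilcoxon_shift_test(x, y) == pytest.approx(
                brute_force_ranksum_p(x, y), abs=1e-12)

    def test_matches_scipy_exact_and_asymptotic(self, rng):
        for _ in range(25):
            n, m = rng.integers(2, 12, 2)
            x, y = rng.normal(0, 1, n), rng.normal(0.3, 1, m)
            ref = stats.mannwhitneyu(x, y, method="exact").pvalue
            assert wilcoxon_shift_test(x, y) == pytest.approx(ref, abs=1e-12)
        for _ in range(25):
            x = np.round(rng.normal(0, 1, 40), 1)  # ties force the z branch
            y = np.round(rng.normal(0.3, 1, 50), 1)
            ref = stats.mannwhitneyu(
                x, y, method="asymptotic", use_continuity=True).pvalue
            assert wilcoxon_shift_test(x, y) == pytest.approx(ref, abs=1e-12)

    def test_type_one_error_rate(self, rng):
        rej = sum(
            wilcoxon_shift_test(rng.normal(0, 1, 200), rng.normal(0, 1, 200)) < 0.05
            for _ in range(2000)
        )
        assert 0.03 <= rej / 2000 <= 0.07

    def test_power_monotone_in_planted_shift(self):
        deltas = (0.0, 0.1, 0.3, 1.0)
        rates = []
        for delta in deltas:
            rej = 0
            for seed in range(200):
                table, sets = simulate_lfc_table(
                    LfcSimConfig(1000, {"s": 50}, delta, 0.3,
                                 seed=seed + int(delta * 10000)))
                if compute_shift(table, sets["s"]).wilcoxon_p < 0.05:
                    rej += 1
            rates.append(rej / 200)
        assert all(a <= b + 1e-9 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > 0.9  # delta = 1 is essentially always detected


class TestEcdf:
    def test_step_values(self):
        e = compute_ecdf([1.0, 2.0, 3.0])
        assert e(2.0) == pytest.approx(2 / 3)
        assert e(3.0) == 1.0
        assert e(1.0 - 1e-9) == 0.0

    def test_right_continuity_with_duplicates(self):
        e = compute_ecdf([1, 1, 2])
        assert e(1.0) == pytest.approx(2 / 3)
        assert e(1.5) == pytest.approx(2 / 3)

    def test_fractions_monotone_end_at_one(self, rng):
        e = compute_ecdf(rng.normal(0, 1, 137))
        assert (np.diff(e.fractions) > 0).all()
        assert e.fractions[-1] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            compute_ecdf([])


class TestDeriveInvivoSets:
    def test_toy_counts(self):
        df = pd.DataFrame({
            "gene_id": list("abcdef"),
            "lfc": [1.0, 2.0, 0.5, -1.0, -0.2, 3.0],
            "qval": [0.01, 0.01, 0.01, 0.01, 0.01, 0.5],
        })
        up, down = derive_invivo_sets(LfcTable(df))
        assert (len(up), len(down)) == (3, 2)
        assert "f" not in up.gene_ids  # not significant

    def test_zero_lfc_in_neither(self):
        df = pd.DataFrame({"gene_id": ["a"], "lfc": [0.0], "qval": [0.001]})
        up, down = derive_invivo_sets(LfcTable(df))
        assert len(up) == 0 and len(down) == 0

    def test_zero_threshold_empty(self):
        df = pd.DataFrame({"gene_id": ["a"], "lfc": [1.0], "qval": [0.0]})
        up, down = derive_invivo_sets(LfcTable(df), q_threshold=0.0)
        assert len(up) == 0 and len(down) == 0


class TestFilterExpressed:
    def test_all_zero_matrix_empty(self):
        tpm = pd.DataFrame(np.zeros((3, 2)), index=["a", "b", "c"])
        out = filter_expressed(GeneSet("s", frozenset("abc")), tpm)
        assert len(out) == 0

    def test_zero_threshold_keeps_present_genes(self):
        tpm = pd.DataFrame(np.zeros((2, 2)), index=["a", "b"])
        out = filter_expressed(GeneSet("s", frozenset(["a", "b", "zz"])), tpm,
                               min_tpm=0.0)
        assert out.gene_ids == frozenset(["a", "b"])

    def test_min_samples(self):
        tpm = pd.DataFrame([[5.0, 0.0], [5.0, 5.0]], index=["a", "b"])
        out = filter_expressed(GeneSet("s", frozenset(["a", "b"])), tpm,
                               min_tpm=1.0, min_samples=2)
        assert out.gene_ids == frozenset(["b"])


class TestZScore:
    def test_value_at_mean(self):
        r = zscore_vs_group(2.0, [1, 2, 3])
        assert r.z == 0.0 and r.p == pytest.approx(1.0)

    def test_closed_form(self):
        r = zscore_vs_group(4.0, [1, 2, 3])
        assert r.z == pytest.approx(2.0)
        assert r.p == pytest.approx(2 * stats.norm.sf(2.0), abs=1e-12)
        assert r.group_sd == pytest.approx(1.0)

    def test_sign_symmetry(self):
        r_hi = zscore_vs_group(4.0, [1, 2, 3])
        r_lo = zscore_vs_group(0.0, [1, 2, 3])
        assert r_lo.z == pytest.approx(-r_hi.z)
        assert r_lo.p == pytest.approx(r_hi.p)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValidationError):
            zscore_vs_group(1.0, [2.0])
        with pytest.raises(ValidationError):
            zscore_vs_group(1.0, [2.0, 2.0])


class TestShiftPanel:
    def test_grid_shape_and_order(self):
        t1 = _table([0.1, 0.2, 0.3], label="b")
        t2 = _table([0.4, 0.5, 0.6], label="a")
        s1 = GeneSet("z", frozenset(["g0"]))
        s2 = GeneSet("a", frozenset(["g1"]))
        panel = run_shift_panel([t1, t2], [s1, s2])
        assert len(panel) == 4
        assert list(panel["comparison"]) == ["a", "a", "b", "b"]
        assert list(panel["set"]) == ["a", "z", "a", "z"]

    def test_missing_cell_flagged_not_fatal(self):
        t1 = _table([0.1, 0.2], label="t1")
        s_ok = GeneSet("ok", frozenset(["g0"]))
        s_missing = GeneSet("gone", frozenset(["nope"]))
        panel = run_shift_panel([t1], [s_ok, s_missing])
        by_set = panel.set_index("set")
        assert by_set.loc["ok", "status"] == "ok"
        assert by_set.loc["gone", "status"] == "missing"
        assert np.isnan(by_set.loc["gone", "statistic"])

    def test_planted_deltas_recovered(self):
        stats_ = {}
        for seed in range(30):
            table, sets = simulate_lfc_table(LfcSimConfig(
                3000, {"s1": 100, "s2": 100}, {"s1": 0.2, "s2": 0.8},
                sigma=0.3, seed=seed))
            # complement background: with two shifted sets in one table, the
            # all-genes median itself moves, so only the complement version
            # is an unbiased estimate of the planted deltas
            panel = run_shift_panel([table], list(sets.values()), "complement")
            for _, row in panel.iterrows():
                stats_.setdefault(row["set"], []).append(row["statistic"])
        assert np.mean(stats_["s1"]) == pytest.approx(0.2, abs=0.02)
        assert np.mean(stats_["s2"]) == pytest.approx(0.8, abs=0.02)
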