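"""Differential-methylation statistics: tests against enumeration and
direct-formula oracles, plus calibration/power simulations with planted truth.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methref import (
    BetaMatrix,
    MethylationCall,
    Parameters,
    bh_fdr,
    call_dmcs,
    compare_probe_groups,
    mann_whitney_u,
    matrix_mann_whitney,
    permutation_fdr_threshold,
    platform_abs_diff,
    replicate_sd,
)
from methref.simulate import MethylationConfig, generate_methylation_dataset


def _enumeration_p(x, y):
    """Two-sided MW p by exhaustive enumeration of label assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    mu = n1 * len(y) / 2

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2

    obs = abs(u_of(range(n1)) - mu)
    hits = sum(
        abs(u_of(c) - mu) >= obs - 1e-12
        for c in itertools.combinations(range(len(pooled)), n1)
    )
    return hits / math.comb(len(pooled), n1)


class TestMannWhitney:
    def test_exact_branch_worked_example(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0 and p == pytest.approx(2 / 6)

    def test_identical_groups_p_one(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_all_tied_flagged_p_one(self, caplog):
        with caplog.at_level("WARNING"):
            _, p = mann_whitney_u([5, 5, 5], [5, 5])
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_branch_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=int(rng.integers(3, 8)))
        y = rng.normal(0.5, 1, size=int(rng.integers(3, 8)))
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(_enumeration_p(x, y), abs=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_approximate_branch_close_to_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(size=10)
        y = rng.normal(0.8, 1, size=10)
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(_enumeration_p(x, y), abs=0.01)

    def test_matrix_path_matches_scipy_per_site(self):
        rng = np.random.default_rng(7)
        X = rng.beta(2, 2, size=(200, 20))
        X[rng.random(X.shape) < 0.05] = np.nan
        X[:40] = np.round(X[:40], 1)  # force ties
        df = pd.DataFrame(X, columns=[f"s{i}" for i in range(20)])
        case = [f"s{i}" for i in range(10)]
        p_vec = matrix_mann_whitney(df, case)
        for i in range(200):
            x = X[i, :10][np.isfinite(X[i, :10])]
            y = X[i, 10:][np.isfinite(X[i, 10:])]
            if len(x) < 2 or len(y) < 2:
                assert np.isnan(p_vec[i])
                continue
            pooled = np.concatenate([x, y])
            if np.all(pooled == pooled[0]):
                assert p_vec[i] == 1.0
                continue
            expected = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
            assert p_vec[i] == pytest.approx(expected, abs=1e-12)

    def test_type_i_error_calibration(self):
        """Under the null the raw p <= 0.05 fraction sits near 0.05."""
        fractions = []
        for seed in range(20):
            rng = np.random.default_rng(1_000 + seed)
            X = rng.beta(5, 5, size=(500, 20))
            df = pd.DataFrame(X, columns=[f"s{i}" for i in range(20)])
            p = matrix_mann_whitney(df, [f"s{i}" for i in range(10)])
            fractions.append(float((p <= 0.05).mean()))
        assert np.mean(fractions) == pytest.approx(0.05, abs=0.02)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_worked_example_all_adjust_to_largest(self):
        adj = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_min_over_tail_formula(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(50)
        adj = bh_fdr(p)
        m = len(p)
        order = np.argsort(p)
        oracle = np.empty(m)
        running = np.inf
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, m * p[i] / (rank + 1))
            oracle[i] = min(1.0, running)
        assert adj == pytest.approx(oracle)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(9)
        p = rng.random(100)
        adj = bh_fdr(p)
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-15)


class TestPermutationFdr:
    def test_constant_matrix_yields_no_threshold(self):
        df = pd.DataFrame(np.full((50, 10), 0.5), columns=[f"s{i}" for i in range(10)])
        groups = {f"s{i}": ("case" if i < 5 else "control") for i in range(10)}
        t_star, _ = permutation_fdr_threshold(BetaMatrix(df, groups), n_perm=50, seed=1)
        assert t_star is None

    def test_deterministic_given_seed(self, meth_dataset):
        bm = BetaMatrix(meth_dataset.betas, meth_dataset.groups)
        t1, p1 = permutation_fdr_threshold(bm, n_perm=50, seed=11)
        t2, p2 = permutation_fdr_threshold(bm, n_perm=50, seed=11)
        assert t1 == t2 and np.array_equal(p1, p2, equal_nan=True)

    def test_planted_shift_controls_fdp(self):
        """Average realized false-discovery proportion stays near target."""
        fdps = []
        for seed in range(10):
            res = generate_methylation_dataset(
                MethylationConfig(n_sites=800, frac_dmc=0.05, delta=0.4, seed=2_000 + seed)
            )
            bm = BetaMatrix(res.betas, res.groups)
            dmc = call_dmcs(bm, Parameters(n_perm=200), fdr_mode="permutation", seed=seed)
            planted = set(res.truth[res.truth["is_dmc"]]["identifier"])
            called = set(dmc[dmc["significant"]]["site"])
            if called:
                fdps.append(len(called - planted) / len(called))
        assert fdps and float(np.mean(fdps)) <= 0.10


class TestCallDmcs:
    def test_null_matrix_bh_significant_fraction_small(self):
        fracs = []
        for seed in range(10):
            res = generate_methylation_dataset(
                MethylationConfig(n_sites=500, frac_dmc=0.0, seed=3_000 + seed)
            )
            bm = BetaMatrix(res.betas, res.groups)
            dmc = call_dmcs(bm, fdr_mode="bh")
            fracs.append(float(dmc["significant"].mean()))
        assert float(np.mean(fracs)) <= 0.01

    def test_effect_filter_blocks_tiny_deltas(self):
        rng = np.random.default_rng(4)
        # strongly separated but tiny-shift site: p minuscule, |delta| < 0.1
        case = 0.50 + rng.normal(0, 0.001, size=(1, 10)) + 0.05
        ctrl = 0.50 + rng.normal(0, 0.001, size=(1, 10))
        df = pd.DataFrame(np.hstack([case, ctrl]),
                          index=["s1"], columns=[f"c{i}" for i in range(20)])
        groups = {f"c{i}": ("case" if i < 10 else "control") for i in range(20)}
        # pad with null sites so BH has a family
        pad = pd.DataFrame(rng.beta(5, 5, size=(50, 20)), columns=df.columns,
                           index=[f"n{i}" for i in range(50)])
        bm = BetaMatrix(pd.concat([df, pad]), groups)
        dmc = call_dmcs(bm, fdr_mode="bh").set_index("site")
        assert dmc.loc["s1", "p_value"] < 1e-3  # the floor of the 10-vs-10 rank test
        assert not dmc.loc["s1", "significant"]

    def test_power_on_planted_design(self):
        recoveries = []
        for seed in range(10):
            res = generate_methylation_dataset(
                MethylationConfig(n_sites=500, frac_dmc=0.05, delta=0.3, seed=4_000 + seed)
            )
            bm = BetaMatrix(res.betas, res.groups)
            dmc = call_dmcs(bm, Parameters(n_perm=200), fdr_mode="permutation", seed=seed)
            planted = set(res.truth[res.truth["is_dmc"]]["identifier"])
            called = set(dmc[dmc["significant"]]["site"])
            recoveries.append(len(called & planted) / len(planted))
        assert float(np.mean(recoveries)) >= 0.80

    def test_invariant_to_column_order(self, meth_dataset):
        bm1 = BetaMatrix(meth_dataset.betas, meth_dataset.groups)
        shuffled = meth_dataset.betas[list(reversed(meth_dataset.betas.columns))]
        bm2 = BetaMatrix(shuffled, meth_dataset.groups)
        d1 = call_dmcs(bm1, fdr_mode="bh").set_index("site")
        d2 = call_dmcs(bm2, fdr_mode="bh").set_index("site")
        pd.testing.assert_frame_equal(d1, d2.loc[d1.index])

    def test_sites_with_too_few_values_excluded(self):
        rng = np.random.default_rng(8)
        X = rng.beta(2, 2, size=(5, 8))
        X[0, :3] = np.nan  # case group down to 1 value
        df = pd.DataFrame(X, index=[f"s{i}" for i in range(5)],
                          columns=[f"c{i}" for i in range(8)])
        groups = {f"c{i}": ("case" if i < 4 else "control") for i in range(8)}
        dmc = call_dmcs(BetaMatrix(df, groups), fdr_mode="bh")
        assert "s0" not in set(dmc["site"]) and len(dmc) == 4


class TestReplicateMetrics:
    def test_constant_site_sd_zero(self):
        df = pd.DataFrame({"r1": [0.5], "r2": [0.5], "r3": [0.5]}, index=["s"])
        bm = BetaMatrix(df, {c: "control" for c in df.columns},
                        {c: "rep" for c in df.columns})
        assert replicate_sd(bm, "rep").iloc[0] == 0.0

    def test_two_point_sd(self):
        df = pd.DataFrame({"r1": [0.0], "r2": [1.0]}, index=["s"])
        bm = BetaMatrix(df, {c: "control" for c in df.columns}, {c: "rep" for c in df.columns})
        assert replicate_sd(bm, "rep").iloc[0] == pytest.approx(math.sqrt(0.5))

    def test_matches_two_pass_formula(self):
        rng = np.random.default_rng(6)
        X = rng.beta(2, 2, size=(100, 6))
        df = pd.DataFrame(X, columns=[f"r{i}" for i in range(6)])
        bm = BetaMatrix(df, {c: "control" for c in df.columns}, {c: "rep" for c in df.columns})
        got = replicate_sd(bm, "rep").to_numpy()
        mean = X.mean(axis=1, keepdims=True)
        oracle = np.sqrt(((X - mean) ** 2).sum(axis=1) / (X.shape[1] - 1))
        assert got == pytest.approx(oracle, abs=1e-12)


class TestPlatformDiff:
    def test_worked_example(self):
        arr = pd.Series({("chr1", 10): 0.8})
        wgbs = [MethylationCall("chr1", 10, 7, 3)]
        diff = platform_abs_diff(arr, wgbs, coverage_min=10)
        assert diff[("chr1", 10)] == pytest.approx(0.1)

    def test_low_coverage_wgbs_excluded(self):
        arr = pd.Series({("chr1", 10): 0.8})
        wgbs = [MethylationCall("chr1", 10, 6, 3)]
        assert platform_abs_diff(arr, wgbs, coverage_min=10).empty

    def test_identical_inputs_all_zero(self):
        wgbs = [MethylationCall("chr1", p, 7, 3) for p in range(0, 50, 10)]
        arr = pd.Series({("chr1", p): 0.7 for p in range(0, 50, 10)})
        diff = platform_abs_diff(arr, wgbs, coverage_min=10)
        assert (diff == 0).all() and len(diff) == 5


class TestCompareProbeGroups:
    def test_identical_groups_p_one(self):
        vals = {"a": np.arange(10.0), "b": np.arange(10.0)}
        df = compare_probe_groups(vals, [("a", "b")])
        assert df["p_value"].iloc[0] == pytest.approx(1.0)
        assert df["fdr"].iloc[0] == pytest.approx(1.0)

    def test_single_comparison_fdr_equals_raw(self):
        rng = np.random.default_rng(2)
        vals = {"a": rng.normal(size=30), "b": rng.normal(0.5, 1, size=30)}
        df = compare_probe_groups(vals, [("a", "b")])
        assert df["fdr"].iloc[0] == pytest.approx(df["p_value"].iloc[0])

    def test_shifted_group_detected_consistently(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(5_000 + seed)
            vals = {"a": rng.normal(size=500), "b": rng.normal(0.5, 1, size=500)}
            df = compare_probe_groups(vals, [("a", "b")])
            hits += df["fdr"].iloc[0] < 0.001
        assert hits >= 19

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            compare_probe_groups({"a": np.arange(5.0)}, [("a", "zzz")])
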