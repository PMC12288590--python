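"""Feature annotation bands, enrichment statistics, driver permutation, ORA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methref import (
    Gene,
    GenomicInterval,
    Parameters,
    annotate_sites,
    assign_repeat_category,
    driver_gene_enrichment,
    element_enrichment,
    map_sites_to_genes,
    overrepresentation,
    repeat_category_fold,
)


def _gene(name, start, end, strand="+", contig="chr1"):
    return Gene(name, GenomicInterval(contig, start, end, strand))


ISLAND = [GenomicInterval("chr1", 10_000, 10_500)]


class TestAnnotateSites:
    @pytest.mark.parametrize(
        "pos,flags",
        [
            (10_200, dict(cpg_island=True, cpg_shore=False, cpg_shelf=False)),
            (10_499, dict(cpg_island=True)),
            (10_500, dict(cpg_island=False, cpg_shore=True)),   # first base past the edge
            (12_499, dict(cpg_shore=True)),
            (12_500, dict(cpg_shore=False, cpg_shelf=True)),    # 2-4 kb band
            (13_500, dict(cpg_shelf=True)),                     # 3 kb from the edge
            (14_500, dict(cpg_island=False, cpg_shore=False, cpg_shelf=False)),
            (8_000, dict(cpg_shore=True)),                      # left flank
            (7_999, dict(cpg_shore=False, cpg_shelf=True)),
        ],
    )
    def test_island_shore_shelf_bands(self, pos, flags):
        df = annotate_sites([("chr1", pos)], [], ISLAND)
        for key, val in flags.items():
            assert bool(df[key].iloc[0]) == val, (pos, key)

    def test_band_exclusivity_everywhere(self):
        sites = [("chr1", p) for p in range(5_000, 16_000, 37)]
        df = annotate_sites(sites, [], ISLAND)
        assert (df[["cpg_island", "cpg_shore", "cpg_shelf"]].sum(axis=1) <= 1).all()

    def test_exclusivity_with_close_islands(self):
        """Two islands closer than 8 kb: nearest-edge distance decides."""
        islands = [GenomicInterval("chr1", 1_000, 1_200), GenomicInterval("chr1", 4_000, 4_200)]
        sites = [("chr1", p) for p in range(0, 8_000, 13)]
        df = annotate_sites(sites, [], islands)
        assert (df[["cpg_island", "cpg_shore", "cpg_shelf"]].sum(axis=1) <= 1).all()
        # midpoint between the islands is 1400 bp from both edges: shore
        mid = df[df["position"] == 2_600 - 2_600 % 13]
        assert bool(mid["cpg_shore"].iloc[0])

    def test_promoter_strand_aware(self):
        genes = [_gene("plus", 5_000, 6_000, "+"), _gene("minus", 20_000, 21_000, "-")]
        df = annotate_sites(
            [("chr1", 4_500), ("chr1", 5_500), ("chr1", 21_500), ("chr1", 19_500)],
            genes,
            [],
        ).set_index("position")
        assert df.loc[4_500, "promoter"] and not df.loc[4_500, "gene_body"]
        assert df.loc[5_500, "gene_body"] and not df.loc[5_500, "promoter"]
        assert df.loc[21_500, "promoter"]   # upstream of a minus-strand gene
        assert not df.loc[19_500, "promoter"]

    def test_unstranded_gene_has_no_promoter(self, caplog):
        with caplog.at_level("WARNING"):
            df = annotate_sites([("chr1", 4_500)], [_gene("g", 5_000, 6_000, ".")], [])
        assert not df["promoter"].iloc[0]
        assert "unstranded" in caplog.text


class TestElementEnrichment:
    def _annotations(self, positions, island):
        return annotate_sites([("chr1", p) for p in positions], [], island)

    def test_target_inside_feature_covering_half_background(self):
        background = self._annotations(list(range(10_000, 10_500, 10)) + list(range(50_000, 50_500, 10)), ISLAND)
        target = self._annotations(range(10_000, 10_500, 10), ISLAND)
        df = element_enrichment(target, background).set_index("feature")
        assert df.loc["cpg_island", "fold"] == pytest.approx(2.0)

    def test_uniform_target_fold_near_one(self):
        rng = np.random.default_rng(3)
        bg_pos = list(range(8_000, 15_000, 7))
        background = self._annotations(bg_pos, ISLAND)
        folds = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sub = rng.choice(len(bg_pos), size=200, replace=False)
            target = background.iloc[sorted(sub)]
            df = element_enrichment(target, background).set_index("feature")
            folds.extend(df["fold"].dropna()[["cpg_island", "cpg_shore", "cpg_shelf"][0:3]])
        assert np.mean(folds) == pytest.approx(1.0, abs=0.1)

    def test_background_against_itself_fold_exactly_one(self):
        background = self._annotations(range(8_000, 15_000, 11), ISLAND)
        df = element_enrichment(background, background).set_index("feature")
        present = df["fold"].dropna()
        assert (present == 1.0).all()

    def test_chi2_matches_direct_pearson_formula(self):
        background = self._annotations(range(8_000, 15_000, 7), ISLAND)
        target = self._annotations(range(9_500, 11_000, 7), ISLAND)
        df = element_enrichment(target, background).set_index("feature")
        t_in = int(target["cpg_island"].sum()); t_out = len(target) - t_in
        b_in = int(background["cpg_island"].sum()); b_out = len(background) - b_in
        obs = np.array([[t_in, t_out], [b_in, b_out]], dtype=float)
        row = obs.sum(axis=1, keepdims=True); col = obs.sum(axis=0, keepdims=True)
        exp = row * col / obs.sum()
        chi2 = ((obs - exp) ** 2 / exp).sum()
        p = stats.chi2.sf(chi2, 1)
        assert df.loc["cpg_island", "chi2"] == pytest.approx(chi2, abs=1e-10)
        assert df.loc["cpg_island", "p_value"] == pytest.approx(p, abs=1e-10)

    def test_feature_absent_from_background_flagged(self, caplog):
        background = self._annotations(range(50_000, 50_300, 10), ISLAND)  # no islands
        target = self._annotations(range(10_000, 10_200, 10), ISLAND)
        with caplog.at_level("WARNING"):
            df = element_enrichment(target, background).set_index("feature")
        assert math.isnan(df.loc["cpg_island", "fold"])


class TestRepeatCategories:
    TRACKS = {
        "segdup": [GenomicInterval("chr1", 100, 200)],
        "line_sine": [GenomicInterval("chr1", 150, 300)],
        "satellite": [GenomicInterval("chr1", 400, 500)],
        "other_repeat": [GenomicInterval("chr1", 450, 600)],
    }

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (170, "segdup"),        # in both segdup and LINE: priority
            (250, "line_sine"),
            (420, "satellite"),
            (550, "other_repeat"),
            (700, "none"),
        ],
    )
    def test_priority_order(self, pos, expected):
        cats = assign_repeat_category([("chr1", pos)], self.TRACKS)
        assert cats[("chr1", pos)] == expected

    def test_fold_is_count_ratio(self):
        a = assign_repeat_category([("chr1", p) for p in (170, 171, 250)], self.TRACKS)
        b = assign_repeat_category([("chr1", p) for p in (172, 251)], self.TRACKS)
        df = repeat_category_fold(a, b).set_index("category")
        assert df.loc["segdup", "fold"] == pytest.approx(2.0)
        assert df.loc["line_sine", "fold"] == pytest.approx(1.0)


class TestDriverEnrichment:
    UNIVERSE = {f"g{i}" for i in range(200)}
    DRIVERS = {f"g{i}" for i in range(20)}  # 10% of the universe

    def test_null_target_fold_near_one(self):
        calm = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            target = set(rng.choice(sorted(self.UNIVERSE), size=40, replace=False))
            res = driver_gene_enrichment(target, self.DRIVERS, self.UNIVERSE, n_perm=200, seed=seed)
            calm += res["p_value"] >= 0.05
        assert calm >= 18

    def test_target_subset_of_drivers_is_extreme(self):
        target = {f"g{i}" for i in range(15)}
        res = driver_gene_enrichment(target, self.DRIVERS, self.UNIVERSE, n_perm=200, seed=0)
        assert res["p_value"] == pytest.approx(1 / 201)
        assert res["fold"] == pytest.approx(10.0, rel=0.25)

    def test_mean_permuted_overlap_matches_hypergeometric_expectation(self):
        rng = np.random.default_rng(1)
        target = set(rng.choice(sorted(self.UNIVERSE), size=50, replace=False))
        res = driver_gene_enrichment(target, self.DRIVERS, self.UNIVERSE, n_perm=1_000, seed=1)
        n, K, N = len(target), len(self.DRIVERS), len(self.UNIVERSE)
        expectation = n * K / N
        var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1)
        se = math.sqrt(var / 1_000)
        assert abs(res["expected"] - expectation) <= 3 * se

    def test_deterministic_given_seed(self):
        target = {f"g{i}" for i in range(10, 50)}
        r1 = driver_gene_enrichment(target, self.DRIVERS, self.UNIVERSE, n_perm=100, seed=7)
        r2 = driver_gene_enrichment(target, self.DRIVERS, self.UNIVERSE, n_perm=100, seed=7)
        assert r1 == r2

    def test_target_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            driver_gene_enrichment({"zzz"}, self.DRIVERS, self.UNIVERSE)


class TestOverrepresentation:
    def test_target_equal_to_set_is_maximal(self):
        universe = {f"g{i}" for i in range(100)}
        sets = {"s": {f"g{i}" for i in range(10)}}
        df = overrepresentation(sets["s"], sets, universe).set_index("gene_set")
        assert df.loc["s", "fold"] == pytest.approx(10.0)
        assert df.loc["s", "p_value"] < 1e-10

    def test_matches_exhaustive_enumeration_on_ten_gene_universe(self):
        universe = {f"g{i}" for i in range(10)}
        gene_set = {f"g{i}" for i in range(4)}
        target = {"g0", "g1", "g2", "g3", "g9"}  # n=5, k=4
        df = overrepresentation(target, {"s": gene_set}, universe)
        p = df["p_value"].iloc[0]
        # enumeration: over all C(10,5) equally likely draws, P(overlap >= 4)
        hits = sum(
            len(set(c) & gene_set) >= 4
            for c in itertools.combinations(sorted(universe), 5)
        )
        assert p == pytest.approx(hits / math.comb(10, 5), abs=1e-12)

    def test_enumeration_on_every_overlap_threshold(self):
        universe = {f"g{i}" for i in range(12)}
        gene_set = {f"g{i}" for i in range(5)}
        rng = np.random.default_rng(0)
        for _ in range(5):
            target = set(rng.choice(sorted(universe), size=6, replace=False))
            k = len(target & gene_set)
            p = overrepresentation(target, {"s": gene_set}, universe)["p_value"].iloc[0]
            hits = sum(
                len(set(c) & gene_set) >= k
                for c in itertools.combinations(sorted(universe), 6)
            )
            assert p == pytest.approx(hits / math.comb(12, 6), abs=1e-12)

    def test_random_targets_rarely_significant(self):
        universe = {f"g{i}" for i in range(300)}
        rng0 = np.random.default_rng(99)
        sets = {
            f"s{j}": set(rng0.choice(sorted(universe), size=20, replace=False))
            for j in range(10)
        }
        n_sig = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            target = set(rng.choice(sorted(universe), size=30, replace=False))
            df = overrepresentation(target, sets, universe)
            n_sig += int(df["significant"].sum())
        # 20 families x 10 sets at BH 0.05: discoveries stay below the
        # nominal false-discovery budget
        assert n_sig <= 10

    def test_empty_set_skipped(self, caplog):
        universe = {"a", "b"}
        with caplog.at_level("WARNING"):
            df = overrepresentation({"a"}, {"s": {"zzz"}}, universe)
        assert len(df) == 0


class TestMapSitesToGenes:
    GENES = [_gene("g1", 5_000, 6_000, "+"), _gene("g2", 9_000, 9_500, "-")]

    def test_site_in_body_maps_once(self):
        assert map_sites_to_genes([("chr1", 5_500)], self.GENES) == {"g1"}

    def test_two_sites_same_promoter_dedup(self):
        got = map_sites_to_genes([("chr1", 4_500), ("chr1", 4_600)], self.GENES)
        assert got == {"g1"}

    def test_intergenic_site_contributes_nothing(self):
        assert map_sites_to_genes([("chr1", 100)], self.GENES) == set()
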