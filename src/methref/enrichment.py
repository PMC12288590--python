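"""Genomic-feature annotation and enrichment statistics.

Sites are flagged for promoters (2 kb upstream of the TSS, strand-aware),
gene bodies, and the island / shore / shelf bands around CpG islands
(distance 0 / up to 2 kb / 2-4 kb from the nearest island edge, mutually
exclusive). Enrichment of a target site set against a background uses the
2x2 Pearson chi-squared test with BH correction across features; repeat
categories are assigned with segdup > LINE/SINE > satellite > other
priority; driver-gene enrichment uses a permutation test that re-samples
gene sets of the target's size from the universe; pathway
over-representation uses the one-sided hypergeometric upper tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .ewas import bh_fdr
from .io import GenomicInterval
from .params import Parameters

logger = logging.getLogger("methref")

Site = tuple[str, int]

REPEAT_PRIORITY = ("segdup", "line_sine", "satellite", "other_repeat")


@dataclass
class Gene:
    """A gene span with strand and name; TSS at start (+) or end (-)."""

    name: str
    interval: GenomicInterval

    @property
    def tss(self) -> int:
        return self.interval.start if self.interval.strand == "+" else self.interval.end - 1

    def promoter(self, upstream: int) -> GenomicInterval | None:
        iv = self.interval
        if iv.strand == "+":
            start, end = max(0, iv.start - upstream), iv.start
        elif iv.strand == "-":
            start, end = iv.end, iv.end + upstream
        else:
            return None
        if start >= end:
            return None
        return GenomicInterval(iv.contig, start, end, iv.strand)


def _tree_of(intervals: list[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def annotate_sites(
    sites: list[Site],
    genes: list[Gene],
    islands: list[GenomicInterval],
    params: Parameters | None = None,
) -> pd.DataFrame:
    """Per-site boolean feature flags.

    Columns: promoter, gene_body, cpg_island, cpg_shore, cpg_shelf. The
    island / shore / shelf flags are mutually exclusive, decided by the
    distance to the nearest island edge (ties broken toward the
    lower-coordinate island by the nearest-distance rule itself).
    """
    params = params or Parameters()
    promoter_ivs = []
    for g in genes:
        if g.interval.strand == ".":
            logger.warning("gene %s is unstranded; promoter undefined", g.name)
            continue
        p = g.promoter(params.promoter_upstream)
        if p is not None:
            promoter_ivs.append(p)
    prom_trees = _tree_of(promoter_ivs)
    body_trees = _tree_of([g.interval for g in genes])
    islands_by_contig: dict[str, list[GenomicInterval]] = {}
    for iv in sorted(islands, key=lambda i: (i.contig, i.start)):
        islands_by_contig.setdefault(iv.contig, []).append(iv)

    rows = []
    for contig, pos in sites:
        promoter = bool(prom_trees.get(contig, IntervalTree()).overlap(pos, pos + 1))
        gene_body = bool(body_trees.get(contig, IntervalTree()).overlap(pos, pos + 1))
        island = shore = shelf = False
        dist = _nearest_island_distance(pos, islands_by_contig.get(contig, []))
        if dist is not None:
            if dist == 0:
                island = True
            elif dist <= params.shore_width:
                shore = True
            elif dist <= params.shore_width + params.shelf_width:
                shelf = True
        rows.append(
            {
                "contig": contig,
                "position": pos,
                "promoter": promoter,
                "gene_body": gene_body,
                "cpg_island": island,
                "cpg_shore": shore,
                "cpg_shelf": shelf,
            }
        )
    return pd.DataFrame(rows)


def _nearest_island_distance(pos: int, islands: list[GenomicInterval]) -> int | None:
    """Distance from a point to the nearest island (0 when inside)."""
    if not islands:
        return None
    best: int | None = None
    for iv in islands:
        if iv.start <= pos < iv.end:
            return 0
        # bases beyond the island edge: a site directly adjacent is at
        # distance 1, so each band spans exactly shore_width bases
        d = iv.start - pos if pos < iv.start else pos - iv.end + 1
        if best is None or d < best:
            best = d
    return best


def element_enrichment(
    target: pd.DataFrame,
    background: pd.DataFrame,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Per-feature fold enrichment of target sites over background sites.

    ``target`` and ``background`` are annotate_sites outputs. fold =
    (target fraction in feature) / (background fraction in feature); p from
    the uncorrected 2x2 Pearson chi-squared test on member/non-member
    counts; BH across features.
    """
    if len(target) == 0 or len(background) == 0:
        raise ValueError("target and background must be non-empty")
    features = features or ["promoter", "gene_body", "cpg_island", "cpg_shore", "cpg_shelf"]
    rows = []
    for feat in features:
        t_in = int(target[feat].sum())
        b_in = int(background[feat].sum())
        t_out = len(target) - t_in
        b_out = len(background) - b_in
        if b_in == 0:
            logger.warning("feature %s absent from background; fold undefined", feat)
            rows.append({"feature": feat, "fold": np.nan, "chi2": np.nan, "p_value": np.nan})
            continue
        fold = (t_in / len(target)) / (b_in / len(background))
        table = np.array([[t_in, t_out], [b_in, b_out]])
        if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append({"feature": feat, "fold": fold, "chi2": chi2, "p_value": p})
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    return df


def assign_repeat_category(
    sites: list[Site],
    tracks: dict[str, list[GenomicInterval]],
) -> pd.Series:
    """One repeat category per site, by priority.

    ``tracks`` maps category names ("segdup", "line_sine", "satellite",
    "other_repeat") to interval lists; a site overlapping several tracks
    takes the highest-priority one; sites outside all tracks get "none".
    """
    trees = {cat: _tree_of(tracks.get(cat, [])) for cat in REPEAT_PRIORITY}
    out = {}
    for contig, pos in sites:
        category = "none"
        for cat in REPEAT_PRIORITY:
            if trees[cat].get(contig, IntervalTree()).overlap(pos, pos + 1):
                category = cat
                break
        out[(contig, pos)] = category
    return pd.Series(out, dtype=object)


def repeat_category_fold(categories_a: pd.Series, categories_b: pd.Series) -> pd.DataFrame:
    """Per-category fold: observed count in group A over observed in group B."""
    rows = []
    for cat in REPEAT_PRIORITY + ("none",):
        n_a = int((categories_a == cat).sum())
        n_b = int((categories_b == cat).sum())
        fold = n_a / n_b if n_b else np.nan
        rows.append({"category": cat, "count_a": n_a, "count_b": n_b, "fold": fold})
    return pd.DataFrame(rows)


def driver_gene_enrichment(
    target_genes: set[str],
    driver_genes: set[str],
    gene_universe: set[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation enrichment of a gene list in a driver-gene catalog.

    Each permutation samples |target| genes uniformly without replacement
    from the universe; fold = observed overlap / mean permuted overlap; the
    permutation p uses the add-one estimator (1 + #{perm >= obs}) /
    (1 + n_perm). Deterministic given the seed.
    """
    if not target_genes <= gene_universe:
        raise ValueError("target genes must be a subset of the universe")
    if not driver_genes <= gene_universe:
        raise ValueError("driver genes must be a subset of the universe")
    if len(target_genes) > len(gene_universe):
        raise ValueError("target larger than universe")
    observed = len(target_genes & driver_genes)
    universe = np.array(sorted(gene_universe))
    is_driver = np.isin(universe, sorted(driver_genes))
    rng = np.random.default_rng(seed)
    k = len(target_genes)
    perm_overlaps = np.array(
        [int(is_driver[rng.choice(len(universe), size=k, replace=False)].sum()) for _ in range(n_perm)]
    )
    mean_perm = float(perm_overlaps.mean())
    fold = observed / mean_perm if mean_perm > 0 else np.inf
    p = (1 + int((perm_overlaps >= observed).sum())) / (1 + n_perm)
    return {
        "observed": float(observed),
        "expected": mean_perm,
        "fold": float(fold),
        "p_value": float(p),
        "n_perm": float(n_perm),
    }


def overrepresentation(
    target_genes: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in pathway sets.

    One-sided upper-tail p per set for overlap k, target size n, set size
    K, universe N; fold = (k/n)/(K/N); BH across sets, significant at
    adjusted p < 0.05.
    """
    if not target_genes <= universe:
        raise ValueError("target genes must be a subset of the universe")
    n = len(target_genes)
    big_n = len(universe)
    rows = []
    for name, members in gene_sets.items():
        members = members & universe
        if not members:
            logger.warning("gene set %s is empty within the universe; skipped", name)
            continue
        big_k = len(members)
        k = len(target_genes & members)
        fold = (k / n) / (big_k / big_n) if n else np.nan
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"gene_set": name, "overlap": k, "set_size": big_k, "fold": fold, "p_value": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = bh_fdr(df["p_value"].to_numpy())
        df["significant"] = df["fdr"] < 0.05
    return df


def map_sites_to_genes(
    sites: list[Site],
    genes: list[Gene],
    params: Parameters | None = None,
) -> set[str]:
    """Genes whose promoter or body contains at least one site (deduplicated)."""
    params = params or Parameters()
    ivs: list[tuple[GenomicInterval, str]] = []
    for g in genes:
        ivs.append((g.interval, g.name))
        p = g.promoter(params.promoter_upstream)
        if p is not None:
            ivs.append((p, g.name))
    trees: dict[str, IntervalTree] = {}
    for iv, name in ivs:
        trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end, name)
    hit: set[str] = set()
    for contig, pos in sites:
        for ov in trees.get(contig, IntervalTree()).overlap(pos, pos + 1):
            hit.add(ov.data)
    return hit
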