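"""CpG calling from cytosine reports, strand merging, interval
intersection, coordinate liftover, and cross-reference CpG-set comparison.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

from .bisulfite import CpGSet
from .io import Assembly, ChainMap, GenomicInterval, MethylationCall

logger = logging.getLogger("methref")

Site = tuple[str, int]  # (contig, 0-based position of the C)


@dataclass
class CpGComparison:
    """Counts of CpGs called by two references, after lifting B into A."""

    n_a: int
    n_b: int
    n_b_lifted: int
    intersection: int
    a_unique: int
    b_unique: int

    @property
    def percent_increase(self) -> float:
        """Percent more CpGs called by A than B: 100 x (A - B) / B."""
        return 100 * (self.n_a - self.n_b) / self.n_b


def call_cpgs(
    reports: dict[str, list[MethylationCall]],
    coverage_min: int = 10,
    autosomes: tuple[str, ...] | None = None,
) -> tuple[dict[str, dict[Site, MethylationCall]], set[Site]]:
    """Filter per-sample calls and intersect sites across samples.

    A site survives when its total read count reaches ``coverage_min`` in
    *every* sample; contigs outside ``autosomes`` (when given) are dropped.
    Returns the filtered per-sample call maps and the across-sample site
    intersection.
    """
    filtered: dict[str, dict[Site, MethylationCall]] = {}
    for sample, calls in reports.items():
        kept = {
            (c.contig, c.position): c
            for c in calls
            if c.coverage >= coverage_min and (autosomes is None or c.contig in autosomes)
        }
        filtered[sample] = kept
    sites: set[Site] | None = None
    for kept in filtered.values():
        sites = set(kept) if sites is None else sites & set(kept)
    sites = sites or set()
    if not sites:
        logger.warning("call_cpgs: no sites survive the %dx per-sample filter", coverage_min)
    logger.info(
        "call_cpgs: %d samples -> %d sites at >=%dx in every sample",
        len(reports), len(sites), coverage_min,
    )
    return filtered, sites


def merge_cpg_strands(
    calls: list[MethylationCall], assembly: Assembly | None = None
) -> list[MethylationCall]:
    """Sum a C-strand call at p and a G-strand call at p+1 onto position p.

    When an assembly is given, a (p, p+1) pair is only merged if the
    reference sequence at p is "CG"; other adjacent pairs are left
    unmerged with a warning.
    """
    by_site = {(c.contig, c.position): c for c in calls}
    merged: list[MethylationCall] = []
    consumed: set[Site] = set()
    for (contig, pos), call in sorted(by_site.items()):
        if (contig, pos) in consumed:
            continue
        partner = by_site.get((contig, pos + 1))
        if partner is not None:
            is_cg = True
            if assembly is not None:
                seq = assembly[contig]
                is_cg = seq[pos : pos + 2] == "CG"
            if is_cg:
                merged.append(
                    MethylationCall(
                        contig, pos,
                        call.count_methylated + partner.count_methylated,
                        call.count_unmethylated + partner.count_unmethylated,
                    )
                )
                consumed.add((contig, pos + 1))
                continue
            logger.warning("merge_cpg_strands: %s:%d..%d is not a CG; left unmerged", contig, pos, pos + 1)
        merged.append(call)
    return merged


def count_cpgs_in_intervals(
    intervals: list[GenomicInterval], cpg_set: CpGSet
) -> tuple[set[Site], int]:
    """CpGs whose C position lies inside at least one read interval."""
    covered: set[Site] = set()
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
    for contig, ivs in by_contig.items():
        positions = cpg_set.positions.get(contig)
        if positions is None or len(positions) == 0:
            continue
        # merge intervals, then sweep the sorted CpG positions
        ivs.sort()
        merged: list[tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        pos = np.asarray(positions)
        for s, e in merged:
            lo = int(np.searchsorted(pos, s, side="left"))
            hi = int(np.searchsorted(pos, e, side="left"))
            covered.update((contig, int(p)) for p in pos[lo:hi])
    return covered, len(covered)


def liftover_positions(
    chain: ChainMap, positions: list[Site]
) -> tuple[dict[Site, Site], list[Site]]:
    """Map point positions through a chain; gaps and absent contigs unmap.

    A position inside an aligned block maps by block offset (reverse-strand
    blocks were normalized at read time); positions falling in inter-block
    gaps are returned in the unmapped list.
    """
    mapped: dict[Site, Site] = {}
    unmapped: list[Site] = []
    starts_cache: dict[str, list[int]] = {}
    for contig, pos in positions:
        blocks = chain.blocks_for(contig)
        if not blocks:
            unmapped.append((contig, pos))
            continue
        if contig not in starts_cache:
            starts_cache[contig] = [b.source.start for b in blocks]
        i = bisect_right(starts_cache[contig], pos) - 1
        if i < 0:
            unmapped.append((contig, pos))
            continue
        b = blocks[i]
        if pos >= b.source.end:
            unmapped.append((contig, pos))
            continue
        mapped[(contig, pos)] = (b.target.contig, b.target.start + (pos - b.source.start))
    return mapped, unmapped


def compare_cpg_sets(
    sites_a: set[Site], sites_b: set[Site], chain_b_to_a: ChainMap | None = None
) -> CpGComparison:
    """Compare CpG calls from reference A against calls from reference B.

    B's calls are lifted into A's coordinates (identity when no chain is
    given); the intersection is taken in A space, A-unique is defined by
    excluding all intersecting CpGs from A's calls, and B calls that fail
    liftover count toward B-unique (they cannot intersect).
    """
    if chain_b_to_a is None:
        lifted = set(sites_b)
    else:
        mapped, _unmapped = liftover_positions(chain_b_to_a, sorted(sites_b))
        lifted = set(mapped.values())
    inter = sites_a & lifted
    return CpGComparison(
        n_a=len(sites_a),
        n_b=len(sites_b),
        n_b_lifted=len(lifted),
        intersection=len(inter),
        a_unique=len(sites_a) - len(inter),
        b_unique=len(sites_b) - len(inter),
    )
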