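"""Gapless probe alignment to bisulfite-converted genomes and the
unambiguous / cross-reactive / mismatched trichotomy.

Array probes hybridize to bisulfite-converted DNA, so each 50-nt probe is
aligned (seed-and-extend, no gaps) against the four converted variants of a
genome. A placement qualifies when it has at least ``match_min`` identical
bases and identity at least ``identity_min``. A probe is *mismatched* when
no qualifying placement hits its declared target CpG with the CpG
dinucleotide perfectly matched; otherwise it is *unambiguous* when it has
exactly one distinct qualifying locus genome-wide and *cross-reactive* when
it has more. Degenerate R bases (type II probes) are expanded to A and G
before alignment.
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from dataclasses import dataclass

from .bisulfite import VARIANTS, ConvertedGenomeSet
from .io import Assembly, GenomicInterval, Probe
from .params import Parameters

logger = logging.getLogger("methref")

LOCUS_COLLAPSE_TOL = 2  # bp tolerance when collapsing hits into one locus

STATUSES = ("unambiguous", "cross_reactive", "mismatched")


@dataclass(frozen=True)
class AlignmentHit:
    """One qualifying gapless placement of a probe on one converted variant.

    ``locus`` is reported in forward source-assembly coordinates even for
    hits found on the reverse-complement variants (strand "-").
    """

    locus: GenomicInterval
    variant: str
    matches: int
    aligned_length: int
    cpg_locus_matched: bool
    expansion: str  # concrete sequence index label, "" when no R

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_length if self.aligned_length else 0.0


@dataclass(frozen=True)
class ProbeStatus:
    """Classification of one probe against one assembly."""

    probe_id: str
    status: str
    n_loci: int
    assembly: str
    best_hit: AlignmentHit | None = None


def expand_probe_sequence(probe: Probe) -> list[str]:
    """Cartesian expansion of each degenerate R base to {A, G}."""
    options = [("A", "G") if b == "R" else (b,) for b in probe.sequence]
    return ["".join(s) for s in itertools.product(*options)]


class SeedIndex:
    """K-mer index of one converted genome variant (BLAT-style tiling).

    Genome k-mers of length ``tile_size`` sampled every ``step_size`` bases
    map to their start positions; tiles occurring more than ``rep_match``
    times are masked from the index.
    """

    def __init__(self, genome: Assembly, tile_size: int, step_size: int, rep_match: int):
        self.tile_size = tile_size
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for contig, seq in genome.contigs.items():
            if len(seq) < tile_size:
                raise ValueError(f"contig {contig} shorter than tile_size")
            for pos in range(0, len(seq) - tile_size + 1, step_size):
                tile = seq[pos : pos + tile_size]
                if "N" in tile:
                    continue
                self.index[tile].append((contig, pos))
        masked = [t for t, hits in self.index.items() if len(hits) > rep_match]
        for t in masked:
            del self.index[t]
        if masked:
            logger.info("seed index: masked %d tiles above rep_match", len(masked))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.index.get(kmer, [])


def build_seed_index(genome: Assembly, tile_size: int, step_size: int, rep_match: int) -> SeedIndex:
    return SeedIndex(genome, tile_size, step_size, rep_match)


class ConvertedIndexSet:
    """Seed indexes for all four converted variants of one assembly."""

    def __init__(self, converted: ConvertedGenomeSet, params: Parameters):
        self.converted = converted
        self.params = params
        self.indexes = {
            v: build_seed_index(converted[v], params.tile_size, params.step_size, params.rep_match)
            for v in VARIANTS
        }


def _score_placement(seq: str, genome_seq: str, start: int) -> tuple[int, int, int, int]:
    """Score an ungapped placement of ``seq`` at genome offset ``start``.

    Returns (matches, aligned_length, in-bounds genome start, genome end).
    Bases hanging over a contig end are excluded from the aligned span.
    """
    g_start = max(start, 0)
    g_end = min(start + len(seq), len(genome_seq))
    if g_end <= g_start:
        return 0, 0, g_start, g_start
    probe_part = seq[g_start - start : g_end - start]
    genome_part = genome_seq[g_start:g_end]
    matches = sum(a == b and a != "N" for a, b in zip(probe_part, genome_part))
    return matches, g_end - g_start, g_start, g_end


def _to_forward(contig_len: int, start: int, end: int, variant: str) -> tuple[int, int, str]:
    """Map a placement on a converted variant to forward source coordinates."""
    if variant.endswith("_rev"):
        return contig_len - end, contig_len - start, "-"
    return start, end, "+"


def _probe_base_at_source_pos(seq: str, variant: str, contig_len: int, placement_start: int, source_pos: int) -> str | None:
    """The probe base aligned over forward source position ``source_pos``.

    ``placement_start`` is the placement offset on the variant's own
    coordinate system (which for reverse variants runs along the reverse
    complement).
    """
    if variant.endswith("_rev"):
        var_pos = contig_len - 1 - source_pos
    else:
        var_pos = source_pos
    off = var_pos - placement_start
    if 0 <= off < len(seq):
        return seq[off]
    return None


def align_probe(
    seq: str,
    index_set: ConvertedIndexSet,
    params: Parameters | None = None,
    target: GenomicInterval | None = None,
    expansion: str = "",
) -> list[AlignmentHit]:
    """All qualifying gapless placements of one concrete probe sequence.

    Every seed hit in every variant implies a candidate placement; duplicate
    placements from multiple seeds are collapsed; a placement is returned
    when matches >= match_min and identity >= identity_min. When ``target``
    is given, the CpG-locus flag of overlapping hits is evaluated against
    it (both bases of the CpG aligned and identical).
    """
    params = params or index_set.params
    k = params.tile_size
    hits: list[AlignmentHit] = []
    for variant in VARIANTS:
        genome = index_set.converted[variant]
        idx = index_set.indexes[variant]
        candidates: set[tuple[str, int]] = set()
        for off in range(0, len(seq) - k + 1):
            for contig, pos in idx.lookup(seq[off : off + k]):
                candidates.add((contig, pos - off))
        for contig, start in candidates:
            genome_seq = genome[contig]
            matches, aligned_len, g_start, g_end = _score_placement(seq, genome_seq, start)
            if matches < params.match_min or aligned_len == 0:
                continue
            if matches / aligned_len < params.identity_min:
                continue
            contig_len = len(genome_seq)
            f_start, f_end, strand = _to_forward(contig_len, g_start, g_end, variant)
            locus = GenomicInterval(contig, f_start, f_end, strand)
            cpg_ok = False
            if target is not None and locus.overlaps(target):
                cpg_ok = _cpg_perfectly_matched(seq, variant, genome_seq, contig_len, start, target)
            hits.append(AlignmentHit(locus, variant, matches, aligned_len, cpg_ok, expansion))
    return hits


def _cpg_perfectly_matched(
    seq: str,
    variant: str,
    genome_seq: str,
    contig_len: int,
    placement_start: int,
    target: GenomicInterval,
) -> bool:
    """Both bases of the target CpG aligned and identical, in the hit's orientation."""
    for source_pos in (target.start, target.start + 1):
        base = _probe_base_at_source_pos(seq, variant, contig_len, placement_start, source_pos)
        if base is None:
            return False
        if variant.endswith("_rev"):
            var_pos = contig_len - 1 - source_pos
        else:
            var_pos = source_pos
        if base != genome_seq[var_pos] or base == "N":
            return False
    return True


def check_cpg_locus(hit: AlignmentHit, probe: Probe, index_set: ConvertedIndexSet) -> bool:
    """Re-evaluate the CpG-locus flag of a hit overlapping the probe target."""
    if not hit.locus.overlaps(probe.target):
        raise ValueError("hit does not overlap the probe's declared target")
    return hit.cpg_locus_matched


def collapse_loci(hits: list[AlignmentHit], tol: int = LOCUS_COLLAPSE_TOL) -> list[list[AlignmentHit]]:
    """Group hits sharing one physical locus (same contig, start within +-tol).

    The same locus necessarily appears in complementary converted variants
    and in both R-expansions; counting those copies separately would label
    nearly every probe cross-reactive.
    """
    clusters: list[list[AlignmentHit]] = []
    for hit in sorted(hits, key=lambda h: (h.locus.contig, h.locus.start)):
        if (
            clusters
            and clusters[-1][0].locus.contig == hit.locus.contig
            and abs(hit.locus.start - clusters[-1][0].locus.start) <= tol
        ):
            clusters[-1].append(hit)
        else:
            clusters.append([hit])
    return clusters


def classify_probe(
    probe: Probe,
    index_set: ConvertedIndexSet,
    params: Parameters | None = None,
) -> ProbeStatus:
    """Classify one probe against one assembly.

    Qualifying hits are collected over all R-expansions and all four
    converted variants, collapsed into physical loci, and counted. A "good
    alignment" is a collapsed locus overlapping the declared target with
    the CpG dinucleotide perfectly matched; without one the probe is
    mismatched, with one and exactly one total locus it is unambiguous,
    otherwise cross-reactive.
    """
    params = params or index_set.params
    assembly_name = index_set.converted.source.name
    if probe.target.contig not in index_set.converted.source:
        logger.info("probe %s targets contig absent from %s: mismatched", probe.probe_id, assembly_name)
        return ProbeStatus(probe.probe_id, "mismatched", 0, assembly_name)
    all_hits: list[AlignmentHit] = []
    for i, seq in enumerate(expand_probe_sequence(probe)):
        label = "" if "R" not in probe.sequence else str(i)
        all_hits.extend(align_probe(seq, index_set, params, target=probe.target, expansion=label))
    clusters = collapse_loci(all_hits)
    n_loci = len(clusters)
    good = None
    for cluster in clusters:
        if any(h.cpg_locus_matched for h in cluster):
            good = cluster
            break
    if good is None:
        status = "mismatched"
        best = max(all_hits, key=lambda h: h.matches) if all_hits else None
    elif n_loci == 1:
        status = "unambiguous"
        best = max(good, key=lambda h: h.matches)
    else:
        status = "cross_reactive"
        best = max(good, key=lambda h: h.matches)
    return ProbeStatus(probe.probe_id, status, n_loci, assembly_name, best)


def classify_manifest(
    probes: list[Probe],
    index_set: ConvertedIndexSet,
    params: Parameters | None = None,
) -> dict[str, ProbeStatus]:
    """Classify every probe of a manifest; logs the Table-1-style tallies."""
    statuses = {p.probe_id: classify_probe(p, index_set, params) for p in probes}
    counts = {s: sum(1 for st in statuses.values() if st.status == s) for s in STATUSES}
    logger.info(
        "classified %d probes on %s: %s", len(probes), index_set.converted.source.name, counts
    )
    return statuses
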