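"""Bisulfite-converted genome variants, CpG enumeration, CpG island detection.

Bisulfite chemistry converts unmethylated cytosine to uracil (read as T)
while methylated cytosine is protected. In-silico probe alignment therefore
targets four converted variants of a genome: fully unmethylated (all C -> T)
and fully CpG-methylated (only non-CpG C -> T), each on the forward strand
and on the reverse complement. N bases pass through unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .io import Assembly, GenomicInterval
from .params import Parameters

_RC = str.maketrans("ACGTNRacgtnr", "TGCANYtgcany")

VARIANTS = ("unmeth_fwd", "meth_fwd", "unmeth_rev", "meth_rev")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N} (R -> Y for completeness)."""
    return seq.translate(_RC)[::-1]


def convert_unmethylated(seq: str) -> str:
    """All cytosines read as thymine (fully unmethylated bisulfite genome)."""
    return seq.replace("C", "T")


def convert_methylated(seq: str) -> str:
    """Only non-CpG cytosines read as thymine; CpG cytosines are protected."""
    # C followed by G survives; any other C becomes T
    return re.sub(r"C(?!G)", "T", seq)


@dataclass
class ConvertedGenomeSet:
    """The four bisulfite-converted variants of one source assembly.

    Variants keyed ``unmeth_fwd``, ``meth_fwd``, ``unmeth_rev``, ``meth_rev``.
    The reverse variants are the reverse complement of the source with the
    respective conversion applied on that strand; contig names and lengths
    match the source in every variant.
    """

    source: Assembly
    variants: dict[str, Assembly] = field(default_factory=dict)

    def __getitem__(self, key: str) -> Assembly:
        return self.variants[key]


def build_converted_set(assembly: Assembly) -> ConvertedGenomeSet:
    """Build the four converted genome variants used for probe alignment."""
    if not assembly.contigs:
        raise ValueError("assembly has no contigs")
    variants: dict[str, Assembly] = {}
    maps = {
        "unmeth_fwd": lambda s: convert_unmethylated(s),
        "meth_fwd": lambda s: convert_methylated(s),
        "unmeth_rev": lambda s: convert_unmethylated(revcomp(s)),
        "meth_rev": lambda s: convert_methylated(revcomp(s)),
    }
    for key, fn in maps.items():
        variants[key] = Assembly(
            f"{assembly.name}.{key}", {c: fn(s) for c, s in assembly.contigs.items()}
        )
    return ConvertedGenomeSet(assembly, variants)


@dataclass
class CpGSet:
    """Per-contig sorted 0-based positions of the C of each forward-strand CG."""

    assembly_name: str
    positions: dict[str, np.ndarray] = field(default_factory=dict)

    def count(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def as_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(c, int(p), int(p) + 2)
            for c in sorted(self.positions)
            for p in self.positions[c]
        ]


def enumerate_cpgs(assembly: Assembly) -> CpGSet:
    """All forward-strand CG dinucleotides, positioned at the C.

    CpG is its own reverse complement, so one forward scan covers both
    strands of each physical CpG.
    """
    positions: dict[str, np.ndarray] = {}
    for contig, seq in assembly.contigs.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        hits = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))) if len(arr) > 1 else np.array([], dtype=np.int64)
        positions[contig] = hits.astype(np.int64)
    return CpGSet(assembly.name, positions)


def detect_cpg_islands(assembly: Assembly, params: Parameters | None = None) -> list[GenomicInterval]:
    """CpG islands: maximal merged runs of qualifying 200-bp windows.

    A window of ``cgi_min_len`` bp qualifies when its GC fraction exceeds
    ``cgi_gc_min``, its observed/expected CpG ratio exceeds ``cgi_oe_min``
    (expected = #C x #G / window length), and at most 10% of its bases are
    N. Overlapping qualifying windows are merged, and each merged region is
    re-verified against both thresholds over its full span (dropped if it
    fails).
    """
    params = params or Parameters()
    w = params.cgi_min_len
    islands: list[GenomicInterval] = []
    for contig, seq in assembly.contigs.items():
        n = len(seq)
        if n < w:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_c = (arr == ord("C")).astype(np.int64)
        is_g = (arr == ord("G")).astype(np.int64)
        is_n = (arr == ord("N")).astype(np.int64)
        is_cg = np.zeros(n, dtype=np.int64)
        if n > 1:
            is_cg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))

        def windowed(x: np.ndarray, span: int) -> np.ndarray:
            cs = np.concatenate([[0], np.cumsum(x)])
            return cs[span:] - cs[: n - span + 1]

        c_cnt = windowed(is_c, w)
        g_cnt = windowed(is_g, w)
        n_cnt = windowed(is_n, w)
        # CG dinucleotides fully inside the window: starts in [i, i+w-1)
        cg_cnt = windowed(is_cg, w - 1)[: n - w + 1]

        gc_ok = (c_cnt + g_cnt) > params.cgi_gc_min * w
        expected = c_cnt * g_cnt / w
        oe_ok = (expected > 0) & (cg_cnt > params.cgi_oe_min * expected)
        n_ok = n_cnt <= 0.10 * w
        qual = gc_ok & oe_ok & n_ok
        starts = np.flatnonzero(qual)
        if len(starts) == 0:
            continue
        # merge windows whose starts are closer than the window length
        breaks = np.flatnonzero(np.diff(starts) >= w)
        run_bounds = np.concatenate([[0], breaks + 1, [len(starts)]])
        for a, b in zip(run_bounds[:-1], run_bounds[1:]):
            region_start = int(starts[a])
            region_end = int(starts[b - 1]) + w
            sub = seq[region_start:region_end]
            if _region_qualifies(sub, params):
                islands.append(GenomicInterval(contig, region_start, region_end))
    return islands


def _region_qualifies(seq: str, params: Parameters) -> bool:
    length = len(seq)
    c = seq.count("C")
    g = seq.count("G")
    if (c + g) <= params.cgi_gc_min * length:
        return False
    expected = c * g / length
    if expected <= 0:
        return False
    observed = len(re.findall(r"(?=CG)", seq))
    return observed > params.cgi_oe_min * expected
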