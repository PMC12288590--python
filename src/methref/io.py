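"""Readers and writers for the external formats the pipeline touches.

All interval-bearing records use 0-based half-open coordinates internally.
The two 1-based inputs (Illumina-style probe manifests via MAPINFO, Bismark
cytosine coverage reports) are shifted exactly once, here at the boundary;
BED and chain files are consumed in their native conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("methref")

STRANDS = ("+", "-", ".")
FASTA_ALPHABET = frozenset("ACGTN")
PROBE_ALPHABET = frozenset("ACGTR")

MANIFEST_COLUMNS = ("probe_id", "sequence", "design_type", "contig", "position_1based", "strand")


class FormatError(ValueError):
    """A malformed input file; the message names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.contig == other.contig and self.start < other.end and other.start < self.end


@dataclass
class Assembly:
    """A named genome assembly: contig name -> upper-case sequence."""

    name: str
    contigs: dict[str, str] = field(default_factory=dict)

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def __getitem__(self, contig: str) -> str:
        return self.contigs[contig]

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.contigs.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass(frozen=True)
class Probe:
    """One array probe: 50-nt sequence plus its declared target CpG locus."""

    probe_id: str
    sequence: str
    design_type: str
    target: GenomicInterval

    def __post_init__(self):
        if len(self.sequence) != 50:
            raise ValueError(f"probe {self.probe_id}: sequence must be 50 nt, got {len(self.sequence)}")
        bad = set(self.sequence) - PROBE_ALPHABET
        if bad:
            raise ValueError(f"probe {self.probe_id}: invalid characters {sorted(bad)}")
        if self.design_type not in ("I", "II"):
            raise ValueError(f"probe {self.probe_id}: design_type must be I or II")
        if len(self.target) != 2:
            raise ValueError(f"probe {self.probe_id}: target must span the 2-bp CpG dinucleotide")


@dataclass(frozen=True)
class MethylationCall:
    """Per-CpG methylated/unmethylated read counts; beta derived from counts."""

    contig: str
    position: int  # 0-based position of the C
    count_methylated: int
    count_unmethylated: int

    def __post_init__(self):
        if self.count_methylated < 0 or self.count_unmethylated < 0:
            raise ValueError("counts must be non-negative")

    @property
    def coverage(self) -> int:
        return self.count_methylated + self.count_unmethylated

    @property
    def beta(self) -> float | None:
        total = self.coverage
        if total == 0:
            return None
        return self.count_methylated / total


@dataclass(frozen=True)
class ChainBlock:
    """One gapless aligned block of a chain, in forward coordinates on both sides."""

    source: GenomicInterval
    target: GenomicInterval

    def __post_init__(self):
        if len(self.source) != len(self.target):
            raise ValueError("chain block source and target lengths differ")


@dataclass
class ChainMap:
    """An ordered, non-overlapping set of aligned blocks mapping source -> target."""

    source_name: str
    target_name: str
    blocks: list[ChainBlock] = field(default_factory=list)

    def __post_init__(self):
        by_contig: dict[str, list[ChainBlock]] = {}
        for b in self.blocks:
            by_contig.setdefault(b.source.contig, []).append(b)
        for contig, blks in by_contig.items():
            blks.sort(key=lambda b: b.source.start)
            prev_end = -1
            for b in blks:
                if b.source.start < prev_end:
                    raise ValueError(f"overlapping chain blocks in source coordinates on {contig}")
                prev_end = b.source.end
        self._by_contig = {c: sorted(bs, key=lambda b: b.source.start) for c, bs in by_contig.items()}

    def blocks_for(self, contig: str) -> list[ChainBlock]:
        return self._by_contig.get(contig, [])


def read_fasta(path: str | Path, name: str | None = None) -> Assembly:
    """Read a FASTA file into an :class:`Assembly`.

    Contigs are keyed by the first whitespace-delimited header token and
    sequences are upper-cased. Raises :class:`FormatError` for an empty
    file, duplicate contig names, or characters outside {A,C,G,T,N},
    naming the offending line.
    """
    path = Path(path)
    contigs: dict[str, list[str]] = {}
    current: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0] if line[1:].split() else ""
                if not current:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                if current in contigs:
                    raise FormatError(f"{path}:{lineno}: duplicate contig name {current!r}")
                contigs[current] = []
            else:
                if current is None:
                    raise FormatError(f"{path}:{lineno}: sequence before first header")
                seq = line.upper()
                bad = set(seq) - FASTA_ALPHABET
                if bad:
                    raise FormatError(f"{path}:{lineno}: invalid characters {sorted(bad)}")
                contigs[current].append(seq)
    if not contigs:
        raise FormatError(f"{path}: empty FASTA file")
    asm = Assembly(name or path.stem, {c: "".join(parts) for c, parts in contigs.items()})
    logger.info("read_fasta: %s -> %d contigs, %d bp", path, len(asm.contigs), asm.total_length())
    return asm


def write_fasta(assembly: Assembly, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for contig, seq in assembly.contigs.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_probe_manifest(path: str | Path) -> list[Probe]:
    """Read a probe manifest (CSV or TSV) into :class:`Probe` records.

    Expected columns: probe_id, sequence, design_type, contig,
    position_1based (Illumina MAPINFO convention: 1-based position of the
    CpG C), strand. The target is stored 0-based internally.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing manifest columns {missing}")
    probes: list[Probe] = []
    for idx, row in df.iterrows():
        lineno = idx + 2  # header + 1-based
        seq = str(row["sequence"]).upper()
        bad = set(seq) - PROBE_ALPHABET
        if bad:
            raise FormatError(f"{path}:{lineno}: probe sequence has invalid characters {sorted(bad)}")
        pos1 = int(row["position_1based"])
        if pos1 <= 0:
            raise FormatError(f"{path}:{lineno}: non-positive position {pos1}")
        strand = str(row.get("strand", "+")) if "strand" in df.columns else "+"
        try:
            probes.append(
                Probe(
                    probe_id=str(row["probe_id"]),
                    sequence=seq,
                    design_type=str(row["design_type"]),
                    target=GenomicInterval(str(row["contig"]), pos1 - 1, pos1 + 1, strand),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    logger.info("read_probe_manifest: %s -> %d probes", path, len(probes))
    return probes


def write_probe_manifest(probes: Sequence[Probe], path: str | Path) -> None:
    rows = [
        {
            "probe_id": p.probe_id,
            "sequence": p.sequence,
            "design_type": p.design_type,
            "contig": p.target.contig,
            "position_1based": p.target.start + 1,
            "strand": p.target.strand,
        }
        for p in probes
    ]
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_cytosine_report(path: str | Path) -> list[MethylationCall]:
    """Read a Bismark-style coverage report (1-based) into calls.

    Columns: contig, start (1-based), end, methylation percentage, count
    methylated, count unmethylated. Beta is recomputed from the counts; a
    percentage disagreeing with the counts by more than 0.5 points is
    logged as a warning and the counts win.
    """
    path = Path(path)
    calls: list[MethylationCall] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            contig, start1, _end, pct, n_meth, n_unmeth = fields[:6]
            try:
                n_meth, n_unmeth = int(n_meth), int(n_unmeth)
                pct = float(pct)
                pos0 = int(start1) - 1
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if n_meth < 0 or n_unmeth < 0:
                raise FormatError(f"{path}:{lineno}: negative counts")
            call = MethylationCall(contig, pos0, n_meth, n_unmeth)
            if call.coverage > 0 and abs(100 * call.beta - pct) > 0.5:
                logger.warning(
                    "%s:%d: percentage %.2f disagrees with counts (%d/%d); counts win",
                    path, lineno, pct, n_meth, n_unmeth,
                )
            calls.append(call)
    logger.info("read_cytosine_report: %s -> %d records", path, len(calls))
    return calls


def write_cytosine_report(calls: Iterable[MethylationCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            pct = 0.0 if c.beta is None else 100 * c.beta
            fh.write(
                f"{c.contig}\t{c.position + 1}\t{c.position + 1}\t{pct:.6g}\t"
                f"{c.count_methylated}\t{c.count_unmethylated}\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file (0-based half-open) into intervals."""
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
            try:
                intervals.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path, names: Sequence[str] | None = None) -> None:
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_chain(path: str | Path) -> ChainMap:
    """Read a UCSC chain file into a :class:`ChainMap`.

    The chain's target side (tName) is treated as the source genome of the
    map and the query side (qName) as its target, matching liftOver usage
    where coordinates on the "t" genome are lifted to the "q" genome.
    Reverse-strand query blocks are normalized to forward coordinates.
    Block size/dt/dq triples must sum to the spans stated in the header.
    """
    path = Path(path)
    blocks: list[ChainBlock] = []
    source_name = target_name = ""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i]
        if not line or line.startswith("#"):
            i += 1
            continue
        if not line.startswith("chain"):
            raise FormatError(f"{path}:{i + 1}: expected chain header, got {line!r}")
        parts = line.split()
        if len(parts) < 12:
            raise FormatError(f"{path}:{i + 1}: malformed chain header")
        (_, _score, t_name, _t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end) = parts[:12]
        t_start, t_end = int(t_start), int(t_end)
        q_size, q_start, q_end = int(q_size), int(q_start), int(q_end)
        if t_strand != "+":
            raise FormatError(f"{path}:{i + 1}: chain tStrand must be '+'")
        source_name, target_name = t_name, q_name
        i += 1
        t_pos, q_pos = t_start, q_start
        done = False
        while i < n and not done:
            body = lines[i]
            i += 1
            if not body:
                continue
            nums = body.split()
            size = int(nums[0])
            dt = int(nums[1]) if len(nums) > 1 else 0
            dq = int(nums[2]) if len(nums) > 2 else 0
            if size > 0:
                if q_strand == "+":
                    q_iv = GenomicInterval(q_name, q_pos, q_pos + size)
                else:
                    # q coordinates counted on the reverse strand; normalize
                    q_iv = GenomicInterval(q_name, q_size - (q_pos + size), q_size - q_pos)
                blocks.append(ChainBlock(GenomicInterval(t_name, t_pos, t_pos + size), q_iv))
            t_pos += size + dt
            q_pos += size + dq
            if len(nums) == 1:
                done = True
        if t_pos != t_end or q_pos != q_end:
            raise FormatError(
                f"{path}: chain blocks sum to ({t_pos}, {q_pos}), header states ({t_end}, {q_end})"
            )
    if not blocks:
        raise FormatError(f"{path}: chain file contains no alignment blocks")
    return ChainMap(source_name, target_name, blocks)


def write_chain(chain: ChainMap, path: str | Path, source_sizes: dict[str, int], target_sizes: dict[str, int]) -> None:
    """Write a ChainMap as one UCSC chain per (source contig, target contig) run."""
    with open(path, "w") as fh:
        runs: list[list[ChainBlock]] = []
        for b in sorted(chain.blocks, key=lambda b: (b.source.contig, b.source.start)):
            if runs and runs[-1][-1].source.contig == b.source.contig and runs[-1][-1].target.contig == b.target.contig:
                runs[-1].append(b)
            else:
                runs.append([b])
        for chain_id, run in enumerate(runs, start=1):
            t_name = run[0].source.contig
            q_name = run[0].target.contig
            t_size = source_sizes[t_name]
            q_size = target_sizes[q_name]
            t_start, t_end = run[0].source.start, run[-1].source.end
            q_start, q_end = run[0].target.start, run[-1].target.end
            fh.write(
                f"chain 1000 {t_name} {t_size} + {t_start} {t_end} "
                f"{q_name} {q_size} + {q_start} {q_end} {chain_id}\n"
            )
            for j, b in enumerate(run):
                size = len(b.source)
                if j == len(run) - 1:
                    fh.write(f"{size}\n")
                else:
                    dt = run[j + 1].source.start - b.source.end
                    dq = run[j + 1].target.start - b.target.end
                    fh.write(f"{size}\t{dt}\t{dq}\n")
            fh.write("\n")


def write_table(records: pd.DataFrame | Sequence[dict], path: str | Path) -> None:
    """Write records as a TSV with a header row."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
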