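"""Pangenome consensus probe sets and cross-reference bookkeeping.

Integrates per-assembly probe classifications into consensus sets (a probe
enters when it is unambiguous in at least a fraction ``consensus_frac`` of
the panel's haplotype assemblies), per-population sets, and four-way
partitions comparing two reference genomes, with the percentage summaries
used in tabular reporting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

logger = logging.getLogger("methref")

# The status maps consumed here are {probe_id: status-string} with status in
# probemap.STATUSES; only "unambiguous" matters for set membership.

POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")
SUBPOPULATIONS = (
    "ACB", "ASW", "ESN", "GWD", "MKK", "MSL", "YRI",  # AFR
    "CLM", "PEL", "PUR",                              # AMR
    "CHS", "KHV",                                     # EAS
)


@dataclass
class AssemblyPanel:
    """Named haplotype assemblies with population / subpopulation labels."""

    assemblies: list[str]
    population: dict[str, str] = field(default_factory=dict)
    subpopulation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.assemblies)) != len(self.assemblies):
            raise ValueError("assembly names must be unique")
        missing = [a for a in self.assemblies if a not in self.population]
        if missing:
            raise ValueError(f"assemblies without a population label: {missing}")

    def by_population(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for a in self.assemblies:
            out.setdefault(self.population[a], []).append(a)
        return out

    def by_subpopulation(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for a in self.assemblies:
            if a in self.subpopulation:
                out.setdefault(self.subpopulation[a], []).append(a)
        return out


@dataclass
class FourWayPartition:
    """Probe sets both / A-unique / B-unique / neither for references A, B."""

    name_a: str
    name_b: str
    both: set[str]
    a_unique: set[str]
    b_unique: set[str]
    neither: set[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "both": len(self.both),
            f"{self.name_a}_unique": len(self.a_unique),
            f"{self.name_b}_unique": len(self.b_unique),
            "neither": len(self.neither),
        }

    @property
    def total(self) -> int:
        return len(self.both) + len(self.a_unique) + len(self.b_unique) + len(self.neither)

    @property
    def discordant(self) -> int:
        return len(self.a_unique) + len(self.b_unique)


def consensus_threshold(n_assemblies: int, consensus_frac: float) -> int:
    """Number of assemblies a probe must be unambiguous in to enter the set.

    "No less than ``consensus_frac``" of an integer count reads as
    ceiling(frac x N); small panels (N < 5) require all assemblies, per the
    population-level rule.
    """
    if n_assemblies < 5:
        return n_assemblies
    return math.ceil(consensus_frac * n_assemblies)


def consensus_unambiguous(
    status_by_assembly: dict[str, dict[str, str]],
    assemblies: list[str],
    consensus_frac: float = 0.95,
) -> set[str]:
    """Probes unambiguous in at least the consensus fraction of assemblies."""
    if not assemblies:
        raise ValueError("empty assembly panel")
    missing = [a for a in assemblies if a not in status_by_assembly]
    if missing:
        raise ValueError(f"no status map for assemblies: {missing}")
    need = consensus_threshold(len(assemblies), consensus_frac)
    probes = set(status_by_assembly[assemblies[0]])
    for a in assemblies[1:]:
        if set(status_by_assembly[a]) != probes:
            raise ValueError("status maps cover different probe sets")
    out = {
        p
        for p in probes
        if sum(status_by_assembly[a][p] == "unambiguous" for a in assemblies) >= need
    }
    logger.info(
        "consensus over %d assemblies (need %d): %d of %d probes",
        len(assemblies), need, len(out), len(probes),
    )
    return out


def population_sets(
    status_by_assembly: dict[str, dict[str, str]],
    panel: AssemblyPanel,
    consensus_frac: float = 0.95,
    level: str = "population",
) -> dict[str, set[str]]:
    """Per-population (or per-subpopulation) consensus probe sets."""
    groups = panel.by_population() if level == "population" else panel.by_subpopulation()
    out: dict[str, set[str]] = {}
    for label, members in groups.items():
        if not members:
            logger.warning("population %s has no assemblies; omitted", label)
            continue
        out[label] = consensus_unambiguous(status_by_assembly, members, consensus_frac)
    return out


def compare_reference_sets(
    status_a: dict[str, str],
    status_b: dict[str, str],
    name_a: str = "A",
    name_b: str = "B",
) -> FourWayPartition:
    """Four-way partition of a manifest by unambiguity under two references."""
    if set(status_a) != set(status_b):
        raise ValueError("the two status maps cover different manifests")
    ua = {p for p, s in status_a.items() if s == "unambiguous"}
    ub = {p for p, s in status_b.items() if s == "unambiguous"}
    allp = set(status_a)
    return FourWayPartition(
        name_a, name_b,
        both=ua & ub,
        a_unique=ua - ub,
        b_unique=ub - ua,
        neither=allp - (ua | ub),
    )


def summarize_classification(counts: dict[str, int], manifest_size: int) -> dict[str, float | int | None]:
    """Percentage / fold summaries of classification counts.

    Percentages are reported to one decimal, folds between counts to two
    decimals; a zero denominator yields None (flagged in the log).
    """
    if sum(counts.values()) > manifest_size:
        raise ValueError("counts exceed the manifest size")
    out: dict[str, float | int | None] = dict(counts)
    for key, value in counts.items():
        if manifest_size == 0:
            logger.warning("summarize_classification: zero manifest size")
            out[f"{key}_pct"] = None
        else:
            out[f"{key}_pct"] = round(100 * value / manifest_size, 1)
    return out


def percentage(part: int, whole: int) -> float:
    """Percentage to one decimal, the convention of the summary tables."""
    if whole == 0:
        raise ZeroDivisionError("zero denominator")
    return round(100 * part / whole, 1)


def fold_ratio(a: int, b: int) -> float:
    """Fold ratio between two counts, to two decimals."""
    if b == 0:
        raise ZeroDivisionError("zero denominator")
    return round(a / b, 2)
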