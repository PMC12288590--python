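"""Pipeline-wide numeric parameters.

Every tunable constant used by the probe aligner, consensus rules, CpG
filters, EWAS thresholds and annotation band widths lives here, so a single
:class:`Parameters` instance documents the full configuration of a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class Parameters:
    """Numeric constants governing every pipeline stage.

    Attributes
    ----------
    identity_min : float
        Minimum alignment identity (matches / aligned length) for a probe
        placement to qualify.
    match_min : int
        Minimum number of identical aligned bases (out of the 50-nt probe).
    tile_size, step_size, rep_match : int
        Seed-index configuration: k-mer length, genome sampling stride, and
        the occurrence count above which a tile is masked as repetitive.
    consensus_frac : float
        Fraction of panel assemblies in which a probe must be unambiguous to
        enter a consensus set.
    coverage_min : int
        Minimum per-sample read coverage for a CpG call.
    delta_min : float
        Minimum absolute between-group beta difference for significance.
    fdr_max : float
        FDR threshold for significance calls.
    n_perm : int
        Number of label permutations (permutation FDR, driver enrichment).
    promoter_upstream : int
        Promoter definition: bases upstream of the TSS, strand-aware.
    shore_width, shelf_width : int
        Widths of the CpG shore and shelf bands flanking islands, in bp.
    cgi_min_len : int
        Minimum CpG-island length in bp.
    cgi_gc_min : float
        Minimum GC fraction of an island window (exclusive threshold).
    cgi_oe_min : float
        Minimum observed/expected CpG ratio of an island window (exclusive).
    """

    identity_min: float = 0.90
    match_min: int = 40
    tile_size: int = 11
    step_size: int = 5
    rep_match: int = 1_000_000
    consensus_frac: float = 0.95
    coverage_min: int = 10
    delta_min: float = 0.10
    fdr_max: float = 0.05
    n_perm: int = 1000
    promoter_upstream: int = 2000
    shore_width: int = 2000
    shelf_width: int = 2000
    cgi_min_len: int = 200
    cgi_gc_min: float = 0.50
    cgi_oe_min: float = 0.6
    autosomes: tuple = field(default_factory=lambda: tuple(f"chr{i}" for i in range(1, 23)))

    def __post_init__(self) -> None:
        for name in ("identity_min", "consensus_frac", "cgi_gc_min"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        for name in (
            "match_min", "tile_size", "step_size", "rep_match", "coverage_min",
            "n_perm", "promoter_upstream", "shore_width", "shelf_width",
            "cgi_min_len",
        ):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if not 0 < self.delta_min < 1:
            raise ValueError("delta_min must lie in (0, 1)")
        if not 0 < self.fdr_max < 1:
            raise ValueError("fdr_max must lie in (0, 1)")
        if self.cgi_oe_min <= 0:
            raise ValueError("cgi_oe_min must be positive")

    def to_dict(self) -> dict:
        return asdict(self)
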