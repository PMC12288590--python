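"""Seeded generators for every input the pipeline consumes, with planted truth.

The generators emulate the study's data shapes at desk scale: pairs/panels
of assemblies sharing a backbone but differing by extra sequence blocks
(present only in the "complete" assembly), planted segmental duplications,
tandem (satellite-like) repeats and per-haplotype SNVs; probe manifests
with planted unambiguous / cross-reactive / mismatched probes; two-group
beta-value matrices with planted differential methylation, technical
replicates, and matching binomially sampled cytosine reports. Every
planted event is recorded in a machine-readable truth table, and the
base-to-complete chain is emitted by the generator itself (it knows the
edit script), so liftover can be checked against exact truth.

All randomness flows through one ``numpy.random.default_rng(seed)``;
identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bisulfite import convert_methylated, enumerate_cpgs
from .consensus import AssemblyPanel, POPULATIONS, SUBPOPULATIONS
from .enrichment import Gene
from .io import Assembly, ChainBlock, ChainMap, GenomicInterval, MethylationCall, Probe

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# assembly panel


@dataclass
class PanelConfig:
    """Layout of the synthetic assembly panel.

    One backbone contig carries planted CpG-dense (island-like) regions,
    tandem-repeat arrays and segmental duplications; the "complete"
    assembly additionally contains extra sequence blocks absent from the
    "base" assembly; haplotypes add per-assembly SNVs and, optionally, a
    population-private duplication.
    """

    contig: str = "chr1"
    backbone_length: int = 30_000
    n_islands: int = 4
    island_length: int = 400
    n_tandem_repeats: int = 2
    tandem_unit: int = 6
    tandem_copies: int = 30
    n_duplications: int = 2
    duplication_length: int = 300
    n_extra_blocks: int = 2
    extra_block_length: int = 1_000
    n_haplotypes: int = 0
    snv_rate: float = 0.001
    private_dup_population: str | None = None
    background_cpg_retention: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.snv_rate <= 1:
            raise ValueError("snv_rate must lie in [0, 1]")
        for name in ("backbone_length", "island_length", "tandem_unit", "tandem_copies",
                     "duplication_length", "extra_block_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PanelResult:
    base: Assembly
    complete: Assembly
    haplotypes: list[Assembly]
    panel: AssemblyPanel | None
    chain_base_to_complete: ChainMap
    tracks: dict[str, list[GenomicInterval]]
    genes: list[Gene]
    truth: pd.DataFrame
    config: PanelConfig


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _deplete_cpgs(rng: np.random.Generator, seq: np.ndarray, retention: float) -> None:
    """Destroy a fraction of background CG dinucleotides in place.

    Mammalian genomes are CpG-depleted outside islands (methylated CpGs
    deaminate); without depletion a uniform background would satisfy the
    island observed/expected threshold almost everywhere.
    """
    cg = np.flatnonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))
    kill = cg[rng.random(len(cg)) > retention]
    seq[kill + 1] = np.where(rng.random(len(kill)) < 0.5, ord("A"), ord("T")).astype(np.uint8)


def _cpg_rich_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    """GC-rich sequence with frequent CG dinucleotides (island substrate)."""
    out = np.empty(length, dtype=np.uint8)
    i = 0
    while i < length:
        if rng.random() < 0.35 and i + 1 < length:
            out[i], out[i + 1] = ord("C"), ord("G")
            i += 2
        else:
            out[i] = BASES[rng.choice(4, p=[0.15, 0.35, 0.35, 0.15])]
            i += 1
    return out


def _allocate_slots(rng: np.random.Generator, total: int, lengths: list[int], pad: int = 100) -> list[int]:
    """Non-overlapping start positions for planted features, by rejection."""
    taken: list[tuple[int, int]] = []
    starts: list[int] = []
    for length in lengths:
        for _ in range(10_000):
            s = int(rng.integers(pad, total - length - pad))
            if all(s + length + pad <= a or s >= b + pad for a, b in taken):
                taken.append((s, s + length))
                starts.append(s)
                break
        else:
            raise ValueError("config demands more planted events than the genome accommodates")
    return starts


def generate_assembly_panel(config: PanelConfig) -> PanelResult:
    """Base + complete assemblies, haplotype panel, chain and truth."""
    rng = np.random.default_rng(config.seed)
    L = config.backbone_length
    seq = _random_seq(rng, L)
    _deplete_cpgs(rng, seq, config.background_cpg_retention)
    truth_rows: list[dict] = []
    tracks: dict[str, list[GenomicInterval]] = {"segdup": [], "satellite": [], "island": [], "line_sine": []}
    contig = config.contig

    tandem_len = config.tandem_unit * config.tandem_copies
    lengths = (
        [config.island_length] * config.n_islands
        + [tandem_len] * config.n_tandem_repeats
        + [config.duplication_length] * (2 * config.n_duplications)
    )
    starts = _allocate_slots(rng, L, lengths)
    island_starts = starts[: config.n_islands]
    tandem_starts = starts[config.n_islands : config.n_islands + config.n_tandem_repeats]
    dup_starts = starts[config.n_islands + config.n_tandem_repeats :]

    for s in island_starts:
        seq[s : s + config.island_length] = _cpg_rich_seq(rng, config.island_length)
        tracks["island"].append(GenomicInterval(contig, s, s + config.island_length))
        truth_rows.append({"kind": "island", "identifier": f"island:{s}", "contig": contig,
                           "start": s, "end": s + config.island_length, "label": "planted_cpg_dense"})
    for s in tandem_starts:
        unit = _random_seq(rng, config.tandem_unit)
        seq[s : s + tandem_len] = np.tile(unit, config.tandem_copies)
        tracks["satellite"].append(GenomicInterval(contig, s, s + tandem_len))
        truth_rows.append({"kind": "tandem_repeat", "identifier": f"tandem:{s}", "contig": contig,
                           "start": s, "end": s + tandem_len, "label": "planted_satellite"})
    for i in range(config.n_duplications):
        src, dst = dup_starts[2 * i], dup_starts[2 * i + 1]
        dlen = config.duplication_length
        # guarantee CpGs inside the duplicated segment so probes can target it
        segment = _random_seq(rng, dlen)
        for off in range(20, dlen - 20, 60):
            segment[off], segment[off + 1] = ord("C"), ord("G")
        seq[src : src + dlen] = segment
        seq[dst : dst + dlen] = segment
        for s in (src, dst):
            tracks["segdup"].append(GenomicInterval(contig, s, s + dlen))
        truth_rows.append({"kind": "duplication", "identifier": f"dup:{src}->{dst}", "contig": contig,
                           "start": src, "end": src + dlen, "label": f"copy_at:{dst}"})

    base = Assembly("base", {contig: seq.tobytes().decode()})

    # complete assembly: insert extra blocks into the backbone
    insert_positions = sorted(
        int(p) for p in rng.integers(1_000, L - 1_000, size=config.n_extra_blocks)
    ) if config.n_extra_blocks else []
    blocks_seq = [_cpg_rich_seq(rng, config.extra_block_length) for _ in insert_positions]
    pieces: list[np.ndarray] = []
    chain_blocks: list[ChainBlock] = []
    prev = 0
    offset = 0
    for pos, block in zip(insert_positions, blocks_seq):
        pieces.append(seq[prev:pos])
        if pos > prev:
            chain_blocks.append(
                ChainBlock(
                    GenomicInterval(contig, prev, pos),
                    GenomicInterval(contig, prev + offset, pos + offset),
                )
            )
        truth_rows.append({"kind": "extra_block", "identifier": f"extra:{pos}", "contig": contig,
                           "start": pos, "end": pos,
                           "label": f"complete_coords:{pos + offset}-{pos + offset + len(block)}"})
        pieces.append(block)
        offset += len(block)
        prev = pos
    pieces.append(seq[prev:])
    if L > prev:
        chain_blocks.append(
            ChainBlock(GenomicInterval(contig, prev, L), GenomicInterval(contig, prev + offset, L + offset))
        )
    complete = Assembly("complete", {contig: np.concatenate(pieces).tobytes().decode()})
    chain = ChainMap("base", "complete", chain_blocks)

    # haplotypes: base backbone + per-assembly SNVs (+ private duplication)
    haplotypes: list[Assembly] = []
    panel: AssemblyPanel | None = None
    if config.n_haplotypes:
        pops = [POPULATIONS[i % len(POPULATIONS)] for i in range(config.n_haplotypes)]
        subs = [SUBPOPULATIONS[i % len(SUBPOPULATIONS)] for i in range(config.n_haplotypes)]
        names = [f"hap{i:03d}" for i in range(config.n_haplotypes)]
        for name, pop in zip(names, pops):
            hseq = seq.copy()
            n_snv = rng.binomial(L, config.snv_rate)
            if n_snv:
                snv_pos = rng.choice(L, size=n_snv, replace=False)
                for p in snv_pos:
                    current = hseq[p]
                    alternatives = BASES[BASES != current]
                    hseq[p] = alternatives[rng.integers(0, 3)]
                truth_rows.append({"kind": "snv_set", "identifier": f"snv:{name}", "contig": contig,
                                   "start": -1, "end": -1,
                                   "label": ",".join(str(int(p)) for p in sorted(snv_pos))})
            if config.private_dup_population is not None and pop == config.private_dup_population:
                dlen = config.duplication_length
                src = int(rng.integers(1_000, L // 2))
                dst = int(rng.integers(L // 2, L - dlen - 1_000))
                hseq[dst : dst + dlen] = hseq[src : src + dlen]
                truth_rows.append({"kind": "private_duplication", "identifier": f"privdup:{name}",
                                   "contig": contig, "start": src, "end": src + dlen,
                                   "label": f"copy_at:{dst};population:{pop}"})
            haplotypes.append(Assembly(name, {contig: hseq.tobytes().decode()}))
        panel = AssemblyPanel(names, dict(zip(names, pops)), dict(zip(names, subs)))

    genes = _plant_genes(rng, contig, L)
    truth = pd.DataFrame(truth_rows)
    return PanelResult(base, complete, haplotypes, panel, chain, tracks, genes, truth, config)


def _plant_genes(rng: np.random.Generator, contig: str, length: int, n_genes: int = 20) -> list[Gene]:
    """Random non-overlapping gene spans with strand, for annotation tests."""
    genes: list[Gene] = []
    span = length // n_genes
    for i in range(n_genes):
        lo = i * span
        g_len = int(rng.integers(span // 4, span // 2))
        g_start = lo + int(rng.integers(0, span - g_len))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(f"gene{i:03d}", GenomicInterval(contig, g_start, g_start + g_len, strand)))
    return genes


# ---------------------------------------------------------------------------
# probe manifest


@dataclass
class ManifestConfig:
    n_unambiguous: int = 20
    n_cross_reactive: int = 20
    n_mismatched: int = 20
    frac_type2_with_r: float = 0.3
    n_substitutions_mismatch: int = 11
    seed: int = 0


def generate_probe_manifest(
    panel: PanelResult, config: ManifestConfig
) -> tuple[list[Probe], pd.DataFrame]:
    """Manifest of planted probes against the panel's base assembly.

    Unambiguous probes are 50-mers copied verbatim from the
    CpG-methylated forward-converted genome at unique loci; cross-reactive
    probes are copied from inside planted duplications (two identical
    loci); mismatched probes carry either ``n_substitutions_mismatch``
    substitutions (no qualifying placement: fewer than 40 of 50 bases
    match) or a damaged target CpG. A fraction of type II probes carries
    one R base consistent with an A or G at that position.
    """
    rng = np.random.default_rng(config.seed)
    assembly = panel.base
    contig = config_contig = panel.config.contig
    seq = assembly[contig]
    converted = convert_methylated(seq)
    cpgs = enumerate_cpgs(assembly).positions[contig]

    repeat_ivs = panel.tracks["segdup"] + panel.tracks["satellite"]

    def in_repeat(p: int) -> bool:
        return any(iv.start - 50 <= p < iv.end + 50 for iv in repeat_ivs)

    unique_cpgs = [int(p) for p in cpgs if 24 <= p <= len(seq) - 26 and not in_repeat(int(p))]
    dup_cpgs = []
    for iv in panel.tracks["segdup"]:
        for p in cpgs:
            if iv.start + 24 <= p <= iv.end - 26:
                dup_cpgs.append(int(p))
    # one probe per physical duplicated window: use only source-copy CpGs
    dup_cpgs = sorted(set(dup_cpgs))
    need_unique = config.n_unambiguous + config.n_mismatched
    if len(unique_cpgs) < need_unique or len(dup_cpgs) < config.n_cross_reactive:
        raise ValueError("requested probe counts exceed available loci")
    chosen_unique = list(rng.choice(unique_cpgs, size=need_unique, replace=False))
    chosen_dup = list(rng.choice(dup_cpgs, size=config.n_cross_reactive, replace=False))

    probes: list[Probe] = []
    truth_rows: list[dict] = []

    def window(p: int) -> str:
        return converted[p - 24 : p + 26]

    def maybe_add_r(s: str, design: str) -> str:
        if design == "II" and rng.random() < config.frac_type2_with_r:
            candidates = [i for i, b in enumerate(s) if b in "AG" and i not in (24, 25)]
            if candidates:
                i = int(rng.choice(candidates))
                s = s[:i] + "R" + s[i + 1 :]
        return s

    counter = 0

    def add(p: int, s: str, label: str):
        nonlocal counter
        design = "II" if rng.random() < 0.7 else "I"
        if label != "mismatched":
            s = maybe_add_r(s, design)
        pid = f"cg{counter:06d}"
        counter += 1
        probes.append(Probe(pid, s, design, GenomicInterval(config_contig, p, p + 2, "+")))
        truth_rows.append({"kind": "probe", "identifier": pid, "contig": config_contig,
                           "start": p, "end": p + 2, "label": label})

    for p in chosen_unique[: config.n_unambiguous]:
        add(p, window(p), "unambiguous")
    for p in chosen_dup:
        add(p, window(p), "cross_reactive")
    for j, p in enumerate(chosen_unique[config.n_unambiguous :]):
        s = list(window(p))
        if j % 2 == 0:
            # heavy substitution load: below the 40-of-50 match floor everywhere
            positions = rng.choice([i for i in range(50) if i not in (24, 25)],
                                   size=config.n_substitutions_mismatch, replace=False)
            for i in positions:
                alternatives = [b for b in "ACGT" if b != s[i]]
                s[i] = alternatives[int(rng.integers(0, 3))]
        else:
            # perfect probe with a damaged target CpG: qualifies but fails the
            # perfect-CpG-locus rule
            s[24] = "A" if s[24] != "A" else "T"
        add(p, "".join(s), "mismatched")

    return probes, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# methylation dataset


@dataclass
class MethylationConfig:
    n_sites: int = 2_000
    n_case: int = 10
    n_control: int = 10
    frac_dmc: float = 0.05
    delta: float = 0.3
    precision: float = 50.0
    n_replicates: int = 0
    technical_sd: float = 0.016
    coverage: float = 30.0
    contig: str = "chr1"
    seed: int = 0


@dataclass
class MethylationResult:
    betas: pd.DataFrame          # sites x samples
    groups: dict[str, str]
    replicate_betas: pd.DataFrame | None
    reports: dict[str, list[MethylationCall]]
    truth: pd.DataFrame
    config: MethylationConfig


def generate_methylation_dataset(config: MethylationConfig) -> MethylationResult:
    """Two-group beta matrix with planted DMCs plus matching count reports.

    Null sites share one group mean drawn from a mildly bimodal Beta;
    planted DMCs separate the group means by ``delta`` (direction
    alternating, clipped into (0.02, 0.98) with the event recorded).
    Per-sample betas are Beta-distributed around the group mean
    (mean/precision parameterization); technical replicates add Gaussian
    noise of ``technical_sd``; cytosine reports binomially sample reads at
    Poisson(``coverage``) depth so count-derived betas are noisy
    realizations of the matrix.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_sites
    n_dmc = int(round(config.frac_dmc * m))
    is_dmc = np.zeros(m, dtype=bool)
    if n_dmc:
        is_dmc[rng.choice(m, size=n_dmc, replace=False)] = True
    mu_control = rng.beta(0.85, 0.85, size=m) * 0.9 + 0.05
    direction = np.where(rng.random(m) < 0.5, 1.0, -1.0)
    mu_case = mu_control.copy()
    mu_case[is_dmc] += direction[is_dmc] * config.delta
    clipped = (mu_case < 0.02) | (mu_case > 0.98)
    mu_case = np.clip(mu_case, 0.02, 0.98)

    def draw(mu: np.ndarray, n: int) -> np.ndarray:
        a = mu[:, None] * config.precision
        b = (1 - mu[:, None]) * config.precision
        return rng.beta(a, b, size=(m, n))

    case = draw(mu_case, config.n_case)
    control = draw(mu_control, config.n_control)
    sites = [f"{config.contig}:{100 * (i + 1)}" for i in range(m)]
    samples = [f"case{i:02d}" for i in range(config.n_case)] + [
        f"control{i:02d}" for i in range(config.n_control)
    ]
    betas = pd.DataFrame(np.hstack([case, control]), index=sites, columns=samples)
    groups = {s: ("case" if s.startswith("case") else "control") for s in samples}

    replicate_betas = None
    if config.n_replicates >= 2:
        base_sample = betas[samples[0]].to_numpy()
        reps = np.clip(
            base_sample[:, None] + rng.normal(0, config.technical_sd, size=(m, config.n_replicates)),
            0.0, 1.0,
        )
        replicate_betas = pd.DataFrame(
            reps, index=sites, columns=[f"rep{i:02d}" for i in range(config.n_replicates)]
        )

    reports: dict[str, list[MethylationCall]] = {}
    for j, s in enumerate(samples):
        coverage = rng.poisson(config.coverage, size=m)
        meth = rng.binomial(coverage, betas[s].to_numpy())
        reports[s] = [
            MethylationCall(config.contig, 100 * (i + 1), int(meth[i]), int(coverage[i] - meth[i]))
            for i in range(m)
        ]

    truth = pd.DataFrame(
        {
            "kind": "dmc_site",
            "identifier": sites,
            "is_dmc": is_dmc,
            "mu_control": mu_control,
            "mu_case": mu_case,
            "delta": mu_case - mu_control,
            "clipped": clipped,
        }
    )
    return MethylationResult(betas, groups, replicate_betas, reports, truth, config)


# ---------------------------------------------------------------------------
# gene sets


@dataclass
class GeneSetConfig:
    driver_fraction: float = 0.1
    n_pathways: int = 10
    pathway_size: int = 15
    seed: int = 0


def generate_gene_sets(
    genes: list[str], config: GeneSetConfig, enriched_target: set[str] | None = None
) -> tuple[set[str], dict[str, set[str]], pd.DataFrame]:
    """Driver-gene list and pathway (GMT-style) sets over a gene universe.

    A ``driver_fraction`` of the universe is labeled driver; pathways are
    sampled uniformly, except that when ``enriched_target`` is given the
    first pathway is built to contain all of it (a planted enrichment).
    """
    rng = np.random.default_rng(config.seed)
    universe = sorted(genes)
    n_driver = int(round(config.driver_fraction * len(universe)))
    drivers = set(rng.choice(universe, size=n_driver, replace=False))
    pathways: dict[str, set[str]] = {}
    truth_rows = [{"kind": "driver_set", "identifier": "drivers", "label": ",".join(sorted(drivers))}]
    for i in range(config.n_pathways):
        name = f"pathway{i:02d}"
        if i == 0 and enriched_target:
            extra = [g for g in universe if g not in enriched_target]
            pad = max(0, config.pathway_size - len(enriched_target))
            members = set(enriched_target) | set(rng.choice(extra, size=min(pad, len(extra)), replace=False))
        else:
            members = set(rng.choice(universe, size=min(config.pathway_size, len(universe)), replace=False))
        if not members:
            continue
        pathways[name] = members
        truth_rows.append({"kind": "pathway", "identifier": name, "label": ",".join(sorted(members))})
    return drivers, pathways, pd.DataFrame(truth_rows)
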