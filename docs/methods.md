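# Methods

This note documents the models, algorithms and numerical choices behind
methref, in the order of the pipeline.

## Coordinates and formats

All internal coordinates are 0-based half-open; the two 1-based input
dialects (Illumina-style manifests via the MAPINFO position column, and
Bismark cytosine coverage reports) are shifted exactly once, inside their
readers. BED and UCSC chain files are consumed in their native
conventions; reverse-strand chain blocks are normalized to forward
coordinates at read time so downstream point liftover handles a single
orientation. Cytosine-report beta values are always recomputed from the
methylated/unmethylated counts; a percentage column disagreeing with the
counts by more than 0.5 points triggers a warning and the counts win.
Every pipeline stage logs input, filtered and output counts so the
partition-style bookkeeping is auditable.

## Bisulfite-converted genomes and probe alignment

Bisulfite chemistry reads unmethylated C as T and leaves methylated C
intact, so probe hybridization targets are modeled by four converted
variants of each assembly: all-C→T and CpG-protected (only non-CpG C→T),
each on the forward strand and on the reverse complement. N passes
through all conversions unchanged.

The aligner is a gapless seed-and-extend: genome 11-mers sampled every 5
bases are indexed (tiles occurring more than 1,000,000 times are masked —
inert at desk scale but kept for configuration fidelity); every probe
11-mer is looked up, each seed implies an ungapped placement, duplicates
are collapsed, and placements are scored as matches over the in-bounds
aligned span. A placement qualifies with ≥ 40 matching bases and identity
≥ 0.90. Gapless-only alignment is a deliberate design: the qualification
rule rejects gapped placements anyway, so a general aligner would add
machinery without changing any decision. Using the in-bounds span as the
identity denominator reconciles the otherwise redundant dual thresholds:
a probe overhanging a contig end can still reach identity 0.90 but may
fail the 40-base floor.

Degenerate R bases (type II probes) are expanded to both A and G before
alignment; hits from all expansions and all four variants are mapped to
forward source coordinates and collapsed into physical loci with a ±2 bp
start tolerance, because one physical locus necessarily surfaces in
complementary variants and in both expansions — counting those copies
separately would label nearly every probe cross-reactive. A probe is then
*mismatched* when no collapsed locus overlaps its declared target with
both bases of the CpG dinucleotide aligned and identical; *unambiguous*
when it has a target-perfect locus and exactly one locus in total; and
*cross-reactive* otherwise. The CpG-perfection test applies only to the
target-defining locus; secondary loci count toward uniqueness whether or
not their CpG is intact. Manifest rows targeting a contig absent from the
assembly are classified mismatched (logged), not raised. The "extension
base" subtype of mismatch that array re-annotation efforts derive from
next-base manifest fields is out of scope: those fields are not part of
the manifest contract here, and silently broadening the mismatch class
was judged worse than documenting the omission.

## CpG islands

Islands follow the classical definition: maximal merged runs of 200-bp
windows with GC fraction > 0.50 and observed/expected CpG ratio > 0.6,
where expected = #C·#G/length; merged regions are re-verified against
both thresholds over their full span and dropped if they fail. Windows
with more than 10% N are ineligible — a conservative choice, since the
definition itself is silent on ambiguous bases. This is a
definition-driven caller; the UCSC island-track algorithm differs in its
mechanics and is intentionally not reproduced.

## Consensus sets

"Unambiguous in no less than 95% of N assemblies" is realized as a count
threshold of ceiling(0.95·N) — the only reading that never admits less
than 95% — with panels of fewer than five assemblies requiring unanimity.
Population and subpopulation sets apply the same rule restricted to each
label's assemblies. The synthetic panel labels assemblies with the five
continental population codes and twelve subpopulation codes purely as
vocabulary; no claim is made of matching any real panel's composition.

## CpG calling, liftover and set comparison

A sequencing-derived CpG survives when its total read count reaches the
coverage floor (default 10×) in *every* sample; the autosome filter is a
configurable contig list (default chr1–chr22) rather than being inferred,
since synthetic contigs have arbitrary names. Strand merging sums a
G-strand call at p+1 onto its C-strand partner at p, but only when the
reference actually has CG there; other adjacent pairs are left unmerged
with a warning. Point liftover maps positions inside chain blocks by
offset and reports gap positions unmapped. In cross-reference
comparisons, B-side calls that fail liftover count toward B-unique — they
cannot intersect — and A-unique is defined by excluding all intersecting
CpGs from A's calls. Aligned reads are consumed as BED intervals; BAM
conversion is out of scope, keeping the package free of alignment-tool
dependencies.

## EWAS statistics

Per-site testing is the two-sided Mann-Whitney U test. The scalar
implementation delegates to scipy: exact enumeration when both samples
have ≤ 8 values and no ties, otherwise the tie-corrected normal
approximation with continuity correction. Matrix-wide testing (thousands
of sites × permutations) uses an in-package vectorized implementation of
the same normal approximation: per-site ranks and tie corrections are
computed once and each permutation costs one matrix product, which is
what makes 1,000-permutation runs affordable; tests verify it against
scipy per site to 1e-12.

The permutation FDR uses the plug-in estimator

    FDR(t) = mean over permutations of #{p_perm <= t} / max(1, #{p_obs <= t})

with t\* the largest observed p-value at or below the target (none when
no p qualifies). Permutations shuffle the group-label vector uniformly
(group sizes preserved; the observed labeling is not placed in the null
set; distinctness is not enforced — with 10-vs-10 designs repeats are
rare and the estimator stays unbiased). An alternative reading of
permutation FDR — a per-site null from each site's own permutation
minima — exists and is not implemented; the plug-in estimator is the
declared choice because it yields the single genome-wide p threshold the
downstream DMC rule consumes. Significance additionally requires
|Δβ| > 0.1 with Δβ = mean(case) − mean(control) (both hyper- and
hypomethylation count). Missing betas are dropped pairwise per site;
sites with fewer than two non-missing values in either group are excluded
and counted in the log. Replicate variability is the per-site sample SD
(n−1); array-vs-sequencing differences are |array − WGBS-style beta| over
the cross-platform intersection after the 10× coverage floor.

## Annotation and enrichment

Promoters are the 2-kb strand-aware window upstream of the TSS;
promoter/gene-body flags are per-gene, so a site in an overlapping gene
pair may set both. Island/shore/shelf flags are mutually exclusive by
nearest-edge distance: 0 / (0, 2 kb] / (2 kb, 4 kb] bands measured from
island edges (not midpoints), clipped at contig boundaries; equidistant
ties resolve to the lower-coordinate island. Element enrichment is fold =
target fraction / background fraction with an uncorrected 2×2 Pearson
chi-squared p, BH-adjusted across features. Repeat categories are
assigned with priority segdup > LINE/SINE > satellite > other, mirroring
the track-subtraction order used when such tracks are built. Driver-gene
enrichment re-samples gene sets of the target's size from the universe;
the add-one estimator (1 + exceedances)/(1 + permutations) avoids p = 0
and matches the resolution of a 1,000-permutation test. Pathway
over-representation is a local hypergeometric upper-tail test with BH
across sets — a deliberate stand-in for web-service enrichment tools,
preserving the BH < 0.05 rule while removing any network dependency.

## Synthetic data

The generators produce every input shape the pipeline consumes, from one
seeded RNG, with all planted events in a truth table:

- **Assemblies.** A uniform-composition backbone (default 30 kb) whose
  background CG dinucleotides are depleted to 20% retention — without
  depletion, uniform sequence satisfies the island observed/expected
  threshold almost everywhere, which no real methylome does. Planted
  features occupy non-overlapping slots: CpG-dense island regions,
  tandem-repeat (satellite-like) arrays, and segmental duplications
  written as identical copies at two loci with CpGs guaranteed inside.
  The "complete" assembly inserts extra CpG-rich blocks into the same
  backbone; the chain mapping base to complete coordinates is emitted by
  the generator from its own edit script, so liftover truth is exact
  rather than re-derived by alignment. Haplotypes add per-assembly SNVs
  (default rate 1e-3) and optional population-private duplications.
- **Probes.** Unambiguous probes are 50-mers copied verbatim from the
  CpG-protected forward-converted genome at unique loci; cross-reactive
  probes are copied from inside planted duplications; mismatched probes
  carry either 11 substitutions (below the 40-of-50 floor everywhere) or
  a single damaged target-CpG base (qualifies, fails the CpG rule). A
  fraction of type II probes carries one R base consistent with the A/G
  at that position.
- **Methylation.** Null sites share a group mean drawn from a mildly
  bimodal Beta; planted DMCs separate the means by the configured Δβ
  (default 0.3, the alternating-direction effect used in the power
  checks), clipped into (0.02, 0.98) with the clip recorded. Per-sample
  betas are Beta-distributed around the group mean (precision 50 ≈
  per-site SD 0.07 at β = 0.5, an array-like noise level); technical
  replicates add Gaussian noise of SD 0.016; cytosine reports sample
  binomial reads at Poisson(30) depth, so count-derived betas are noisy
  realizations of the matrix. The defaults — 2,000 sites, 10 cases vs 10
  controls, 5% planted DMCs, 200 permutations in the fast checks and
  1,000 by default in the pipeline — are the conditions under which the
  calibration and power properties are stated.

What the generator does **not** emulate: realistic human variant spectra
or demography, read-level errors and mapping ambiguity, probe chemistry
(type I/II intensity differences, background, dye bias), cell-type
mixtures, or batch structure. Passing the planted-truth suites therefore
demonstrates the correctness of the algorithms under their stated models,
not the end-to-end accuracy of any real-data study.

## Problem sizes and determinism

The test suite and the acceptance script run on 30-kb genomes, 60-probe
manifests, 8-haplotype panels, and 2,000-site × 20-sample matrices with
200 permutations over 10–20 seeds — sizes chosen so every planted-truth
property is exercised end to end while the whole suite completes in well
under a minute of compute per stage. Every stochastic component takes an
explicit seed and is deterministic given it; byte-identical regeneration
of all synthetic outputs is itself a tested property.

## Known limitations

Single-chain point liftover does not implement multi-chain netting or
inversion-aware mapping. The island caller is definition-driven, not a
UCSC-track reproduction. The mismatch class omits the extension-base
subtype (above). Consensus behavior at real-panel scale (94 haplotypes)
is exercised with synthetic status vectors, since real per-population
assembly compositions are not part of this package's inputs.
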