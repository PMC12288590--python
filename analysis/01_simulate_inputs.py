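"""Generate the synthetic study inputs: assembly pair + haplotype panel,
probe manifest with planted classes, methylation dataset, and gene sets.

Writes FASTA/chain/BED/TSV inputs plus truth tables under results/simulated/.
"""

from pathlib import Path

import pandas as pd

from methref import io
from methref.simulate import (
    GeneSetConfig,
    ManifestConfig,
    MethylationConfig,
    PanelConfig,
    generate_assembly_panel,
    generate_gene_sets,
    generate_methylation_dataset,
    generate_probe_manifest,
)

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    panel = generate_assembly_panel(PanelConfig(seed=SEED, n_haplotypes=8))
    io.write_fasta(panel.base, OUT / "base.fa")
    io.write_fasta(panel.complete, OUT / "complete.fa")
    for hap in panel.haplotypes:
        io.write_fasta(hap, OUT / f"{hap.name}.fa")
    io.write_chain(panel.chain_base_to_complete, OUT / "base_to_complete.chain",
                   panel.base.lengths(), panel.complete.lengths())
    for name, track in panel.tracks.items():
        io.write_bed(track, OUT / f"{name}.bed")
    io.write_bed([g.interval for g in panel.genes], OUT / "genes.bed",
                 names=[g.name for g in panel.genes])
    panel.truth.to_csv(OUT / "panel_truth.tsv", sep="\t", index=False)
    pd.DataFrame({
        "assembly": panel.panel.assemblies,
        "population": [panel.panel.population[a] for a in panel.panel.assemblies],
        "subpopulation": [panel.panel.subpopulation[a] for a in panel.panel.assemblies],
    }).to_csv(OUT / "panel.tsv", sep="\t", index=False)

    probes, probe_truth = generate_probe_manifest(panel, ManifestConfig(seed=SEED + 1))
    io.write_probe_manifest(probes, OUT / "manifest.tsv")
    probe_truth.to_csv(OUT / "manifest_truth.tsv", sep="\t", index=False)

    meth = generate_methylation_dataset(MethylationConfig(seed=SEED + 2, n_replicates=4))
    meth.betas.to_csv(OUT / "betas.tsv", sep="\t")
    pd.Series(meth.groups, name="group").rename_axis("sample").to_csv(OUT / "groups.tsv", sep="\t")
    meth.replicate_betas.to_csv(OUT / "replicates.tsv", sep="\t")
    for sample, calls in meth.reports.items():
        io.write_cytosine_report(calls, OUT / f"{sample}.cov")
    meth.truth.to_csv(OUT / "methylation_truth.tsv", sep="\t", index=False)

    gene_names = [g.name for g in panel.genes]
    drivers, pathways, gs_truth = generate_gene_sets(
        gene_names, GeneSetConfig(driver_fraction=0.2, n_pathways=6, pathway_size=6, seed=SEED + 3)
    )
    (OUT / "drivers.txt").write_text("\n".join(sorted(drivers)) + "\n")
    with open(OUT / "pathways.gmt", "w") as fh:
        for name, members in pathways.items():
            fh.write(name + "\tsynthetic\t" + "\t".join(sorted(members)) + "\n")
    gs_truth.to_csv(OUT / "gene_set_truth.tsv", sep="\t", index=False)

    print(f"base assembly: {panel.base.total_length()} bp; "
          f"complete: {panel.complete.total_length()} bp; "
          f"{len(panel.haplotypes)} haplotypes; {len(probes)} probes; "
          f"{meth.betas.shape[0]} methylation sites x {meth.betas.shape[1]} samples")
    print(f"inputs written to {OUT}")


if __name__ == "__main__":
    main()
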