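"""Pangenome-style consensus: classify probes against every haplotype
assembly, then build the cross-panel (>=95%) and per-population consensus
unambiguous probe sets.

Writes results/consensus_sets.tsv with one row per (set, probe).
"""

from pathlib import Path

import pandas as pd

from methref import (
    ConvertedIndexSet,
    Parameters,
    build_converted_set,
    classify_manifest,
    consensus_unambiguous,
    io,
    population_sets,
)
from methref.consensus import AssemblyPanel

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "results" / "simulated"
OUT = ROOT / "results"


def main() -> None:
    params = Parameters()
    probes = io.read_probe_manifest(SIM / "manifest.tsv")
    panel_df = pd.read_csv(SIM / "panel.tsv", sep="\t")
    panel = AssemblyPanel(
        list(panel_df["assembly"]),
        dict(zip(panel_df["assembly"], panel_df["population"])),
        dict(zip(panel_df["assembly"], panel_df["subpopulation"])),
    )

    status_by_assembly = {}
    for name in panel.assemblies:
        asm = io.read_fasta(SIM / f"{name}.fa", name=name)
        index_set = ConvertedIndexSet(build_converted_set(asm), params)
        statuses = classify_manifest(probes, index_set, params)
        status_by_assembly[name] = {pid: st.status for pid, st in statuses.items()}

    consensus = consensus_unambiguous(status_by_assembly, panel.assemblies, params.consensus_frac)
    pop_sets = population_sets(status_by_assembly, panel, params.consensus_frac)

    rows = [{"set": "cross_population", "probe_id": p} for p in sorted(consensus)]
    for label, members in sorted(pop_sets.items()):
        rows.extend({"set": label, "probe_id": p} for p in sorted(members))
    pd.DataFrame(rows).to_csv(OUT / "consensus_sets.tsv", sep="\t", index=False)

    print(f"{len(panel.assemblies)} haplotype assemblies; "
          f"{len(consensus)} cross-panel consensus unambiguous probes of {len(probes)}")
    for label, members in sorted(pop_sets.items()):
        print(f"  {label}: {len(members)} probes")


if __name__ == "__main__":
    main()
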