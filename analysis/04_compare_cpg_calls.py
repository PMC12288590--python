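"""Call CpGs from the per-sample cytosine reports, apply the >=10x
every-sample coverage filter, and compare the CpG repertoires of the two
assemblies through the generator-emitted liftover chain.

Writes results/cpg_comparison.tsv.
"""

from pathlib import Path

import pandas as pd

from methref import (
    Parameters,
    call_cpgs,
    compare_cpg_sets,
    enumerate_cpgs,
    io,
    liftover_positions,
)

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "results" / "simulated"
OUT = ROOT / "results"


def main() -> None:
    params = Parameters()

    # coverage-filtered calls from the sequencing-like reports
    reports = {}
    for path in sorted(SIM.glob("*.cov"))[:4]:  # four samples suffice for the demo
        reports[path.stem] = io.read_cytosine_report(path)
    filtered, sites = call_cpgs(reports, params.coverage_min)
    print(f"{len(reports)} samples: {len(sites)} sites at >={params.coverage_min}x in every sample "
          f"(of {len(next(iter(reports.values())))} reported)")

    # assembly-level CpG repertoires, compared through the chain
    base = io.read_fasta(SIM / "base.fa", name="base")
    complete = io.read_fasta(SIM / "complete.fa", name="complete")
    chain = io.read_chain(SIM / "base_to_complete.chain")
    sites_base = {("chr1", int(p)) for p in enumerate_cpgs(base).positions["chr1"]}
    sites_complete = {("chr1", int(p)) for p in enumerate_cpgs(complete).positions["chr1"]}
    cmp_res = compare_cpg_sets(sites_complete, sites_base, chain)

    mapped, unmapped = liftover_positions(chain, sorted(sites_base))
    summary = {
        "cpgs_complete": cmp_res.n_a,
        "cpgs_base": cmp_res.n_b,
        "lifted_base_cpgs": len(mapped),
        "unmapped_base_cpgs": len(unmapped),
        "intersection": cmp_res.intersection,
        "complete_unique": cmp_res.a_unique,
        "base_unique": cmp_res.b_unique,
        "percent_increase": round(cmp_res.percent_increase, 1),
        "filtered_sequencing_sites": len(sites),
    }
    pd.DataFrame([summary]).to_csv(OUT / "cpg_comparison.tsv", sep="\t", index=False)
    print("CpG repertoire comparison (complete vs base):", summary)


if __name__ == "__main__":
    main()
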