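"""Assemble per-network SNP panels and count the candidate model space.

Maps the simulated SNPs into two toy gene networks, writes the panel table
to results/panels.tsv, and reports the k-way model counts both for the
simulated panels and for the bundled reference panel sizes (which
reproduce the published totals of 173,425 two-way and 26,125,277
three-way candidate models across the five Wnt interactome panels).
"""

from pathlib import Path

import pandas as pd

from mdrscan import genotype_io, network_panel

ROOT = Path(__file__).resolve().parent.parent / "results"

NETWORKS = "netA\tGENEA\nnetA\tGENEB\nnetB\tGENEC\n"
# simulated variants sit at pos 100000*(j+1) on chrom 1
INTERVALS = (
    "GENEA\t1\t50000\t450000\n"
    "GENEB\t1\t450001\t750000\n"
    "GENEC\t1\t750001\t1300000\n"
)


def main() -> None:
    (ROOT / "cohort" / "networks.tsv").write_text(NETWORKS)
    (ROOT / "cohort" / "intervals.tsv").write_text(INTERVALS)
    matrix = genotype_io.read_genotypes(ROOT / "cohort" / "cohort", "ped_map")
    kept, _ = genotype_io.apply_qc(matrix)
    nets = network_panel.read_networks(ROOT / "cohort" / "networks.tsv")
    ivals = network_panel.read_intervals(ROOT / "cohort" / "intervals.tsv")
    mapping = network_panel.map_snps_to_genes(kept.variants, ivals)
    rows = []
    sizes = []
    for net in nets:
        p = network_panel.build_panel(net, mapping, kept)
        sizes.append(p.size)
        rows += [(p.network, s, ";".join(p.snp_to_gene[s])) for s in p.snp_ids]
        print(f"panel {p.network}: {p.size} SNPs, "
              f"{network_panel.count_combinations([p.size], 2)} 2-way models")
    pd.DataFrame(rows, columns=["network", "snp_id", "genes"]).to_csv(
        ROOT / "panels.tsv", sep="\t", index=False
    )

    ref = network_panel.load_reference_panel_sizes()
    two = network_panel.count_combinations(ref.values(), 2)
    three = network_panel.count_combinations(ref.values(), 3)
    print(f"reference panels {dict(ref)}:")
    print(f"  2-way models {two:,}; 3-way models {three:,}; total {two + three:,}")


if __name__ == "__main__":
    main()
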