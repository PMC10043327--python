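"""SNP quality control on the simulated cohort.

Applies the study gates — MAF >= 0.05, exact-HWE p > 1e-4, 0% missing
calls — followed by sliding-window LD pruning (r^2 <= 0.8), and writes the
per-SNP QC report to results/qc_report.tsv.
"""

from pathlib import Path

from mdrscan import genotype_io

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    matrix = genotype_io.read_genotypes(ROOT / "cohort" / "cohort", "ped_map")
    kept, report = genotype_io.apply_qc(matrix)
    pruned = genotype_io.ld_prune(kept)
    report.to_csv(ROOT / "qc_report.tsv", sep="\t", index=False)
    print(f"QC: {matrix.n_snps} SNPs in, {kept.n_snps} pass gates, "
          f"{pruned.n_snps} after LD pruning")
    failed = report[~report["passed"]]
    for _, row in failed.iterrows():
        print(f"  removed {row.snp_id}: {row.reason}")


if __name__ == "__main__":
    main()
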