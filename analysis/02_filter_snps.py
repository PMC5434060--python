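"""Apply the SNP filter cascade to the simulated panel.

Site quality > 20, alternate-allele read support >= 4, per-call GQ >= 10
(failing calls masked to missing), missingness <= 20%, MAF >= 0.01,
biallelic only. Writes the filtered VCF and the per-step survivor report.
"""

from pathlib import Path

from thermoscreen import vcf_filter

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    panel = vcf_filter.read_vcf(str(DATA / "snp_panel.vcf"))
    filtered, report = vcf_filter.filter_variants(panel, vcf_filter.FilterConfig())
    vcf_filter.write_vcf(filtered, str(OUT / "snp_panel.filtered.vcf"))
    report.to_table().to_csv(OUT / "filter_report.tsv", sep="\t", index=False)

    print(report.to_table().to_string(index=False))
    print(f"{report.final_count}/{report.input_count} SNPs pass all filters")


if __name__ == "__main__":
    main()
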