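"""Classify SNP effects on coding transcripts and run the dN/dS screen.

Within each screening locality, a gene needs at least 5 variable SNPs
(within-locality MAF > 0.01) and a site-normalized dN/dS above 1 to be
called positively selected. The control locality is not screened.
"""

from pathlib import Path

import pandas as pd

from thermoscreen import seleffect, syndata, vcf_filter

DATA = Path("results/data")
OUT = Path("results")
SCREENING = ("TAT", "CAT")


def main() -> None:
    geno = vcf_filter.read_vcf(str(DATA / "coding_variants.vcf"))
    geno, _ = vcf_filter.filter_variants(geno, vcf_filter.FilterConfig())
    transcripts = syndata.read_orf_table(DATA / "transcripts.fasta", DATA / "orf_table.tsv")
    samples = pd.read_csv(DATA / "samples.tsv", sep="\t", index_col=0)
    pop_map = samples["locality"]

    site_ids = geno.site_ids()
    annotations = [
        seleffect.classify_variant_effect(
            transcripts[geno.chrom[i]], int(geno.pos[i]), str(geno.ref[i]),
            str(geno.alt[i]), variant_id=site_ids[i],
        )
        for i in range(geno.n_sites)
    ]
    pd.DataFrame([vars(a) for a in annotations]).to_csv(
        OUT / "variant_effects.tsv", sep="\t", index=False
    )

    variable = seleffect.locality_maf_gate(geno, pop_map, min_maf=0.01)
    rows = []
    for loc in SCREENING:
        ids_loc = set(site_ids[variable[loc]])
        genes_loc = sorted({a.gene_id for a in annotations if a.variant_id in ids_loc})
        for gene in genes_loc:
            res = seleffect.gene_dnds(annotations, ids_loc, transcripts[gene], loc)
            rows.append(vars(res))
    dnds = pd.DataFrame(rows)
    dnds.to_csv(OUT / "dnds.tsv", sep="\t", index=False)

    n_eff = pd.Series([a.effect for a in annotations]).value_counts()
    print("variant effects:", dict(n_eff))
    for loc in SCREENING:
        sub = dnds[dnds["locality"] == loc]
        print(
            f"{loc}: {len(sub)} genes with variable SNPs, "
            f"{int(sub['positively_selected'].sum())} positively selected"
        )


if __name__ == "__main__":
    main()
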