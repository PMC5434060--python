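"""Quantify differentiation and relatedness on the filtered SNP panel.

Computes Weir-Cockerham F_ST among and between localities (the simulation
plants a target of 0.2) and builds the UPGMA dendrogram of allele-sharing
distances; samples should group by locality, not by condition.
"""

from pathlib import Path

import pandas as pd

from thermoscreen import popgen, vcf_filter

OUT = Path("results")


def main() -> None:
    panel = vcf_filter.read_vcf(str(OUT / "snp_panel.filtered.vcf"))
    popmap = pd.read_csv(OUT / "data" / "popmap.tsv", sep="\t", index_col=0)["population"]

    fst = popgen.wc_fst(panel, popmap)
    rows = [{"comparison": "all_localities", "fst": fst.genomewide_fst}]
    rows += [{"comparison": f"{a}-{b}", "fst": v} for (a, b), v in fst.pairwise.items()]
    pd.DataFrame(rows).to_csv(OUT / "fst.tsv", sep="\t", index=False)
    per_site = pd.DataFrame(
        {"chrom": panel.chrom, "pos": panel.pos, "fst": fst.per_site()}
    )
    per_site.to_csv(OUT / "fst_per_site.tsv", sep="\t", index=False)

    dist = popgen.allele_sharing_distance(panel)
    tree = popgen.build_dendrogram(dist, panel.samples)
    (OUT / "dendrogram.nwk").write_text(tree.newick + "\n")

    for row in rows:
        print(f"F_ST {row['comparison']}: {row['fst']:.5f}")
    print(f"dendrogram over {len(tree.labels)} samples -> results/dendrogram.nwk")


if __name__ == "__main__":
    main()
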