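"""Intersect DE and PS evidence into the candidate table; check truth recovery.

A candidate gene is differentially expressed AND positively selected in
the same screening locality. Also prints the two-locality overlap
arithmetic for the DE sets (unique/shared counts and percentages).
"""

import json
from pathlib import Path

import pandas as pd

from thermoscreen import screen

DATA = Path("results/data")
OUT = Path("results")
SCREENING = ("TAT", "CAT")


def main() -> None:
    de_sets, stats_parts = {}, []
    for loc in SCREENING:
        res = pd.read_csv(OUT / f"de_{loc}.tsv", sep="\t", index_col=0)
        de_sets[loc] = set(res.index[res["de"]])
        stats_parts.append(
            res.reset_index()[["locality", "gene", "log2fc", "padj"]]
        )
    dnds = pd.read_csv(OUT / "dnds.tsv", sep="\t")
    ps_sets = {
        loc: set(dnds.loc[(dnds["locality"] == loc) & dnds["positively_selected"], "gene_id"])
        for loc in SCREENING
    }
    stats = pd.concat(stats_parts, ignore_index=True).merge(
        dnds.rename(columns={"gene_id": "gene"})[["locality", "gene", "dnds"]],
        on=["locality", "gene"],
        how="outer",
    )
    cand = screen.intersect_candidates(de_sets, ps_sets, stats=stats)
    cand.table.to_csv(OUT / "candidates.tsv", sep="\t", index=False)

    overlap = screen.summarize_de_overlap(de_sets)
    (OUT / "overlap_summary.json").write_text(
        json.dumps(
            {
                "de_counts": overlap.counts,
                "shared": overlap.shared,
                "unique": overlap.unique,
                "pct_unique": overlap.pct_unique,
                "pct_shared": overlap.pct_shared,
                "summed_total": overlap.summed_total,
                "union_total": overlap.union_total,
            },
            indent=2,
        )
        + "\n"
    )

    for loc in SCREENING:
        found = cand.intersection[loc]
        truth = set(
            pd.read_csv(DATA / "truth_candidates.tsv", sep="\t")
            .query("locality == @loc")["gene"]
        )
        tp = len(found & truth)
        print(
            f"{loc}: DE {len(de_sets[loc])}, PS {len(ps_sets[loc])}, "
            f"candidates {len(found)} (recall {tp/len(truth):.2f}, "
            f"precision {tp/max(len(found),1):.2f} vs planted truth)"
        )
    print(
        f"DE overlap: shared {overlap.shared}, summed total {overlap.summed_total}, "
        f"union {overlap.union_total}"
    )


if __name__ == "__main__":
    main()
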