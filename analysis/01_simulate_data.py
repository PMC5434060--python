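"""Generate the synthetic study inputs.

Emulates the common-garden design (3 localities x 2 stages x 2
temperatures x 3 replicates): a multi-population SNP panel with a known
differentiation target, NB gene counts with planted temperature effects,
and coding transcripts with planted syn/nonsyn variants. Writes everything
under results/data/ together with the truth tables downstream stages are
checked against.
"""

from pathlib import Path

import pandas as pd

from thermoscreen import syndata, vcf_filter

SEED = 7
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    data = syndata.simulate_screen_dataset(syndata.ScreenSimConfig(seed=SEED))
    data.counts.to_csv(OUT / "counts.tsv", sep="\t")
    data.samples.to_csv(OUT / "samples.tsv", sep="\t")
    syndata.write_fasta(data.transcripts, OUT / "transcripts.fasta")
    syndata.write_orf_table(data.transcripts, OUT / "orf_table.tsv")
    vcf_filter.write_vcf(data.genotypes, str(OUT / "coding_variants.vcf"))
    data.variants.to_csv(OUT / "truth_variants.tsv", sep="\t", index=False)
    for name, truth in (
        ("truth_de", data.truth_de),
        ("truth_ps", data.truth_ps),
        ("truth_candidates", data.truth_candidates),
    ):
        rows = [
            {"locality": loc, "gene": g} for loc, genes in truth.items() for g in sorted(genes)
        ]
        pd.DataFrame(rows).to_csv(OUT / f"{name}.tsv", sep="\t", index=False)

    panel_cfg = syndata.SnpSimConfig(
        n_populations=3,
        pop_names=("TAT", "CAT", "FAR"),
        samples_per_population=12,
        n_sites=20000,
        target_fst=0.2,
        seed=SEED,
    )
    panel, truth_freqs = syndata.simulate_snp_panel(panel_cfg)
    vcf_filter.write_vcf(panel, str(OUT / "snp_panel.vcf"))
    syndata.population_map(panel).rename_axis("sample_id").to_csv(OUT / "popmap.tsv", sep="\t")
    truth_freqs.to_csv(OUT / "truth_panel_freqs.tsv", sep="\t", index=False)

    print(f"counts: {data.counts.shape[0]} genes x {data.counts.shape[1]} samples")
    print(f"coding variants: {len(data.variants)} across {len(data.transcripts)} transcripts")
    print(f"SNP panel: {panel.n_sites} sites x {panel.n_samples} samples, target F_ST 0.2")
    for loc, genes in data.truth_candidates.items():
        print(f"planted candidates in {loc}: {len(genes)}")


if __name__ == "__main__":
    main()
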