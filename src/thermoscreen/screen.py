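"""Candidate-gene screen: intersect DE and PS evidence, summarize overlaps.

A candidate gene for thermal local adaptation is one that is both
differentially expressed in response to temperature (DE) and carries an
excess of nonsynonymous polymorphism (PS, dN/dS > 1) within the same
locality. ``run_pipeline`` drives the whole analysis end-to-end on
simulated inputs and writes every stage artifact with a manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, popgen, seleffect, syndata, vcf_filter
from .containers import CountMatrix, ModelSpec


@dataclass
class CandidateTable:
    """Per-locality DE, PS and intersection gene sets with per-gene stats."""

    de: dict[str, set[str]]
    ps: dict[str, set[str]]
    intersection: dict[str, set[str]]
    table: pd.DataFrame  # locality, gene, de, ps, candidate (+ stats columns)


def intersect_candidates(
    de: dict[str, set[str]],
    ps: dict[str, set[str]],
    stats: pd.DataFrame | None = None,
) -> CandidateTable:
    """Intersect per-locality DE and PS sets into the candidate table.

    ``stats`` may carry per (locality, gene) supporting columns (log2fc,
    padj, dnds) merged into the output. Localities must match between the
    two inputs; genes are ordered lexicographically.
    """
    if set(de) != set(ps):
        raise ValueError(
            f"locality mismatch between DE ({sorted(de)}) and PS ({sorted(ps)}) inputs"
        )
    inter = {loc: de[loc] & ps[loc] for loc in de}
    rows = []
    for loc in sorted(de):
        for gene in sorted(de[loc] | ps[loc]):
            rows.append(
                {
                    "locality": loc,
                    "gene": gene,
                    "de": gene in de[loc],
                    "ps": gene in ps[loc],
                    "candidate": gene in inter[loc],
                }
            )
    table = pd.DataFrame(rows, columns=["locality", "gene", "de", "ps", "candidate"])
    if stats is not None and len(table):
        table = table.merge(stats, on=["locality", "gene"], how="left")
    return CandidateTable(de=de, ps=ps, intersection=inter, table=table)


@dataclass
class OverlapSummary:
    """Two-locality DE overlap arithmetic (inclusion-exclusion exact)."""

    counts: dict[str, int]
    shared: int
    unique: dict[str, int]
    pct_unique: dict[str, float]
    pct_shared: dict[str, float]
    summed_total: int
    union_total: int
    flags: list[str] = field(default_factory=list)

    def pct_of_total(self) -> dict[str, float]:
        """Each locality's share of the summed total, to one decimal."""
        if self.summed_total == 0:
            return {loc: 0.0 for loc in self.counts}
        return {
            loc: round(100.0 * n / self.summed_total, 1) for loc, n in self.counts.items()
        }

    def total_fold(self, loc: str) -> float:
        """Summed total as a multiple of one locality's DE count (1 decimal)."""
        return round(self.summed_total / self.counts[loc], 1)


def summarize_de_overlap(de: dict[str, set[str] | int], shared: int | None = None) -> OverlapSummary:
    """Overlap summary for two per-locality DE gene sets.

    Accepts either actual gene sets, or printed counts plus an explicit
    ``shared`` count (so reported tallies can be re-checked without the
    underlying lists). Percentages are relative to each locality's own DE
    count, reported to one decimal. Empty sets yield zero percentages with
    a flag rather than NaN.
    """
    if len(de) != 2:
        raise ValueError("overlap summary is defined for exactly 2 localities")
    locs = sorted(de)
    if all(isinstance(v, (int, np.integer)) for v in de.values()):
        if shared is None:
            raise ValueError("shared count required when passing counts")
        counts = {loc: int(de[loc]) for loc in locs}
        n_shared = int(shared)
    else:
        sets = {loc: set(de[loc]) for loc in locs}
        counts = {loc: len(sets[loc]) for loc in locs}
        n_shared = len(sets[locs[0]] & sets[locs[1]])
    if any(n_shared > counts[loc] for loc in locs):
        raise ValueError("shared count exceeds a locality's DE count")

    unique = {loc: counts[loc] - n_shared for loc in locs}
    flags = []
    pct_unique, pct_shared = {}, {}
    for loc in locs:
        if counts[loc] == 0:
            pct_unique[loc] = pct_shared[loc] = 0.0
            flags.append(f"{loc}: empty DE set, percentages reported as 0")
        else:
            pct_unique[loc] = round(100.0 * unique[loc] / counts[loc], 1)
            pct_shared[loc] = round(100.0 * n_shared / counts[loc], 1)
    summed = counts[locs[0]] + counts[locs[1]]
    return OverlapSummary(
        counts=counts,
        shared=n_shared,
        unique=unique,
        pct_unique=pct_unique,
        pct_shared=pct_shared,
        summed_total=summed,
        union_total=summed - n_shared,
        flags=flags,
    )


# ------------------------------------------------------------------ pipeline

@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    screening_localities: tuple[str, ...] = ("TAT", "CAT")
    fdr: float = 0.05
    min_snps: int = 5
    locality_min_maf: float = 0.01
    dnds_mode: str = "site_normalized"
    drop_samples: tuple[str, ...] = ()
    sim: syndata.ScreenSimConfig | None = None
    snp_panel: syndata.SnpSimConfig | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full screen end-to-end; returns the manifest dictionary.

    Stages: simulate inputs -> SNP filter cascade -> F_ST + dendrogram ->
    per-variant effects + per-gene dN/dS -> CPM filter, RLE normalization,
    dispersion, nested NB fits, temperature LRT -> DE/PS intersection and
    overlap summary. Every stage writes a TSV under ``outdir`` and the
    manifest records content hashes, applied thresholds and the seed, so
    equal config + seed reproduces identical artifacts.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}

    def stage(name):
        log_lines.append(f"stage: {name}")

    def save(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, sep="\t", **kw)
        manifest["files"][name] = _sha256(path)

    try:
        stage("simulate")
        sim_cfg = config.sim or syndata.ScreenSimConfig(seed=config.seed)
        data = syndata.simulate_screen_dataset(sim_cfg)
        panel_cfg = config.snp_panel or syndata.SnpSimConfig(
            n_populations=3,
            pop_names=("TAT", "CAT", "FAR"),
            samples_per_population=12,
            n_sites=3000,
            target_fst=0.2,
            seed=config.seed,
        )
        panel, panel_truth = syndata.simulate_snp_panel(panel_cfg)
        save(data.counts, "counts.tsv")
        save(data.samples, "samples.tsv")
        vcf_filter.write_vcf(data.genotypes, str(out / "coding_variants.vcf"))
        vcf_filter.write_vcf(panel, str(out / "snp_panel.vcf"))
        manifest["files"]["coding_variants.vcf"] = _sha256(out / "coding_variants.vcf")
        manifest["files"]["snp_panel.vcf"] = _sha256(out / "snp_panel.vcf")

        stage("filter_snps")
        fcfg = vcf_filter.FilterConfig()
        filtered_panel, report = vcf_filter.filter_variants(panel, fcfg)
        save(report.to_table(), "filter_report.tsv", index=False)
        manifest["stages"]["filter_snps"] = {
            "input": report.input_count,
            "final": report.final_count,
            "thresholds": vars(fcfg),
        }
        log_lines += [f"  {s}: {n}" for s, n in report.survivors_after_each_step]

        stage("fst_dendrogram")
        pop_map = syndata.population_map(filtered_panel)
        fst = popgen.wc_fst(filtered_panel, pop_map)
        fst_rows = [{"comparison": "all", "fst": fst.genomewide_fst}] + [
            {"comparison": f"{a}-{b}", "fst": v} for (a, b), v in fst.pairwise.items()
        ]
        save(pd.DataFrame(fst_rows), "fst.tsv", index=False)
        dist = popgen.allele_sharing_distance(filtered_panel)
        tree = popgen.build_dendrogram(dist, filtered_panel.samples)
        (out / "dendrogram.nwk").write_text(tree.newick + "\n")
        manifest["files"]["dendrogram.nwk"] = _sha256(out / "dendrogram.nwk")

        stage("dnds")
        geno = data.genotypes
        fgeno, _ = vcf_filter.filter_variants(geno, vcf_filter.FilterConfig())
        variable = seleffect.locality_maf_gate(
            fgeno, data.pop_map, min_maf=config.locality_min_maf
        )
        site_ids = fgeno.site_ids()
        annotations = [
            seleffect.classify_variant_effect(
                data.transcripts[fgeno.chrom[i]],
                int(fgeno.pos[i]),
                str(fgeno.ref[i]),
                str(fgeno.alt[i]),
                variant_id=site_ids[i],
            )
            for i in range(fgeno.n_sites)
        ]
        ps_sets: dict[str, set[str]] = {}
        dnds_rows = []
        for loc in config.screening_localities:
            ids_loc = set(site_ids[variable[loc]])
            genes_loc = sorted({a.gene_id for a in annotations if a.variant_id in ids_loc})
            ps_sets[loc] = set()
            for gene in genes_loc:
                res = seleffect.gene_dnds(
                    annotations,
                    ids_loc,
                    data.transcripts[gene],
                    loc,
                    min_snps=config.min_snps,
                    mode=config.dnds_mode,
                )
                dnds_rows.append(vars(res))
                if res.positively_selected:
                    ps_sets[loc].add(gene)
        save(pd.DataFrame(dnds_rows), "dnds.tsv", index=False)

        stage("differential_expression")
        cm = CountMatrix(data.counts, data.samples)
        if config.drop_samples:
            cm = cm.drop_samples(list(config.drop_samples))
        kept = diffexpr.filter_low_expression(cm)
        counts = cm.counts.loc[kept]
        sf = diffexpr.rle_size_factors(counts)
        save(sf.to_frame(), "size_factors.tsv")
        model = ModelSpec()
        common, tagwise = diffexpr.estimate_dispersion(counts, model, cm.samples, sf)
        fit = diffexpr.fit_nested_model(counts, model, cm.samples, sf, tagwise.to_numpy())
        de_sets: dict[str, set[str]] = {}
        de_stats = []
        for loc in config.screening_localities:
            res = diffexpr.test_temperature_effect(
                counts, model, cm.samples, loc, sf, tagwise.to_numpy(),
                alpha=config.fdr, full_fit=fit,
            )
            save(res, f"de_{loc}.tsv")
            de_sets[loc] = set(res.index[res["de"]])
            de_stats.append(
                res.reset_index()[["locality", "gene", "log2fc", "padj"]]
            )
        mds = diffexpr.mds_logfc(counts, sf)
        save(mds, "mds.tsv")
        manifest["stages"]["differential_expression"] = {
            "genes_after_cpm_filter": int(len(kept)),
            "common_dispersion": float(common),
            "fdr": config.fdr,
        }

        stage("screen")
        dnds_df = pd.DataFrame(dnds_rows)
        stats = pd.concat(de_stats, ignore_index=True)
        if len(dnds_df):
            stats = stats.merge(
                dnds_df.rename(columns={"gene_id": "gene"})[["locality", "gene", "dnds"]],
                on=["locality", "gene"],
                how="outer",
            )
        cand = intersect_candidates(de_sets, ps_sets, stats=stats)
        save(cand.table, "candidates.tsv", index=False)
        overlap = summarize_de_overlap(
            {loc: de_sets[loc] for loc in config.screening_localities[:2]}
        )
        manifest["stages"]["screen"] = {
            "de_counts": overlap.counts,
            "shared": overlap.shared,
            "ps_counts": {loc: len(ps_sets[loc]) for loc in ps_sets},
            "candidates": {loc: sorted(cand.intersection[loc]) for loc in cand.intersection},
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {log_lines[-1].split(': ')[-1]!r}: {exc}") from exc

    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
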