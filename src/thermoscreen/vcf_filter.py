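"""VCF input/output and the SNP filter cascade.

The cascade mirrors a conventional transcriptome SNP-calling workflow:
raw calls are accepted when site quality exceeds 20 (strict) and the site
has at least 4 reads supporting the alternate allele, then individual
genotype calls with GQ below 10 are masked to missing, then whole sites are
dropped on missingness (> 20%), minor allele frequency (< 0.01, inclusive
boundary kept) and multi-allelism. The report records survivors per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

from .containers import MISSING, GenotypeMatrix


class VcfParseError(ValueError):
    pass


@dataclass
class FilterConfig:
    """Thresholds of the SNP filter cascade.

    ``site_quality`` is compared strictly (> min), all other thresholds
    inclusively, matching how the filters are conventionally stated.
    ``read_support_mode`` selects whether "supporting reads" means summed
    depth over alternate-allele carriers (``alt_carriers``, default) or the
    summed site depth over all samples (``site_total``).
    """

    min_site_quality: float = 20.0
    min_supporting_reads: int = 4
    min_genotype_quality: int = 10
    max_missing_fraction: float = 0.20
    min_maf: float = 0.01
    biallelic_only: bool = True
    mask_low_gq: bool = True
    read_support_mode: str = "alt_carriers"

    def __post_init__(self) -> None:
        if min(self.min_site_quality, self.min_supporting_reads, self.min_genotype_quality) < 0:
            raise ValueError("thresholds must be non-negative")
        if not (0 <= self.max_missing_fraction <= 1 and 0 <= self.min_maf <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.read_support_mode not in ("alt_carriers", "site_total"):
            raise ValueError(f"unknown read_support_mode {self.read_support_mode!r}")


@dataclass
class FilterReport:
    input_count: int
    survivors_after_each_step: list[tuple[str, int]] = field(default_factory=list)

    @property
    def final_count(self) -> int:
        if not self.survivors_after_each_step:
            return self.input_count
        return self.survivors_after_each_step[-1][1]

    def to_table(self):
        import pandas as pd

        rows = [("input", self.input_count)] + self.survivors_after_each_step
        return pd.DataFrame(rows, columns=["step", "survivors"])


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    GT/GQ/DP are retained per call; ``./.`` becomes the missing code.
    Multi-allelic records are kept (alt alleles comma-joined) so the
    biallelic filter can count and remove them.
    """
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    chrom, pos, ref, alt, qual = [], [], [], [], []
    gt_rows, gq_rows, dp_rows = [], [], []
    for line_no, v in enumerate(vcf, start=1):
        try:
            chrom.append(v.CHROM)
            pos.append(v.POS)
            ref.append(v.REF)
            alt.append(",".join(v.ALT) if v.ALT else ".")
            qual.append(v.QUAL if v.QUAL is not None else np.nan)
            g = v.gt_types.astype(np.int8)  # 0/1/2 dosage, 3 = no call
            g[g == 3] = MISSING
            gt_rows.append(g)
            gq_rows.append(_format_field(v, "GQ", len(samples)))
            dp_rows.append(_format_field(v, "DP", len(samples)))
        except Exception as exc:
            raise VcfParseError(f"malformed VCF record at data line {line_no}: {exc}") from exc
    n = len(pos)
    return GenotypeMatrix(
        samples=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=int),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        gt=np.vstack(gt_rows) if n else np.empty((0, len(samples)), dtype=np.int8),
        gq=np.vstack(gq_rows) if n else np.empty((0, len(samples)), dtype=int),
        dp=np.vstack(dp_rows) if n else np.empty((0, len(samples)), dtype=int),
        site_qual=np.array(qual, dtype=float),
    )


def _format_field(variant, key: str, n_samples: int) -> np.ndarray:
    """Per-sample integer FORMAT field; zeros when absent from the record."""
    try:
        vals = variant.format(key)
    except KeyError:
        vals = None
    if vals is None:
        return np.zeros(n_samples, dtype=int)
    vals = np.asarray(vals, dtype=float).ravel()
    return np.where(np.isfinite(vals) & (vals >= 0), vals, 0).astype(int)


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a GenotypeMatrix as VCFv4.2 with GT:GQ:DP sample fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for contig in dict.fromkeys(gm.chrom):  # insertion order, unique
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for s in range(gm.n_sites):
            qual = gm.site_qual[s]
            qual_str = f"{qual:.6g}" if np.isfinite(qual) else "."
            calls = "\t".join(
                f"{_GT_STRING[int(gm.gt[s, j])]}:{int(gm.gq[s, j])}:{int(gm.dp[s, j])}"
                for j in range(gm.n_samples)
            )
            fh.write(
                f"{gm.chrom[s]}\t{gm.pos[s]}\t.\t{gm.ref[s]}\t{gm.alt[s]}\t"
                f"{qual_str}\t.\t.\tGT:GQ:DP\t{calls}\n"
            )


def compute_maf(genotypes: np.ndarray) -> np.ndarray:
    """Minor allele frequency per site over non-missing diploid calls.

    ``genotypes`` is (n_sites, n_samples) dosage with MISSING for no-calls.
    Sites where every call is missing get NaN (they fail any MAF gate by
    convention).
    """
    g = np.atleast_2d(np.asarray(genotypes))
    called = g != MISSING
    n_called = called.sum(axis=1)
    alt = np.where(called, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    return np.minimum(f, 1.0 - f)


def filter_variants(
    gm: GenotypeMatrix, config: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the filter cascade; returns survivors and a per-step report.

    Cascade: site quality -> GQ masking (per-call, sets calls missing
    rather than dropping records) -> read support -> missing rate ->
    MAF (recomputed after masking) -> biallelic. Masking precedes the
    read-support step so that re-filtering an already-filtered panel is a
    no-op: carrier status is judged on the calls that actually survive.
    """
    config = config or FilterConfig()
    report = FilterReport(input_count=gm.n_sites)

    def log(step: str, g: GenotypeMatrix) -> GenotypeMatrix:
        report.survivors_after_each_step.append((step, g.n_sites))
        return g

    # 1. site quality, strict ">"
    keep = np.nan_to_num(gm.site_qual, nan=-np.inf) > config.min_site_quality
    gm = log("site_quality", gm.take_sites(keep))

    # 2. per-call GQ masking (removes no records)
    if config.mask_low_gq:
        masked = gm.gt.copy()
        masked[(gm.gq < config.min_genotype_quality) & (masked != MISSING)] = MISSING
        gm = GenotypeMatrix(
            samples=gm.samples, chrom=gm.chrom, pos=gm.pos, ref=gm.ref, alt=gm.alt,
            gt=masked, gq=gm.gq, dp=gm.dp, site_qual=gm.site_qual,
        )
    gm = log("genotype_quality_mask", gm)

    # 3. read support for the alternate allele
    if config.read_support_mode == "alt_carriers":
        carriers = (gm.gt == 1) | (gm.gt == 2)
        support = np.where(carriers, gm.dp, 0).sum(axis=1)
    else:
        support = gm.dp.sum(axis=1)
    gm = log("read_support", gm.take_sites(support >= config.min_supporting_reads))

    # 4. missing rate: call rate >= 1 - max_missing_fraction required
    if gm.n_samples:
        miss_frac = (gm.gt == MISSING).mean(axis=1)
    else:
        miss_frac = np.zeros(gm.n_sites)
    gm = log("missing_rate", gm.take_sites(miss_frac <= config.max_missing_fraction))

    # 5. MAF (after masking), inclusive boundary
    maf = compute_maf(gm.gt)
    gm = log("maf", gm.take_sites(np.nan_to_num(maf, nan=-1.0) >= config.min_maf))

    # 6. biallelic
    if config.biallelic_only:
        gm = gm.take_sites(gm.is_biallelic())
    gm = log("biallelic", gm)

    return gm, report
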