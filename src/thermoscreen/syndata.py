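"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators stand in for the study's raw sequencing data:

* ``simulate_snp_panel`` — multi-population biallelic SNP genotypes under
  the Balding–Nichols model, with a controllable target F_ST, per-call
  Poisson depths and depth-derived genotype qualities, writable as VCF.
* ``simulate_counts`` — negative-binomial gene counts over the nested
  common-garden design (localities x stages x temperatures x replicates),
  with planted temperature effects in a chosen fraction of genes.
* ``simulate_coding_variants`` — random ORFs with planted point variants
  whose true synonymous/nonsynonymous labels are recorded by translating
  the whole reference and mutated ORFs.

``simulate_screen_dataset`` couples the count and coding generators on a
shared gene namespace and plants candidate genes (differentially expressed
AND nonsynonymous-enriched) for end-to-end truth-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .containers import GenotypeMatrix, ModelSpec
from .seleffect import CodingTranscript

_STOPS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))


# ------------------------------------------------------------------ SNP panel

@dataclass
class SnpSimConfig:
    n_populations: int = 3
    samples_per_population: int = 12
    n_sites: int = 5000
    target_fst: float = 0.2
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    mean_depth: float = 20.0
    seed: int = 0
    pop_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.target_fst < 1):
            raise ValueError("target_fst must lie in [0, 1)")
        if self.samples_per_population < 1 or self.n_populations < 1:
            raise ValueError("need >= 1 sample per population and >= 1 population")
        lo, hi = self.ancestral_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("ancestral_freq_range must lie within (0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.pop_names is not None and len(self.pop_names) != self.n_populations:
            raise ValueError("pop_names length must equal n_populations")


def simulate_snp_panel(config: SnpSimConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Balding–Nichols SNP panel plus the per-population true frequencies.

    Ancestral frequency p ~ Uniform(range); population frequency ~
    Beta(p(1-F)/F, (1-p)(1-F)/F) with F the target F_ST (at F = 0 the
    population frequency equals p exactly); genotypes ~ Binomial(2, freq);
    depth ~ Poisson(mean_depth), a zero depth becomes a missing call;
    genotype quality is a monotone function of depth plus noise, clipped
    to [0, 60].
    """
    rng = np.random.default_rng(config.seed)
    pops = list(config.pop_names) if config.pop_names else [
        f"P{i+1}" for i in range(config.n_populations)
    ]
    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=config.n_sites)
    F = config.target_fst
    if F < 1e-12:  # Beta parameterization degenerates; frequencies equal p exactly
        freqs = np.tile(p_anc[:, None], (1, len(pops)))
    else:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        freqs = rng.beta(a[:, None], b[:, None], size=(config.n_sites, len(pops)))

    n_per = config.samples_per_population
    gt = np.concatenate(
        [rng.binomial(2, freqs[:, [k]], size=(config.n_sites, n_per)) for k in range(len(pops))],
        axis=1,
    ).astype(np.int8)
    samples = [f"{pop}_s{i+1}" for pop in pops for i in range(n_per)]

    dp = rng.poisson(config.mean_depth, size=gt.shape)
    gq = np.clip(np.round(3.0 * dp + rng.normal(0, 2, size=gt.shape)), 0, 60).astype(int)
    gt[dp == 0] = -1

    ref_idx = rng.integers(0, 4, size=config.n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=config.n_sites)) % 4
    site_qual = np.clip(rng.normal(45, 12, size=config.n_sites), 1, None)

    gm = GenotypeMatrix(
        samples=samples,
        chrom=np.array(["snp_panel"] * config.n_sites, dtype=object),
        pos=np.arange(1, config.n_sites + 1),
        ref=_BASES[ref_idx].astype(object),
        alt=_BASES[alt_idx].astype(object),
        gt=gt,
        gq=gq,
        dp=dp,
        site_qual=site_qual,
    )
    truth = pd.DataFrame(freqs, columns=pops)
    truth.insert(0, "ancestral_freq", p_anc)
    return gm, truth


def population_map(gm: GenotypeMatrix) -> pd.Series:
    """Sample -> population map for panels named ``{pop}_s{i}``."""
    return pd.Series({s: s.rsplit("_s", 1)[0] for s in gm.samples}, name="population")


# ------------------------------------------------------------------ counts

@dataclass
class CountSimConfig:
    n_genes: int = 2000
    design: ModelSpec = field(default_factory=ModelSpec)
    n_replicates: int = 3
    frac_de_per_locality: float = 0.1
    log2_effect_size: float = 2.0
    dispersion: float = 0.1
    libsize_range: tuple[float, float] = (8e5, 1.2e6)
    base_log_mean: float = np.log(100.0)
    base_log_sd: float = 1.2
    locality_sd: float = 0.5
    stage_sd: float = 0.5
    drop_samples: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_de_per_locality <= 1):
            raise ValueError("frac_de_per_locality must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if min(self.libsize_range) <= 0:
            raise ValueError("library sizes must be positive")


def simulate_counts(
    config: CountSimConfig,
    de_genes: dict[str, list[str]] | None = None,
) -> tuple["pd.DataFrame", pd.DataFrame, pd.DataFrame]:
    """NB counts over the nested design, with a planted-DE truth table.

    Every gene carries random per-locality and per-(locality, stage)
    offsets (the biology the nested model adjusts away); a fraction of
    genes per locality additionally carries a temperature effect of
    ``log2_effect_size`` log2-units with random sign, independently across
    localities. Pass ``de_genes`` to plant effects in named genes instead
    of a random subset. Returns (counts, sample sheet, truth table).
    """
    rng = np.random.default_rng(config.seed)
    sheet = config.design.sample_sheet(config.n_replicates, config.drop_samples)
    genes = [f"g{i+1:05d}" for i in range(config.n_genes)]
    locs = config.design.localities

    base = rng.normal(config.base_log_mean, config.base_log_sd, size=config.n_genes)
    loc_off = {
        loc: rng.normal(0, config.locality_sd, size=config.n_genes) for loc in locs
    }
    stage_off = {
        (loc, st): rng.normal(0, config.stage_sd, size=config.n_genes)
        for loc in locs
        for st in config.design.stages
        if st != config.design.ref_stage
    }

    truth_rows = []
    temp_off = {loc: np.zeros(config.n_genes) for loc in locs}
    for loc in locs:
        if de_genes is not None:
            chosen = np.array([genes.index(g) for g in de_genes.get(loc, [])])
        else:
            n_de = round(config.frac_de_per_locality * config.n_genes)
            chosen = rng.choice(config.n_genes, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=len(chosen))
        for idx, sg in zip(chosen, signs):
            effect = sg * config.log2_effect_size
            temp_off[loc][idx] = effect * np.log(2.0)
            truth_rows.append({"gene": genes[idx], "locality": loc, "log2_effect": effect})

    log_mu = np.empty((config.n_genes, len(sheet)))
    for j, (sid, row) in enumerate(sheet.iterrows()):
        loc, st, tp = row["locality"], int(row["stage"]), int(row["temperature"])
        mu = base + loc_off[loc]
        if st != config.design.ref_stage:
            mu = mu + stage_off[(loc, st)]
        if tp != config.design.ref_temp:
            mu = mu + temp_off[loc]
        log_mu[:, j] = mu
    mu = np.exp(log_mu)

    target_lib = rng.uniform(*config.libsize_range, size=len(sheet))
    mu *= target_lib[None, :] / mu.sum(axis=0)[None, :]

    if config.dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=genes, columns=sheet.index)
    truth = pd.DataFrame(truth_rows, columns=["gene", "locality", "log2_effect"])
    return counts_df, sheet.copy(), truth


# ------------------------------------------------------------------ coding

@dataclass
class CodingSimConfig:
    n_genes: int = 50
    codons_per_gene: int = 60          # ORF codons incl. start, excl. stop
    n_variants_per_gene: int = 5
    nonsyn_fraction: float = 0.5
    utr_length: int = 10
    minus_strand_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.codons_per_gene < 2:
            raise ValueError("need at least 2 codons (start codon + body)")
        if not (0 <= self.nonsyn_fraction <= 1):
            raise ValueError("nonsyn_fraction must lie in [0, 1]")
        if not (0 <= self.minus_strand_fraction <= 1):
            raise ValueError("minus_strand_fraction must lie in [0, 1]")


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + a stop codon."""
    body = []
    while len(body) < n_codons - 1:
        codon = "".join(rng.choice(list("ACGT"), size=3))
        if codon not in _STOPS:
            body.append(codon)
    return "ATG" + "".join(body) + str(rng.choice(_STOPS))


def simulate_coding_variants(
    config: CodingSimConfig,
) -> tuple[dict[str, CodingTranscript], pd.DataFrame]:
    """Random coding transcripts with planted point variants and truth labels.

    Variants are planted inside the ORF (start codon excluded); each
    variant's true effect label comes from translating the full reference
    and mutated ORFs and comparing proteins — an independent route from
    the codon-local classifier this generator is used to test. Returns
    (transcripts by id, variant table with truth labels).
    """
    rng = np.random.default_rng(config.seed)
    transcripts: dict[str, CodingTranscript] = {}
    rows = []
    for gi in range(config.n_genes):
        gene = f"g{gi+1:05d}"
        orf = _random_orf(rng, config.codons_per_gene)
        utr5 = "".join(rng.choice(list("ACGT"), size=config.utr_length))
        utr3 = "".join(rng.choice(list("ACGT"), size=config.utr_length))
        plus_seq = utr5 + orf + utr3
        minus = rng.random() < config.minus_strand_fraction
        if minus:
            seq = str(Seq(plus_seq).reverse_complement())
            orf_start = config.utr_length + 1
            orf_end = config.utr_length + len(orf)
            # ORF occupies the mirrored coordinates on the stored strand
            orf_start, orf_end = len(seq) - orf_end + 1, len(seq) - orf_start + 1
            strand = "-"
        else:
            seq = plus_seq
            orf_start = config.utr_length + 1
            orf_end = config.utr_length + len(orf)
            strand = "+"
        tx = CodingTranscript(gene, seq, orf_start, orf_end, strand)
        transcripts[gene] = tx

        want_nonsyn = rng.random(config.n_variants_per_gene) < config.nonsyn_fraction
        used_pos: set[int] = set()
        for want in want_nonsyn:
            label, pos, ref, alt = _plant_variant(rng, tx, bool(want), used_pos)
            used_pos.add(pos)
            rows.append(
                {"gene": gene, "pos": pos, "ref": ref, "alt": alt, "truth_effect": label}
            )
    variants = pd.DataFrame(rows, columns=["gene", "pos", "ref", "alt", "truth_effect"])
    return transcripts, variants


def _orf_truth_label(tx: CodingTranscript, pos: int, alt: str) -> str:
    """Effect label by translating the whole mutated ORF vs the reference."""
    mutated = tx.sequence[: pos - 1] + alt + tx.sequence[pos:]
    tx_mut = CodingTranscript(tx.id, mutated, tx.orf_start, tx.orf_end, tx.strand)
    return "synonymous" if tx_mut.protein() == tx.protein() else "nonsynonymous"


def _plant_variant(
    rng: np.random.Generator, tx: CodingTranscript, nonsyn: bool, used: set[int]
) -> tuple[str, int, str, str]:
    want = "nonsynonymous" if nonsyn else "synonymous"
    # skip the start codon (and terminal stop for synonymous-at-will planting)
    if tx.strand == "+":
        lo, hi = tx.orf_start + 3, tx.orf_end
    else:
        lo, hi = tx.orf_start, tx.orf_end - 3
    for _ in range(10000):
        pos = int(rng.integers(lo, hi + 1))
        if pos in used:
            continue
        ref = tx.sequence[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        if _orf_truth_label(tx, pos, alt) == want:
            return want, pos, ref, alt
    raise RuntimeError(f"could not plant a {want} variant in {tx.id}")


# ------------------------------------------------------------------ writers

def write_fasta(transcripts: dict[str, CodingTranscript], path: str) -> None:
    """60-column-wrapped FASTA of transcript sequences."""
    with open(path, "w") as fh:
        for tx in transcripts.values():
            fh.write(f">{tx.id}\n")
            for i in range(0, len(tx.sequence), 60):
                fh.write(tx.sequence[i : i + 60] + "\n")


def write_orf_table(transcripts: dict[str, CodingTranscript], path: str) -> None:
    pd.DataFrame(
        [
            {
                "transcript_id": tx.id,
                "orf_start": tx.orf_start,
                "orf_end": tx.orf_end,
                "strand": tx.strand,
            }
            for tx in transcripts.values()
        ]
    ).to_csv(path, sep="\t", index=False)


def read_orf_table(fasta_path: str, orf_path: str) -> dict[str, CodingTranscript]:
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta_path, "fasta")}
    table = pd.read_csv(orf_path, sep="\t")
    out = {}
    for _, row in table.iterrows():
        tid = row["transcript_id"]
        out[tid] = CodingTranscript(
            tid, seqs[tid], int(row["orf_start"]), int(row["orf_end"]), row["strand"]
        )
    return out


# ------------------------------------------------------------------ screen bundle

@dataclass
class ScreenSimConfig:
    """End-to-end scenario: counts + coding variants + genotypes, with truth.

    Per screening locality, ``n_candidates`` genes are planted both
    differentially expressed and nonsynonymous-enriched (the truth
    candidates), ``n_de_only`` genes only DE, and ``n_ps_only`` genes only
    selection-enriched; remaining genes are null. The control locality
    gets no planted effects and is excluded from screening downstream.
    """

    design: ModelSpec = field(default_factory=ModelSpec)
    screening_localities: tuple[str, ...] = ("TAT", "CAT")
    n_genes: int = 300
    n_candidates: int = 10
    n_de_only: int = 15
    n_ps_only: int = 15
    log2_effect_size: float = 2.0
    dispersion: float = 0.1
    codons_per_gene: int = 60
    ps_variants: int = 7
    ps_nonsyn_fraction: float = 0.9
    null_variants: int = 6
    null_nonsyn_fraction: float = 0.15
    variant_freq: float = 0.3
    seed: int = 0


@dataclass
class ScreenDataset:
    counts: pd.DataFrame
    samples: pd.DataFrame
    transcripts: dict[str, CodingTranscript]
    variants: pd.DataFrame
    genotypes: GenotypeMatrix
    pop_map: pd.Series
    truth_candidates: dict[str, set[str]]
    truth_de: dict[str, set[str]]
    truth_ps: dict[str, set[str]]


def simulate_screen_dataset(config: ScreenSimConfig) -> ScreenDataset:
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i+1:05d}" for i in range(config.n_genes)]
    locs = config.screening_localities
    need = len(locs) * (config.n_candidates + config.n_de_only + config.n_ps_only)
    if need > config.n_genes:
        raise ValueError("not enough genes for the requested planted sets")
    pool = list(rng.permutation(genes))

    truth_de: dict[str, set[str]] = {}
    truth_ps: dict[str, set[str]] = {}
    truth_cand: dict[str, set[str]] = {}
    for loc in locs:
        cand = {pool.pop() for _ in range(config.n_candidates)}
        de_only = {pool.pop() for _ in range(config.n_de_only)}
        ps_only = {pool.pop() for _ in range(config.n_ps_only)}
        truth_cand[loc] = cand
        truth_de[loc] = cand | de_only
        truth_ps[loc] = cand | ps_only

    counts, sheet, _ = simulate_counts(
        CountSimConfig(
            n_genes=config.n_genes,
            design=config.design,
            log2_effect_size=config.log2_effect_size,
            dispersion=config.dispersion,
            seed=int(rng.integers(2**31)),
        ),
        de_genes={loc: sorted(s) for loc, s in truth_de.items()},
    )

    # coding transcripts; variant load depends on the gene's PS status
    transcripts: dict[str, CodingTranscript] = {}
    var_rows = []
    ps_any = {g: loc for loc in locs for g in truth_ps[loc]}
    for gene in genes:
        sub = CodingSimConfig(
            n_genes=1,
            codons_per_gene=config.codons_per_gene,
            n_variants_per_gene=(
                config.ps_variants if gene in ps_any else config.null_variants
            ),
            nonsyn_fraction=(
                config.ps_nonsyn_fraction if gene in ps_any else config.null_nonsyn_fraction
            ),
            seed=int(rng.integers(2**31)),
        )
        tx_map, variants = simulate_coding_variants(sub)
        tx = next(iter(tx_map.values()))
        tx = CodingTranscript(gene, tx.sequence, tx.orf_start, tx.orf_end, tx.strand)
        transcripts[gene] = tx
        variants = variants.assign(gene=gene)
        var_rows.append(variants)
    variants = pd.concat(var_rows, ignore_index=True)

    # genotypes at all planted variants: variable only where the gene is
    # PS-planted (that locality) or at background frequency for null genes
    all_locs = config.design.localities
    sample_ids = list(sheet.index)
    pops = sheet["locality"]
    n_sites = len(variants)
    gt = np.zeros((n_sites, len(sample_ids)), dtype=np.int8)
    for s_idx, v in variants.iterrows():
        gene = v["gene"]
        for loc in all_locs:
            cols = np.flatnonzero((pops == loc).to_numpy())
            if gene in ps_any and loc == ps_any[gene]:
                freq = config.variant_freq
            elif gene in ps_any:
                freq = 0.0
            else:
                freq = config.variant_freq if rng.random() < 0.5 else 0.0
            gt[s_idx, cols] = rng.binomial(2, freq, size=len(cols))
    dp = rng.poisson(20, size=gt.shape)
    gt[dp == 0] = -1
    gq = np.clip(np.round(3.0 * dp + rng.normal(0, 2, size=gt.shape)), 0, 60).astype(int)
    gm = GenotypeMatrix(
        samples=sample_ids,
        chrom=variants["gene"].to_numpy(dtype=object),
        pos=variants["pos"].to_numpy(dtype=int),
        ref=variants["ref"].to_numpy(dtype=object),
        alt=variants["alt"].to_numpy(dtype=object),
        gt=gt,
        gq=gq,
        dp=dp,
        site_qual=np.clip(rng.normal(45, 12, size=n_sites), 1, None),
    )
    return ScreenDataset(
        counts=counts,
        samples=sheet,
        transcripts=transcripts,
        variants=variants,
        genotypes=gm,
        pop_map=pops.rename("population"),
        truth_candidates=truth_cand,
        truth_de=truth_de,
        truth_ps=truth_ps,
    )
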