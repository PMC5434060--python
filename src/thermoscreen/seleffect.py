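"""SNP effect classification on coding transcripts and the dN/dS screen.

A variant inside an annotated ORF is synonymous when both alleles' codons
translate to the same amino acid and nonsynonymous otherwise (stop gain and
stop loss count as nonsynonymous — the screen is binary and premature stops
are protein-altering); variants outside the ORF are noncoding. Per gene and
locality, nonsynonymous/synonymous tallies over the locality's variable
SNPs yield a dN/dS ratio, site-normalized by Nei–Gojobori (1986) expected
site counts by default. A gene is called positively selected in a locality
when it carries at least ``min_snps`` variable SNPs there and dN/dS > 1.

This is a polymorphism-based (pN/pS-style) screen: ratios come from
within-locality variants, not fixed differences between localities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .containers import GenotypeMatrix
from .vcf_filter import compute_maf

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
NONCODING = "noncoding"

_BASES = "ACGT"


@dataclass(frozen=True)
class CodingTranscript:
    """A transcript with a single annotated ORF (1-based inclusive coords)."""

    id: str
    sequence: str
    orf_start: int
    orf_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (1 <= self.orf_start <= self.orf_end <= len(self.sequence)):
            raise ValueError(f"{self.id}: ORF coordinates outside the sequence")
        if (self.orf_end - self.orf_start + 1) % 3:
            raise ValueError(f"{self.id}: ORF length not divisible by 3")

    def orf_nucleotides(self) -> str:
        """Coding-strand ORF sequence (reverse-complemented for '-')."""
        sub = self.sequence[self.orf_start - 1 : self.orf_end]
        return str(Seq(sub).reverse_complement()) if self.strand == "-" else sub

    def protein(self) -> str:
        return str(Seq(self.orf_nucleotides()).translate())


@dataclass(frozen=True)
class EffectAnnotation:
    variant_id: str
    gene_id: str
    effect: str
    codon_index: int | None = None      # 0-based codon within the ORF
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None


def classify_variant_effect(
    transcript: CodingTranscript, pos: int, ref: str, alt: str, variant_id: str | None = None
) -> EffectAnnotation:
    """Classify a point variant on a transcript as syn/nonsyn/noncoding.

    ``pos`` is the 1-based position on the transcript's given (plus-strand)
    sequence; ``ref``/``alt`` are the alleles on that same strand. For a
    minus-strand ORF the alleles are complemented internally.
    """
    if not (1 <= pos <= len(transcript.sequence)):
        raise ValueError(f"{transcript.id}: position {pos} outside transcript")
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("only single-nucleotide variants are classifiable")
    base = transcript.sequence[pos - 1].upper()
    if base != ref.upper():
        raise ValueError(
            f"{transcript.id}: reference allele {ref!r} does not match "
            f"transcript base {base!r} at position {pos}"
        )
    vid = variant_id or f"{transcript.id}:{pos}"
    if not (transcript.orf_start <= pos <= transcript.orf_end):
        return EffectAnnotation(vid, transcript.id, NONCODING)

    if transcript.strand == "+":
        offset = pos - transcript.orf_start
        r, a = ref.upper(), alt.upper()
    else:
        offset = transcript.orf_end - pos
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        r, a = comp[ref.upper()], comp[alt.upper()]
    codon_idx, within = divmod(offset, 3)
    orf = transcript.orf_nucleotides()
    ref_codon = orf[3 * codon_idx : 3 * codon_idx + 3]
    assert ref_codon[within] == r
    alt_codon = ref_codon[:within] + a + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    effect = SYNONYMOUS if ref_aa == alt_aa else NONSYNONYMOUS
    return EffectAnnotation(vid, transcript.id, effect, codon_idx, ref_codon, alt_codon, ref_aa, alt_aa)


def ng86_site_counts(transcript: CodingTranscript) -> tuple[float, float]:
    """Nei–Gojobori expected nonsynonymous and synonymous site counts.

    Each position of each non-stop reference codon contributes the fraction
    of its 3 possible point mutations that are nonsynonymous (resp.
    synonymous); mutations creating or destroying a stop count as
    nonsynonymous, so N_sites + S_sites = 3 x (number of non-stop codons).
    """
    orf = transcript.orf_nucleotides().upper()
    n_sites = s_sites = 0.0
    for c0 in range(0, len(orf), 3):
        codon = orf[c0 : c0 + 3]
        if any(b not in _BASES for b in codon):
            raise ValueError(f"{transcript.id}: invalid codon {codon!r}")
        aa = str(Seq(codon).translate())
        if aa == "*":
            continue
        for within in range(3):
            syn = 0
            for b in _BASES:
                if b == codon[within]:
                    continue
                mut = codon[:within] + b + codon[within + 1 :]
                if str(Seq(mut).translate()) == aa:
                    syn += 1
            s_sites += syn / 3.0
            n_sites += (3 - syn) / 3.0
    return n_sites, s_sites


def locality_maf_gate(
    gm: GenotypeMatrix,
    pop_labels: dict[str, str] | "object",
    min_maf: float = 0.01,
    localities: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Per-locality sets of variable SNPs (within-locality MAF strictly > min_maf).

    Returns a mapping locality -> boolean mask over the panel's sites.
    A SNP monomorphic within a locality is excluded for that locality even
    if polymorphic elsewhere. ``localities`` restricts (and validates) the
    localities examined; a requested locality with no samples is an error.
    """
    labels = {s: pop_labels[s] for s in gm.samples}
    pops = np.array([labels[s] for s in gm.samples], dtype=object)
    out: dict[str, np.ndarray] = {}
    for loc in localities if localities is not None else sorted(set(pops)):
        cols = pops == loc
        if not cols.any():
            raise ValueError(f"locality {loc!r} has no samples")
        maf = compute_maf(gm.gt[:, cols])
        out[loc] = np.nan_to_num(maf, nan=0.0) > min_maf
    return out


@dataclass
class DnDsResult:
    gene_id: str
    locality: str
    n_variants: int
    n_count: int
    s_count: int
    n_sites: float
    s_sites: float
    dnds: float                 # nan when undefined, inf when S-rate is 0 with N > 0
    positively_selected: bool

    def __post_init__(self) -> None:
        assert self.n_variants == self.n_count + self.s_count


def gene_dnds(
    annotations: list[EffectAnnotation],
    variable_ids: set[str],
    transcript: CodingTranscript,
    locality: str,
    min_snps: int = 5,
    mode: str = "site_normalized",
) -> DnDsResult:
    """dN/dS verdict for one gene in one locality.

    Tallies N/S over the locality's variable SNPs that fall in the ORF
    (noncoding annotations are ignored). ``mode='site_normalized'`` uses
    (N/N_sites)/(S/S_sites) with NG86 site counts from the reference ORF;
    ``mode='raw'`` uses the plain N/S count ratio. Genes with fewer than
    ``min_snps`` variable coding SNPs are never called positively selected
    and get an undefined ratio. S = 0 with N > 0 yields an infinite ratio,
    called positively selected (flagged by the inf value).
    """
    if mode not in ("site_normalized", "raw"):
        raise ValueError(f"unknown mode {mode!r}")
    mine = [
        a
        for a in annotations
        if a.gene_id == transcript.id and a.variant_id in variable_ids and a.effect != NONCODING
    ]
    n_count = sum(a.effect == NONSYNONYMOUS for a in mine)
    s_count = sum(a.effect == SYNONYMOUS for a in mine)
    n_sites, s_sites = ng86_site_counts(transcript)
    n_var = n_count + s_count

    if n_count == 0 and s_count == 0:
        dnds = math.nan
    elif s_count == 0:
        dnds = math.inf
    elif mode == "raw":
        dnds = n_count / s_count
    else:
        dnds = (n_count / n_sites) / (s_count / s_sites)
    ps = bool(n_var >= min_snps and not math.isnan(dnds) and dnds > 1.0)
    if n_var < min_snps:
        dnds = math.nan
        ps = False
    return DnDsResult(transcript.id, locality, n_var, n_count, s_count, n_sites, s_sites, dnds, ps)
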