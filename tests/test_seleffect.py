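"""Effect classification vs brute-force oracle; NG86 sites; dN/dS rules."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq

from thermoscreen import seleffect, syndata
from thermoscreen.seleffect import (
    CodingTranscript,
    EffectAnnotation,
    classify_variant_effect,
    gene_dnds,
    locality_maf_gate,
    ng86_site_counts,
)

from conftest import make_panel


def make_tx(orf_codons, utr5="", utr3="", strand="+"):
    orf = "".join(orf_codons)
    plus = utr5 + orf + utr3
    start, end = len(utr5) + 1, len(utr5) + len(orf)
    if strand == "-":
        seq = str(Seq(plus).reverse_complement())
        start, end = len(plus) - end + 1, len(plus) - start + 1
        return CodingTranscript("tx", seq, start, end, "-")
    return CodingTranscript("tx", plus, start, end, "+")


class TestClassifier:
    def test_genetic_code_examples(self):
        tx = make_tx(["ATG", "GAA", "AAA", "TAA"])
        # GAA -> GAG at codon position 3: both Glu
        assert classify_variant_effect(tx, 6, "A", "G").effect == "synonymous"
        # AAA -> GAA at codon position 1: Lys -> Glu
        assert classify_variant_effect(tx, 7, "A", "G").effect == "nonsynonymous"

    def test_positions_outside_orf_are_noncoding(self):
        tx = make_tx(["ATG", "TAA"], utr5="GGGG", utr3="CCCC")
        assert classify_variant_effect(tx, 2, "G", "A").effect == "noncoding"
        assert classify_variant_effect(tx, 11, "C", "A").effect == "noncoding"

    def test_ref_mismatch_raises_with_position(self):
        tx = make_tx(["ATG", "TAA"])
        with pytest.raises(ValueError, match="position 2"):
            classify_variant_effect(tx, 2, "C", "G")

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exhaustive_against_translate_both_oracle(self, strand):
        tx = make_tx(["ATG", "TTT", "CGA", "AGC", "TAA"], utr5="AC", utr3="GT", strand=strand)
        # oracle: mutate the stored sequence, translate the whole ORF on the
        # annotated strand, compare proteins
        for pos in range(1, len(tx.sequence) + 1):
            ref = tx.sequence[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                ann = classify_variant_effect(tx, pos, ref, alt)
                mutated = tx.sequence[: pos - 1] + alt + tx.sequence[pos:]
                tx_mut = CodingTranscript(tx.id, mutated, tx.orf_start, tx.orf_end, tx.strand)
                in_orf = tx.orf_start <= pos <= tx.orf_end
                if not in_orf:
                    assert ann.effect == "noncoding"
                else:
                    expected = (
                        "synonymous"
                        if tx_mut.protein() == tx.protein()
                        else "nonsynonymous"
                    )
                    assert ann.effect == expected, (pos, ref, alt)

    def test_stop_gain_is_nonsynonymous(self):
        tx = make_tx(["ATG", "TAC", "TAA"])
        # TAC (Tyr) -> TAA (stop)
        ann = classify_variant_effect(tx, 6, "C", "A")
        assert ann.effect == "nonsynonymous"


class TestNg86:
    def test_ttt_third_position_contribution(self):
        # TTT: of the 3 changes at position 3, only TTC is synonymous
        tx = make_tx(["ATG", "TTT", "TAA"])
        n_sites, s_sites = ng86_site_counts(tx)
        tx0 = make_tx(["ATG", "TAA"])
        n0, s0 = ng86_site_counts(tx0)
        assert (s_sites - s0) == pytest.approx(1 / 3)
        assert (n_sites - n0) == pytest.approx(3 - 1 / 3)

    def test_totals_conserve_three_per_codon(self):
        tx = make_tx(["ATG", "TTT", "CGA", "AGC", "TAA"])
        n_sites, s_sites = ng86_site_counts(tx)
        assert n_sites + s_sites == pytest.approx(3 * 4)  # stop codon excluded

    def test_atg_contributes_no_synonymous_sites(self):
        n_sites, s_sites = ng86_site_counts(make_tx(["ATG", "TAA"]))
        assert s_sites == 0.0
        assert n_sites == pytest.approx(3.0)

    def test_invalid_codon_characters_rejected(self):
        tx = CodingTranscript("bad", "ATGNNNTAA", 1, 9, "+")
        with pytest.raises(ValueError, match="invalid codon"):
            ng86_site_counts(tx)


class TestLocalityGate:
    def test_monomorphic_in_locality_excluded(self):
        # variable in B, monomorphic in A
        gt = np.array([[0, 0, 0, 0, 1, 1, 0, 0]])
        gm = make_panel(gt)
        pops = {f"s{i+1}": ("A" if i < 4 else "B") for i in range(8)}
        sets = locality_maf_gate(gm, pops)
        assert not sets["A"][0]
        assert sets["B"][0]

    def test_boundary_is_strict(self):
        # locality of 50 samples, one het: MAF exactly 0.01 -> excluded
        gt = np.zeros((1, 52), dtype=int)
        gt[0, 0] = 1
        gt[0, 50] = 1  # second locality variable
        gm = make_panel(gt)
        pops = {f"s{i+1}": ("A" if i < 50 else "B") for i in range(52)}
        sets = locality_maf_gate(gm, pops, min_maf=0.01)
        assert not sets["A"][0]
        assert sets["B"][0]  # MAF 0.25 in the 2-sample locality

    def test_hand_enumerated_toy_panel(self):
        gt = np.array(
            [
                [0, 1, 0, 0],  # variable in A only
                [0, 0, 1, 1],  # variable in B only
                [1, 0, 0, 1],  # variable in both
                [0, 0, 0, 0],  # nowhere
            ]
        )
        gm = make_panel(gt)
        pops = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
        sets = locality_maf_gate(gm, pops)
        assert sets["A"].tolist() == [True, False, True, False]
        assert sets["B"].tolist() == [False, True, True, False]

    def test_empty_locality_raises(self):
        gm = make_panel(np.array([[0, 1]]))
        with pytest.raises(ValueError, match="no samples"):
            locality_maf_gate(gm, {"s1": "A", "s2": "A"}, localities=["A", "B"])


def _annotations(tx, n_nonsyn, n_syn):
    anns, ids = [], set()
    for i in range(n_nonsyn):
        anns.append(EffectAnnotation(f"v{i}", tx.id, "nonsynonymous"))
    for i in range(n_syn):
        anns.append(EffectAnnotation(f"w{i}", tx.id, "synonymous"))
    ids = {a.variant_id for a in anns}
    return anns, ids


class TestGeneDnds:
    def setup_method(self):
        self.tx = make_tx(["ATG"] + ["TTT"] * 20 + ["TAA"])

    def test_below_min_snps_never_selected(self):
        anns, ids = _annotations(self.tx, 4, 0)
        res = gene_dnds(anns, ids, self.tx, "L", min_snps=5)
        assert not res.positively_selected
        assert math.isnan(res.dnds)

    def test_raw_ratio(self):
        anns, ids = _annotations(self.tx, 6, 3)
        res = gene_dnds(anns, ids, self.tx, "L", mode="raw")
        assert res.dnds == pytest.approx(2.0)
        assert res.positively_selected

    def test_all_synonymous_not_selected(self):
        anns, ids = _annotations(self.tx, 0, 7)
        res = gene_dnds(anns, ids, self.tx, "L")
        assert res.dnds == 0.0
        assert not res.positively_selected

    def test_zero_synonymous_is_infinite_and_selected(self):
        anns, ids = _annotations(self.tx, 5, 0)
        res = gene_dnds(anns, ids, self.tx, "L")
        assert math.isinf(res.dnds)
        assert res.positively_selected

    def test_site_normalization_uses_ng86_counts(self):
        anns, ids = _annotations(self.tx, 5, 4)
        res = gene_dnds(anns, ids, self.tx, "L", mode="site_normalized")
        n_sites, s_sites = ng86_site_counts(self.tx)
        assert res.dnds == pytest.approx((5 / n_sites) / (4 / s_sites))

    def test_count_conservation_under_locality_partition(self):
        anns, ids = _annotations(self.tx, 6, 5)
        ids_a = {i for i in ids if i.endswith(("0", "2", "4"))}
        ids_b = ids - ids_a
        full = gene_dnds(anns, ids, self.tx, "all")
        part_a = gene_dnds(anns, ids_a, self.tx, "A")
        part_b = gene_dnds(anns, ids_b, self.tx, "B")
        assert full.n_count == part_a.n_count + part_b.n_count
        assert full.s_count == part_a.s_count + part_b.s_count

    def test_noncoding_variants_ignored(self):
        anns, ids = _annotations(self.tx, 3, 3)
        anns.append(EffectAnnotation("u0", self.tx.id, "noncoding"))
        ids.add("u0")
        res = gene_dnds(anns, ids, self.tx, "L")
        assert res.n_variants == 6


class TestEndToEndTruth:
    def test_classifier_agrees_on_planted_screen_variants(self, screen_data):
        for _, v in screen_data.variants.iterrows():
            ann = classify_variant_effect(
                screen_data.transcripts[v["gene"]], int(v["pos"]), v["ref"], v["alt"]
            )
            assert ann.effect == v["truth_effect"]
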