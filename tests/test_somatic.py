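"""Paired subtraction, exact Fisher filter, compartments, coding effects."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from somaclone._seq import encode
from somaclone.genotyping import SamplePileup
from somaclone.somatic import (GeneModel, SomaticEvent, add_compartments,
                               annotate_effect, apply_fisher_filter,
                               classify_compartment, fisher_exact_p,
                               fisher_somatic_filter, mito_state,
                               subtract_paired)


class TestFisher:
    def test_balanced_table_has_p_one(self):
        assert fisher_exact_p(((5, 5), (5, 5))) == pytest.approx(1.0)

    def test_strongly_unbalanced_table_kept(self):
        p = fisher_exact_p(((10, 10), (20, 0)))
        assert p < 0.05
        ev = SomaticEvent("chr1", 1, "A", "G", "SNV", "autosomal", p,
                          (10, 10), (20, 0))
        assert fisher_somatic_filter(ev)

    def test_zero_margin_dropped(self):
        ev = SomaticEvent("chr1", 1, "A", "G", "SNV", "autosomal", 1.0,
                          (0, 0), (10, 5))
        assert not fisher_somatic_filter(ev)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_p(((-1, 5), (5, 5)))

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 26, size=4)
            mine = fisher_exact_p(((int(a), int(b)), (int(c), int(d))))
            _, theirs = scipy_fisher([[a, b], [c, d]], alternative="two-sided")
            assert mine == pytest.approx(theirs, abs=1e-12)


class TestCompartments:
    @pytest.mark.parametrize("chrom,expected", [
        ("chrM", "mitochondrial"), ("MT", "mitochondrial"),
        ("chrX", "sex"), ("Y", "sex"),
        ("chr12", "autosomal"), ("7", "autosomal"),
    ])
    def test_default_mapping(self, chrom, expected):
        assert classify_compartment(chrom) == expected

    def test_unknown_contig_raises_with_name(self):
        with pytest.raises(ValueError, match="scaffold_17"):
            classify_compartment("scaffold_17")

    def test_alias_override(self):
        assert classify_compartment("chrZ", {"chrZ": "sex"}) == "sex"


def mk_pileup(depth=30, L=2000, chrom="chr1", alt_at=None):
    counts = np.zeros((4, L), dtype=np.uint16)
    counts[0] = depth
    if alt_at:
        for pos0, alt_code, n_alt in alt_at:
            counts[0, pos0] = depth - n_alt
            counts[alt_code, pos0] = n_alt
    return SamplePileup([chrom], {chrom: counts},
                        {chrom: np.full(L, depth, dtype=np.int32)}, {})


def calls_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "genotype",
                                       "gq", "depth", "ref_ad", "alt_ad"])


class TestSubtraction:
    def test_identical_call_sets_give_no_candidates(self):
        calls = calls_frame([("chr1", 100, "A", "G", "0/1", 99, 30, 15, 15)])
        cand, unres = subtract_paired(calls, calls, mk_pileup(), mk_pileup())
        assert cand.empty and unres == 0

    def test_clone_only_call_with_clean_donor_is_candidate(self):
        clone = calls_frame([("chr1", 100, "A", "G", "0/1", 99, 30, 15, 15)])
        donor_calls = calls_frame([])
        cand, unres = subtract_paired(clone, donor_calls, mk_pileup(), mk_pileup())
        assert len(cand) == 1 and unres == 0
        assert cand.iloc[0]["donor_alt"] == 0

    def test_uncallable_donor_site_counted_unresolvable(self):
        clone = calls_frame([("chr1", 100, "A", "G", "0/1", 99, 30, 15, 15)])
        shallow = mk_pileup(depth=3)
        cand, unres = subtract_paired(clone, calls_frame([]), mk_pileup(), shallow)
        assert cand.empty and unres == 1

    def test_donor_allele_evidence_suppresses_candidate(self):
        # donor shows 15 alt reads but its genotype fell between classes
        clone = calls_frame([("chr1", 100, "A", "G", "0/1", 99, 29, 11, 18)])
        donor_pile = mk_pileup(depth=16, alt_at=[(99, 2, 15)])
        cand, unres = subtract_paired(clone, calls_frame([]), mk_pileup(), donor_pile)
        assert cand.empty and unres == 0

    def test_fisher_filter_keeps_discordant_drops_balanced(self):
        cand = calls_frame([
            ("chr1", 100, "A", "G", "0/1", 99, 20, 10, 10),
            ("chr1", 200, "A", "G", "0/1", 99, 10, 5, 5),
        ]).assign(donor_ref=[20, 5], donor_alt=[0, 5])
        kept = apply_fisher_filter(cand, alpha=0.05)
        assert list(kept["pos"]) == [100]
        assert kept["fisher_p"].iloc[0] <= 0.05


class TestMitoState:
    def test_homoplasmic_at_high_allele_fraction(self):
        assert mito_state({"ref_ad": 1, "alt_ad": 19}) == "homoplasmic"
        assert mito_state({"ref_ad": 10, "alt_ad": 10}) == "heteroplasmic"


def make_reference(seq_by_chrom):
    return {c: encode(s) for c, s in seq_by_chrom.items()}


class TestAnnotateEffect:
    def test_synonymous_third_position(self):
        #         codon1   codon2(TTT->TTC Phe)  stop
        cds = "ATG" + "TTT" + "TAA"
        ref = make_reference({"chr1": "AAAA" + cds + "AAAA"})
        gene = GeneModel("g1", "chr1", "+", [(5, 5 + len(cds) - 1)])
        effect, change, in_cds = annotate_effect("chr1", 10, "T", "C", "SNV",
                                                 [gene], ref)
        assert effect == "synonymous" and change == "" and in_cds

    def test_nonsynonymous_with_change_string(self):
        # 811th codon AAG (Lys); A->G at its first position gives GAG (Glu)
        codons = ["ATG"] + ["GCT"] * 809 + ["AAG"] + ["TAA"]
        # K is codon index 810 (1-based codon number 811)
        codons[810] = "AAG"
        cds = "".join(codons[:811]) + "TAA"
        assert len(cds) % 3 == 0
        ref = make_reference({"chr1": "CC" + cds + "CC"})
        gene = GeneModel("esco_like", "chr1", "+", [(3, 3 + len(cds) - 1)])
        pos = 3 + 810 * 3  # first base of codon 811, 1-based
        effect, change, _ = annotate_effect("chr1", pos, "A", "G", "SNV",
                                            [gene], ref)
        assert effect == "nonsynonymous" and change == "K811E"

    def test_upstream_snv_is_noncoding(self):
        ref = make_reference({"chr1": "A" * 50 + "ATGTTTTAA" + "A" * 50})
        gene = GeneModel("g1", "chr1", "+", [(51, 59)])
        effect, change, in_cds = annotate_effect("chr1", 10, "A", "G", "SNV",
                                                 [gene], ref)
        assert effect == "noncoding" and not in_cds

    def test_minus_strand_translation(self):
        # gene on '-': genomic revcomp is ATG TTT TAA
        from somaclone._seq import revcomp_str
        cds_plus = "ATGAAATAA"          # M K *
        genomic = revcomp_str(cds_plus)
        ref = make_reference({"chr1": "GG" + genomic + "GG"})
        gene = GeneModel("g1", "chr1", "-", [(3, 3 + len(genomic) - 1)])
        # mutate codon 2 (AAA, Lys): genomic base complementary to its first A
        # codon 2 occupies CDS offsets 3..5 -> genomic positions e-3..e-5
        e = 3 + len(genomic) - 1
        pos = e - 3                       # CDS offset 3 on the minus strand
        ref_base = "ACGTN"[ref["chr1"][pos - 1]]
        effect, change, _ = annotate_effect("chr1", pos, ref_base, "G", "SNV",
                                            [gene], ref)
        assert effect == "nonsynonymous"
        assert change.startswith("K2")

    def test_indel_in_cds_flagged_not_translated(self):
        ref = make_reference({"chr1": "AA" + "ATGTTTTAA" + "AA"})
        gene = GeneModel("g1", "chr1", "+", [(3, 11)])
        effect, change, in_cds = annotate_effect("chr1", 6, "", "ACG", "INS",
                                                 [gene], ref)
        assert effect == "NA" and in_cds

    def test_internal_stop_reference_annotated_na(self):
        ref = make_reference({"chr1": "AA" + "ATGTAATTTTAA" + "AA"})
        gene = GeneModel("g1", "chr1", "+", [(3, 14)])
        effect, _, _ = annotate_effect("chr1", 9, "T", "C", "SNV", [gene], ref)
        assert effect == "NA"

    def test_gene_model_validation(self):
        with pytest.raises(ValueError, match="divisible"):
            GeneModel("g", "chr1", "+", [(1, 10)])
        with pytest.raises(ValueError, match="overlap"):
            GeneModel("g", "chr1", "+", [(1, 6), (4, 9)])
        with pytest.raises(ValueError, match="strand"):
            GeneModel("g", "chr1", "*", [(1, 6)])


def test_add_compartments_on_frame():
    df = pd.DataFrame({"chrom": ["chr1", "chrX", "chrM"], "pos": [1, 2, 3]})
    out = add_compartments(df)
    assert list(out["compartment"]) == ["autosomal", "sex", "mitochondrial"]


def test_gff3_roundtrip(tmp_path):
    from somaclone.somatic import load_gene_models_gff3, write_gene_models_gff3
    models = [GeneModel("gA", "chr1", "+", [(100, 201), (300, 401)]),
              GeneModel("gB", "chr2", "-", [(50, 151)])]
    path = tmp_path / "genes.gff3"
    write_gene_models_gff3(models, path)
    loaded = sorted(load_gene_models_gff3(path), key=lambda g: g.gene_id)
    assert len(loaded) == 2
    assert loaded[0].cds == [(100, 201), (300, 401)]
    assert loaded[1].strand == "-"
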