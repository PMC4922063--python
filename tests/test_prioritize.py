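"""Co-segregation classification, panel exclusion, merging, annotation
and candidate ranking."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from recmap.core import MISSING, CandidateInterval, GeneModel, Variant
from recmap.prioritize import (
    ClassifiedVariant,
    CosegClass,
    Region,
    annotate_variant,
    classify_cosegregation,
    merge_variant_sets,
    panel_exclude,
    rank_candidates,
)


class TestClassification:
    @pytest.mark.parametrize("cases,controls,expected", [
        ((2, 2, 2), (0, 1, 0), CosegClass.CONSISTENT),
        ((2, MISSING, 2), (0, 1), CosegClass.AMBIGUOUS),
        ((1, 2, 2), (0, 0), CosegClass.INCONSISTENT),   # het case
        ((2, 2), (0, 2, 1), CosegClass.INCONSISTENT),   # hom-alt control
        ((2, 2), (MISSING, 1), CosegClass.AMBIGUOUS),
    ])
    def test_recessive_trichotomy(self, cases, controls, expected):
        assert classify_cosegregation(cases, controls) is expected

    def test_strict_mode_rejects_carrier_controls(self):
        assert classify_cosegregation((2, 2), (0, 1)) is CosegClass.CONSISTENT
        assert classify_cosegregation((2, 2), (0, 1),
                                      strict=True) is CosegClass.INCONSISTENT

    @settings(derandomize=True, max_examples=80)
    @given(cases=st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=1,
                          max_size=6),
           controls=st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=1,
                             max_size=6),
           extra=st.sampled_from([0, 1, 2, MISSING]))
    def test_extra_observation_never_rescues_inconsistency(self, cases,
                                                           controls, extra):
        before = classify_cosegregation(cases, controls)
        after = classify_cosegregation(cases + [extra], controls)
        if before is CosegClass.INCONSISTENT:
            assert after is CosegClass.INCONSISTENT
        if before is CosegClass.CONSISTENT:
            assert after in (CosegClass.CONSISTENT, CosegClass.INCONSISTENT)


def make_cv(pos, panel, ref="C", alt="A", coseg=CosegClass.CONSISTENT):
    cv = ClassifiedVariant(variant=Variant("13", pos, ref, alt),
                           case_genotypes=np.array([2, 2, 2]),
                           control_genotypes=np.array([0, 0, 1]),
                           panel_genotypes=np.array(panel))
    cv.coseg_class = coseg
    return cv


class TestPanelExclusion:
    def test_single_het_panel_carrier_excludes(self):
        retained, excluded = panel_exclude([make_cv(100, [0] * 10 + [1])])
        assert not retained and len(excluded) == 1

    def test_absent_from_full_panel_is_private(self):
        retained, _ = panel_exclude([make_cv(100, [0] * 103)])
        assert len(retained) == 1
        assert retained[0].private_to_cases

    def test_missing_panel_calls_do_not_exclude(self):
        retained, _ = panel_exclude([make_cv(100, [0, MISSING, 0])])
        assert len(retained) == 1

    @settings(derandomize=True, max_examples=50)
    @given(panel=st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=1,
                          max_size=20),
           extension=st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=1,
                              max_size=20))
    def test_enlarging_the_panel_never_unexcludes(self, panel, extension):
        small = panel_exclude([make_cv(100, panel)])[0]
        big = panel_exclude([make_cv(100, panel + extension)])[0]
        if not small:  # excluded under the small panel
            assert not big


class TestMerge:
    def test_overlapping_sets_merge_to_26(self):
        sanger = [make_cv(1000 + i, [0]) for i in range(12)]
        reseq = [make_cv(5000 + i, [0]) for i in range(14)]
        shared = make_cv(1000, [0])  # same key as the first Sanger variant
        shared.sources = {"reseq"}
        for cv in sanger:
            cv.sources = {"sanger"}
        for cv in reseq:
            cv.sources = {"reseq"}
        merged = merge_variant_sets(sanger, reseq + [shared])
        assert len(merged) == 26
        overlap = next(cv for cv in merged if cv.variant.pos == 1000)
        assert overlap.sources == {"sanger", "reseq"}

    def test_idempotent_and_identity_on_empty(self):
        a = [make_cv(10, [0]), make_cv(20, [0])]
        assert [cv.key for cv in merge_variant_sets(a, a)] == \
            [cv.key for cv in a]
        assert [cv.key for cv in merge_variant_sets(a, [])] == \
            [cv.key for cv in a]


def toy_gene(n_codons=30, strand="+", gene_start=1001):
    """Single-exon plus-strand CDS of ``n_codons`` with known sequence."""
    rng = np.random.default_rng(n_codons)
    cds = "ATG" + "".join("ACGT"[k] for k in rng.integers(0, 4,
                                                          size=3 * (n_codons - 1)))
    length = 3 * n_codons
    exon = (gene_start, gene_start + length - 1)
    model = GeneModel(gene_id="toy", chrom="13", strand=strand, exons=[exon],
                      cds_start=exon[0], cds_end=exon[1],
                      first_exons={"t": exon}, promoter_window=500)
    return model, cds


class TestAnnotation:
    def test_n106k_style_codon_change(self):
        # codon 106 = AAC (Asn); C>A at its third base gives AAA (Lys)
        model, _ = toy_gene(n_codons=120)
        cds = "ATG" + "GCT" * 104 + "AAC" + "GCT" * 14
        pos = model.cds_start + 105 * 3 + 2  # third base of codon 106
        var = Variant("13", pos, "C", "A")
        ann = annotate_variant(var, model, cds)
        assert ann.region is Region.CODING
        assert ann.coding_effect.kind == "NONSYNONYMOUS"
        assert ann.coding_effect.label == "N106K"

    def test_wobble_position_synonymous(self):
        model, _ = toy_gene(n_codons=30)
        cds = "ATG" + "GCT" * 8 + "GGC" + "GCT" * 20
        pos = model.cds_start + 9 * 3 + 2  # third base of codon 10 (GGC)
        ann = annotate_variant(Variant("13", pos, "C", "T"), model, cds)
        assert ann.coding_effect.kind == "SYNONYMOUS"
        assert ann.coding_effect.label == "G10G"

    def test_every_single_base_change_matches_translation_oracle(self):
        model, cds = toy_gene(n_codons=30)
        for off in range(1, 91):
            pos = model.cds_start + off - 1
            ref = cds[off - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                ann = annotate_variant(Variant("13", pos, ref, alt), model, cds)
                mutated = cds[:off - 1] + alt + cds[off:]
                p0 = str(Seq(cds).translate())
                p1 = str(Seq(mutated).translate())
                if p0 == p1:
                    assert ann.coding_effect.kind == "SYNONYMOUS"
                else:
                    diff = [k for k, (x, y) in enumerate(zip(p0, p1)) if x != y]
                    assert len(diff) == 1
                    k = diff[0]
                    assert ann.coding_effect.kind == "NONSYNONYMOUS"
                    assert ann.coding_effect.label == f"{p0[k]}{k + 1}{p1[k]}"

    def test_minus_strand_codon_mapping(self):
        # single exon gene on the minus strand: CDS base 1 pairs with the
        # exon's rightmost genomic base
        model, cds = toy_gene(n_codons=30, strand="-")
        pos = model.cds_end  # genomic position of CDS offset 1 (the A of ATG)
        ref = str(Seq(cds[0]).complement())  # genomic plus-strand base
        alt = next(b for b in "ACGT"
                   if b != ref and str(Seq(b).complement()) != "G")
        ann = annotate_variant(Variant("13", pos, ref, alt), model, cds)
        assert ann.region is Region.CODING
        assert ann.coding_effect.label.startswith("M1")

    def test_coding_indel_frameshift_vs_in_frame(self):
        model, cds = toy_gene(n_codons=30)
        pos = model.cds_start + 10
        fs = annotate_variant(Variant("13", pos, cds[10], cds[10] + "AT"),
                              model, cds)
        assert fs.coding_effect.kind == "FRAMESHIFT"
        inf = annotate_variant(Variant("13", pos, cds[10], cds[10] + "ATG"),
                               model, cds)
        assert inf.coding_effect.kind == "IN_FRAME_INDEL"

    def test_region_assignment_precedence(self):
        exon1 = (10_000, 10_150)
        exon2 = (20_000, 20_300)
        model = GeneModel(gene_id="g", chrom="13", strand="+",
                          exons=[exon1, exon2], cds_start=20_000,
                          cds_end=20_299, first_exons={"M": exon1},
                          promoter_window=5_000)
        cases = {
            9_000: Region.PROMOTER,        # upstream window of the M TSS
            10_152: Region.SPLICE_BOUNDARY,  # 2 bp past exon 1 end
            15_000: Region.INTRON,
            19_999: Region.SPLICE_BOUNDARY,
            30_000: Region.INTERGENIC,
            4_000: Region.INTERGENIC,      # beyond the promoter window
        }
        for pos, expected in cases.items():
            ann = annotate_variant(Variant("13", pos, "C", "A"), model,
                                   "ATG" * 100)
            assert ann.region is expected, pos
        assert annotate_variant(Variant("13", 9_000, "C", "A"), model,
                                "ATG" * 100).promoter_of == "M"

    def test_minus_strand_promoter_is_downstream_in_genome_coordinates(self):
        exon = (10_000, 10_150)
        model = GeneModel(gene_id="g", chrom="13", strand="-", exons=[exon],
                          cds_start=10_000, cds_end=10_149,
                          first_exons={"M": exon}, promoter_window=1_000)
        ann = annotate_variant(Variant("13", 10_500, "C", "A"), model, None)
        assert ann.region is Region.PROMOTER
        assert annotate_variant(Variant("13", 9_500, "C", "A"), model,
                                None).region is Region.INTERGENIC


class TestRanking:
    def test_focus_promoter_first_then_region_priority(self):
        exon1 = (50_000, 50_150)
        exon2 = (60_000, 60_299)
        model = GeneModel(gene_id="g", chrom="13", strand="+",
                          exons=[exon1, exon2], cds_start=60_000,
                          cds_end=60_299, first_exons={"M": exon1},
                          promoter_window=10_000)
        interval = CandidateInterval("13", 40_000, 70_000)
        cds = "ATG" + "GCT" * 99
        variants = {
            "focus_snp": make_cv(45_000, [0]),
            "focus_ins": make_cv(46_000, [0], ref="C", alt="CAGCTAGCTAGCTAG"),
            "coding": make_cv(60_002, [0], ref="G", alt="T"),
            "intron": make_cv(55_000, [0]),
            "panel_hit": make_cv(45_500, [1]),
        }
        retained, _ = panel_exclude(list(variants.values()))
        for cv in retained:
            from recmap.prioritize import annotate_variant as ann
            cv.annotation = ann(cv.variant, model, cds)
        ranked = rank_candidates(retained, interval=interval,
                                 focus_promoter="M")
        keys = [cv.variant.pos for cv in ranked]
        # focus promoter first (insertion before SNP), then coding, intron;
        # the panel carrier is absent entirely
        assert keys == [46_000, 45_000, 60_002, 55_000]

    def test_eight_focus_variants_occupy_the_first_eight_ranks(self):
        exon1 = (50_000, 50_150)
        model = GeneModel(gene_id="g", chrom="13", strand="+", exons=[exon1],
                          cds_start=50_000, cds_end=50_149,
                          first_exons={"M": exon1}, promoter_window=10_000)
        interval = CandidateInterval("13", 30_000, 70_000)
        cvs = [make_cv(41_000 + 500 * i, [0]) for i in range(8)]  # promoter
        cvs += [make_cv(30_100 + 100 * i, [0]) for i in range(18)]  # intergenic
        retained, _ = panel_exclude(cvs)
        for cv in retained:
            cv.annotation = annotate_variant(cv.variant, model, None)
        ranked = rank_candidates(retained, interval=interval,
                                 focus_promoter="M")
        assert len(ranked) == 26
        assert all(cv.annotation.promoter_of == "M" for cv in ranked[:8])
        assert all(cv.annotation.promoter_of != "M" for cv in ranked[8:])

    def test_cascade_recovers_planted_private_set_exactly(self):
        from recmap import prioritize
        from recmap.simulate import sim_variant_calls

        interval = CandidateInterval("13", 56_170_062, 56_933_573)
        for seed in range(10):
            calls, truth = sim_variant_calls(interval, missing_rate=0.0,
                                             seed=seed)
            cvs = [ClassifiedVariant(variant=v,
                                     case_genotypes=calls.case_calls[i],
                                     control_genotypes=calls.control_calls[i],
                                     panel_genotypes=calls.panel_calls[i])
                   for i, v in enumerate(calls.variants)]
            cvs = prioritize.classify_all(cvs)
            assert all(cv.coseg_class is CosegClass.CONSISTENT for cv in cvs)
            retained, _ = panel_exclude(cvs)
            assert sorted(cv.key for cv in retained) == truth.private_keys
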