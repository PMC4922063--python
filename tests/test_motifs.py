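"""Motif scanning, indel-aware coordinate projection, gained/lost site
calling and the in-silico deletion test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recmap.core import SequenceRecord, reverse_complement
from recmap.motifs import (
    SOX_CONSENSUS,
    Edit,
    EditType,
    MotifModel,
    PromoterPair,
    apply_edits,
    deletion_test,
    diff_sites,
    iupac_reverse_complement,
    project_alt_to_ref,
    project_ref_to_alt,
    scan,
    tss_relative,
)

IUPAC_SETS = {"A": "A", "C": "C", "G": "G", "T": "T", "W": "AT", "S": "CG",
              "R": "AG", "Y": "CT", "K": "GT", "M": "AC", "N": "ACGT",
              "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG"}


def naive_scan(seq, pattern):
    """Position-by-position oracle over both strands."""
    hits = set()
    L = len(pattern)
    for strand, pat in (("+", pattern),
                        ("-", iupac_reverse_complement(pattern))):
        for i in range(len(seq) - L + 1):
            if all(seq[i + k] in IUPAC_SETS[c] for k, c in enumerate(pat)):
                hits.add((i + 1, strand))
    return hits


class TestScan:
    def test_forward_consensus_hit(self):
        seq = "GGGG" + "AACAAAG" + "GGGG"
        hits = scan(seq, MotifModel(iupac="WWCAAWG"))
        assert [(h.start, h.strand, h.matched) for h in hits] == \
            [(5, "+", "AACAAAG")]

    def test_reverse_strand_hit(self):
        payload = "AACAAAG"
        seq = "GGGG" + reverse_complement(payload) + "GGGG"
        hits = scan(seq, MotifModel(iupac="WWCAAWG"))
        assert [(h.start, h.strand, h.matched) for h in hits] == \
            [(5, "-", payload)]

    def test_agrees_with_naive_oracle_on_random_sequences(self):
        rng = np.random.default_rng(21)
        for pattern in ("WWCAAWG", "CACGTG", "RYRYNNSW"):
            for _ in range(34):
                seq = "".join("ACGT"[k] for k in rng.integers(0, 4, size=1000))
                got = {(h.start, h.strand)
                       for h in scan(seq, MotifModel(iupac=pattern))}
                assert got == naive_scan(seq, pattern)

    def test_pattern_longer_than_sequence_gives_empty(self):
        assert scan("ACGT", MotifModel(iupac="WWCAAWG")) == []

    def test_doubled_sequence_finds_each_hit_twice(self):
        rng = np.random.default_rng(3)
        motif = MotifModel(iupac="WWCAAWG")
        for _ in range(10):
            seq = "".join("ACGT"[k] for k in rng.integers(0, 4, size=400))
            single = scan(seq, motif)
            double = scan(seq + seq, motif)
            # every hit appears at its position and shifted by len(seq);
            # at most patternlength-1 extra junction hits can appear
            expect = {(h.start, h.strand) for h in single} | \
                {(h.start + len(seq), h.strand) for h in single}
            got = {(h.start, h.strand) for h in double}
            assert expect <= got
            assert len(got - expect) <= motif.length - 1

    def test_pwm_mode_matches_threshold_rule(self):
        # strongly favours ACGT at each of 4 positions
        pwm = np.full((4, 4), -2.0)
        for i, b in enumerate("ACGT"):
            pwm[i, "ACGT".index(b)] = 1.0
        motif = MotifModel(pwm=pwm, threshold=4.0)
        hits = scan("GGACGTGG", motif, strands="+")
        assert [(h.start, h.score) for h in hits] == [(3, 4.0)]

    def test_strand_symmetry_of_consensus(self):
        assert iupac_reverse_complement("WWCAAWG") == "CWTTGWW"
        rng = np.random.default_rng(8)
        motif = MotifModel(iupac="WWCAAWG")
        seq = "".join("ACGT"[k] for k in rng.integers(0, 4, size=600))
        rc = reverse_complement(seq)
        fwd_of_rc = {(len(seq) - h.start - motif.length + 2)
                     for h in scan(rc, motif, strands="+")}
        minus = {h.start for h in scan(seq, motif, strands="-")}
        assert fwd_of_rc == minus


def edits_strategy():
    """Random non-overlapping edit lists over a 200-bp reference."""
    base = st.sampled_from("ACGT")

    @st.composite
    def build(draw):
        n = draw(st.integers(0, 4))
        offsets = sorted(draw(st.lists(st.integers(5, 180), min_size=n,
                                       max_size=n, unique=True)))
        edits = []
        prev_end = 0
        for off in offsets:
            if off <= prev_end + 1:
                continue
            kind = draw(st.sampled_from(["INS", "SUB", "DEL"]))
            size = draw(st.integers(1, 6))
            piece = "".join(draw(st.lists(base, min_size=size, max_size=size)))
            if kind == "INS":
                edits.append(Edit(off, EditType.INS, alt_piece=piece))
                prev_end = off
            elif kind == "SUB":
                edits.append(Edit(off, EditType.SUB, ref_piece="X" * size,
                                  alt_piece=piece))
                prev_end = off + size - 1
            else:
                edits.append(Edit(off, EditType.DEL, ref_piece="X" * size))
                prev_end = off + size - 1
        return edits

    return build()


def concretize(edits, ref):
    """Replace placeholder ref pieces with the actual reference bases."""
    out = []
    for e in edits:
        if e.ref_piece:
            piece = ref[e.ref_offset - 1: e.ref_offset - 1 + len(e.ref_piece)]
            out.append(Edit(e.ref_offset, e.etype, ref_piece=piece,
                            alt_piece=e.alt_piece))
        else:
            out.append(e)
    return out


def oracle_maps(ref, edits):
    """Per-base coordinate maps built by explicit walk-through."""
    ref2alt, alt2ref = {}, {}
    ref_pos, alt_pos = 1, 1
    for e in sorted(edits, key=lambda e: e.ref_span[0]):
        boundary = e.ref_offset + 1 if e.etype is EditType.INS else e.ref_offset
        while ref_pos < boundary:
            ref2alt[ref_pos] = alt_pos
            alt2ref[alt_pos] = ref_pos
            ref_pos += 1
            alt_pos += 1
        if e.etype is EditType.INS:
            for _ in e.alt_piece:
                alt2ref[alt_pos] = None
                alt_pos += 1
        elif e.etype is EditType.SUB:
            for _ in e.ref_piece:
                ref2alt[ref_pos] = alt_pos
                alt2ref[alt_pos] = ref_pos
                ref_pos += 1
                alt_pos += 1
        else:  # DEL
            for _ in e.ref_piece:
                ref2alt[ref_pos] = None
                ref_pos += 1
    while ref_pos <= len(ref):
        ref2alt[ref_pos] = alt_pos
        alt2ref[alt_pos] = ref_pos
        ref_pos += 1
        alt_pos += 1
    return ref2alt, alt2ref


class TestProjection:
    def test_positions_before_edits_unchanged(self):
        edits = [Edit(50, EditType.INS, alt_piece="ACGTACGTACGTAC")]
        assert project_ref_to_alt(10, edits) == 10

    def test_shift_after_14_bp_insertion(self):
        edits = [Edit(50, EditType.INS, alt_piece="ACGTACGTACGTAC")]
        assert project_ref_to_alt(60, edits) == 74

    def test_inserted_span_has_no_reference_counterpart(self):
        edits = [Edit(50, EditType.INS, alt_piece="ACGTACGTACGTAC")]
        for pos in (51, 57, 64):
            assert project_alt_to_ref(pos, edits) is None

    @settings(derandomize=True, max_examples=60)
    @given(edits=edits_strategy(), data=st.data())
    def test_round_trip_and_oracle_agreement(self, edits, data):
        rng = np.random.default_rng(5)
        ref = "".join("ACGT"[k] for k in rng.integers(0, 4, size=200))
        edits = concretize(edits, ref)
        alt = apply_edits(ref, edits)
        r2a, a2r = oracle_maps(ref, edits)
        pos = data.draw(st.integers(1, 200))
        assert project_ref_to_alt(pos, edits) == r2a[pos]
        apos = data.draw(st.integers(1, len(alt)))
        assert project_alt_to_ref(apos, edits) == a2r[apos]
        # round trip is the identity on mappable positions
        if r2a[pos] is not None:
            assert project_alt_to_ref(r2a[pos], edits) == pos


class TestDiffSites:
    def test_default_fixture_gains_exactly_one_site_in_the_14bp_insertion(
            self, default_promoter_pair):
        pair, truth = default_promoter_pair
        gained, lost = diff_sites(pair, MotifModel(iupac=SOX_CONSENSUS))
        assert len(gained) == 1 and lost == []
        hit = gained[0]
        lo, hi = truth.planted_motif_span
        assert lo <= hit.start and hit.end <= hi
        assert any(e.etype is EditType.INS and len(e.alt_piece) == 14
                   for e in hit.edits)
        # the gained silencer sits ~7.5 kb upstream of the TSS
        assert -7_600 <= hit.tss_relative <= -7_450

    def test_identical_alleles_diff_to_nothing(self):
        rng = np.random.default_rng(9)
        seq = "".join("ACGT"[k] for k in rng.integers(0, 4, size=500))
        pair = PromoterPair(ref=SequenceRecord("r", seq),
                            alt=SequenceRecord("a", seq), edits=[],
                            tss_ref_offset=501)
        assert diff_sites(pair, MotifModel(iupac=SOX_CONSENSUS)) == ([], [])

    def test_agrees_with_bruteforce_projection_matching(
            self, default_promoter_pair):
        pair, _ = default_promoter_pair
        motif = MotifModel(iupac=SOX_CONSENSUS)
        gained, lost = diff_sites(pair, motif)
        r2a, a2r = oracle_maps(pair.ref.seq, pair.edits)
        ref_hits = {(h.start, h.strand) for h in scan(pair.ref.seq, motif)}
        alt_hits = {(h.start, h.strand) for h in scan(pair.alt.seq, motif)}
        oracle_gained = {(s, d) for (s, d) in alt_hits
                         if a2r[s] is None or (a2r[s], d) not in ref_hits}
        oracle_lost = {(s, d) for (s, d) in ref_hits
                       if r2a[s] is None or (r2a[s], d) not in alt_hits}
        assert {(h.start, h.strand) for h in gained} == oracle_gained
        assert {(h.start, h.strand) for h in lost} == oracle_lost

    def test_substitution_destroying_a_site_is_reported_lost(self):
        seq = "GGGG" + "AACAAAG" + "GGGGGGGG"
        edits = [Edit(8, EditType.SUB, ref_piece="A", alt_piece="G")]
        pair = PromoterPair(ref=SequenceRecord("r", seq),
                            alt=SequenceRecord("a", apply_edits(seq, edits)),
                            edits=edits, tss_ref_offset=len(seq) + 1)
        gained, lost = diff_sites(pair, MotifModel(iupac="WWCAAWG"))
        assert gained == []
        assert [(h.start, h.strand) for h in lost] == [(5, "+")]


class TestDeletionTest:
    def test_deleting_the_96bp_cluster_predicts_restoration(
            self, default_promoter_pair):
        pair, truth = default_promoter_pair
        motif = MotifModel(iupac=SOX_CONSENSUS)
        lo = min(e.ref_offset for e in pair.edits)
        region = (lo - 5, truth.planted_motif_span[1] + 5)
        res = deletion_test(pair, region, motif)
        assert res.restored

    def test_deleting_only_the_payload_insertion_suffices(
            self, default_promoter_pair):
        pair, truth = default_promoter_pair
        res = deletion_test(pair, truth.planted_motif_span,
                            MotifModel(iupac=SOX_CONSENSUS))
        assert res.restored

    def test_deleting_an_untouched_span_changes_nothing(
            self, default_promoter_pair):
        pair, _ = default_promoter_pair
        motif = MotifModel(iupac=SOX_CONSENSUS)
        gained_before, _ = diff_sites(pair, motif)
        res = deletion_test(pair, (2_000, 2_095), motif)
        assert {(h.start, h.strand) for h in res.gained} == \
            {(h.start, h.strand) for h in gained_before}


class TestTssRelative:
    def test_upstream_positions_are_negative(self):
        assert tss_relative(468, 8_000) == -7_532

    def test_tss_itself_is_plus_one_and_no_zero_exists(self):
        assert tss_relative(8_000, 8_000) == 1
        assert tss_relative(7_999, 8_000) == -1

    def test_strictly_monotone_in_position(self):
        vals = [tss_relative(p, 100) for p in range(1, 200)]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert 0 not in vals
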