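"""Strand-aware motif scanning over allele pairs with indel-aware
coordinate projection.

Used to ask whether promoter edits (insertions, substitutions) create or
destroy transcription-factor binding sites: both alleles are scanned, hit
positions are projected through the edit list, and hits present on one
allele without a counterpart at the projected position and strand on the
other are reported as gained or lost.  Positions are reported both
1-based in-sequence and TSS-relative with the no-zero convention
(... -2, -1, +1, +2 ...; negative = upstream).

The default SOX-family model is the IUPAC consensus WWCAAWG (the
HMG-box core); any IUPAC pattern or a position weight matrix with a
score threshold can be supplied instead.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import SequenceRecord, reverse_complement

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
                     "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
                     "D": "H", "H": "D", "N": "N"}

#: SOX HMG-box consensus used by default
SOX_CONSENSUS = "WWCAAWG"

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def iupac_reverse_complement(pattern: str) -> str:
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(pattern))


@dataclass
class MotifModel:
    """Either an IUPAC consensus pattern or a PWM with a score threshold."""

    iupac: str | None = None
    pwm: np.ndarray | None = None  # shape (L, 4), column order A C G T
    threshold: float | None = None
    name: str = "motif"

    def __post_init__(self) -> None:
        if (self.iupac is None) == (self.pwm is None):
            raise ValueError("provide exactly one of iupac or pwm")
        if self.iupac is not None:
            self.iupac = self.iupac.upper()
            bad = set(self.iupac) - set(IUPAC)
            if bad:
                raise ValueError(f"invalid IUPAC codes: {sorted(bad)}")
            if len(self.iupac) < 4:
                raise ValueError("pattern length must be >= 4")
        else:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.ndim != 2 or self.pwm.shape[1] != 4 or self.pwm.shape[0] < 4:
                raise ValueError("PWM must have shape (L >= 4, 4)")
            if self.threshold is None or not np.isfinite(self.threshold):
                raise ValueError("PWM mode requires a finite score threshold")

    @property
    def length(self) -> int:
        return len(self.iupac) if self.iupac is not None else self.pwm.shape[0]


@dataclass
class MotifHit:
    start: int  # 1-based leftmost position in the scanned sequence
    strand: str  # '+' or '-'
    matched: str  # the site as read 5'->3' on its strand
    score: float | None = None
    tss_relative: int | None = None
    edits: list["Edit"] = field(default_factory=list)

    @property
    def end(self) -> int:
        return self.start + len(self.matched) - 1


def _scan_forward(seq: str, motif: MotifModel) -> list[tuple[int, float | None]]:
    L = motif.length
    out: list[tuple[int, float | None]] = []
    if motif.iupac is not None:
        sets = [IUPAC[c] for c in motif.iupac]
        for i in range(len(seq) - L + 1):
            if all(seq[i + k] in sets[k] for k in range(L)):
                out.append((i, None))
    else:
        for i in range(len(seq) - L + 1):
            window = seq[i:i + L]
            if "N" in window:
                continue
            score = float(sum(motif.pwm[k, _BASE_INDEX[b]] for k, b in enumerate(window)))
            if score >= motif.threshold:
                out.append((i, score))
    return out


def scan(seq: str | SequenceRecord, motif: MotifModel,
         strands: str = "both") -> list[MotifHit]:
    """All motif hits in a sequence, sorted by position.

    Minus-strand hits are found by scanning the forward sequence with the
    reverse-complement pattern; their ``start`` is the leftmost forward
    position and ``matched`` is the site as read on the minus strand.
    """
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    s = s.upper()
    hits: list[MotifHit] = []
    if strands in ("both", "+"):
        for i, score in _scan_forward(s, motif):
            hits.append(MotifHit(start=i + 1, strand="+",
                                 matched=s[i:i + motif.length], score=score))
    if strands in ("both", "-"):
        if motif.iupac is not None:
            rc = MotifModel(iupac=iupac_reverse_complement(motif.iupac), name=motif.name)
        else:
            rc = MotifModel(pwm=motif.pwm[::-1, ::-1], threshold=motif.threshold,
                            name=motif.name)
        for i, score in _scan_forward(s, rc):
            hits.append(MotifHit(start=i + 1, strand="-",
                                 matched=reverse_complement(s[i:i + motif.length]),
                                 score=score))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# allele pairs and coordinate projection

class EditType(str, enum.Enum):
    INS = "INS"
    SUB = "SUB"
    DEL = "DEL"
    COMPLEX = "COMPLEX"


@dataclass(frozen=True)
class Edit:
    """One difference between the reference and alternate allele.

    ``ref_offset`` is 1-based: an INS is inserted *after* that reference
    position (0 = before the first base); SUB/DEL/COMPLEX replace the
    reference span starting *at* that position.
    """

    ref_offset: int
    etype: EditType
    ref_piece: str = ""
    alt_piece: str = ""

    def __post_init__(self) -> None:
        t = self.etype
        lr, la = len(self.ref_piece), len(self.alt_piece)
        if t is EditType.INS and not (lr == 0 and la > 0):
            raise ValueError("INS must have empty ref_piece and non-empty alt_piece")
        if t is EditType.DEL and not (lr > 0 and la == 0):
            raise ValueError("DEL must have non-empty ref_piece and empty alt_piece")
        if t is EditType.SUB and not (lr == la > 0):
            raise ValueError("SUB must have equal-length non-empty pieces")
        if t is EditType.COMPLEX and lr == 0 and la == 0:
            raise ValueError("empty COMPLEX edit")
        if self.ref_offset < (0 if t is EditType.INS else 1):
            raise ValueError("edit offset out of range")

    @property
    def ref_span(self) -> tuple[int, int]:
        """Occupied reference span, inclusive; empty for INS (end < start)."""
        if self.etype is EditType.INS:
            return (self.ref_offset + 1, self.ref_offset)
        return (self.ref_offset, self.ref_offset + len(self.ref_piece) - 1)


def _check_edits(edits: Sequence[Edit]) -> list[Edit]:
    edits = sorted(edits, key=lambda e: (e.ref_span[0], e.ref_span[1]))
    prev_end = 0
    prev_point = -1
    for e in edits:
        s, t = e.ref_span
        if s <= prev_end:
            raise ValueError(f"overlapping edits at reference position {s}")
        if e.etype is EditType.INS and e.ref_offset == prev_point:
            raise ValueError(f"two insertions at reference offset {e.ref_offset}")
        prev_end = max(prev_end, t)
        if e.etype is EditType.INS:
            prev_point = e.ref_offset
            prev_end = max(prev_end, e.ref_offset)
    return edits


def apply_edits(ref: str, edits: Sequence[Edit]) -> str:
    """Apply an ordered, non-overlapping edit list to a reference sequence."""
    edits = _check_edits(edits)
    out: list[str] = []
    cursor = 0  # 0-based index into ref of the next unconsumed base
    for e in edits:
        s, t = e.ref_span
        if e.etype is EditType.INS:
            out.append(ref[cursor:e.ref_offset])
            out.append(e.alt_piece)
            cursor = e.ref_offset
        else:
            if t > len(ref):
                raise ValueError(f"edit at {s} extends past the sequence end")
            if ref[s - 1:t] != e.ref_piece:
                raise ValueError(f"edit at {s} expects {e.ref_piece!r}, "
                                 f"reference has {ref[s - 1:t]!r}")
            out.append(ref[cursor:s - 1])
            out.append(e.alt_piece)
            cursor = t
    out.append(ref[cursor:])
    return "".join(out)


@dataclass
class PromoterPair:
    """Reference / alternate upstream sequences related by an edit list.

    ``tss_ref_offset`` is the 1-based reference coordinate of the
    transcription start site; a fragment that is entirely upstream of the
    TSS uses ``len(ref) + 1``.
    """

    ref: SequenceRecord
    alt: SequenceRecord
    edits: list[Edit]
    tss_ref_offset: int

    def __post_init__(self) -> None:
        self.edits = _check_edits(self.edits)
        expected = apply_edits(self.ref.seq, self.edits)
        if expected != self.alt.seq:
            raise ValueError("edit list does not transform ref into alt")

    @property
    def tss_alt_offset(self) -> int:
        pos = project_ref_to_alt(self.tss_ref_offset, self.edits)
        assert pos is not None  # TSS cannot sit inside an inserted span
        return pos


def _edit_alt_span(e: Edit, shift: int) -> tuple[int, int]:
    la = len(e.alt_piece)
    if e.etype is EditType.INS:
        s = e.ref_offset + shift + 1
    else:
        s = e.ref_offset + shift
    return (s, s + la - 1)


def project_ref_to_alt(pos: int, edits: Sequence[Edit]) -> int | None:
    """Map a 1-based reference position to the alternate allele.

    Positions left of all edits map identically; positions after an
    insertion/deletion shift by its length; positions inside a deleted or
    complex-replaced reference span have no alternate counterpart (None).
    Substitutions preserve positions.
    """
    if pos < 1:
        raise ValueError("position must be >= 1")
    shift = 0
    for e in _check_edits(edits):
        s, t = e.ref_span
        if e.etype is EditType.INS:
            if pos <= e.ref_offset:
                break
            shift += len(e.alt_piece)
            continue
        if pos < s:
            break
        if pos <= t:
            if e.etype is EditType.SUB:
                return pos + shift
            return None
        shift += len(e.alt_piece) - len(e.ref_piece)
    return pos + shift


def project_alt_to_ref(pos: int, edits: Sequence[Edit]) -> int | None:
    """Inverse of :func:`project_ref_to_alt`; positions inside inserted
    spans map to None."""
    if pos < 1:
        raise ValueError("position must be >= 1")
    shift = 0
    for e in _check_edits(edits):
        a_s, a_t = _edit_alt_span(e, shift)
        if pos < a_s:
            break
        if pos <= a_t:
            if e.etype is EditType.SUB:
                return pos - shift
            return None
        shift += len(e.alt_piece) - len(e.ref_piece)
    return pos - shift


def tss_relative(pos: int, tss: int) -> int:
    """Signed TSS-relative coordinate with no zero: the TSS itself is +1,
    the base immediately upstream is -1."""
    return pos - tss if pos < tss else pos - tss + 1


def _attach_tss(hits: Iterable[MotifHit], tss: int) -> None:
    for h in hits:
        h.tss_relative = tss_relative(h.start, tss)


def _overlapping_edits(hit: MotifHit, edits: Sequence[Edit]) -> list[Edit]:
    out = []
    shift = 0
    for e in _check_edits(edits):
        a_s, a_t = _edit_alt_span(e, shift)
        if a_t < a_s:  # pure deletion: a point between a_s-1 and a_s
            if hit.start <= a_s - 1 and hit.end >= a_s:
                out.append(e)
        elif hit.start <= a_t and hit.end >= a_s:
            out.append(e)
        shift += len(e.alt_piece) - len(e.ref_piece)
    return out


def diff_sites(pair: PromoterPair, motif: MotifModel,
               strands: str = "both") -> tuple[list[MotifHit], list[MotifHit]]:
    """(gained, lost) motif hits of the alternate allele vs the reference.

    A hit is matched across alleles when the projected start position
    agrees exactly and the strand is the same; alternate-allele hits whose
    start lies inside an inserted span are always gained (including sites
    created across an insertion junction).  Gained hits carry the edits
    they overlap and TSS-relative coordinates; lost hits are reported in
    reference coordinates.
    """
    ref_hits = scan(pair.ref, motif, strands=strands)
    alt_hits = scan(pair.alt, motif, strands=strands)
    ref_keys = {(h.start, h.strand) for h in ref_hits}
    alt_keys = {(h.start, h.strand) for h in alt_hits}

    gained = []
    for h in alt_hits:
        rpos = project_alt_to_ref(h.start, pair.edits)
        if rpos is None or (rpos, h.strand) not in ref_keys:
            h.edits = _overlapping_edits(h, pair.edits)
            gained.append(h)
    lost = []
    for h in ref_hits:
        apos = project_ref_to_alt(h.start, pair.edits)
        if apos is None or (apos, h.strand) not in alt_keys:
            lost.append(h)
    _attach_tss(gained, pair.tss_alt_offset)
    _attach_tss(lost, pair.tss_ref_offset)
    return gained, lost


# ---------------------------------------------------------------------------
# in-silico region deletion

@dataclass
class DeletionTestResult:
    gained: list[MotifHit]

    @property
    def restored(self) -> bool:
        """No gained site survives the deletion: predicted restoration."""
        return not self.gained


def _compose_deletion(pair: PromoterPair, region: tuple[int, int]) -> list[Edit]:
    """Edit list for ref -> (alt with ``region`` removed), region in
    1-based inclusive alternate coordinates."""
    d_s, d_e = region
    if not (1 <= d_s <= d_e <= len(pair.alt.seq)):
        raise ValueError(f"deletion region {region} outside the alternate sequence")
    new_edits: list[Edit] = []
    shift = 0
    cursor_ref = 1  # next ref position not yet covered by an edit block
    for e in pair.edits:
        a_s, a_t = _edit_alt_span(e, shift)
        # match segment before this edit block
        m_ref_s, m_ref_e = cursor_ref, e.ref_span[0] - 1
        m_alt_s = m_ref_s + shift
        m_alt_e = m_ref_e + shift
        ov_s, ov_e = max(m_alt_s, d_s), min(m_alt_e, d_e)
        if m_ref_s <= m_ref_e and ov_s <= ov_e:
            r_s = m_ref_s + (ov_s - m_alt_s)
            r_e = m_ref_s + (ov_e - m_alt_s)
            new_edits.append(Edit(r_s, EditType.DEL,
                                  ref_piece=pair.ref.seq[r_s - 1:r_e]))
        # the edit block itself
        piece = e.alt_piece
        if piece and a_s <= a_t:
            ov_s, ov_e = max(a_s, d_s), min(a_t, d_e)
            if ov_s <= ov_e:
                piece = piece[: ov_s - a_s] + piece[ov_e - a_s + 1:]
        if piece != e.alt_piece or e.etype is EditType.COMPLEX:
            lr = len(e.ref_piece)
            if lr == 0 and not piece:
                pass  # insertion fully deleted: no edit remains
            elif lr == 0:
                new_edits.append(Edit(e.ref_offset, EditType.INS, alt_piece=piece))
            elif not piece:
                new_edits.append(Edit(e.ref_offset, EditType.DEL, ref_piece=e.ref_piece))
            elif lr == len(piece):
                new_edits.append(Edit(e.ref_offset, EditType.SUB,
                                      ref_piece=e.ref_piece, alt_piece=piece))
            else:
                new_edits.append(Edit(e.ref_offset, EditType.COMPLEX,
                                      ref_piece=e.ref_piece, alt_piece=piece))
        else:
            new_edits.append(e)
        cursor_ref = e.ref_span[1] + 1 if e.etype is not EditType.INS else e.ref_offset + 1
        shift += len(e.alt_piece) - len(e.ref_piece)
    # trailing match segment
    m_ref_s = cursor_ref
    m_ref_e = len(pair.ref.seq)
    m_alt_s = m_ref_s + shift
    ov_s, ov_e = max(m_alt_s, d_s), min(m_ref_e + shift, d_e)
    if m_ref_s <= m_ref_e and ov_s <= ov_e:
        r_s = m_ref_s + (ov_s - m_alt_s)
        r_e = m_ref_s + (ov_e - m_alt_s)
        new_edits.append(Edit(r_s, EditType.DEL, ref_piece=pair.ref.seq[r_s - 1:r_e]))
    return new_edits


def deletion_test(pair: PromoterPair, region: tuple[int, int],
                  motif: MotifModel, strands: str = "both") -> DeletionTestResult:
    """Remove ``region`` (alternate coordinates, 1-based inclusive) from
    the alternate allele and report the gained sites that remain relative
    to the reference; an empty set is a predicted restoration of
    reference-like regulation."""
    new_edits = _compose_deletion(pair, region)
    new_alt = apply_edits(pair.ref.seq, new_edits)
    new_pair = PromoterPair(ref=pair.ref,
                            alt=SequenceRecord(id=pair.alt.id + "_del", seq=new_alt),
                            edits=new_edits, tss_ref_offset=pair.tss_ref_offset)
    gained, _ = diff_sites(new_pair, motif, strands=strands)
    return DeletionTestResult(gained=gained)
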