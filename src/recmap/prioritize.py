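"""The variant-filter cascade for a recessive trait: co-segregation
classification with missing-data ambiguity, population-panel private-allele
exclusion, merging of screening sources, coding/regulatory annotation and
deterministic candidate ranking.

The co-segregation model is recessive: a variant is CONSISTENT when every
case is homozygous for the alternate allele and no control is, with no
missing call; AMBIGUOUS when missing calls exist but all observed calls
fit; INCONSISTENT otherwise.  Controls may be heterozygous carriers (the
parents of affected offspring are), unless ``strict`` mode demands
hom-ref controls.  Panel exclusion is absolute: any alternate allele in
any panel individual disqualifies a variant from being private to cases.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq

from .core import MISSING, CandidateInterval, GeneModel, Variant, VariantClass, complement


class CosegClass(str, enum.Enum):
    CONSISTENT = "CONSISTENT"
    AMBIGUOUS = "AMBIGUOUS"
    INCONSISTENT = "INCONSISTENT"


class Region(str, enum.Enum):
    CODING = "CODING"
    PROMOTER = "PROMOTER"
    INTRON = "INTRON"
    SPLICE_BOUNDARY = "SPLICE_BOUNDARY"
    INTERGENIC = "INTERGENIC"


@dataclass
class CodingEffect:
    kind: str  # SYNONYMOUS | NONSYNONYMOUS | FRAMESHIFT | IN_FRAME_INDEL
    label: str | None = None  # e.g. "N106K" for SNVs


@dataclass
class Annotation:
    region: Region
    promoter_of: str | None = None  # isoform label when region is PROMOTER
    coding_effect: CodingEffect | None = None


@dataclass
class ClassifiedVariant:
    variant: Variant
    case_genotypes: np.ndarray
    control_genotypes: np.ndarray
    panel_genotypes: np.ndarray | None = None
    coseg_class: CosegClass | None = None
    private_to_cases: bool = False
    annotation: Annotation | None = None
    sources: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.case_genotypes = np.asarray(self.case_genotypes, dtype=np.int8)
        self.control_genotypes = np.asarray(self.control_genotypes, dtype=np.int8)
        if self.panel_genotypes is not None:
            self.panel_genotypes = np.asarray(self.panel_genotypes, dtype=np.int8)

    @property
    def key(self):
        return self.variant.key


def classify_cosegregation(case_genotypes: Sequence[int],
                           control_genotypes: Sequence[int],
                           strict: bool = False) -> CosegClass:
    """Trichotomous recessive co-segregation call for one variant."""
    cases = np.asarray(case_genotypes)
    controls = np.asarray(control_genotypes)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("need at least one case and one control call")
    case_ok = cases != MISSING
    ctrl_ok = controls != MISSING
    fits = bool((cases[case_ok] == 2).all())
    if strict:
        fits = fits and bool((controls[ctrl_ok] == 0).all())
    else:
        fits = fits and bool((controls[ctrl_ok] != 2).all())
    if not fits:
        return CosegClass.INCONSISTENT
    if (~case_ok).any() or (~ctrl_ok).any():
        return CosegClass.AMBIGUOUS
    return CosegClass.CONSISTENT


def classify_all(variants: Iterable[ClassifiedVariant], strict: bool = False
                 ) -> list[ClassifiedVariant]:
    out = []
    for cv in variants:
        cv.coseg_class = classify_cosegregation(cv.case_genotypes,
                                                cv.control_genotypes, strict=strict)
        out.append(cv)
    return out


def panel_exclude(variants: Iterable[ClassifiedVariant]
                  ) -> tuple[list[ClassifiedVariant], list[ClassifiedVariant]]:
    """Split variants into (retained = private to cases, excluded).

    A variant is excluded as soon as any panel individual carries at least
    one alternate allele (non-missing call >= 1); retained variants are
    marked ``private_to_cases``.  Variants without panel calls are treated
    as unobserved in the panel and retained.
    """
    retained, excluded = [], []
    for cv in variants:
        panel = cv.panel_genotypes
        carried = False
        if panel is not None and panel.size:
            ok = panel != MISSING
            carried = bool((panel[ok] >= 1).any())
        if carried:
            cv.private_to_cases = False
            excluded.append(cv)
        else:
            cv.private_to_cases = True
            retained.append(cv)
    return retained, excluded


def merge_variant_sets(set_a: Iterable[ClassifiedVariant],
                       set_b: Iterable[ClassifiedVariant]
                       ) -> list[ClassifiedVariant]:
    """Deduplicated union keyed on (chrom, pos, ref, alt), ordered by
    position; same-key records merge their source provenance tags."""
    merged: dict[tuple, ClassifiedVariant] = {}
    for cv in list(set_a) + list(set_b):
        if cv.key in merged:
            merged[cv.key].sources |= cv.sources
        else:
            merged[cv.key] = cv
    return sorted(merged.values(), key=lambda c: (c.variant.chrom, c.variant.pos,
                                                  c.variant.ref, c.variant.alt))


# ---------------------------------------------------------------------------
# annotation

def _cds_offset(model: GeneModel, pos: int) -> int | None:
    """1-based offset of a genomic position within the spliced CDS, on the
    coding strand; None when the position is not coding."""
    if not (model.cds_start <= pos <= model.cds_end):
        return None
    cds_exons = []
    for s, e in model.exons:
        s2, e2 = max(s, model.cds_start), min(e, model.cds_end)
        if s2 <= e2:
            cds_exons.append((s2, e2))
    off = 0
    found = False
    for s, e in cds_exons:
        if s <= pos <= e:
            off += pos - s + 1
            found = True
            break
        off += e - s + 1
    if not found:
        return None
    if model.strand == "-":
        total = sum(e - s + 1 for s, e in cds_exons)
        off = total - off + 1
    return off


def _in_exon(model: GeneModel, pos: int) -> bool:
    return any(s <= pos <= e for s, e in model.exons)


def _near_splice(model: GeneModel, pos: int) -> bool:
    span = model.span
    for s, e in model.exons:
        if s > span[0] and s - 2 <= pos <= s - 1:
            return True
        if e < span[1] and e + 1 <= pos <= e + 2:
            return True
    return False


def _promoter_of(model: GeneModel, pos: int) -> str | None:
    best, best_dist = None, None
    for label in model.first_exons:
        s, e = model.promoter_interval(label)
        if s <= pos <= e:
            dist = abs(model.isoform_tss(label) - pos)
            if best is None or dist < best_dist:
                best, best_dist = label, dist
    return best


def _snv_effect(model: GeneModel, cds: str, pos: int, ref: str, alt: str,
                offset: int) -> CodingEffect:
    codon_index = math.ceil(offset / 3)  # 1-based
    within = offset - 3 * (codon_index - 1)  # 1..3
    codon = cds[3 * (codon_index - 1): 3 * codon_index]
    ref_c, alt_c = (ref, alt) if model.strand == "+" else (complement(ref), complement(alt))
    if codon[within - 1] != ref_c:
        raise ValueError(
            f"CDS sequence disagrees with reference allele at codon {codon_index} "
            f"(CDS has {codon[within - 1]}, variant ref implies {ref_c})")
    mutated = codon[: within - 1] + alt_c + codon[within:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    kind = "SYNONYMOUS" if aa_ref == aa_alt else "NONSYNONYMOUS"
    return CodingEffect(kind=kind, label=f"{aa_ref}{codon_index}{aa_alt}")


def annotate_variant(variant: Variant, model: GeneModel,
                     cds_sequence: str | None = None) -> Annotation:
    """Region and coding-effect annotation against one gene model.

    Region precedence: CODING (within CDS and exonic) > SPLICE_BOUNDARY
    (within 2 bp of an internal exon edge, intronic side) > PROMOTER
    (inside the strand-aware upstream window of an isoform TSS; isoform
    promoters may sit inside introns of longer isoforms and win over
    INTRON) > INTRON (elsewhere within the gene span, including
    non-coding exonic sequence) > INTERGENIC.  Coding SNVs get a
    refAA+codon+altAA label from the standard genetic code; coding indels
    are labelled frameshift or in-frame by length difference mod 3.
    """
    if variant.chrom != model.chrom:
        return Annotation(region=Region.INTERGENIC)
    pos = variant.pos
    offset = _cds_offset(model, pos)
    if offset is not None and _in_exon(model, pos):
        if variant.vclass is VariantClass.SNP:
            if cds_sequence is None:
                raise ValueError("coding SNV annotation requires the CDS sequence")
            if len(cds_sequence) % 3 != 0:
                raise ValueError("CDS length must be divisible by 3")
            return Annotation(region=Region.CODING,
                              coding_effect=_snv_effect(model, cds_sequence, pos,
                                                        variant.ref, variant.alt,
                                                        offset))
        shift = abs(len(variant.alt) - len(variant.ref)) % 3
        kind = "FRAMESHIFT" if shift else "IN_FRAME_INDEL"
        return Annotation(region=Region.CODING, coding_effect=CodingEffect(kind=kind))
    if _near_splice(model, pos):
        return Annotation(region=Region.SPLICE_BOUNDARY)
    label = _promoter_of(model, pos)
    if label is not None:
        return Annotation(region=Region.PROMOTER, promoter_of=label)
    span = model.span
    if span[0] <= pos <= span[1]:
        return Annotation(region=Region.INTRON)
    return Annotation(region=Region.INTERGENIC)


def annotate_all(variants: Iterable[ClassifiedVariant], model: GeneModel,
                 cds_sequence: str | None = None) -> list[ClassifiedVariant]:
    out = []
    for cv in variants:
        cv.annotation = annotate_variant(cv.variant, model, cds_sequence)
        out.append(cv)
    return out


# ---------------------------------------------------------------------------
# ranking

def _region_rank(cv: ClassifiedVariant) -> int:
    ann = cv.annotation
    if ann is None:
        return 9
    if ann.region is Region.CODING and ann.coding_effect is not None:
        if ann.coding_effect.kind in ("NONSYNONYMOUS", "FRAMESHIFT", "IN_FRAME_INDEL"):
            return 0
        return 5  # synonymous coding ranks below intronic
    return {Region.SPLICE_BOUNDARY: 1, Region.PROMOTER: 2,
            Region.INTRON: 3, Region.INTERGENIC: 6}.get(ann.region, 9)


def rank_candidates(variants: Iterable[ClassifiedVariant],
                    interval: CandidateInterval | None = None,
                    focus_promoter: str | None = None) -> list[ClassifiedVariant]:
    """Deterministically ordered candidate list.

    Retains CONSISTENT and AMBIGUOUS variants that are private to cases
    (and within ``interval`` when given); orders focus-promoter variants
    first, then by region priority (non-synonymous coding > splice >
    promoter > intron), then by position.
    """
    kept = []
    for cv in variants:
        if cv.coseg_class not in (CosegClass.CONSISTENT, CosegClass.AMBIGUOUS):
            continue
        if not cv.private_to_cases:
            continue
        if interval is not None and not interval.contains(cv.variant.chrom, cv.variant.pos):
            continue
        kept.append(cv)

    def sort_key(cv: ClassifiedVariant):
        in_focus = (focus_promoter is not None and cv.annotation is not None
                    and cv.annotation.promoter_of == focus_promoter)
        # within a region class, structural changes (indels, the candidates
        # for de-novo regulatory-element creation) outrank point substitutions
        is_snp = cv.variant.vclass is VariantClass.SNP
        return (0 if in_focus else 1, _region_rank(cv), 1 if is_snp else 0,
                cv.variant.chrom, cv.variant.pos, cv.variant.ref, cv.variant.alt)

    return sorted(kept, key=sort_key)
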