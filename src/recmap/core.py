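"""Shared domain types for the mapping / prioritization pipeline.

Coordinate convention: 1-based inclusive everywhere internally (the VCF
convention); the BED writer in :mod:`recmap.io` is the only place the
0-based half-open convention appears.

Genotypes are stored as small integer codes counting copies of the B
(alternate) allele: 0, 1, 2, with :data:`MISSING` (= -1) as a distinct
sentinel for no-calls.  The missing sentinel is never conflated with
hom-ref; the co-segregation ambiguity logic depends on the distinction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: genotype code for a missing call
MISSING: int = -1

_VALID_CODES = frozenset({0, 1, 2, MISSING})
_DNA = frozenset("ACGT")
_DNA_N = frozenset("ACGTN")


class VariantClass(str, enum.Enum):
    SNP = "SNP"
    INS = "INS"
    DEL = "DEL"


class Status(str, enum.Enum):
    AFFECTED = "AFFECTED"
    UNAFFECTED = "UNAFFECTED"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class Variant:
    """A biallelic variant, anchored-base convention for indels.

    ``ref`` and ``alt`` are non-empty uppercase A/C/G/T strings; an
    insertion is represented as ref="C", alt="C" + inserted bases, so the
    inserted length is ``len(alt) - len(ref)``.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _DNA:
                raise ValueError(f"{name} allele {allele!r} must be non-empty uppercase A/C/G/T")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if len(self.ref) == len(self.alt) and len(self.ref) != 1:
            raise ValueError(
                f"equal-length multi-base substitution {self.ref}>{self.alt} is not "
                "representable; decompose into SNPs"
            )

    @property
    def vclass(self) -> VariantClass:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return VariantClass.SNP
        return VariantClass.INS if len(self.alt) > len(self.ref) else VariantClass.DEL

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class Marker:
    """An array marker: id, location and its two alleles (codes count B)."""

    id: str
    chrom: str
    pos: int
    alleleA: str
    alleleB: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("marker pos must be >= 1")
        if self.alleleA == self.alleleB:
            raise ValueError("marker alleles must differ")


@dataclass
class GenotypeMatrix:
    """Samples x markers allele-count codes plus the marker map."""

    sample_ids: list[str]
    markers: list[Marker]
    calls: np.ndarray  # shape (n_samples, n_markers), int8 codes

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.calls, list(_VALID_CODES))
        if bad.any():
            raise ValueError(f"invalid genotype codes: {np.unique(self.calls[bad])}")
        last: dict[str, int] = {}
        for m in self.markers:
            if m.chrom in last and m.pos <= last[m.chrom]:
                raise ValueError(
                    f"marker positions must be strictly increasing within a "
                    f"chromosome (marker {m.id} at {m.chrom}:{m.pos})"
                )
            last[m.chrom] = m.pos

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def chrom_slice(self, chrom: str) -> tuple["GenotypeMatrix", np.ndarray]:
        """Sub-matrix restricted to one chromosome, plus original indices."""
        idx = np.array([i for i, m in enumerate(self.markers) if m.chrom == chrom], dtype=int)
        sub = GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            markers=[self.markers[i] for i in idx],
            calls=self.calls[:, idx],
        )
        return sub, idx


@dataclass
class PhenotypeTable:
    """Sample id -> affection status."""

    status: dict[str, Status]

    @classmethod
    def from_groups(cls, affected: Iterable[str], unaffected: Iterable[str]) -> "PhenotypeTable":
        d = {s: Status.AFFECTED for s in affected}
        d.update({s: Status.UNAFFECTED for s in unaffected})
        return cls(d)

    def affected_mask(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Boolean affected vector over ``sample_ids``; UNKNOWN samples are
        excluded from all tests and may not appear here."""
        out = np.zeros(len(sample_ids), dtype=bool)
        for i, s in enumerate(sample_ids):
            st = self.status.get(s)
            if st is None:
                raise KeyError(f"sample {s} has no phenotype entry")
            if st is Status.UNKNOWN:
                raise ValueError(f"sample {s} has UNKNOWN status; drop it before testing")
            out[i] = st is Status.AFFECTED
        return out

    def counts(self) -> tuple[int, int]:
        n_aff = sum(1 for s in self.status.values() if s is Status.AFFECTED)
        n_un = sum(1 for s in self.status.values() if s is Status.UNAFFECTED)
        return n_aff, n_un


@dataclass
class CandidateInterval:
    """Recombinant-bounded candidate region, 1-based inclusive ends."""

    chrom: str
    start: int
    end: int
    open_left: bool = False
    open_right: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"interval start must be < end ({self.start} .. {self.end})")

    @property
    def length_kb(self) -> int:
        """Length in whole kilobases, truncated."""
        return (self.end - self.start) // 1000

    @property
    def is_open(self) -> bool:
        return self.open_left or self.open_right

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over A/C/G/T/N."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("sequence must be non-empty")
        bad = set(self.seq) - _DNA_N
        if bad:
            raise ValueError(f"sequence {self.id} contains non-ACGTN symbols: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """A multi-promoter gene model.

    ``first_exons`` maps an isoform label to its isoform-specific first
    exon (1-based inclusive interval); each isoform's TSS is the 5' end of
    that exon on the gene's strand, and its promoter is the
    ``promoter_window`` bp immediately upstream of that TSS (strand-aware).
    Exons not listed as first exons are shared.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    first_exons: dict[str, tuple[int, int]] = field(default_factory=dict)
    promoter_window: int = 10_000

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise ValueError("exons must be non-overlapping")
        for s, e in ex:
            if s > e:
                raise ValueError("exon start must be <= end")
        self.exons = ex
        if not (self.span[0] <= self.cds_start <= self.cds_end <= self.span[1]):
            raise ValueError("CDS must lie within the gene span")
        for label, fe in self.first_exons.items():
            if tuple(fe) not in {tuple(x) for x in ex}:
                raise ValueError(f"first exon of isoform {label} is not an exon of the model")

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    def isoform_tss(self, label: str) -> int:
        s, e = self.first_exons[label]
        return s if self.strand == "+" else e

    def promoter_interval(self, label: str) -> tuple[int, int]:
        """Strand-aware promoter window for an isoform, 1-based inclusive."""
        tss = self.isoform_tss(label)
        if self.strand == "+":
            return (max(1, tss - self.promoter_window), tss - 1)
        return (tss + 1, tss + self.promoter_window)

    def shared_exons(self) -> list[tuple[int, int]]:
        firsts = {tuple(v) for v in self.first_exons.values()}
        return [e for e in self.exons if tuple(e) not in firsts]


@dataclass
class ExonCountTable:
    """Per-exon read counts with exon metadata and library sizes.

    ``exons`` is indexed by exon id with columns ``length`` (bp) and
    ``isoform`` (isoform label for isoform-specific first exons, the
    string ``"shared"`` otherwise); ``counts`` is exons x samples;
    ``library_sizes`` gives total mapped reads per sample (not the column
    sum over this gene alone).
    """

    exons: pd.DataFrame
    counts: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if not self.exons.index.equals(self.counts.index):
            raise ValueError("exon metadata and count table must share the exon index")
        missing = [s for s in self.counts.columns if s not in self.library_sizes.index]
        if missing:
            raise ValueError(f"samples without library size: {missing}")
        if (self.exons["length"] <= 0).any():
            raise ValueError("exon lengths must be > 0")
        if (self.library_sizes.loc[self.counts.columns] <= 0).any():
            raise ValueError("library sizes must be > 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset(self, samples: Sequence[str]) -> "ExonCountTable":
        return ExonCountTable(
            exons=self.exons.copy(),
            counts=self.counts[list(samples)].copy(),
            library_sizes=self.library_sizes.loc[list(samples)].copy(),
        )


@dataclass
class TruthRecord:
    """Planted truth of a simulation call, for recovery checks."""

    seed: int
    causal_marker_index: int | None = None
    causal_block: tuple[int, int] | None = None  # marker-index span, inclusive
    causal_variant: Variant | None = None
    private_keys: list[tuple] = field(default_factory=list)
    penetrance_hom: float | None = None
    penetrance_het: float | None = None
    genotype_class_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    planted_exon_fc: dict[str, float] = field(default_factory=dict)
    planted_motif_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for p in (self.penetrance_hom, self.penetrance_het):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError("penetrances must lie in [0, 1]")
        if any(fc <= 0 for fc in self.planted_exon_fc.values()):
            raise ValueError("planted fold changes must be > 0")


def complement(base: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}[base]


def reverse_complement(seq: str) -> str:
    return "".join(complement(b) for b in reversed(seq))
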