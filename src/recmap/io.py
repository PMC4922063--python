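"""Readers and writers for the standard formats the pipeline touches.

Supported formats: VCF v4.x (GT field; read through pysam, written as
plain text), PLINK-style PED/MAP text, a documented TSV genotype dialect
(header row = marker ids, one row per sample, codes 0/1/2/NA counted
against alleleB of the companion map), BED (the one place 0-based
half-open coordinates appear), FASTA (Biopython), and TSV tables for
phenotypes, litters and exon counts.

The map file used by both genotype dialects has six tab-separated
columns: chrom, marker_id, genetic_distance (ignored, kept for PLINK
compatibility), pos, alleleA, alleleB.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .core import (
    MISSING,
    CandidateInterval,
    ExonCountTable,
    GenotypeMatrix,
    Marker,
    PhenotypeTable,
    SequenceRecord,
    Status,
    Variant,
)


class VcfParseError(ValueError):
    """Raised for malformed VCF input; names the offending record."""


@dataclass
class GenotypedVariant:
    """A variant together with its per-sample genotype codes."""

    variant: Variant
    calls: np.ndarray  # int codes, one per sample

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str | os.PathLike) -> tuple[list[str], list[GenotypedVariant]]:
    """Read a VCF with GT calls into biallelic :class:`GenotypedVariant` rows.

    Multi-allelic records are split into one biallelic entry per alternate
    allele (codes count copies of that allele); missing GTs (./.) map to
    :data:`MISSING`.  Positions stay 1-based as in the file.
    """
    try:
        vf = pysam.VariantFile(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF header of {path}: {exc}") from exc
    samples = list(vf.header.samples)
    records: list[GenotypedVariant] = []
    try:
        for n, rec in enumerate(vf, start=1):
            if rec.alts is None:
                continue
            for ai, alt in enumerate(rec.alts, start=1):
                try:
                    var = Variant(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                                  id=rec.id)
                except ValueError as exc:
                    raise VcfParseError(
                        f"{path} record {n} ({rec.chrom}:{rec.pos}): {exc}") from exc
                codes = np.empty(len(samples), dtype=np.int8)
                for si, s in enumerate(samples):
                    gt = rec.samples[s].get("GT")
                    if gt is None or any(a is None for a in gt):
                        codes[si] = MISSING
                    else:
                        codes[si] = sum(1 for a in gt if a == ai)
                records.append(GenotypedVariant(var, codes))
    except (OSError, ValueError) as exc:
        if isinstance(exc, VcfParseError):
            raise
        raise VcfParseError(f"malformed VCF record in {path}: {exc}") from exc
    finally:
        vf.close()
    return samples, records


def write_vcf(path: str | os.PathLike, samples: Sequence[str],
              records: Iterable[GenotypedVariant]) -> None:
    """Write biallelic GT-only records as a VCF v4.2 text file."""
    records = list(records)
    contigs: list[str] = []
    for gv in records:
        if gv.variant.chrom not in contigs:
            contigs.append(gv.variant.chrom)
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for gv in records:
            v = gv.variant
            if len(gv.calls) != len(samples):
                raise ValueError(f"record {v.key} has {len(gv.calls)} calls "
                                 f"for {len(samples)} samples")
            gts = "\t".join(gt_of[int(c)] for c in gv.calls)
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}"
                     f"\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# genotype matrices

def _read_map(map_path: str | os.PathLike) -> list[Marker]:
    markers: list[Marker] = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(
                    f"{map_path}:{ln}: expected 6 columns "
                    "(chrom id dist pos alleleA alleleB), got "
                    f"{len(parts)}")
            chrom, mid, _dist, pos, a, b = parts
            markers.append(Marker(id=mid, chrom=chrom, pos=int(pos),
                                  alleleA=a.upper(), alleleB=b.upper()))
    return markers


def _write_map(markers: Sequence[Marker], map_path: str | os.PathLike) -> None:
    with open(map_path, "w") as fh:
        for m in markers:
            fh.write(f"{m.chrom}\t{m.id}\t0\t{m.pos}\t{m.alleleA}\t{m.alleleB}\n")


def read_genotype_matrix(path: str | os.PathLike, map_path: str | os.PathLike,
                         dialect: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix in the ``tsv`` or ``pedmap`` dialect.

    Codes always count copies of alleleB as declared in the map file.
    """
    markers = _read_map(map_path)
    if dialect == "tsv":
        return _read_tsv_genotypes(path, markers)
    if dialect == "pedmap":
        return _read_ped(path, markers)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_tsv_genotypes(path, markers: list[Marker]) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        if not header or header[0] != "sample_id":
            raise ValueError(f"{path}: first header column must be 'sample_id'")
        ids = header[1:]
        if ids != [m.id for m in markers]:
            raise ValueError(f"{path}: header marker ids do not match the map file")
        sample_ids: list[str] = []
        rows: list[list[int]] = []
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != len(ids) + 1:
                raise ValueError(f"{path}:{ln}: ragged row "
                                 f"({len(parts) - 1} calls for {len(ids)} markers)")
            sample_ids.append(parts[0])
            row = []
            for tok in parts[1:]:
                if tok in ("NA", "."):
                    row.append(MISSING)
                elif tok in ("0", "1", "2"):
                    row.append(int(tok))
                else:
                    raise ValueError(f"{path}:{ln}: invalid genotype code {tok!r}")
            rows.append(row)
    return GenotypeMatrix(sample_ids=sample_ids, markers=markers,
                          calls=np.array(rows, dtype=np.int8))


def _read_ped(path, markers: list[Marker]) -> GenotypeMatrix:
    sample_ids: list[str] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * len(markers):
                raise ValueError(
                    f"{path}:{ln}: expected {6 + 2 * len(markers)} fields "
                    f"(6 + 2 alleles x {len(markers)} markers), got {len(parts)}")
            sample_ids.append(parts[1])
            row = []
            for mi, m in enumerate(markers):
                a1, a2 = parts[6 + 2 * mi].upper(), parts[7 + 2 * mi].upper()
                if a1 == "0" or a2 == "0":
                    row.append(MISSING)
                    continue
                code = 0
                for a in (a1, a2):
                    if a == m.alleleB:
                        code += 1
                    elif a != m.alleleA:
                        raise ValueError(
                            f"{path}:{ln}: unknown allele {a!r} for marker {m.id} "
                            f"(expected {m.alleleA}/{m.alleleB})")
                row.append(code)
            rows.append(row)
    return GenotypeMatrix(sample_ids=sample_ids, markers=markers,
                          calls=np.array(rows, dtype=np.int8))


def write_genotype_matrix(gm: GenotypeMatrix, path: str | os.PathLike,
                          map_path: str | os.PathLike, dialect: str = "tsv") -> None:
    _write_map(gm.markers, map_path)
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write("sample_id\t" + "\t".join(m.id for m in gm.markers) + "\n")
            for si, sid in enumerate(gm.sample_ids):
                toks = ["NA" if c == MISSING else str(int(c)) for c in gm.calls[si]]
                fh.write(sid + "\t" + "\t".join(toks) + "\n")
    elif dialect == "pedmap":
        with open(path, "w") as fh:
            for si, sid in enumerate(gm.sample_ids):
                toks = [sid, sid, "0", "0", "0", "-9"]
                for mi, m in enumerate(gm.markers):
                    c = int(gm.calls[si, mi])
                    if c == MISSING:
                        toks += ["0", "0"]
                    else:
                        toks += [m.alleleA if k < 2 - c else m.alleleB
                                 for k in range(2)]
                fh.write(" ".join(toks) + "\n")
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


# ---------------------------------------------------------------------------
# BED

def write_bed(intervals: Iterable[CandidateInterval], path: str | os.PathLike) -> None:
    """Write intervals as BED: 0-based half-open, i.e. (start-1, end)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")


def read_bed(path: str | os.PathLike) -> list[CandidateInterval]:
    """Read a 3-column BED back into 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split()[:3]
            out.append(CandidateInterval(chrom=chrom, start=int(start) + 1, end=int(end)))
    return out


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    return [SequenceRecord(id=r.id, seq=str(r.seq).upper())
            for r in SeqIO.parse(os.fspath(path), "fasta")]


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    SeqIO.write(
        [BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records],
        os.fspath(path), "fasta")


# ---------------------------------------------------------------------------
# gene models (YAML)

def read_gene_model(path: str | os.PathLike):
    import yaml

    from .core import GeneModel

    with open(path) as fh:
        d = yaml.safe_load(fh)
    return GeneModel(
        gene_id=d["gene_id"], chrom=str(d["chrom"]), strand=d["strand"],
        exons=[tuple(e) for e in d["exons"]],
        cds_start=int(d["cds_start"]), cds_end=int(d["cds_end"]),
        first_exons={k: tuple(v) for k, v in d.get("first_exons", {}).items()},
        promoter_window=int(d.get("promoter_window", 10_000)))


def write_gene_model(model, path: str | os.PathLike) -> None:
    import yaml

    d = dict(gene_id=model.gene_id, chrom=model.chrom, strand=model.strand,
             exons=[list(e) for e in model.exons],
             cds_start=model.cds_start, cds_end=model.cds_end,
             first_exons={k: list(v) for k, v in model.first_exons.items()},
             promoter_window=model.promoter_window)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# phenotype / litter / count tables

_STATUS_ALIASES = {
    "affected": Status.AFFECTED, "case": Status.AFFECTED, "2": Status.AFFECTED,
    "unaffected": Status.UNAFFECTED, "control": Status.UNAFFECTED, "1": Status.UNAFFECTED,
    "unknown": Status.UNKNOWN, "0": Status.UNKNOWN, "-9": Status.UNKNOWN,
}


def read_phenotypes(path: str | os.PathLike) -> PhenotypeTable:
    """TSV with columns sample_id, status (affected/unaffected/unknown)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "status"]:
        raise ValueError(f"{path}: expected columns sample_id, status")
    status = {}
    for _, row in df.iterrows():
        key = str(row["status"]).strip().lower()
        if key not in _STATUS_ALIASES:
            raise ValueError(f"{path}: unknown status {row['status']!r}")
        status[str(row["sample_id"])] = _STATUS_ALIASES[key]
    return PhenotypeTable(status)


def write_phenotypes(phen: PhenotypeTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tstatus\n")
        for sid, st in phen.status.items():
            fh.write(f"{sid}\t{st.value.lower()}\n")


def read_litters(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    """TSV with columns litter_id, affected, unaffected."""
    df = pd.read_csv(path, sep="\t")
    for col in ("litter_id", "affected", "unaffected"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return [(str(r.litter_id), int(r.affected), int(r.unaffected))
            for r in df.itertuples()]


def write_litters(litters: Sequence[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("litter_id\taffected\tunaffected\n")
        for lid, aff, un in litters:
            fh.write(f"{lid}\t{aff}\t{un}\n")


def read_exon_counts(path: str | os.PathLike,
                     libsize_path: str | os.PathLike | None = None) -> ExonCountTable:
    """Counts TSV with columns exon_id, isoform, length, then one column per
    sample; library sizes from a two-column TSV (sample_id, library_size) or,
    failing that, the per-sample column sums."""
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["exon_id", "isoform", "length"]
    for col in meta_cols:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    df = df.set_index("exon_id")
    counts = df.drop(columns=["isoform", "length"]).astype(float)
    exons = df[["length", "isoform"]].copy()
    if libsize_path is not None:
        ls = pd.read_csv(libsize_path, sep="\t").set_index("sample_id")["library_size"]
        ls = ls.astype(float)
        ls.index = ls.index.astype(str)
    else:
        ls = counts.sum(axis=0)
    return ExonCountTable(exons=exons, counts=counts, library_sizes=ls)


def write_exon_counts(table: ExonCountTable, path: str | os.PathLike,
                      libsize_path: str | os.PathLike | None = None) -> None:
    out = table.exons[["isoform", "length"]].join(table.counts)
    out.index.name = "exon_id"
    out.to_csv(path, sep="\t")
    if libsize_path is not None:
        ls = table.library_sizes.rename("library_size")
        ls.index.name = "sample_id"
        ls.to_csv(libsize_path, sep="\t")
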