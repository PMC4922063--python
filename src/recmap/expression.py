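"""Exon-level expression normalization and fold-change analysis.

Gene-level RPKM averages over all transcripts of a locus and cannot see
the loss of one isoform when sibling isoforms stay expressed; comparing
the normalized read count of each exon separately can, because an
isoform-specific first exon reports only its own promoter's activity.
Values are exon-level RPKM: count / (library_size / 1e6) / (length / 1e3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ExonCountTable


def normalize_exon(table: ExonCountTable) -> pd.DataFrame:
    """Per-exon, per-sample RPKM (exons x samples)."""
    lib = table.library_sizes.loc[table.counts.columns].astype(float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be > 0")
    length_kb = table.exons["length"].astype(float) / 1e3
    per_million = table.counts.div(lib / 1e6, axis=1)
    return per_million.div(length_kb, axis=0)


@dataclass
class ExonFoldChange:
    exon_id: str
    values_a: np.ndarray  # normalized values, reference group
    values_b: np.ndarray  # comparison group
    mean_a: float
    mean_b: float
    fold_change: float  # (mean_a + pc) / (mean_b + pc); > 1 = decrease in B
    direction: str  # "decrease_in_B" | "increase_in_B" | "none"


def exon_fold_change(table_a: ExonCountTable, table_b: ExonCountTable,
                     pseudocount: float = 0.5) -> list[ExonFoldChange]:
    """Per-exon fold change of group A over group B on the RPKM scale.

    The pseudocount is 0.5 reads converted to the per-million scale with
    the median library size of both groups, keeping the ratio finite for
    silenced exons without distorting well-expressed ones.
    """
    if list(table_a.exons.index) != list(table_b.exons.index):
        raise ValueError("both groups must share the same exon set")
    norm_a = normalize_exon(table_a)
    norm_b = normalize_exon(table_b)
    med_lib = float(np.median(np.concatenate([
        table_a.library_sizes.loc[table_a.counts.columns].to_numpy(float),
        table_b.library_sizes.loc[table_b.counts.columns].to_numpy(float)])))
    pc = pseudocount / (med_lib / 1e6)

    out = []
    for exon in table_a.exons.index:
        va = norm_a.loc[exon].to_numpy(float)
        vb = norm_b.loc[exon].to_numpy(float)
        ma, mb = float(va.mean()), float(vb.mean())
        fc = (ma + pc) / (mb + pc)
        if mb < ma:
            direction = "decrease_in_B"
        elif mb > ma:
            direction = "increase_in_B"
        else:
            direction = "none"
        out.append(ExonFoldChange(exon_id=str(exon), values_a=va, values_b=vb,
                                  mean_a=ma, mean_b=mb, fold_change=float(fc),
                                  direction=direction))
    return out


def call_isoform_specific_loss(exon_isoform: Mapping[str, str],
                               fold_changes: Sequence[ExonFoldChange],
                               threshold: float = 2.0) -> list[str]:
    """Isoforms whose specific first exon lost expression while shared
    exons did not.

    ``exon_isoform`` maps exon id to an isoform label or ``"shared"``.
    An isoform is flagged iff its specific first exon has fold change >=
    ``threshold`` (a decrease in group B) while no shared exon does —
    a uniform gene-level shift flags nothing.
    """
    by_exon = {fc.exon_id: fc for fc in fold_changes}
    shared_hit = any(by_exon[e].fold_change >= threshold
                     for e, iso in exon_isoform.items()
                     if iso == "shared" and e in by_exon)
    if shared_hit:
        return []
    flagged = []
    for exon, iso in exon_isoform.items():
        if iso == "shared" or exon not in by_exon:
            continue
        if by_exon[exon].fold_change >= threshold:
            flagged.append(iso)
    return sorted(set(flagged))


def de_genes(values_a: pd.DataFrame, values_b: pd.DataFrame,
             fold_threshold: float = 2.0, pseudocount: float = 0.5
             ) -> list[str]:
    """Genes with at least ``fold_threshold``-fold difference of group
    means (either direction, boundary inclusive) on already-normalized
    gene-level values (genes x samples)."""
    if list(values_a.index) != list(values_b.index):
        raise ValueError("both groups must share the same gene set")
    ma = values_a.mean(axis=1).to_numpy(float) + pseudocount
    mb = values_b.mean(axis=1).to_numpy(float) + pseudocount
    ratio = np.maximum(ma / mb, mb / ma)
    return [str(g) for g, r in zip(values_a.index, ratio) if r >= fold_threshold]
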