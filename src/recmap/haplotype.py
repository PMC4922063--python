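"""Haplotype-concordance scanning and recombinant-bounded interval
definition for a semi-recessive trait.

No statistical phasing is done: haplotypes are read only from
window-homozygotes (samples homozygous at every marker of a window, with
no missing call), for whom the haplotype is the genotype.  A window is
concordant when all affected window-homozygotes share a single (risk)
haplotype, no unaffected sample is homozygous for it, and at least one
unaffected homozygote of a different (protective) haplotype exists.
Heterozygous and unclassifiable samples contribute only to penetrance
counts.  The candidate interval is bounded by the nearest flanking
markers at which an affected risk-homozygote breaks homozygosity
(informative recombinants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .core import MISSING, CandidateInterval, GenotypeMatrix, PhenotypeTable


@dataclass
class ConcordantBlock:
    """A maximal marker window whose homozygote classes separate phenotype."""

    chrom: str
    start_index: int  # global marker index into the scanned GenotypeMatrix
    end_index: int    # inclusive
    marker_ids: list[str]
    risk_haplotype: str
    protective_haplotype: str
    risk_codes: tuple[int, ...]  # genotype codes (0/2) of a risk homozygote
    prot_codes: tuple[int, ...]
    n_risk_hom: int
    n_prot_hom: int
    n_het: int
    het_affected: int
    fisher_p: float | None = None
    p_chr: float | None = None

    def __post_init__(self) -> None:
        if self.het_affected > self.n_het:
            raise ValueError("het_affected cannot exceed n_het")

    @property
    def score(self) -> int:
        """Concordance score: number of correctly separated homozygotes."""
        return self.n_risk_hom + self.n_prot_hom


def _window_classids(calls: np.ndarray, i: int, j: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Class id per sample for window [i, j): -1 for samples that are not
    window-homozygotes (het or missing anywhere in the window); otherwise
    the bit-packed haplotype."""
    sub = calls[:, i:j]
    hom = ((sub == 0) | (sub == 2)).all(axis=1)  # excludes hets and MISSING
    ids = np.full(calls.shape[0], -1, dtype=np.int64)
    if hom.any():
        bits = (sub[hom] == 2).astype(np.int64)
        ids[hom] = bits @ (1 << np.arange(j - i, dtype=np.int64))
    return ids, hom


def _eval_window(ids: np.ndarray, affected: np.ndarray
                 ) -> tuple[bool, int, int, int, int]:
    """Concordance of one window.

    Returns (concordant, risk_class_id, prot_class_id, n_risk, n_prot);
    the protective class is the largest homozygote class among unaffected
    samples when concordance holds.
    """
    hom = ids >= 0
    aff_ids = ids[hom & affected]
    if aff_ids.size == 0:
        return False, -1, -1, 0, 0
    risk = int(aff_ids[0])
    if (aff_ids != risk).any():
        return False, -1, -1, 0, 0
    un_ids = ids[hom & ~affected]
    if (un_ids == risk).any():
        return False, -1, -1, 0, 0
    if un_ids.size == 0:
        return False, -1, -1, 0, 0
    classes, counts = np.unique(un_ids, return_counts=True)
    k = int(counts.argmax())
    return True, risk, int(classes[k]), int(aff_ids.size), int(counts[k])


def _hap_string(class_id: int, width: int, markers) -> str:
    return "".join(
        (m.alleleB if (class_id >> k) & 1 else m.alleleA)
        for k, m in enumerate(markers[:width]))


def _codes(class_id: int, width: int) -> tuple[int, ...]:
    return tuple(2 if (class_id >> k) & 1 else 0 for k in range(width))


def concordant_windows(gm: GenotypeMatrix, phen: PhenotypeTable,
                       min_window: int = 2, max_window: int = 10,
                       ) -> list[tuple[int, int]]:
    """All concordant marker windows, as (first, last) inclusive global
    marker indices; windows never span a chromosome boundary."""
    affected = phen.affected_mask(gm.sample_ids)
    out: list[tuple[int, int]] = []
    for chrom in dict.fromkeys(m.chrom for m in gm.markers):
        idx = [i for i, m in enumerate(gm.markers) if m.chrom == chrom]
        lo, hi = idx[0], idx[-1]
        for w in range(min_window, max_window + 1):
            for i in range(lo, hi - w + 2):
                ids, _ = _window_classids(gm.calls, i, i + w)
                ok, *_rest = _eval_window(ids, affected)
                if ok:
                    out.append((i, i + w - 1))
    out.sort()
    return out


def find_concordant_blocks(gm: GenotypeMatrix, phen: PhenotypeTable,
                           min_window: int = 2, max_window: int = 10,
                           ) -> list[ConcordantBlock]:
    """Scan all windows of ``min_window``..``max_window`` markers per
    chromosome and return maximal concordant blocks, best score first.

    Overlapping concordant windows are merged; the merged span is reported
    when it is itself concordant and separates at least as many
    homozygotes, otherwise the best-separating constituent window.
    An empty list means no concordant window exists (not an error).
    """
    affected = phen.affected_mask(gm.sample_ids)
    blocks: list[ConcordantBlock] = []
    chroms = list(dict.fromkeys(m.chrom for m in gm.markers))
    for chrom in chroms:
        idx = [i for i, m in enumerate(gm.markers) if m.chrom == chrom]
        lo, hi = idx[0], idx[-1]
        hits: list[tuple[int, int, int]] = []  # (i, j_exclusive, score)
        for w in range(min_window, max_window + 1):
            for i in range(lo, hi - w + 2):
                ids, _ = _window_classids(gm.calls, i, i + w)
                ok, risk, prot, nr, npn = _eval_window(ids, affected)
                if ok:
                    hits.append((i, i + w, nr + npn))
        if not hits:
            continue
        hits.sort()
        merged: list[list[tuple[int, int, int]]] = [[hits[0]]]
        right = hits[0][1]
        for h in hits[1:]:
            if h[0] < right:
                merged[-1].append(h)
                right = max(right, h[1])
            else:
                merged.append([h])
                right = h[1]
        for group in merged:
            i0 = min(h[0] for h in group)
            j0 = max(h[1] for h in group)
            cand = {(h[0], h[1]) for h in group} | {(i0, j0)}
            # among the union and every concordant window, keep the span
            # separating the most homozygotes (ties: the widest span)
            chosen = None
            best_key = None
            for (i, j) in sorted(cand):
                ids, _ = _window_classids(gm.calls, i, j)
                ok, risk, prot, nr, npn = _eval_window(ids, affected)
                if not ok:
                    continue
                key = (nr + npn, j - i)
                if best_key is None or key > best_key:
                    best_key = key
                    chosen = (i, j, ids, risk, prot, nr, npn)
            if chosen is None:
                continue
            i, j, ids, risk, prot, nr, npn = chosen
            w = j - i
            n_het = gm.n_samples - nr - npn
            het_aff = int(affected.sum()) - nr  # risk homozygotes are all affected
            blocks.append(ConcordantBlock(
                chrom=chrom, start_index=i, end_index=j - 1,
                marker_ids=[gm.markers[k].id for k in range(i, j)],
                risk_haplotype=_hap_string(risk, w, gm.markers[i:j]),
                protective_haplotype=_hap_string(prot, w, gm.markers[i:j]),
                risk_codes=_codes(risk, w), prot_codes=_codes(prot, w),
                n_risk_hom=nr, n_prot_hom=npn, n_het=n_het, het_affected=het_aff))
    blocks.sort(key=lambda b: (-b.score, b.chrom, b.start_index))
    return blocks


def block_membership(block: ConcordantBlock, gm: GenotypeMatrix
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(risk-homozygote mask, protective-homozygote mask) over samples."""
    i, j = block.start_index, block.end_index + 1
    sub = gm.calls[:, i:j]
    risk = (sub == np.array(block.risk_codes)).all(axis=1)
    prot = (sub == np.array(block.prot_codes)).all(axis=1)
    return risk, prot


# ---------------------------------------------------------------------------
# block-level significance

def fisher_exact_rx2(table: list[tuple[int, int]]) -> float:
    """Two-sided Fisher exact p for an R x 2 table by exhaustive enumeration
    of all tables with the observed margins (multivariate hypergeometric
    null), summing probabilities <= that of the observed table."""
    rows = np.array(table, dtype=np.int64)
    if rows.min() < 0 or rows.sum() == 0:
        raise ValueError("degenerate table")
    r = rows.sum(axis=1)
    c_aff = int(rows[:, 0].sum())
    n = int(r.sum())

    logc = lambda nn, kk: (gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1))
    denom = logc(n, c_aff)

    def table_logp(a: np.ndarray) -> float:
        return float(sum(logc(r[i], a[i]) for i in range(len(r))) - denom)

    obs_logp = table_logp(rows[:, 0])
    total = 0.0
    # enumerate the first R-1 affected-column cells; the last is determined
    def rec(i: int, remaining: int, acc: list[int], acc_logp: float) -> None:
        nonlocal total
        if i == len(r) - 1:
            if 0 <= remaining <= r[i]:
                lp = acc_logp + float(logc(r[i], remaining)) - float(denom)
                if lp <= obs_logp + 1e-9:
                    total += np.exp(lp)
            return
        for a in range(0, min(int(r[i]), remaining) + 1):
            rec(i + 1, remaining - a, acc + [a], acc_logp + float(logc(r[i], a)))

    rec(0, c_aff, [], 0.0)
    return min(1.0, total)


def _window_class_data(calls: np.ndarray, windows: list[tuple[int, int]]
                       ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per window: one-hot homozygote-class membership H (samples x classes)
    and class sizes; windows with < 2 classes are dropped (cannot be
    concordant)."""
    out = []
    for (i, j) in windows:
        ids, hom = _window_classids(calls, i, j)
        if not hom.any():
            continue
        classes = np.unique(ids[hom])
        if classes.size < 2:
            continue
        h = (ids[:, None] == classes[None, :]).astype(np.float64)
        out.append((h, h.sum(axis=0)))
    return out


def _perm_scores(class_data, perms: np.ndarray) -> np.ndarray:
    """Max concordance score per permutation (rows of ``perms`` are
    affected indicator vectors)."""
    n_perm = perms.shape[0]
    best = np.zeros(n_perm)
    for h, sizes in class_data:
        ac = perms @ h                      # affected count per class
        t = ac.sum(axis=1)
        cond = (ac == sizes[None, :]) & (ac == t[:, None]) & (t[:, None] > 0)
        has = cond.any(axis=1)
        if not has.any():
            continue
        c = cond.argmax(axis=1)
        unaff = sizes[None, :] - ac
        unaff[np.arange(n_perm), c] = 0
        prot = unaff.max(axis=1)
        score = np.where(has & (prot >= 1), sizes[c] + prot, 0.0)
        best = np.maximum(best, score)
    return best


def block_assoc(block: ConcordantBlock, gm: GenotypeMatrix, phen: PhenotypeTable,
                n_perm: int = 25_000, seed: int = 0,
                min_window: int = 2, max_window: int = 10,
                chunk: int = 2_000) -> ConcordantBlock:
    """Attach significance to a concordant block.

    ``fisher_p``: two-sided Fisher exact on the 3 x 2 table
    (risk-hom / het / prot-hom x affected / unaffected), by enumeration.
    ``p_chr``: add-one empirical probability that a phenotype permutation
    produces an equally-or-more concordant window (by score) anywhere on
    the block's chromosome.
    """
    affected = phen.affected_mask(gm.sample_ids)
    table = [
        (block.n_risk_hom, 0),
        (block.het_affected, block.n_het - block.het_affected),
        (0, block.n_prot_hom),
    ]
    block.fisher_p = fisher_exact_rx2(table)

    idx = [i for i, m in enumerate(gm.markers) if m.chrom == block.chrom]
    lo, hi = idx[0], idx[-1]
    windows = [(i, i + w)
               for w in range(min_window, max_window + 1)
               for i in range(lo, hi - w + 2)]
    class_data = _window_class_data(gm.calls, windows)
    rng = np.random.default_rng(seed)
    n = len(affected)
    n_cases = int(affected.sum())
    b = 0
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        order = np.argsort(rng.random((k, n)), axis=1)
        perms = np.zeros((k, n))
        np.put_along_axis(perms, order[:, :n_cases], 1.0, axis=1)
        b += int((_perm_scores(class_data, perms) >= block.score).sum())
        done += k
    block.p_chr = (b + 1) / (n_perm + 1)
    return block


def chromosome_null_pvalue(gm: GenotypeMatrix, phen: PhenotypeTable,
                           n_perm: int = 1_000, seed: int = 0,
                           min_window: int = 2, max_window: int = 10) -> float:
    """Add-one permutation p of the best observed concordance score on the
    (single-chromosome) matrix; used for null calibration.  A dataset with
    no concordant window has observed score 0 and p = 1."""
    affected = phen.affected_mask(gm.sample_ids)
    idx = list(range(gm.n_markers))
    windows = [(i, i + w)
               for w in range(min_window, max_window + 1)
               for i in range(idx[0], idx[-1] - w + 2)]
    class_data = _window_class_data(gm.calls, windows)
    obs = float(_perm_scores(class_data, affected[None, :].astype(float))[0])
    if obs == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    n = len(affected)
    n_cases = int(affected.sum())
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perms = np.zeros((n_perm, n))
    np.put_along_axis(perms, order[:, :n_cases], 1.0, axis=1)
    b = int((_perm_scores(class_data, perms) >= obs).sum())
    return (b + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# interval definition

def define_interval(block: ConcordantBlock, gm: GenotypeMatrix,
                    phen: PhenotypeTable) -> CandidateInterval:
    """Recombinant-bounded candidate interval around a concordant block.

    Walks outward from the block over the block's chromosome: each
    boundary is the position of the nearest flanking marker at which any
    affected risk-homozygote fails to be homozygous for a single shared
    allele (an informative recombinant).  If no recombinant occurs before
    the chromosome end, the boundary is the terminal marker and the
    interval is flagged open on that side.
    """
    affected = phen.affected_mask(gm.sample_ids)
    risk, _ = block_membership(block, gm)
    walkers = np.flatnonzero(risk & affected)
    if walkers.size == 0:
        raise ValueError("block has no affected risk-homozygote")
    chrom_idx = [i for i, m in enumerate(gm.markers) if m.chrom == block.chrom]
    lo, hi = chrom_idx[0], chrom_idx[-1]

    def consistent(k: int) -> bool:
        c = gm.calls[walkers, k]
        c = c[c != MISSING]
        if c.size == 0:
            return True
        return bool(((c == 0).all() or (c == 2).all()))

    left, open_left = gm.markers[lo].pos, True
    for k in range(block.start_index - 1, lo - 1, -1):
        if not consistent(k):
            left, open_left = gm.markers[k].pos, False
            break
    right, open_right = gm.markers[hi].pos, True
    for k in range(block.end_index + 1, hi + 1):
        if not consistent(k):
            right, open_right = gm.markers[k].pos, False
            break
    return CandidateInterval(chrom=block.chrom, start=left, end=right,
                             open_left=open_left, open_right=open_right)
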