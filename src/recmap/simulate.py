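"""Synthetic cohorts, litters, variant calls, exon counts and promoter
pairs with the statistical structure the analysis assumes.

The generators emulate a semi-recessive mapping study: an autosomal
locus with fully penetrant homozygotes and low-penetrance (~4/51)
heterozygotes segregating in a case/control cohort of 28 affected and 73
normal animals; linkage disequilibrium induced by a small founder
haplotype pool organised in blocks (no explicit recombination map);
re-sequencing calls for a handful of cases and controls plus a large
wild-type panel; negative-binomial exon counts for a multi-promoter gene
with one isoform-specific first exon carrying a planted fold change; and
a promoter allele pair differing by two insertions and a double SNP, the
larger insertion carrying a SOX-consensus payload.

Every generator is deterministic given its arguments and seed and
records the planted truth in a :class:`~recmap.core.TruthRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    CandidateInterval,
    ExonCountTable,
    GenotypeMatrix,
    Marker,
    PhenotypeTable,
    SequenceRecord,
    TruthRecord,
    Variant,
)
from .motifs import Edit, EditType, MotifModel, PromoterPair, SOX_CONSENSUS, apply_edits, scan

#: heterozygote penetrance default: the observed 4 affected of 51 carriers
DEFAULT_HET_PENETRANCE = 4 / 51

_BASES = np.array(list("ACGT"))


class SimulationError(RuntimeError):
    """Raised when a requested cohort cannot be sampled (e.g. affected
    quota with zero penetrance)."""


# ---------------------------------------------------------------------------
# cohort

def sim_cohort(n_cases: int = 28, n_controls: int = 73, n_markers: int = 2_000,
               causal_index: int | None = None, founder_haplotypes: int = 8,
               penetrance_hom: float = 1.0,
               penetrance_het: float = DEFAULT_HET_PENETRANCE,
               missing_rate: float = 0.02, seed: int = 0,
               block_len: int = 20, haps_per_block: int = 4,
               risk_founders: int = 4, chrom: str = "13",
               start_pos: int = 55_000_000, marker_spacing: int = 1_000,
               max_attempts_factor: int = 5_000,
               ) -> tuple[GenotypeMatrix, PhenotypeTable, TruthRecord]:
    """Simulate a case/control cohort segregating a semi-recessive locus.

    Markers are organised in founder blocks of ``block_len`` markers;
    within a block each of the ``founder_haplotypes`` founders carries one
    of ``haps_per_block`` block haplotypes, and an individual draws one
    founder per block per chromosome copy (block-level LD, free
    recombination between blocks).  In the causal block, ``risk_founders``
    founders share one identical-by-descent risk haplotype that carries
    the alternate allele at the causal marker; with 4 of 8 founders the
    risk-haplotype frequency is 0.5, which reproduces the cohort
    composition the analysis expects (about 24 risk-homozygote cases, 4
    affected carriers among ~51, and ~26 protective homozygotes among the
    controls).  Phenotypes are drawn per causal genotype at the stated
    penetrances and individuals are rejection-sampled until the
    case/control quotas fill.  ``causal_index=None`` with
    ``penetrance_hom=penetrance_het`` is not needed for a null model: pass
    ``causal_index=-1`` to label phenotypes independently of genotype.
    """
    if not (0 <= missing_rate <= 1):
        raise ValueError("missing_rate must lie in [0, 1]")
    if founder_haplotypes < 2:
        raise ValueError("need at least two founder haplotypes")
    rng = np.random.default_rng(seed)
    n_blocks = (n_markers + block_len - 1) // block_len
    blocks = [(b * block_len, min((b + 1) * block_len, n_markers))
              for b in range(n_blocks)]
    if causal_index is None:
        causal_index = n_markers // 2
    null_model = causal_index < 0
    causal_block_i = 0 if null_model else next(
        bi for bi, (s, e) in enumerate(blocks) if s <= causal_index < e)

    # founder block haplotypes: per block a (haps_per_block x width) 0/1 table
    block_haps: list[np.ndarray] = []
    founder_hap: np.ndarray = np.empty((n_blocks, founder_haplotypes), dtype=np.int64)
    for bi, (s, e) in enumerate(blocks):
        w = e - s
        haps = rng.integers(0, 2, size=(haps_per_block, w))
        while len({h.tobytes() for h in haps}) < haps_per_block:
            haps = rng.integers(0, 2, size=(haps_per_block, w))
        if bi == causal_block_i and not null_model:
            # two complementary block haplotypes: an identical-by-descent
            # risk haplotype carrying the alternate causal allele, and one
            # common protective haplotype (the GGGGA-vs-AAAAG structure)
            haps[0, causal_index - s] = 1
            haps[1] = 1 - haps[0]
            founder_hap[bi, :risk_founders] = 0
            founder_hap[bi, risk_founders:] = 1
        else:
            founder_hap[bi] = rng.integers(0, haps_per_block, size=founder_haplotypes)
        block_haps.append(haps)

    def draw_individual() -> np.ndarray:
        g = np.empty(n_markers, dtype=np.int8)
        for bi, (s, e) in enumerate(blocks):
            f1, f2 = rng.integers(0, founder_haplotypes, size=2)
            h = block_haps[bi]
            g[s:e] = h[founder_hap[bi, f1]] + h[founder_hap[bi, f2]]
        return g

    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    quota = n_cases + n_controls
    max_attempts = max_attempts_factor * max(1, quota)
    attempts = 0
    while (len(cases) < n_cases or len(controls) < n_controls):
        if attempts >= max_attempts:
            raise SimulationError(
                f"could not fill the cohort quota in {max_attempts} attempts "
                f"(penetrances {penetrance_hom}/{penetrance_het})")
        attempts += 1
        g = draw_individual()
        if null_model:
            affected = False  # assigned independently below
            if len(cases) < n_cases:
                cases.append(g)
            elif len(controls) < n_controls:
                controls.append(g)
            continue
        gc = g[causal_index]
        p_aff = penetrance_hom if gc == 2 else penetrance_het if gc == 1 else 0.0
        affected = rng.random() < p_aff
        if affected and len(cases) < n_cases:
            cases.append(g)
        elif not affected and len(controls) < n_controls:
            controls.append(g)

    calls = np.vstack(cases + controls).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = MISSING
    sample_ids = [f"case{i + 1}" for i in range(n_cases)] + \
                 [f"ctrl{i + 1}" for i in range(n_controls)]
    phen = PhenotypeTable.from_groups(affected=sample_ids[:n_cases],
                                      unaffected=sample_ids[n_cases:])
    letters = rng.choice(4, size=(n_markers, 2))
    while (letters[:, 0] == letters[:, 1]).any():
        same = letters[:, 0] == letters[:, 1]
        letters[same, 1] = rng.choice(4, size=int(same.sum()))
    markers = [Marker(id=f"M{i:05d}", chrom=chrom,
                      pos=start_pos + i * marker_spacing,
                      alleleA=str(_BASES[letters[i, 0]]),
                      alleleB=str(_BASES[letters[i, 1]]))
               for i in range(n_markers)]
    gm = GenotypeMatrix(sample_ids=sample_ids, markers=markers, calls=calls)
    truth = TruthRecord(seed=seed,
                        causal_marker_index=None if null_model else causal_index,
                        causal_block=None if null_model else
                        (blocks[causal_block_i][0], blocks[causal_block_i][1] - 1),
                        penetrance_hom=penetrance_hom, penetrance_het=penetrance_het)
    return gm, phen, truth


# ---------------------------------------------------------------------------
# litters

def default_litter_sizes(n_litters: int = 11, total: int = 74) -> list[int]:
    base = total // n_litters
    sizes = [base] * n_litters
    for i in range(total - base * n_litters):
        sizes[i] += 1
    return sizes


def sim_litters(n_litters: int = 11, litter_sizes: list[int] | None = None,
                penetrance_hom: float = 1.0,
                penetrance_het: float = 0.0,
                seed: int = 0) -> tuple[list[tuple[int, int]], TruthRecord]:
    """Offspring of heterozygote x heterozygote matings, per litter.

    Genotypes are Mendelian 1:2:1; affection is Bernoulli per genotype
    class at the stated penetrances (hom-ref offspring are never
    affected).  Returns per-litter (affected, unaffected) counts; the
    truth record carries the per-genotype-class (affected, total) counts.
    """
    if litter_sizes is None:
        litter_sizes = default_litter_sizes(n_litters)
    if len(litter_sizes) != n_litters or any(s <= 0 for s in litter_sizes):
        raise ValueError("need one positive size per litter")
    rng = np.random.default_rng(seed)
    out: list[tuple[int, int]] = []
    class_counts = {"hom_risk": [0, 0], "het": [0, 0], "hom_ref": [0, 0]}
    pen = {"hom_risk": penetrance_hom, "het": penetrance_het, "hom_ref": 0.0}
    for size in litter_sizes:
        genos = rng.choice(["hom_ref", "het", "hom_risk"], size=size,
                           p=[0.25, 0.5, 0.25])
        aff = 0
        for g in genos:
            is_aff = rng.random() < pen[g]
            class_counts[g][1] += 1
            if is_aff:
                class_counts[g][0] += 1
                aff += 1
        out.append((aff, size - aff))
    truth = TruthRecord(seed=seed, penetrance_hom=penetrance_hom,
                        penetrance_het=penetrance_het,
                        genotype_class_counts={k: tuple(v) for k, v in
                                               class_counts.items()})
    return out, truth


# ---------------------------------------------------------------------------
# re-sequencing variant calls

@dataclass
class VariantCallSet:
    """Grouped genotype calls from the re-sequencing design: a few cases
    and controls plus a large wild-type panel."""

    variants: list[Variant]
    case_calls: np.ndarray     # (n_variants, n_cases)
    control_calls: np.ndarray  # (n_variants, n_controls)
    panel_calls: np.ndarray    # (n_variants, panel_size)


def sim_variant_calls(interval: CandidateInterval, n_private_linked: int = 15,
                      n_shared_common: int = 50, n_cases: int = 3,
                      n_controls: int = 3, panel_size: int = 103,
                      missing_rate: float = 0.02, seed: int = 0,
                      causal_pos: int | None = None,
                      ) -> tuple[VariantCallSet, TruthRecord]:
    """Variant calls inside a candidate interval.

    Private-linked variants sit on the case haplotype: homozygous
    alternate in every case, reference (or carrier) in controls, absent
    from every panel individual.  One designated private variant is the
    causal insertion (14 bp).  Shared-common variants co-segregate in the
    small case/control panel too, but at least one wild-type panel
    individual carries the alternate allele, so panel exclusion removes
    them.  Missingness applies to case/control calls only.
    """
    rng = np.random.default_rng(seed)
    n_var = n_private_linked + n_shared_common
    lo, hi = interval.start, interval.end
    if hi - lo + 1 < n_var:
        raise ValueError("interval too small for the requested variant count")
    pos = rng.choice(np.arange(lo, hi + 1), size=n_var, replace=False)
    private_pos = set(pos[:n_private_linked].tolist())
    if causal_pos is None:
        causal_pos = int(sorted(private_pos)[len(private_pos) // 2]) if private_pos else None
    elif causal_pos not in private_pos:
        # force the designated causal position into the private set
        old = int(sorted(private_pos)[0])
        private_pos.discard(old)
        private_pos.add(int(causal_pos))
        pos = np.array(sorted(set(pos.tolist()) - {old} | {int(causal_pos)}))
    pos = np.sort(pos)

    variants: list[Variant] = []
    case_calls = np.zeros((len(pos), n_cases), dtype=np.int8)
    control_calls = np.zeros((len(pos), n_controls), dtype=np.int8)
    panel_calls = np.zeros((len(pos), panel_size), dtype=np.int8)
    private_keys: list[tuple] = []
    causal_variant: Variant | None = None
    for i, p in enumerate(pos.tolist()):
        ref = str(_BASES[rng.integers(0, 4)])
        if n_private_linked and p == causal_pos:
            payload = "".join(_BASES[rng.integers(0, 4, size=14)])  # 14-bp INS
            var = Variant(chrom=interval.chrom, pos=int(p), ref=ref,
                          alt=ref + payload, id=f"v{i:04d}")
            causal_variant = var
        else:
            alt = str(_BASES[rng.integers(0, 4)])
            while alt == ref:
                alt = str(_BASES[rng.integers(0, 4)])
            var = Variant(chrom=interval.chrom, pos=int(p), ref=ref, alt=alt,
                          id=f"v{i:04d}")
        variants.append(var)
        if p in private_pos:
            case_calls[i] = 2
            control_calls[i] = rng.integers(0, 2, size=n_controls)  # ref or carrier
            panel_calls[i] = 0
            private_keys.append(var.key)
        else:
            case_calls[i] = 2
            control_calls[i] = rng.integers(0, 2, size=n_controls)
            q = rng.uniform(0.1, 0.5)
            draw = rng.binomial(2, q, size=panel_size).astype(np.int8)
            if (draw == 0).all():
                draw[rng.integers(0, panel_size)] = 1
            panel_calls[i] = draw
    if missing_rate > 0:
        case_calls[rng.random(case_calls.shape) < missing_rate] = MISSING
        control_calls[rng.random(control_calls.shape) < missing_rate] = MISSING
    calls = VariantCallSet(variants=variants, case_calls=case_calls,
                           control_calls=control_calls, panel_calls=panel_calls)
    truth = TruthRecord(seed=seed, causal_variant=causal_variant,
                        private_keys=sorted(private_keys))
    return calls, truth


# ---------------------------------------------------------------------------
# exon counts

DEFAULT_EXONS: list[tuple[str, str, int]] = [
    # (exon id, isoform or "shared", length bp)
    ("M-exon", "M", 150),
    ("A-exon", "A", 180),
    ("E2", "shared", 120), ("E3", "shared", 140), ("E4", "shared", 110),
    ("E5", "shared", 160), ("E6", "shared", 130), ("E7", "shared", 170),
    ("E8", "shared", 100), ("E9", "shared", 220),
]


def sim_exon_counts(exons: list[tuple[str, str, int]] | None = None,
                    group_sizes: tuple[int, int] = (3, 3),
                    planted_fc: dict[str, float] | None = None,
                    dispersion: float = 0.1, mean_depth: float = 1e6,
                    base_rpkm: float = 500.0, seed: int = 0,
                    ) -> tuple[ExonCountTable, ExonCountTable, TruthRecord]:
    """Negative-binomial exon counts for two groups (A = reference/wild
    type, B = comparison/mutant).

    Counts are NB with mean proportional to exon length x library size x
    a group factor, variance m + dispersion * m^2 (dispersion 0 =
    Poisson); the group-B mean of every exon flagged in ``planted_fc`` is
    divided by its planted fold change.  Library sizes jitter around
    ``mean_depth``.  Returns (table_A, table_B, truth).
    """
    if exons is None:
        exons = DEFAULT_EXONS
    planted_fc = dict(planted_fc or {})
    if any(fc <= 0 for fc in planted_fc.values()):
        raise ValueError("planted fold changes must be > 0")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    n_a, n_b = group_sizes
    libs = mean_depth * rng.uniform(0.8, 1.2, size=n_a + n_b)

    def draw(group: str, lib_sizes: np.ndarray) -> np.ndarray:
        counts = np.zeros((len(exons), len(lib_sizes)))
        for ei, (eid, _iso, length) in enumerate(exons):
            m = base_rpkm * (length / 1e3) * (lib_sizes / 1e6)
            if group == "B" and eid in planted_fc:
                m = m / planted_fc[eid]
            if dispersion == 0:
                counts[ei] = rng.poisson(m)
            else:
                r = 1.0 / dispersion
                counts[ei] = rng.negative_binomial(r, r / (r + m))
        return counts

    ids = [e[0] for e in exons]
    meta = pd.DataFrame({"length": [e[2] for e in exons],
                         "isoform": [e[1] for e in exons]},
                        index=pd.Index(ids, name="exon_id"))
    samples_a = [f"wt{i + 1}" for i in range(n_a)]
    samples_b = [f"mut{i + 1}" for i in range(n_b)]
    table_a = ExonCountTable(
        exons=meta.copy(),
        counts=pd.DataFrame(draw("A", libs[:n_a]), index=meta.index, columns=samples_a),
        library_sizes=pd.Series(libs[:n_a], index=samples_a))
    table_b = ExonCountTable(
        exons=meta.copy(),
        counts=pd.DataFrame(draw("B", libs[n_a:]), index=meta.index, columns=samples_b),
        library_sizes=pd.Series(libs[n_a:], index=samples_b))
    truth = TruthRecord(seed=seed,
                        planted_exon_fc={e[0]: planted_fc.get(e[0], 1.0) for e in exons})
    return table_a, table_b, truth


# ---------------------------------------------------------------------------
# promoter pair

#: 9-bp insertion payload (motif-free on both strands for the SOX consensus)
DEFAULT_INS9 = "CCGGCCGGC"
#: 14-bp insertion payload; positions 4..10 match the SOX consensus WWCAAWG
DEFAULT_INS14 = "GACTTCAATGCTGG"


def default_promoter_edits(ins9: str = DEFAULT_INS9,
                           ins14: str = DEFAULT_INS14) -> list[Edit]:
    """The study-structure edit list: a 9-bp insertion, a GC>TT double
    substitution ~35 bp downstream, and a 14-bp insertion carrying the
    SOX payload, all clustered within a ~96-bp window near the far
    upstream end of the promoter fragment."""
    return [
        Edit(280, EditType.INS, alt_piece=ins9),
        Edit(316, EditType.SUB, ref_piece="GC", alt_piece="TT"),
        Edit(330, EditType.INS, alt_piece=ins14),
    ]


def sim_promoter_pair(length: int = 7_852, edits: list[Edit] | None = None,
                      motif_payload: str = SOX_CONSENSUS, seed: int = 0,
                      max_tries: int = 200,
                      ) -> tuple[PromoterPair, TruthRecord]:
    """A promoter allele pair whose alternate allele gains exactly one
    motif site inside the payload-carrying insertion.

    The reference is a uniform-composition random sequence (seeded) made
    motif-free by construction: windows matching the payload pattern on
    either strand are rejected and locally resampled until zero matches
    remain (global resampling is hopeless for a degenerate 7-mer over
    ~8 kb, where several matches are expected by chance).  The whole draw
    is repeated until the applied edit list yields exactly the planted
    alternate-allele hit; SUB edits have their required reference bases
    written in before the check.  The TSS sits immediately downstream of
    the fragment (reference offset ``length + 1``).
    """
    if edits is None:
        edits = default_promoter_edits()
    motif = MotifModel(iupac=motif_payload, name="payload")
    rng = np.random.default_rng(seed)
    payload_edit = max((e for e in edits if e.etype is EditType.INS),
                       key=lambda e: len(e.alt_piece), default=None)

    def write_pieces(chars: list[str]) -> None:
        for e in edits:
            if e.ref_piece:
                chars[e.ref_offset - 1: e.ref_offset - 1 + len(e.ref_piece)] = e.ref_piece

    for _ in range(max_tries):
        chars = list("".join(_BASES[rng.integers(0, 4, size=length)]))
        write_pieces(chars)
        seq = "".join(chars)
        for _round in range(100):
            hits = scan(seq, motif, strands="both")
            if not hits:
                break
            chars = list(seq)
            for h in hits:
                chars[h.start - 1: h.end] = _BASES[rng.integers(0, 4, size=h.end - h.start + 1)]
            write_pieces(chars)
            seq = "".join(chars)
        if scan(seq, motif, strands="both"):
            continue
        alt = apply_edits(seq, edits)
        alt_hits = scan(alt, motif, strands="both")
        if len(alt_hits) != (1 if payload_edit is not None else 0):
            continue
        pair = PromoterPair(ref=SequenceRecord("R_allele", seq),
                            alt=SequenceRecord("r_allele", alt),
                            edits=list(edits), tss_ref_offset=length + 1)
        span = None
        if payload_edit is not None:
            shift = sum(len(e.alt_piece) - len(e.ref_piece)
                        for e in edits
                        if e is not payload_edit
                        and e.ref_span[1] < payload_edit.ref_span[0])
            start = payload_edit.ref_offset + shift + 1
            span = (start, start + len(payload_edit.alt_piece) - 1)
        truth = TruthRecord(seed=seed, planted_motif_span=span)
        return pair, truth
    raise SimulationError("could not sample a motif-free reference sequence")
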