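# Methods

This note documents the statistical models, conventions and design
choices behind `recmap`, and what the synthetic-data generators do and
do not emulate.

## Inheritance model

The trait model is autosomal semi-recessive: genotype classes at the
causal locus have penetrances `(0, f_het, f_hom)` for 0/1/2 copies of
the risk allele, with defaults `f_hom = 1.0` and `f_het = 4/51 ≈ 0.078`
(the observed fraction of affected carriers in the motivating cohort).
Segregation testing uses the classical χ² goodness of fit with df = 1
and no continuity correction (a `yates=True` flag is available);
candidate ratios are expressed as unaffected:affected, so 3:1 is the
single-locus recessive expectation. Ratio selection takes the candidate
with maximal p, ties broken toward the simpler ratio. Penetrance
estimates are binomial proportions with Wilson 95 % intervals
(z = 1.959964); an empty genotype class yields an undefined estimate,
never 0.

Note that a goodness-of-fit p-value near 0.08 for 49:25 against 3:1 is
a *non-rejection* (support for 3:1); at n = 74 the exact binomial tail
(~0.105) differs visibly from the asymptotic χ² value — a discreteness
effect, documented in the tests.

## Association and genome-wide significance

Marker QC retains markers with MAF strictly above 0.05 and call rate
strictly above 0.75, computed on non-missing alleles; missing genotypes
are dropped per marker, never imputed. The single-marker statistic is
the Pearson allelic χ² on the 2×2 allele-count table (two alleles per
called genotype); when any expected cell is below 5 the reported raw p
comes from the two-sided Fisher exact test instead, but the χ² remains
the permutation statistic so that all markers share one comparable
scale. Family-wise significance is single-step max-T: phenotype labels
are permuted with the case count fixed, the maximum χ² across markers is
recorded per permutation, and the empirical p uses the add-one estimator
`(b+1)/(n_perm+1)`, which is conservative and never zero. Permutations
are vectorized (a permutation-by-sample indicator matrix multiplied
against the genotype matrix), making 10⁵ permutations over a few
thousand markers a matter of seconds.

## Haplotype concordance and the candidate interval

No statistical phasing is performed. A sample is a *window homozygote*
when it is homozygous at every marker of a window with no missing call;
its haplotype is then read directly from the genotypes. A window is
*concordant* when (i) every affected window-homozygote carries one and
the same (risk) haplotype, (ii) no unaffected sample is homozygous for
it, and (iii) at least one unaffected homozygote of a different
haplotype exists; the protective haplotype is the most frequent
haplotype among unaffected homozygotes, and everything not homozygous
for either haplotype counts as a carrier/unclassified ("het") for
penetrance purposes. A sample with a missing call in a window is
excluded from homozygote classification for that window only.

Windows of 2–10 markers are scanned per chromosome; overlapping
concordant windows are merged, and the reported block is the span
(union or constituent window) that separates the most homozygotes
(`score = n_risk_hom + n_prot_hom`), ties going to the wider span. The
block's 3×2 table (risk-hom / het / prot-hom × affected / unaffected)
gets a two-sided Fisher exact p computed by exhaustive enumeration of
fixed-margin tables with log-factorial probabilities (scipy provides no
R×C exact test); chromosome-wide significance permutes phenotypes and
asks how often any window achieves an equal-or-better concordance
score, again with the add-one estimator.

The candidate interval is bounded by the proximal informative
recombinants: walking outward from the block, each boundary is the
first flanking marker at which the affected risk-homozygotes fail to
share a single homozygous allele. Interval endpoints are the recombinant
marker positions themselves (1-based inclusive) and the length is
truncated to whole kb — with boundary coordinates 56,170,062 and
56,933,573 this convention yields 763 kb (763,511 bp). If no recombinant
exists before the chromosome end the interval is flagged open on that
side. BED output converts to 0-based half-open coordinates at the
writer only.

## Variant cascade

Co-segregation under the recessive model is a trichotomy: CONSISTENT
(every case hom-alt, no control hom-alt, no missing call), AMBIGUOUS
(missing calls present but all observed calls fit) or INCONSISTENT.
Carrier (heterozygous) controls are allowed by default — obligate
carrier parents demand it — with a `strict` flag requiring hom-ref
controls. Ambiguous variants are retained through the cascade but
flagged. Panel exclusion is absolute: any non-missing panel call
carrying at least one alternate allele disqualifies a variant from
being private to cases (exclusion is therefore monotone in the panel).
Merging screening sources deduplicates on (chrom, pos, ref, alt) with
indels in the anchored-base VCF convention, preserving provenance tags.

Annotation precedence is CODING (exonic and within the CDS) >
SPLICE_BOUNDARY (within 2 bp of an internal exon edge) > PROMOTER >
INTRON > INTERGENIC. Promoters are strand-aware windows (default
10 kb) upstream of each isoform's first-exon TSS; an isoform promoter
inside another isoform's intron is classified PROMOTER, which is the
biologically relevant call for multi-promoter genes. Coding SNVs are
labelled `refAA + codon + altAA` via the standard code (codon index
`ceil(offset/3)`, 1-based); coding indels are frameshift or in-frame by
length mod 3. Ranking keeps private CONSISTENT/AMBIGUOUS variants in
the interval, puts focus-promoter variants first, then orders by region
priority (non-synonymous coding > splice > promoter > intron >
synonymous > intergenic). Within a region class, indels precede SNVs:
structural changes are the candidates for de-novo regulatory-element
creation, and this makes the ranking a deterministic total order with
the planted causal insertion first in simulation. Position breaks the
remaining ties.

## Exon-level expression

Normalization is exon-level RPKM: `count / (library_size/10⁶) /
(exon_length/10³)`, invariant under uniform library scaling. Group
fold change is the ratio of arithmetic group means of normalized
values, with a pseudocount of 0.5 reads on the per-million scale
(0.5 / (median library / 10⁶)) so that a fully silenced exon yields a
finite, large ratio without distorting expressed exons. An isoform is
called as specifically lost when its own first exon's fold change
reaches the threshold (default 2.0) while no shared exon does — a
uniform gene-wide shift therefore flags nothing, which is exactly the
distinction gene-level RPKM cannot make. Gene-level differential calls
use the plain two-fold rule (boundary inclusive, either direction).

At the default simulation conditions (3 vs 3, NB dispersion 0.1) a
ratio of group means carries an irreducible ~26 % sampling error
(per-sample CV ≥ √0.1); recovery of a planted fold change is therefore
assessed by the median recovered value across seeds (unbiased within a
few percent for planted values 2–20), not by per-seed precision.

## Motif scanning and projection

IUPAC patterns are matched position-by-position (default SOX HMG-box
consensus `WWCAAWG`); PWMs score windows against a threshold. Minus-
strand hits come from scanning the forward sequence with the
reverse-complement pattern; a hit's `start` is always the leftmost
forward coordinate and `matched` the site as read on its strand.
Allele pairs carry an explicit edit list (INS anchored after a
reference position; SUB/DEL/COMPLEX replacing a span); projection maps
coordinates across alleles, with positions inside inserted or deleted
spans mapping to none. Gained/lost calls require projected-position
and strand agreement exactly (±0 bp), so junction-created sites count
as gained; gained hits are annotated with the overlapping edits and
with TSS-relative coordinates in the no-zero convention (TSS = +1, the
base upstream = −1). The in-silico deletion test removes an
alternate-coordinate region by composing it into the edit list and
re-running the diff; an empty gained set is reported as predicted
restoration.

## Synthetic data

`sim_cohort` draws each chromosome copy as a mosaic over founder blocks
(default 8 founders, 4 block haplotypes, 5 markers per block): within a
block the copy takes one founder's block haplotype, blocks recombine
freely. This produces local LD without a recombination map. In the
causal block there are exactly two complementary haplotypes: an
identical-by-descent risk haplotype (carried by 4 of 8 founders, hence
frequency 0.5) bearing the alternate causal allele, and one common
protective haplotype — the two-haplotype structure the concordance
stage expects. With the default 28/73 ascertainment and penetrances
(1.0, 4/51) this reproduces the expected cohort composition (~24 risk
homozygotes, ~26 protective homozygotes, ~4 affected among ~50
carriers). Phenotypes are drawn per causal genotype and individuals
rejection-sampled to the case/control quotas; calls are masked missing
at 2 % by default. A negative causal index gives a null cohort with
labels independent of genotype.

`sim_litters` draws het×het offspring 1:2:1 (default 11 litters, 74
offspring). `sim_variant_calls` plants private-linked variants
(hom-alt in all cases, absent from the panel, one designated 14-bp
causal insertion) among shared-common variants that at least one of the
103 panel animals carries. `sim_exon_counts` draws negative-binomial
counts with mean ∝ exon length × library size × group factor and
variance `m + φm²` (φ = 0 is Poisson; default φ = 0.1), dividing the
mutant-group mean of flagged exons by the planted fold change; the
default gene has isoform-specific first exons "M" and "A" plus eight
shared exons at a well-expressed baseline (500 RPKM, ~10⁶-read
libraries). `sim_promoter_pair` plants the study-structure edits (9-bp
INS, GC>TT double substitution, 14-bp INS whose payload contains a SOX
consensus match) ~7.5 kb upstream of the TSS on a reference made
motif-free by construction: windows matching the payload pattern are
rejected and locally resampled until none remain (whole-sequence
rejection is hopeless for a degenerate 7-mer over 7.8 kb, where ~8
matches are expected per draw), and the draw is repeated until the
mutant allele carries exactly the one planted hit.

All generators are deterministic given their arguments and a single
integer seed, and return a truth record sufficient to verify recovery
without re-running them.

What the generators do **not** emulate: realistic demography or
recombination maps, genotyping-error and allele-dropout patterns,
read-level data (the pipeline consumes count tables, not FASTQ),
sequencing-error models, or correlated expression noise between exons.
Passing recovery tests therefore demonstrate that the statistical
machinery is correct under its stated model, not that the model captures
every property of real array or RNA-seq data.

## Numerical choices and problem sizes

Empirical p estimators are add-one throughout (floor `1/(n_perm+1)`).
Permutation maxima are compared to observed statistics with a 10⁻⁹
absolute tolerance so ties count as exceedances (conservative). The R×2
exact test sums table probabilities ≤ the observed probability with a
relative tolerance of 10⁻⁹. Fold-change direction is reported
explicitly rather than as signed ratios. Degenerate inputs are flagged
rather than fatal where the pipeline can continue (empty test strata,
absent concordant blocks, open intervals).

The test suite and the acceptance script run reduced problem sizes
chosen to keep full runs in minutes on one CPU while leaving
comfortable statistical margins: 2000 permutations (not 10⁵) for the
mapping recovery rates over 50–100 seeded cohorts, 200–400 permutations
and 150–300 seeds for the null-calibration checks, and 100 seeds for
fold-change recovery. The demo pipeline's default is 20,000
permutations; the CLI accepts the full 100,000 of a production run.

## Known limitations

- Haplotypes are read only from homozygotes; a causal haplotype never
  observed homozygous in controls' complement cannot define a
  protective class, and regions of extreme haplotype diversity will
  yield no concordant block (returned as an empty list, not an error).
- The concordance score is integer-valued; its permutation p is
  slightly conservative under heavy ties.
- Coding annotation assumes a single, consistent transcript model per
  gene and does not handle CDS that disagrees with the supplied
  reference alleles (it raises instead).
- The motif component treats binding as consensus/threshold matching;
  it makes no thermodynamic or chromatin-context claims.
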