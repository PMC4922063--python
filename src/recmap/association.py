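"""Marker QC, single-marker allelic case/control tests, and max-T
permutation genome-wide empirical significance.

The family-wise correction is single-step max-T: for each phenotype
permutation the maximum allelic chi-square over all markers is recorded,
and a marker's genome-wide empirical p is the add-one estimate
(b + 1) / (n_perm + 1), where b counts permutations whose maximum reaches
the marker's observed statistic.  Missing genotypes are dropped
per marker, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import MISSING, GenotypeMatrix, PhenotypeTable


@dataclass
class MarkerExclusion:
    marker_id: str
    reason: str  # "maf" or "call_rate"
    value: float


def _allele_stats(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker (call rate, B-allele frequency, n non-missing) over samples."""
    miss = calls == MISSING
    n_called = (~miss).sum(axis=0)
    call_rate = n_called / calls.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = np.where(n_called > 0,
                          np.where(miss, 0, calls).sum(axis=0) / (2.0 * n_called), 0.0)
    return call_rate, freq_b, n_called


def filter_markers(gm: GenotypeMatrix, maf_min: float = 0.05,
                   call_rate_min: float = 0.75,
                   ) -> tuple[GenotypeMatrix, list[MarkerExclusion]]:
    """Retain markers with MAF strictly above ``maf_min`` and call rate
    strictly above ``call_rate_min``; MAF is computed on non-missing alleles."""
    call_rate, freq_b, _ = _allele_stats(gm.calls)
    maf = np.minimum(freq_b, 1.0 - freq_b)
    keep = np.ones(gm.n_markers, dtype=bool)
    excluded: list[MarkerExclusion] = []
    for i, m in enumerate(gm.markers):
        if not call_rate[i] > call_rate_min:
            keep[i] = False
            excluded.append(MarkerExclusion(m.id, "call_rate", float(call_rate[i])))
        elif not maf[i] > maf_min:
            keep[i] = False
            excluded.append(MarkerExclusion(m.id, "maf", float(maf[i])))
    idx = np.flatnonzero(keep)
    filtered = GenotypeMatrix(sample_ids=list(gm.sample_ids),
                              markers=[gm.markers[i] for i in idx],
                              calls=gm.calls[:, idx])
    return filtered, excluded


@dataclass
class AllelicTest:
    statistic: float  # Pearson allelic chi-square (uncorrected)
    p_raw: float
    method: str  # "chi2" or "fisher"
    table: tuple[tuple[int, int], tuple[int, int]]  # (case, control) x (A, B)
    valid: bool = True


def _chi2_2x2(a: float, b: float, c: float, d: float) -> float:
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def allelic_test(calls: np.ndarray, affected: np.ndarray) -> AllelicTest:
    """Case/control allelic test on one marker.

    Builds the 2x2 allele-count table (two alleles per non-missing
    genotype).  Pearson chi-square without correction by default; Fisher's
    exact two-sided p when any expected cell is below 5.
    """
    calls = np.asarray(calls)
    affected = np.asarray(affected, dtype=bool)
    ok = calls != MISSING
    case_ok, ctrl_ok = ok & affected, ok & ~affected
    if case_ok.sum() == 0 or ctrl_ok.sum() == 0:
        return AllelicTest(0.0, 1.0, "empty_stratum", ((0, 0), (0, 0)), valid=False)
    case_b = int(calls[case_ok].sum())
    ctrl_b = int(calls[ctrl_ok].sum())
    case_a = 2 * int(case_ok.sum()) - case_b
    ctrl_a = 2 * int(ctrl_ok.sum()) - ctrl_b
    table = ((case_a, case_b), (ctrl_a, ctrl_b))
    stat = _chi2_2x2(case_a, case_b, ctrl_a, ctrl_b)
    n = case_a + case_b + ctrl_a + ctrl_b
    expected_min = min((case_a + case_b) * (case_a + ctrl_a),
                       (case_a + case_b) * (case_b + ctrl_b),
                       (ctrl_a + ctrl_b) * (case_a + ctrl_a),
                       (ctrl_a + ctrl_b) * (case_b + ctrl_b)) / n
    if expected_min < 5:
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        method = "fisher"
    else:
        p = float(stats.chi2.sf(stat, df=1))
        method = "chi2"
    return AllelicTest(float(stat), p, method, table)


@dataclass
class AssociationResult:
    marker_id: str
    statistic: float
    p_raw: float
    p_genome: float
    n_perm: int

    def __post_init__(self) -> None:
        if not (0.0 < self.p_genome <= 1.0 and 0.0 < self.p_raw <= 1.0):
            raise ValueError("p values must lie in (0, 1]")
        if self.p_genome < 1.0 / (self.n_perm + 1):
            raise ValueError("p_genome below the add-one estimator floor")


def _chi2_vector(case_b: np.ndarray, case_n: np.ndarray,
                 tot_b: np.ndarray, tot_n: np.ndarray) -> np.ndarray:
    """Vectorized allelic chi-square given per-marker case alt-allele counts
    (``case_b``), case called-genotype counts (``case_n``) and totals."""
    a = 2.0 * case_n - case_b           # case A alleles
    b = case_b
    c = 2.0 * (tot_n - case_n) - (tot_b - case_b)
    d = tot_b - case_b
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    return chi2


def permutation_genomewide(gm: GenotypeMatrix, phen: PhenotypeTable,
                           n_perm: int = 100_000, seed: int = 0,
                           chunk: int = 1_000) -> list[AssociationResult]:
    """Max-T phenotype-permutation genome-wide p values for every marker.

    Phenotype labels are shuffled (genotypes fixed) ``n_perm`` times with
    the case count preserved; the statistic is the allelic chi-square for
    every marker (a single comparable statistic, even where Fisher supplied
    p_raw).  Deterministic for a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    affected = phen.affected_mask(gm.sample_ids)
    n_cases = int(affected.sum())
    if n_cases == 0 or n_cases == len(affected):
        raise ValueError("need at least one case and one control")

    calls = gm.calls
    miss = calls == MISSING
    geno = np.where(miss, 0, calls).astype(np.float64)
    called = (~miss).astype(np.float64)
    tot_b = geno.sum(axis=0)
    tot_n = called.sum(axis=0)

    obs = _chi2_vector(affected @ geno, affected @ called, tot_b, tot_n)

    max_stats = np.empty(n_perm)
    done = 0
    n = len(affected)
    while done < n_perm:
        k = min(chunk, n_perm - done)
        # random case subsets of the fixed size = label permutations
        order = np.argsort(rng.random((k, n)), axis=1)
        perm = np.zeros((k, n))
        np.put_along_axis(perm, order[:, :n_cases], 1.0, axis=1)
        case_b = perm @ geno
        case_n = perm @ called
        chi2 = _chi2_vector(case_b, case_n, tot_b, tot_n)
        max_stats[done:done + k] = chi2.max(axis=1)
        done += k

    results = []
    tol = 1e-9  # permutation maxima equal to the observed statistic count as >=
    for i, m in enumerate(gm.markers):
        b = int((max_stats >= obs[i] - tol).sum())
        p_genome = (b + 1) / (n_perm + 1)
        raw = allelic_test(calls[:, i], affected)
        results.append(AssociationResult(marker_id=m.id, statistic=float(obs[i]),
                                         p_raw=raw.p_raw if raw.valid else 1.0,
                                         p_genome=p_genome, n_perm=n_perm))
    return results
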