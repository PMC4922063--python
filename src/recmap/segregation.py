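"""Mendelian segregation-ratio testing and penetrance estimation.

Given offspring counts from carrier x carrier matings, these routines ask
which classical Mendelian ratio (unaffected : affected) fits the data
best, and estimate per-genotype-class penetrance with Wilson confidence
intervals.  Ratios follow the recessive convention: 3:1 reads as three
normal offspring to one affected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.proportion import proportion_confint

#: classical single-, mono- and duplicate-recessive ratios
DEFAULT_RATIOS: tuple[tuple[int, int], ...] = ((1, 1), (3, 1), (15, 1))


@dataclass
class SegregationResult:
    observed: tuple[int, int]  # (n_unaffected, n_affected)
    candidate_ratio: tuple[int, int]  # unaffected : affected
    chi2: float
    df: int
    p: float

    def __post_init__(self) -> None:
        if self.chi2 < 0 or not 0.0 <= self.p <= 1.0:
            raise ValueError("invalid test result")


def gof_chisq(observed: tuple[int, int], ratio: tuple[int, int],
              yates: bool = False) -> SegregationResult:
    """Chi-square goodness of fit of (unaffected, affected) counts to a
    candidate Mendelian ratio, df = 1.

    No continuity correction by default; set ``yates=True`` for the Yates
    corrected statistic.
    """
    u, a = observed
    ru, ra = ratio
    if u < 0 or a < 0 or u + a == 0:
        raise ValueError("observed counts must be non-negative with a positive total")
    if ru <= 0 or ra <= 0:
        raise ValueError("ratio terms must be positive")
    total = u + a
    exp_u = total * ru / (ru + ra)
    exp_a = total * ra / (ru + ra)
    if yates:
        chi2 = sum((abs(o - e) - 0.5) ** 2 / e for o, e in ((u, exp_u), (a, exp_a)))
    else:
        chi2 = (u - exp_u) ** 2 / exp_u + (a - exp_a) ** 2 / exp_a
    p = float(stats.chi2.sf(chi2, df=1))
    return SegregationResult(observed=(u, a), candidate_ratio=(ru, ra),
                             chi2=float(chi2), df=1, p=p)


def select_mendelian_ratio(
    observed: tuple[int, int],
    candidates: tuple[tuple[int, int], ...] = DEFAULT_RATIOS,
    yates: bool = False,
) -> tuple[tuple[int, int], dict[tuple[int, int], SegregationResult]]:
    """Pick the candidate ratio with the best goodness-of-fit p.

    Ties break toward the simpler ratio (smaller ru + ra).  Returns the
    selected ratio and the per-candidate results.
    """
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    results = {tuple(r): gof_chisq(observed, r, yates=yates) for r in candidates}
    best = max(results, key=lambda r: (results[r].p, -(r[0] + r[1])))
    return best, results


@dataclass
class PenetranceEstimate:
    affected: int
    total: int
    estimate: float | None  # None when the class is empty (undefined, not 0)
    ci_low: float | None
    ci_high: float | None

    @property
    def defined(self) -> bool:
        return self.estimate is not None


def estimate_penetrance(
    genotype_class_counts: dict[str, tuple[int, int]],
    alpha: float = 0.05,
) -> dict[str, PenetranceEstimate]:
    """Per-genotype-class penetrance: affected/total with a Wilson interval.

    ``genotype_class_counts`` maps a class label (e.g. "hom_risk", "het",
    "hom_protective") to (n_affected, n_total).  Empty classes yield an
    undefined estimate rather than 0.
    """
    out: dict[str, PenetranceEstimate] = {}
    for label, (aff, total) in genotype_class_counts.items():
        if total < 0 or aff < 0 or aff > total:
            raise ValueError(f"bad counts for class {label}: {aff}/{total}")
        if total == 0:
            out[label] = PenetranceEstimate(aff, total, None, None, None)
            continue
        lo, hi = proportion_confint(aff, total, alpha=alpha, method="wilson")
        out[label] = PenetranceEstimate(aff, total, aff / total,
                                        float(lo), float(hi))
    return out
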