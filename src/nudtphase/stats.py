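"""Tolerated 6-MP dose comparison between diplotype groups.

Patients are grouped as heterozygous (*1/x, one variant allele) versus
homozygous-or-compound-heterozygous (two variant alleles); *1/*1 and any
diplotype containing an unknown allele are excluded from the comparison and
reported separately. Dose differences are tested with a two-sided
Mann–Whitney U test: U is computed from mid-ranks (ties averaged) and, for
pooled sample sizes up to ``EXACT_CUTOFF`` (25), the p-value is exact over
all C(n_a+n_b, n_a) assignments of the pooled values to groups — evaluated
with a rank-sum counting recursion rather than literal enumeration, which is
what makes ties and n ≈ 25 tractable. Larger samples use the normal
approximation with tie-corrected variance and a continuity correction.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .catalog import Diplotype, DiplotypeCategory
from .errors import ValidationError

EXACT_CUTOFF = 25


class DoseGroup(str, Enum):
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS_OR_COMPOUND = "homozygous_or_compound"


@dataclass(frozen=True)
class DoseRecord:
    sample_id: str
    diplotype: Diplotype
    dose: float  # tolerated 6-MP, mg/m2/day

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise ValidationError(f"{self.sample_id}: dose must be > 0, got {self.dose}")


def assign_group(diplotype: Diplotype) -> DoseGroup | None:
    """Dose-comparison group for a diplotype; None means excluded.

    *1/*1 carries no variant allele and unknown alleles have no defined
    status, so both are excluded from the two-group comparison.
    """
    if any(a.is_unknown for a in diplotype.alleles):
        return None
    cat = diplotype.category
    if cat is DiplotypeCategory.REFERENCE:
        return None
    if cat is DiplotypeCategory.HETEROZYGOUS:
        return DoseGroup.HETEROZYGOUS
    return DoseGroup.HOMOZYGOUS_OR_COMPOUND


@dataclass(frozen=True)
class TestResult:
    u: float           # U statistic for the first group
    p_value: float     # two-sided
    n_a: int
    n_b: int
    method: str        # "exact" | "normal_approx"


def _exact_rank_sum_tail_probs(ranks2: np.ndarray, n_a: int, observed2: int) -> tuple[float, float]:
    """P(R_a <= obs) and P(R_a >= obs) under random group assignment.

    ``ranks2`` are doubled mid-ranks (integers even with ties); the counting
    recursion dp[j][s] = number of j-subsets with doubled rank sum s is the
    exact permutation distribution, identical to enumerating all
    C(N, n_a) assignments.
    """
    total_sum = int(ranks2.sum())
    dp = np.zeros((n_a + 1, total_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        dp[1:, r:] += dp[:-1, : total_sum + 1 - r]
    counts = dp[n_a]
    total = counts.sum()
    p_le = counts[: observed2 + 1].sum() / total
    p_ge = counts[observed2:].sum() / total
    return p_le, p_ge


def mann_whitney_exact(
    doses_a: Sequence[float], doses_b: Sequence[float]
) -> TestResult:
    """Two-sided Mann–Whitney U test with an exact small-sample path.

    Returns U for the first group. The exact two-sided p is
    min(1, 2·min(lower tail, upper tail)) of the permutation distribution of
    the rank sum; above pooled n of 25 a tie-corrected, continuity-corrected
    normal approximation is used and recorded in ``method``.
    """
    a = np.asarray(doses_a, dtype=float)
    b = np.asarray(doses_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r_a = ranks[:n_a].sum()
    u_a = r_a - n_a * (n_a + 1) / 2.0

    n = n_a + n_b
    if n <= EXACT_CUTOFF:
        ranks2 = np.rint(2 * ranks).astype(int)
        observed2 = int(round(2 * r_a))
        p_le, p_ge = _exact_rank_sum_tail_probs(ranks2, n_a, observed2)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(u=u_a, p_value=p, n_a=n_a, n_b=n_b, method="exact")

    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult(u=u_a, p_value=1.0, n_a=n_a, n_b=n_b, method="normal_approx")
    z = max(abs(u_a - mu) - 0.5, 0.0) / np.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return TestResult(u=u_a, p_value=p, n_a=n_a, n_b=n_b, method="normal_approx")


@dataclass(frozen=True)
class DoseSummary:
    n: int
    median: float
    minimum: float
    maximum: float


def dose_summary(doses: Sequence[float]) -> DoseSummary:
    """Sample median (mean of the middle two for even n), min and max."""
    arr = np.asarray(doses, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot summarize an empty dose list")
    return DoseSummary(
        n=int(arr.size),
        median=float(np.median(arr)),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
    )


def compare_dose_groups(records: Sequence[DoseRecord]) -> dict:
    """Group records, summarize each group, and run the dose comparison."""
    groups: dict[DoseGroup, list[float]] = {g: [] for g in DoseGroup}
    excluded: list[str] = []
    for rec in records:
        g = assign_group(rec.diplotype)
        if g is None:
            excluded.append(rec.sample_id)
        else:
            groups[g].append(rec.dose)
    het = groups[DoseGroup.HETEROZYGOUS]
    hom = groups[DoseGroup.HOMOZYGOUS_OR_COMPOUND]
    result: dict = {"excluded": excluded}
    for name, doses in (("heterozygous", het), ("homozygous_or_compound", hom)):
        if doses:
            s = dose_summary(doses)
            result[name] = {
                "n": s.n, "median": s.median, "min": s.minimum, "max": s.maximum,
            }
    if het and hom:
        t = mann_whitney_exact(het, hom)
        result["test"] = {
            "u": t.u, "p_value": t.p_value, "n_a": t.n_a, "n_b": t.n_b, "method": t.method,
        }
    return result


def synthetic_het_doses(
    n: int = 35,
    median: float = 12.5,
    low: float = 5.0,
    high: float = 42.5,
    seed: int = 0,
) -> list[float]:
    """SYNTHETIC per-patient doses for the heterozygous group.

    The study reports only this group's summary (median 12.5, range
    5.0–42.5 mg/m2/day), not individual doses; this generator pins the
    summary's order statistics exactly — minimum, median (for odd n) and
    maximum — and fills the rest with seeded random values inside the range.
    Use for demonstration pipelines only; the values are not patient data.
    """
    if n < 3:
        raise ValidationError("need at least 3 doses to pin min, median and max")
    rng = np.random.default_rng(seed)
    mid = (n - 1) // 2
    lower = np.sort(rng.uniform(low, median, size=mid - 1))
    upper = np.sort(rng.uniform(median, high, size=n - mid - 2))
    doses = np.concatenate([[low], lower, [median], upper, [high]])
    return [float(round(d, 1)) for d in doses]
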