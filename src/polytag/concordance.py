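"""Cross-dataset / cross-platform DEG-list concordance.

Two analyses of the same contrast rarely survey the same genes: an array
only sees its probes, a tag dataset only sees genes with a mappable DpnII
tag. Before intersecting DEG lists each list is therefore "survey
corrected": genes the other analysis could never have seen are removed
from the count being compared. The overlap is then expressed as a
percentage of the smaller corrected list, so a perfect subset relation
reads as 100%.

Disagreements use the same correction applied to *opposite* lists (up in
species 1 on platform A vs up in species 2 on platform B).

Significance of an observed overlap z is assessed against a resampling
null: from the Y genes surveyed by both platforms, draw a random n-subset
and an independent random m-subset (without replacement, matching the two
DEG-list sizes) and record the intersection size; repeat (default 10,000
times). The null is exactly Hypergeometric(Y, n, m), so the analytic tail
probability is reported alongside the resampled one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class DEGListPair:
    list_a: set
    list_b: set
    surveyed_a: set
    surveyed_b: set

    def __post_init__(self) -> None:
        if not self.list_a <= self.surveyed_a:
            raise ValueError("list_a must be a subset of surveyed_a")
        if not self.list_b <= self.surveyed_b:
            raise ValueError("list_b must be a subset of surveyed_b")


@dataclass
class OverlapResult:
    a_corrected: int
    b_corrected: int
    overlap: int
    percentage: float | None  # of the smaller corrected list; None if undefined

    def rounded(self, decimals: int = 0) -> float | None:
        if self.percentage is None:
            return None
        r = round(self.percentage, decimals)
        return int(r) if decimals == 0 else r


def corrected_overlap(pair: DEGListPair) -> OverlapResult:
    """Survey-corrected agreement between two DEG lists (same direction).

    a_corrected = |list_a restricted to genes surveyed by b|, and
    symmetrically; percentage = 100 * overlap / min(corrected counts).
    """
    a_corr = len(pair.list_a & pair.surveyed_b)
    b_corr = len(pair.list_b & pair.surveyed_a)
    overlap = len(pair.list_a & pair.list_b)
    denom = min(a_corr, b_corr)
    pct = 100.0 * overlap / denom if denom > 0 else None
    return OverlapResult(a_corr, b_corr, overlap, pct)


def disagreement(pair: DEGListPair) -> OverlapResult:
    """Survey-corrected contradiction percentage between opposite lists.

    The caller passes opposite-direction lists (up in species 1 on one
    platform vs up in species 2 on the other); the arithmetic is the same
    min-denominator rule as for agreements.
    """
    return corrected_overlap(pair)


@dataclass
class ConcordanceTest:
    Y: int
    n: int
    m: int
    z: int
    reps: int = 10_000
    seed: int = 0
    alternative: str = "greater"  # overlap higher than chance
    null_distribution: np.ndarray | None = field(default=None, repr=False)
    p_resampled: float | None = None
    p_exact: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.n <= self.Y and 0 <= self.m <= self.Y):
            raise ValueError("n and m must lie in [0, Y]")
        if self.z > min(self.n, self.m):
            raise ValueError("z cannot exceed min(n, m)")


def resampling_test(test: ConcordanceTest) -> ConcordanceTest:
    """Monte-Carlo null for the overlap of two random gene subsets.

    Each rep draws independent uniform n- and m-subsets of the Y shared
    genes; the recorded intersection sizes form the null. The one-sided
    p-value uses the add-one correction p = (#{null >= z} + 1)/(reps + 1)
    (">=" including ties; "<=" when testing for a deficit). The exact
    hypergeometric tail is attached for reference.
    """
    rng = np.random.default_rng(test.seed)
    null = np.empty(test.reps, dtype=np.int64)
    mask = np.zeros(test.Y, dtype=bool)
    for i in range(test.reps):
        first = rng.choice(test.Y, size=test.n, replace=False)
        mask[:] = False
        mask[first] = True
        second = rng.choice(test.Y, size=test.m, replace=False)
        null[i] = int(mask[second].sum())
    test.null_distribution = null
    if test.alternative == "greater":
        extreme = int((null >= test.z).sum())
        test.p_exact = float(stats.hypergeom.sf(test.z - 1, test.Y, test.n, test.m))
    elif test.alternative == "less":
        extreme = int((null <= test.z).sum())
        test.p_exact = float(stats.hypergeom.cdf(test.z, test.Y, test.n, test.m))
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    test.p_resampled = (extreme + 1) / (test.reps + 1)
    return test


def concordance_report(
    pair: DEGListPair, reps: int = 10_000, seed: int = 0
) -> dict:
    """Corrected overlap plus its resampling significance, as one report."""
    ov = corrected_overlap(pair)
    shared = pair.surveyed_a & pair.surveyed_b
    test = ConcordanceTest(
        Y=len(shared),
        n=len(pair.list_a & shared),
        m=len(pair.list_b & shared),
        z=len(pair.list_a & pair.list_b & shared),
        reps=reps,
        seed=seed,
    )
    resampling_test(test)
    return {
        "a_corrected": ov.a_corrected,
        "b_corrected": ov.b_corrected,
        "overlap": ov.overlap,
        "percentage": ov.percentage,
        "Y": test.Y,
        "n": test.n,
        "m": test.m,
        "z": test.z,
        "reps": test.reps,
        "seed": test.seed,
        "p_resampled": test.p_resampled,
        "p_exact": test.p_exact,
    }
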