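"""Cluster-vs-survival association statistics.

Patient cluster assignments are cross-tabulated against 5-year survival
in a 2x2 table with the convention

=========  ==================  ==================
           did not survive     survived
=========  ==================  ==================
Cluster 2  a                   c
Cluster 1  b                   d
=========  ==================  ==================

i.e. under the ideal grouping (Cluster 1 = survivors) a "positive test"
is membership in Cluster 2. Association is assessed by the two-tailed
Fisher exact test; the five diagnostic ratios and the ad/bc odds ratio
with a Woolf (log-normal) 95% CI quantify prognostic performance.
Unassigned (tied) patients are excluded before counting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.stats import fisher_exact

from .clustering import PatientAssignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Patient cluster vs 5-year survival counts.

    ``a``: non-survivors in Cluster 2, ``b``: non-survivors in Cluster 1,
    ``c``: survivors in Cluster 2, ``d``: survivors in Cluster 1.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer")
            object.__setattr__(self, name, int(v))
        if self.n == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity, specificity, accuracy, PPV, NPV of a 2x2 table.

    Positive = Cluster 2 (predicted non-survivor). Ratios with a zero
    denominator are NaN and listed in ``undefined``.
    """

    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    undefined: frozenset[str]


@dataclass(frozen=True)
class FisherResult:
    p_two_tailed: float


@dataclass(frozen=True)
class OddsRatioResult:
    """ad/bc odds ratio; undefined (``defined=False``) when b*c = 0.

    ``ci95`` is the Woolf interval exp(ln OR +- 1.96 sqrt(sum 1/cell)),
    available only when all four cells are positive.
    """

    value: float | None
    ci95: tuple[float, float] | None
    defined: bool


def contingency(
    assignments: Iterable[PatientAssignment],
    survival: Mapping[object, int],
) -> ContingencyTable2x2:
    """Count assigned patients into the a/b/c/d convention.

    Unassigned patients (majority-vote ties) are dropped with a logged
    count; a patient missing from ``survival`` raises.
    """
    counts = {"a": 0, "b": 0, "c": 0, "d": 0}
    n_unassigned = 0
    n_seen = 0
    for asg in assignments:
        n_seen += 1
        if asg.cluster is None:
            n_unassigned += 1
            continue
        if asg.patient_id not in survival:
            raise ValueError(f"no survival label for patient {asg.patient_id!r}")
        survived = bool(survival[asg.patient_id])
        if asg.cluster == 2:
            counts["c" if survived else "a"] += 1
        else:
            counts["d" if survived else "b"] += 1
    if n_seen == 0:
        raise ValueError("no patient assignments given")
    if n_unassigned:
        logger.info("excluded %d unassigned (tied) patient(s)", n_unassigned)
    return ContingencyTable2x2(**counts)


def fisher_two_tailed(t: ContingencyTable2x2) -> FisherResult:
    """Two-tailed Fisher exact test of cluster vs survival.

    Exact hypergeometric convention: the p-value sums the point
    probabilities of all tables with the observed margins that are no
    more probable than the observed one. Requires both margins nonzero.
    """
    if (t.a + t.b == 0 or t.c + t.d == 0 or t.a + t.c == 0 or t.b + t.d == 0):
        raise ValueError("a zero margin leaves the association undefined")
    p = fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1]
    return FisherResult(p_two_tailed=float(min(p, 1.0)))


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def diagnostics(t: ContingencyTable2x2) -> DiagnosticMetrics:
    """The five diagnostic ratios with zero-denominator flags."""
    values = {
        "sensitivity": _ratio(t.a, t.a + t.b),
        "specificity": _ratio(t.d, t.c + t.d),
        "accuracy": _ratio(t.a + t.d, t.n),
        "ppv": _ratio(t.a, t.a + t.c),
        "npv": _ratio(t.d, t.b + t.d),
    }
    undefined = frozenset(k for k, v in values.items() if math.isnan(v))
    return DiagnosticMetrics(**values, undefined=undefined)


def odds_ratio(t: ContingencyTable2x2) -> OddsRatioResult:
    """ad/bc odds ratio with Woolf 95% CI; no continuity correction."""
    if t.b * t.c == 0:
        return OddsRatioResult(value=None, ci95=None, defined=False)
    value = (t.a * t.d) / (t.b * t.c)
    ci = None
    if min(t.a, t.b, t.c, t.d) > 0:
        se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
        log_or = math.log(value)
        ci = (math.exp(log_or - 1.96 * se), math.exp(log_or + 1.96 * se))
    return OddsRatioResult(value=value, ci95=ci, defined=True)


#: Published cluster-vs-survival contingency tables of the 32-patient
#: stage III colorectal cancer cohort the pipeline was developed on,
#: reconstructed from the reported sensitivity/specificity/PPV/NPV,
#: total accuracy and sample size of each model/aggregation row (the
#: reconstruction is uniquely determined by those ratios). Majority-vote
#: rows have n < 32 because tied patients were unassigned. These serve
#: as reference inputs for recomputing the reported association
#: statistics.
REFERENCE_TABLES: dict[tuple[str, str], ContingencyTable2x2] = {
    ("kmeans", "majority_vote"): ContingencyTable2x2(3, 6, 5, 17),
    ("kmeans", "feature_average"): ContingencyTable2x2(7, 2, 5, 18),
    ("fcm", "majority_vote"): ContingencyTable2x2(7, 2, 6, 16),
    ("fcm", "feature_average"): ContingencyTable2x2(8, 1, 6, 17),
    ("gmm", "majority_vote"): ContingencyTable2x2(3, 6, 0, 21),
    ("gmm", "feature_average"): ContingencyTable2x2(4, 5, 2, 21),
}
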