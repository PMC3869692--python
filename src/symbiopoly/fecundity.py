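"""Ovary fecundity classes and between-line class-distribution comparisons.

Ovaries are scored by the number of mature (stage-14) eggs and binned into
four classes: I = 0 eggs, II = 1-2, III = 3-9, IV = 10 or more.  Lines are
compared either on a 2x2 table (class IV vs not, Fisher exact) or on the
full 2x4 class table by exhaustive enumeration of the multivariate
hypergeometric null — feasible at the study's 40 ovaries per line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

from symbiopoly.polymorphism_stats import ContingencyResult, fisher_exact

CLASSES = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class OvaryRecord:
    line: str
    individual_id: str
    mature_egg_count: int

    def __post_init__(self):
        if self.mature_egg_count < 0:
            raise ValueError("egg count must be >= 0")

    @property
    def fecundity_class(self) -> str:
        return classify_ovary(self.mature_egg_count)


def classify_ovary(count: int) -> str:
    """Fecundity class from mature-egg count: 0 -> I, 1-2 -> II, 3-9 -> III,
    >= 10 -> IV."""
    if count < 0 or int(count) != count:
        raise ValueError("count must be a non-negative integer")
    if count == 0:
        return "I"
    if count <= 2:
        return "II"
    if count <= 9:
        return "III"
    return "IV"


def class_distribution(records: Sequence[OvaryRecord], line: str,
                       ) -> tuple[dict[str, float], int]:
    """Percent of ovaries per class for one line, plus n."""
    sub = [r for r in records if r.line == line]
    if not sub:
        raise ValueError(f"no records for line {line!r}")
    n = len(sub)
    counts = {k: 0 for k in CLASSES}
    for r in sub:
        counts[r.fecundity_class] += 1
    return {k: 100.0 * v / n for k, v in counts.items()}, n


def _class_counts(records: Sequence[OvaryRecord]) -> list[int]:
    counts = {k: 0 for k in CLASSES}
    for r in records:
        counts[r.fecundity_class] += 1
    return [counts[k] for k in CLASSES]


def _fisher_2xk(row_a: Sequence[int], row_b: Sequence[int]) -> float:
    """Two-tailed Fisher exact p for a 2xk table by full enumeration.

    Enumerates every table with the observed margins; p is the total
    probability of tables no more probable than the observed one.
    """
    cols = [a + b for a, b in zip(row_a, row_b)]
    n_a = sum(row_a)
    n = n_a + sum(row_b)
    lf = [math.lgamma(i + 1) for i in range(n + 1)]

    def log_weight(row):
        # product of per-column binomials (row-conditional hypergeometric)
        w = 0.0
        for x, c in zip(row, cols):
            w += lf[c] - lf[x] - lf[c - x]
        return w

    log_denom = lf[n] - lf[n_a] - lf[n - n_a]
    obs = log_weight(row_a) - log_denom
    p = 0.0
    ranges = [range(0, min(c, n_a) + 1) for c in cols[:-1]]
    for head in product(*ranges):
        last = n_a - sum(head)
        if not 0 <= last <= cols[-1]:
            continue
        lw = log_weight(list(head) + [last]) - log_denom
        if lw <= obs + 1e-9:
            p += math.exp(lw)
    return min(p, 1.0)


def compare_fecundity(records_a: Sequence[OvaryRecord],
                      records_b: Sequence[OvaryRecord],
                      mode: str = "classIV") -> ContingencyResult:
    """Compare two lines' fecundity class distributions.

    ``classIV`` collapses to class IV vs not (2x2 Fisher exact); ``full``
    runs the exact test on the complete 2x4 class table.
    """
    if not records_a or not records_b:
        raise ValueError("both record sets must be non-empty")
    ca = _class_counts(records_a)
    cb = _class_counts(records_b)
    if mode == "classIV":
        table = [[ca[3], sum(ca) - ca[3]], [cb[3], sum(cb) - cb[3]]]
        return fisher_exact(table)
    if mode == "full":
        p = _fisher_2xk(ca, cb)
        return ContingencyResult(table=(tuple(ca), tuple(cb)),
                                 statistic=float("nan"), p_two_tailed=p,
                                 method="fisher_exact")
    raise ValueError(f"unknown mode {mode!r}")
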