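"""Per-group SNP frequencies and between-group contingency tests.

Frequencies are SNP occurrences per kilobase of sequenced clone bases;
baseline-corrected values subtract a polymerase-error baseline and may go
negative.  Group comparisons build a 2x2 table of base counts — SNP
occurrences vs non-variant bases — the construction under which the
published P values are recovered, and apply either a chi-square test with
Yates continuity correction or Fisher's exact test (two-tailed).

Display rounding is half-up to 2 decimals; all statistics run on unrounded
values.  No multiple-testing correction is applied; callers are told how
many tests they ran.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import hypergeom


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.005 -> 0.01), unlike bankers' rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FrequencyRecord:
    """SNP occurrences over sequenced bases for one group, as rate per kb."""

    group_label: str
    n_snp_occurrences: int
    n_bases: int

    def __post_init__(self):
        if self.n_bases <= 0:
            raise ValueError("n_bases must be > 0")
        if self.n_snp_occurrences < 0:
            raise ValueError("n_snp_occurrences must be >= 0")

    @property
    def rate_per_kb(self) -> float:
        return 1000.0 * self.n_snp_occurrences / self.n_bases

    @property
    def display_rate(self) -> float:
        return round_half_up(self.rate_per_kb, 2)

    def corrected(self, baseline: float) -> float:
        return corrected_frequency(self.rate_per_kb, baseline)


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 test outcome; ``p_two_tailed`` always in [0, 1]."""

    table: tuple
    statistic: float
    p_two_tailed: float
    method: str

    def __post_init__(self):
        if not 0.0 <= self.p_two_tailed <= 1.0:
            raise ValueError("p outside [0, 1]")


def snp_frequency(n: int, L: int, label: str = "") -> FrequencyRecord:
    """Per-kb SNP frequency record from ``n`` occurrences in ``L`` bases."""
    return FrequencyRecord(group_label=label, n_snp_occurrences=n, n_bases=L)


def corrected_frequency(rate: float, baseline: float) -> float:
    """Baseline-corrected per-kb rate; unclamped, negatives allowed."""
    if baseline < 0:
        raise ValueError("baseline must be >= 0")
    return rate - baseline


def fold_over_baseline(rate: float, baseline: float) -> float:
    """How many times the observed rate exceeds the error baseline."""
    if baseline <= 0:
        raise ValueError("baseline must be > 0 for a fold change")
    return rate / baseline


def infer_snp_count(printed_rate: float, n_bases: int,
                    n_max: int = 1000) -> int:
    """Unique occurrence count consistent with a printed 2-decimal rate.

    Returns the only integer ``n`` with ``round_half_up(1000 n / L, 2)``
    equal to ``printed_rate``; no or multiple candidates is a hard error.
    """
    candidates = [n for n in range(min(n_max, n_bases) + 1)
                  if round_half_up(1000.0 * n / n_bases, 2) == printed_rate]
    if len(candidates) != 1:
        raise ValueError(
            f"rate {printed_rate}/kb over {n_bases} bases matches "
            f"{len(candidates)} integer counts: {candidates}")
    return candidates[0]


def _as_2x2(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 non-negative integers")
    return t


def chi2_yates(table) -> ContingencyResult:
    """Chi-square test with Yates continuity correction on a 2x2 table.

    statistic = sum((|O - E| - 0.5)^2 / E), the continuity term floored at 0
    where |O - E| < 0.5; p is the upper tail of chi-square with 1 df
    (two-tailed by construction).  A zero margin yields p = 1 with a warning.
    """
    t = _as_2x2(table)
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    total = t.sum()
    if total == 0 or (row == 0).any() or (col == 0).any():
        warnings.warn("degenerate 2x2 table (zero margin); p set to 1",
                      stacklevel=2)
        return ContingencyResult(table=tuple(map(tuple, t.astype(int))),
                                 statistic=0.0, p_two_tailed=1.0,
                                 method="chi2_yates")
    expected = np.outer(row, col) / total
    adj = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    stat = float((adj ** 2 / expected).sum())
    p = float(chi2_dist.sf(stat, df=1))
    return ContingencyResult(table=tuple(map(tuple, t.astype(int))),
                             statistic=stat, p_two_tailed=min(p, 1.0),
                             method="chi2_yates")


def fisher_exact(table) -> ContingencyResult:
    """Two-tailed Fisher exact test on a 2x2 table by full enumeration.

    Sums hypergeometric probabilities of all tables (margins fixed) whose
    probability does not exceed the observed table's, with a small relative
    slack for floating-point ties.
    """
    t = _as_2x2(table).astype(int)
    a = t[0, 0]
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    n = int(t.sum())
    if n == 0:
        warnings.warn("empty 2x2 table; p set to 1", stacklevel=2)
        return ContingencyResult(table=tuple(map(tuple, t)), statistic=1.0,
                                 p_two_tailed=1.0, method="fisher_exact")
    kmin = max(0, r1 + c1 - n)
    kmax = min(r1, c1)
    support = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = float(hypergeom.pmf(a, n, c1, r1))
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    odds = math.inf
    if t[0, 1] * t[1, 0] > 0:
        odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return ContingencyResult(table=tuple(map(tuple, t)), statistic=odds,
                             p_two_tailed=min(p, 1.0), method="fisher_exact")


def compare_groups(rec_a: FrequencyRecord, rec_b: FrequencyRecord,
                   method: str = "chi2_yates") -> ContingencyResult:
    """Compare two groups' SNP rates on the base-count contingency table.

    Builds ``[[n_A, L_A - n_A], [n_B, L_B - n_B]]`` and applies the chosen
    test (``chi2_yates`` or ``fisher_exact``).
    """
    table = [[rec_a.n_snp_occurrences,
              rec_a.n_bases - rec_a.n_snp_occurrences],
             [rec_b.n_snp_occurrences,
              rec_b.n_bases - rec_b.n_snp_occurrences]]
    if method == "chi2_yates":
        return chi2_yates(table)
    if method == "fisher_exact":
        return fisher_exact(table)
    raise ValueError(f"unknown method {method!r}")
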