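"""Polymerase/cloning error baselines from control re-sequencing sets.

Re-PCR and re-sequencing of fragments of known sequence yields control sets
in which every observed substitution is an artefact of the lumped
PCR + cloning + sequencing process.  Pooling controls gives a per-kilobase
error rate used to correct observed SNP frequencies.

Two baselines coexist deliberately: the pooled estimate from the printed
control counts (0.15/kb) and the constant 0.28/kb used for the corrected
frequency columns of the published table; the correction step takes the
baseline as an explicit parameter (default 0.28) because the source never
reconciles the two numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from scipy.stats import beta

from symbiopoly.polymorphism_stats import round_half_up

#: Published mean error estimate for standard non-proof-reading Taq (per kb).
PUBLISHED_TAQ_RATE = 0.21
#: Constant baseline used in the corrected-frequency columns (per kb).
TABLE_FOOTNOTE_RATE = 0.28


@dataclass(frozen=True)
class ControlSet:
    """One control re-sequencing batch: known fragments, counted artefacts."""

    gene: str
    n_clones: int
    clone_length: int
    n_error_snps: int

    def __post_init__(self):
        if self.n_clones < 0 or self.clone_length <= 0:
            raise ValueError("need n_clones >= 0 and clone_length > 0")
        if not 0 <= self.n_error_snps <= self.n_clones * self.clone_length:
            raise ValueError("n_error_snps outside [0, n_clones * length]")

    @property
    def n_bases(self) -> int:
        return self.n_clones * self.clone_length


@dataclass(frozen=True)
class Baseline:
    """A per-kb error rate; ``rate_per_kb`` is the raw (unrounded) value."""

    rate_per_kb: float
    source: str = "estimated"

    def __post_init__(self):
        if self.rate_per_kb < 0:
            raise ValueError("rate must be >= 0")

    @property
    def display(self) -> float:
        """Rate rounded half-up to 2 decimals, as printed."""
        return round_half_up(self.rate_per_kb, 2)


#: The printed control batches: 0 errors in 10x444 bp of coxA, 0 in 10x290 bp
#: of ftsZ, 2 in 14x429 bp of gatB — pooling to 0.15/kb.
PRINTED_CONTROLS = (
    ControlSet("coxA", 10, 444, 0),
    ControlSet("ftsZ", 10, 290, 0),
    ControlSet("gatB", 14, 429, 2),
)


def pooled_error_rate(controls: Iterable[ControlSet]) -> Baseline:
    """Pooled per-kb error rate: 1000 * total errors / total bases."""
    controls = list(controls)
    total_bases = sum(c.n_bases for c in controls)
    if total_bases <= 0:
        raise ValueError("zero total bases in controls")
    total_errors = sum(c.n_error_snps for c in controls)
    return Baseline(rate_per_kb=1000.0 * total_errors / total_bases,
                    source="estimated")


def error_ci(controls: Iterable[ControlSet], level: float = 0.95,
             ) -> tuple[float, float]:
    """Clopper-Pearson interval on the per-base error probability, per kb.

    The exact binomial interval: lower bound 0 at zero observed errors.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    controls = list(controls)
    n = sum(c.n_bases for c in controls)
    if n <= 0:
        raise ValueError("zero total bases in controls")
    k = sum(c.n_error_snps for c in controls)
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else beta.ppf(1 - alpha / 2, k + 1, n - k)
    return 1000.0 * lo, 1000.0 * hi
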