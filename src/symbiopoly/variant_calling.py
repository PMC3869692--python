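"""Call clone substitutions against the strain consensus; classify recurrence.

A variant call is one (clone, position) where the read carries an unambiguous
base differing from the consensus.  Positions where a read shows an IUPAC
ambiguity code are skipped (and logged): ambiguous peaks cannot be told apart
from sequencing artefacts without the chromatogram, so they are excluded the
same way visually unconfirmed SNPs were.

Recurrence is counted over distinct clones: a (position, alternate) seen in
two or more independent clones — regardless of whether those clones share a
host line — is *recurrent*; seen in exactly one clone it is a *singleton*.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from symbiopoly.amplicon_io import AmpliconSet, SampleMeta, STRICT_BASES

logger = logging.getLogger("symbiopoly")


@dataclass(frozen=True)
class VariantCall:
    """A single-clone substitution against the consensus (1-based position)."""

    clone_id: str
    line: str
    gene: str
    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self):
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt must differ")
        if self.ref_base not in STRICT_BASES or self.alt_base not in STRICT_BASES:
            raise ValueError("ref/alt must be unambiguous A/C/G/T")
        if self.position < 1:
            raise ValueError("position is 1-based")


@dataclass
class RecurrenceClass:
    """Occurrence tally for one (position, alternate) variant identity."""

    position: int
    alt_base: str
    n_occurrences: int
    contexts: set = field(default_factory=set)
    clone_ids: set = field(default_factory=set)

    @property
    def recurrence_class(self) -> str:
        return "recurrent" if self.n_occurrences >= 2 else "singleton"


def call_snps(amplicons: AmpliconSet,
              meta: Optional[Mapping[str, SampleMeta]] = None,
              ) -> list[VariantCall]:
    """One call per (clone, position) where the read differs from consensus.

    ``meta`` maps clone ids to :class:`SampleMeta`; clones without metadata
    get line ``"NA"``.  Ambiguity-coded read positions yield no call.
    """
    consensus = amplicons.consensus
    calls: list[VariantCall] = []
    n_ambiguous = 0
    for clone_id, seq in amplicons.reads:
        line = meta[clone_id].line if meta and clone_id in meta else "NA"
        for i, (ref, obs) in enumerate(zip(consensus, seq)):
            if obs == ref:
                continue
            if obs not in STRICT_BASES:
                n_ambiguous += 1
                logger.debug("clone %s: ambiguity code %s at position %d "
                             "excluded", clone_id, obs, i + 1)
                continue
            calls.append(VariantCall(clone_id=clone_id, line=line,
                                     gene=amplicons.gene, position=i + 1,
                                     ref_base=ref, alt_base=obs))
    if n_ambiguous:
        logger.info("excluded %d ambiguity-coded positions from calling",
                    n_ambiguous)
    return calls


def classify_recurrence(calls: Iterable[VariantCall]) -> list[RecurrenceClass]:
    """Group calls by (position, alternate) and tally distinct clones.

    Duplicate calls from the same clone are counted once.  Two different
    alternates at the same position are distinct variant identities.
    """
    groups: dict[tuple[int, str], RecurrenceClass] = {}
    for c in calls:
        key = (c.position, c.alt_base)
        rc = groups.get(key)
        if rc is None:
            rc = groups[key] = RecurrenceClass(position=c.position,
                                               alt_base=c.alt_base,
                                               n_occurrences=0)
        if c.clone_id not in rc.clone_ids:
            rc.clone_ids.add(c.clone_id)
            rc.n_occurrences += 1
        rc.contexts.add(c.line)
    return sorted(groups.values(), key=lambda r: (r.position, r.alt_base))


def summarize_recurrence(classes: Sequence[RecurrenceClass],
                         ) -> tuple[int, int, dict[str, int]]:
    """(n_recurrent, n_singleton, integer percentages) over variant identities."""
    if not classes:
        raise ValueError("empty classification")
    n_rec = sum(1 for r in classes if r.recurrence_class == "recurrent")
    n_sing = len(classes) - n_rec
    total = len(classes)
    pct = {"recurrent": int(round(100 * n_rec / total)),
           "singleton": int(round(100 * n_sing / total))}
    return n_rec, n_sing, pct


def annotate_calls(calls: Sequence[VariantCall],
                   classes: Sequence[RecurrenceClass]) -> list:
    """Return call-like records carrying their recurrence class (for output)."""
    lookup = {(r.position, r.alt_base): r.recurrence_class for r in classes}

    class _Annotated:
        __slots__ = ("clone_id", "line", "gene", "position", "ref_base",
                     "alt_base", "recurrence_class")

        def __init__(self, c: VariantCall, klass: str):
            for f in ("clone_id", "line", "gene", "position", "ref_base",
                      "alt_base"):
                setattr(self, f, getattr(c, f))
            self.recurrence_class = klass

    return [_Annotated(c, lookup.get((c.position, c.alt_base), "NA"))
            for c in calls]
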