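"""In-silico restriction digest and probe-hybridization fragment counts.

Predicts the restriction-fragment fingerprint a Southern hybridization
would show: cut a (circular or linear) genome at every occurrence of an
enzyme recognition site (HindIII's A^AGCTT by default) and count the
fragments that overlap a probe locus by enough bases to light up.

Coordinates are 1-based inclusive.  On a circular genome the fragment
spanning the origin is represented with ``start > end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

HINDIII_SITE = "AAGCTT"


@dataclass(frozen=True)
class Fragment:
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive; end < start means origin-spanning
    length: int


@dataclass
class DigestResult:
    """Non-overlapping covering fragments of one digested genome."""

    fragments: list = field(default_factory=list)
    topology: str = "circular"
    genome_length: int = 0

    def __post_init__(self):
        if self.topology not in ("circular", "linear"):
            raise ValueError("topology must be circular or linear")
        total = sum(f.length for f in self.fragments)
        if total != self.genome_length:
            raise ValueError(f"fragment lengths sum to {total}, genome is "
                             f"{self.genome_length}")


@dataclass
class ProbeLocus:
    """Named probe with one or more genomic occurrence intervals."""

    name: str
    intervals: list  # list of (start, end), 1-based inclusive

    def __post_init__(self):
        for s, e in self.intervals:
            if s < 1 or e < s:
                raise ValueError(f"bad interval ({s}, {e})")


def _find_sites(sequence: str, site: str, circular: bool) -> list[int]:
    """0-based start offsets of site occurrences (wrapping when circular)."""
    n = len(sequence)
    haystack = sequence + (sequence[:len(site) - 1] if circular else "")
    hits = []
    i = haystack.find(site)
    while i != -1:
        if i < n:
            hits.append(i)
        i = haystack.find(site, i + 1)
    return hits


def digest(sequence: str, site: str = HINDIII_SITE,
           topology: str = "circular", cut_offset: int = 1) -> DigestResult:
    """Digest a genome at every recognition-site occurrence.

    ``cut_offset`` is the number of site bases left of the cut (1 mirrors
    HindIII's A^AGCTT).  A circular genome with no site yields one
    full-length fragment; so does a linear one.
    """
    sequence = sequence.upper()
    site = site.upper()
    if not sequence:
        raise ValueError("empty sequence")
    if len(site) < 4:
        raise ValueError("recognition site must be >= 4 bp")
    if not 0 <= cut_offset <= len(site):
        raise ValueError("cut_offset outside the recognition site")
    n = len(sequence)
    circular = topology == "circular"
    # cut points: 1-based position of the first base AFTER the cut
    cuts = sorted({(i + cut_offset) % n + 1 for i in
                   _find_sites(sequence, site, circular)})
    frags: list[Fragment] = []
    if not cuts:
        frags.append(Fragment(1, n, n))
    elif circular:
        for a, b in zip(cuts, cuts[1:] + [cuts[0]]):
            if a < b:
                frags.append(Fragment(a, b - 1, b - a))
            else:  # wraps the origin
                frags.append(Fragment(a, (b - 1) % n if b > 1 else n,
                                      n - a + b))
    else:
        bounds = [1] + cuts + [n + 1]
        for a, b in zip(bounds, bounds[1:]):
            if b > a:
                frags.append(Fragment(a, b - 1, b - a))
    return DigestResult(fragments=frags, topology=topology, genome_length=n)


def _fragment_intervals(f: Fragment, n: int) -> list[tuple[int, int]]:
    if f.end >= f.start:
        return [(f.start, f.end)]
    return [(f.start, n), (1, f.end)]


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def probe_fragment_count(result: DigestResult, probe: ProbeLocus,
                         min_overlap: int = 20) -> int:
    """Fragments overlapping any probe interval by >= ``min_overlap`` bp.

    ``min_overlap`` approximates hybridization detectability and is a
    modelling choice, not a wet-lab constant.
    """
    n = result.genome_length
    for s, e in probe.intervals:
        if e > n:
            raise ValueError(f"probe interval ({s}, {e}) beyond genome "
                             f"length {n}")
    count = 0
    for f in result.fragments:
        pieces = _fragment_intervals(f, n)
        total = 0
        for iv in probe.intervals:
            total += sum(_overlap(piece, iv) for piece in pieces)
        if total >= min_overlap:
            count += 1
    return count


def rotate_genome(sequence: str, k: int) -> str:
    """Rotate a circular genome so old position k+1 becomes position 1."""
    k %= len(sequence)
    return sequence[k:] + sequence[:k]
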