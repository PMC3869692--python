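"""Strain assignment from diagnostic sites, co-infection and switch detection.

A diagnostic profile lists sequence positions whose base differs between
strains (e.g. wCer1 vs wCer2 on a wsp fragment) and/or strain-specific
amplicon lengths for a length-polymorphic tandem-repeat marker (VNTR).
Clone reads are typed by the fraction of diagnostic sites matching each
strain; ties and sub-threshold matches are never assigned, they are
``unknown``.

The true diagnostic sequences of the biological system are not public;
:func:`make_synthetic_profile` builds a clearly labelled synthetic stand-in
with the same logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np


@dataclass
class DiagnosticProfile:
    """Strain-discriminating sites and/or amplicon lengths for one marker.

    ``sites`` is a list of ``(position, {strain: base})``; every site must
    discriminate at least two strains.  ``lengths`` maps strains to expected
    amplicon lengths for length-polymorphic markers.
    """

    marker: str
    sites: list = field(default_factory=list)
    lengths: dict = field(default_factory=dict)

    def __post_init__(self):
        for pos, by_strain in self.sites:
            if len(set(by_strain.values())) < 2:
                raise ValueError(f"site {pos} does not discriminate strains")
        if not self.sites and not self.lengths:
            raise ValueError("profile needs sites or lengths")

    @property
    def strains(self) -> list[str]:
        out: set[str] = set()
        for _, by_strain in self.sites:
            out |= set(by_strain)
        out |= set(self.lengths)
        return sorted(out)


@dataclass(frozen=True)
class StrainCall:
    """Typing outcome for one read/sample: best strain or ``unknown``."""

    sample_id: str
    strain: str
    confidence: float
    evidence: tuple = ()

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence outside [0, 1]")


@dataclass
class PrevalenceSeries:
    """Detected strain sets over host generations for one line."""

    line: str
    observations: list  # list of (generation, set of strains)

    def __post_init__(self):
        gens = [g for g, _ in self.observations]
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise ValueError("generations must be strictly increasing")


def type_clone(read: str, profile: DiagnosticProfile,
               sample_id: str = "", threshold: float = 0.9) -> StrainCall:
    """Type a read by its match fraction over the profile's diagnostic sites.

    The call is the unique argmax strain if its score reaches ``threshold``;
    ties or sub-threshold best matches give ``unknown``.
    """
    if not profile.sites:
        raise ValueError("profile has no sequence sites")
    max_pos = max(pos for pos, _ in profile.sites)
    if len(read) < max_pos:
        raise ValueError(f"read length {len(read)} < max site position "
                         f"{max_pos}")
    read = read.upper()
    scores: dict[str, float] = {}
    evidence: dict[str, list[int]] = {}
    for strain in profile.strains:
        sites = [(pos, by) for pos, by in profile.sites if strain in by]
        if not sites:
            continue
        matched = [pos for pos, by in sites if read[pos - 1] == by[strain]]
        scores[strain] = len(matched) / len(sites)
        evidence[strain] = matched
    best = max(scores.values())
    winners = [s for s, v in scores.items() if v == best]
    if len(winners) == 1 and best >= threshold:
        w = winners[0]
        return StrainCall(sample_id=sample_id, strain=w, confidence=best,
                          evidence=tuple(evidence[w]))
    return StrainCall(sample_id=sample_id, strain="unknown", confidence=best)


def type_by_length(observed_length: int, profile: DiagnosticProfile,
                   sample_id: str = "", tolerance: int = 2) -> StrainCall:
    """Type a length-polymorphic (tandem-repeat) amplicon by its size.

    Mirrors gel-based VNTR discrimination: the call is the unique strain
    whose expected length lies within ``tolerance`` bp; ties are unknown.
    """
    if not profile.lengths:
        raise ValueError("profile has no length table")
    hits = [(abs(observed_length - l), s)
            for s, l in profile.lengths.items()
            if abs(observed_length - l) <= tolerance]
    if not hits:
        return StrainCall(sample_id=sample_id, strain="unknown",
                          confidence=0.0)
    hits.sort()
    best = [s for d, s in hits if d == hits[0][0]]
    if len(best) > 1:
        return StrainCall(sample_id=sample_id, strain="unknown",
                          confidence=0.0)
    return StrainCall(sample_id=sample_id, strain=best[0], confidence=1.0,
                      evidence=(observed_length,))


def detect_coinfection(calls: Sequence[StrainCall],
                       min_reads: int = 1) -> tuple[str, frozenset]:
    """Infection status from per-read strain calls.

    Returns ``("multiple", strains)`` when two or more distinct non-unknown
    strains each have at least ``min_reads`` supporting calls,
    ``("single", {strain})`` for exactly one, ``("none", {})`` otherwise.
    """
    if not calls:
        raise ValueError("no calls")
    counts: dict[str, int] = {}
    for c in calls:
        if c.strain != "unknown":
            counts[c.strain] = counts.get(c.strain, 0) + 1
    supported = frozenset(s for s, k in counts.items() if k >= min_reads)
    if len(supported) >= 2:
        return "multiple", supported
    if len(supported) == 1:
        return "single", supported
    return "none", frozenset()


def locate_switch(series: PrevalenceSeries, from_strain: str,
                  to_strain: str) -> Optional[tuple[int, int]]:
    """Bracket a prevalence switch between two strains.

    Returns ``(g_last_from, g_first_to_only)``: the last generation at which
    ``from_strain`` was detected, and the first generation at which
    ``to_strain`` was detected without ``from_strain`` — provided that
    transition generation follows the last ``from`` detection pattern
    coherently.  ``None`` when no switch occurred.
    """
    if len(series.observations) < 2:
        raise ValueError("need at least two observations")
    from_gens = [g for g, s in series.observations if from_strain in s]
    to_only = [g for g, s in series.observations
               if to_strain in s and from_strain not in s]
    if not from_gens or not to_only:
        return None
    g_last_from = max(g for g in from_gens if g < min(to_only))
    g_first_to_only = min(to_only)
    if g_first_to_only <= g_last_from:
        return None
    return g_last_from, g_first_to_only


def detection_power(titer_fraction: float, n_reads: int,
                    error_rate: float, profile: DiagnosticProfile,
                    n_reps: int = 1000, seed: int = 0,
                    min_reads: int = 1, threshold: float = 0.9,
                    ) -> tuple[float, float]:
    """Monte-Carlo probability of detecting a minor strain by clone typing.

    Simulates ``n_reads`` clones per replicate, each from the minor strain
    with probability ``titer_fraction``, applies per-site sequencing error
    at ``error_rate``, types every read against ``profile`` and declares
    detection when the minor strain collects ``min_reads`` calls.  Returns
    ``(power, mc_standard_error)``.
    """
    if not 0.0 <= titer_fraction <= 1.0:
        raise ValueError("titer_fraction outside [0, 1]")
    strains = profile.strains
    if len(strains) < 2:
        raise ValueError("need a two-strain profile")
    minor, major = strains[0], strains[1]
    rng = np.random.default_rng(seed)
    sites = [(pos, by) for pos, by in profile.sites]
    max_pos = max(pos for pos, _ in sites)
    detected = 0
    others = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
    for _ in range(n_reps):
        is_minor = rng.random(n_reads) < titer_fraction
        n_minor_calls = 0
        for im in is_minor:
            strain = minor if im else major
            read = ["A"] * max_pos
            for pos, by in sites:
                read[pos - 1] = by[strain]
            if error_rate > 0:
                errs = rng.random(max_pos) < error_rate
                for i in np.flatnonzero(errs):
                    read[i] = others[read[i]][rng.integers(3)]
            call = type_clone("".join(read), profile, threshold=threshold)
            if call.strain == minor:
                n_minor_calls += 1
        if n_minor_calls >= min_reads:
            detected += 1
    power = detected / n_reps
    se = float(np.sqrt(power * (1 - power) / n_reps))
    return power, se


def make_synthetic_profile(seed: int = 0, n_sites: int = 4,
                           fragment_length: int = 36,
                           strains: Iterable[str] = ("wCer1", "wCer2"),
                           ) -> DiagnosticProfile:
    """A SYNTHETIC diagnostic profile (stand-in; real sites are not public).

    Draws ``n_sites`` distinct positions on a short fragment and assigns
    each strain a distinct base at every site.
    """
    rng = np.random.default_rng(seed)
    strains = list(strains)
    positions = sorted(rng.choice(np.arange(1, fragment_length + 1),
                                  size=n_sites, replace=False).tolist())
    sites = []
    for pos in positions:
        bases = rng.permutation(list("ACGT"))[:len(strains)]
        sites.append((int(pos), dict(zip(strains, bases))))
    return DiagnosticProfile(marker="wsp-synthetic", sites=sites)
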