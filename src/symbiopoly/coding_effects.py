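"""Codon mapping, stop-codon annotation and Nei-Gojobori (1986) dN/dS.

The MLST fragments are internal pieces of protein-coding genes; with frame
offset 0 every fragment starts on a codon boundary and a trailing incomplete
codon (e.g. the last base of a 478-bp fragment) is flagged and excluded from
codon-level analyses.

dN/dS follows the NG86 path-counting method: potential synonymous and
nonsynonymous sites are counted fractionally per codon (each position
contributes the fraction of its three possible changes that are synonymous;
changes creating a stop codon count as nonsynonymous so that sites per codon
always sum to 3); observed differences in multi-hit codons are averaged over
all equally weighted mutational orderings, excluding orderings that pass
through a premature stop unless no stop-free ordering exists; proportions
are corrected for multiple hits with the Jukes-Cantor formula
``d = -3/4 ln(1 - 4/3 p)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Optional

from Bio.Data import CodonTable

from symbiopoly.amplicon_io import AmpliconSet, STRICT_BASES

#: Bacterial/plastid genetic code; same stop set as the standard code.
DEFAULT_CODE_ID = 11

_TABLE = CodonTable.unambiguous_dna_by_id[DEFAULT_CODE_ID]
STOP_CODONS = set(_TABLE.stop_codons)
STOP_CLASS = {"TAA": "ochre", "TAG": "amber", "TGA": "opal"}


def translate_codon(codon: str) -> str:
    """One-letter amino acid, '*' for a stop (bacterial code)."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        return "*"
    return _TABLE.forward_table[codon]


@dataclass(frozen=True)
class FrameSpec:
    """Reading-frame anchor for a fragment: bases to skip before codon 1."""

    gene: str = "gatB"
    frame_offset: int = 0
    genetic_code: int = DEFAULT_CODE_ID

    def __post_init__(self):
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")


@dataclass(frozen=True)
class CodonEffect:
    """Effect of one substitution on its codon."""

    position: int
    codon_index: int
    codon_pos: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect: str           # synonymous | nonsynonymous | nonsense
    stop_class: str       # ochre | amber | opal | none
    clone_id: str = ""
    line: str = ""
    gene: str = ""


@dataclass(frozen=True)
class DnDsResult:
    """NG86 site/difference counts and Jukes-Cantor corrected rates."""

    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    ratio: Optional[float]    # dN/dS; None when dS == 0 (undefined)
    n_codons_compared: int


def map_codon(position: int, frame: FrameSpec, fragment_length: int,
              ) -> tuple[int, int]:
    """(codon_index, codon_pos), both 1-based, for a fragment position.

    Raises on positions before the first complete codon; positions inside a
    trailing incomplete codon raise ``ValueError`` so callers can exclude
    them from codon-level analysis.
    """
    off = frame.frame_offset
    if not 1 <= position <= fragment_length:
        raise ValueError(f"position {position} outside fragment "
                         f"1..{fragment_length}")
    if position <= off:
        raise ValueError(f"position {position} precedes the first complete "
                         f"codon (offset {off})")
    codon_index = math.ceil((position - off) / 3)
    codon_pos = (position - off - 1) % 3 + 1
    last_complete = (fragment_length - off) // 3
    if codon_index > last_complete:
        raise ValueError(f"position {position} lies in a trailing incomplete "
                         "codon")
    return codon_index, codon_pos


def classify_substitution(ref_codon: str, alt_codon: str,
                          position: int = 0, codon_index: int = 0,
                          codon_pos: int = 0, **context) -> CodonEffect:
    """Annotate a codon change as synonymous / nonsynonymous / nonsense."""
    ref_codon = ref_codon.upper()
    alt_codon = alt_codon.upper()
    if ref_codon == alt_codon:
        raise ValueError("codons are identical")
    for c in (ref_codon, alt_codon):
        if len(c) != 3 or set(c) - STRICT_BASES:
            raise ValueError(f"invalid codon {c!r}")
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if alt_codon in STOP_CODONS and ref_codon not in STOP_CODONS:
        effect = "nonsense"
        stop_class = STOP_CLASS[alt_codon]
    elif ref_aa == alt_aa:
        effect, stop_class = "synonymous", "none"
    else:
        effect, stop_class = "nonsynonymous", "none"
    return CodonEffect(position=position, codon_index=codon_index,
                       codon_pos=codon_pos, ref_codon=ref_codon,
                       alt_codon=alt_codon, ref_aa=ref_aa, alt_aa=alt_aa,
                       effect=effect, stop_class=stop_class, **context)


def scan_premature_stops(amplicons: AmpliconSet,
                         frame: Optional[FrameSpec] = None,
                         meta=None) -> list[CodonEffect]:
    """Premature stop codons in clone reads (consensus codon is not a stop).

    One record per (clone, codon) whose read codon is a stop; codons with
    ambiguity codes are skipped.
    """
    if frame is None:
        frame = FrameSpec(gene=amplicons.gene)
    off = frame.frame_offset
    length = amplicons.expected_length
    n_codons = (length - off) // 3
    consensus = amplicons.consensus
    out: list[CodonEffect] = []
    for clone_id, seq in amplicons.reads:
        line = meta[clone_id].line if meta and clone_id in meta else "NA"
        for ci in range(n_codons):
            start = off + 3 * ci
            ref = consensus[start:start + 3]
            obs = seq[start:start + 3]
            if obs == ref or set(obs) - STRICT_BASES:
                continue
            if obs in STOP_CODONS and ref not in STOP_CODONS:
                diff = next(i for i in range(3) if obs[i] != ref[i])
                out.append(classify_substitution(
                    ref, obs, position=start + diff + 1, codon_index=ci + 1,
                    codon_pos=diff + 1, clone_id=clone_id, line=line,
                    gene=amplicons.gene))
    return out


def _syn_fraction(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) potential sites of one codon (sum 3)."""
    aa = translate_codon(codon)
    syn = 0.0
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1:]
            # changes creating a stop count as nonsynonymous
            if mut not in STOP_CODONS and translate_codon(mut) == aa:
                syn += 1.0
    return syn / 3.0, 3.0 - syn / 3.0


def _path_differences(c1: str, c2: str) -> tuple[float, float, bool]:
    """Mean (Sd, Nd) over equally weighted mutational orderings c1 -> c2.

    Orderings passing through a stop codon are dropped when a stop-free
    ordering exists; otherwise all orderings are used and the third return
    value flags that a stop could not be avoided.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths = []
    for order in permutations(diff):
        cur = c1
        steps = []
        through_stop = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            steps.append((cur, nxt))
            if nxt in STOP_CODONS:
                through_stop = True
            cur = nxt
        paths.append((steps, through_stop))
    usable = [p for p, ts in paths if not ts]
    stop_unavoidable = not usable
    if stop_unavoidable:
        usable = [p for p, _ in paths]
    sd = nd = 0.0
    for steps in usable:
        for a, b in steps:
            if translate_codon(a) == translate_codon(b):
                sd += 1.0
            else:
                nd += 1.0
    k = len(usable)
    return sd / k, nd / k, stop_unavoidable


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.inf
    if p <= 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_dnds(seq_a: str, seq_b: str,
              frame: Optional[FrameSpec] = None) -> DnDsResult:
    """NG86 pairwise dN/dS between two equal-length in-frame sequences.

    Codons containing ambiguity codes or gaps in either sequence are skipped
    pairwise; the trailing incomplete codon is ignored.  ``ratio`` is None
    (undefined) when dS = 0.
    """
    if frame is None:
        frame = FrameSpec()
    seq_a = seq_a.upper()
    seq_b = seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    off = frame.frame_offset
    n_codons = (len(seq_a) - off) // 3
    S = N = Sd = Nd = 0.0
    n_compared = 0
    any_stop_unavoidable = False
    for ci in range(n_codons):
        start = off + 3 * ci
        ca = seq_a[start:start + 3]
        cb = seq_b[start:start + 3]
        if (set(ca) | set(cb)) - STRICT_BASES:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            # terminal/aberrant stop codons carry no rate information
            continue
        n_compared += 1
        sa, na = _syn_fraction(ca)
        sb, nb = _syn_fraction(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        if ca != cb:
            sd, nd, flagged = _path_differences(ca, cb)
            Sd += sd
            Nd += nd
            any_stop_unavoidable = any_stop_unavoidable or flagged
    if any_stop_unavoidable:
        warnings.warn("no stop-free mutational path for at least one codon "
                      "pair; stop-containing paths included", stacklevel=2)
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jukes_cantor(pS)
    dN = _jukes_cantor(pN)
    ratio = None if dS == 0.0 or math.isinf(dS) else dN / dS
    return DnDsResult(S_sites=S, N_sites=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
                      dS=dS, dN=dN, ratio=ratio, n_codons_compared=n_compared)


def mean_pairwise_dnds(amplicons: AmpliconSet,
                       frame: Optional[FrameSpec] = None,
                       ) -> tuple[Optional[float], list[DnDsResult]]:
    """dN/dS of each clone vs the consensus; mean of the defined ratios.

    Pairs with undefined ratio (dS = 0, including identical pairs) are
    dropped from the mean; all pairwise results are returned.
    """
    results = [ng86_dnds(amplicons.consensus, seq, frame)
               for _, seq in amplicons.reads]
    defined = [r.ratio for r in results if r.ratio is not None]
    mean = sum(defined) / len(defined) if defined else None
    return mean, results
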