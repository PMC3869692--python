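"""Packaged fixtures: the published variable-position and stop-codon tables.

The variant matrices of the source MLST survey are public, but the full
amplicon sequences are not; fixtures therefore apply the published
substitutions to an arbitrary, deterministically generated background
consensus.  Every downstream quantity the package reproduces (positions,
occurrence counts, per-kb frequencies, stop-codon classes) depends only on
the substitutions, never on the background sequence.

Known internal inconsistencies of the published tables are preserved, not
resolved, and are listed in :data:`KNOWN_INCONSISTENCIES`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from symbiopoly.amplicon_io import AmpliconSet, SampleMeta, GENE_LENGTHS

# Background-sequence generator seed; fixed so fixtures are versioned content.
_FIXTURE_SEED = 20131220

STOP_CODONS = {"TAA": "ochre", "TAG": "amber", "TGA": "opal"}

#: gatB variable positions: (position, consensus base, {line: alt}, annotation)
#: exactly as printed; 38 positions, 6 with a multi-occurrence annotation.
GATB_TABLE1 = [
    (3, "T", {"RC45": "C"}, "singleton"),
    (11, "A", {"RC50": "G"}, "2x in RC"),
    (16, "G", {"WolMed88.6": "A"}, "singleton"),
    (31, "C", {"WolMed88.6": "T"}, "singleton"),
    (32, "T", {"RC33": "A"}, "singleton"),
    (36, "C", {"WolMed88.6": "A"}, "singleton"),
    (42, "T", {"Rcerasi": "C", "RC20": "C"}, "3x in RC, 1x in R. cerasi"),
    (61, "A", {"Rcerasi": "G"}, "singleton"),
    (72, "A", {"Rcerasi": "G"}, "singleton"),
    (88, "T", {"RC50": "C"}, "singleton"),
    (89, "A", {"RC33": "G"}, "singleton"),
    (93, "T", {"RC20": "C"}, "2x in RC"),
    (102, "T", {"RC20": "C"}, "singleton"),
    (112, "A", {"RC21": "G"}, "singleton"),
    (121, "A", {"RC20": "T"}, "singleton"),
    (149, "C", {"Rcerasi": "T"}, "singleton"),
    (186, "T", {"RC20": "C"}, "2x in RC"),
    (195, "A", {"Rcerasi": "G"}, "singleton"),
    (206, "A", {"WolMed88.6": "G"}, "singleton"),
    (221, "T", {"Rcerasi": "C"}, "singleton"),
    (226, "C", {"RC20": "T"}, "singleton"),
    (238, "T", {"RC45": "C"}, "singleton"),
    (250, "A", {"RC33": "G", "WolMed88.6": "G"}, "1x RC, 1x in WolMed88.6"),
    (253, "C", {"RC50": "T", "WolMed88.6": "T"}, "1x RC, 1x in WolMed88.6"),
    (257, "T", {"RC45": "C"}, "singleton"),
    (288, "T", {"RC45": "C"}, "singleton"),
    (305, "T", {"RC20": "C"}, "singleton"),
    (321, "A", {"Rcerasi": "G"}, "singleton"),
    (323, "A", {"RC20": "G"}, "singleton"),
    (324, "A", {"Rcerasi": "G"}, "singleton"),
    (343, "A", {"RC20": "G"}, "singleton"),
    (350, "A", {"WolMed88.6": "G"}, "singleton"),
    (354, "A", {"RC45": "G"}, "singleton"),
    (355, "A", {"RC50": "G"}, "singleton"),
    (367, "T", {"RC33": "C"}, "singleton"),
    (371, "T", {"RC50": "C"}, "singleton"),
    (390, "A", {"RC45": "C"}, "singleton"),
    (398, "A", {"WolMed88.6": "G"}, "singleton"),
]

#: Clones carrying an alternate, where the annotation names more than one
#: occurrence within a line; every other (position, line) pair has one clone.
GATB_MULTIPLICITY = {(42, "RC20"): 3, (11, "RC50"): 2, (93, "RC20"): 2,
                     (186, "RC20"): 2}

#: Recipient lines of the first (fly) and second (medfly) transfer experiment.
RECIPIENT_LINES = ["RC20", "RC21", "RC33", "RC45", "RC50", "WolMed88.6"]
DONOR_LINE = "Rcerasi"
CLONES_PER_RECIPIENT = 12
DONOR_CLONES = 22

#: Published premature-stop records: (line, gene, position, fragment length,
#: consensus codon, mutant codon, stop class, strain).
TABLE3_STOPS = [
    ("RC20", "gatB", 226, 404, "CAA", "TAA", "ochre", "wCer2"),
    ("RC50", "gatB", 253, 404, "CAA", "TAA", "ochre", "wCer2"),
    ("WolMed88.6", "gatB", 253, 404, "CAA", "TAA", "ochre", "wCer2"),
    ("RC20", "coxA", 22, 444, "AAA", "TAA", "ochre", "wCer1"),
    ("F37 eastern Sicily", "ftsZ", 25, 478, "GGA", "TGA", "opal", "wCer1"),
    ("F38 eastern Sicily", "ftsZ", 25, 478, "GGA", "TGA", "opal", "wCer1"),
    ("F40 western Sicily", "ftsZ", 25, 478, "GGA", "TGA", "opal", "wCer1"),
    ("F42 western Sicily", "ftsZ", 25, 478, "GGA", "TGA", "opal", "wCer1"),
]

KNOWN_INCONSISTENCIES = [
    "RC21 carries an alternate at position 112 in the variant matrix yet the "
    "frequency table prints RC21 = 0.00/kb",
    "RC50's annotations imply 6 clone occurrences (position 11 twice) yet the "
    "frequency table prints 1.03/kb (5 occurrences in 4848 bases)",
    "the pooled recipient row (29088 bases, 1.01/kb) matches no integer "
    "occurrence count",
]


@dataclass
class FixtureTables:
    """Structured content of the published variant and stop tables."""

    table1_positions: list = field(default_factory=list)
    table3_stops: list = field(default_factory=list)
    inconsistencies: list = field(default_factory=list)


def _random_codon(rng, fixed: dict[int, str], codon_start: int,
                  alt_positions: dict[int, list[str]],
                  allowed_stops: set[int]) -> str:
    """Draw one background codon honouring fixed bases and stop constraints.

    The codon (consensus) must not be a stop; applying any single published
    alternate base inside it must not create a stop either, unless that
    position is an intended nonsense mutation.
    """
    bases = "ACGT"
    for _ in range(1000):
        codon = [fixed.get(codon_start + i, bases[rng.integers(4)])
                 for i in range(3)]
        s = "".join(codon)
        if s in STOP_CODONS:
            continue
        ok = True
        for pos, alts in alt_positions.items():
            off = pos - codon_start
            for alt in alts:
                mutated = codon.copy()
                mutated[off] = alt
                m = "".join(mutated)
                is_stop = m in STOP_CODONS
                if is_stop != (pos in allowed_stops):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return s
    raise RuntimeError("could not satisfy codon constraints")  # pragma: no cover


def _build_consensus(length: int, fixed: dict[int, str],
                     alt_positions: dict[int, list[str]],
                     allowed_stops: set[int], rng) -> str:
    """Deterministic background consensus with 1-based fixed bases."""
    seq = []
    n_codons = length // 3
    for ci in range(n_codons):
        start = 3 * ci + 1
        local_alts = {p: a for p, a in alt_positions.items()
                      if start <= p < start + 3}
        seq.append(_random_codon(rng, fixed, start, local_alts, allowed_stops))
    for pos in range(3 * n_codons + 1, length + 1):
        seq.append(fixed.get(pos, "ACGT"[rng.integers(4)]))
    return "".join(seq)


def _gatb_amplicons() -> tuple[dict[str, AmpliconSet], list[SampleMeta]]:
    """Per-line gatB amplicon sets realising the published variant matrix."""
    rng = np.random.default_rng(_FIXTURE_SEED)
    fixed = {p: base for p, base, _, _ in GATB_TABLE1}
    # Intended ochre mutations sit in CAA codons; pin the two trailing A's.
    for stop_pos in (226, 253):
        fixed[stop_pos + 1] = "A"
        fixed[stop_pos + 2] = "A"
    alt_positions: dict[int, list[str]] = {}
    for p, _, alts, _ in GATB_TABLE1:
        alt_positions[p] = sorted(set(alts.values()))
    consensus = _build_consensus(404, fixed, alt_positions,
                                 allowed_stops={226, 253}, rng=rng)

    lines = [DONOR_LINE] + RECIPIENT_LINES
    n_clones = {ln: CLONES_PER_RECIPIENT for ln in RECIPIENT_LINES}
    n_clones[DONOR_LINE] = DONOR_CLONES

    # substitutions per line: list of (position, alt, n_occurrences)
    per_line: dict[str, list[tuple[int, str, int]]] = {ln: [] for ln in lines}
    for p, _, alts, _ in GATB_TABLE1:
        for ln, alt in alts.items():
            per_line[ln].append((p, alt, GATB_MULTIPLICITY.get((p, ln), 1)))

    sets: dict[str, AmpliconSet] = {}
    metas: list[SampleMeta] = []
    for ln in lines:
        n = n_clones[ln]
        reads = {f"{ln}_c{i + 1:02d}": list(consensus) for i in range(n)}
        ids = sorted(reads)
        cursor = 0
        for pos, alt, mult in per_line[ln]:
            for _ in range(mult):
                reads[ids[cursor % n]][pos - 1] = alt
                cursor += 1
        sets[ln] = AmpliconSet(
            gene="gatB", consensus=consensus,
            reads=[(cid, "".join(reads[cid])) for cid in ids],
            expected_length=404)
        host = ("Rhagoletis cerasi" if ln == DONOR_LINE else
                "Ceratitis capitata" if ln == "WolMed88.6" else
                "Drosophila simulans")
        for cid in ids:
            metas.append(SampleMeta(clone_id=cid, line=ln, host_species=host,
                                    generation=None, gene="gatB",
                                    strain_label="wCer2"))
    return sets, metas


def _stop_amplicons(gene: str) -> AmpliconSet:
    """Amplicon set realising the published premature-stop records for a gene."""
    rng = np.random.default_rng(_FIXTURE_SEED + {"coxA": 1, "ftsZ": 2,
                                                 "gatB": 3}[gene])
    rows = [r for r in TABLE3_STOPS if r[1] == gene]
    length = GENE_LENGTHS[gene]
    fixed: dict[int, str] = {}
    alt_positions: dict[int, list[str]] = {}
    allowed: set[int] = set()
    for _, _, pos, _, cons_codon, mut_codon, _, _ in rows:
        for i, b in enumerate(cons_codon):
            fixed[pos + i] = b
        alt_positions[pos] = [mut_codon[0]]
        allowed.add(pos)
    consensus = _build_consensus(length, fixed, alt_positions, allowed, rng)
    reads = []
    seen: dict[str, int] = {}
    for line, _, pos, _, _, mut_codon, _, _ in rows:
        seen[line] = seen.get(line, 0) + 1
        cid = f"{line.split()[0]}_s{seen[line]:02d}"
        read = list(consensus)
        read[pos - 1] = mut_codon[0]
        reads.append((cid, "".join(read)))
    # pad with consensus-identical clones so stop carriers are a minority
    for i in range(4):
        reads.append((f"{gene}_wt{i + 1:02d}", consensus))
    return AmpliconSet(gene=gene, consensus=consensus, reads=reads,
                       expected_length=length)


_REGISTRY_DOC = {
    "gatB_table1": "FixtureTables with the 38 gatB variable positions",
    "table3_stops": "FixtureTables with the 8 premature-stop records",
    "gatB_table1_amplicons": "dict line -> AmpliconSet realising the matrix",
    "gatB_table1_metadata": "list of SampleMeta for the gatB clone sets",
    "coxA_table3_amplicons": "coxA AmpliconSet with the ochre stop clone",
    "ftsZ_table3_amplicons": "ftsZ AmpliconSet with the 4 opal stop clones",
}


def list_fixtures() -> dict[str, str]:
    """Names and one-line descriptions of the packaged fixtures."""
    return dict(_REGISTRY_DOC)


def load_fixtures(name: str):
    """Load a packaged fixture by registry name (see :func:`list_fixtures`)."""
    if name == "gatB_table1":
        return FixtureTables(table1_positions=list(GATB_TABLE1),
                             inconsistencies=list(KNOWN_INCONSISTENCIES))
    if name == "table3_stops":
        return FixtureTables(table3_stops=list(TABLE3_STOPS))
    if name == "gatB_table1_amplicons":
        return _gatb_amplicons()[0]
    if name == "gatB_table1_metadata":
        return _gatb_amplicons()[1]
    if name == "coxA_table3_amplicons":
        return _stop_amplicons("coxA")
    if name == "ftsZ_table3_amplicons":
        return _stop_amplicons("ftsZ")
    raise KeyError(f"unknown fixture {name!r}; available: "
                   f"{sorted(_REGISTRY_DOC)}")
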