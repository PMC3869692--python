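"""Read/write clone-read FASTA amplicon sets, sample metadata, and variant tables.

Conventions used throughout the package:

* Positions are 1-based within each amplicon fragment.
* The consensus is an explicit input (the published reference haplotype of a
  strain), never derived by majority vote from the clones being analysed.
* Reads may contain IUPAC ambiguity codes; such positions are excluded from
  variant calling downstream (the automated analogue of discarding SNPs that
  could not be confirmed in the chromatogram).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("symbiopoly")

#: Default amplicon fragment length per MLST locus (bp).
GENE_LENGTHS = {"gatB": 404, "coxA": 444, "ftsZ": 478, "wsp": 600}

SUPPORTED_GENES = frozenset(GENE_LENGTHS)

STRICT_BASES = frozenset("ACGT")
#: IUPAC nucleotide alphabet (uppercase), ambiguity codes included.
IUPAC_BASES = frozenset("ACGTRYSWKMBDHVN")

VARIANT_TABLE_COLUMNS = ["clone_id", "line", "gene", "position", "ref", "alt",
                         "recurrence_class"]

METADATA_COLUMNS = ["clone_id", "line", "host_species", "generation", "gene",
                    "strain_label"]


@dataclass(frozen=True)
class SampleMeta:
    """Per-clone sample metadata.

    ``generation`` is ``None`` when unknown; ``strain_label`` is one of
    ``wCer1``, ``wCer2`` or ``unknown``.
    """

    clone_id: str
    line: str
    host_species: str = "unknown"
    generation: Optional[int] = None
    gene: str = "gatB"
    strain_label: str = "unknown"

    def __post_init__(self):
        if self.gene not in SUPPORTED_GENES:
            raise ValueError(f"unsupported gene {self.gene!r}; "
                             f"expected one of {sorted(SUPPORTED_GENES)}")
        if self.generation is not None and self.generation < 0:
            raise ValueError("generation must be >= 0 or None (unknown)")


@dataclass
class AmpliconSet:
    """Clone reads of one gene fragment plus the strain consensus.

    All sequences share ``expected_length``; reads are ``(clone_id, sequence)``
    pairs with clone ids unique within the set.
    """

    gene: str
    consensus: str
    reads: list[tuple[str, str]] = field(default_factory=list)
    expected_length: Optional[int] = None

    def __post_init__(self):
        if self.gene not in SUPPORTED_GENES:
            raise ValueError(f"unsupported gene {self.gene!r}")
        self.consensus = self.consensus.upper()
        self.reads = [(cid, seq.upper()) for cid, seq in self.reads]
        if self.expected_length is None:
            self.expected_length = len(self.consensus)
        self.validate()

    def validate(self) -> None:
        exp = self.expected_length
        if len(self.consensus) != exp:
            raise ValueError(
                f"consensus length {len(self.consensus)} != expected {exp}")
        bad = [cid for cid, seq in self.reads if len(seq) != exp]
        if bad:
            raise ValueError(
                f"reads with length != {exp} bp: {', '.join(bad)}")
        seen: set[str] = set()
        for cid, seq in self.reads:
            if cid in seen:
                raise ValueError(f"duplicate clone_id {cid!r}")
            seen.add(cid)
            illegal = set(seq) - IUPAC_BASES
            if illegal:
                raise ValueError(
                    f"clone {cid!r} contains non-IUPAC characters "
                    f"{sorted(illegal)}")
        illegal = set(self.consensus) - STRICT_BASES
        if illegal:
            raise ValueError(
                f"consensus contains ambiguous/illegal characters "
                f"{sorted(illegal)}")

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    @property
    def total_read_bases(self) -> int:
        return self.n_reads * self.expected_length

    def clone_ids(self) -> list[str]:
        return [cid for cid, _ in self.reads]


def read_amplicon_fasta(path, gene: str,
                        expected_length: Optional[int] = None,
                        consensus_path=None) -> AmpliconSet:
    """Load an amplicon clone set from FASTA.

    The first record is taken as the strain consensus unless a separate
    ``consensus_path`` is given (then every record in ``path`` is a read).
    Length violations are a hard error naming the offending clone ids.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty or unparseable FASTA: {path}")
    if expected_length is None:
        expected_length = GENE_LENGTHS[gene]
    if consensus_path is not None:
        cons_records = list(SeqIO.parse(str(Path(consensus_path)), "fasta"))
        if not cons_records:
            raise ValueError(f"empty consensus FASTA: {consensus_path}")
        consensus = str(cons_records[0].seq)
        reads = [(r.id, str(r.seq)) for r in records]
    else:
        consensus = str(records[0].seq)
        reads = [(r.id, str(r.seq)) for r in records[1:]]
    return AmpliconSet(gene=gene, consensus=consensus, reads=reads,
                       expected_length=expected_length)


def write_amplicon_fasta(amplicons: AmpliconSet, path,
                         consensus_id: str = "consensus") -> None:
    """Write consensus (first record) and reads to FASTA."""
    records = [SeqRecord(Seq(amplicons.consensus), id=consensus_id,
                         description="")]
    records += [SeqRecord(Seq(seq), id=cid, description="")
                for cid, seq in amplicons.reads]
    SeqIO.write(records, str(Path(path)), "fasta")


def read_metadata(path) -> dict[str, SampleMeta]:
    """Read a tab-delimited sample table into a clone_id -> SampleMeta map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    out: dict[str, SampleMeta] = {}
    for row in df.itertuples(index=False):
        gen = None if row.generation in ("", "NA", "unknown", None) \
            else int(row.generation)
        meta = SampleMeta(clone_id=row.clone_id, line=row.line,
                          host_species=row.host_species, generation=gen,
                          gene=row.gene, strain_label=row.strain_label)
        if meta.clone_id in out:
            raise ValueError(f"duplicate clone_id in metadata: {meta.clone_id}")
        out[meta.clone_id] = meta
    return out


def write_metadata(metas: Iterable[SampleMeta], path) -> None:
    rows = [{"clone_id": m.clone_id, "line": m.line,
             "host_species": m.host_species,
             "generation": "unknown" if m.generation is None else m.generation,
             "gene": m.gene, "strain_label": m.strain_label}
            for m in metas]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        path, sep="\t", index=False)


def write_variant_table(calls: Sequence, path,
                        allow_empty: bool = False) -> None:
    """Write variant calls to a stable-order tab-delimited table.

    ``calls`` are :class:`~symbiopoly.variant_calling.VariantCall` objects,
    optionally carrying a ``recurrence_class`` attribute (else ``NA``).
    """
    if not calls and not allow_empty:
        raise ValueError("no calls to write (pass allow_empty=True to force)")
    rows = []
    for c in calls:
        rows.append({
            "clone_id": c.clone_id, "line": c.line, "gene": c.gene,
            "position": c.position, "ref": c.ref_base, "alt": c.alt_base,
            "recurrence_class": getattr(c, "recurrence_class", None) or "NA",
        })
    pd.DataFrame(rows, columns=VARIANT_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False)


def read_variant_table(path) -> list:
    """Round-trip companion of :func:`write_variant_table`."""
    from symbiopoly.variant_calling import VariantCall

    df = pd.read_csv(path, sep="\t", dtype={"position": int})
    calls = []
    for row in df.itertuples(index=False):
        calls.append(VariantCall(
            clone_id=row.clone_id, line=row.line, gene=row.gene,
            position=int(row.position), ref_base=row.ref, alt_base=row.alt))
    return calls
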