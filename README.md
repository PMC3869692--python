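# symbiopoly

Tools for uncovering cryptic *Wolbachia* strain and haplotype diversity from
cloned MLST amplicon libraries, with a focus on artificial host-transfer
experiments (microinjection of *Wolbachia* from the cherry fruit fly
*Rhagoletis cerasi* into *Drosophila simulans* and the medfly *Ceratitis
capitata*).

## Why clone libraries?

Direct sequencing of a PCR product reports only the majority base at each
position: low-titer strains and rare sequence haplotypes inside a single host
are invisible.  Sequencing many individual plasmid clones of the same
amplicon recovers this hidden within-host diversity — but every clone also
carries polymerase misincorporation errors, so the raw single-nucleotide
variants in a clone library mix genuine haplotype polymorphism with PCR
artefacts.  `symbiopoly` implements the full analysis chain needed to tell
those apart:

- **`amplicon_io`** — FASTA clone libraries with per-clone metadata
  (host line, generation, gene fragment), strict consensus handling, and a
  TSV variant-table interchange format.
- **`variant_calling`** — per-clone SNP calls against the consensus
  (IUPAC ambiguity codes excluded) and classification of each variable
  position as *recurrent* (seen in ≥ 2 distinct clones, potentially across
  host systems) or *singleton*.
- **`error_baseline`** — the polymerase error baseline from control
  re-sequencing batches of clones with known sequence.  The packaged control
  totals pool to 0.15 errors/kb; a published mean of 0.21/kb for
  non-proof-reading polymerases and the 0.28/kb correction constant are
  provided.
- **`polymorphism_stats`** — SNPs/kb with half-up display rounding,
  baseline-corrected rates, χ² tests with Yates continuity correction and
  exact Fisher tests on base-count contingency tables.
- **`coding_effects`** — premature stop-codon scanning (ochre/amber/opal)
  under the bacterial genetic code and Nei–Gojobori (1986) dN/dS with
  Jukes–Cantor correction.
- **`strain_typing`** — diagnostic-site strain assignment (wCer1/wCer2),
  fragment-length (VNTR) typing, coinfection detection, prevalence-switch
  localization across generations, and Monte-Carlo detection power for
  low-titer strains.
- **`rflp_insilico`** — restriction digests (HindIII by default) of circular
  or linear genomes and Southern-probe fragment counts.
- **`fecundity`** — ovary egg-count classes (I: 0, II: 1–2, III: 3–9,
  IV: ≥ 10) and exact 2×2 / 2×4 comparisons between host lines.
- **`synthetic_data`** — a generative model of the whole experiment:
  haplotype pools, transfer bottleneck, Wright–Fisher drift with optional
  selection and transmission failure, clone sequencing with polymerase
  error, and a complete ground-truth ledger for validation.

## Worked example

Call SNPs in a 12-clone gatB library from one transinfected *D. simulans*
line and convert them to a per-kb polymorphism rate (the packaged fixture
for line RC45 is used here):

```python
import symbiopoly as sp
from symbiopoly.fixtures import load_fixtures

amp = load_fixtures("gatB_table1_amplicons")["RC45"]
meta = load_fixtures("gatB_table1_metadata")
sp.write_amplicon_fasta(amp, "rc45.fasta")
sp.write_metadata([m for m in meta if m.line == "RC45"], "meta.tsv")
```

```console
$ symbiopoly call-snps --fasta rc45.fasta --gene gatB --meta meta.tsv --out variants.tsv
6 calls at 6 variable positions -> variants.tsv

$ symbiopoly freqs --variants variants.tsv --bases-per-line RC45=4848
line    n_snps  bases   rate_per_kb     corrected_per_kb
RC45    6       4848    1.24    0.96

$ head -4 variants.tsv
clone_id        line    gene    position        ref     alt     recurrence_class
RC45_c01        RC45    gatB    3       T       C       singleton
RC45_c02        RC45    gatB    238     T       C       singleton
RC45_c03        RC45    gatB    257     T       C       singleton
```

Six variants in 12 × 404 bp of gatB clones give 1.24 SNPs/kb; subtracting
the 0.28/kb error correction leaves 0.96 SNPs/kb of putatively genuine
polymorphism.  Comparing the two donor strains on their published base
counts:

```console
$ symbiopoly compare --a wCer1=5/9696 --b wCer2=9/8888
method=chi2_yates       statistic=0.9327        p_two_tailed=0.3342
```

The same operations are available as a Python API (`sp.call_snps`,
`sp.snp_frequency`, `sp.compare_groups`, …) and further subcommands cover
stop-codon scanning (`symbiopoly stops`), dN/dS (`dnds`), strain typing
(`type-strains`), ovary classes (`fecundity`), in-silico RFLP (`rflp`) and
the synthetic-study generator (`simulate`).

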