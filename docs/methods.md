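# Methods

This note documents the statistical and algorithmic conventions used by
`symbiopoly`.  All formulas are implemented in the package and covered by
tests against independent oracles.

## Clone-based SNP calling

Each clone library (`AmpliconSet`) holds one consensus sequence and the
individual clone reads for a single gene fragment (gatB 404 bp, coxA
444 bp, ftsZ 478 bp; 600 bp default for wsp).  A SNP call is any position
where a clone read differs from the consensus by an unambiguous base
(A/C/G/T).  Positions carrying IUPAC ambiguity codes are excluded from
calling and logged, never counted as variants.

A variable position is **recurrent** when the same substitution is observed
in at least two distinct clones (occurrences are de-duplicated per clone),
and **singleton** otherwise.  The set of host lines contributing clones to
a recurrent SNP is retained, since recurrence *across* independent host
systems cannot be produced by independent PCR errors and therefore marks
genuine haplotype polymorphism in the donor population.

## Polymerase error baseline

Control batches re-sequence clones of a template with known sequence, so
every observed variant is a polymerase/cloning artefact.  The pooled error
rate is

    rate/kb = 1000 · Σ errors / Σ bases

over all control batches.  The packaged controls (10 × 444 bp with 0
errors, 10 × 290 bp with 0, 14 × 429 bp with 2) pool to 2/13,346 bases =
0.15/kb.  Binomial confidence intervals use the Clopper–Pearson (exact
beta) method.  Two constants are exposed: 0.21/kb, a published mean error
rate for non-proof-reading polymerases, and 0.28/kb, the correction
constant used for baseline-corrected rates.

## SNP frequencies

Per-kb frequency is 1000 · n / L for n variant occurrences in L sequenced
bases.  Displayed values are rounded half-up to two decimals; the raw rate
is retained for arithmetic.  Corrected rates subtract the error baseline
(default 0.28/kb) and may be negative, which simply indicates a line whose
observed rate is below the error expectation.  `infer_snp_count` inverts a
printed per-kb rate back to the unique integer count when one exists and
raises when rounding makes the inversion ambiguous.

## Contingency tests

Two lines are compared on the 2×2 base-count table

    [[n_A, L_A − n_A], [n_B, L_B − n_B]]

- **χ² with Yates correction**: Σ (|O − E| − ½)² / E, with the continuity
  term floored at zero when |O − E| < ½; the p-value is the upper tail of
  χ²₁.  Degenerate tables (a zero margin) warn and return p = 1.
- **Fisher's exact test** (two-tailed): full enumeration of the
  hypergeometric support, summing all tables with probability ≤ the
  observed one (relative tie slack 1e-7).
- **2×k exact test** (fecundity "full" mode): exhaustive enumeration of
  all tables with the observed margins under the multivariate
  hypergeometric null, via log-factorials.

## Coding effects

Translation uses the bacterial/plastid genetic code (table 11); premature
stops are classed ochre (TAA), amber (TAG) or opal (TGA).  Reading frames
are specified per fragment as codon offsets (0 for all three MLST
fragments used here).

dN/dS follows Nei & Gojobori (1986): potential synonymous sites by
fractional counting (stop-creating single changes count as nonsynonymous so
every sense codon contributes exactly 3 sites), observed differences by
averaging over all mutational pathways between codon pairs, excluding
pathways through stop codons when avoidable, and Jukes–Cantor correction
d = −¾ ln(1 − 4p/3).  The ratio is undefined (None) when dS = 0.  Codon
pairs containing ambiguity codes or stops are skipped.

## Strain typing and prevalence switches

Diagnostic-site typing assigns a read to the strain with the highest
fraction of matching diagnostic positions, requiring ≥ 0.9 by default;
ties or sub-threshold scores yield "unknown".  Fragment-length (VNTR)
typing matches within ± 2 bp.  A host is called coinfected when at least
two strains each reach the minimum read support.  A prevalence switch
between strains is localized as the pair (last generation the source
strain was detected, first generation only the target strain was
detected).  Detection power for a low-titer strain is estimated by Monte
Carlo over clone sampling and agrees with the closed form
1 − (1 − titer)^n.

## In-silico RFLP

Digestion scans for recognition sites (HindIII A^AGCTT, cut offset 1)
on circular genomes including sites spanning the origin, or on linear
genomes.  Fragments conserve total length; a probe locus hybridizes to a
fragment when their overlap is at least 20 bp (configurable), so a cut
inside a tandem-repeat locus yields two probe-positive fragments.

## Fecundity classes

Ovaries are classed by egg count: I = 0, II = 1–2, III = 3–9, IV = ≥ 10.
Lines are compared either on the class-IV-vs-rest 2×2 table (Fisher) or on
the full 2×4 table (exact enumeration).

## Synthetic studies

The generator mirrors the experimental design: a donor haplotype pool
(per-strain pools mixed at strain titers, default 0.95 wCer2 / 0.05
wCer1, with a ledger of every planted variant site and its carrier
haplotype), a founding bottleneck into each recipient line (multinomial
draw of the bottleneck size), Wright–Fisher drift (per-generation
multinomial resampling at the effective size, optional fitness weights,
transmission failures counted and redrawn conditional on persistence), and
clone sequencing (binomial haplotype sampling plus uniform per-base
polymerase error, every error position ledgered).  An optional planted
prevalence switch forces a major→minor strain replacement inside a chosen
generation window, with the minor strain held just below the detection
threshold beforehand.  Because the ledger records the exact ground truth
of every read, pipeline output can be validated exactly, not just
statistically.
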