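"""Synthetic study generator: haplotype pools, bottleneck, drift, cloning.

Emulates the sampling structure the analysis pipeline assumes:

* a donor symbiont population that is a mixture of strains (a major strain
  plus a low-titer minor strain), each strain itself a pool of haplotypes —
  one canonical plus rare variants at known sites;
* an artificial host transfer that founds each recipient line from a small
  multinomial draw (the bottleneck), followed by neutral Wright-Fisher
  multinomial resampling per host generation at effective size ``N_e``,
  optionally with per-haplotype fitness (selection) and imperfect maternal
  transmission (an all-or-nothing loss event; lines are conditioned on
  non-loss, mirroring selection regimes that only breed from infected
  females — conditioning is recorded in the ledger);
* clone re-sequencing: each clone read draws a haplotype proportional to
  its current frequency, then i.i.d. per-base polymerase errors (uniform
  over the three alternate bases) at a configurable rate, 1.5e-4 per base
  (0.15/kb) by default.

Every draw descends from one seed; the ground-truth ledger fully determines
the expected output of the analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from symbiopoly.amplicon_io import AmpliconSet, SampleMeta, GENE_LENGTHS

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class HaplotypePool:
    """Haplotypes of one gene fragment with population frequencies.

    ``strains[i]`` labels haplotype ``i``; a single-strain pool repeats one
    label.  ``variant_sites`` is ground truth: (position, ref, alt,
    haplotype index) for every planted deviation from the canonical
    (index 0) haplotype.
    """

    gene: str
    sequences: list
    frequencies: np.ndarray
    strains: list
    variant_sites: list = field(default_factory=list)

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")
        if (self.frequencies < 0).any():
            raise ValueError("negative frequency")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("haplotype sequences must share one length")
        if not (len(self.sequences) == len(self.frequencies)
                == len(self.strains)):
            raise ValueError("sequences, frequencies, strains disagree")

    @property
    def consensus(self) -> str:
        """The canonical haplotype (explicit reference, not a majority vote)."""
        return self.sequences[0]

    def strain_titers(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for s, f in zip(self.strains, self.frequencies):
            out[s] = out.get(s, 0.0) + float(f)
        return out


@dataclass
class SimConfig:
    """Study conditions for the end-to-end simulation.

    Defaults mirror the modelled system: a major strain at high prevalence
    with a low-titer minor co-infection, a founding bottleneck small enough
    to reshuffle rare-haplotype frequencies, near-complete late maternal
    transmission, and the measured polymerase error rate.
    """

    strain_titers: dict = field(
        default_factory=lambda: {"wCer2": 0.95, "wCer1": 0.05})
    haplotypes_per_strain: int = 3
    variant_sites_per_strain: int = 4
    rare_haplotype_freq: float = 0.05
    bottleneck_size: int = 50
    generations: int = 50
    effective_size: int = 1000
    transmission: float = 0.95
    error_rate: float = 1.5e-4
    clones_per_sample: int = 12
    n_recipient_lines: int = 5
    sample_generations: tuple = (0, 25, 50)
    gene: str = "gatB"
    fitness: Optional[Sequence[float]] = None
    plant_switch: Optional[tuple] = None   # (g_last_major, g_first_minor_only)
    detection_threshold: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.transmission <= 1.0:
            raise ValueError("transmission outside [0, 1]")
        if self.bottleneck_size < 1:
            raise ValueError("bottleneck_size must be >= 1")
        if self.bottleneck_size > self.effective_size:
            raise ValueError("bottleneck cannot exceed effective size")
        titers = np.array(list(self.strain_titers.values()))
        if abs(titers.sum() - 1.0) > 1e-9 or (titers < 0).any():
            raise ValueError("strain titers must be a probability vector")


@dataclass
class SimOutput:
    """End-to-end synthetic dataset plus its ground-truth ledger."""

    amplicon_sets: dict          # (line, generation) -> AmpliconSet
    metadata: list               # SampleMeta per clone
    ledger: dict                 # full ground truth


def _random_sequence(length: int, rng) -> str:
    return "".join(np.array(["A", "C", "G", "T"])[rng.integers(0, 4, length)])


def make_pool(n_haplotypes: int, n_variant_sites: int,
              freq_spec="canonical", seed: int = 0, gene: str = "gatB",
              length: Optional[int] = None, consensus: Optional[str] = None,
              strain: str = "wCer2") -> HaplotypePool:
    """Build a haplotype pool: canonical haplotype 0 plus rare variants.

    ``freq_spec`` may be an explicit frequency sequence, ``"uniform"``,
    ``"dirichlet"`` (seeded Dirichlet(1) draw), or ``"canonical"`` (canonical
    haplotype at 0.95, the rest sharing 0.05 equally).  Variant sites are
    drawn without replacement and assigned round-robin to the non-canonical
    haplotypes, so every site's carrier is known exactly.
    """
    rng = np.random.default_rng(seed)
    if length is None:
        length = GENE_LENGTHS[gene]
    if n_variant_sites >= length:
        raise ValueError("more variant sites than fragment positions")
    if n_haplotypes < 1:
        raise ValueError("need at least the canonical haplotype")
    if n_haplotypes == 1 and n_variant_sites > 0:
        raise ValueError("variant sites need a non-canonical carrier")
    if consensus is None:
        consensus = _random_sequence(length, rng)
    seqs = [list(consensus) for _ in range(n_haplotypes)]
    sites = []
    if n_variant_sites:
        positions = sorted(rng.choice(np.arange(1, length + 1),
                                      size=n_variant_sites,
                                      replace=False).tolist())
        for k, pos in enumerate(positions):
            hap = 1 + k % (n_haplotypes - 1)
            ref = consensus[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            seqs[hap][pos - 1] = alt
            sites.append((int(pos), ref, alt, hap))
    if isinstance(freq_spec, str):
        if freq_spec == "uniform":
            freqs = np.full(n_haplotypes, 1.0 / n_haplotypes)
        elif freq_spec == "dirichlet":
            freqs = rng.dirichlet(np.ones(n_haplotypes))
        elif freq_spec == "canonical":
            if n_haplotypes == 1:
                freqs = np.array([1.0])
            else:
                freqs = np.full(n_haplotypes, 0.05 / (n_haplotypes - 1))
                freqs[0] = 0.95
        else:
            raise ValueError(f"unknown freq_spec {freq_spec!r}")
    else:
        freqs = np.asarray(list(freq_spec), dtype=float)
        if len(freqs) != n_haplotypes:
            raise ValueError("freq_spec length mismatch")
    return HaplotypePool(gene=gene, sequences=["".join(s) for s in seqs],
                         frequencies=freqs, strains=[strain] * n_haplotypes,
                         variant_sites=sites)


def combine_pools(pools: Sequence[HaplotypePool],
                  titers: Sequence[float]) -> HaplotypePool:
    """Mix per-strain pools into one population at given strain titers."""
    titers = np.asarray(titers, dtype=float)
    if abs(titers.sum() - 1.0) > 1e-9:
        raise ValueError("titers must sum to 1")
    seqs, freqs, strains, sites = [], [], [], []
    for pool, t in zip(pools, titers):
        offset = len(seqs)
        seqs += list(pool.sequences)
        freqs += list(t * pool.frequencies)
        strains += list(pool.strains)
        sites += [(p, r, a, h + offset) for p, r, a, h in pool.variant_sites]
    return HaplotypePool(gene=pools[0].gene, sequences=seqs,
                         frequencies=np.array(freqs), strains=strains,
                         variant_sites=sites)


def bottleneck_and_drift(pool: HaplotypePool, n_bottleneck: int,
                         generations: int, effective_size: int,
                         transmission: float = 1.0,
                         fitness: Optional[Sequence[float]] = None,
                         rng=None, seed: int = 0):
    """Found a line through a bottleneck and drift it for G generations.

    Returns ``(trajectory, n_transmission_failures)``: trajectory is a
    ``(G + 1, n_haplotypes)`` frequency array, row 0 the post-bottleneck
    founding frequencies.  Each generation is a multinomial resample of
    ``effective_size`` individuals (fitness-weighted when given).  With
    probability ``1 - transmission`` a generation's mother fails to transmit;
    under the infected-female selection regime such lineages are discarded
    and redrawn, so the count of failures is returned rather than a loss.
    Loss/fixation of a haplotype is absorbing.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_bottleneck, pool.frequencies)
    traj = np.empty((generations + 1, len(pool.frequencies)))
    traj[0] = counts / counts.sum()
    n_failures = 0
    for g in range(1, generations + 1):
        while transmission < 1.0 and rng.random() >= transmission:
            n_failures += 1
        p = traj[g - 1]
        if fitness is not None:
            w = np.asarray(fitness, dtype=float)
            p = p * w
            p = p / p.sum()
        counts = rng.multinomial(effective_size, p)
        traj[g] = counts / counts.sum()
    return traj, n_failures


def sequence_clones(pool: HaplotypePool, n_clones: int,
                    error_rate: float = 1.5e-4, rng=None, seed: int = 0,
                    clone_prefix: str = "clone",
                    frequencies: Optional[np.ndarray] = None,
                    ) -> tuple[AmpliconSet, dict]:
    """Re-sequence a pool state as clone reads with polymerase error.

    Each clone draws a haplotype proportional to ``frequencies`` (pool's
    own by default), then injects i.i.d. per-base errors uniform over the
    three alternates.  The ledger records each clone's true haplotype,
    strain and error positions.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    freqs = pool.frequencies if frequencies is None else \
        np.asarray(frequencies, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must sum to 1")
    length = len(pool.consensus)
    hap_idx = rng.choice(len(freqs), size=n_clones, p=freqs)
    reads = []
    ledger_clones = []
    for i, h in enumerate(hap_idx):
        cid = f"{clone_prefix}_c{i + 1:03d}"
        seq = np.frombuffer(pool.sequences[h].encode(), dtype="S1").copy()
        error_positions = []
        if error_rate > 0:
            hits = np.flatnonzero(rng.random(length) < error_rate)
            for j in hits:
                cur = seq[j]
                alts = _BASES[_BASES != cur]
                seq[j] = alts[rng.integers(3)]
                error_positions.append(int(j) + 1)
        reads.append((cid, seq.tobytes().decode()))
        ledger_clones.append({"clone_id": cid, "haplotype": int(h),
                              "strain": pool.strains[h],
                              "error_positions": error_positions})
    amplicons = AmpliconSet(gene=pool.gene, consensus=pool.consensus,
                            reads=reads, expected_length=length)
    ledger = {"clones": ledger_clones,
              "n_error_bases": sum(len(c["error_positions"])
                                   for c in ledger_clones),
              "total_bases": n_clones * length}
    return amplicons, ledger


def _strain_titers_from(pool: HaplotypePool,
                        freqs: np.ndarray) -> dict[str, float]:
    out: dict[str, float] = {}
    for s, f in zip(pool.strains, freqs):
        out[s] = out.get(s, 0.0) + float(f)
    return out


def _plant_switch(traj: np.ndarray, pool: HaplotypePool, major: str,
                  minor: str, window: tuple) -> None:
    """Force a major -> minor prevalence switch inside ``window`` in place.

    Through ``window[0]`` the major strain keeps its frequencies; from
    ``window[1]`` on its mass is reassigned to the minor strain's
    haplotypes (proportionally), with a linear transition in between.
    """
    g1, g2 = window
    major_ix = np.array([i for i, s in enumerate(pool.strains) if s == major])
    minor_ix = np.array([i for i, s in enumerate(pool.strains) if s == minor])
    for g in range(len(traj)):
        if g <= g1:
            # guarantee both strains present before the switch
            if traj[g][minor_ix].sum() == 0.0:
                traj[g][minor_ix] = 1e-3 / len(minor_ix)
            if traj[g][major_ix].sum() == 0.0:
                traj[g][major_ix[0]] = 1.0
            traj[g] /= traj[g].sum()
            continue
        frac = 1.0 if g >= g2 else (g - g1) / (g2 - g1)
        major_mass = traj[g][major_ix].sum()
        if traj[g][minor_ix].sum() == 0.0:
            traj[g][minor_ix] = 1.0 / len(minor_ix)
        moved = frac * major_mass
        traj[g][major_ix] *= (1.0 - frac)
        minor_mass = traj[g][minor_ix].sum()
        traj[g][minor_ix] *= (minor_mass + moved) / minor_mass
        traj[g] /= traj[g].sum()


def simulate_study(config: SimConfig) -> SimOutput:
    """Generate a full synthetic transfer study from one seed.

    Donor sample plus ``n_recipient_lines`` independent bottlenecked lines,
    each re-sequenced as clones at the configured sample generations.  When
    ``plant_switch=(g1, g2)`` is set, line 1 carries a forced prevalence
    switch from the major to the minor strain detectable exactly in that
    window.  The ledger holds true haplotype frequencies per generation,
    true variant sites, strain titers, transmission-failure counts and the
    planted window.
    """
    rng = np.random.default_rng(config.seed)
    strains = sorted(config.strain_titers, key=config.strain_titers.get,
                     reverse=True)
    titers = [config.strain_titers[s] for s in strains]
    major = strains[0]
    minor = strains[1] if len(strains) > 1 else None

    consensus = _random_sequence(GENE_LENGTHS[config.gene], rng)
    pools = []
    for s in strains:
        pools.append(make_pool(
            n_haplotypes=config.haplotypes_per_strain,
            n_variant_sites=config.variant_sites_per_strain,
            freq_spec="canonical", seed=int(rng.integers(2 ** 31)),
            gene=config.gene, consensus=consensus, strain=s))
    donor = combine_pools(pools, titers)

    amplicon_sets: dict = {}
    metadata: list[SampleMeta] = []
    ledger: dict = {
        "seed": config.seed,
        "strains": strains,
        "donor_titers": dict(zip(strains, titers)),
        "variant_sites": donor.variant_sites,
        "consensus": consensus,
        "lines": {},
        "planted_switch": config.plant_switch,
    }

    def sample(line: str, generation, pool, freqs, host: str):
        amp, clone_ledger = sequence_clones(
            pool, config.clones_per_sample, config.error_rate, rng=rng,
            clone_prefix=f"{line}_g{generation}", frequencies=freqs)
        amplicon_sets[(line, generation)] = amp
        for cid, _ in amp.reads:
            metadata.append(SampleMeta(
                clone_id=cid, line=line, host_species=host,
                generation=None if generation == "donor" else generation,
                gene=config.gene, strain_label="unknown"))
        return clone_ledger

    donor_ledger = sample("donor", "donor", donor, donor.frequencies,
                          "Rhagoletis cerasi")
    ledger["lines"]["donor"] = {"clones": donor_ledger,
                                "frequencies": donor.frequencies.tolist()}

    for k in range(1, config.n_recipient_lines + 1):
        line = f"L{k:02d}"
        traj, n_fail = bottleneck_and_drift(
            donor, config.bottleneck_size, config.generations,
            config.effective_size, transmission=config.transmission,
            fitness=config.fitness, rng=rng)
        switched = (config.plant_switch is not None and k == 1
                    and minor is not None)
        if switched:
            _plant_switch(traj, donor, major, minor, config.plant_switch)
        line_ledger = {"trajectory": traj.tolist(),
                       "n_transmission_failures": n_fail,
                       "switched": switched, "samples": {}}
        observations = []
        for g in config.sample_generations:
            if g > config.generations:
                continue
            freqs = traj[g]
            clone_ledger = sample(line, g, donor, freqs,
                                  "Drosophila simulans")
            line_ledger["samples"][g] = clone_ledger
            det = {s for s, t in
                   _strain_titers_from(donor, freqs).items()
                   if t >= config.detection_threshold}
            observations.append((g, det))
        line_ledger["observations"] = observations
        ledger["lines"][line] = line_ledger

    return SimOutput(amplicon_sets=amplicon_sets, metadata=metadata,
                     ledger=ledger)
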