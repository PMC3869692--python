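import numpy as np
import pytest

import symbiopoly as sp
from symbiopoly.synthetic_data import combine_pools


class TestMakePool:
    def test_single_haplotype_is_consensus(self):
        pool = sp.make_pool(1, 0, "uniform", seed=1)
        assert pool.sequences == [pool.consensus]
        assert pool.frequencies.tolist() == [1.0]
        assert pool.variant_sites == []

    def test_biallelic_site_at_low_frequency(self):
        pool = sp.make_pool(2, 1, [0.9, 0.1], seed=2)
        assert len(pool.variant_sites) == 1
        pos, ref, alt, hap = pool.variant_sites[0]
        assert pool.consensus[pos - 1] == ref
        assert pool.sequences[hap][pos - 1] == alt
        assert pool.frequencies[hap] == 0.1

    def test_ledger_matches_realized_sequences(self):
        """The site ledger is exact ground truth: rebuilding haplotypes from
        consensus + ledger reproduces every sequence."""
        pool = sp.make_pool(5, 10, "dirichlet", seed=3)
        rebuilt = [list(pool.consensus) for _ in range(5)]
        for pos, ref, alt, hap in pool.variant_sites:
            assert pool.consensus[pos - 1] == ref
            rebuilt[hap][pos - 1] = alt
        assert ["".join(s) for s in rebuilt] == pool.sequences

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            sp.make_pool(1, 3, "uniform", seed=0)
        with pytest.raises(ValueError):
            sp.make_pool(2, 500, "uniform", seed=0, length=404)

    def test_frequencies_validated(self):
        with pytest.raises(ValueError):
            sp.make_pool(2, 1, [0.9, 0.2], seed=0)


class TestBottleneckAndDrift:
    def test_single_haplotype_constant_trajectory(self):
        pool = sp.make_pool(1, 0, "uniform", seed=1)
        traj, _ = sp.bottleneck_and_drift(pool, 10, 5, 100, seed=1)
        assert np.all(traj == 1.0)

    def test_frequencies_sum_to_one_every_generation(self):
        pool = sp.make_pool(4, 6, "dirichlet", seed=4)
        traj, _ = sp.bottleneck_and_drift(pool, 30, 40, 500, seed=4)
        assert np.allclose(traj.sum(axis=1), 1.0, atol=1e-9)

    def test_loss_is_absorbing(self):
        pool = sp.make_pool(3, 2, "dirichlet", seed=5)
        traj, _ = sp.bottleneck_and_drift(pool, 10, 60, 50, seed=5)
        for j in range(traj.shape[1]):
            zeros = np.flatnonzero(traj[:, j] == 0.0)
            if zeros.size:
                assert np.all(traj[zeros[0]:, j] == 0.0)

    def test_large_population_preserves_frequencies(self):
        """At N = 1e6 and G = 5 drift is negligible: frequencies stay within
        1% of the donor pool."""
        pool = sp.make_pool(3, 2, [0.6, 0.3, 0.1], seed=6)
        traj, _ = sp.bottleneck_and_drift(pool, 10 ** 6, 5, 10 ** 6, seed=6)
        assert np.abs(traj[-1] - pool.frequencies).max() < 0.01

    def test_minor_strain_founding_loss_probability(self):
        """Minor strain at titer 0.02 through a 20-individual bottleneck:
        empirical loss-at-founding within 3 MC sigma of 0.98^20."""
        major = sp.make_pool(1, 0, "uniform", seed=7, strain="wCer2")
        minor = sp.make_pool(1, 0, "uniform", seed=8, strain="wCer1")
        pool = combine_pools([major, minor], [0.98, 0.02])
        rng = np.random.default_rng(9)
        n_reps = 500
        lost = 0
        for _ in range(n_reps):
            traj, _ = sp.bottleneck_and_drift(pool, 20, 0, 100, rng=rng)
            lost += traj[0][1] == 0.0
        expected = 0.98 ** 20
        sigma = np.sqrt(expected * (1 - expected) / n_reps)
        assert abs(lost / n_reps - expected) <= 3 * sigma

    def test_selection_shifts_frequencies(self):
        pool = sp.make_pool(2, 1, [0.5, 0.5], seed=10)
        traj, _ = sp.bottleneck_and_drift(pool, 10 ** 5, 30, 10 ** 5,
                                          fitness=[1.0, 1.2], seed=10)
        assert traj[-1][1] > 0.9


class TestSequenceClones:
    def test_error_free_single_haplotype(self):
        pool = sp.make_pool(1, 0, "uniform", seed=11)
        amp, ledger = sp.sequence_clones(pool, 5, error_rate=0.0, seed=11)
        assert all(seq == pool.consensus for _, seq in amp.reads)
        assert ledger["n_error_bases"] == 0

    def test_haplotype_sampling_is_binomial(self):
        pool = sp.make_pool(2, 1, [0.5, 0.5], seed=12)
        amp, ledger = sp.sequence_clones(pool, 10000, error_rate=0.0,
                                         seed=12)
        n1 = sum(c["haplotype"] == 1 for c in ledger["clones"])
        assert abs(n1 - 5000) <= 3 * np.sqrt(10000 * 0.25)

    def test_error_rate_recovered_by_baseline_estimator(self):
        """Pooled error estimate over ledger-flagged artefacts recovers the
        injected 1.5e-4 per-base rate within its binomial CI."""
        pool = sp.make_pool(1, 0, "uniform", seed=13, length=500)
        n_clones = 240  # 120 kb total
        amp, ledger = sp.sequence_clones(pool, n_clones, error_rate=1.5e-4,
                                         seed=13)
        controls = [sp.ControlSet("gatB", n_clones, 500,
                                  ledger["n_error_bases"])]
        lo, hi = sp.error_ci(controls, 0.95)
        assert lo <= 0.15 <= hi

    def test_ledger_errors_match_read_differences(self):
        pool = sp.make_pool(2, 3, "dirichlet", seed=14)
        amp, ledger = sp.sequence_clones(pool, 50, error_rate=2e-3, seed=14)
        for (cid, seq), entry in zip(amp.reads, ledger["clones"]):
            assert cid == entry["clone_id"]
            true_seq = pool.sequences[entry["haplotype"]]
            diffs = [i + 1 for i, (a, b) in enumerate(zip(true_seq, seq))
                     if a != b]
            assert diffs == sorted(entry["error_positions"])


class TestSimulateStudy:
    @pytest.fixture()
    def small_config(self):
        return sp.SimConfig(generations=10, sample_generations=(0, 5, 10),
                            n_recipient_lines=2, clones_per_sample=6,
                            seed=42)

    def test_deterministic_given_seed(self, small_config):
        a = sp.simulate_study(small_config)
        b = sp.simulate_study(small_config)
        assert a.ledger == b.ledger
        for key in a.amplicon_sets:
            assert a.amplicon_sets[key].reads == b.amplicon_sets[key].reads

    def test_different_seeds_differ(self, small_config):
        import dataclasses
        a = sp.simulate_study(small_config)
        b = sp.simulate_study(dataclasses.replace(small_config, seed=43))
        assert a.ledger != b.ledger

    def test_planted_switch_recovered(self):
        config = sp.SimConfig(generations=30, sample_generations=(0, 15, 30),
                              n_recipient_lines=2, clones_per_sample=6,
                              plant_switch=(15, 30), seed=7)
        out = sp.simulate_study(config)
        line = out.ledger["lines"]["L01"]
        assert line["switched"]
        series = sp.PrevalenceSeries("L01", line["observations"])
        assert sp.locate_switch(series, "wCer2", "wCer1") == (15, 30)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            sp.SimConfig(strain_titers={"wCer2": 0.7, "wCer1": 0.2})
        with pytest.raises(ValueError):
            sp.SimConfig(bottleneck_size=0)
        with pytest.raises(ValueError):
            sp.SimConfig(transmission=1.5)

    def test_shared_rare_haplotype_recurrent_across_lines(self):
        """A rare donor haplotype sampled into several recipient lines makes
        its site recurrent across host systems in the pipeline output.

        The carrier haplotype segregates at ~0.0475, so 60 clones/line give
        a ~95% per-line detection rate and a ~1e-4 chance that fewer than
        two of five lines sample it."""
        config = sp.SimConfig(generations=2, sample_generations=(2,),
                              n_recipient_lines=5, clones_per_sample=60,
                              bottleneck_size=2000, effective_size=2000,
                              error_rate=0.0, haplotypes_per_strain=2,
                              variant_sites_per_strain=2, seed=2)
        out = sp.simulate_study(config)
        meta = {m.clone_id: m for m in out.metadata}
        calls = []
        for (line, gen), amp in out.amplicon_sets.items():
            if line == "donor":
                continue
            calls += sp.call_snps(amp, meta)
        classes = sp.classify_recurrence(calls)
        true_sites = {(p, a) for p, r, a, h in out.ledger["variant_sites"]}
        observed = {(r.position, r.alt_base): r for r in classes}
        assert set(observed) <= true_sites  # error-free: no spurious calls
        # at least one planted site seen in clones from >= 2 lines
        assert any(len(r.contexts) >= 2 for r in observed.values())
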