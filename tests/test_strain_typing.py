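import numpy as np
import pytest

import symbiopoly as sp
from symbiopoly.strain_typing import type_by_length


@pytest.fixture(scope="module")
def profile():
    return sp.make_synthetic_profile(seed=5, n_sites=4, fragment_length=36)


def _read_for(strain, profile, length=36):
    read = ["A"] * length
    for pos, by in profile.sites:
        read[pos - 1] = by[strain]
    return "".join(read)


class TestTypeClone:
    def test_perfect_match(self, profile):
        call = sp.type_clone(_read_for("wCer1", profile), profile, "r1")
        assert (call.strain, call.confidence) == ("wCer1", 1.0)

    def test_tie_is_unknown(self):
        # single site, read matches neither strain's base fully -> tie at 0
        p = sp.DiagnosticProfile(marker="m", sites=[
            (1, {"wCer1": "A", "wCer2": "C"}),
            (2, {"wCer1": "C", "wCer2": "A"})])
        call = sp.type_clone("AA", p)
        assert call.strain == "unknown"
        assert call.confidence == 0.5

    def test_sub_threshold_is_unknown(self, profile):
        # corrupt one of four diagnostic sites -> best score 0.75 < 0.9
        read = list(_read_for("wCer1", profile))
        pos, by = profile.sites[0]
        read[pos - 1] = next(b for b in "ACGT" if b not in by.values())
        call = sp.type_clone("".join(read), profile)
        assert call.strain == "unknown"
        assert call.confidence == 0.75

    def test_short_read_rejected(self, profile):
        with pytest.raises(ValueError):
            sp.type_clone("ACGT", profile)

    def test_simulated_reads_typed_correctly(self, profile):
        """100 reads per strain at 0.2% per-base error: the miss count stays
        within 3 sigma of its binomial expectation.  A read can only be
        mistyped or left unknown if an error lands on a diagnostic site, so
        per-read miss probability is at most 1 - (1 - 0.002)^4."""
        rng = np.random.default_rng(17)
        correct = total = 0
        for strain in ("wCer1", "wCer2"):
            base = _read_for(strain, profile)
            for _ in range(100):
                read = list(base)
                errs = rng.random(len(read)) < 0.002
                for i in np.flatnonzero(errs):
                    read[i] = "ACGT"[(("ACGT".index(read[i])) + 1) % 4]
                call = sp.type_clone("".join(read), profile, threshold=0.9)
                total += 1
                correct += call.strain == strain
        p_miss = 1 - (1 - 0.002) ** len(profile.sites)
        bound = total * p_miss + 3 * np.sqrt(total * p_miss * (1 - p_miss))
        assert total - correct <= bound


class TestLengthTyping:
    def test_vntr_length_discrimination(self):
        p = sp.DiagnosticProfile(marker="VNTR-141",
                                 lengths={"wCer1": 420, "wCer2": 561,
                                          "wCer4": 702})
        assert type_by_length(419, p).strain == "wCer1"
        assert type_by_length(561, p).strain == "wCer2"
        assert type_by_length(500, p).strain == "unknown"

    def test_length_tie_is_unknown(self):
        p = sp.DiagnosticProfile(marker="m", lengths={"a": 100, "b": 102})
        assert type_by_length(101, p).strain == "unknown"


class TestCoinfection:
    def _calls(self, spec):
        return [sp.StrainCall(f"r{i}", s, 1.0)
                for i, s in enumerate(spec)]

    def test_multiple(self):
        status, strains = sp.detect_coinfection(
            self._calls(["wCer1"] * 3 + ["wCer2"] * 5))
        assert status == "multiple"
        assert strains == {"wCer1", "wCer2"}

    def test_single(self):
        status, strains = sp.detect_coinfection(self._calls(["wCer2"] * 8))
        assert (status, strains) == ("single", {"wCer2"})

    def test_all_unknown(self):
        status, strains = sp.detect_coinfection(self._calls(["unknown"] * 4))
        assert (status, strains) == ("none", frozenset())

    def test_min_reads_filters_weak_support(self):
        status, strains = sp.detect_coinfection(
            self._calls(["wCer1"] + ["wCer2"] * 5), min_reads=2)
        assert (status, strains) == ("single", {"wCer2"})

    def test_never_reports_unsupported_strain(self):
        status, strains = sp.detect_coinfection(
            self._calls(["wCer1", "wCer2"]), min_reads=3)
        assert status == "none" and not strains


class TestLocateSwitch:
    def test_published_time_course_pattern(self):
        series = sp.PrevalenceSeries("RC20", [
            (140, {"wCer2"}), (150, {"wCer2"}), (167, {"wCer1"}),
            (168, {"wCer1"})])
        assert sp.locate_switch(series, "wCer2", "wCer1") == (150, 167)

    def test_constant_series_no_switch(self):
        series = sp.PrevalenceSeries("RC50", [(1, {"wCer2"}),
                                              (99, {"wCer2"})])
        assert sp.locate_switch(series, "wCer2", "wCer1") is None

    def test_unsorted_generations_rejected(self):
        with pytest.raises(ValueError):
            sp.PrevalenceSeries("X", [(5, {"wCer2"}), (4, {"wCer1"})])

    def test_planted_random_switch_recovered(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            gens = sorted(rng.choice(np.arange(1, 200), size=8,
                                     replace=False).tolist())
            cut = int(rng.integers(1, 7))
            obs = [(g, {"wCer2"}) for g in gens[:cut + 1]] + \
                  [(g, {"wCer1"}) for g in gens[cut + 1:]]
            series = sp.PrevalenceSeries("sim", obs)
            assert sp.locate_switch(series, "wCer2", "wCer1") \
                == (gens[cut], gens[cut + 1])


class TestDetectionPower:
    def test_zero_titer_zero_power(self, profile):
        power, _ = sp.detection_power(0.0, 12, 0.0, profile, n_reps=50,
                                      seed=1)
        assert power == 0.0

    def test_full_titer_full_power(self, profile):
        power, _ = sp.detection_power(1.0, 12, 0.0, profile, n_reps=50,
                                      seed=1)
        assert power == 1.0

    def test_closed_form_binomial_agreement(self, profile):
        """Error-free, min_reads=1: power = 1 - (1 - titer)^n within 3 MC
        standard errors."""
        n_reps = 400
        power, se = sp.detection_power(0.05, 12, 0.0, profile,
                                       n_reps=n_reps, seed=9)
        expected = 1 - 0.95 ** 12
        sigma = max(se, np.sqrt(expected * (1 - expected) / n_reps))
        assert abs(power - expected) <= 3 * sigma

    def test_monotone_in_titer_and_reads(self, profile):
        grid_t = [sp.detection_power(t, 8, 0.0, profile, n_reps=300,
                                     seed=4)[0]
                  for t in (0.0, 0.1, 0.5, 1.0)]
        assert all(b >= a - 0.1 for a, b in zip(grid_t, grid_t[1:]))
        grid_n = [sp.detection_power(0.1, n, 0.0, profile, n_reps=300,
                                     seed=4)[0]
                  for n in (2, 8, 32)]
        assert all(b >= a - 0.1 for a, b in zip(grid_n, grid_n[1:]))


def test_synthetic_profile_is_labelled_and_valid():
    p = sp.make_synthetic_profile(seed=0)
    assert "synthetic" in p.marker
    assert len(p.sites) == 4
    assert p.strains == ["wCer1", "wCer2"]
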