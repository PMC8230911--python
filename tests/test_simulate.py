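"""Cohort simulator: Hardy-Weinberg draws, exception channels, fixtures."""

import math

import pytest

from caniphen import predict_all
from caniphen.evaluate import score_cohort
from caniphen.simulate import (
    DEFAULT_LOCUS_FREQS,
    SimConfig,
    make_reference_cohorts,
    simulate_cohort,
)
from caniphen.vocab import Certainty


class TestConfigValidation:
    def test_frequencies_must_sum_to_one(self):
        freqs = {k: dict(v) for k, v in DEFAULT_LOCUS_FREQS.items()}
        freqs["E"]["e"] = 0.5  # now sums to 1.25
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(n_samples=10, seed=1, locus_freqs=freqs)

    def test_unknown_haplotype_rejected(self):
        freqs = {k: dict(v) for k, v in DEFAULT_LOCUS_FREQS.items()}
        freqs["E"] = {"e": 0.5, "E": 0.4, "E^x": 0.1}
        with pytest.raises(ValueError, match="E\\^x"):
            SimConfig(n_samples=10, seed=1, locus_freqs=freqs)

    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(n_samples=10, seed=1, p_bc=1.5)

    def test_seed_mandatory(self):
        with pytest.raises(ValueError):
            SimConfig(n_samples=10)


class TestSimulation:
    def test_same_seed_identical_cohorts(self, panel):
        cfg = SimConfig(n_samples=40, seed=11, p_bc=0.1, p_docked=0.2)
        a = simulate_cohort(cfg, panel)
        b = simulate_cohort(cfg, panel)
        assert a.profiles == b.profiles
        assert a.phenotypes == b.phenotypes
        assert a.hidden_factors == b.hidden_factors

    def test_lethal_genotype_never_drawn(self, panel):
        cohort = simulate_cohort(SimConfig(n_samples=300, seed=5), panel)
        for p in cohort.profiles:
            assert p.calls["T-Box_C295G"].alleles != ("G", "G")

    def test_zero_noise_closure(self, panel):
        # every determined, observable trait matches the engine's prediction
        cohort = simulate_cohort(SimConfig(n_samples=200, seed=2), panel)
        reports = [predict_all(p, panel) for p in cohort.profiles]
        result = score_cohort(reports, cohort.phenotypes)
        for counts in result.counts.values():
            assert counts["mismatch"] == 0

    def test_hardy_weinberg_single_marker(self, panel):
        n = 4000
        cohort = simulate_cohort(SimConfig(n_samples=n, seed=9), panel)
        p_small = DEFAULT_LOCUS_FREQS["SIZE"]["A"]
        counts = {0: 0, 1: 0, 2: 0}
        for prof in cohort.profiles:
            counts[prof.calls["IGF1R"].count("A")] += 1
        expected = {
            2: p_small**2,
            1: 2 * p_small * (1 - p_small),
            0: (1 - p_small) ** 2,
        }
        for k, p in expected.items():
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts[k] / n - p) <= 3 * se

    def test_hidden_factors_explain_every_discordance(self, panel):
        cfg = SimConfig(
            n_samples=400, seed=17, p_bc=0.1, p_ancestral_bobtail=0.2,
            p_size_misclass=0.2,
        )
        cohort = simulate_cohort(cfg, panel)
        reports = {p.sample_id: predict_all(p, panel) for p in cohort.profiles}
        result = score_cohort(reports, cohort.phenotypes)
        for cell in result.cells:
            if cell.outcome != "mismatch":
                continue
            factors = cohort.hidden_factors[cell.sample_id]
            assert any(
                factors.get(ch)
                for ch in ("bc_allele", "ancestral_bobtail", "size_misclass")
            ), (cell, factors)


class TestFixtures:
    def test_cohort_sizes(self, cohorts):
        assert len(cohorts["pilot"].profiles) == 12
        assert len(cohorts["coat_colour"].profiles) == 16
        for name in ("coat_structure", "tail_length", "ear_shape", "body_size"):
            assert len(cohorts[name].profiles) == 10
        assert len(cohorts["blind"].profiles) == 9

    def test_coat_colour_fixture_missingness(self, cohorts):
        missing_asip = [
            p.sample_id
            for p in cohorts["coat_colour"].profiles
            if p.calls["ASIP_SINE"].is_missing
        ]
        assert sorted(missing_asip) == ["DE01_006", "DE01_052", "DE02_20"]

    def test_tail_fixture_three_discordant(self, panel, cohorts):
        cohort = cohorts["tail_length"]
        reports = [predict_all(p, panel) for p in cohort.profiles]
        result = score_cohort(reports, cohort.phenotypes)
        mismatched = sorted(
            c.sample_id for c in result.cells
            if c.trait == "tail_length" and c.outcome == "mismatch"
        )
        assert mismatched == ["AT0056", "AT0062", "AT0210"]
        assert all(
            cohort.hidden_factors[s]["ancestral_bobtail"] for s in mismatched
        )

    def test_pilot_state_coverage(self, panel, cohorts):
        # all previously described allelic states found except at PMEL,
        # PSMB7 and T-Box
        seen: dict[str, set] = {m.marker_id: set() for m in panel.markers}
        for prof in cohorts["pilot"].profiles:
            for mid, call in prof.calls.items():
                if not call.is_missing:
                    seen[mid].update(call.raw_states)
        for marker in panel.markers:
            expected = set(marker.states)
            if marker.marker_id == "PMEL":
                assert seen[marker.marker_id] == {"no SINE"}
            elif marker.marker_id == "PSMB7":
                assert seen[marker.marker_id] == {"T"}
            elif marker.marker_id == "T-Box_C295G":
                assert seen[marker.marker_id] == {"C"}
            else:
                assert seen[marker.marker_id] == expected, marker.marker_id

    def test_blind_trio_identity(self, panel, cohorts):
        profiles = cohorts["blind"].profiles
        non_ear = [m.marker_id for m in panel.markers if m.marker_id != "BICFPJ1062878"]
        keyed: dict[tuple, list[str]] = {}
        for p in profiles:
            key = tuple(p.calls[m].alleles for m in non_ear)
            keyed.setdefault(key, []).append(p.sample_id)
        trio = [ids for ids in keyed.values() if len(ids) == 3]
        assert trio == [["D4926", "D4928", "D4931"]]

    def test_blind_fully_genotyped(self, cohorts):
        assert all(p.n_missing() == 0 for p in cohorts["blind"].profiles)

    def test_cropped_tail_not_scored_genetic(self, panel, cohorts):
        cohort = cohorts["blind"]
        reports = [predict_all(p, panel) for p in cohort.profiles]
        result = score_cohort(reports, cohort.phenotypes)
        cell = next(
            c for c in result.cells
            if c.sample_id == "D4925" and c.trait == "tail_length"
        )
        assert cell.outcome == "not_assessable_phenotype"

    def test_fixture_determinism(self, panel, cohorts):
        again = make_reference_cohorts(panel)
        for name, cohort in cohorts.items():
            assert again[name].profiles == cohort.profiles
            assert again[name].phenotypes == cohort.phenotypes

    def test_ear_fixture_heterozygote_ambiguity(self, panel, cohorts):
        cohort = cohorts["ear_shape"]
        reports = [predict_all(p, panel) for p in cohort.profiles]
        ambiguous = [
            r.sample_id for r in reports
            if r.predictions["ear_shape"].certainty is Certainty.AMBIGUOUS
        ]
        assert len(ambiguous) == 6
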