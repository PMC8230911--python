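"""Dominance-hierarchy inference: locus reconstruction and trait rules."""

import json

import pytest

from caniphen.inference import (
    identikit_text,
    predict_all,
    predict_coat_colour,
    predict_coat_pattern,
    reconstruct_loci,
    reconstruct_locus,
)
from caniphen.io import GenotypeProfile
from caniphen.simulate import profile_from_loci
from caniphen.vocab import Certainty


def prof(panel, loci, missing=(), sid="T1"):
    return profile_from_loci(sid, loci, panel, missing=missing)


class TestLocusReconstruction:
    def test_ee_overrides_k_and_a(self, panel):
        states = reconstruct_loci(prof(panel, {"E": ("e", "e")}), panel)
        assert states["E"].genotype == ("e", "e")
        assert states["K"].relevance == "overridden"
        assert states["K"].overridden_by == "E"
        assert states["A"].relevance == "overridden"

    def test_kb_overrides_a_even_when_asip_missing(self, panel):
        p = prof(panel, {"K": ("K^B", "K^B")}, missing=("ASIP_SINE",))
        a = reconstruct_locus(p, "A", panel)
        assert a.relevance == "overridden"
        assert a.overridden_by == "K"
        # the prediction stays determined despite the missing marker
        pred = predict_all(p, panel).predictions["coat_colour"]
        assert pred.certainty is Certainty.DETERMINED

    def test_k_marker_disagreement_sets_conflict(self, panel):
        p = prof(panel, {"K": ("K^B", "k^y")})
        # overwrite the redundant SNP to a contradictory k^y/k^y call
        from caniphen.io import GenotypeCall

        marker = panel.marker_by_id("CBD103_S53")
        p.calls["CBD103_S53"] = GenotypeCall.from_states(marker, ("G", "G"))
        k = reconstruct_locus(p, "K", panel)
        assert k.conflict_flag
        assert k.genotype == ("K^B", "k^y")  # the causal micro-indel wins

    def test_em_assigned_to_non_e_dosage(self, panel):
        e = reconstruct_locus(prof(panel, {"E": ("E^m", "e")}), "E", panel)
        assert e.genotype == ("E^m", "e")
        assert e.expressed == "E^m"

    def test_mitf_snp_disagreement_flags_conflict(self, panel):
        p = prof(panel, {"S": ("S", "S")})
        from caniphen.io import GenotypeCall

        marker = panel.marker_by_id("MITF_SNP")
        p.calls["MITF_SNP"] = GenotypeCall.from_states(marker, ("G", "G"))
        s = reconstruct_locus(p, "S", panel)
        assert s.conflict_flag
        assert s.genotype == ("S", "S")  # SINE call wins


class TestCoatColour:
    def test_ee_red_regardless_of_downstream(self, panel):
        p = prof(panel, {"E": ("e", "e"), "B": ("B", "b^s")})
        pred = predict_all(p, panel).predictions["coat_colour"]
        assert pred.values == ("red/yellow/cream",)
        assert pred.certainty is Certainty.DETERMINED

    def test_compound_het_brown(self, panel):
        p = prof(panel, {"K": ("K^B", "K^B"), "B": ("b^s", "b^d")})
        pred = predict_all(p, panel).predictions["coat_colour"]
        assert pred.values == ("brown",)

    def test_blue_dilute_with_caveats(self, panel):
        p = prof(panel, {"K": ("K^B", "k^y"), "B": ("B", "B"), "D": ("d", "d")})
        report = predict_all(p, panel)
        colour = report.predictions["coat_colour"]
        assert colour.values == ("blue (diluted black)",)
        assert "untested_allele_bc" in colour.caveats
        assert "possible_brindle" in report.predictions["coat_pattern"].caveats

    def test_mask_modifier_and_solid_caveat(self, panel):
        masked_tan = prof(panel, {"E": ("E^m", "e"), "A": ("a^t", "a^t")})
        pred = predict_all(masked_tan, panel).predictions["coat_colour"]
        assert "melanistic mask" in pred.modifiers
        solid = prof(panel, {"E": ("E^m", "E"), "K": ("K^B", "K^B")})
        pred = predict_all(solid, panel).predictions["coat_colour"]
        assert "mask_not_visible_on_solid" in pred.caveats
        assert not pred.modifiers

    def test_agouti_hierarchy(self, panel):
        for geno, value in [
            (("A^y", "a"), "fawn/sable"),
            (("a^w", "a^t"), "agouti (wild type)"),
            (("a^t", "a"), "black with tan points"),
            (("a", "a"), "black"),
        ]:
            p = prof(panel, {"A": geno})
            pred = predict_all(p, panel).predictions["coat_colour"]
            assert pred.values == (value,), geno


class TestCoatPattern:
    def test_spotting_series(self, panel):
        for geno, value in [
            (("S", "S"), "solid or minimal white spotting"),
            (("S", "S^p"), "pseudo irish spotting"),
            (("S^p", "S^p"), "piebald or extreme white spotting"),
        ]:
            pred = predict_all(prof(panel, {"S": geno}), panel).predictions["coat_pattern"]
            assert pred.values == (value,)

    def test_harlequin_on_merle(self, panel):
        p = prof(panel, {"M": ("M", "m"), "H": ("H", "h")})
        pred = predict_all(p, panel).predictions["coat_pattern"]
        assert pred.values == ("harlequin",)

    def test_harlequin_requires_merle(self, panel):
        p = prof(panel, {"M": ("m", "m"), "H": ("H", "h")})
        pred = predict_all(p, panel).predictions["coat_pattern"]
        assert pred.values == ("solid or minimal white spotting",)

    def test_hidden_merle_on_ee(self, panel):
        p = prof(panel, {"E": ("e", "e"), "M": ("M", "m")})
        pred = predict_all(p, panel).predictions["coat_pattern"]
        assert "hidden_merle" in pred.caveats
        assert "merle" not in pred.values[0]

    def test_double_merle(self, panel):
        pred = predict_all(prof(panel, {"M": ("M", "M")}), panel).predictions["coat_pattern"]
        assert pred.values == ("mainly white (double merle)",)


class TestSingleMarkerTraits:
    def test_structure_composite(self, panel):
        p = prof(panel, {"FGF5": ("T", "T"), "KRT71": ("A", "G"),
                         "RSPO2": ("no Ins", "no Ins")})
        pred = predict_all(p, panel).predictions["coat_structure"]
        assert pred.values == ("long, wavy, no furnishings",)

    def test_structure_dominance(self, panel):
        short = predict_all(prof(panel, {"FGF5": ("G", "T")}), panel)
        assert short.predictions["coat_structure"].values[0].startswith("short")
        furn = predict_all(prof(panel, {"RSPO2": ("Ins", "no Ins")}), panel)
        assert furn.predictions["coat_structure"].values[0].endswith(", furnishings")

    def test_structure_missing_axis_inconclusive(self, panel):
        p = prof(panel, {"FGF5": ("T", "T")}, missing=("KRT71",))
        pred = predict_all(p, panel).predictions["coat_structure"]
        assert pred.certainty is Certainty.INCONCLUSIVE
        assert any("curl" in line for line in pred.derivation)

    def test_tail_rules(self, panel):
        bob = predict_all(prof(panel, {"TAIL": ("G", "C")}), panel).predictions["tail_length"]
        assert bob.values == ("bobtail",)
        long = predict_all(prof(panel, {"TAIL": ("C", "C")}), panel).predictions["tail_length"]
        assert long.values == ("long tail",)
        assert {"possible_docking", "possible_ancestral_bobtail"} <= set(long.caveats)
        lethal = predict_all(prof(panel, {"TAIL": ("G", "G")}), panel).predictions["tail_length"]
        assert lethal.certainty is Certainty.INCONCLUSIVE
        assert "lethal_genotype_observed" in lethal.caveats

    def test_ear_rules(self, panel):
        drop = predict_all(prof(panel, {"EAR": ("A", "A")}), panel).predictions["ear_shape"]
        assert drop.values == ("drop ears",)
        het = predict_all(prof(panel, {"EAR": ("G", "A")}), panel).predictions["ear_shape"]
        assert het.certainty is Certainty.AMBIGUOUS
        assert set(het.values) == {"drop ears", "non-drop ears"}
        missing = predict_all(prof(panel, {}, missing=("BICFPJ1062878",)), panel)
        assert missing.predictions["ear_shape"].certainty is Certainty.NOT_EVALUABLE

    def test_size_dominant_small(self, panel):
        for geno, value in [(("A", "A"), "rather small"), (("A", "G"), "rather small"),
                            (("G", "G"), "rather tall")]:
            pred = predict_all(prof(panel, {"SIZE": geno}), panel).predictions["body_size"]
            assert pred.values == (value,)


class TestDominanceMonotonicity:
    """Replacing one recessive allele by its dominant counterpart never flips
    a prediction from the dominant phenotype to the recessive one."""

    @pytest.mark.parametrize(
        "locus,recessive,dominant,trait",
        [
            ("SIZE", "G", "A", "body_size"),
            ("FGF5", "T", "G", "coat_structure"),
            ("RSPO2", "no Ins", "Ins", "coat_structure"),
            ("D", "d", "D", "coat_colour"),
            ("K", "k^y", "K^B", "coat_colour"),
        ],
    )
    def test_single_locus_perturbation(self, panel, locus, recessive, dominant, trait):
        base_het = prof(panel, {locus: (dominant, recessive)})
        base_hom = prof(panel, {locus: (dominant, dominant)})
        het_value = predict_all(base_het, panel).predictions[trait].values
        hom_value = predict_all(base_hom, panel).predictions[trait].values
        assert het_value == hom_value


class TestPredictAll:
    def test_deterministic_and_pure(self, panel, cohorts):
        p = cohorts["blind"].profiles[1]
        a = json.dumps(predict_all(p, panel).to_dict(), sort_keys=True)
        b = json.dumps(predict_all(p, panel).to_dict(), sort_keys=True)
        assert a == b

    def test_equal_profiles_equal_identikits(self, panel, cohorts):
        by_id = {p.sample_id: p for p in cohorts["blind"].profiles}
        r26 = predict_all(by_id["D4926"], panel)
        r28 = predict_all(by_id["D4928"], panel)
        assert r26.identikit == r28.identikit

    def test_blind_tanpoint_identikit_phrases(self, panel, cohorts):
        by_id = {p.sample_id: p for p in cohorts["blind"].profiles}
        text = predict_all(by_id["D4926"], panel).identikit
        for phrase in ("black with tan points", "minimal white spotting",
                       "long smooth hair", "long tail", "rather tall"):
            assert phrase in text
        assert text.index("black with tan points") < text.index("long tail") < text.index("rather tall")

    def test_all_missing_profile(self, panel):
        empty = GenotypeProfile.build("BLANK", {}, panel)
        report = predict_all(empty, panel)
        assert all(
            p.certainty is Certainty.NOT_EVALUABLE for p in report.predictions.values()
        )
        assert report.identikit == "no traits evaluable from this profile"

    def test_override_completeness(self, panel):
        # determined despite a MISSING marker: the derivation names the
        # overriding locus
        p = prof(panel, {"E": ("e", "e")}, missing=("ASIP_SINE", "CBD103_S54", "CBD103_S53"))
        pred = predict_all(p, panel).predictions["coat_colour"]
        assert pred.certainty is Certainty.DETERMINED
        assert any("overridden" in line and "K and A" in line for line in pred.derivation)

    def test_identikit_exclude(self, panel, cohorts):
        by_id = {p.sample_id: p for p in cohorts["blind"].profiles}
        r26 = predict_all(by_id["D4926"], panel)
        r31 = predict_all(by_id["D4931"], panel)
        assert r26.identikit != r31.identikit
        assert identikit_text(r26.predictions, exclude=("ear_shape",)) == identikit_text(
            r31.predictions, exclude=("ear_shape",)
        )
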