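"""Trace calling: point variants, out-of-phase insertion superposition."""

import random

import pytest

from caniphen.traces import (
    TraceRead,
    TraceCallError,
    Zygosity,
    call_point_variant,
    call_profile,
    resolve_superposition,
    synthesize_trace,
)

# ---------------------------------------------------------------------------
# Independent oracle: builds the ideal trace for each zygosity directly from
# the definition (per-position expected base sets of the two aligned alleles).


def ideal_trace(short: str, long: str, zygosity: str, marker_id: str = "X") -> TraceRead:
    if zygosity == "hom_short":
        return TraceRead(marker_id, short, "-" * len(short))
    if zygosity == "hom_long":
        return TraceRead(marker_id, long, "-" * len(long))
    primary, secondary = [], []
    for i in range(len(long)):
        sh = short[i] if i < len(short) else None
        primary.append(long[i])
        secondary.append(sh if sh is not None and sh != long[i] else "-")
    return TraceRead(marker_id, "".join(primary), "".join(secondary))


def random_allele_pair(rng: random.Random, min_window: int = 15):
    """(short, long) with the divergence point far enough from the short end,
    and with the three ideal traces pairwise distinct (degenerate periodic
    insertions are regenerated)."""
    while True:
        n = rng.randint(40, 60)
        short = "".join(rng.choice("ACGT") for _ in range(n))
        pos = rng.randint(5, 25)
        block = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
        long = short[:pos] + block + short[pos:]
        d = next((i for i in range(len(short)) if short[i] != long[i]), len(short))
        if d + min_window > len(short):
            continue
        traces = [ideal_trace(short, long, z).primary + "|" + ideal_trace(short, long, z).secondary
                  for z in ("hom_short", "hom_long", "het")]
        if len(set(traces)) == 3:
            return short, long


class TestSuperposition:
    def test_worked_example_het(self):
        short, long = "ACGTACGTACGTACGTACGT", "ACGT" + "TTT" + "ACGTACGTACGTACGT"
        trace = ideal_trace(short, long, "het")
        assert resolve_superposition(trace, short, long) is Zygosity.HET

    def test_hom_long_identity(self):
        short, long = "ACGTACGTACGTACGTACGT", "ACGT" + "TTT" + "ACGTACGTACGTACGT"
        trace = ideal_trace(short, long, "hom_long")
        assert resolve_superposition(trace, short, long) is Zygosity.HOM_LONG

    @pytest.mark.parametrize("zygosity,expected", [
        ("hom_short", Zygosity.HOM_SHORT),
        ("hom_long", Zygosity.HOM_LONG),
        ("het", Zygosity.HET),
    ])
    def test_oracle_equivalence_random(self, zygosity, expected):
        rng = random.Random(20240600 + len(zygosity))
        for _ in range(200):
            short, long = random_allele_pair(rng)
            trace = ideal_trace(short, long, zygosity)
            assert resolve_superposition(trace, short, long) is expected

    def test_perturbation_scan_inconsistent(self):
        # a single mutated position anywhere breaks all three hypotheses
        rng = random.Random(7)
        short, long = random_allele_pair(rng)
        trace = ideal_trace(short, long, "het")
        for i in range(len(trace.primary)):
            wrong = next(
                b for b in "ACGT" if b != trace.primary[i] and b != trace.secondary[i]
            )
            mutated = TraceRead(
                "X", trace.primary[:i] + wrong + trace.primary[i + 1 :], trace.secondary
            )
            assert resolve_superposition(mutated, short, long) is Zygosity.INCONSISTENT

    def test_short_read_is_insufficient(self):
        short, long = "ACGTACGTACGTACGTACGT", "ACGT" + "TTT" + "ACGTACGTACGTACGT"
        trace = ideal_trace(short, long, "het")
        clipped = TraceRead("X", trace.primary[:10], trace.secondary[:10])
        assert resolve_superposition(clipped, short, long) is Zygosity.INSUFFICIENT

    def test_degenerate_insertion_right_shifted(self):
        # block starts with the base that follows the insertion site: the
        # divergence point shifts right; classification is unaffected
        short = "AAACGTGTCAGTACGTGGCATCAGTTACGATG"
        long = short[:3] + "CGTT" + short[3:]  # insert "CGTT" before "CGT..."
        for zyg, expected in [
            ("hom_short", Zygosity.HOM_SHORT),
            ("hom_long", Zygosity.HOM_LONG),
            ("het", Zygosity.HET),
        ]:
            trace = ideal_trace(short, long, zyg)
            assert resolve_superposition(trace, short, long, min_window=10) is expected


class TestPointVariants:
    def test_hom_and_het_snp(self, panel):
        marker = panel.marker_by_id("MC1R_306ter")
        hom = synthesize_trace(marker, ("E", "E"))
        assert call_point_variant(hom, marker).alleles == ("E", "E")
        het = synthesize_trace(marker, ("E", "e"))
        call = call_point_variant(het, marker)
        assert call.alleles == ("E", "e")

    def test_unrecognized_base_raises(self, panel):
        marker = panel.marker_by_id("MC1R_306ter")
        trace = synthesize_trace(marker, ("E", "E"))
        ctx = marker.reference_context["E"]
        v = next(i for i, (x, y) in enumerate(zip(ctx, marker.reference_context["e"])) if x != y)
        bad = TraceRead(
            marker.marker_id,
            trace.primary[:v] + "A" + trace.primary[v + 1 :],  # A is not C/T
            trace.secondary,
        )
        with pytest.raises(TraceCallError, match="unrecognized"):
            call_point_variant(bad, marker)

    def test_anchor_failure_returns_missing(self, panel):
        marker = panel.marker_by_id("MC1R_306ter")
        stray = TraceRead(marker.marker_id, "ACGT" * 10, "-" * 40)
        assert call_point_variant(stray, marker).is_missing

    def test_micro_indel_het(self, panel):
        marker = panel.marker_by_id("CBD103_S54")
        call = call_point_variant(marker=marker, trace=synthesize_trace(marker, ("K^B", "k^y")))
        assert call.alleles == ("K^B", "k^y")


class TestStrandInvariance:
    @pytest.mark.parametrize(
        "marker_id,genotype",
        [
            ("MC1R_306ter", ("E", "e")),
            ("ASIP_SINE", ("a^t", "a^w")),
            ("RSPO2", ("Ins", "no Ins")),
            ("TYRP1_345delP", ("B", "b^d")),
            ("PMEL", ("M", "M")),
        ],
    )
    def test_reverse_equals_forward(self, panel, marker_id, genotype):
        marker = panel.marker_by_id(marker_id)
        fwd = synthesize_trace(marker, genotype, "forward")
        rev = synthesize_trace(marker, genotype, "reverse")
        profile_f, _ = call_profile([fwd], panel, "S")
        profile_r, _ = call_profile([rev], panel, "S")
        assert profile_f.calls[marker_id] == profile_r.calls[marker_id]


class TestCallProfile:
    def test_full_panel(self, panel, cohorts):
        profile = cohorts["blind"].profiles[0]
        traces = [
            synthesize_trace(panel.marker_by_id(mid), call.alleles)
            for mid, call in profile.calls.items()
        ]
        called, errors = call_profile(traces, panel, profile.sample_id)
        assert errors == {}
        assert called.n_missing() == 0
        assert all(
            called.calls[m].alleles == profile.calls[m].alleles for m in called.calls
        )

    def test_omitted_marker_is_missing(self, panel, cohorts):
        profile = cohorts["blind"].profiles[0]
        traces = [
            synthesize_trace(panel.marker_by_id(mid), call.alleles)
            for mid, call in profile.calls.items()
            if mid != "ASIP_SINE"
        ]
        called, errors = call_profile(traces, panel, profile.sample_id)
        assert called.calls["ASIP_SINE"].is_missing
        assert errors == {}

    def test_errors_aggregated_not_fatal(self, panel):
        marker = panel.marker_by_id("MC1R_306ter")
        trace = synthesize_trace(marker, ("E", "E"))
        ctx = marker.reference_context["E"]
        v = next(i for i, (x, y) in enumerate(zip(ctx, marker.reference_context["e"])) if x != y)
        bad = TraceRead(
            marker.marker_id, trace.primary[:v] + "A" + trace.primary[v + 1 :], trace.secondary
        )
        profile, errors = call_profile([bad], panel, "S1")
        assert "MC1R_306ter" in errors
        assert profile.calls["MC1R_306ter"].is_missing
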