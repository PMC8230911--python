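"""Genotype -> visible-trait inference.

Translates a :class:`~caniphen.io.GenotypeProfile` into six trait predictions
by applying the classical dominance hierarchy of the canine coat-colour loci
and the single-marker rules for structure, tail, ear and size.

The epistatic cascade for fur colour runs E -> K -> A -> B -> D:

* ``e/e`` at MC1R hides everything downstream -- the coat is red/yellow/cream
  regardless of the K and A genotypes (and merle becomes invisible);
* otherwise a ``K^B`` allele at CBD103 forces solid eumelanin and silences the
  A locus;
* otherwise (``k^y/k^y``) the top-ranked ASIP allele is expressed, in the
  order ``A^y > a^w > a^t > a``;
* the B locus renders eumelanin brown when two recessive TYRP1 alleles are
  present (compound heterozygotes count), else black;
* ``d/d`` at MLPH dilutes both pigments (black -> blue, brown -> isabella,
  red/yellow/cream -> pale cream).

Unphased shortcuts reconstruct each locus from its redundant markers; the
assumptions they rest on (one ASIP/TYRP1 variant per haplotype, E^m assigned
only to non-e dosage) are recorded in every derivation chain they touch.
Conflicts between redundant markers and missing data are carried as states,
never exceptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .io import GenotypeCall, GenotypeProfile
from .panel import PanelConfig
from .vocab import CAVEAT_CODES, Certainty

__all__ = [
    "LocusState",
    "TraitPrediction",
    "SampleReport",
    "reconstruct_locus",
    "reconstruct_loci",
    "predict_coat_colour",
    "predict_coat_pattern",
    "predict_coat_structure",
    "predict_tail",
    "predict_ear",
    "predict_size",
    "predict_all",
    "identikit_text",
]

COAT_LOCI = ("E", "K", "A", "B", "D", "S", "M", "H")


@dataclass
class LocusState:
    """Reconstructed genotype at one classical locus."""

    locus: str
    genotype: Optional[tuple[str, str]]  # unordered, canonically sorted
    expressed: Optional[str] = None      # top-of-hierarchy allele, if decidable
    basis: tuple[str, ...] = ()          # marker ids used
    conflict_flag: bool = False
    missing_flag: bool = False
    relevance: str = "relevant"          # relevant | overridden | not_evaluable
    overridden_by: Optional[str] = None
    notes: tuple[str, ...] = ()

    def has(self, allele: str) -> bool:
        return self.genotype is not None and allele in self.genotype

    def is_hom(self, allele: str) -> bool:
        return self.genotype == (allele, allele)

    def count(self, allele: str) -> int:
        if self.genotype is None:
            return 0
        return sum(1 for a in self.genotype if a == allele)


@dataclass(frozen=True)
class TraitPrediction:
    """Predicted state(s) for one trait category with a certainty grade."""

    trait: str
    values: tuple[str, ...]
    certainty: Certainty
    caveats: tuple[str, ...] = ()
    derivation: tuple[str, ...] = ()
    modifiers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.certainty is Certainty.DETERMINED and len(self.values) != 1:
            raise ValueError(f"{self.trait}: determined requires exactly one value")
        if self.certainty is Certainty.NOT_EVALUABLE and self.values:
            raise ValueError(f"{self.trait}: not_evaluable carries no value")
        unknown = set(self.caveats) - CAVEAT_CODES
        if unknown:
            raise ValueError(f"{self.trait}: undocumented caveat code(s) {unknown}")

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "values": list(self.values),
            "certainty": self.certainty.value,
            "caveats": list(self.caveats),
            "derivation": list(self.derivation),
            "modifiers": list(self.modifiers),
        }


def _pred(
    trait: str,
    values,
    certainty: Certainty,
    caveats=(),
    derivation=(),
    modifiers=(),
) -> TraitPrediction:
    return TraitPrediction(
        trait=trait,
        values=tuple(sorted(set(values))) if certainty is Certainty.AMBIGUOUS else tuple(values),
        certainty=certainty,
        caveats=tuple(sorted(set(caveats))),
        derivation=tuple(derivation),
        modifiers=tuple(modifiers),
    )


# ---------------------------------------------------------------------------
# Locus reconstruction


def _sorted_genotype(alleles) -> tuple[str, str]:
    a, b = sorted(alleles)
    return (a, b)


def _reconstruct_E(profile: GenotypeProfile) -> LocusState:
    """E series E^m > E > e: e dosage from MC1R_306ter; E^m assigned only to
    the non-e dosage (phase between the two MC1R SNPs is unrecoverable)."""
    m306 = profile.call("MC1R_306ter")
    m264 = profile.call("MC1R_M264V")
    basis = ("MC1R_306ter", "MC1R_M264V")
    if m306.is_missing:
        return LocusState("E", None, basis=basis, missing_flag=True)
    e_count = m306.count("e")
    notes = []
    if m264.is_missing:
        genotype = _sorted_genotype(("e",) * e_count + ("E",) * (2 - e_count))
        if e_count < 2:
            notes.append("mask_status_unknown: MC1R_M264V missing")
        expressed = "e" if e_count == 2 else "E"
        return LocusState(
            "E", genotype, expressed=expressed, basis=basis, notes=tuple(notes)
        )
    g_count = m264.count("E^m")
    em = min(g_count, 2 - e_count)
    if g_count > 2 - e_count:
        notes.append("M264V G dosage exceeds non-e dosage; surplus ignored (e is epistatic)")
    genotype = _sorted_genotype(("e",) * e_count + ("E^m",) * em + ("E",) * (2 - e_count - em))
    expressed = "e" if e_count == 2 else ("E^m" if em else "E")
    return LocusState("E", genotype, expressed=expressed, basis=basis, notes=tuple(notes))


def _reconstruct_K(profile: GenotypeProfile) -> LocusState:
    """K from the redundant CBD103 markers; agreement required, the causal
    micro-indel (S54) wins on disagreement with the conflict flag set."""
    s54 = profile.call("CBD103_S54")
    s53 = profile.call("CBD103_S53")
    basis = ("CBD103_S54", "CBD103_S53")
    if s54.is_missing and s53.is_missing:
        return LocusState("K", None, basis=basis, missing_flag=True)
    primary = s54 if not s54.is_missing else s53
    conflict = (
        not s54.is_missing and not s53.is_missing and s54.alleles != s53.alleles
    )
    genotype = _sorted_genotype(primary.alleles)
    expressed = "K^B" if "K^B" in genotype else "k^y"
    return LocusState("K", genotype, expressed=expressed, basis=basis, conflict_flag=conflict)


def _reconstruct_A(profile: GenotypeProfile) -> LocusState:
    """Unphased ASIP shortcut over the dominance series A^y > a^w > a^t > a.

    Any A^y-defining variant (S82 T or H83 A) expresses A^y.  Otherwise, under
    the assumption that at most one ASIP variant sits on a haplotype, a
    variant-free haplotype exists iff the SINE and R96 variant dosages sum to
    at most one, and then a^w is expressed; else the SINE (a^t) outranks
    recessive black (a)."""
    s82 = profile.call("ASIP_S82")
    h83 = profile.call("ASIP_H83")
    sine = profile.call("ASIP_SINE")
    r96 = profile.call("ASIP_R96")
    basis = ("ASIP_S82", "ASIP_H83", "ASIP_SINE", "ASIP_R96")
    calls = (s82, h83, sine, r96)
    if all(c.is_missing for c in calls):
        return LocusState("A", None, basis=basis, missing_flag=True)
    notes = ["assumes at most one ASIP variant per haplotype"]
    conflict = False
    ay_counts = [c.count("A^y") for c in (s82, h83) if not c.is_missing]
    n_ay = max(ay_counts) if ay_counts else 0
    if len(ay_counts) == 2 and ay_counts[0] != ay_counts[1]:
        conflict = True
        notes.append("S82/H83 A^y dosages disagree")
    if n_ay == 2:
        return LocusState(
            "A", ("A^y", "A^y"), expressed="A^y", basis=basis,
            conflict_flag=conflict, notes=tuple(notes),
        )
    if sine.is_missing or r96.is_missing:
        if n_ay > 0:
            # top-ranked allele already present; partner haplotype unknown
            return LocusState(
                "A", None, expressed="A^y", basis=basis, conflict_flag=conflict,
                missing_flag=True, notes=tuple(notes + ["partner haplotype unresolved"]),
            )
        return LocusState(
            "A", None, basis=basis, conflict_flag=conflict, missing_flag=True,
            notes=tuple(notes),
        )
    n_at = sine.count("a^t")
    n_a = r96.count("a")
    total = n_ay + n_at + n_a
    if total > 2:
        conflict = True
        notes.append("variant dosages exceed two haplotypes")
        expressed = "A^y" if n_ay else ("a^t" if n_at else "a")
        return LocusState(
            "A", None, expressed=expressed, basis=basis, conflict_flag=True,
            notes=tuple(notes),
        )
    n_aw = 2 - total
    genotype = _sorted_genotype(
        ("A^y",) * n_ay + ("a^w",) * n_aw + ("a^t",) * n_at + ("a",) * n_a
    )
    if n_ay:
        expressed = "A^y"
    elif n_aw:
        expressed = "a^w"
    elif n_at:
        expressed = "a^t"
    else:
        expressed = "a"
    return LocusState(
        "A", genotype, expressed=expressed, basis=basis, conflict_flag=conflict,
        notes=tuple(notes),
    )


def _reconstruct_B(profile: GenotypeProfile) -> LocusState:
    """Brown requires two recessive TYRP1 alleles across Q331ter and 345delP,
    compound heterozygotes included (the variants are assumed never to share a
    haplotype)."""
    q = profile.call("TYRP1_Q331ter")
    p = profile.call("TYRP1_345delP")
    basis = ("TYRP1_Q331ter", "TYRP1_345delP")
    if q.is_missing and p.is_missing:
        return LocusState("B", None, basis=basis, missing_flag=True)
    notes = ["assumes b^s and b^d never share a haplotype"]
    partial = q.is_missing or p.is_missing
    if partial:
        notes.append("one TYRP1 marker missing; recessive count is a lower bound")
    n_bs = q.count("b^s")
    n_bd = p.count("b^d")
    total = n_bs + n_bd
    if total > 2:
        return LocusState(
            "B", None, expressed="b", basis=basis, conflict_flag=True,
            notes=tuple(notes + ["recessive dosage exceeds two haplotypes"]),
        )
    genotype = _sorted_genotype(("b^s",) * n_bs + ("b^d",) * n_bd + ("B",) * (2 - total))
    expressed = "b" if total >= 2 else "B"
    return LocusState(
        "B", genotype, expressed=expressed, basis=basis, missing_flag=partial,
        notes=tuple(notes),
    )


def _reconstruct_single(profile: GenotypeProfile, locus: str, marker_id: str) -> LocusState:
    call = profile.call(marker_id)
    if call.is_missing:
        return LocusState(locus, None, basis=(marker_id,), missing_flag=True)
    return LocusState(locus, _sorted_genotype(call.alleles), basis=(marker_id,))


def _reconstruct_S(profile: GenotypeProfile) -> LocusState:
    """Spotting from the MITF SINE; the linked SNP is secondary evidence only
    (dominance not clarified) -- opposite homozygotes set the conflict flag,
    the SINE call wins."""
    state = _reconstruct_single(profile, "S", "MITF_INS")
    state.basis = ("MITF_INS", "MITF_SNP")
    snp = profile.call("MITF_SNP")
    if state.genotype is not None and not snp.is_missing:
        if (state.is_hom("S") and snp.alleles == ("S^p", "S^p")) or (
            state.is_hom("S^p") and snp.alleles == ("S", "S")
        ):
            state.conflict_flag = True
            state.notes = state.notes + ("MITF_SNP disagrees; SINE call wins",)
    if state.genotype is not None:
        state.expressed = "S^p" if "S^p" in state.genotype else "S"
    return state


def reconstruct_loci(profile: GenotypeProfile, panel: PanelConfig) -> dict[str, LocusState]:
    """Reconstruct all eight coat loci and mark epistatic overrides.

    ``e/e`` at E overrides K and A; a ``K^B`` allele at K overrides A.  An
    overridden locus stays overridden even when its markers are missing -- the
    prediction can remain determined without it."""
    states = {
        "E": _reconstruct_E(profile),
        "K": _reconstruct_K(profile),
        "A": _reconstruct_A(profile),
        "B": _reconstruct_B(profile),
        "D": _reconstruct_single(profile, "D", "MLPH_157471_c.-22G>A"),
        "S": _reconstruct_S(profile),
        "M": _reconstruct_single(profile, "M", "PMEL"),
        "H": _reconstruct_single(profile, "H", "PSMB7"),
    }
    for locus in ("D", "M", "H"):
        st = states[locus]
        if st.genotype is not None:
            recessive = {"D": "d", "M": "m", "H": "h"}[locus]
            dominant = {"D": "D", "M": "M", "H": "H"}[locus]
            st.expressed = dominant if dominant in st.genotype else recessive
    e = states["E"]
    if e.expressed == "e":
        for locus in ("K", "A"):
            states[locus].relevance = "overridden"
            states[locus].overridden_by = "E"
    elif states["K"].has("K^B"):
        states["A"].relevance = "overridden"
        states["A"].overridden_by = "K"
    for locus, st in states.items():
        if st.missing_flag and st.genotype is None and st.relevance == "relevant":
            if st.expressed is None:
                st.relevance = "not_evaluable"
    return states


def reconstruct_locus(profile: GenotypeProfile, locus: str, panel: PanelConfig) -> LocusState:
    """Reconstruct a single locus (context-aware: overrides are applied)."""
    states = reconstruct_loci(profile, panel)
    if locus not in states:
        raise LookupError(f"unknown locus {locus!r}")
    return states[locus]


# ---------------------------------------------------------------------------
# Coat colour


def _eumelanin_shades(b_state: LocusState, d_state: LocusState, derivation: list[str]):
    """Possible eumelanin shade(s) given the B and D states; enumerates both
    branches of any locus that cannot be resolved."""
    if b_state.genotype is not None:
        brown_opts = [sum(1 for a in b_state.genotype if a != "B") >= 2]
    elif b_state.expressed == "b":
        brown_opts = [True]
    else:
        brown_opts = [True, False]
        derivation.append("B locus unresolved: black and brown both possible")
    if d_state.genotype is not None:
        dilute_opts = [d_state.is_hom("d")]
    else:
        dilute_opts = [True, False]
        derivation.append("D locus unresolved: dilution unknown")
    shades = set()
    for brown in brown_opts:
        for dilute in dilute_opts:
            if brown:
                shades.add("isabella (diluted brown)" if dilute else "brown")
            else:
                shades.add("blue (diluted black)" if dilute else "black")
    return shades


def _phaeomelanin_values(d_state: LocusState, base: str, derivation: list[str]):
    diluted = {
        "red/yellow/cream": "pale cream (diluted red/yellow/cream)",
        "fawn/sable": "fawn/sable (diluted)",
        "agouti (wild type)": "agouti (wild type, diluted)",
    }[base]
    if d_state.genotype is not None:
        if d_state.is_hom("d"):
            derivation.append("D locus d/d: pigment diluted")
            return {diluted}
        return {base}
    derivation.append("D locus unresolved: dilution unknown")
    return {base, diluted}


def predict_coat_colour(locus_states: dict[str, LocusState]) -> TraitPrediction:
    """Fur base colour from the E -> K -> A -> B -> D cascade."""
    e, k, a = locus_states["E"], locus_states["K"], locus_states["A"]
    b, d = locus_states["B"], locus_states["D"]
    derivation: list[str] = []
    caveats: list[str] = []
    modifiers: list[str] = []
    for st in (e, k, a, b, d):
        if st.conflict_flag:
            derivation.append(f"{st.locus} locus: redundant markers disagree (conflict)")
    if e.genotype is None and e.expressed is None:
        return _pred(
            "coat_colour", (), Certainty.NOT_EVALUABLE,
            derivation=["E locus not evaluable: MC1R_306ter missing"],
        )
    # melanistic mask bookkeeping (resolved once the base is known)
    mask_present = e.has("E^m")
    mask_unknown = any(n.startswith("mask_status_unknown") for n in e.notes)

    if e.expressed == "e":
        derivation.append(
            "E locus e/e: phaeomelanin coat; K and A loci are overridden (epistasis)"
        )
        values = _phaeomelanin_values(d, "red/yellow/cream", derivation)
        certainty = Certainty.DETERMINED if len(values) == 1 else Certainty.AMBIGUOUS
        return _pred("coat_colour", sorted(values), certainty, caveats, derivation)

    solid = False
    tan = False
    base: Optional[str] = None  # None -> eumelanin shade; else phaeomelanin-class base
    if k.has("K^B"):
        derivation.append("K locus carries K^B: solid eumelanin; A locus overridden")
        solid = True
    elif k.genotype is None:
        derivation.append("K locus not resolvable: solid vs. agouti expression unknown")
        return _pred("coat_colour", (), Certainty.INCONCLUSIVE, caveats, derivation)
    else:
        derivation.append("K locus k^y/k^y: A locus is expressed")
        if a.expressed is None:
            derivation.append("A locus not resolvable")
            return _pred("coat_colour", (), Certainty.INCONCLUSIVE, caveats, derivation)
        derivation.append(f"A locus expresses {a.expressed} (A^y > a^w > a^t > a)")
        if a.expressed == "A^y":
            base = "fawn/sable"
        elif a.expressed == "a^w":
            base = "agouti (wild type)"
        elif a.expressed == "a^t":
            tan = True
        else:  # recessive black
            solid = True

    if base is not None:
        values = _phaeomelanin_values(d, base, derivation)
    else:
        shades = _eumelanin_shades(b, d, derivation)
        if b.genotype is None or sum(1 for x in b.genotype if x != "B") <= 1:
            caveats.append("untested_allele_bc")
            derivation.append(
                "B reconstruction compatible with B/B or B/b: an untested brown "
                "allele (b^c) cannot be excluded"
            )
        values = {f"{s} with tan points" if tan else s for s in shades}
        if tan:
            derivation.append("a^t expressed: tan points on the eumelanin base")

    if mask_present:
        if solid and base is None:
            caveats.append("mask_not_visible_on_solid")
            derivation.append("E^m present: melanistic mask (indistinct on a solid coat)")
        else:
            modifiers.append("melanistic mask")
            derivation.append("E^m present: melanistic mask")
    elif mask_unknown:
        derivation.append("melanistic-mask status unknown (MC1R_M264V missing)")

    certainty = Certainty.DETERMINED if len(values) == 1 else Certainty.AMBIGUOUS
    return _pred("coat_colour", sorted(values), certainty, caveats, derivation, modifiers)


# ---------------------------------------------------------------------------
# Coat pattern


def predict_coat_pattern(locus_states: dict[str, LocusState]) -> TraitPrediction:
    """White spotting, merle and harlequin overlays."""
    s, m, h, e, k = (
        locus_states["S"],
        locus_states["M"],
        locus_states["H"],
        locus_states["E"],
        locus_states["K"],
    )
    derivation: list[str] = []
    caveats: list[str] = []
    if k.genotype == ("K^B", "k^y"):
        caveats.append("possible_brindle")
        derivation.append(
            "K^B/k^y: a brindle pattern cannot be excluded (K^br is not genotyped)"
        )
    if s.genotype is None and m.genotype is None:
        return _pred(
            "coat_pattern", (), Certainty.NOT_EVALUABLE, caveats,
            derivation + ["spotting and merle markers missing"],
        )
    if s.conflict_flag:
        derivation.append("S locus: MITF_SNP disagrees with the SINE; SINE call wins")
    spotting = None
    if s.genotype is not None:
        spotting = {
            ("S", "S"): "solid or minimal white spotting",
            ("S", "S^p"): "pseudo irish spotting",
            ("S^p", "S^p"): "piebald or extreme white spotting",
        }[s.genotype]
        derivation.append(f"MITF SINE {s.genotype[0]}/{s.genotype[1]}: {spotting}")
    if m.genotype is None or spotting is None:
        derivation.append("pattern markers partially missing")
        values = (spotting,) if spotting else ()
        return _pred("coat_pattern", values, Certainty.INCONCLUSIVE, caveats, derivation)

    merle_dose = m.count("M")
    if merle_dose and e.expressed == "e":
        caveats.append("hidden_merle")
        derivation.append(
            "M allele present but e/e: merle is phenotypically invisible (hidden merle)"
        )
        merle_dose = 0
    if merle_dose == 2:
        derivation.append("PMEL M/M: mainly white (double merle)")
        return _pred(
            "coat_pattern", ("mainly white (double merle)",), Certainty.DETERMINED,
            caveats, derivation,
        )
    if merle_dose == 1:
        if h.genotype is not None and h.has("H"):
            derivation.append("M/m with H: harlequin (expressed on a merle background)")
            return _pred("coat_pattern", ("harlequin",), Certainty.DETERMINED, caveats, derivation)
        if h.genotype is None:
            derivation.append("M/m but H locus missing: harlequin cannot be excluded")
            merle_value = (
                "merle" if spotting == "solid or minimal white spotting" else f"merle + {spotting}"
            )
            return _pred(
                "coat_pattern", (merle_value, "harlequin"), Certainty.AMBIGUOUS,
                caveats, derivation,
            )
        derivation.append("PMEL M/m: merle")
        value = "merle" if spotting == "solid or minimal white spotting" else f"merle + {spotting}"
        return _pred("coat_pattern", (value,), Certainty.DETERMINED, caveats, derivation)
    if h.genotype is not None and h.has("H"):
        derivation.append("H allele without merle: harlequin is only expressed on merle")
    return _pred("coat_pattern", (spotting,), Certainty.DETERMINED, caveats, derivation)


# ---------------------------------------------------------------------------
# Single/multi-marker traits


def predict_coat_structure(profile: GenotypeProfile) -> TraitPrediction:
    """Hair length (FGF5, short dominant), furnishings (RSPO2 insertion,
    dominant) and curl (KRT71, semi-dominant: G/G curly, A/G wavy, A/A smooth)
    combined into one composite description."""
    fgf5 = profile.call("FGF5")
    rspo2 = profile.call("RSPO2")
    krt71 = profile.call("KRT71")
    derivation: list[str] = []
    length = curl = furn = None
    if not fgf5.is_missing:
        length = "short" if "G" in fgf5.alleles else "long"
        derivation.append(f"FGF5 {'/'.join(fgf5.alleles)}: {length} hair (short is dominant)")
    if not krt71.is_missing:
        curl = {0: "smooth", 1: "wavy", 2: "curly"}[krt71.count("G")]
        derivation.append(f"KRT71 {'/'.join(krt71.alleles)}: {curl} coat (semi-dominant)")
    if not rspo2.is_missing:
        furn = "furnishings" if "Ins" in rspo2.alleles else "no furnishings"
        derivation.append(f"RSPO2 {'/'.join(rspo2.alleles)}: {furn} (insertion is dominant)")
    axes = (length, curl, furn)
    if all(x is None for x in axes):
        return _pred(
            "coat_structure", (), Certainty.NOT_EVALUABLE,
            derivation=["all three structure markers missing"],
        )
    if any(x is None for x in axes):
        missing_axes = [
            name for name, x in zip(("length", "curl", "furnishings"), axes) if x is None
        ]
        derivation.append(f"missing axis/axes: {', '.join(missing_axes)}")
        return _pred("coat_structure", (), Certainty.INCONCLUSIVE, derivation=derivation)
    return _pred(
        "coat_structure", (f"{length}, {curl}, {furn}",), Certainty.DETERMINED,
        derivation=derivation,
    )


def predict_tail(profile: GenotypeProfile) -> TraitPrediction:
    """Tail length from the T-Box C189G mutation (heterozygotes are bobtailed;
    homozygous mutants are not viable)."""
    call = profile.call("T-Box_C295G")
    if call.is_missing:
        return _pred("tail_length", (), Certainty.NOT_EVALUABLE,
                     derivation=["tail marker missing"])
    g = call.count("G")
    if g == 2:
        return _pred(
            "tail_length", (), Certainty.INCONCLUSIVE,
            caveats=("lethal_genotype_observed",),
            derivation=[
                "T-Box G/G observed: homozygosity for the mutation is embryonic/"
                "early-postnatal lethal; the call is biologically implausible"
            ],
        )
    if g == 1:
        return _pred(
            "tail_length", ("bobtail",), Certainty.DETERMINED,
            derivation=["T-Box G/C: bobtail (dominant mutation)"],
        )
    return _pred(
        "tail_length", ("long tail",), Certainty.DETERMINED,
        caveats=("possible_docking", "possible_ancestral_bobtail"),
        derivation=[
            "T-Box C/C: long tail",
            "caveats: the tail may be docked, and some breeds are bobtailed "
            "without this mutation",
        ],
    )


def predict_ear(profile: GenotypeProfile) -> TraitPrediction:
    """Ear carriage from the single IGF2BP2-region SNP; heterozygotes admit
    both shapes (dominance not clarified)."""
    call = profile.call("BICFPJ1062878")
    if call.is_missing:
        return _pred("ear_shape", (), Certainty.NOT_EVALUABLE,
                     derivation=["ear marker missing"])
    if call.is_het:
        return _pred(
            "ear_shape", ("drop ears", "non-drop ears"), Certainty.AMBIGUOUS,
            caveats=("possible_cropping",),
            derivation=["BICFPJ1062878 G/A: no clear interpretation (both shapes observed)"],
        )
    value = "non-drop ears" if "G" in call.alleles else "drop ears"
    return _pred(
        "ear_shape", (value,), Certainty.DETERMINED,
        caveats=("possible_cropping",),
        derivation=[f"BICFPJ1062878 {'/'.join(call.alleles)}: {value}"],
    )


def predict_size(profile: GenotypeProfile) -> TraitPrediction:
    """Binary body-size class from IGF1R; the small-size A allele is treated
    as dominant (any A -> rather small)."""
    call = profile.call("IGF1R")
    if call.is_missing:
        return _pred("body_size", (), Certainty.NOT_EVALUABLE,
                     derivation=["size marker missing"])
    if "A" in call.alleles:
        return _pred(
            "body_size", ("rather small",), Certainty.DETERMINED,
            derivation=[
                f"IGF1R {'/'.join(call.alleles)}: rather small (A allele dominant)"
            ],
        )
    return _pred(
        "body_size", ("rather tall",), Certainty.DETERMINED,
        derivation=["IGF1R G/G: rather tall"],
    )


# ---------------------------------------------------------------------------
# Whole-sample prediction and identikit text


@dataclass
class SampleReport:
    """All six trait predictions for one sample plus the identikit text."""

    sample_id: str
    predictions: dict[str, TraitPrediction]
    identikit: str
    locus_states: dict[str, LocusState] = field(default_factory=dict)
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "calls": {
                mid: {
                    "alleles": list(c.alleles) if not c.is_missing else None,
                    "states": list(c.raw_states) if not c.is_missing else None,
                    "conflict": c.conflict_flag,
                }
                for mid, c in self.calls.items()
            },
            "predictions": {t: p.to_dict() for t, p in self.predictions.items()},
            "identikit": self.identikit,
        }


def predict_all(profile: GenotypeProfile, panel: PanelConfig) -> SampleReport:
    """Run every predictor and assemble the standardized identikit description.

    A pure function of the profile: repeated invocation is byte-identical."""
    states = reconstruct_loci(profile, panel)
    predictions = {
        "coat_colour": predict_coat_colour(states),
        "coat_pattern": predict_coat_pattern(states),
        "coat_structure": predict_coat_structure(profile),
        "tail_length": predict_tail(profile),
        "ear_shape": predict_ear(profile),
        "body_size": predict_size(profile),
    }
    return SampleReport(
        sample_id=profile.sample_id,
        predictions=predictions,
        identikit=identikit_text(predictions),
        locus_states=states,
        calls=dict(profile.calls),
    )


_TRAIT_ORDER = ("coat_colour", "coat_pattern", "coat_structure", "tail_length", "ear_shape", "body_size")


def _structure_phrase(value: str) -> str:
    length, curl, furn = value.split(", ")
    phrase = f"{length} {curl} hair"
    if furn == "furnishings":
        phrase += " with furnishings"
    return phrase


def identikit_text(predictions: dict[str, TraitPrediction], exclude: tuple[str, ...] = ()) -> str:
    """Composite textual description assembled from the predicted trait states."""
    phrases = []
    for trait in _TRAIT_ORDER:
        if trait in exclude or trait not in predictions:
            continue
        pred = predictions[trait]
        if pred.certainty in (Certainty.NOT_EVALUABLE, Certainty.INCONCLUSIVE):
            continue
        if trait == "coat_colour":
            phrase = " or ".join(pred.values)
            if "melanistic mask" in pred.modifiers:
                phrase += " with melanistic mask"
        elif trait == "coat_pattern":
            values = [
                "minimal white spotting" if v == "solid or minimal white spotting" else v
                for v in pred.values
            ]
            phrase = " or ".join(values)
        elif trait == "coat_structure":
            phrase = " or ".join(_structure_phrase(v) for v in pred.values)
        elif trait == "ear_shape" and pred.certainty is Certainty.AMBIGUOUS:
            phrase = "drop or non-drop ears"
        else:
            phrase = " or ".join(pred.values)
        phrases.append(phrase)
    if not phrases:
        return "no traits evaluable from this profile"
    return ", ".join(phrases)
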