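"""Synthetic genotype/phenotype cohorts with documented discordance channels.

Two generators live here:

* :func:`simulate_cohort` draws multi-locus genotypes under Hardy-Weinberg
  equilibrium from configurable haplotype frequencies (loci independent, no
  linkage) and produces ground-truth phenotypes by running the inference
  engine's ground-truth twin on the genotype plus hidden exception factors:

  - a hidden untested TYRP1 brown allele (b^c) that renders a dog brown while
    it genotypes black,
  - breed-specific "ancestral" bobtails without the T-Box mutation,
  - tail docking (the tail becomes unobservable, not discordant),
  - phenotype of heterozygous ear-marker dogs decided by a coin with
    configurable bias,
  - body-size misclassification for the single-marker size predictor.

  Lethal T-Box homozygotes are rejection-sampled away, so the configured
  frequencies are pre-selection frequencies.

* :func:`make_reference_cohorts` emits the packaged deterministic fixture
  cohorts reconstructed from the published study narrative (pilot, the
  trait-specific marker-test sets, and the nine-dog blind set); each sample
  carries a provenance comment citing the constraint it realizes.

Frequencies are keyed per *locus haplotype* for the multi-marker loci
(E/K/A/B/S) so that redundant markers of one locus are always emitted
consistently; single-marker traits are keyed per marker allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .inference import predict_all
from .io import GenotypeCall, GenotypeProfile, PhenotypeRecord
from .panel import PanelConfig, load_panel
from .vocab import TRAIT_CATEGORIES

__all__ = [
    "SimConfig",
    "CohortTruth",
    "simulate_cohort",
    "make_reference_cohorts",
    "profile_from_loci",
    "HAPLOTYPE_STATES",
    "DEFAULT_LOCUS_FREQS",
]

# ---------------------------------------------------------------------------
# Haplotype -> marker-state tables

#: Marker states carried by each haplotype of the multi-marker loci.
HAPLOTYPE_STATES: dict[str, dict[str, dict[str, str]]] = {
    "E": {
        "e": {"MC1R_306ter": "T", "MC1R_M264V": "A"},
        "E": {"MC1R_306ter": "C", "MC1R_M264V": "A"},
        "E^m": {"MC1R_306ter": "C", "MC1R_M264V": "G"},
    },
    "K": {
        "k^y": {"CBD103_S54": "GGG", "CBD103_S53": "G"},
        "K^B": {"CBD103_S54": "DelGGG", "CBD103_S53": "C"},
    },
    "A": {
        "A^y": {"ASIP_S82": "T", "ASIP_H83": "A", "ASIP_SINE": "no SINE", "ASIP_R96": "C"},
        "a^w": {"ASIP_S82": "G", "ASIP_H83": "G", "ASIP_SINE": "no SINE", "ASIP_R96": "C"},
        "a^t": {"ASIP_S82": "G", "ASIP_H83": "G", "ASIP_SINE": "SINE", "ASIP_R96": "C"},
        "a": {"ASIP_S82": "G", "ASIP_H83": "G", "ASIP_SINE": "no SINE", "ASIP_R96": "T"},
    },
    "B": {
        "B": {"TYRP1_Q331ter": "C", "TYRP1_345delP": "CCT"},
        "b^s": {"TYRP1_Q331ter": "T", "TYRP1_345delP": "CCT"},
        "b^d": {"TYRP1_Q331ter": "C", "TYRP1_345delP": "DelCCT"},
    },
    "D": {
        "D": {"MLPH_157471_c.-22G>A": "G"},
        "d": {"MLPH_157471_c.-22G>A": "A"},
    },
    "S": {
        "S": {"MITF_INS": "no SINE", "MITF_SNP": "A"},
        "S^p": {"MITF_INS": "SINE", "MITF_SNP": "G"},
    },
    "M": {
        "M": {"PMEL": "SINE"},
        "m": {"PMEL": "no SINE"},
    },
    "H": {
        "H": {"PSMB7": "G"},
        "h": {"PSMB7": "T"},
    },
    # single-marker traits (haplotype symbol == marker state)
    "FGF5": {"G": {"FGF5": "G"}, "T": {"FGF5": "T"}},
    "RSPO2": {"Ins": {"RSPO2": "Ins"}, "no Ins": {"RSPO2": "no Ins"}},
    "KRT71": {"A": {"KRT71": "A"}, "G": {"KRT71": "G"}},
    "TAIL": {"G": {"T-Box_C295G": "G"}, "C": {"T-Box_C295G": "C"}},
    "EAR": {"G": {"BICFPJ1062878": "G"}, "A": {"BICFPJ1062878": "A"}},
    "SIZE": {"G": {"IGF1R": "G"}, "A": {"IGF1R": "A"}},
}

_LOCUS_ORDER = ("E", "K", "A", "B", "D", "S", "M", "H", "FGF5", "RSPO2", "KRT71", "TAIL", "EAR", "SIZE")

#: Default haplotype frequencies: plausible mixed-breed companion-dog values
#: (documented in the methods note; not estimates for any particular breed).
DEFAULT_LOCUS_FREQS: dict[str, dict[str, float]] = {
    "E": {"e": 0.25, "E": 0.60, "E^m": 0.15},
    "K": {"K^B": 0.25, "k^y": 0.75},
    "A": {"A^y": 0.35, "a^w": 0.15, "a^t": 0.40, "a": 0.10},
    "B": {"B": 0.70, "b^s": 0.20, "b^d": 0.10},
    "D": {"D": 0.85, "d": 0.15},
    "S": {"S": 0.65, "S^p": 0.35},
    "M": {"M": 0.05, "m": 0.95},
    "H": {"H": 0.02, "h": 0.98},
    "FGF5": {"G": 0.55, "T": 0.45},
    "RSPO2": {"Ins": 0.30, "no Ins": 0.70},
    "KRT71": {"A": 0.70, "G": 0.30},
    "TAIL": {"G": 0.05, "C": 0.95},
    "EAR": {"G": 0.50, "A": 0.50},
    "SIZE": {"G": 0.60, "A": 0.40},
}


#: Wild-type-like background genotype used for loci a fixture does not pin.
DEFAULT_LOCUS_GENOTYPES: dict[str, tuple[str, str]] = {
    "E": ("E", "E"),
    "K": ("k^y", "k^y"),
    "A": ("a^w", "a^w"),
    "B": ("B", "B"),
    "D": ("D", "D"),
    "S": ("S", "S"),
    "M": ("m", "m"),
    "H": ("h", "h"),
    "FGF5": ("G", "G"),
    "RSPO2": ("no Ins", "no Ins"),
    "KRT71": ("A", "A"),
    "TAIL": ("C", "C"),
    "EAR": ("G", "G"),
    "SIZE": ("G", "G"),
}


def profile_from_loci(
    sample_id: str,
    loci: dict[str, tuple[str, str]],
    panel: PanelConfig,
    missing: tuple[str, ...] = (),
) -> GenotypeProfile:
    """Build a full-panel profile from locus-level haplotype pairs.

    Loci absent from ``loci`` default to the wild-type-like background
    genotype.  Marker ids in ``missing`` are forced to MISSING (failed
    sequencing)."""
    calls: dict[str, GenotypeCall] = {}
    for locus in _LOCUS_ORDER:
        table = HAPLOTYPE_STATES[locus]
        pair = loci.get(locus, DEFAULT_LOCUS_GENOTYPES[locus])
        hap1, hap2 = table[pair[0]], table[pair[1]]
        for marker_id in hap1:
            marker = panel.marker_by_id(marker_id)
            calls[marker_id] = GenotypeCall.from_states(
                marker, (hap1[marker_id], hap2[marker_id])
            )
    for marker_id in missing:
        calls[marker_id] = GenotypeCall.missing(marker_id)
    return GenotypeProfile.build(sample_id, calls, panel)


# ---------------------------------------------------------------------------
# Configuration


class SimConfig(BaseModel):
    """Cohort-simulation parameters; the seed is mandatory."""

    n_samples: int = Field(gt=0)
    seed: int
    locus_freqs: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LOCUS_FREQS.items()}
    )
    p_bc: float = Field(default=0.0, ge=0.0, le=1.0)
    p_ancestral_bobtail: float = Field(default=0.0, ge=0.0, le=1.0)
    p_docked: float = Field(default=0.0, ge=0.0, le=1.0)
    p_ear_drop_given_het: float = Field(default=0.5, ge=0.0, le=1.0)
    p_size_misclass: float = Field(default=0.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check_freqs(self) -> "SimConfig":
        for locus, freqs in self.locus_freqs.items():
            if locus not in HAPLOTYPE_STATES:
                raise ValueError(f"unknown locus {locus!r} in locus_freqs")
            unknown = set(freqs) - set(HAPLOTYPE_STATES[locus])
            if unknown:
                raise ValueError(f"locus {locus}: unknown haplotype(s) {sorted(unknown)}")
            if any(not (0.0 <= p <= 1.0) for p in freqs.values()):
                raise ValueError(f"locus {locus}: frequencies outside [0, 1]")
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(f"locus {locus}: frequencies must sum to 1")
        missing = set(HAPLOTYPE_STATES) - set(self.locus_freqs)
        if missing:
            raise ValueError(f"locus_freqs missing locus/loci: {sorted(missing)}")
        return self


@dataclass
class CohortTruth:
    """Simulated genotypes, ground-truth phenotypes and the hidden exception
    factors that explain every engineered discordance."""

    profiles: list[GenotypeProfile]
    phenotypes: list[PhenotypeRecord]
    hidden_factors: dict[str, dict] = dc_field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        ids = [p.sample_id for p in self.profiles]
        pids = [p.sample_id for p in self.phenotypes]
        if ids != pids:
            raise ValueError("profiles and phenotypes must be parallel lists")


# ---------------------------------------------------------------------------
# Hardy-Weinberg simulation

_BROWN_SWAP = {
    "black": "brown",
    "blue (diluted black)": "isabella (diluted brown)",
    "black with tan points": "brown with tan points",
    "blue (diluted black) with tan points": "isabella (diluted brown) with tan points",
}


def simulate_cohort(config: SimConfig, panel: PanelConfig | None = None) -> CohortTruth:
    """Draw a cohort under Hardy-Weinberg equilibrium (loci independent).

    Same seed, same cohort -- byte-identical.  Lethal T-Box G/G draws are
    rejected and resampled."""
    if panel is None:
        panel = load_panel()
    rng = np.random.default_rng(config.seed)
    profiles: list[GenotypeProfile] = []
    phenotypes: list[PhenotypeRecord] = []
    hidden: dict[str, dict] = {}
    freq_tables = {
        locus: (sorted(freqs), [freqs[h] for h in sorted(freqs)])
        for locus, freqs in config.locus_freqs.items()
    }
    for i in range(config.n_samples):
        sample_id = f"SIM{i:05d}"
        loci: dict[str, tuple[str, str]] = {}
        for locus in _LOCUS_ORDER:
            haps, probs = freq_tables[locus]
            pair = tuple(rng.choice(haps, size=2, p=probs))
            if locus == "TAIL":
                while pair == ("G", "G"):  # lethal genotype: rejection-sample
                    pair = tuple(rng.choice(haps, size=2, p=probs))
            loci[locus] = pair  # type: ignore[assignment]
        profile = profile_from_loci(sample_id, loci, panel)
        report = predict_all(profile, panel)
        factors: dict[str, object] = {}

        # hidden untested TYRP1 b^c alleles on tested-wild-type haplotypes
        b_haps = loci["B"]
        hidden_bc = sum(
            1 for hap in b_haps if hap == "B" and rng.random() < config.p_bc
        )
        factors["hidden_bc_count"] = hidden_bc
        tested_recessive = sum(1 for hap in b_haps if hap != "B")
        bc_discordant = tested_recessive < 2 and tested_recessive + hidden_bc >= 2

        values: dict[str, Optional[str]] = {}
        observable: dict[str, bool] = {}
        notes: dict[str, str] = {}

        def set_observed(trait: str, value: Optional[str], note: str = "") -> None:
            values[trait] = value
            observable[trait] = value is not None
            if note:
                notes[trait] = note

        colour_pred = report.predictions["coat_colour"]
        colour = colour_pred.values[0] if len(colour_pred.values) == 1 else None
        if colour is not None and bc_discordant and colour in _BROWN_SWAP:
            colour = _BROWN_SWAP[colour]
            factors["bc_allele"] = True
        set_observed("coat_colour", colour)

        for trait in ("coat_pattern", "coat_structure"):
            pred = report.predictions[trait]
            set_observed(trait, pred.values[0] if len(pred.values) == 1 else None)

        # tail: ancestral bobtail, then docking, on genetically long tails
        tail_pair = loci["TAIL"]
        if tail_pair.count("G") == 1:
            set_observed("tail_length", "bobtail")
        else:  # C/C
            if rng.random() < config.p_ancestral_bobtail:
                factors["ancestral_bobtail"] = True
                set_observed("tail_length", "bobtail")
            elif rng.random() < config.p_docked:
                factors["docked"] = True
                values["tail_length"] = None
                observable["tail_length"] = False
                notes["tail_length"] = "artificially docked"
            else:
                set_observed("tail_length", "long tail")

        ear_pair = loci["EAR"]
        if ear_pair[0] != ear_pair[1]:
            drop = rng.random() < config.p_ear_drop_given_het
            factors["ear_drop_given_het"] = bool(drop)
            set_observed("ear_shape", "drop ears" if drop else "non-drop ears")
        else:
            set_observed(
                "ear_shape", "non-drop ears" if ear_pair[0] == "G" else "drop ears"
            )

        size_pred = report.predictions["body_size"].values[0]
        if rng.random() < config.p_size_misclass:
            factors["size_misclass"] = True
            size_pred = "rather tall" if size_pred == "rather small" else "rather small"
        set_observed("body_size", size_pred)

        profiles.append(profile)
        phenotypes.append(
            PhenotypeRecord(sample_id, values=values, observable=observable, notes=notes)
        )
        hidden[sample_id] = factors
    return CohortTruth(profiles=profiles, phenotypes=phenotypes, hidden_factors=hidden, name="simulated")


# ---------------------------------------------------------------------------
# Packaged narrative-constrained fixtures


def _phen(sample_id: str, **traits) -> PhenotypeRecord:
    """Observed-phenotype shorthand: trait=value, trait=None (explicitly not
    assessable); omitted traits were not recorded for that cohort."""
    values: dict[str, Optional[str]] = {}
    observable: dict[str, bool] = {}
    notes: dict[str, str] = {}
    for trait in TRAIT_CATEGORIES:
        if trait in traits:
            if traits[trait] is None:
                values[trait] = None
                observable[trait] = False
                notes[trait] = "marked not assessable"
            else:
                values[trait] = traits[trait]
                observable[trait] = True
        else:
            values[trait] = None
            observable[trait] = False
    return PhenotypeRecord(sample_id, values=values, observable=observable, notes=notes)


def make_reference_cohorts(panel: PanelConfig | None = None) -> dict[str, CohortTruth]:
    """Deterministic fixture cohorts reconstructed from the study narrative.

    Per-sample genotypes are minimal reconstructions consistent with the
    narrated phenotype composition and discordance counts (the study's own
    per-sample tables are not published); each sample carries a provenance
    comment naming the constraint it realizes.
    """
    if panel is None:
        panel = load_panel()
    P = lambda sid, loci, missing=(): profile_from_loci(sid, loci, panel, missing)
    cohorts: dict[str, CohortTruth] = {}

    # ------------------------------------------------------------------
    # Pilot set: 12 dogs x 21 markers, all genotyped (252 genotypes); every
    # described allelic state observed except at PMEL, PSMB7 and T-Box.
    pilot_profiles = [
        P("PT001", {"E": ("e", "e")}),                                     # recessive red
        P("PT002", {"E": ("E", "E^m"), "A": ("A^y", "a^w"),
                    "FGF5": ("T", "T"), "EAR": ("A", "A")}),               # masked fawn, long hair
        P("PT003", {"K": ("K^B", "k^y"), "B": ("B", "b^s"),
                    "RSPO2": ("Ins", "no Ins"), "SIZE": ("A", "G")}),      # dominant black carrier
        P("PT004", {"A": ("a^t", "a^w"), "B": ("B", "b^d"),
                    "KRT71": ("A", "G")}),                                 # tan-point carrier, wavy
        P("PT005", {"A": ("a", "a^w"), "D": ("d", "d"),
                    "S": ("S", "S^p")}),                                   # dilute, pseudo-irish
        P("PT006", {"K": ("K^B", "K^B"), "B": ("b^s", "b^s")}),            # solid brown
        P("PT007", {"A": ("A^y", "A^y"), "FGF5": ("G", "T")}),             # fawn
        P("PT008", {"A": ("a^t", "a^t"), "S": ("S^p", "S^p")}),            # tricolour-type
        P("PT009", {"E": ("E", "e"), "B": ("b^s", "b^d")}),                # brown compound het
        P("PT010", {"D": ("D", "d"), "KRT71": ("G", "G")}),                # curly carrier
        P("PT011", {"S": ("S^p", "S^p"), "RSPO2": ("Ins", "Ins")}),        # piebald, furnished
        P("PT012", {"E": ("E^m", "e"), "SIZE": ("A", "A")}),               # masked, small
    ]
    cohorts["pilot"] = CohortTruth(
        profiles=pilot_profiles,
        phenotypes=[_phen(p.sample_id) for p in pilot_profiles],
        name="pilot",
    )

    # ------------------------------------------------------------------
    # Coat-colour marker-test set: 16 dogs (five solid brown, two solid
    # black, two fawn/sable with white spotting, two brown with white
    # spotting, one wild-type agouti, one brown sable, one black with white
    # spotting, one black merle, one blue).  Four TYRP1-discordant dogs
    # (AT0282, DE01_006, DE01_052, DE02_017) genotype black but are brown;
    # ASIP_SINE failed in three dogs (DE02_20, DE01_006, DE01_052) where the
    # hierarchy makes the A locus deducibly irrelevant; six dogs are
    # Q331ter-heterozygous (three brown, one black, one grey, one e/e);
    # AT0134 lacks both MITF markers.
    cc = [
        # solid brown, genotyping black via B/b^s: the b^c failure mode
        (P("DE01_006", {"K": ("K^B", "K^B"), "B": ("B", "b^s")}, missing=("ASIP_SINE",)),
         _phen("DE01_006", coat_colour="brown", coat_pattern="solid or minimal white spotting")),
        (P("DE01_052", {"K": ("K^B", "K^B"), "B": ("B", "b^s")}, missing=("ASIP_SINE",)),
         _phen("DE01_052", coat_colour="brown", coat_pattern="solid or minimal white spotting")),
        (P("AT0282", {"K": ("K^B", "K^B"), "B": ("B", "b^s")}),
         _phen("AT0282", coat_colour="brown", coat_pattern="solid or minimal white spotting")),
        (P("DE02_017", {"K": ("K^B", "K^B"), "B": ("B", "b^d")}),
         _phen("DE02_017", coat_colour="brown", coat_pattern="solid or minimal white spotting")),
        # solid brown, concordant (b^s/b^s); both MITF markers failed
        (P("AT0134", {"K": ("K^B", "K^B"), "B": ("b^s", "b^s")},
           missing=("MITF_INS", "MITF_SNP")),
         _phen("AT0134", coat_colour="brown", coat_pattern="solid or minimal white spotting")),
        # solid black K^B/k^y heterozygotes: possible brindle, not observed
        (P("AT0183", {"K": ("K^B", "k^y"), "A": ("a^w", "a^w"), "B": ("B", "b^s")}),
         _phen("AT0183", coat_colour="black", coat_pattern="solid or minimal white spotting")),
        (P("AT0257", {"K": ("K^B", "k^y"), "A": ("a^w", "a^w")}),
         _phen("AT0257", coat_colour="black", coat_pattern="solid or minimal white spotting")),
        # black with white spotting, K^B/k^y
        (P("AT0062", {"K": ("K^B", "k^y"), "A": ("a^w", "a^w"), "S": ("S^p", "S^p")}),
         _phen("AT0062", coat_colour="black", coat_pattern="piebald or extreme white spotting")),
        # fawn/sable with white spotting (A^y)
        (P("AT0101", {"A": ("A^y", "a^w"), "S": ("S^p", "S^p")}),
         _phen("AT0101", coat_colour="fawn/sable", coat_pattern="piebald or extreme white spotting")),
        # e/e dog with white spotting and a B/b^s genotype; ASIP_SINE failed
        # but E is epistatic; clear-fawn coat recorded as the red/yellow/cream class
        (P("DE02_20", {"E": ("e", "e"), "B": ("B", "b^s"), "S": ("S^p", "S^p")},
           missing=("ASIP_SINE",)),
         _phen("DE02_20", coat_colour="red/yellow/cream", coat_pattern="piebald or extreme white spotting")),
        # brown with white spotting (compound het and b^d/b^d)
        (P("AT0144", {"K": ("K^B", "K^B"), "B": ("b^s", "b^d"), "S": ("S^p", "S^p")}),
         _phen("AT0144", coat_colour="brown", coat_pattern="piebald or extreme white spotting")),
        (P("AT0168", {"K": ("K^B", "K^B"), "B": ("b^d", "b^d"), "S": ("S", "S^p")}),
         _phen("AT0168", coat_colour="brown", coat_pattern="pseudo irish spotting")),
        # wild-type agouti
        (P("AT0190", {"A": ("a^w", "a^w")}),
         _phen("AT0190", coat_colour="agouti (wild type)", coat_pattern="solid or minimal white spotting")),
        # brown sable (A^y over a brown eumelanin background)
        (P("AT0205", {"A": ("A^y", "a^t"), "B": ("b^s", "b^s")}),
         _phen("AT0205", coat_colour="fawn/sable", coat_pattern="solid or minimal white spotting")),
        # black merle
        (P("AT0221", {"K": ("K^B", "K^B"), "M": ("M", "m")}),
         _phen("AT0221", coat_colour="black", coat_pattern="merle")),
        # blue (grey): dilute black, Q331ter heterozygous
        (P("AT0242", {"K": ("K^B", "K^B"), "B": ("B", "b^s"), "D": ("d", "d")}),
         _phen("AT0242", coat_colour="blue (diluted black)", coat_pattern="solid or minimal white spotting")),
    ]
    cohorts["coat_colour"] = CohortTruth(
        profiles=[p for p, _ in cc],
        phenotypes=[ph for _, ph in cc],
        hidden_factors={
            sid: {"bc_allele": True}
            for sid in ("DE01_006", "DE01_052", "AT0282", "DE02_017")
        },
        name="coat_colour",
    )

    # ------------------------------------------------------------------
    # Coat-structure marker-test set: 10 dogs, both manifestations of every
    # axis, all concordant.
    structure_specs = [
        ("AT0351", {"FGF5": ("G", "G"), "KRT71": ("A", "A"), "RSPO2": ("no Ins", "no Ins")}),
        ("AT0352", {"FGF5": ("T", "T"), "KRT71": ("A", "A"), "RSPO2": ("no Ins", "no Ins")}),
        ("AT0353", {"FGF5": ("T", "T"), "KRT71": ("G", "G"), "RSPO2": ("Ins", "Ins")}),
        ("AT0354", {"FGF5": ("G", "T"), "KRT71": ("A", "G"), "RSPO2": ("no Ins", "no Ins")}),
        ("AT0355", {"FGF5": ("T", "T"), "KRT71": ("A", "G"), "RSPO2": ("Ins", "no Ins")}),
        ("AT0356", {"FGF5": ("G", "G"), "KRT71": ("G", "G"), "RSPO2": ("Ins", "Ins")}),
        ("AT0357", {"FGF5": ("T", "T"), "KRT71": ("A", "A"), "RSPO2": ("Ins", "no Ins")}),
        ("AT0358", {"FGF5": ("G", "T"), "KRT71": ("A", "A"), "RSPO2": ("no Ins", "no Ins")}),
        ("AT0359", {"FGF5": ("T", "T"), "KRT71": ("G", "G"), "RSPO2": ("no Ins", "no Ins")}),
        ("AT0360", {"FGF5": ("G", "T"), "KRT71": ("A", "G"), "RSPO2": ("no Ins", "no Ins")}),
    ]
    structure_profiles = [P(sid, loci) for sid, loci in structure_specs]
    structure_phen = []
    for prof in structure_profiles:
        value = predict_all(prof, panel).predictions["coat_structure"].values[0]
        structure_phen.append(_phen(prof.sample_id, coat_structure=value))
    cohorts["coat_structure"] = CohortTruth(
        profiles=structure_profiles, phenotypes=structure_phen, name="coat_structure"
    )

    # ------------------------------------------------------------------
    # Tail-length marker-test set: 10 dogs, 70% concordant; the English
    # Bulldog (AT0056), Boston Terrier (AT0062) and French Bulldog (AT0210)
    # are bobtailed without the T-Box mutation.
    tail = [
        ("AT0056", ("C", "C"), "bobtail", True),
        ("AT0062", ("C", "C"), "bobtail", True),
        ("AT0210", ("C", "C"), "bobtail", True),
        ("AT0291", ("G", "C"), "bobtail", False),
        ("AT0292", ("G", "C"), "bobtail", False),
        ("AT0293", ("G", "C"), "bobtail", False),
        ("AT0294", ("C", "C"), "long tail", False),
        ("AT0295", ("C", "C"), "long tail", False),
        ("AT0296", ("C", "C"), "long tail", False),
        ("AT0297", ("C", "C"), "long tail", False),
    ]
    cohorts["tail_length"] = CohortTruth(
        profiles=[P(sid, {"TAIL": pair}) for sid, pair, _, _ in tail],
        phenotypes=[_phen(sid, tail_length=obs) for sid, _, obs, _ in tail],
        hidden_factors={
            sid: {"ancestral_bobtail": True} for sid, _, _, anc in tail if anc
        },
        name="tail_length",
    )

    # ------------------------------------------------------------------
    # Ear-shape marker-test set: 10 dogs; two concordant homozygotes, one
    # discordant homozygote, six uninterpretable heterozygotes (three drop,
    # three non-drop) and one sequencing failure (AT0274).
    ear = [
        ("AT0271", ("G", "G"), "non-drop ears", ()),
        ("AT0272", ("A", "A"), "drop ears", ()),
        ("AT0273", ("A", "A"), "non-drop ears", ()),
        ("AT0274", ("G", "G"), "drop ears", ("BICFPJ1062878",)),
        ("AT0275", ("G", "A"), "drop ears", ()),
        ("AT0276", ("G", "A"), "drop ears", ()),
        ("AT0277", ("G", "A"), "drop ears", ()),
        ("AT0278", ("G", "A"), "non-drop ears", ()),
        ("AT0279", ("G", "A"), "non-drop ears", ()),
        ("AT0280", ("G", "A"), "non-drop ears", ()),
    ]
    cohorts["ear_shape"] = CohortTruth(
        profiles=[P(sid, {"EAR": pair}, missing=miss) for sid, pair, _, miss in ear],
        phenotypes=[_phen(sid, ear_shape=obs) for sid, _, obs, _ in ear],
        name="ear_shape",
    )

    # ------------------------------------------------------------------
    # Body-size marker-test set: 10 dogs, 7 concordant.
    size = [
        ("AT0301", ("A", "A"), "rather small"),
        ("AT0302", ("A", "G"), "rather small"),
        ("AT0303", ("A", "A"), "rather small"),
        ("AT0304", ("G", "G"), "rather tall"),
        ("AT0305", ("G", "G"), "rather tall"),
        ("AT0306", ("G", "G"), "rather tall"),
        ("AT0307", ("A", "G"), "rather small"),
        ("AT0308", ("G", "G"), "rather small"),   # breed-specific bias
        ("AT0309", ("G", "G"), "rather small"),
        ("AT0310", ("A", "G"), "rather tall"),
    ]
    cohorts["body_size"] = CohortTruth(
        profiles=[P(sid, {"SIZE": pair}) for sid, pair, _ in size],
        phenotypes=[_phen(sid, body_size=obs) for sid, _, obs in size],
        hidden_factors={
            sid: {"size_misclass": True} for sid in ("AT0308", "AT0309", "AT0310")
        },
        name="body_size",
    )

    # ------------------------------------------------------------------
    # Blind-test set: nine dogs (D4925-D4931, D4933-D4934), all markers
    # genotyped (189 genotypes, zero missing).  D4926/D4928/D4931 share one
    # genotype except for the ear marker (heterozygous in D4931): black with
    # tan points, minimal white spotting, long smooth hair, long tail,
    # rather tall.  D4927 differs from them only at the two E-locus markers
    # (melanistic mask).  D4925's tail is artificially cropped.  D4930's
    # size and D4934's size and tail are discrepant; their ear marker is
    # heterozygous.  D4933 is a K^B/k^y black with white spotting whose ears
    # are not assessable from the photo.
    tanpoint = {
        "E": ("E", "E"), "K": ("k^y", "k^y"), "A": ("a^t", "a^t"),
        "FGF5": ("T", "T"), "SIZE": ("G", "G"),
    }
    blind = [
        (P("D4925", {"K": ("K^B", "K^B"), "B": ("b^s", "b^s"),
                     "EAR": ("A", "A"), "SIZE": ("A", "A")}),
         _phen("D4925", coat_colour="brown",
               coat_pattern="solid or minimal white spotting",
               coat_structure="short, smooth, no furnishings",
               tail_length=None,   # cropped: not a genetic discrepancy
               ear_shape="drop ears", body_size="rather small")),
        (P("D4926", dict(tanpoint)),
         _phen("D4926", coat_colour="black with tan points",
               coat_pattern="solid or minimal white spotting",
               coat_structure="long, smooth, no furnishings",
               tail_length="long tail", ear_shape=None, body_size="rather tall")),
        (P("D4927", dict(tanpoint, E=("E^m", "e"))),
         _phen("D4927", coat_colour="black with tan points",
               coat_pattern="solid or minimal white spotting",
               coat_structure="long, smooth, no furnishings",
               tail_length="long tail", ear_shape="non-drop ears",
               body_size="rather tall")),
        (P("D4928", dict(tanpoint)),
         _phen("D4928", coat_colour="black with tan points",
               coat_pattern="solid or minimal white spotting",
               coat_structure="long, smooth, no furnishings",
               tail_length="long tail", ear_shape=None, body_size="rather tall")),
        (P("D4929", {"E": ("e", "e"), "SIZE": ("A", "G")}),
         _phen("D4929", coat_colour="red/yellow/cream",
               coat_pattern="solid or minimal white spotting",
               coat_structure="short, smooth, no furnishings",
               tail_length="long tail", ear_shape="non-drop ears",
               body_size="rather small")),
        (P("D4930", {"K": ("K^B", "K^B"), "S": ("S", "S^p"),
                     "FGF5": ("G", "T"), "RSPO2": ("Ins", "no Ins"),
                     "KRT71": ("A", "G"), "TAIL": ("G", "C"),
                     "EAR": ("G", "A"), "SIZE": ("G", "G")}),
         _phen("D4930", coat_colour="black", coat_pattern="pseudo irish spotting",
               coat_structure="short, wavy, furnishings",
               tail_length="bobtail", ear_shape="drop ears",
               body_size="rather small")),   # size discrepant
        (P("D4931", dict(tanpoint, EAR=("G", "A"))),
         _phen("D4931", coat_colour="black with tan points",
               coat_pattern="solid or minimal white spotting",
               coat_structure="long, smooth, no furnishings",
               tail_length="long tail", ear_shape=None, body_size="rather tall")),
        (P("D4933", {"K": ("K^B", "k^y"), "A": ("a^t", "a^w"),
                     "S": ("S^p", "S^p")}),
         _phen("D4933", coat_colour="black",
               coat_pattern="piebald or extreme white spotting",
               coat_structure="short, smooth, no furnishings",
               tail_length="long tail", ear_shape=None, body_size="rather tall")),
        (P("D4934", {"E": ("E", "e"), "A": ("A^y", "a^t"),
                     "FGF5": ("T", "T"), "KRT71": ("G", "G"),
                     "RSPO2": ("Ins", "Ins"), "EAR": ("G", "A"),
                     "SIZE": ("A", "A")}),
         _phen("D4934", coat_colour="fawn/sable",
               coat_pattern="solid or minimal white spotting",
               coat_structure="long, curly, furnishings",
               tail_length="bobtail",   # discrepant vs. genetic long tail
               ear_shape="drop ears", body_size="rather tall")),  # discrepant
    ]
    cohorts["blind"] = CohortTruth(
        profiles=[p for p, _ in blind],
        phenotypes=[ph for _, ph in blind],
        hidden_factors={"D4925": {"docked": True}},
        name="blind",
    )
    return cohorts
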