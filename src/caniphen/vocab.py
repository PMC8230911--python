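"""Controlled vocabulary shared across the package.

Six externally visible trait categories are predicted: coat colour, coat
pattern, coat structure, tail length, ear shape and body size.  Every trait
value that a prediction can emit -- and that an observed-phenotype record may
carry -- comes from the fixed vocabulary below, so predictions and
observations are directly comparable.
"""

from __future__ import annotations

from enum import Enum

TRAIT_CATEGORIES: tuple[str, ...] = (
    "coat_colour",
    "coat_pattern",
    "coat_structure",
    "tail_length",
    "ear_shape",
    "body_size",
)


class Certainty(str, Enum):
    """Grades of a trait prediction, strongest first.

    determined   -- exactly one value follows from the genotype
    ambiguous    -- a finite set of values remains (e.g. heterozygous ear marker)
    inconclusive -- the rules fired but yield no usable value
                    (e.g. lethal tail genotype, partially missing structure axes)
    not_evaluable -- no data and no epistatic override
    """

    DETERMINED = "determined"
    AMBIGUOUS = "ambiguous"
    INCONCLUSIVE = "inconclusive"
    NOT_EVALUABLE = "not_evaluable"


#: Documented caveat codes a prediction may carry.
CAVEAT_CODES: frozenset[str] = frozenset(
    {
        "possible_brindle",            # K^B/k^y: brindle cannot be excluded (not genotyped)
        "possible_docking",            # genetically long tail may have been cropped
        "possible_cropping",           # ears may have been cropped
        "possible_ancestral_bobtail",  # some breeds are bobtailed without the T-Box mutation
        "untested_allele_bc",          # TYRP1 b^c not in the panel; B/B or B/b may hide brown
        "hidden_merle",                # M allele present but masked by e/e
        "lethal_genotype_observed",    # homozygous T-Box mutation is not viable
        "mask_not_visible_on_solid",   # E^m mask indistinct on a solid eumelanistic coat
    }
)

# ---------------------------------------------------------------------------
# Trait values

_EUMELANIN_SHADES = ("black", "brown", "blue (diluted black)", "isabella (diluted brown)")

COAT_COLOUR_VALUES: frozenset[str] = frozenset(
    {
        "red/yellow/cream",
        "pale cream (diluted red/yellow/cream)",
        "fawn/sable",
        "fawn/sable (diluted)",
        "agouti (wild type)",
        "agouti (wild type, diluted)",
    }
    | set(_EUMELANIN_SHADES)
    | {f"{shade} with tan points" for shade in _EUMELANIN_SHADES}
)

_SPOTTING_VALUES = (
    "solid or minimal white spotting",
    "pseudo irish spotting",
    "piebald or extreme white spotting",
)

COAT_PATTERN_VALUES: frozenset[str] = frozenset(
    set(_SPOTTING_VALUES)
    | {"merle", "merle + pseudo irish spotting", "merle + piebald or extreme white spotting"}
    | {"harlequin", "mainly white (double merle)"}
)

HAIR_LENGTHS = ("short", "long")
HAIR_CURLS = ("smooth", "wavy", "curly")
FURNISHING_STATES = ("no furnishings", "furnishings")

COAT_STRUCTURE_VALUES: frozenset[str] = frozenset(
    f"{length}, {curl}, {furn}"
    for length in HAIR_LENGTHS
    for curl in HAIR_CURLS
    for furn in FURNISHING_STATES
)

TAIL_VALUES: frozenset[str] = frozenset({"long tail", "bobtail"})
EAR_VALUES: frozenset[str] = frozenset({"drop ears", "non-drop ears"})
SIZE_VALUES: frozenset[str] = frozenset({"rather small", "rather tall"})

CONTROLLED_VOCABULARY: dict[str, frozenset[str]] = {
    "coat_colour": COAT_COLOUR_VALUES,
    "coat_pattern": COAT_PATTERN_VALUES,
    "coat_structure": COAT_STRUCTURE_VALUES,
    "tail_length": TAIL_VALUES,
    "ear_shape": EAR_VALUES,
    "body_size": SIZE_VALUES,
}

#: Token in phenotype tables marking a trait that could not be assessed
#: (e.g. docked tail, ear shape not visible on the reference photo).
NOT_ASSESSABLE_TOKEN = "NOT_ASSESSABLE"
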