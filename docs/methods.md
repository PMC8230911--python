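# Methods

## Scope and model

`caniphen` predicts six externally visible trait categories of a domestic dog
(coat colour, coat pattern, coat structure, tail length, ear shape, body
size) from a 21-marker genotype. The genetics is deterministic rule
application, not statistical estimation: each trait is a function of a small
number of loci with known dominance relations, and the package's job is to
apply those relations exactly, to grade how certain the resulting statement
is, and to be explicit about every assumption the unphased data forces.

### Certainty grammar

Every prediction carries one of four grades, strongest first:
`determined` (exactly one value follows), `ambiguous` (a finite value set
remains, e.g. the heterozygous ear marker), `inconclusive` (rules fired but
yield no usable value, e.g. a lethal tail genotype or a partially missing
structure axis), `not_evaluable` (no data and no epistatic override).
Caveats are drawn from a fixed enumeration (`possible_brindle`,
`possible_docking`, `possible_cropping`, `possible_ancestral_bobtail`,
`untested_allele_bc`, `hidden_merle`, `lethal_genotype_observed`,
`mask_not_visible_on_solid`) so that downstream consumers can branch on them
programmatically; free text lives only in derivation chains.

### Locus reconstruction from redundant markers

Sanger data gives unordered allele pairs per marker and no cross-marker
phase, so multi-marker loci are reconstructed with documented shortcuts:

* **E (MC1R)** — the `e` dosage comes from MC1R_306ter; `E^m` (M264V G) is
  assigned only to the non-`e` dosage. A surplus G on a presumed `e`
  haplotype is noted and ignored rather than flagged: `e` is epistatic, so
  the call cannot change. If M264V is missing, the `E`-vs-`e` series is still
  resolved and only the mask axis is left open.
* **K (CBD103)** — the two markers are redundant assays of one variant;
  agreement is required, disagreement sets the conflict flag and the causal
  micro-indel (S54) wins.
* **A (ASIP)** — dominance series `A^y > a^w > a^t > a`. Any A^y-defining
  variant (S82 T or H83 A) expresses A^y. Otherwise, assuming at most one
  ASIP variant per haplotype, a variant-free (`a^w`) haplotype exists iff the
  SINE and R96 variant dosages sum to at most one; if none exists the SINE
  (`a^t`) outranks recessive black. This shortcut is exact over every
  phased-realizable genotype (verified by enumeration against a direct
  dominance-table oracle); dosages that exceed two haplotypes set the
  conflict flag.
* **B (TYRP1)** — brown requires a total of two recessive alleles across
  Q331ter and 345delP; compound heterozygotes count, and the two variants are
  assumed never to share a haplotype. Reconstructions compatible with `B/B`
  or `B/b` always carry `untested_allele_bc`: a third, untested brown allele
  can silently turn such a dog brown, and this is the dominant real-world
  failure mode of the two-marker design.
* **S (MITF)** — the SINE is causal for spotting; the linked SNP is
  secondary evidence whose dominance is not clarified. Opposite homozygotes
  set the conflict flag; the SINE call always wins.

Epistatic overrides are applied once per profile: `e/e` silences K and A;
`K^B` silences A. An overridden locus may be missing without costing
certainty — the derivation chain then names the overriding locus, which is
what makes e.g. a failed ASIP SINE irrelevant for a `K^B/K^B` dog.

### Decisions taken where the rules were open

* The IGF1R small-size allele A is treated as dominant (`A/G → rather
  small`); the marker table marks the dominance on A and the packaged
  body-size cohort reproduces its 7/10 concordance under this reading.
* `d/d` on an `e/e` base emits "pale cream (diluted red/yellow/cream)"; MLPH
  dilutes both pigments but no canonical name exists for the dilute-`e`
  coat, so the label is this package's own.
* Nose and eye colour are not predicted. TYRP1 affects them, but a `B/b`
  genotype was observed with liver nose pigmentation, which the two-marker
  recessive model cannot express; guessing is worse than staying silent.
* PSMB7 `H/H` viability and expressivity are undescribed; it is treated like
  `H/h` (harlequin on a merle background) with the derivation noting the
  assumption.
* Harlequin requires both `H` and visible merle; `M` carriers that are `e/e`
  get `hidden_merle` instead of a merle value.
* A missing structure axis (one of length/curl/furnishings) drops the whole
  composite to `inconclusive` while the derivation keeps the known axes;
  enumerating completions as an ambiguous set was rejected to keep the
  composite value space closed.

## Trace calling

Chromatograms are modelled at the base-call level: a primary string over
`ACGTN` plus an equal-length secondary string over `ACGT-` ("-" = no second
peak). Raw signal processing is out of scope. Point variants need an exact
10-base anchor on each side of the site (configurable); anchor failure yields
MISSING, an unrecognized base an error.

Heterozygous insertion markers produce out-of-phase superposed reads. The
caller locates the divergence point (first true mismatch between the aligned
short and long alleles — a left-aligned insertion whose block repeats the
following bases is implicitly right-shifted, and calls are invariant to the
repositioning), then tests three hypotheses: the read equals the short
allele, the long allele, or their exact position-wise superposition (observed
{primary, secondary} set = base set of the two alignments). Exactly one
hypothesis may pass at the configured mismatch tolerance; zero or several
yield `inconsistent`. The tolerance defaults to 0 — forensic use favours
failing loudly over rescuing a noisy read — and a read shorter than the
divergence point plus a 15-base evaluable window (an engineering choice; no
published minimum exists) is reported as an insufficient-read MISSING.

The bundled amplicon contexts are **synthetic** sequences
(`reference_contexts.synthetic.fasta`) with the documented insertion sizes
(3 bp micro-indels, 167 bp intermediate insertion, SINE-scale blocks); real
amplicon sequences are not redistributed. Trace orientation is explicit
metadata, not inferred.

## Simulator

`simulate_cohort` draws per-locus haplotype pairs under Hardy–Weinberg
equilibrium, loci independent (the panel spans many chromosomes; no linkage,
no breed structure, no kinship — a documented simplification). Frequencies
are keyed per locus haplotype so redundant markers are always emitted
consistently. Defaults are plausible companion-dog values chosen once
(`E^m` 0.15, `K^B` 0.25, `a^t` 0.40, merle 0.05, bobtail mutation 0.05,
small-size allele 0.40, ...); they are not estimates for any particular
breed. Lethal T-Box homozygotes are rejection-sampled, so configured
frequencies are pre-selection frequencies.

Ground-truth phenotypes come from the inference engine's ground-truth twin:
the predicted value, modified by hidden exception channels whose firing is
recorded per sample —

| channel | default | meaning |
|---|---|---|
| `p_bc` | 0.0 | per tested-wild-type TYRP1 haplotype: hidden untested brown allele; a dog reaching two true recessives while genotyping fewer is phenotypically brown |
| `p_ancestral_bobtail` | 0.0 | a genetically long-tailed dog is bobtailed by a non-T-Box mechanism |
| `p_docked` | 0.0 | a genetically long tail is cropped; the observed tail becomes *not assessable*, not discordant |
| `p_ear_drop_given_het` | 0.5 | phenotype coin for the uninformative heterozygous ear marker (the observed split in heterozygous dogs) |
| `p_size_misclass` | 0.0 | observed size class contradicts IGF1R |

With all exception rates at zero the loop closes: every determined,
observable trait matches its prediction, for every seed. What passing
simulator-based tests shows is therefore internal consistency of engine,
generator and scorer under the stated genetic model — not accuracy on real
dogs, whose discordances arise from breed structure, unmodelled alleles and
cosmetic alteration.

The packaged fixture cohorts (`make_reference_cohorts`) are deterministic,
hand-constructed reconstructions constrained by the published study
narrative: a 12-dog pilot set (252 genotypes, full state coverage except
three markers), a 16-dog coat-colour set with four TYRP1-discordant browns
and three failed ASIP SINEs, 10-dog sets for structure (all concordant),
tail (7/10, three breed-ancestral bobtails), ear (six heterozygotes, one
discordant homozygote, one failure) and size (7/10), and a nine-dog blind
set containing three dogs identical at every marker but the ear SNP. The
study's own per-sample genotype tables are not published; these genotypes
are the minimal ones consistent with the narrated counts, with a provenance
comment per sample.

## Evaluation

Concordance cells take one of seven outcomes: `match`, `mismatch`,
`ambiguous_consistent` (observed value inside an ambiguous prediction's set),
`ambiguous`, `inconclusive`, `not_assessable_phenotype`,
`not_evaluable_genotype`. Per-trait accuracy is `match / (match + mismatch)`;
ambiguous cells are never credited as matches, and unobservable phenotypes
(docked tails, cropped or unphotographed ears) are excluded rather than
scored — those discrepancies are not genetic. The heatmap's TSV twin is the
byte-deterministic artifact; the PNG is cosmetic.

## Numerical/engineering choices

* Heterozygotes are stored order-normalized (canonical sort on the allele
  symbol); allele symbols use ASCII-caret superscripts (`E^m`, `K^B`, `S^p`).
* Reports are byte-stable JSON (sorted keys); identical profiles yield
  byte-identical identikit texts.
* VCF I/O (pysam) matches records by ID first, then chromosome+position;
  SINE and intermediate insertions are written as symbolic `<INS:ME:SINE>` /
  `<INS>` ALTs, micro-indels as explicit alleles with an `N` anchor.
  Markers without published coordinates sit on a synthetic `PANEL` contig.
* Problem sizes in the test suite: the coat-colour cascade is checked
  state-for-state against an independent dominance-table oracle over the
  full E×K×A×B×D genotype space (9,720 combinations); the superposition
  caller against 1,000 random allele pairs × three zygosities; simulator
  closure at n=200 and channel-rate recovery at n=5,000 within three
  binomial standard errors. The whole suite runs in well under a minute on
  one CPU.

## Known limitations

* Brindle (`K^br`) is not genotyped; `K^B/k^y` dogs only carry a caveat.
* Merle subtypes (cryptic/dilute/double nuances beyond `M/M`) are not
  discriminated; quantitative size/height is out of scope (binary class
  only).
* Single-marker traits (tail, ear, size) inherit the markers' breed-specific
  blind spots; the simulator's exception channels model exactly these.
* The trace model operates on base calls, not signal; quality scores,
  three-allele mixtures and contamination detection are out of scope.
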