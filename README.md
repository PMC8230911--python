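# caniphen — canine forensic DNA phenotyping

When a crime-scene DNA trace from a dog (hair on a car seat, saliva on
clothing) matches no reference animal, a description of the dog is still
valuable investigative intelligence: *"a large black-and-tan dog with long
smooth hair"* narrows a search the way an eyewitness statement would.
`caniphen` implements that inference end to end for forensic geneticists and
veterinary-genetics researchers:

1. **Genotype calling** at a 21-marker panel (15 SNPs, two 3-bp micro-indels,
   one 167-bp intermediate insertion, three SINE insertions) from
   Sanger-style base-call traces — including resolution of the out-of-phase
   superposed reads a heterozygous long insertion produces;
2. **Trait inference**: an epistatic dominance-hierarchy rule engine
   translating a multi-locus genotype into six externally visible trait
   categories — coat colour, coat pattern, coat structure, tail length, ear
   shape, body size — each with a certainty grade, caveat codes and a full
   derivation chain;
3. **Identikit text**: a standardized composite description per dog;
4. **Cohort simulation** under Hardy–Weinberg equilibrium with the documented
   real-world discordance channels (an untested TYRP1 brown allele, breed
   ancestral bobtails, tail docking, the uninformative heterozygous ear
   marker, size misclassification);
5. **Concordance evaluation**: per-trait accuracy accounting and a
   heatmap-style sample × trait matrix.

## The genetic model

Fur colour follows the classical locus cascade `E → K → A → B → D`:

| Locus | Gene | Rule |
|---|---|---|
| E | MC1R | `e/e` is epistatic to everything below: red/yellow/cream coat; `E^m` adds a melanistic mask |
| K | CBD103 | any `K^B`: solid eumelanin, A locus silenced |
| A | ASIP | expressed when `k^y/k^y`, dominance `A^y > a^w > a^t > a` |
| B | TYRP1 | two recessive alleles across Q331ter/345delP (compound heterozygotes included) turn eumelanin brown |
| D | MLPH | `d/d` dilutes both pigments: black → blue, brown → isabella |

Pattern overlays come from MITF (white spotting: `S/S`, `S/S^p` pseudo-irish,
`S^p/S^p` piebald), PMEL (merle, invisible on `e/e`; `M/M` mainly white) and
PSMB7 (harlequin, expressed only on a merle background). Coat structure
combines FGF5 (hair length, short dominant), KRT71 (curl, semi-dominant) and
RSPO2 (furnishings, insertion dominant). Tail length, ear shape and body size
are single-marker binary calls; the heterozygous ear marker is genuinely
ambiguous and is reported as such rather than guessed.

Loci are reconstructed from redundant markers with documented unphased
shortcuts (e.g. `e` dosage from MC1R_306ter with `E^m` assigned only to the
non-`e` dosage); every shortcut's assumption is written into the prediction's
derivation chain. Missing genotypes are first-class: an epistatically
overridden locus can be missing without costing certainty.

## Worked example

Emit the packaged narrative-constrained cohorts, predict, and evaluate:

```bash
caniphen fixtures --out-dir fx
caniphen predict fx/blind.genotypes.tsv --out report.json --summary summary.tsv
```

prints one identikit line per dog, e.g.

```
D4926: black with tan points, minimal white spotting, long smooth hair, long tail, non-drop ears, rather tall
D4927: black with tan points with melanistic mask, minimal white spotting, long smooth hair, long tail, non-drop ears, rather tall
D4930: black, pseudo irish spotting, short wavy hair with furnishings, bobtail, drop or non-drop ears, rather tall
```

D4926's line reads: eumelanin base black with tan points (`k^y/k^y` with
`a^t/a^t`), minimal white spotting (`S/S`), long smooth coat without
furnishings, genetically long tail, homozygous non-drop ear marker, and the
tall IGF1R class. D4927 shares the genotype except the two MC1R markers and
gains the mask. Scoring the blind cohort against its observed phenotypes:

```bash
caniphen evaluate fx/blind.genotypes.tsv fx/blind.phenotypes.tsv --out-dir eval
```

```
coat_colour: 100.0%
coat_pattern: 100.0%
coat_structure: 100.0%
tail_length: 87.5%
ear_shape: 100.0%
body_size: 77.8%
```

Accuracies count only determined predictions against observable phenotypes:
D4925's docked tail is scored *not assessable* (a cosmetic, not genetic,
discrepancy), and heterozygous-ear dogs land in their own *ambiguous* class.
`eval/concordance.tsv` holds the full sample × trait outcome matrix
(`eval/heatmap.png` is its cosmetic rendering), `eval/summary.json` the
counts, accuracies and the ear-marker heterozygosity rate.

A seeded synthetic cohort with realistic discordance channels:

```bash
caniphen simulate --n 500 --seed 42 --p-bc 0.02 --p-docked 0.05 --out-dir sim
```

## Layout

```
src/caniphen/
  panel.py      validated 21-marker panel model (+ bundled YAML/FASTA data)
  io.py         genotype/phenotype TSV, VCF, JSON report dialects
  traces.py     Sanger-style base-call trace genotype caller
  inference.py  dominance-hierarchy rule engine + identikit text
  simulate.py   Hardy-Weinberg cohort simulator + packaged fixture cohorts
  evaluate.py   concordance matrix, accuracies, heatmap
  cli.py        `caniphen` command-line interface
docs/methods.md   model, assumptions, parameter choices, limitations
```
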