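"""Genotype-phenotype concordance accounting and heatmap-style summaries.

Per-trait accuracy counts only determined predictions against observable
phenotypes: ``matches / (matches + mismatches)``.  Ambiguous predictions
(e.g. the heterozygous ear marker) are reported as their own class and never
enter the denominator; traits marked not assessable (docked tail, ear not on
the photo) are excluded rather than scored as mismatches -- such
discrepancies are not genetic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .inference import SampleReport
from .io import GenotypeProfile, PhenotypeRecord
from .panel import PanelConfig
from .vocab import Certainty, TRAIT_CATEGORIES

__all__ = [
    "OUTCOMES",
    "ConcordanceCell",
    "ScoreResult",
    "score_cohort",
    "summarize_genotyping",
    "ear_heterozygosity_rate",
    "render_heatmap",
]

OUTCOMES = (
    "match",
    "mismatch",
    "ambiguous_consistent",
    "ambiguous",
    "inconclusive",
    "not_assessable_phenotype",
    "not_evaluable_genotype",
)


@dataclass(frozen=True)
class ConcordanceCell:
    sample_id: str
    trait: str
    outcome: str
    note: str = ""


@dataclass
class ScoreResult:
    """Full sample x trait concordance matrix plus per-trait accuracies."""

    cells: list[ConcordanceCell]
    matrix: pd.DataFrame
    accuracy: dict[str, float]
    counts: dict[str, Counter] = field(default_factory=dict)

    def accuracy_percent(self, trait: str) -> float:
        return 100.0 * self.accuracy[trait]


def _score_cell(report: SampleReport, phen: PhenotypeRecord, trait: str) -> ConcordanceCell:
    sid = report.sample_id
    pred = report.predictions[trait]
    if not phen.observable.get(trait, False):
        return ConcordanceCell(sid, trait, "not_assessable_phenotype", phen.notes.get(trait, ""))
    observed = phen.values[trait]
    if pred.certainty is Certainty.NOT_EVALUABLE:
        return ConcordanceCell(sid, trait, "not_evaluable_genotype")
    if pred.certainty is Certainty.INCONCLUSIVE:
        return ConcordanceCell(sid, trait, "inconclusive")
    if pred.certainty is Certainty.AMBIGUOUS:
        if observed in pred.values:
            return ConcordanceCell(sid, trait, "ambiguous_consistent")
        return ConcordanceCell(sid, trait, "ambiguous")
    if observed == pred.values[0]:
        return ConcordanceCell(sid, trait, "match")
    return ConcordanceCell(
        sid, trait, "mismatch", f"predicted {pred.values[0]!r}, observed {observed!r}"
    )


def score_cohort(
    reports: Mapping[str, SampleReport] | Iterable[SampleReport],
    phenotypes: Iterable[PhenotypeRecord],
) -> ScoreResult:
    """Score predictions against observed phenotypes.

    Builds the complete sample x trait matrix of concordance cells (always
    ``n_samples x 6``) and per-trait accuracies.  Raises ``ValueError``
    listing the orphans when the sample id sets differ."""
    if isinstance(reports, Mapping):
        by_id = dict(reports)
    else:
        by_id = {r.sample_id: r for r in reports}
    phen_by_id = {p.sample_id: p for p in phenotypes}
    orphans = set(by_id) ^ set(phen_by_id)
    if orphans:
        raise ValueError(f"sample_id mismatch between predictions and phenotypes: {sorted(orphans)}")
    cells: list[ConcordanceCell] = []
    for sid in sorted(by_id):
        for trait in TRAIT_CATEGORIES:
            cells.append(_score_cell(by_id[sid], phen_by_id[sid], trait))
    counts: dict[str, Counter] = {t: Counter() for t in TRAIT_CATEGORIES}
    for cell in cells:
        counts[cell.trait][cell.outcome] += 1
    accuracy = {}
    for trait, ctr in counts.items():
        denom = ctr["match"] + ctr["mismatch"]
        accuracy[trait] = ctr["match"] / denom if denom else float("nan")
    matrix = pd.DataFrame(
        {
            trait: {c.sample_id: c.outcome for c in cells if c.trait == trait}
            for trait in TRAIT_CATEGORIES
        }
    ).loc[sorted(by_id), list(TRAIT_CATEGORIES)]
    return ScoreResult(cells=cells, matrix=matrix, accuracy=accuracy, counts=counts)


def summarize_genotyping(profiles: Iterable[GenotypeProfile], panel: PanelConfig) -> dict:
    """Genotyping arithmetic: attempted genotypes = samples x panel size."""
    profiles = list(profiles)
    n_markers = len(panel)
    missing = sum(p.n_missing() for p in profiles)
    return {
        "samples": len(profiles),
        "markers": n_markers,
        "attempted_genotypes": len(profiles) * n_markers,
        "missing_genotypes": missing,
        "successful_genotypes": len(profiles) * n_markers - missing,
    }


def ear_heterozygosity_rate(
    profiles: Iterable[GenotypeProfile], marker_id: str = "BICFPJ1062878"
) -> float:
    """Fraction of profiles heterozygous at the ear-shape marker."""
    profiles = list(profiles)
    if not profiles:
        return float("nan")
    het = sum(1 for p in profiles if p.calls[marker_id].is_het)
    return het / len(profiles)


_OUTCOME_COLOURS = {
    "match": "#2e7d32",
    "ambiguous_consistent": "#9ccc65",
    "ambiguous": "#ffb300",
    "mismatch": "#c62828",
    "inconclusive": "#8d6e63",
    "not_assessable_phenotype": "#b0bec5",
    "not_evaluable_genotype": "#eceff1",
}


def render_heatmap(
    result: ScoreResult | pd.DataFrame,
    image_path: str | Path | None = None,
    tsv_path: str | Path | None = None,
) -> pd.DataFrame:
    """Colour-coded sample x trait grid plus its TSV twin.

    The TSV is the testable, byte-deterministic artifact; the image is
    cosmetic."""
    matrix = result.matrix if isinstance(result, ScoreResult) else result
    if tsv_path is not None:
        matrix.to_csv(tsv_path, sep="\t", index_label="sample_id")
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap
        from matplotlib.patches import Patch

        categories = list(OUTCOMES)
        coded = matrix.apply(lambda col: col.map(categories.index)).to_numpy()
        cmap = ListedColormap([_OUTCOME_COLOURS[c] for c in categories])
        fig, ax = plt.subplots(
            figsize=(2 + 0.9 * matrix.shape[1], 1 + 0.45 * matrix.shape[0])
        )
        ax.imshow(coded, cmap=cmap, vmin=0, vmax=len(categories) - 1, aspect="auto")
        ax.set_xticks(np.arange(matrix.shape[1]), labels=matrix.columns, rotation=45, ha="right")
        ax.set_yticks(np.arange(matrix.shape[0]), labels=matrix.index)
        ax.legend(
            handles=[Patch(color=_OUTCOME_COLOURS[c], label=c) for c in categories],
            bbox_to_anchor=(1.02, 1),
            loc="upper left",
            fontsize="small",
        )
        fig.tight_layout()
        fig.savefig(image_path, dpi=120)
        plt.close(fig)
    return matrix
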