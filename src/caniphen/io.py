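"""Readers and writers for every external representation.

Dialects:

* genotype table -- TSV, one row per sample, one column per marker, cells are
  raw nucleotide/presence states joined with ``/`` (``C/T``, ``SINE/no SINE``);
  empty cells or ``.`` mean MISSING.
* phenotype table -- TSV with the controlled trait vocabulary; the token
  ``NOT_ASSESSABLE`` marks a trait that could not be observed (docked tail,
  ear not visible on the reference photo), an empty cell a trait that was
  simply not recorded.
* VCF v4.x -- diploid GT only; records are matched to panel markers by the ID
  field or by chromosome+position; SINE/intermediate insertions are written as
  symbolic ``<INS...>`` ALTs (mobile-element insertions in standard VCF
  vocabulary).
* prediction report -- JSON (keys sorted, byte-stable) plus a flat TSV summary.

MISSING is a first-class state, not an error: failed sequencing must be
carried through the pipeline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import pysam

from .panel import Marker, PanelConfig
from .vocab import CONTROLLED_VOCABULARY, NOT_ASSESSABLE_TOKEN, TRAIT_CATEGORIES

logger = logging.getLogger("caniphen.io")

__all__ = [
    "MISSING",
    "GenotypeIOError",
    "GenotypeCall",
    "GenotypeProfile",
    "PhenotypeRecord",
    "read_genotype_table",
    "write_genotype_table",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_vcf",
    "write_vcf",
    "write_report",
    "read_report",
]

#: Sentinel for a failed/absent genotype (alias of ``None`` for readability).
MISSING = None


class GenotypeIOError(ValueError):
    """Malformed external data; the message names the offending sample/marker."""


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's unordered allele pair at one marker (or MISSING).

    Heterozygotes are stored order-normalized (canonical sort on the allele
    symbol) so they compare equal regardless of input order; single-marker
    phase is never meaningful in Sanger data.
    """

    marker_id: str
    alleles: Optional[tuple[str, str]] = MISSING
    raw_states: Optional[tuple[str, str]] = MISSING
    conflict_flag: bool = False

    @property
    def is_missing(self) -> bool:
        return self.alleles is MISSING

    @property
    def is_het(self) -> bool:
        return self.alleles is not MISSING and self.alleles[0] != self.alleles[1]

    def count(self, allele_name: str) -> int:
        if self.alleles is MISSING:
            return 0
        return sum(1 for a in self.alleles if a == allele_name)

    @classmethod
    def missing(cls, marker_id: str) -> "GenotypeCall":
        return cls(marker_id=marker_id)

    @classmethod
    def from_states(cls, marker: Marker, states: tuple[str, str]) -> "GenotypeCall":
        pairs = sorted(
            ((marker.allele_by_state(s).name, s) for s in states),
            key=lambda p: p[0],
        )
        return cls(
            marker_id=marker.marker_id,
            alleles=(pairs[0][0], pairs[1][0]),
            raw_states=(pairs[0][1], pairs[1][1]),
        )

    @classmethod
    def from_allele_names(cls, marker: Marker, names: tuple[str, str]) -> "GenotypeCall":
        states = tuple(marker.allele_by_name(n).state for n in names)
        return cls.from_states(marker, states)  # normalizes ordering


@dataclass
class GenotypeProfile:
    """One sample's calls across the full panel (MISSING allowed)."""

    sample_id: str
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise GenotypeIOError("sample_id must be non-empty")

    @classmethod
    def build(
        cls, sample_id: str, calls: Mapping[str, GenotypeCall], panel: PanelConfig
    ) -> "GenotypeProfile":
        """Normalize to exactly one call slot per panel marker."""
        full = {}
        for marker in panel.markers:
            full[marker.marker_id] = calls.get(
                marker.marker_id, GenotypeCall.missing(marker.marker_id)
            )
        unknown = set(calls) - set(full)
        if unknown:
            raise GenotypeIOError(
                f"sample {sample_id}: calls for unknown marker(s): {sorted(unknown)}"
            )
        return cls(sample_id=sample_id, calls=full)

    def call(self, marker_id: str) -> GenotypeCall:
        return self.calls[marker_id]

    def n_missing(self) -> int:
        return sum(1 for c in self.calls.values() if c.is_missing)


@dataclass
class PhenotypeRecord:
    """Observed trait values for one sample, with per-trait observability."""

    sample_id: str
    values: dict[str, Optional[str]] = field(default_factory=dict)
    observable: dict[str, bool] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for trait in TRAIT_CATEGORIES:
            self.values.setdefault(trait, None)
            self.observable.setdefault(trait, self.values[trait] is not None)
        for trait, value in self.values.items():
            if trait not in TRAIT_CATEGORIES:
                raise GenotypeIOError(f"sample {self.sample_id}: unknown trait {trait!r}")
            if value is not None and value not in CONTROLLED_VOCABULARY[trait]:
                raise GenotypeIOError(
                    f"sample {self.sample_id}: value {value!r} outside the "
                    f"controlled vocabulary for {trait}"
                )
            if not self.observable[trait] and value is not None:
                raise GenotypeIOError(
                    f"sample {self.sample_id}: unobservable trait {trait} carries a value"
                )


# ---------------------------------------------------------------------------
# Genotype tables

_MISSING_CELL = {"", ".", "NA"}


def read_genotype_table(path: str | Path, panel: PanelConfig) -> list[GenotypeProfile]:
    """Read the TSV genotype dialect; every row yields a profile or a named error."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "sample_id":
        raise GenotypeIOError(f"{path}: first column must be 'sample_id'")
    known = set(panel.marker_ids())
    unknown_cols = [c for c in df.columns[1:] if c not in known]
    if unknown_cols:
        logger.warning("%s: ignoring unknown marker column(s): %s", path, unknown_cols)
    profiles = []
    for _, row in df.iterrows():
        sample_id = row["sample_id"]
        calls: dict[str, GenotypeCall] = {}
        for marker_id in df.columns[1:]:
            if marker_id in unknown_cols:
                continue
            cell = row[marker_id].strip()
            marker = panel.marker_by_id(marker_id)
            if cell in _MISSING_CELL:
                calls[marker_id] = GenotypeCall.missing(marker_id)
                continue
            states = tuple(s.strip() for s in cell.split("/"))
            if len(states) != 2:
                raise GenotypeIOError(
                    f"sample {sample_id}, marker {marker_id}: cell {cell!r} is not "
                    "two '/'-separated states"
                )
            try:
                calls[marker_id] = GenotypeCall.from_states(marker, states)  # type: ignore[arg-type]
            except Exception as err:
                raise GenotypeIOError(
                    f"sample {sample_id}, marker {marker_id}: {err}"
                ) from err
        profiles.append(GenotypeProfile.build(sample_id, calls, panel))
    return profiles


def write_genotype_table(
    profiles: Iterable[GenotypeProfile], panel: PanelConfig, path: str | Path
) -> Path:
    path = Path(path)
    marker_ids = panel.marker_ids()
    rows = []
    for profile in profiles:
        row = {"sample_id": profile.sample_id}
        for marker_id in marker_ids:
            call = profile.calls.get(marker_id, GenotypeCall.missing(marker_id))
            row[marker_id] = "" if call.is_missing else "/".join(call.raw_states)
        rows.append(row)
    pd.DataFrame(rows, columns=["sample_id", *marker_ids]).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Phenotype tables


def read_phenotype_table(path: str | Path) -> list[PhenotypeRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        values: dict[str, Optional[str]] = {}
        observable: dict[str, bool] = {}
        notes: dict[str, str] = {}
        for trait in TRAIT_CATEGORIES:
            cell = row.get(trait, "").strip()
            if cell == NOT_ASSESSABLE_TOKEN:
                values[trait] = None
                observable[trait] = False
                notes[trait] = "marked not assessable"
            elif cell == "":
                values[trait] = None
                observable[trait] = False
            else:
                values[trait] = cell
                observable[trait] = True
        records.append(
            PhenotypeRecord(row["sample_id"], values=values, observable=observable, notes=notes)
        )
    return records


def write_phenotype_table(records: Iterable[PhenotypeRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for rec in records:
        row = {"sample_id": rec.sample_id}
        for trait in TRAIT_CATEGORIES:
            if rec.values.get(trait) is not None:
                row[trait] = rec.values[trait]
            elif not rec.observable.get(trait, False) and rec.notes.get(trait):
                row[trait] = NOT_ASSESSABLE_TOKEN
            else:
                row[trait] = ""
        rows.append(row)
    pd.DataFrame(rows, columns=["sample_id", *TRAIT_CATEGORIES]).to_csv(
        path, sep="\t", index=False
    )
    return path


# ---------------------------------------------------------------------------
# VCF

_PANEL_CONTIG = "PANEL"


def _marker_site(marker: Marker, index: int) -> tuple[str, int]:
    if marker.coordinate is not None:
        return marker.coordinate.chrom, marker.coordinate.pos
    return _PANEL_CONTIG, 1000 * (index + 1)


def _vcf_alleles(marker: Marker) -> tuple[tuple[str, str], tuple[str, str]]:
    """(REF, ALT) strings and the (allele-name for index 0, for index 1)."""
    if marker.marker_type == "SNP":
        a0, a1 = marker.alleles[0], marker.alleles[1]
        return (a0.state, a1.state), (a0.name, a1.name)
    ins, dele = marker.insertion_allele(), marker.deletion_allele()
    if marker.marker_type == "microINDEL":
        # explicit-sequence indel with an N anchor base
        return ("N" + ins.state, "N"), (ins.name, dele.name)
    alt = "<INS:ME:SINE>" if marker.marker_type == "SINE" else "<INS>"
    return ("N", alt), (dele.name, ins.name)


def write_vcf(
    profiles: list[GenotypeProfile], panel: PanelConfig, path: str | Path
) -> Path:
    path = Path(path)
    header = pysam.VariantHeader()
    contigs = {}
    for i, marker in enumerate(panel.markers):
        chrom, pos = _marker_site(marker, i)
        contigs[chrom] = max(contigs.get(chrom, 0), pos + 1000)
    for chrom, length in contigs.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    header.add_line('##ALT=<ID=INS,Description="Insertion">')
    header.add_line('##ALT=<ID=INS:ME:SINE,Description="SINE mobile element insertion">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for profile in profiles:
        header.add_sample(profile.sample_id)
    vcf = pysam.VariantFile(str(path), "w", header=header)
    for i, marker in enumerate(panel.markers):
        chrom, pos = _marker_site(marker, i)
        (ref, alt), (name0, name1) = _vcf_alleles(marker)
        rec = vcf.new_record(
            contig=chrom,
            start=pos - 1,
            stop=pos - 1 + len(ref),  # keep END sane for symbolic ALTs
            alleles=(ref, alt),
            id=marker.marker_id,
        )
        for profile in profiles:
            call = profile.calls.get(marker.marker_id)
            if call is None or call.is_missing:
                rec.samples[profile.sample_id]["GT"] = (None, None)
            else:
                gt = tuple(0 if a == name0 else 1 for a in call.alleles)
                rec.samples[profile.sample_id]["GT"] = gt
        vcf.write(rec)
    vcf.close()
    return path


def read_vcf(path: str | Path, panel: PanelConfig) -> list[GenotypeProfile]:
    """Read a diploid VCF restricted to panel loci; one profile per sample column.

    Records are matched by ID, falling back to chromosome+position.  Unmapped
    ALTs or non-diploid GTs skip the marker for that record/sample with a
    warning; unmatched panel markers become MISSING.
    """
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    by_site = {}
    for i, marker in enumerate(panel.markers):
        by_site[_marker_site(marker, i)] = marker
    calls: dict[str, dict[str, GenotypeCall]] = {s: {} for s in samples}
    for rec in vcf:
        marker = None
        if rec.id:
            try:
                marker = panel.marker_by_id(rec.id)
            except LookupError:
                marker = None
        if marker is None:
            marker = by_site.get((rec.chrom, rec.pos))
        if marker is None:
            logger.warning("VCF record %s:%s (%s) matches no panel marker", rec.chrom, rec.pos, rec.id)
            continue
        index_names = _index_to_allele_names(rec, marker)
        if index_names is None:
            continue
        for sample in samples:
            gt = rec.samples[sample].get("GT")
            if gt is None or len(gt) != 2:
                logger.warning(
                    "sample %s, marker %s: ploidy != 2, skipped", sample, marker.marker_id
                )
                continue
            if any(idx is None for idx in gt):
                calls[sample][marker.marker_id] = GenotypeCall.missing(marker.marker_id)
                continue
            try:
                names = tuple(index_names[idx] for idx in gt)
            except (IndexError, KeyError):
                logger.warning(
                    "sample %s, marker %s: GT index outside allele table, skipped",
                    sample,
                    marker.marker_id,
                )
                continue
            calls[sample][marker.marker_id] = GenotypeCall.from_allele_names(marker, names)
    return [GenotypeProfile.build(s, calls[s], panel) for s in samples]


def _index_to_allele_names(rec, marker: Marker) -> Optional[dict[int, str]]:
    ref = rec.ref or ""
    alts = rec.alts or ()
    alt = alts[0] if alts else ""
    if marker.marker_type == "SNP":
        mapping = {}
        try:
            mapping[0] = marker.allele_by_state(ref).name
            if alt:
                mapping[1] = marker.allele_by_state(alt).name
        except Exception:
            logger.warning(
                "marker %s: REF/ALT %r/%r not mappable to allele states, record skipped",
                marker.marker_id,
                ref,
                alt,
            )
            return None
        return mapping
    ins, dele = marker.insertion_allele(), marker.deletion_allele()
    if alt.startswith("<INS"):
        return {0: dele.name, 1: ins.name}
    if len(ref) > len(alt):
        return {0: ins.name, 1: dele.name}
    if len(alt) > len(ref):
        return {0: dele.name, 1: ins.name}
    logger.warning(
        "marker %s: cannot orient indel alleles from REF/ALT %r/%r, record skipped",
        marker.marker_id,
        ref,
        alt,
    )
    return None


# ---------------------------------------------------------------------------
# Prediction reports


def write_report(
    reports: Iterable,
    path: str | Path,
    summary_path: str | Path | None = None,
) -> Path:
    """Write a machine-readable JSON report (byte-stable: keys sorted) and an
    optional flat TSV summary.  ``reports`` are SampleReport objects (anything
    with a ``to_dict()``)."""
    path = Path(path)
    docs = sorted((r.to_dict() for r in reports), key=lambda d: d["sample_id"])
    with open(path, "w") as handle:
        json.dump({"samples": docs}, handle, sort_keys=True, indent=2)
        handle.write("\n")
    if summary_path is not None:
        rows = []
        for doc in docs:
            row = {"sample_id": doc["sample_id"]}
            for trait in TRAIT_CATEGORIES:
                pred = doc["predictions"][trait]
                row[trait] = " | ".join(pred["values"]) if pred["values"] else pred["certainty"]
            row["identikit"] = doc["identikit"]
            rows.append(row)
        pd.DataFrame(rows).to_csv(summary_path, sep="\t", index=False)
    return path


def read_report(path: str | Path) -> dict:
    with open(path) as handle:
        return json.load(handle)
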