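"""Validated data model of the 21-marker phenotyping panel.

The panel ships as a human-editable YAML file (one record per marker) plus a
FASTA of amplicon reference contexts used by the trace caller.  Users may
supply modified panel files -- e.g. adding a third TYRP1 brown allele -- as
long as the markers the inference rules name remain present.

Allele symbols with superscripts are stored ASCII-caret style (``E^m``,
``K^B``, ``S^p``) and all outputs use the same convention.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

from .vocab import TRAIT_CATEGORIES

__all__ = [
    "AlleleDef",
    "Coordinate",
    "Marker",
    "PanelConfig",
    "PanelValidationError",
    "REQUIRED_MARKER_IDS",
    "load_panel",
    "save_panel",
    "marker_by_id",
]


class PanelValidationError(ValueError):
    """A panel file violates the documented schema; names the offending record."""


#: Marker identifiers the inference rules depend on.  A panel missing any of
#: these is rejected; additional markers are permitted.
REQUIRED_MARKER_IDS: frozenset[str] = frozenset(
    {
        "MC1R_306ter",
        "MC1R_M264V",
        "CBD103_S54",
        "CBD103_S53",
        "ASIP_S82",
        "ASIP_H83",
        "ASIP_SINE",
        "ASIP_R96",
        "TYRP1_Q331ter",
        "TYRP1_345delP",
        "MLPH_157471_c.-22G>A",
        "MITF_SNP",
        "MITF_INS",
        "PMEL",
        "PSMB7",
        "FGF5",
        "RSPO2",
        "KRT71",
        "T-Box_C295G",
        "BICFPJ1062878",
        "IGF1R",
    }
)

Dominance = Literal["dominant", "recessive", "semi_dominant", "unclarified"]
MarkerType = Literal["SNP", "microINDEL", "intermediate_INDEL", "SINE"]

#: Presence tokens marking the insertion-bearing state of an insertion marker.
_INSERTION_STATES = {"SINE", "Ins"}


class AlleleDef(BaseModel):
    """One allele of a marker: symbol, nucleotide/presence state, dominance."""

    name: str
    state: str = Field(min_length=1)
    dominance: Dominance
    phenotype: str = ""


class Coordinate(BaseModel):
    """1-based CanFam3.1 chromosome + position."""

    chrom: str
    pos: int = Field(gt=0)


class Marker(BaseModel):
    marker_id: str
    gene: str = ""
    locus: Optional[str] = None
    trait_category: Literal[TRAIT_CATEGORIES]  # type: ignore[valid-type]
    marker_type: MarkerType
    coordinate: Optional[Coordinate] = None
    alleles: list[AlleleDef] = Field(min_length=2)
    #: allele name -> amplicon context sequence (synthetic in the bundled panel)
    reference_context: Optional[dict[str, str]] = None

    @model_validator(mode="after")
    def _distinct_alleles(self) -> "Marker":
        states = [a.state for a in self.alleles]
        names = [a.name for a in self.alleles]
        if len(set(states)) != len(states):
            raise ValueError(f"marker {self.marker_id}: allele states collide: {states}")
        if len(set(names)) != len(names):
            raise ValueError(f"marker {self.marker_id}: allele names collide: {names}")
        return self

    # -- lookup helpers -----------------------------------------------------
    def allele_by_state(self, state: str) -> AlleleDef:
        for allele in self.alleles:
            if allele.state == state:
                return allele
        raise PanelValidationError(
            f"marker {self.marker_id}: state {state!r} matches no allele"
        )

    def allele_by_name(self, name: str) -> AlleleDef:
        for allele in self.alleles:
            if allele.name == name:
                return allele
        raise PanelValidationError(
            f"marker {self.marker_id}: allele {name!r} is not defined"
        )

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(a.state for a in self.alleles)

    @property
    def is_insertion_type(self) -> bool:
        return self.marker_type in ("microINDEL", "intermediate_INDEL", "SINE")

    def insertion_allele(self) -> AlleleDef:
        """The allele carrying the inserted block (GGG/CCT/Ins/SINE state)."""
        for allele in self.alleles:
            if self.marker_type in ("SINE", "intermediate_INDEL"):
                if allele.state in _INSERTION_STATES:
                    return allele
            elif self.marker_type == "microINDEL" and not allele.state.startswith("Del"):
                return allele
        raise PanelValidationError(f"marker {self.marker_id}: no insertion allele")

    def deletion_allele(self) -> AlleleDef:
        ins = self.insertion_allele()
        for allele in self.alleles:
            if allele.name != ins.name:
                return allele
        raise PanelValidationError(f"marker {self.marker_id}: no deletion allele")


class PanelConfig(BaseModel):
    version: str = "custom"
    locus_order: list[str] = Field(default_factory=lambda: list("EKABDSMH"))
    markers: list[Marker]

    @model_validator(mode="after")
    def _validate(self) -> "PanelConfig":
        ids = [m.marker_id for m in self.markers]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate marker_id(s): {sorted(dupes)}")
        missing = REQUIRED_MARKER_IDS - set(ids)
        if missing:
            raise ValueError(f"panel is missing required marker(s): {sorted(missing)}")
        order = self.locus_order
        for earlier, later in (("E", "K"), ("K", "A")):
            if earlier not in order or later not in order or order.index(earlier) > order.index(later):
                raise ValueError(
                    f"locus_order must list {earlier} before {later}: {order}"
                )
        panel_loci = {m.locus for m in self.markers if m.locus}
        unknown = panel_loci - set(order)
        if unknown:
            raise ValueError(f"marker loci missing from locus_order: {sorted(unknown)}")
        return self

    # -- lookups ------------------------------------------------------------
    def marker_by_id(self, marker_id: str) -> Marker:
        for marker in self.markers:
            if marker.marker_id == marker_id:
                return marker
        raise LookupError(f"unknown marker_id: {marker_id!r}")

    def markers_for_locus(self, locus: str) -> list[Marker]:
        return [m for m in self.markers if m.locus == locus]

    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def __len__(self) -> int:
        return len(self.markers)


def marker_by_id(panel: PanelConfig, marker_id: str) -> Marker:
    """Return the unique marker with ``marker_id`` or raise ``LookupError``."""
    return panel.marker_by_id(marker_id)


# ---------------------------------------------------------------------------
# Loading / saving

def _default_panel_dir() -> Path:
    return Path(str(importlib.resources.files("caniphen").joinpath("data")))


def _fasta_record_id(marker_id: str, allele_name: str) -> str:
    return f"{marker_id}|{allele_name.replace(' ', '_')}"


def _load_contexts(fasta_path: Path, markers: list[Marker]) -> None:
    """Attach reference_context sequences from a FASTA keyed marker|allele."""
    if not fasta_path.exists():
        return
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    for marker in markers:
        ctx: dict[str, str] = {}
        for allele in marker.alleles:
            rec_id = _fasta_record_id(marker.marker_id, allele.name)
            if rec_id in seqs:
                ctx[allele.name] = seqs[rec_id]
        if ctx:
            marker.reference_context = ctx


def load_panel(path: str | Path | None = None) -> PanelConfig:
    """Load and validate a panel file (the bundled default when ``path`` is None).

    Raises :class:`PanelValidationError` naming the offending record when the
    file violates the schema (missing required marker, duplicate marker_id,
    allele-state collision, unknown trait_category, ...).
    """
    if path is None:
        path = _default_panel_dir() / "panel.yaml"
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"panel file not found: {path}")
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict) or "markers" not in raw:
        raise PanelValidationError(f"{path}: not a panel file (no 'markers' key)")
    fasta_name = raw.pop("reference_fasta", None)
    try:
        panel = PanelConfig(**raw)
    except ValidationError as err:
        raise PanelValidationError(f"{path}: {err}") from err
    if fasta_name:
        _load_contexts(path.parent / fasta_name, panel.markers)
    return panel


def save_panel(panel: PanelConfig, path: str | Path, fasta_name: str | None = None) -> Path:
    """Serialize ``panel`` to YAML (+ FASTA of contexts); round-trips via load_panel."""
    path = Path(path)
    doc = panel.model_dump(exclude_none=True)
    for marker in doc["markers"]:
        marker.pop("reference_context", None)
    if fasta_name is None and any(m.reference_context for m in panel.markers):
        fasta_name = path.stem + ".contexts.fasta"
    if fasta_name:
        doc["reference_fasta"] = fasta_name
        records = []
        for marker in panel.markers:
            for allele_name, seq in (marker.reference_context or {}).items():
                records.append(
                    SeqRecord(
                        Seq(seq),
                        id=_fasta_record_id(marker.marker_id, allele_name),
                        description="amplicon context",
                    )
                )
        SeqIO.write(records, str(path.parent / fasta_name), "fasta")
    with open(path, "w") as handle:
        yaml.safe_dump(doc, handle, sort_keys=False, allow_unicode=True)
    return path
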