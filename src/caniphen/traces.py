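"""Genotype calling from Sanger-style base-call strings.

A chromatogram is modelled at the base-call level as two equal-length strings:
the primary (strongest-peak) call over ``ACGTN`` and a secondary call over
``ACGT-`` where ``-`` means "no secondary peak"; together they encode IUPAC
mixtures.  SNP and 3-bp micro-indel sites are read directly.  For the long
insertion markers (the SINEs and the intermediate RSPO2 insertion) a
heterozygote superimposes the short and long amplicon sequences downstream of
the insertion point -- the read goes out of phase -- and zygosity is resolved
by checking, position by position, that the observed primary/secondary pair
equals the base multiset expected from the two aligned alleles.

Mismatch tolerance defaults to 0: forensic use favours failing loudly, and
clean single-source traces are expected to be unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Literal

from .io import GenotypeCall, GenotypeProfile, MISSING
from .panel import Marker, PanelConfig

__all__ = [
    "TraceRead",
    "Zygosity",
    "TraceCallError",
    "resolve_superposition",
    "call_point_variant",
    "call_profile",
    "synthesize_trace",
]

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")

#: exact flank required on each side of a point-variant site
DEFAULT_ANCHOR = 10
#: minimum evaluable bases past the divergence point of an insertion site
DEFAULT_MIN_WINDOW = 15


class TraceCallError(ValueError):
    """Observed base(s) match no defined allele, or the trace is inconsistent."""


class Zygosity(Enum):
    HOM_SHORT = "hom_short"
    HOM_LONG = "hom_long"
    HET = "het"
    INCONSISTENT = "inconsistent"
    INSUFFICIENT = "insufficient"


@dataclass(frozen=True)
class TraceRead:
    """Primary/secondary base-call strings standing in for a chromatogram."""

    marker_id: str
    primary: str
    secondary: str
    orientation: Literal["forward", "reverse"] = "forward"

    def __post_init__(self) -> None:
        if len(self.primary) != len(self.secondary):
            raise ValueError(
                f"trace {self.marker_id}: primary and secondary lengths differ"
            )
        bad = set(self.primary) - set("ACGTN")
        if bad:
            raise ValueError(f"trace {self.marker_id}: invalid primary bases {bad}")
        bad = set(self.secondary) - set("ACGT-")
        if bad:
            raise ValueError(f"trace {self.marker_id}: invalid secondary bases {bad}")
        for p, s in zip(self.primary, self.secondary):
            if s != "-" and s == p:
                raise ValueError(
                    f"trace {self.marker_id}: secondary peak equals primary call"
                )

    def forward(self) -> "TraceRead":
        """The trace expressed in reference (forward) orientation."""
        if self.orientation == "forward":
            return self
        return TraceRead(
            marker_id=self.marker_id,
            primary=self.primary.translate(_COMPLEMENT)[::-1],
            secondary=self.secondary.translate(_COMPLEMENT)[::-1],
            orientation="forward",
        )


# ---------------------------------------------------------------------------
# Superposition resolution


def _divergence_point(short: str, long: str) -> int:
    """Index of the first true mismatch between the aligned alleles.

    A left-aligned insertion whose block starts with the base that follows the
    insertion site produces no mismatch there; scanning for the first actual
    mismatch performs the documented right-shift, and the call is invariant to
    the repositioning.
    """
    if len(long) <= len(short):
        raise ValueError("long_allele must be longer than short_allele")
    for i, (a, b) in enumerate(zip(short, long)):
        if a != b:
            return i
    return len(short)


def _check_prefix_suffix(short: str, long: str, d: int) -> None:
    k = len(long) - len(short)
    if long[:d] != short[:d] or long[d + k :] != short[d:]:
        raise ValueError(
            "short_allele is not a prefix-suffix subsequence of long_allele"
        )


def _mismatches_hom(trace: TraceRead, allele: str) -> int:
    n = 0
    for i, (p, s) in enumerate(zip(trace.primary, trace.secondary)):
        if i >= len(allele):
            n += 1  # read extends past the template
            continue
        if p != allele[i] or s != "-":
            n += 1
    return n


def _mismatches_het(trace: TraceRead, short: str, long: str) -> int:
    n = 0
    for i, (p, s) in enumerate(zip(trace.primary, trace.secondary)):
        expected = set()
        if i < len(short):
            expected.add(short[i])
        if i < len(long):
            expected.add(long[i])
        if not expected:
            n += 1
            continue
        if len(expected) == 2:
            if {p, s} != expected:
                n += 1
        else:
            if p not in expected or s != "-":
                n += 1
    return n


def resolve_superposition(
    trace: TraceRead,
    short_allele: str,
    long_allele: str,
    *,
    tolerance: int = 0,
    min_window: int = DEFAULT_MIN_WINDOW,
) -> Zygosity:
    """Classify an insertion-marker trace as hom-short / hom-long / het.

    Heterozygous reads are the exact superposition of the two alleles: at every
    position the observed {primary, secondary} set must equal the base set of
    the two alignments (a lone base where they coincide).  Homozygous reads
    match a single allele with no secondary peaks after the divergence point.
    Anything else is inconsistent at the given tolerance.
    """
    trace = trace.forward()
    d = _divergence_point(short_allele, long_allele)
    _check_prefix_suffix(short_allele, long_allele, d)
    if len(trace.primary) < d + min_window:
        return Zygosity.INSUFFICIENT
    scores = {
        Zygosity.HOM_SHORT: _mismatches_hom(trace, short_allele),
        Zygosity.HOM_LONG: _mismatches_hom(trace, long_allele),
        Zygosity.HET: _mismatches_het(trace, short_allele, long_allele),
    }
    passing = [z for z, n in scores.items() if n <= tolerance]
    if len(passing) == 1:
        return passing[0]
    return Zygosity.INCONSISTENT


# ---------------------------------------------------------------------------
# Point variants


def _snp_site(marker: Marker) -> tuple[str, str, int]:
    """(context_a, context_b, variant_index) for a SNP marker."""
    ctx = marker.reference_context
    if not ctx or len(ctx) < 2:
        raise TraceCallError(f"marker {marker.marker_id}: no reference_context")
    seq_a = ctx[marker.alleles[0].name]
    seq_b = ctx[marker.alleles[1].name]
    if len(seq_a) != len(seq_b):
        raise TraceCallError(f"marker {marker.marker_id}: SNP contexts differ in length")
    for i, (a, b) in enumerate(zip(seq_a, seq_b)):
        if a != b:
            return seq_a, seq_b, i
    raise TraceCallError(f"marker {marker.marker_id}: contexts are identical")


def _indel_contexts(marker: Marker) -> tuple[str, str, str, str]:
    """(short_name, short_seq, long_name, long_seq) for an insertion marker."""
    ctx = marker.reference_context
    if not ctx or len(ctx) < 2:
        raise TraceCallError(f"marker {marker.marker_id}: no reference_context")
    ins, dele = marker.insertion_allele(), marker.deletion_allele()
    return dele.name, ctx[dele.name], ins.name, ctx[ins.name]


def call_point_variant(
    trace: TraceRead,
    marker: Marker,
    *,
    anchor: int = DEFAULT_ANCHOR,
    tolerance: int = 0,
    min_window: int = DEFAULT_MIN_WINDOW,
) -> GenotypeCall:
    """Call a SNP or 3-bp micro-indel marker from one trace.

    SNP sites: a primary-only base is homozygous, a primary+secondary pair
    matching both allele states heterozygous.  Micro-indels are resolved via
    :func:`resolve_superposition`.  Returns MISSING when the flanking anchor
    cannot be located; raises :class:`TraceCallError` for bases matching no
    defined allele.
    """
    if marker.marker_type == "SNP":
        seq_a, _, v = _snp_site(marker)
        fwd = trace.forward()
        anchor_seq = seq_a[max(0, v - anchor) : v]
        idx = fwd.primary.find(anchor_seq)
        if not anchor_seq or idx < 0:
            return GenotypeCall.missing(marker.marker_id)
        vpos = idx + len(anchor_seq)
        if vpos >= len(fwd.primary):
            return GenotypeCall.missing(marker.marker_id)
        p, s = fwd.primary[vpos], fwd.secondary[vpos]
        states = {a.state for a in marker.alleles}
        if s == "-":
            if p not in states:
                raise TraceCallError(
                    f"marker {marker.marker_id}: unrecognized allele state {p!r}"
                )
            return GenotypeCall.from_states(marker, (p, p))
        if {p, s} != states:
            raise TraceCallError(
                f"marker {marker.marker_id}: unrecognized allele states {p!r}/{s!r}"
            )
        return GenotypeCall.from_states(marker, (p, s))
    if marker.marker_type == "microINDEL":
        return _call_insertion(trace, marker, tolerance=tolerance, min_window=min_window)
    raise ValueError(
        f"call_point_variant handles SNP/microINDEL markers, not {marker.marker_type}"
    )


def _call_insertion(
    trace: TraceRead,
    marker: Marker,
    *,
    tolerance: int = 0,
    min_window: int = DEFAULT_MIN_WINDOW,
) -> GenotypeCall:
    short_name, short_seq, long_name, long_seq = _indel_contexts(marker)
    zyg = resolve_superposition(
        trace, short_seq, long_seq, tolerance=tolerance, min_window=min_window
    )
    if zyg is Zygosity.INSUFFICIENT:
        return GenotypeCall.missing(marker.marker_id)
    if zyg is Zygosity.INCONSISTENT:
        raise TraceCallError(
            f"marker {marker.marker_id}: trace matches no zygosity hypothesis"
        )
    names = {
        Zygosity.HOM_SHORT: (short_name, short_name),
        Zygosity.HOM_LONG: (long_name, long_name),
        Zygosity.HET: (short_name, long_name),
    }[zyg]
    return GenotypeCall.from_allele_names(marker, names)


# ---------------------------------------------------------------------------
# Whole-profile dispatch


def call_profile(
    traces: Iterable[TraceRead],
    panel: PanelConfig,
    sample_id: str,
    *,
    tolerance: int = 0,
) -> tuple[GenotypeProfile, dict[str, str]]:
    """Call every marker with a trace; markers with no trace become MISSING.

    Per-marker errors are aggregated into the returned mapping (marker_id ->
    message); the sample as a whole is never aborted.
    """
    by_marker: dict[str, TraceRead] = {}
    for trace in traces:
        if trace.marker_id in by_marker:
            raise ValueError(f"multiple traces for marker {trace.marker_id}")
        by_marker[trace.marker_id] = trace
    calls: dict[str, GenotypeCall] = {}
    errors: dict[str, str] = {}
    for marker in panel.markers:
        trace = by_marker.get(marker.marker_id)
        if trace is None:
            calls[marker.marker_id] = GenotypeCall.missing(marker.marker_id)
            continue
        try:
            if marker.marker_type in ("SNP", "microINDEL"):
                calls[marker.marker_id] = call_point_variant(
                    trace, marker, tolerance=tolerance
                )
            else:
                calls[marker.marker_id] = _call_insertion(
                    trace, marker, tolerance=tolerance
                )
        except TraceCallError as err:
            errors[marker.marker_id] = str(err)
            calls[marker.marker_id] = GenotypeCall.missing(marker.marker_id)
    return GenotypeProfile.build(sample_id, calls, panel), errors


# ---------------------------------------------------------------------------
# Ideal-trace synthesis (the forward model; used by the simulator and tests)


def synthesize_trace(
    marker: Marker,
    allele_names: tuple[str, str],
    orientation: Literal["forward", "reverse"] = "forward",
) -> TraceRead:
    """Build the ideal noise-free trace a genotype would produce at a marker."""
    ctx = marker.reference_context
    if not ctx:
        raise ValueError(f"marker {marker.marker_id}: no reference_context")
    a, b = allele_names
    if marker.marker_type == "SNP":
        seq_a = ctx[a]
        seq_b = ctx[b]
        if a == b:
            primary, secondary = seq_a, "-" * len(seq_a)
        else:
            _, _, v = _snp_site(marker)
            primary = seq_a
            secondary = "-" * v + seq_b[v] + "-" * (len(seq_a) - v - 1)
    else:
        ins = marker.insertion_allele().name
        short_seq = ctx[marker.deletion_allele().name]
        long_seq = ctx[ins]
        if a == b:
            seq = long_seq if a == ins else short_seq
            primary, secondary = seq, "-" * len(seq)
        else:
            primary_chars, secondary_chars = [], []
            for i in range(len(long_seq)):
                lo = long_seq[i]
                sh = short_seq[i] if i < len(short_seq) else None
                primary_chars.append(lo)
                secondary_chars.append(sh if sh is not None and sh != lo else "-")
            primary = "".join(primary_chars)
            secondary = "".join(secondary_chars)
    trace = TraceRead(marker_id=marker.marker_id, primary=primary, secondary=secondary)
    if orientation == "reverse":
        return TraceRead(
            marker_id=marker.marker_id,
            primary=trace.primary.translate(_COMPLEMENT)[::-1],
            secondary=trace.secondary.translate(_COMPLEMENT)[::-1],
            orientation="reverse",
        )
    return trace
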