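"""Transcript-context annotation of IRE predictions.

The regulatory consequence of IRP binding depends on where in the mRNA
the element sits: a 5'UTR IRE represses translation, a 3'UTR IRE
stabilizes the message.  Given the CDS coordinates of a transcript, each
prediction is assigned one of five location classes - 5UTR, 5UTR-CDS,
CDS, CDS-3UTR, 3UTR - using the IRE midpoint (position N16, or N17 for
cores with a 3' bulge) and a strict <|15| nt window around the start and
stop codons for the boundary classes.  Three distances to key transcript
landmarks are computed for UTR-located elements.
"""

from __future__ import annotations

from dataclasses import dataclass

from .scanner import IRECore
from .scoring import ScoredIRE

__all__ = [
    "TranscriptContext",
    "LocatedIRE",
    "BOUNDARY_WINDOW",
    "ire_midpoint",
    "classify_location",
    "compute_distances",
    "locate",
    "collapse_redundant",
    "region_enrichment",
]

LOCATIONS = ("5UTR", "5UTR-CDS", "CDS", "CDS-3UTR", "3UTR")
BOUNDARY_WINDOW = 15  # strict <|15| nt around start/stop codon


@dataclass(frozen=True)
class TranscriptContext:
    """CDS coordinates on a transcript, 1-based inclusive.

    ``cds_start`` is the first nucleotide of the start codon (the A of
    AUG, "A + 1" in most transcripts); ``cds_end`` is the last nucleotide
    of the stop codon.
    """

    transcript_id: str
    cds_start: int
    cds_end: int
    length: int

    def __post_init__(self) -> None:
        if not (1 <= self.cds_start < self.cds_end <= self.length):
            raise ValueError(
                f"{self.transcript_id}: need 1 <= cds_start < cds_end <= length, "
                f"got {self.cds_start}, {self.cds_end}, {self.length}"
            )
        if (self.cds_end - self.cds_start + 1) % 3:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_end - self.cds_start + 1} "
                "is not a multiple of 3"
            )


@dataclass(frozen=True)
class LocatedIRE:
    """A scored prediction with its transcript location and distances.

    Distances are signed: ``d5_ire_aug`` = cds_start - midpoint (present
    for 5UTR and 5UTR-CDS), ``d_cap_5ire`` = midpoint - 1 (idem),
    ``d_ter_3ire`` = midpoint - cds_end (present for 3UTR and CDS-3UTR).
    """

    scored: ScoredIRE
    midpoint: int  # 1-based transcript position
    location: str
    d5_ire_aug: int | None = None
    d_cap_5ire: int | None = None
    d_ter_3ire: int | None = None
    gene: str | None = None


def ire_midpoint(core: IRECore) -> int:
    """1-based transcript position of the IRE midpoint (N16, or N17 with a 3' bulge)."""
    name = "N17" if core.has_3prime_bulge else "N16"
    return core.positions[name] + 1


def classify_location(mid: int, ctx: TranscriptContext) -> str:
    """Assign one of the five location classes from the midpoint position.

    Boundary classes use a strict ``< 15`` nt window on the distance to
    the first nucleotide of the start codon (5UTR-CDS) or the last
    nucleotide of the stop codon (CDS-3UTR); 5UTR-CDS takes precedence
    when both windows overlap (possible only for a CDS under 30 nt).
    """
    if not (1 <= mid <= ctx.length):
        raise ValueError(
            f"midpoint {mid} outside transcript {ctx.transcript_id} [1, {ctx.length}]"
        )
    if abs(mid - ctx.cds_start) < BOUNDARY_WINDOW:
        return "5UTR-CDS"
    if abs(mid - ctx.cds_end) < BOUNDARY_WINDOW:
        return "CDS-3UTR"
    if mid < ctx.cds_start:
        return "5UTR"
    if mid <= ctx.cds_end:
        return "CDS"
    return "3UTR"


def compute_distances(mid: int, location: str, ctx: TranscriptContext) -> dict[str, int | None]:
    """Distances to the cap, start codon and stop codon, per location class.

    5'-side elements get the distance to the translational start
    (d5_ire_aug) and to the m7G cap at transcript position 1 (d_cap_5ire);
    3'-side elements get the distance from the terminal codon
    (d_ter_3ire); CDS-internal elements get none.
    """
    d: dict[str, int | None] = {"d5_ire_aug": None, "d_cap_5ire": None, "d_ter_3ire": None}
    if location in ("5UTR", "5UTR-CDS"):
        d["d5_ire_aug"] = ctx.cds_start - mid
        d["d_cap_5ire"] = mid - 1
    elif location in ("3UTR", "CDS-3UTR"):
        d["d_ter_3ire"] = mid - ctx.cds_end
    return d


def locate(scored: ScoredIRE, ctx: TranscriptContext, gene: str | None = None) -> LocatedIRE:
    """Convenience: midpoint -> location class -> distances, in one call."""
    mid = ire_midpoint(scored.core)
    location = classify_location(mid, ctx)
    dist = compute_distances(mid, location, ctx)
    return LocatedIRE(scored=scored, midpoint=mid, location=location, gene=gene, **dist)


def collapse_redundant(located: list[LocatedIRE]) -> list[LocatedIRE]:
    """Collapse identical IREs predicted in multiple transcripts of one gene.

    Within one gene, records identical in (core sequence, motif, location)
    keep a single occurrence; distinct cores in the same gene are all
    kept, as is the same core in different genes.  Output order is stable
    (first occurrence wins).  Idempotent.
    """
    seen: set[tuple] = set()
    out: list[LocatedIRE] = []
    for rec in located:
        key = (rec.gene, rec.scored.core.core_seq, rec.scored.core.motif.motif_id, rec.location)
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


def region_enrichment(
    located: list[LocatedIRE],
    contexts: dict[str, TranscriptContext],
) -> dict[str, dict[str, float | int | None]]:
    """Per-location-class counts and length-normalized densities.

    Density = count / total nt of that region class across the supplied
    transcripts (5UTR = cds_start-1 nt, CDS = cds_end-cds_start+1,
    3UTR = length-cds_end).  The boundary classes are windows rather than
    annotated regions; each contributes an effective 29 nt per transcript
    (the span of midpoints the strict <|15| rule admits).
    """
    counts = {loc: 0 for loc in LOCATIONS}
    for rec in located:
        counts[rec.location] += 1
    window_nt = 2 * BOUNDARY_WINDOW - 1
    totals = {loc: 0 for loc in LOCATIONS}
    for ctx in contexts.values():
        totals["5UTR"] += ctx.cds_start - 1
        totals["CDS"] += ctx.cds_end - ctx.cds_start + 1
        totals["3UTR"] += ctx.length - ctx.cds_end
        totals["5UTR-CDS"] += window_nt
        totals["CDS-3UTR"] += window_nt
    return {
        loc: {
            "count": counts[loc],
            "region_nt": totals[loc],
            "density": (counts[loc] / totals[loc]) if totals[loc] else None,
        }
        for loc in LOCATIONS
    }
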