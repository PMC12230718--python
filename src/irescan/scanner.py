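"""Assembly of full IRE candidates around apical-loop matches.

An IRE core, in the standard position numbering, is::

        N14 N15 N16 N17            apical loop (N14-N19; N19i/N19ii for
      N13              N18          the extended-loop motif 22)
      N12              N19
       |  upper stem    |
      N9 . . . . . . . N24         five base pairs N9.N24 .. N13.N20
      N8 (bulge)        [b]        unpaired 5' bulge; optional single
      N7 ------------- N25         3' bulged nucleotide between N24 and
       |  lower stem    |          N25; N7.N25 is the first lower-stem
                                   pair and is part of the prediction

The minimal core spans 19 nt (N7..N25), 20 nt with a 3' bulge, +2 nt for
the extended loop.  The scanner finds every loop match, then attempts all
stem assemblies consistent with the configured defect limits, recording
mismatches, G.U wobbles and single-nucleotide stem bulges as defects for
the scorer.  A mismatch at N7.N25 never rejects a candidate - it is
heavily penalized instead, mirroring the disease-associated mutations at
that position.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .registry import MotifDefinition, default_registry, match_loop

__all__ = [
    "PairClass",
    "Defect",
    "IRECore",
    "ScanParams",
    "InputSizeError",
    "normalize_sequence",
    "is_pair",
    "scan_sequence",
    "dedupe_site_interpretations",
]

MAX_INPUT_LEN = 50_000  # per-record cap enforced in interactive mode

# Ordered position names of the 19-nt core, 5' to 3'.
CORE_POSITIONS = (
    "N7", "N8", "N9", "N10", "N11", "N12", "N13",
    "N14", "N15", "N16", "N17", "N18", "N19",
    "N20", "N21", "N22", "N23", "N24", "N25",
)

UPPER_STEM_PAIRS = (("N9", "N24"), ("N10", "N23"), ("N11", "N22"), ("N12", "N21"), ("N13", "N20"))


class PairClass(enum.Enum):
    WATSON_CRICK = "watson_crick"
    WOBBLE = "wobble"
    MISMATCH = "mismatch"


_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def is_pair(a: str, b: str, allow_wobble: bool = True) -> PairClass:
    """Classify a putative base pair as Watson-Crick, wobble or mismatch."""
    if (a, b) in _WC:
        return PairClass.WATSON_CRICK
    if (a, b) in _WOBBLE:
        return PairClass.WOBBLE if allow_wobble else PairClass.MISMATCH
    return PairClass.MISMATCH


class InputSizeError(ValueError):
    """Input record exceeds the per-submission length cap."""


def normalize_sequence(raw: str, max_len: int | None = None) -> str:
    """Normalize a DNA/RNA string to uppercase RNA.

    Uppercases and maps T->U.  IUPAC ambiguity codes are preserved but
    never match a motif pattern position downstream.  Positions map 1:1 to
    the input (the offset map is the identity - nothing is dropped), so
    coordinates reported against the normalized string are valid against
    the input as given.

    Raises :class:`InputSizeError` when ``max_len`` is given and exceeded,
    and ``ValueError`` for empty input or non-nucleotide characters.
    """
    if not raw:
        raise ValueError("empty input sequence")
    if max_len is not None and len(raw) > max_len:
        raise InputSizeError(
            f"sequence of {len(raw)} nt exceeds the {max_len} nt per-submission cap"
        )
    seq = raw.upper().replace("T", "U")
    bad = set(seq) - set("ACGUNRYSWKMBDHV")
    if bad:
        raise ValueError(f"non-nucleotide characters in input: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class Defect:
    """A structural deviation from the ideal core model.

    ``kind`` is one of ``upper_stem_mismatch``, ``upper_stem_wobble``,
    ``upper_stem_bulge``, ``n7_n25_mismatch``, ``n7_n25_wobble``;
    ``where`` is the pair index (0..4) for stem defects or -1.
    """

    kind: str
    where: int = -1


@dataclass(frozen=True)
class ScanParams:
    """Structural tolerance knobs for candidate assembly."""

    max_mismatches: int = 1
    max_stem_bulges: int = 1
    allow_wobble: bool = True
    allow_3prime_bulge: bool = True


@dataclass(frozen=True)
class IRECore:
    """A positioned structural parse of a putative IRE."""

    seq_id: str
    loop_start: int  # 0-based offset of N14
    motif: MotifDefinition
    positions: dict[str, int]  # position name -> 0-based sequence offset
    core_seq: str
    has_3prime_bulge: bool = False
    bulge3p_offset: int | None = None
    stem_bulge_offset: int | None = None
    defects: tuple[Defect, ...] = ()

    @property
    def start(self) -> int:
        """0-based offset of N7 (core 5' end)."""
        return self.positions["N7"]

    @property
    def end(self) -> int:
        """0-based offset of N25 (core 3' end, inclusive)."""
        return self.positions["N25"]

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def defect_count(self, kind: str) -> int:
        return sum(1 for d in self.defects if d.kind == kind)

    def model_pairs(self) -> list[tuple[int, int]]:
        """The six model base pairs as absolute sequence offsets."""
        pairs = [(self.positions[a], self.positions[b]) for a, b in UPPER_STEM_PAIRS]
        pairs.append((self.positions["N7"], self.positions["N25"]))
        return pairs


def _arm_layouts(offsets: list[int], bulge: bool) -> list[tuple[list[int], int | None]]:
    """Paired-offset layouts for a stem arm occupying ``offsets``.

    Without a bulge the five offsets pair directly.  With a bulge the arm
    occupies six offsets and one *interior* offset (never the first or
    last, which would merely shift the arm) is the unpaired insertion.
    """
    if not bulge:
        return [(offsets, None)]
    layouts = []
    for b in range(1, 5):
        paired = offsets[:b] + offsets[b + 1 :]
        layouts.append((paired, offsets[b]))
    return layouts


def scan_sequence(
    seq: str,
    registry: list[MotifDefinition] | None = None,
    params: ScanParams | None = None,
    seq_id: str = "seq",
) -> list[IRECore]:
    """Find every IRE candidate in a normalized RNA sequence.

    For each loop match at each offset, all stem assemblies consistent
    with the defect limits are attempted: a contiguous 5' arm N9-N13
    immediately 5' of the loop and 3' arm N20-N24 immediately 3' of it
    (after N19ii when the loop is extended), each optionally carrying one
    single-nucleotide insertion; N8 must equal the motif's bulge base and
    sit immediately 5' of N9; N7.N25 is evaluated as a pair with an
    optional single bulged nucleotide between N24 and N25.  Candidates
    whose loop sits nearer than the required flank to either sequence end
    are skipped silently, so a bare 19-nt perfect core is detectable with
    zero flanks.
    """
    if registry is None:
        registry = default_registry()
    if params is None:
        params = ScanParams()
    out: list[IRECore] = []
    n = len(seq)
    for pos in range(n - 5):
        for motif, _matched in match_loop(seq, pos, registry):
            loop_len = motif.loop_length
            # 5' side: N8 + arm; arm needs 5 nt (6 with bulge).
            for arm5_bulge in ([False, True] if params.max_stem_bulges else [False]):
                arm5_len = 5 + arm5_bulge
                n8_off = pos - arm5_len - 1
                n7_off = n8_off - 1
                if n7_off < 0:
                    continue
                if seq[n8_off] != motif.n8_bulge:
                    continue
                arm5_offsets = list(range(pos - arm5_len, pos))
                for arm5_paired, arm5_bulge_off in _arm_layouts(arm5_offsets, arm5_bulge):
                    for arm3_bulge in ([False, True] if params.max_stem_bulges else [False]):
                        if arm5_bulge + arm3_bulge > params.max_stem_bulges:
                            continue
                        arm3_len = 5 + arm3_bulge
                        loop_end = pos + loop_len
                        for closing_bulge in (
                            [False, True] if params.allow_3prime_bulge else [False]
                        ):
                            n25_off = loop_end + arm3_len + closing_bulge
                            if n25_off >= n:
                                continue
                            arm3_offsets = list(range(loop_end, loop_end + arm3_len))
                            for arm3_paired, arm3_bulge_off in _arm_layouts(
                                arm3_offsets, arm3_bulge
                            ):
                                core = _assemble(
                                    seq, seq_id, pos, motif, params,
                                    n7_off, n8_off, arm5_paired, arm5_bulge_off,
                                    arm3_paired, arm3_bulge_off,
                                    n25_off, closing_bulge,
                                )
                                if core is not None:
                                    out.append(core)
    return out


def _assemble(
    seq: str,
    seq_id: str,
    pos: int,
    motif: MotifDefinition,
    params: ScanParams,
    n7_off: int,
    n8_off: int,
    arm5_paired: list[int],
    arm5_bulge_off: int | None,
    arm3_paired: list[int],
    arm3_bulge_off: int | None,
    n25_off: int,
    closing_bulge: bool,
) -> IRECore | None:
    positions: dict[str, int] = {"N7": n7_off, "N8": n8_off}
    for name, off in zip(("N9", "N10", "N11", "N12", "N13"), arm5_paired):
        positions[name] = off
    for i in range(6):
        positions[f"N{14 + i}"] = pos + i
    if motif.loop_extension:
        positions["N19i"] = pos + 6
        positions["N19ii"] = pos + 7
    # 3' arm reads 5'->3' as N20..N24.
    for name, off in zip(("N20", "N21", "N22", "N23", "N24"), arm3_paired):
        positions[name] = off
    positions["N25"] = n25_off

    defects: list[Defect] = []
    mismatches = 0
    for idx, (a, b) in enumerate(UPPER_STEM_PAIRS):
        cls = is_pair(seq[positions[a]], seq[positions[b]], params.allow_wobble)
        if cls is PairClass.MISMATCH:
            mismatches += 1
            if mismatches > params.max_mismatches:
                return None
            defects.append(Defect("upper_stem_mismatch", idx))
        elif cls is PairClass.WOBBLE:
            defects.append(Defect("upper_stem_wobble", idx))
    stem_bulge_off = arm5_bulge_off if arm5_bulge_off is not None else arm3_bulge_off
    if stem_bulge_off is not None:
        defects.append(Defect("upper_stem_bulge"))
    closing = is_pair(seq[n7_off], seq[n25_off], params.allow_wobble)
    if closing is PairClass.MISMATCH:
        defects.append(Defect("n7_n25_mismatch"))
    elif closing is PairClass.WOBBLE:
        defects.append(Defect("n7_n25_wobble"))
    return IRECore(
        seq_id=seq_id,
        loop_start=pos,
        motif=motif,
        positions=positions,
        core_seq=seq[n7_off : n25_off + 1],
        has_3prime_bulge=closing_bulge,
        bulge3p_offset=(n25_off - 1) if closing_bulge else None,
        stem_bulge_offset=stem_bulge_off,
        defects=tuple(defects),
    )


def dedupe_site_interpretations(cands: list[IRECore]) -> list[list[IRECore]]:
    """Group candidates from one sequence by apical-loop offset.

    Every interpretation is retained for scoring; the per-site winner is
    chosen after scoring (highest score, then lowest registry row).
    Groups are ordered by loop offset.
    """
    groups: dict[int, list[IRECore]] = {}
    for c in cands:
        groups.setdefault(c.loop_start, []).append(c)
    return [groups[k] for k in sorted(groups)]
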