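"""Curated registry of IRE apical-loop motifs and degenerate loop matching.

The registry encodes the 22 motif families (23 pattern rows, since family 9
is split into the 9a/9b variants) that define which 6-nt apical loops can
seed an IRE prediction.  Each row fixes:

* the identity of the unpaired N8 bulge base (C for canonical IREs, G for
  motif 18, U for motifs 20-22),
* a 6-position degenerate pattern for the loop N14-N19 (IUPAC codes),
* the cross-loop N14.N18 interaction implied by the pattern, and
* for motif 22 only, a 2-nt "CA" loop extension (positions N19i/N19ii)
  that widens the apical loop to 8 nt.

The registry is data, not code: the bundled table lives in
``data/motifs.tsv`` and users may supply an override file in the same
format to extend or replace it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "MotifDefinition",
    "RegistryError",
    "IUPAC",
    "load_registry",
    "match_loop",
    "default_registry",
]

# IUPAC nucleotide codes over the RNA alphabet.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}

LEGACY = "legacy_v1_2"
NEW_V3 = "new_v3"


class RegistryError(ValueError):
    """Raised when a motif registry file is malformed or inconsistent."""


@dataclass(frozen=True)
class MotifDefinition:
    """One row of the motif registry.

    Attributes
    ----------
    motif_id:
        Row label, e.g. ``"1"``, ``"9a"``, ``"22"``.
    family:
        Numeric family; ``"9a"`` and ``"9b"`` share family ``"9"``.
    row:
        0-based registry row rank, used as a deterministic tie-break.
    version_tag:
        ``"legacy_v1_2"`` for the original 18 motifs, ``"new_v3"`` for the
        additions (9b, 19, 20, 21, 22).
    n8_bulge:
        Required identity of the unpaired bulge base N8.
    loop_pattern:
        Six IUPAC positions for loop N14-N19.
    cross_loop_pair:
        The (N14, N18) cross-loop bases, fixed by the pattern.
    loop_extension:
        Extra loop nucleotides N19i-N19ii; non-empty only for motif 22
        (value ``"CA"``).
    """

    motif_id: str
    family: str
    row: int
    version_tag: str
    n8_bulge: str
    loop_pattern: str
    cross_loop_pair: tuple[str, str]
    loop_extension: str = ""

    @property
    def loop_length(self) -> int:
        """Total apical-loop length including any extension (6 or 8)."""
        return 6 + len(self.loop_extension)

    def allowed(self, position: int) -> frozenset[str]:
        """Set of bases the pattern admits at loop position 0..5."""
        return IUPAC[self.loop_pattern[position]]

    def enumerate_loops(self) -> list[str]:
        """All concrete loop strings (without extension) the pattern admits."""
        loops = [""]
        for code in self.loop_pattern:
            loops = [pre + b for pre in loops for b in sorted(IUPAC[code])]
        return loops


def _validate(rows: list[MotifDefinition], source: str) -> None:
    for m in rows:
        if len(m.loop_pattern) != 6 or any(c not in IUPAC for c in m.loop_pattern):
            raise RegistryError(
                f"{source}: motif {m.motif_id!r} loop pattern {m.loop_pattern!r} "
                "is not 6 IUPAC positions"
            )
        if m.n8_bulge not in {"A", "C", "G", "U"}:
            raise RegistryError(f"{source}: motif {m.motif_id!r} has invalid N8 {m.n8_bulge!r}")
        if m.version_tag not in {LEGACY, NEW_V3}:
            raise RegistryError(f"{source}: motif {m.motif_id!r} has unknown version tag")
        # Table consistency: pattern position 1 (N14) and 5 (N18) must equal
        # the declared cross-loop pair.
        if (m.loop_pattern[0], m.loop_pattern[4]) != m.cross_loop_pair:
            raise RegistryError(
                f"{source}: motif {m.motif_id!r} cross-loop pair "
                f"{m.cross_loop_pair} disagrees with pattern {m.loop_pattern!r}"
            )
        if m.loop_extension and any(c not in "ACGU" for c in m.loop_extension):
            raise RegistryError(
                f"{source}: motif {m.motif_id!r} extension {m.loop_extension!r} not concrete RNA"
            )
    ids = [m.motif_id for m in rows]
    if len(set(ids)) != len(ids):
        raise RegistryError(f"{source}: duplicate motif_id")


def _parse_table(text: str, source: str) -> list[MotifDefinition]:
    rows: list[MotifDefinition] = []
    header: list[str] | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            expected = ["motif_id", "version", "n8", "loop_pattern", "cross_pair", "extension"]
            if header != expected:
                raise RegistryError(f"{source}:{lineno}: header must be {expected}, got {header}")
            continue
        if len(fields) != 6:
            raise RegistryError(f"{source}:{lineno}: expected 6 columns, got {len(fields)}")
        motif_id, version, n8, pattern, cross, ext = fields
        pair = tuple(cross.split("-"))
        if len(pair) != 2:
            raise RegistryError(f"{source}:{lineno}: cross_pair {cross!r} must be like 'C-G'")
        family = motif_id.rstrip("ab")
        rows.append(
            MotifDefinition(
                motif_id=motif_id,
                family=family,
                row=len(rows),
                version_tag=version,
                n8_bulge=n8,
                loop_pattern=pattern.upper().replace("T", "U"),
                cross_loop_pair=(pair[0], pair[1]),
                loop_extension="" if ext in {"-", ""} else ext,
            )
        )
    if header is None:
        raise RegistryError(f"{source}: empty registry file")
    _validate(rows, source)
    return rows


def load_registry(config_override: str | Path | None = None) -> list[MotifDefinition]:
    """Load the motif registry, from the bundled table or an override file.

    Returns the rows in table order (stable; the order defines the
    tie-break rank).  Raises :class:`RegistryError` naming the offending
    row when the override file is malformed.
    """
    if config_override is None:
        text = resources.files("irescan.data").joinpath("motifs.tsv").read_text()
        return _parse_table(text, "builtin motifs.tsv")
    path = Path(config_override)
    return _parse_table(path.read_text(), str(path))


_DEFAULT: list[MotifDefinition] | None = None


def default_registry() -> list[MotifDefinition]:
    """The bundled registry, loaded once and cached."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_registry()
    return _DEFAULT


def match_loop(
    seq: str,
    pos: int,
    registry: list[MotifDefinition] | None = None,
) -> list[tuple[MotifDefinition, str]]:
    """Match every registry motif whose loop pattern fits ``seq`` at ``pos``.

    ``seq`` must already be normalized RNA (``A/C/G/U``; ambiguity codes are
    permitted in the sequence but never match a pattern position).  ``pos``
    is the 0-based offset of loop position N14.  For motif 22 the match
    additionally requires the ``CA`` extension at the two following
    positions and the reported loop string covers all 8 nt.

    Patterns are not mutually exclusive: several motifs may match one site
    (e.g. motifs 1, 20 and 22 share the loop pattern) and all are returned.
    """
    if registry is None:
        registry = default_registry()
    if pos < 0 or pos + 6 > len(seq):
        raise ValueError(f"loop window [{pos}, {pos + 6}) outside sequence of length {len(seq)}")
    window = seq[pos : pos + 6]
    bad = set(window) - set("ACGUNRYSWKMBDHV")
    if bad:
        raise ValueError(f"non-RNA characters {sorted(bad)} at position {pos}; normalize first")
    hits: list[tuple[MotifDefinition, str]] = []
    for motif in registry:
        if any(window[i] not in motif.allowed(i) for i in range(6)):
            continue
        if motif.loop_extension:
            ext_end = pos + 6 + len(motif.loop_extension)
            if ext_end > len(seq) or seq[pos + 6 : ext_end] != motif.loop_extension:
                continue
            hits.append((motif, seq[pos:ext_end]))
        else:
            hits.append((motif, window))
    return hits
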