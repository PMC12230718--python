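"""Deterministic synthetic IRE fixtures.

Builds perfect or defect-bearing IRE cores for every registry motif,
optionally wraps them in a complementary lower stem (so the full hairpin
folds exactly as the structural model), and plants cores in seeded
random backgrounds whose spurious loop-pattern hits are rejected away.
These generators define the study conditions of the test suite: every
truth record they emit must be recovered by the scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .registry import IUPAC, MotifDefinition, default_registry, match_loop
from .scanner import PairClass, is_pair

__all__ = ["CoreTruth", "PlantTruth", "FixtureError", "build_core", "build_hairpin", "plant"]

RNA = "ACGU"
COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# Default stems: strong, unambiguous helices so fixtures fold robustly.
ARM5 = "GCGUC"  # N9..N13; N20..N24 is its reverse complement
N7_N25 = ("G", "C")
LOWER5 = "GGCAG"  # default lower stem for contextualized hairpins

_DEFECT_KEYS = {"upper_stem_mismatch", "upper_stem_wobble", "upper_stem_bulge", "n7_n25"}


class FixtureError(ValueError):
    """The requested fixture cannot be constructed."""


@dataclass(frozen=True)
class CoreTruth:
    """Ground truth for one constructed core."""

    motif_id: str
    family: str
    loop_offset: int  # offset of N14 within the core string
    length: int
    with_3prime_bulge: bool
    defect_count: int  # total scanner-visible defects (incl. wobbles, N7.N25)
    defects: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PlantTruth:
    """Ground truth for a core planted in a background sequence."""

    core: CoreTruth
    position: int  # offset of the core within the record
    loop_offset: int  # absolute offset of N14 within the record


def _motif(motif_id: str, registry: list[MotifDefinition]) -> MotifDefinition:
    for m in registry:
        if m.motif_id == motif_id:
            return m
    raise FixtureError(f"unknown motif {motif_id!r}")


def _revcomp(s: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(s))


def _mismatching(base: str, rng: np.random.Generator) -> str:
    """A base that neither Watson-Crick- nor wobble-pairs with ``base``."""
    choices = [b for b in RNA if is_pair(base, b) is PairClass.MISMATCH]
    return choices[rng.integers(len(choices))]


def build_core(
    motif_id: str,
    defects: dict | None = None,
    with_3prime_bulge: bool = False,
    seed: int = 0,
    registry: list[MotifDefinition] | None = None,
) -> tuple[str, CoreTruth]:
    """Construct a core realizing the structural model for one motif.

    ``defects`` may request ``upper_stem_mismatch`` (0/1),
    ``upper_stem_wobble`` (count), ``upper_stem_bulge`` (0/1) and
    ``n7_n25`` ("mismatch" or "wobble").  The emitted core satisfies the
    model exactly except for the requested defects; deterministic given
    ``seed``.  Raises :class:`FixtureError` for unsatisfiable requests
    (beyond the scanner's defect caps).
    """
    if registry is None:
        registry = default_registry()
    motif = _motif(motif_id, registry)
    defects = dict(defects or {})
    unknown = set(defects) - _DEFECT_KEYS
    if unknown:
        raise FixtureError(f"unknown defect keys {sorted(unknown)}")
    if defects.get("upper_stem_mismatch", 0) > 1 or defects.get("upper_stem_bulge", 0) > 1:
        raise FixtureError("at most one stem mismatch and one stem bulge are constructible")
    rng = np.random.default_rng(seed)

    loop = "".join(
        sorted(IUPAC[c])[rng.integers(len(IUPAC[c]))] for c in motif.loop_pattern
    ) + motif.loop_extension
    arm5 = list(ARM5)
    arm3 = list(_revcomp(ARM5))  # N20..N24; N24 (last) pairs N9 (first of arm5)
    n7, n25 = N7_N25
    used_pairs: set[int] = set()

    n_wob = int(defects.get("upper_stem_wobble", 0))
    if n_wob > 5:
        raise FixtureError("at most 5 wobble pairs exist")
    for _ in range(n_wob):
        idx = int(rng.integers(5))
        while idx in used_pairs:
            idx = int(rng.integers(5))
        used_pairs.add(idx)
        arm5[idx], arm3[4 - idx] = "G", "U"  # pair index i: N(9+i) . N(24-i)
    if defects.get("upper_stem_mismatch", 0):
        idx = int(rng.integers(5))
        while idx in used_pairs:
            idx = int(rng.integers(5))
        used_pairs.add(idx)
        arm3[4 - idx] = _mismatching(arm5[idx], rng)
    n7_defect = defects.get("n7_n25")
    # Realized on the 5' side (N7) so that in a lower-stem context the
    # defect cannot be "rescued" by re-reading the next 3' base as N25.
    if n7_defect == "wobble":
        n7, n25 = "U", "G"
    elif n7_defect == "mismatch":
        n7 = _mismatching(n25, rng)
    elif n7_defect not in (None, 0):
        raise FixtureError(f"n7_n25 defect must be 'mismatch' or 'wobble', got {n7_defect!r}")

    arm5_s = "".join(arm5)
    if defects.get("upper_stem_bulge", 0):
        slot = int(rng.integers(1, 5))  # interior insertion, as the scanner models it
        ins = RNA[rng.integers(4)]
        arm5_s = arm5_s[:slot] + ins + arm5_s[slot:]
    arm3_s = "".join(arm3)
    if with_3prime_bulge:
        # The bulged base must not pair with N7, otherwise a 19-nt
        # truncation would read it as a perfect N25.
        arm3_s = arm3_s + _mismatching(n7, rng)

    core = n7 + motif.n8_bulge + arm5_s + loop + arm3_s + n25
    loop_offset = 2 + len(arm5_s)
    n_defects = (
        n_wob
        + int(bool(defects.get("upper_stem_mismatch", 0)))
        + int(bool(defects.get("upper_stem_bulge", 0)))
        + int(n7_defect in ("mismatch", "wobble"))
    )
    truth = CoreTruth(
        motif_id=motif.motif_id,
        family=motif.family,
        loop_offset=loop_offset,
        length=len(core),
        with_3prime_bulge=with_3prime_bulge,
        defect_count=n_defects,
        defects=defects,
    )
    return core, truth


def build_hairpin(
    motif_id: str,
    lower_stem: int = 5,
    seed: int = 0,
    defects: dict | None = None,
    with_3prime_bulge: bool = False,
    registry: list[MotifDefinition] | None = None,
) -> tuple[str, CoreTruth]:
    """A core wrapped in a complementary lower stem of ``lower_stem`` bp.

    The lower stem is not part of the positional model but stabilizes the
    fold so the closing N7.N25 pair forms in the MFE structure - use this
    for fixtures that must reach full structure concordance.
    """
    if lower_stem > len(LOWER5):
        raise FixtureError(f"lower_stem up to {len(LOWER5)} bp supported")
    core, truth = build_core(
        motif_id, defects=defects, with_3prime_bulge=with_3prime_bulge,
        seed=seed, registry=registry,
    )
    lower = LOWER5[:lower_stem]
    seq = lower + core + _revcomp(lower)
    shifted = CoreTruth(
        motif_id=truth.motif_id,
        family=truth.family,
        loop_offset=truth.loop_offset + lower_stem,
        length=truth.length,
        with_3prime_bulge=truth.with_3prime_bulge,
        defect_count=truth.defect_count,
        defects=truth.defects,
    )
    return seq, shifted


def plant(
    core: str,
    background_len: int,
    position: int,
    seed: int = 0,
    truth: CoreTruth | None = None,
    registry: list[MotifDefinition] | None = None,
    max_attempts: int = 500,
) -> tuple[str, PlantTruth | None]:
    """Splice a core into a seeded uniform-random background.

    The background is rejection-sampled so no loop-pattern hit other than
    the planted one touches a background position (a hit lying entirely
    inside the supplied core is the core's own property and is kept).
    Partial/spurious stem-level hits are allowed - they exercise the stem
    filter.  Deterministic given ``seed``.
    """
    if registry is None:
        registry = default_registry()
    if position + len(core) > background_len:
        raise FixtureError("core does not fit the background at that position")
    rng = np.random.default_rng(seed)
    planted_loop = None if truth is None else position + truth.loop_offset
    for _ in range(max_attempts):
        bg = rng.integers(0, 4, size=background_len)
        seq = "".join(RNA[b] for b in bg)
        seq = seq[:position] + core + seq[position + len(core) :]
        clean = True
        for off in range(len(seq) - 5):
            if off == planted_loop:
                continue
            if position <= off and off + 6 <= position + len(core):
                continue  # entirely inside the planted core
            if match_loop(seq, off, registry):
                clean = False
                break
        if clean:
            pt = None if truth is None else PlantTruth(
                core=truth, position=position, loop_offset=planted_loop
            )
            return seq, pt
    raise FixtureError(
        f"no spurious-loop-free background of {background_len} nt found "
        f"in {max_attempts} attempts; shorten the background"
    )
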