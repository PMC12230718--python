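"""Secondary-structure evidence for IRE candidates.

Each candidate is folded together with flanking context (default 15 nt per
side, so a centered core sees >= 31 nt - enough for the variable lower
stem, which is not part of the positional model but does stabilize the
hairpin).  The fold contributes two quantities to scoring:

* ``delta_g`` - the minimum free energy (kcal/mol) of the folded window;
  0 is the worst possible value (no structure at all);
* ``concordance`` - the fraction (k/6) of the candidate's six model base
  pairs (five upper-stem pairs plus N7.N25) that appear in the predicted
  minimum-free-energy structure.

The default engine is ViennaRNA's deterministic MFE folder through its
Python bindings.  A built-in approximate folder is provided so the
library works without the bindings: it forms only the candidate's own
model helix (Watson-Crick at -1.0, wobble at -0.5 kcal/mol per pair,
additive) and is clearly labelled approximate in its output.
"""

from __future__ import annotations

from dataclasses import dataclass

from .scanner import IRECore, PairClass, is_pair

__all__ = ["FoldResult", "FoldingEngineError", "fold_window", "fallback_fold", "pair_table"]

DEFAULT_FLANK = 15


class FoldingEngineError(RuntimeError):
    """The requested folding engine is unavailable."""


@dataclass(frozen=True)
class FoldResult:
    """MFE structure of a candidate's window and its concordance with the model."""

    window_start: int
    window_end: int  # exclusive
    dot_bracket: str
    delta_g: float
    concordance: float  # k/6, fraction of model pairs present in the MFE structure
    loop_open: bool  # loop N14-N19 unpaired (N14.N18 interaction tolerated)
    engine: str = "vienna"
    approximate: bool = False


def pair_table(dot_bracket: str) -> dict[int, int]:
    """Map each paired position to its partner (0-based, both directions)."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, ch in enumerate(dot_bracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
    return pairs


def _concordance_and_loop(candidate: IRECore, dot_bracket: str, window_start: int) -> tuple[float, bool]:
    pairs = pair_table(dot_bracket)
    k = 0
    for i, j in candidate.model_pairs():
        wi, wj = i - window_start, j - window_start
        if pairs.get(wi) == wj:
            k += 1
    loop_positions = [candidate.positions[f"N{p}"] - window_start for p in range(14, 20)]
    n14, n18 = loop_positions[0], loop_positions[4]
    loop_open = True
    for w in loop_positions:
        partner = pairs.get(w)
        if partner is None:
            continue
        if {w, partner} == {n14, n18}:
            continue  # the cross-loop N14.N18 interaction is part of the model
        loop_open = False
        break
    return k / 6.0, loop_open


def _window(seq: str, candidate: IRECore, flank: int) -> tuple[int, int]:
    start = max(0, candidate.start - flank)
    end = min(len(seq), candidate.end + 1 + flank)
    return start, end


def fold_window(
    seq: str,
    candidate: IRECore,
    flank: int = DEFAULT_FLANK,
    engine: str = "vienna",
) -> FoldResult:
    """Fold the candidate plus ``flank`` nt of context and score concordance.

    ``engine`` selects ``"vienna"`` (ViennaRNA MFE, deterministic) or
    ``"builtin"`` (the approximate fallback).  Raises
    :class:`FoldingEngineError` with an explicit fallback hint when the
    ViennaRNA bindings are missing - never a silent zero.
    """
    if engine == "builtin":
        return fallback_fold(seq, candidate, flank)
    if engine != "vienna":
        raise FoldingEngineError(f"unknown fold engine {engine!r}; use 'vienna' or 'builtin'")
    try:
        import RNA  # ViennaRNA python bindings
    except ImportError as exc:  # pragma: no cover - bindings present in CI image
        raise FoldingEngineError(
            "ViennaRNA python bindings not importable; re-run with engine='builtin' "
            "for the approximate internal folder"
        ) from exc
    start, end = _window(seq, candidate, flank)
    window = seq[start:end]
    dot_bracket, dg = RNA.fold(window)
    dg = float(dg)
    if "(" not in dot_bracket:
        dg = 0.0  # fully unpaired prediction: worst possible energy
    concordance, loop_open = _concordance_and_loop(candidate, dot_bracket, start)
    return FoldResult(
        window_start=start,
        window_end=end,
        dot_bracket=dot_bracket,
        delta_g=dg,
        concordance=concordance,
        loop_open=loop_open,
        engine="vienna",
        approximate=False,
    )


def fallback_fold(seq: str, candidate: IRECore, flank: int = DEFAULT_FLANK) -> FoldResult:
    """Approximate internal folder: forms only the candidate's model helix.

    Energy is additive over the six model pairs that can form: -1.0 per
    Watson-Crick pair, -0.5 per G.U wobble; mismatched model pairs stay
    unpaired.  No other pairing is considered, so the result is labelled
    approximate.
    """
    start, end = _window(seq, candidate, flank)
    structure = ["."] * (end - start)
    energy = 0.0
    for i, j in candidate.model_pairs():
        cls = is_pair(seq[i], seq[j], allow_wobble=True)
        if cls is PairClass.MISMATCH:
            continue
        energy += -1.0 if cls is PairClass.WATSON_CRICK else -0.5
        structure[i - start] = "("
        structure[j - start] = ")"
    dot_bracket = "".join(structure)
    concordance, loop_open = _concordance_and_loop(candidate, dot_bracket, start)
    return FoldResult(
        window_start=start,
        window_end=end,
        dot_bracket=dot_bracket,
        delta_g=energy,
        concordance=concordance,
        loop_open=loop_open,
        engine="builtin",
        approximate=True,
    )
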