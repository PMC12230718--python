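"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: loop matching
is re-done with regular expressions over fully enumerated IUPAC classes,
and candidate scanning is re-done by testing every offset against every
concrete loop string with exact Watson-Crick stems.
"""

from __future__ import annotations

import re

IUPAC_RE = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "[AG]", "Y": "[CU]", "S": "[CG]", "W": "[AU]", "K": "[GU]", "M": "[AC]",
    "B": "[CGU]", "D": "[AGU]", "H": "[ACU]", "V": "[ACG]", "N": "[ACGU]",
}

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def loop_regex(motif) -> re.Pattern:
    return re.compile("".join(IUPAC_RE[c] for c in motif.loop_pattern))


def regex_match_motifs(six_mer: str, registry) -> set[str]:
    """Motif ids whose 6-nt pattern matches, ignoring extensions entirely."""
    out = set()
    for m in registry:
        if m.loop_extension:
            continue
        if loop_regex(m).fullmatch(six_mer):
            out.add(m.motif_id)
    return out


def enumerate_loops(motif) -> list[str]:
    loops = [""]
    for c in motif.loop_pattern:
        chars = IUPAC_RE[c].strip("[]")
        loops = [p + b for p in loops for b in chars]
    return loops


def brute_force_scan(seq: str, registry) -> set[tuple[int, str]]:
    """(loop_start, motif_id) pairs for defect-free, exact-WC-stem cores.

    Mirrors the scanner run with mismatches, wobble and all bulges
    disabled.  The N7.N25 closing pair may be anything (it is recorded as
    a defect, never a rejection), matching the scanner's contract.
    """
    hits = set()
    for motif in registry:
        ext = motif.loop_extension
        for loop in enumerate_loops(motif):
            full_loop = loop + ext
            start = 0
            while True:
                pos = seq.find(full_loop, start)
                if pos == -1:
                    break
                start = pos + 1
                n7 = pos - 7
                n25 = pos + len(full_loop) + 5
                if n7 < 0 or n25 >= len(seq):
                    continue
                if seq[pos - 6] != motif.n8_bulge:
                    continue
                arm5 = seq[pos - 5 : pos]
                arm3 = seq[pos + len(full_loop) : pos + len(full_loop) + 5]
                # pairs: arm5[i] with arm3[4-i]
                if all((arm5[i], arm3[4 - i]) in WC for i in range(5)):
                    hits.add((pos, motif.motif_id))
    return hits
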