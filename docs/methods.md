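# Methods

## Structural model and scanning

An IRE candidate is a positional parse N7–N25 around a matched apical
loop: the loop N14–N19 (plus N19i/N19ii = CA for the extended-loop motif
22), the 5-bp upper stem (N9·N24 … N13·N20), the unpaired N8 bulge
immediately 5′ of the upper stem, and the N7·N25 closing pair of the
lower stem. The lower stem beyond N7·N25 is deliberately outside the
positional model — it varies widely across functional IREs — and enters
only through the folding evidence.

The motif registry is data (`data/motifs.tsv`): 23 rows, 22 motif
families, each fixing the N8 identity, a 6-position IUPAC pattern for the
loop, the implied cross-loop N14·N18 pair, and any loop extension. Rows
9a/9b split family 9's N19 into complementary halves (C/U vs A/G), so
their union covers all four bases with no overlap. Patterns are not
mutually exclusive; every matching motif is carried through scanning, and
the best-scoring interpretation per loop site wins afterwards (ties break
to the lower registry row, then fewer defects, then the parsimonious
assembly without a 3′ bulge).

Scanning assembles, for each loop match, every stem layout within the
defect caps: up to `max_mismatches` (default 1) upper-stem mismatches, up
to `max_stem_bulges` (default 1) single-nucleotide insertions in either
arm (interior positions only — an edge insertion is just a shifted arm),
unlimited G·U wobbles (each penalized), and optionally one bulged
nucleotide of any identity between N24 and N25. A defect at N7·N25 never
rejects a candidate; it is recorded and heavily penalized, because the
clinically relevant closing-pair mutants must be *found* and *demoted*,
not silenced. The minimal detectable input is therefore the bare 19-nt
core (20 nt with the 3′ bulge).

Wobble pairs are treated as a separate, mildly penalized pair class
rather than mismatches: RNA stems tolerate G·U routinely, and folding
engines pair them, so counting them as mismatches would make the
structure evidence and the defect ledger disagree.

## Folding evidence

Each candidate is folded together with `flank` nt of context per side
(default 15, so a centered candidate sees ≥ 31 nt — enough to include a
typical lower stem). Two quantities feed scoring: the MFE ΔG of the
window (kcal/mol; 0 means no structure and is the worst possible value)
and the concordance k/6 — how many of the six model pairs appear in the
MFE structure. The default engine is ViennaRNA's deterministic MFE fold;
a built-in approximate folder (model-helix-only, −1.0 per Watson–Crick
pair, −0.5 per wobble, additive) keeps the library functional without the
bindings and is labelled approximate in its output.

A note on the bare core: the MFE structure of a 19-nt perfect core forms
the five upper-stem pairs but usually *not* N7·N25, because closing a
helix across the 1-nt N8 bulge costs more than the terminal stack gains.
Full concordance (6/6) requires lower-stem context, which is why the
fixture generator offers `build_hairpin` (core + complementary lower
stem) and why at least ~31 nt of input is recommended for reliable
energies.

## Scoring

`score = 8 − Σ penalties`, with defaults: upper-stem mismatch 1.5, stem
bulge 1.5, wobble 0.5, non-validated loop class 1.0 (families 1, 2 and 19
are exempt — the experimentally validated canonical and profilin-2-type
loops), N7·N25 mismatch 3.0, N7·N25 wobble 1.5, discordance 2.5 × (1 −
concordance), ΔG ≥ 0 penalty 2.0. Category thresholds: High ≥ 7, High-
medium ≥ 6, Medium ≥ 5, Medium-low ≥ 3.5, Low ≥ 1.5, else Very-low. All
values live in `data/scoring_defaults.yaml`, are overridable per run, and
the active config hash is logged.

The exact penalty magnitudes behind the published tool are not public;
these defaults were chosen once so that three anchors hold
simultaneously: (i) perfect fixtures of the validated families score
exactly 8; (ii) a single N7·N25 mismatch demotes a perfect prediction by
at least two categories (8 → 4.58, High → Medium-low, once the lost
closing pair also costs concordance), strictly more than an upper-stem
mismatch (8 → 6.08, High → High-medium); (iii) the score scale admits
negative values for heavily defective candidates. ΔG enters the score
only through the ΔG ≥ 0 penalty; the energy itself is reported separately
(and displayed on a [−12, 0] kcal/mol bar, with the score on a [−4, 8]
bar).

## Transcript annotation

The IRE midpoint is N16, or N17 when a 3′ bulge is present (the bulge
shifts the 3′ half of the core by one, so the physical middle moves).
With CDS coordinates (1-based; `cds_start` = first nucleotide of the
start codon, `cds_end` = last nucleotide of the stop codon), the location
classes are: |midpoint − cds_start| < 15 → 5′UTR-CDS; else |midpoint −
cds_end| < 15 → CDS-3′UTR; else 5′UTR / CDS / 3′UTR by interval. The
strict `<` bound is taken literally, giving exactly 29 boundary midpoints
per junction; 5′UTR-CDS wins if both windows overlap (CDS < 30 nt).
Distances are signed (`d5_ire_aug` = cds_start − midpoint, `d_cap_5ire` =
midpoint − 1 with the cap at position 1, `d_ter_3ire` = midpoint −
cds_end); a negative `d5_ire_aug` marks a boundary IRE whose midpoint
already sits inside the CDS. Per-gene redundancy collapse keeps one
record per (gene, core sequence, motif, location) and is idempotent.
Region enrichment normalizes counts by region length; the boundary
classes are windows, not annotated regions, and are assigned an effective
29 nt per transcript.

## Benchmarking

Truth is per record: a positive-control sequence is a true positive in a
tier when it holds at least one prediction of that pooled tier (overall =
any prediction). Sensitivity, specificity, precision and balanced
accuracy (the mean of sensitivity and specificity, appropriate for the
strongly imbalanced control sets typical of this problem) are reported as
percentages to two decimals; an undefined metric (zero denominator) is
reported as undefined, never as 0.

## Synthetic fixtures and what they show

The generator builds cores that satisfy the structural model exactly
except for requested defects, using fixed strong stems (upper arm GCGUC,
closing pair G·C, lower stem GGCAG) and seeded draws for degenerate loop
positions and defect placement. Defects are realized so the intended
truth is unambiguous: the 3′ bulged base never pairs with N7 (otherwise a
19-nt truncation would read it as a perfect N25), and N7·N25 defects are
realized on the 5′ side so an adjacent lower stem cannot "rescue" the
pair through a bulged re-reading. Planted backgrounds are uniform random
RNA rejection-sampled so no loop-pattern hit touches a background
position; spurious *partial* (stem-level) signals remain, which is what
the stem filter must reject.

These fixtures emulate the geometry and defect structure of real IREs,
not real UTR base composition, codon structure or conservation. Passing
round-trips therefore demonstrate the scanner/scorer contract — every
constructible core is found, positioned and graded as designed — not
field performance on transcriptomes, which depends on sequence context
the generator deliberately does not model.

## Problem sizes and numerics

The test suite and the acceptance script run on desk-scale inputs chosen
to exercise every code path: exhaustive 4⁶ loop-matcher equivalence
against a regex oracle, brute-force scanner equivalence on random
sequences up to 200 nt, a 140-record synthetic benchmark (40 planted
positives, 100 random 150-nt negatives), and full-registry round-trips.
Folding is deterministic MFE (no sampling, no partition function, no
pseudoknots); energies are reported as the engine returns them, with a
fully unpaired prediction clamped to exactly 0.0. All randomness flows
from explicit seeds through `numpy.random.default_rng`.

## Known limitations

- Only the given strand is scanned; reverse-complement scanning requires
  feeding the reverse complement as its own record.
- No multi-nucleotide stem bulges and no lower-stem pairing model beyond
  N7·N25.
- The published tool's exact penalty values, category cut-points and fold
  window are not public; the defaults here are this package's own
  declared calibration (see Scoring) and are config-overridable.
- Live transcript/gene-ID resolution against public databases is out of
  scope; CDS coordinates come from a side table, GenBank or GFF3.
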