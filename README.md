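# irescan

Detection, quality scoring and transcript-context annotation of
**iron-responsive elements (IREs)** in RNA and DNA sequences.

IREs are cis-regulatory stem-loops in the untranslated regions of iron
metabolism mRNAs (ferritins, transferrin receptor, ferroportin, DMT1,
HIF-2α, ALAS2, aconitase and others). Under iron starvation the iron
regulatory proteins IRP1/IRP2 bind them: binding at a 5′UTR IRE represses
translation, binding at a 3′UTR IRE stabilizes the message. `irescan` is a
library (plus a thin CLI) for researchers who want to screen candidate
transcripts for IREs, rank predictions by structural quality, and map them
to their position in the transcript.

## The model

A canonical IRE, in the standard position numbering N7–N25, is

```
        N14 N15 N16 N17        6-nt apical loop (5′-CAGWGH-3′ canonically,
      N13             N18       with a cross-loop N14·N18 interaction;
      N12             N19       motif 22 extends the loop by N19i/N19ii = CA)
       |  upper stem   |
      N9 · · · · · · ·N24      five base pairs N9·N24 … N13·N20
      N8 (bulge)      [b]      unpaired bulge (C; U in motifs 20–22, G in 18);
      N7 ------------ N25      optional single 3′ bulged nucleotide;
       |  lower stem   |       N7·N25 is the first lower-stem pair
```

The scanner matches a registry of 22 degenerate apical-loop motifs (23
pattern rows; family 9 splits into 9a/9b) at every offset, then assembles
the surrounding hairpin, tolerating a configurable number of stem
mismatches, G·U wobbles and single-nucleotide bulges. The minimal core is
19 nt (20 with a 3′ bulge). Each candidate is folded with ±15 nt of
context (ViennaRNA MFE by default) and scored as

```
score = 8 − Σ penalties
```

with penalties for stem mismatches (1.5), stem bulges (1.5), wobbles
(0.5), non-validated loop classes (1.0), a mismatch at the N7·N25 closing
pair (3.0 — the position mutated in two IRE-linked diseases), structure
discordance (2.5 × fraction of the six model pairs absent from the MFE
structure) and an unfolded window (2.0). The score maps onto six quality
categories (High … Very-low), pooled pairwise into high/medium/low
confidence tiers for benchmarking. With CDS coordinates, each prediction's
midpoint (N16, or N17 for 3′-bulge cores) is classified into one of five
locations (5′UTR, 5′UTR-CDS, CDS, CDS-3′UTR, 3′UTR; boundary classes use a
strict <|15| nt window) and annotated with distances to the cap, start
codon and stop codon.

## Worked example

```python
from irescan import build_hairpin, plant, run_scan

hairpin, truth = build_hairpin("1", seed=7)          # perfect canonical IRE
seq, planted = plant(hairpin, 200, 80, seed=7, truth=truth)
print(run_scan([("demo_tx", seq)], mode="batch").to_string(index=False))
```

prints

```
 seq_id motif  start  end  score category pooled_tier    delta_g  concordance location d5_ire_aug d_cap_5ire d_ter_3ire
demo_tx     1     86  104    8.0     High        high -28.700001          1.0     <NA>       <NA>       <NA>       <NA>
```

— one predicted site: a motif-1 (canonical CAGUG loop) IRE whose 19-nt
core spans positions 86–104, scoring the maximal 8.0 (High) because the
stem is perfect and all six model base pairs appear in the MFE structure
(concordance 1.0, ΔG −28.7 kcal/mol for the folded window). The location
columns are NA because no CDS table was supplied. More walkthroughs live
in `examples/` (penalty auditing, transcript location, benchmarking).

The same pipeline is available from the shell:

```bash
irescan scan --input transcripts.fasta --cds cds.tsv --out predictions.tsv
irescan bench --predictions predictions.tsv --labels labels.tsv
```

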