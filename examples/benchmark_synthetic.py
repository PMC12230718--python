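"""Benchmark the predictor on a labelled synthetic control set.

Plants IRE hairpins in half the records (positives) and leaves the rest
as random RNA (negatives), then computes sensitivity, specificity,
precision and balanced accuracy overall and for the high-confidence
tier.
"""

import numpy as np

from irescan import build_hairpin, default_registry, evaluate, plant, run_scan

rng = np.random.default_rng(11)
registry = default_registry()
records, labels = [], {}
for i in range(15):
    motif = registry[int(rng.integers(len(registry)))]
    hp, truth = build_hairpin(motif.motif_id, seed=int(rng.integers(2**31)))
    seq, _ = plant(hp, 150, int(rng.integers(0, 150 - len(hp))), seed=int(rng.integers(2**31)), truth=truth)
    records.append((f"pos{i}", seq))
    labels[f"pos{i}"] = "pos"
for i in range(30):
    seq = "".join("ACGU"[b] for b in rng.integers(0, 4, size=150))
    records.append((f"neg{i}", seq))
    labels[f"neg{i}"] = "neg"

table = run_scan(records, mode="batch")
preds = {rid: [] for rid in labels}
for row in table.itertuples(index=False):
    preds[row.seq_id].append(row.pooled_tier)

for tier in ("overall", "high"):
    r = evaluate(preds, labels, tier=tier)
    print(f"{tier:8s} tp={r.tp:2d} fp={r.fp:2d} tn={r.tn:2d} fn={r.fn:2d}  "
          f"sens={r.sensitivity} spec={r.specificity} prec={r.precision} "
          f"bacc={r.balanced_accuracy}")
print()
print(
    "Restricting to the pooled high tier trades sensitivity for precision: "
    "random RNA occasionally assembles a low-quality IRE-like hairpin, but "
    "rarely a high-scoring one."
)
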