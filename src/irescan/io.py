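"""Input parsing and end-to-end scan orchestration.

FASTA records are read with Biopython; CDS coordinates come from a
delimited side table, GenBank records or GFF3 annotation and all populate
the same :class:`~irescan.annotation.TranscriptContext` type.  The
``run_scan`` driver ties the pipeline together: normalize -> scan ->
fold -> score -> per-site winner -> (optional) locate, returning a
pandas DataFrame in batch mode and the same table plus per-prediction
detail records in interactive mode.  The two modes differ in
presentation only - the retained (seq_id, position, motif, score) tuples
are identical.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .annotation import TranscriptContext, locate
from .folding import fold_window
from .registry import MotifDefinition, default_registry
from .scanner import (
    MAX_INPUT_LEN,
    ScanParams,
    dedupe_site_interpretations,
    normalize_sequence,
    scan_sequence,
)
from .scoring import CATEGORIES, PenaltyConfig, pick_site_winner, score_candidate, summarize_quality

__all__ = [
    "read_fasta",
    "read_cds_table",
    "read_genbank_contexts",
    "read_gff3_contexts",
    "run_scan",
]

log = logging.getLogger("irescan")

COLUMNS = [
    "seq_id", "motif", "start", "end", "score", "category", "pooled_tier",
    "delta_g", "concordance", "location", "d5_ire_aug", "d_cap_5ire", "d_ter_3ire",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(record id, sequence) pairs from a FASTA file, in file order."""
    try:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    except ValueError as exc:
        raise ValueError(f"unreadable FASTA {path}: {exc}") from exc


def read_cds_table(path: str | Path) -> dict[str, TranscriptContext]:
    """CDS side table: tab/comma-delimited transcript_id, cds_start, cds_end, length."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"transcript_id", "cds_start", "cds_end", "length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CDS table {path} lacks columns {sorted(missing)}")
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.transcript_id)] = TranscriptContext(
            transcript_id=str(row.transcript_id),
            cds_start=int(row.cds_start),
            cds_end=int(row.cds_end),
            length=int(row.length),
        )
    return out


def read_genbank_contexts(path: str | Path) -> dict[str, TranscriptContext]:
    """CDS coordinates from GenBank records (first CDS feature per record)."""
    out = {}
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type == "CDS":
                out[rec.id] = TranscriptContext(
                    transcript_id=rec.id,
                    cds_start=int(feat.location.start) + 1,
                    cds_end=int(feat.location.end),
                    length=len(rec.seq),
                )
                break
    return out


def read_gff3_contexts(path: str | Path, lengths: dict[str, int]) -> dict[str, TranscriptContext]:
    """CDS extents from GFF3 rows in transcript coordinates.

    ``seqid`` column must be the transcript id; the CDS extent is the
    union of that transcript's CDS features.  ``lengths`` supplies
    transcript lengths (e.g. from the matching FASTA).
    """
    spans: dict[str, list[int]] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 8 or f[2] != "CDS":
            continue
        spans.setdefault(f[0], []).extend((int(f[3]), int(f[4])))
    out = {}
    for tid, coords in spans.items():
        if tid not in lengths:
            log.warning("GFF3 transcript %s has no length; skipped", tid)
            continue
        out[tid] = TranscriptContext(
            transcript_id=tid, cds_start=min(coords), cds_end=max(coords), length=lengths[tid]
        )
    return out


def _min_category_ok(category: str, min_category: str | None) -> bool:
    if min_category is None:
        return True
    return CATEGORIES.index(category) <= CATEGORIES.index(min_category)


def run_scan(
    records: Iterable[tuple[str, str]],
    mode: str = "batch",
    params: ScanParams | None = None,
    cfg: PenaltyConfig | None = None,
    cds: dict[str, TranscriptContext] | None = None,
    registry: list[MotifDefinition] | None = None,
    fold_engine: str = "vienna",
    flank: int = 15,
    min_category: str | None = None,
) -> pd.DataFrame | tuple[pd.DataFrame, list[dict]]:
    """Scan records end to end; one table row per retained prediction.

    ``mode`` is ``"batch"`` (table only; unlimited record lengths) or
    ``"interactive"`` (enforces the 50 000-nt per-record cap and
    additionally returns per-prediction detail records: itemized penalty
    ledger, dot-bracket and bar summaries).  Rows are sorted by seq_id
    then position.  Location columns are NA when no CDS entry exists for
    a record (a warning is logged, never a crash).
    """
    if mode not in ("batch", "interactive"):
        raise ValueError("mode must be 'batch' or 'interactive'")
    if params is None:
        params = ScanParams()
    if cfg is None:
        cfg = PenaltyConfig()
    if registry is None:
        registry = default_registry()
    log.info("scan config hash %s, fold engine %s", cfg.config_hash, fold_engine)
    cap = MAX_INPUT_LEN if mode == "interactive" else None
    rows: list[dict] = []
    details: list[dict] = []
    for seq_id, raw in records:
        seq = normalize_sequence(raw, max_len=cap)
        cands = scan_sequence(seq, registry=registry, params=params, seq_id=seq_id)
        for group in dedupe_site_interpretations(cands):
            scored_group = [
                score_candidate(c, fold_window(seq, c, flank=flank, engine=fold_engine), cfg)
                for c in group
            ]
            best = pick_site_winner(scored_group)
            if not _min_category_ok(best.category, min_category):
                continue
            row = {
                "seq_id": seq_id,
                "motif": best.core.motif.motif_id,
                "start": best.core.start + 1,  # 1-based inclusive, user-facing
                "end": best.core.end + 1,
                "score": best.score,
                "category": best.category,
                "pooled_tier": best.pooled_tier,
                "delta_g": best.fold.delta_g,
                "concordance": best.fold.concordance,
                "location": pd.NA,
                "d5_ire_aug": pd.NA,
                "d_cap_5ire": pd.NA,
                "d_ter_3ire": pd.NA,
            }
            if cds is not None:
                if seq_id in cds:
                    loc = locate(best, cds[seq_id])
                    row["location"] = loc.location
                    for k in ("d5_ire_aug", "d_cap_5ire", "d_ter_3ire"):
                        v = getattr(loc, k)
                        row[k] = pd.NA if v is None else v
                else:
                    log.warning("no CDS entry for %s; location fields NA", seq_id)
            rows.append(row)
            if mode == "interactive":
                details.append(
                    {
                        "seq_id": seq_id,
                        "start": row["start"],
                        "motif": row["motif"],
                        "dot_bracket": best.fold.dot_bracket,
                        "window": (best.fold.window_start + 1, best.fold.window_end),
                        **summarize_quality(best, cfg),
                    }
                )
    df = pd.DataFrame(rows, columns=COLUMNS)
    df = df.sort_values(["seq_id", "start"], kind="stable").reset_index(drop=True)
    if mode == "interactive":
        details.sort(key=lambda d: (d["seq_id"], d["start"]))
        return df, details
    return df
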