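"""Penalty-based quality scoring of IRE candidates.

A candidate starts from the maximal score of 8 and loses points for every
structural defect, for belonging to a loop class without direct
experimental validation, and for disagreement between the predicted
secondary structure and the IRE model.  The numeric score maps onto six
quality categories (High .. Very-low) via configurable thresholds; for
benchmarking the six categories pool pairwise into three tiers
(high / medium / low).

The N7.N25 closing pair carries a deliberately larger penalty than an
upper-stem mismatch: mutations at that single position underlie two
distinct IRE-linked diseases, so a defect there should demote a
prediction by more than one category.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .folding import FoldResult
from .scanner import IRECore

__all__ = [
    "CATEGORIES",
    "POOLED_TIER",
    "PenaltyConfig",
    "ScoredIRE",
    "score_candidate",
    "categorize",
    "pick_site_winner",
    "summarize_quality",
]

CATEGORIES = ("High", "High-medium", "Medium", "Medium-low", "Low", "Very-low")

POOLED_TIER = {
    "High": "high",
    "High-medium": "high",
    "Medium": "medium",
    "Medium-low": "medium",
    "Low": "low",
    "Very-low": "low",
}


@dataclass(frozen=True)
class PenaltyConfig:
    """Scoring penalties, category thresholds and display-bar clamps.

    All penalties are in score units on the (-inf, 8] scale and must be
    >= 0; thresholds must be strictly decreasing High -> Low.  The
    invariant ``n7_n25_mismatch > upper_stem_mismatch`` encodes the
    elevated weight of the closing pair.
    """

    base_score: float = 8.0
    upper_stem_mismatch: float = 1.5
    upper_stem_bulge: float = 1.5
    upper_stem_wobble: float = 0.5
    noncanonical_motif: float = 1.0
    n7_n25_mismatch: float = 3.0
    n7_n25_wobble: float = 1.5
    discordance_weight: float = 2.5
    nonnegative_dg: float = 2.0
    canonical_families: tuple[str, ...] = ("1", "2", "19")
    thresholds: tuple[tuple[str, float], ...] = (
        ("High", 7.0),
        ("High-medium", 6.0),
        ("Medium", 5.0),
        ("Medium-low", 3.5),
        ("Low", 1.5),
    )
    bar_min: float = -4.0
    energy_min: float = -12.0

    def __post_init__(self) -> None:
        penalties = (
            self.upper_stem_mismatch, self.upper_stem_bulge, self.upper_stem_wobble,
            self.noncanonical_motif, self.n7_n25_mismatch, self.n7_n25_wobble,
            self.discordance_weight, self.nonnegative_dg,
        )
        if any(p < 0 for p in penalties):
            raise ValueError("penalties must be non-negative")
        cuts = [t for _, t in self.thresholds]
        if sorted(cuts, reverse=True) != cuts or len(set(cuts)) != len(cuts):
            raise ValueError("category thresholds must be strictly decreasing")
        if not self.n7_n25_mismatch > self.upper_stem_mismatch:
            raise ValueError("n7_n25_mismatch penalty must exceed upper_stem_mismatch")

    @classmethod
    def from_file(cls, path: str | Path | None = None) -> "PenaltyConfig":
        """Load a config; ``None`` loads the bundled defaults."""
        if path is None:
            text = resources.files("irescan.data").joinpath("scoring_defaults.yaml").read_text()
        else:
            text = Path(path).read_text()
        raw = yaml.safe_load(text)
        thresholds = tuple(raw.pop("thresholds").items()) if "thresholds" in raw else None
        kwargs = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        if "canonical_families" in kwargs:
            kwargs["canonical_families"] = tuple(str(f) for f in kwargs["canonical_families"])
        if thresholds is not None:
            kwargs["thresholds"] = thresholds
        return cls(**kwargs)

    @property
    def config_hash(self) -> str:
        """Short stable hash of the active configuration, for run logs."""
        blob = json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__}, sort_keys=True, default=list
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class ScoredIRE:
    """A candidate with its fold evidence, score, category and audit trail."""

    core: IRECore
    fold: FoldResult
    score: float
    category: str
    pooled_tier: str
    penalties: tuple[tuple[str, float], ...] = ()  # itemized, for auditability


def categorize(score: float, cfg: PenaltyConfig | None = None) -> str:
    """Map a score to the first category whose threshold it meets."""
    if cfg is None:
        cfg = PenaltyConfig()
    for name, cut in cfg.thresholds:
        if score >= cut:
            return name
    return "Very-low"


def score_candidate(core: IRECore, fold: FoldResult, cfg: PenaltyConfig | None = None) -> ScoredIRE:
    """Score one candidate: 8 minus the sum of applicable penalties.

    Deterministic; every contributing term is itemized in the returned
    record so a prediction's score can be audited line by line.
    """
    if cfg is None:
        cfg = PenaltyConfig()
    items: list[tuple[str, float]] = []
    for kind, per in (
        ("upper_stem_mismatch", cfg.upper_stem_mismatch),
        ("upper_stem_wobble", cfg.upper_stem_wobble),
        ("upper_stem_bulge", cfg.upper_stem_bulge),
    ):
        n = core.defect_count(kind)
        if n:
            items.append((kind, n * per))
    if core.defect_count("n7_n25_mismatch"):
        items.append(("n7_n25_mismatch", cfg.n7_n25_mismatch))
    elif core.defect_count("n7_n25_wobble"):
        items.append(("n7_n25_wobble", cfg.n7_n25_wobble))
    if core.motif.family not in cfg.canonical_families:
        items.append(("noncanonical_motif", cfg.noncanonical_motif))
    if fold.concordance < 1.0:
        items.append(("structure_discordance", cfg.discordance_weight * (1.0 - fold.concordance)))
    if fold.delta_g >= 0.0:
        items.append(("nonnegative_delta_g", cfg.nonnegative_dg))
    score = cfg.base_score - sum(v for _, v in items)
    category = categorize(score, cfg)
    return ScoredIRE(
        core=core,
        fold=fold,
        score=score,
        category=category,
        pooled_tier=POOLED_TIER[category],
        penalties=tuple(items),
    )


def pick_site_winner(group: list[ScoredIRE]) -> ScoredIRE:
    """Best interpretation of one apical-loop site.

    Highest score wins; ties break to the lower registry row, then to
    fewer structural defects, then to the parsimonious assembly (no 3'
    bulge, smaller span) so the winner is deterministic.
    """
    if not group:
        raise ValueError("empty site group")
    return min(
        group,
        key=lambda s: (
            -s.score,
            s.core.motif.row,
            len(s.core.defects),
            s.core.has_3prime_bulge,
            s.core.span,
        ),
    )


def summarize_quality(scored: ScoredIRE, cfg: PenaltyConfig | None = None) -> dict:
    """Display record: score, category, energy and normalized bar positions.

    The score bar clamps to ``[bar_min, 8]`` (1.0 = best) and the energy
    bar to ``[energy_min, 0]`` kcal/mol, where 0 - no structure - is the
    worst end (bar position 0.0 = worst energy).
    """
    if cfg is None:
        cfg = PenaltyConfig()
    s = min(max(scored.score, cfg.bar_min), cfg.base_score)
    score_bar = (s - cfg.bar_min) / (cfg.base_score - cfg.bar_min)
    g = min(max(scored.fold.delta_g, cfg.energy_min), 0.0)
    energy_bar = (g - 0.0) / (cfg.energy_min - 0.0)  # 0 kcal/mol -> 0.0 (worst end)
    return {
        "score": scored.score,
        "category": scored.category,
        "pooled_tier": scored.pooled_tier,
        "delta_g": scored.fold.delta_g,
        "score_bar": score_bar,
        "energy_bar": energy_bar,
        "penalties": dict(scored.penalties),
    }
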