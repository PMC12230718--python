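"""Penalty scoring, category mapping, site winners and quality display."""

from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irescan import (
    CATEGORIES,
    PenaltyConfig,
    build_core,
    build_hairpin,
    categorize,
    fallback_fold,
    fold_window,
    pick_site_winner,
    scan_sequence,
    score_candidate,
    summarize_quality,
)
from irescan.folding import FoldResult
from irescan.scoring import POOLED_TIER


def _ideal_fold(cand):
    """A fold record with perfect concordance and favourable energy."""
    return FoldResult(
        window_start=cand.start, window_end=cand.end + 1,
        dot_bracket="." * cand.span, delta_g=-8.0, concordance=1.0, loop_open=True,
    )


def _best(seq, truth, cfg=None):
    cands = [c for c in scan_sequence(seq) if c.loop_start == truth.loop_offset]
    scored = [score_candidate(c, fold_window(seq, c), cfg) for c in cands]
    return pick_site_winner(scored)


class TestScoreCandidate:
    def test_perfect_candidate_scores_eight(self, cfg):
        hp, truth = build_hairpin("1", seed=0)
        best = _best(hp, truth, cfg)
        assert best.score == 8.0
        assert best.category == "High"
        assert best.penalties == ()

    def test_one_stem_mismatch_costs_default_penalty(self, cfg):
        core, truth = build_core("1", defects={"upper_stem_mismatch": 1}, seed=5)
        cand = next(c for c in scan_sequence(core)
                    if c.loop_start == truth.loop_offset and c.defect_count("upper_stem_mismatch"))
        scored = score_candidate(cand, _ideal_fold(cand), cfg)
        assert scored.score == 8.0 - cfg.upper_stem_mismatch == 6.5
        assert scored.category == "High-medium"

    def test_n7_n25_mismatch_is_heavier(self, cfg):
        core, truth = build_core("1", defects={"n7_n25": "mismatch"}, seed=5)
        cand = next(c for c in scan_sequence(core)
                    if c.loop_start == truth.loop_offset and c.defect_count("n7_n25_mismatch"))
        scored = score_candidate(cand, _ideal_fold(cand), cfg)
        assert scored.score == 8.0 - cfg.n7_n25_mismatch == 5.0
        assert scored.category == "Medium"

    def test_noncanonical_motif_penalty(self, cfg):
        core, truth = build_core("15", seed=0)
        cand = next(c for c in scan_sequence(core)
                    if c.loop_start == truth.loop_offset and c.motif.motif_id == "15")
        scored = score_candidate(cand, _ideal_fold(cand), cfg)
        assert ("noncanonical_motif", cfg.noncanonical_motif) in scored.penalties
        assert scored.score == 7.0

    def test_zero_delta_g_is_penalized(self, cfg):
        core, _ = build_core("1", seed=0)
        cand = scan_sequence(core)[0]
        flat = FoldResult(cand.start, cand.end + 1, "." * cand.span, 0.0, 1.0, True)
        scored = score_candidate(cand, flat, cfg)
        assert ("nonnegative_delta_g", cfg.nonnegative_dg) in scored.penalties

    def test_discordance_is_proportional(self, cfg):
        core, _ = build_core("1", seed=0)
        cand = scan_sequence(core)[0]
        half = FoldResult(cand.start, cand.end + 1, "." * cand.span, -3.0, 0.5, True)
        scored = score_candidate(cand, half, cfg)
        assert dict(scored.penalties)["structure_discordance"] == pytest.approx(
            cfg.discordance_weight * 0.5
        )


class TestRefinementProperty:
    """The closing-pair penalty demotes harder than an upper-stem mismatch."""

    def test_category_drops(self, cfg):
        hp, t = build_hairpin("1", seed=0)
        hm, tm = build_hairpin("1", defects={"n7_n25": "mismatch"}, seed=0)
        hs, ts = build_hairpin("1", defects={"upper_stem_mismatch": 1}, seed=0)
        perfect, closing, stem = _best(hp, t, cfg), _best(hm, tm, cfg), _best(hs, ts, cfg)
        assert perfect.category == "High"
        drop_closing = CATEGORIES.index(closing.category) - CATEGORIES.index(perfect.category)
        drop_stem = CATEGORIES.index(stem.category) - CATEGORIES.index(perfect.category)
        assert drop_closing >= 2
        assert drop_closing > drop_stem
        assert cfg.n7_n25_mismatch > cfg.upper_stem_mismatch

    def test_calibration_motifs_all_reach_eight(self, cfg):
        for motif_id in ("1", "2", "19"):
            hp, truth = build_hairpin(motif_id, seed=0)
            assert _best(hp, truth, cfg).score == 8.0


class TestCategorize:
    @pytest.mark.parametrize(
        "score, expected",
        [(8.0, "High"), (7.0, "High"), (6.5, "High-medium"), (5.0, "Medium"),
         (4.0, "Medium-low"), (2.0, "Low"), (-2.0, "Very-low")],
    )
    def test_default_thresholds(self, score, expected, cfg):
        assert categorize(score, cfg) == expected

    @settings(max_examples=60, derandomize=True)
    @given(st.floats(min_value=-10, max_value=8, allow_nan=False),
           st.floats(min_value=-10, max_value=8, allow_nan=False))
    def test_monotone_step_function(self, a, b):
        """Higher scores never land in a worse category; tiers follow suit."""
        lo, hi = sorted((a, b))
        c_lo, c_hi = categorize(lo), categorize(hi)
        assert CATEGORIES.index(c_hi) <= CATEGORIES.index(c_lo)
        tiers = ["high", "medium", "low"]
        assert tiers.index(POOLED_TIER[c_hi]) <= tiers.index(POOLED_TIER[c_lo])

    def test_pooled_tiers_merge_pairwise(self):
        assert [POOLED_TIER[c] for c in CATEGORIES] == \
            ["high", "high", "medium", "medium", "low", "low"]


class TestMonotonicity:
    def test_every_defect_lowers_the_score(self, cfg):
        base, truth = build_hairpin("1", seed=3)
        reference = _best(base, truth, cfg).score
        for defect in ({"upper_stem_mismatch": 1}, {"upper_stem_wobble": 1},
                       {"upper_stem_bulge": 1}, {"n7_n25": "wobble"}, {"n7_n25": "mismatch"}):
            seq, t = build_hairpin("1", defects=defect, seed=3)
            assert _best(seq, t, cfg).score < reference, defect

    def test_removing_a_penalty_never_decreases_score(self, cfg):
        seq, truth = build_hairpin("15", defects={"upper_stem_mismatch": 1}, seed=2)
        cand = next(c for c in scan_sequence(seq)
                    if c.loop_start == truth.loop_offset and c.defect_count("upper_stem_mismatch"))
        fold = fallback_fold(seq, cand)
        full = score_candidate(cand, fold, cfg).score
        for zeroed in ("upper_stem_mismatch", "noncanonical_motif", "discordance_weight"):
            relaxed = PenaltyConfig(**{**{f: getattr(cfg, f) for f in (
                "upper_stem_mismatch", "upper_stem_bulge", "upper_stem_wobble",
                "noncanonical_motif", "n7_n25_mismatch", "n7_n25_wobble",
                "discordance_weight", "nonnegative_dg")}, zeroed: 0.0})
            assert score_candidate(cand, fold, relaxed).score >= full


class TestSiteWinner:
    @staticmethod
    def _scored(motif_id, score, cfg):
        core, _ = build_core(motif_id, seed=0)
        cand = next(c for c in scan_sequence(core) if c.motif.motif_id == motif_id)
        return replace(score_candidate(cand, _ideal_fold(cand), cfg), score=score)

    def test_highest_score_wins(self, cfg):
        a = self._scored("1", 8.0, cfg)
        b = self._scored("20", 7.0, cfg)
        assert pick_site_winner([b, a]) is a

    def test_tie_breaks_to_lower_registry_row(self, cfg):
        a = self._scored("1", 7.0, cfg)
        b = self._scored("20", 7.0, cfg)
        assert pick_site_winner([b, a]) is a
        assert a.core.motif.row < b.core.motif.row

    def test_extended_loop_site_resolves_to_motif_22(self, cfg):
        hp, truth = build_hairpin("22", seed=0)
        cands = [c for c in scan_sequence(hp) if c.loop_start == truth.loop_offset]
        scored = [score_candidate(c, fold_window(hp, c), cfg) for c in cands]
        best = pick_site_winner(scored)
        assert best.core.motif.motif_id == "22"
        assert best.score == max(s.score for s in scored)

    def test_singleton_and_empty(self, cfg):
        hp, truth = build_hairpin("1", seed=0)
        best = _best(hp, truth, cfg)
        assert pick_site_winner([best]) is best
        with pytest.raises(ValueError):
            pick_site_winner([])


class TestSummarize:
    def test_bar_positions(self, cfg):
        hp, truth = build_hairpin("1", seed=0)
        best = _best(hp, truth, cfg)
        summary = summarize_quality(best, cfg)
        assert summary["score_bar"] == 1.0  # score 8 sits at the right end
        assert 0.0 < summary["energy_bar"] <= 1.0

    def test_zero_energy_is_worst_end(self, cfg):
        core, _ = build_core("1", seed=0)
        cand = scan_sequence(core)[0]
        flat = FoldResult(cand.start, cand.end + 1, "." * cand.span, 0.0, 1.0, True)
        summary = summarize_quality(score_candidate(cand, flat, cfg), cfg)
        assert summary["energy_bar"] == 0.0

    def test_score_at_bar_min_is_left_end(self, cfg):
        core, _ = build_core("1", seed=0)
        cand = scan_sequence(core)[0]
        fold = FoldResult(cand.start, cand.end + 1, "." * cand.span, -1.0, 1.0, True)
        scored = replace(score_candidate(cand, fold, cfg), score=cfg.bar_min)
        assert summarize_quality(scored, cfg)["score_bar"] == 0.0


def test_config_file_roundtrip(tmp_path, cfg):
    default = PenaltyConfig.from_file(None)
    assert default == cfg
    override = tmp_path / "cfg.yaml"
    override.write_text("upper_stem_mismatch: 2.0\nn7_n25_mismatch: 4.0\n")
    loaded = PenaltyConfig.from_file(override)
    assert loaded.upper_stem_mismatch == 2.0 and loaded.n7_n25_mismatch == 4.0
    assert loaded.config_hash != cfg.config_hash


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        PenaltyConfig(upper_stem_mismatch=-1.0)
    with pytest.raises(ValueError):
        PenaltyConfig(n7_n25_mismatch=1.0)  # must exceed the stem-mismatch penalty
    with pytest.raises(ValueError):
        PenaltyConfig(thresholds=(("High", 5.0), ("Medium", 6.0)))
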