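"""Average-odds motif scoring and rank-sum enrichment."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sekit.core import Peak, Pwm, ValidationError
from sekit.motifs import (
    FlankSet,
    avg_odds_score,
    enrich_motifs,
    extract_flanks,
    predict_coregulators,
    ranksum_test,
    reverse_complement,
)
from sekit.simulate import make_motif_library, planted_flank_sets, random_flanks

DNA = st.text(alphabet="ACGT", min_size=8, max_size=40)


def sharp_motif(consensus="ACGTACGT", p=0.97):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    m = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        m[i, idx[b]] = p
    return Pwm("sharp", m)


# ------------------------------------------------------------ flank extraction

class TestExtractFlanks:
    def test_window_arithmetic(self):
        genome = {"chr1": "A" * 400 + "C" * 100 + "G" * 100 + "A" * 400}
        pk = Peak.from_coords("chr1", 400, 600, summit=500)
        flanks = extract_flanks([pk], genome, width=200)
        assert flanks.sequences == ("C" * 100 + "G" * 100,)

    def test_clipped_windows_discarded(self):
        genome = {"chr1": "A" * 1000}
        near_edge = Peak.from_coords("chr1", 0, 100, summit=50)
        ok = Peak.from_coords("chr1", 400, 600, summit=500)
        flanks = extract_flanks([near_edge, ok], genome, width=200)
        assert len(flanks) == 1

    def test_missing_chromosome_named(self):
        with pytest.raises(ValidationError, match="chrX"):
            extract_flanks(
                [Peak.from_coords("chrX", 400, 600)], {"chr1": "A" * 1000}, 200
            )


# ----------------------------------------------------------- avg-odds scoring

class TestAvgOdds:
    def test_uniform_motif_scores_one(self):
        uniform = Pwm("u", np.full((4, 4), 0.25))
        assert avg_odds_score("ACGTACGTAC", uniform) == pytest.approx(1.0)

    def test_single_base_hand_arithmetic(self):
        # A-motif on "A": forward odds 0.97/0.25, reverse ("T") odds 0.01/0.25
        motif = Pwm("a", np.array([[0.97, 0.01, 0.01, 0.01]]))
        expected = (0.97 / 0.25 + 0.01 / 0.25) / 2
        assert avg_odds_score("A", motif) == pytest.approx(expected)
        assert expected == pytest.approx(1.96)

    def test_windows_with_n_are_neutral(self):
        motif = sharp_motif("AAAA")
        assert avg_odds_score("NNNN", motif) == pytest.approx(1.0)
        # one clean window + three N windows on each strand
        seq = "AAAANNN"
        clean = avg_odds_score("AAAA", motif)
        n_windows = 2 * (len(seq) - 4 + 1)
        expected = (2 * clean + (n_windows - 2)) / n_windows
        assert avg_odds_score(seq, motif) == pytest.approx(expected)

    def test_too_short_sequence_errors(self):
        with pytest.raises(ValidationError):
            avg_odds_score("AC", sharp_motif("ACGTACGT"))

    @given(DNA)
    @settings(max_examples=50, deadline=None)
    def test_reverse_complement_invariance(self, seq):
        motif = sharp_motif("ACGT")
        assert avg_odds_score(seq, motif) == pytest.approx(
            avg_odds_score(reverse_complement(seq), motif), rel=1e-12
        )

    def test_matches_window_product_oracle(self, rng):
        """Score equals a naive per-window probability-product enumeration."""
        motif = Pwm("r", rng.dirichlet(np.ones(4) * 2, size=5))
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=20))
            windows = []
            for strand_seq in (seq, reverse_complement(seq)):
                for off in range(len(seq) - 5 + 1):
                    odds = 1.0
                    for j, base in enumerate(strand_seq[off : off + 5]):
                        odds *= motif.matrix[j, idx[base]] / 0.25
                    windows.append(odds)
            assert avg_odds_score(seq, motif) == pytest.approx(np.mean(windows))


# --------------------------------------------------------------- rank-sum test

def enumeration_p(fg, bg):
    """Exact one-sided p by full enumeration over rank assignments."""
    pooled = np.concatenate([fg, bg])
    n = len(fg)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n):
        u = ranks[list(comb)].sum() - n * (n + 1) / 2
        total += 1
        hits += u >= u_obs - 1e-9
    return hits / total


class TestRanksum:
    def test_exact_worked_example(self):
        u, p = ranksum_test([3, 4, 5], [0, 1, 2])
        assert u == 9.0
        assert p == pytest.approx(1 / 20)

    def test_identical_samples_near_half(self):
        vals = list(np.linspace(0, 1, 30))
        _, p = ranksum_test(vals, vals)
        assert 0.4 <= p <= 0.6

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            ranksum_test([], [1.0])

    def test_exact_branch_equals_enumeration(self, rng):
        for _ in range(25):
            nf, nb = int(rng.integers(3, 8)), int(rng.integers(3, 8))
            fg, bg = rng.normal(size=nf), rng.normal(size=nb)
            _, p = ranksum_test(fg, bg)
            assert p == pytest.approx(enumeration_p(fg, bg), abs=1e-12)

    def test_exact_and_approximate_branches_agree(self, rng):
        """500 tie-free instances, 5-12 per group: branch gap below 0.01."""
        for _ in range(500):
            nf, nb = int(rng.integers(5, 13)), int(rng.integers(5, 13))
            fg, bg = rng.normal(size=nf), rng.normal(size=nb)
            _, p_exact = ranksum_test(fg, bg)  # combined n <= 24 -> exact
            p_approx = stats.mannwhitneyu(
                fg, bg, alternative="greater", method="asymptotic",
                use_continuity=True,
            ).pvalue
            assert abs(p_exact - p_approx) < 0.01


# ------------------------------------------------------------------ enrichment

class TestEnrichment:
    def test_planted_motif_ranks_first(self):
        rng = np.random.default_rng(1)
        planted, decoys = make_motif_library(rng, n_decoys=10, length=8)
        fg, bg = planted_flank_sets(
            rng, planted, n_fg=200, n_bg=200, width=200, plant_rate=0.30
        )
        results = enrich_motifs(
            FlankSet("cond", tuple(fg)), FlankSet("ctrl", tuple(bg)),
            [planted] + decoys,
        )
        assert results[0].motif_id == planted.motif_id
        assert results[0].enriched and results[0].p_value <= 0.05

    def test_null_rejects_at_nominal_rate(self):
        """fg == bg generator: <=10% of 100 seeded replicates reject at 0.05."""
        motif = sharp_motif("ACGTACGT")
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fg = FlankSet("a", tuple(random_flanks(rng, 50, width=100)))
            bg = FlankSet("b", tuple(random_flanks(rng, 50, width=100)))
            (res,) = enrich_motifs(fg, bg, [motif])
            rejections += res.p_value <= 0.05
        assert rejections <= 10

    def test_empty_motif_list(self):
        rng = np.random.default_rng(0)
        fg = FlankSet("a", tuple(random_flanks(rng, 5, 50)))
        assert enrich_motifs(fg, fg, []) == []

    def test_bonferroni_scales_p(self):
        rng = np.random.default_rng(3)
        planted, decoys = make_motif_library(rng, n_decoys=4, length=8)
        fg, bg = planted_flank_sets(rng, planted, 60, 60, 100, 0.5)
        raw = enrich_motifs(
            FlankSet("a", tuple(fg)), FlankSet("b", tuple(bg)), [planted] + decoys
        )
        adj = enrich_motifs(
            FlankSet("a", tuple(fg)), FlankSet("b", tuple(bg)), [planted] + decoys,
            correction="bonferroni",
        )
        raw_p = {r.motif_id: r.p_value for r in raw}
        for r in adj:
            assert r.p_value == pytest.approx(min(1.0, raw_p[r.motif_id] * 5))


class TestCoregulators:
    def _flanksets(self, seed, rate_cond, rate_ctrl, motif):
        rng = np.random.default_rng(seed)
        cond, _ = planted_flank_sets(rng, motif, 120, 1, 100, rate_cond)
        ctrl, _ = planted_flank_sets(rng, motif, 120, 1, 100, rate_ctrl)
        return FlankSet("cond", tuple(cond)), FlankSet("ctrl", tuple(ctrl))

    def test_condition_only_motif_retained(self):
        motif = sharp_motif("ACGTTGCA")
        cond, ctrl = self._flanksets(1, 0.4, 0.0, motif)
        (call,) = predict_coregulators(cond, ctrl, [motif])
        assert call.retained

    def test_conserved_motif_filtered(self):
        motif = sharp_motif("ACGTTGCA")
        cond, ctrl = self._flanksets(2, 0.4, 0.4, motif)
        (call,) = predict_coregulators(cond, ctrl, [motif])
        assert not call.retained

    def test_control_only_motif_filtered(self):
        motif = sharp_motif("ACGTTGCA")
        cond, ctrl = self._flanksets(3, 0.0, 0.4, motif)
        (call,) = predict_coregulators(cond, ctrl, [motif])
        assert not call.retained
        assert call.p_control_direction <= 0.05


def test_flankset_rejects_mixed_widths():
    with pytest.raises(ValidationError):
        FlankSet("x", ("ACGT", "ACGTA"))
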