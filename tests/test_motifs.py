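"""PWM loading, exact score thresholds, scanning, density and enrichment."""

import itertools
import math

import numpy as np
import pytest

import hoxspec as hs
from hoxspec.core import revcomp
from hoxspec.motifs import (
    LATTICE_BITS, Pwm, density_compare, load_pwm, load_pwms, match_density,
)

from .conftest import random_peakset


@pytest.fixture(scope="module")
def abdb_pwm():
    return hs.bundled_pwm("hox_abdb_like_synthetic")


@pytest.fixture(scope="module")
def ubx_pwm():
    return hs.bundled_pwm("hox_ubx_like_synthetic")


class TestLoadPwm:
    def test_uniform_counts_zero_log_odds(self):
        pwm = Pwm("u", np.full((4, 4), 25.0), pseudocount=0.0)
        assert np.allclose(pwm.log_odds, 0.0)

    def test_zero_pseudocount_zero_count_guarded(self):
        counts = np.tile([10.0, 0, 0, 0], (4, 1))
        with pytest.raises(ValueError, match="pseudocount"):
            Pwm("bad", counts, pseudocount=0.0)

    def test_probabilities_sum_to_one(self, rng):
        counts = rng.integers(0, 50, size=(8, 4)).astype(float) + 0.5
        pwm = Pwm("r", counts)
        assert np.allclose(pwm.probabilities.sum(axis=1), 1.0, atol=1e-9)

    def test_jaspar_parse(self, abdb_pwm):
        assert abdb_pwm.width == 8
        assert abdb_pwm.consensus() == "TTTATGAC"

    def test_bare_matrix_parse(self, tmp_path):
        f = tmp_path / "m.txt"
        f.write_text("1 2 3 4\n4 3 2 1\n1 1 1 1\n2 2 2 2\n")
        pwm = load_pwm(f)
        assert pwm.width == 4

    def test_ragged_matrix_error(self, tmp_path):
        f = tmp_path / "m.jaspar"
        f.write_text(">bad\nA [1 2 3]\nC [1 2]\nG [1 2 3]\nT [1 2 3]\n")
        with pytest.raises(ValueError):
            load_pwm(f)


class TestScoreThreshold:
    def test_p_equal_one_gives_minimum(self, abdb_pwm):
        scores, dist = abdb_pwm.score_distribution()
        attainable = scores[dist > 0]
        assert abdb_pwm.score_threshold(1.0) == pytest.approx(attainable[0])

    def test_distribution_sums_to_one(self, abdb_pwm, ubx_pwm):
        for pwm in (abdb_pwm, ubx_pwm):
            _, dist = pwm.score_distribution()
            assert dist.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("p", [0.25, 0.01, 0.001])
    def test_exhaustive_oracle_width8(self, abdb_pwm, p):
        """Tail probability at the cutoff matches enumeration of all 4^8 words."""
        cutoff = abdb_pwm.score_threshold(p)
        lat = abdb_pwm._lattice
        bg = abdb_pwm.background
        tail = 0.0
        for word in itertools.product(range(4), repeat=8):
            s = sum(lat[i, b] for i, b in enumerate(word)) * LATTICE_BITS
            if s >= cutoff - 1e-9:
                tail += math.prod(bg[b] for b in word)
        assert tail <= p + 1e-12
        # and the cutoff is the smallest such score: one lattice step lower
        # must exceed p
        lower = cutoff - LATTICE_BITS
        tail_lower = 0.0
        for word in itertools.product(range(4), repeat=8):
            s = sum(lat[i, b] for i, b in enumerate(word)) * LATTICE_BITS
            if s >= lower - 1e-9:
                tail_lower += math.prod(bg[b] for b in word)
        scores, dist = abdb_pwm.score_distribution()
        attainable = set(np.round(scores[dist > 0] / LATTICE_BITS).astype(int))
        if round(lower / LATTICE_BITS) >= min(attainable):
            assert tail_lower > p or tail_lower == pytest.approx(tail)

    def test_exhaustive_oracle_random_width6(self, rng):
        counts = rng.integers(1, 40, size=(6, 4)).astype(float)
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        pwm = Pwm("rand6", counts, background=bg)
        p = 0.001
        cutoff = pwm.score_threshold(p)
        tail = 0.0
        for word in itertools.product(range(4), repeat=6):
            s = sum(pwm._lattice[i, b] for i, b in enumerate(word)) * LATTICE_BITS
            if s >= cutoff - 1e-9:
                tail += math.prod(bg[b] for b in word)
        assert tail <= p + 1e-12


class TestScan:
    def test_consensus_matches_at_zero(self, abdb_pwm):
        seq = abdb_pwm.consensus() + "GGGG"
        cutoff = abdb_pwm.score_threshold(0.001)
        ms = hs.scan([seq], abdb_pwm, cutoff)
        assert any(pos == 0 and strand == "+" for pos, strand, _ in ms.matches[0])

    def test_all_n_no_matches(self, abdb_pwm):
        ms = hs.scan(["N" * 50], abdb_pwm, 0.0)
        assert ms.total() == 0 and ms.n_windows == 0

    def test_brute_force_oracle(self, rng, ubx_pwm):
        """Every window of a random sequence scored independently."""
        seq = "".join(rng.choice(list("ACGTN"), 2000, p=[.24, .24, .24, .24, .04]))
        cutoff = ubx_pwm.score_threshold(0.01)
        ms = hs.scan([seq], ubx_pwm, cutoff)
        w = ubx_pwm.width
        lom = ubx_pwm.log_odds
        expected = []
        for i in range(len(seq) - w + 1):
            window = seq[i:i + w]
            if "N" in window:
                continue
            for strand, target in (("+", window), ("-", revcomp(window))):
                s = sum(lom[j, "ACGT".index(b)] for j, b in enumerate(target))
                if s >= cutoff - 1e-9:
                    expected.append((i, strand))
        assert [(p, s) for p, s, _ in ms.matches[0]] == sorted(expected)

    def test_strand_symmetry(self, rng, abdb_pwm):
        """Scanning revcomp(seq) mirrors positions and swaps strands."""
        seq = "".join(rng.choice(list("ACGT"), 500))
        cutoff = abdb_pwm.score_threshold(0.01)
        fwd = hs.scan([seq], abdb_pwm, cutoff).matches[0]
        rev = hs.scan([revcomp(seq)], abdb_pwm, cutoff).matches[0]
        w = abdb_pwm.width
        mirrored = sorted(
            (len(seq) - w - pos, {"+": "-", "-": "+"}[strand], score)
            for pos, strand, score in rev
        )
        assert [(p, s) for p, s, _ in fwd] == [(p, s) for p, s, _ in mirrored]
        assert np.allclose([m[2] for m in fwd], [m[2] for m in mirrored])


class TestMatchDensity:
    def test_formula(self, abdb_pwm):
        ps = hs.PeakSet("p", [hs.Peak("chrA", 0, 1000)], whitelist=("chrA",))
        from hoxspec.motifs import MatchSet
        ms = MatchSet("m", 0.0, [[(i, "+", 1.0) for i in range(5)]], 100)
        dens = match_density(ps, ms)
        assert dens.densities[0] == pytest.approx(5.0)

    def test_no_matches_median_zero(self, rng, toy_genome, ubx_pwm):
        ps = random_peakset(rng, n=10, chrom_len=50_000)
        from hoxspec.motifs import MatchSet
        ms = MatchSet("m", 0.0, [[] for _ in range(10)], 0)
        assert match_density(ps, ms).median == 0.0

    def test_split_peak_preserves_aggregate(self, rng, toy_genome, ubx_pwm):
        """Halving a peak where no match spans the cut keeps the total count."""
        ps = hs.PeakSet("p", [hs.Peak("chrA", 1000, 3000)], whitelist=("chrA",))
        seqs = hs.extract_peak_sequences(ps, toy_genome)
        cutoff = ubx_pwm.score_threshold(0.01)
        whole = hs.scan(seqs, ubx_pwm, cutoff)
        halves = hs.PeakSet("h", [hs.Peak("chrA", 1000, 2000),
                                  hs.Peak("chrA", 2000, 3000)], whitelist=("chrA",))
        half_seqs = hs.extract_peak_sequences(halves, toy_genome)
        split = hs.scan(half_seqs, ubx_pwm, cutoff)
        spanning = [m for m in whole.matches[0] if m[0] < 1000 <= m[0] + ubx_pwm.width - 1]
        assert split.total() == whole.total() - len(spanning)

    def test_planted_rate_difference_detected(self, rng, abdb_pwm):
        """2x planted match rate: density ratio ~2, rank-sum p < 0.01 at n=200."""
        word = abdb_pwm.consensus()
        def build(n_per_peak):
            peaks, chrom = [], []
            for i in range(200):
                s = np.array(list("".join(rng.choice(list("GC"), 1000))))
                for pos in rng.choice(990, size=n_per_peak, replace=False):
                    s[pos:pos + 8] = list(word)
                chrom.append("".join(s))
                peaks.append(hs.Peak("chrA", i * 1000, (i + 1) * 1000))
            return hs.PeakSet("p", peaks, whitelist=("chrA",)), chrom
        ps_hi, seqs_hi = build(4)
        ps_lo, seqs_lo = build(2)
        cutoff = abdb_pwm.score_threshold(0.001)
        d_hi = match_density(ps_hi, hs.scan(seqs_hi, abdb_pwm, cutoff))
        d_lo = match_density(ps_lo, hs.scan(seqs_lo, abdb_pwm, cutoff))
        assert d_hi.median / d_lo.median == pytest.approx(2.0, rel=0.25)
        assert density_compare(d_hi, d_lo) < 0.01


class TestMotifSetEnrichment:
    def test_absent_motif_scores_zero(self, rng, abdb_pwm):
        seqs = ["".join(rng.choice(list("GC"), 500)) for _ in range(5)]
        bg = hs.BackgroundSet(tuple("".join(rng.choice(list("GC"), 500))
                                    for _ in range(5)))
        (res,) = hs.motif_set_enrichment(seqs, bg, [abdb_pwm])
        assert res.p_value == 1.0 and res.score == 0.0

    def test_shuffled_halves_score_low(self, rng, ubx_pwm, abdb_pwm):
        """Foreground drawn from the background population scores near 0."""
        pool = ["".join(rng.choice(list("ACGT"), 1000)) for _ in range(60)]
        fg, bg = pool[:30], hs.BackgroundSet(tuple(pool[30:]))
        results = hs.motif_set_enrichment(fg, bg, [ubx_pwm, abdb_pwm])
        assert np.median([r.score for r in results]) <= 1.0

    def test_planted_motif_ranks_first(self, rng, abdb_pwm, ubx_pwm):
        """A motif planted at 5x background rate out-ranks 19 random motifs."""
        word = abdb_pwm.consensus()
        bg_seqs = []
        for _ in range(40):
            s = np.array(list("".join(rng.choice(list("ACGT"), 2000))))
            for pos in rng.choice(1990, size=1, replace=False):
                s[pos:pos + 8] = list(word)
            bg_seqs.append("".join(s))
        fg = []
        for _ in range(40):
            s = np.array(list("".join(rng.choice(list("ACGT"), 2000))))
            for pos in rng.choice(1990, size=5, replace=False):
                s[pos:pos + 8] = list(word)
            fg.append("".join(s))
        decoys = [Pwm(f"decoy{i:02d}", rng.integers(1, 60, size=(8, 4)).astype(float))
                  for i in range(18)]
        pwms = [abdb_pwm, ubx_pwm] + decoys
        results = hs.motif_set_enrichment(fg, hs.BackgroundSet(tuple(bg_seqs)), pwms)
        assert results[0].motif == abdb_pwm.name and results[0].rank == 1

    def test_monotone_in_planted_matches(self, rng, abdb_pwm):
        """Adding planted matches never lowers the motif's score."""
        word = abdb_pwm.consensus()
        bg = hs.BackgroundSet(tuple("".join(rng.choice(list("ACGT"), 2000))
                                    for _ in range(30)))
        base = ["".join(rng.choice(list("ACGT"), 1000)) for _ in range(30)]
        prev_score = -1.0
        for n_plant in (0, 2, 6):
            fg = []
            for s in base:
                arr = np.array(list(s))
                for pos in rng.choice(990, size=n_plant, replace=False):
                    arr[pos:pos + 8] = list(word)
                fg.append("".join(arr))
            (res,) = hs.motif_set_enrichment(fg, bg, [abdb_pwm])
            assert res.score >= prev_score
            prev_score = res.score
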