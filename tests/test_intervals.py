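"""Peak-set algebra against exhaustive oracles and known identities."""

import math
import shutil
import subprocess

import numpy as np
import pytest

import hoxspec as hs
from hoxspec.intervals import STATES_WITH_UNKNOWN, StateAnnotation, pair_qualifies, venn_counts

from .conftest import random_peakset


def brute_force_mask(a, b, f):
    """All-pairs reciprocal-overlap oracle: True per A peak with a partner."""
    out = []
    for p in a:
        hit = False
        for q in b:
            if p.chrom != q.chrom:
                continue
            ov = min(p.end, q.end) - max(p.start, q.start)
            if ov >= max(1, math.ceil(f * p.length)) and \
               ov >= max(1, math.ceil(f * q.length)):
                hit = True
                break
        out.append(hit)
    return out


class TestReciprocalOverlap:
    def test_reciprocal_rule_rejects_one_sided(self):
        a = hs.PeakSet("a", [hs.Peak("chrA", 100, 200)], whitelist=("chrA",))
        b = hs.PeakSet("b", [hs.Peak("chrA", 195, 400)], whitelist=("chrA",))
        # ov=5 covers 5% of the 100 bp peak but not of the 205 bp peak
        res = hs.reciprocal_overlap(a, b, 0.05)
        assert res.n_a_overlapping == 0 and res.pct_a == 0.0

    def test_identity(self, rng):
        a = random_peakset(rng, n=50)
        res = hs.reciprocal_overlap(a, a, 0.5)
        assert res.pct_a == res.pct_b == 100.0

    def test_empty_set_reports_na(self):
        a = hs.PeakSet("a", [], whitelist=("chrA",))
        b = hs.PeakSet("b", [hs.Peak("chrA", 0, 10)], whitelist=("chrA",))
        res = hs.reciprocal_overlap(a, b)
        assert res.pct_a is None and res.n_a_overlapping == 0

    @pytest.mark.parametrize("f", [0.05, 0.3, 0.9])
    def test_oracle_equivalence(self, rng, f):
        a = random_peakset(rng, "a", n=200, chrom_len=1_000_000)
        b = random_peakset(rng, "b", n=200, chrom_len=1_000_000)
        res = hs.reciprocal_overlap(a, b, f)
        mask = brute_force_mask(a, b, f)
        assert res.n_a_overlapping == sum(mask)
        assert res.n_b_overlapping == sum(brute_force_mask(b, a, f))
        assert [p in set(res.common_a.peaks) for p in a] == mask

    def test_monotone_in_fraction(self, rng):
        a = random_peakset(rng, "a", n=150)
        b = random_peakset(rng, "b", n=150)
        pcts = [hs.reciprocal_overlap(a, b, f).pct_a
                for f in (0.01, 0.05, 0.2, 0.5, 1.0)]
        assert all(x >= y for x, y in zip(pcts, pcts[1:]))

    def test_qualification_symmetric(self, rng):
        a = random_peakset(rng, "a", n=40)
        b = random_peakset(rng, "b", n=40)
        for p in a.peaks[:20]:
            for q in b.peaks[:20]:
                assert pair_qualifies(p, q, 0.05) == pair_qualifies(q, p, 0.05)

    def test_counts_partition_the_set(self, rng):
        a = random_peakset(rng, "a", n=120)
        b = random_peakset(rng, "b", n=120)
        res = hs.reciprocal_overlap(a, b)
        assert res.n_a_overlapping + len(res.specific_a) == res.n_a
        assert len(res.common_a) + len(res.specific_a) == len(a)


@pytest.mark.skipif(shutil.which("bedtools") is None,
                    reason="bedtools not on PATH")
def test_bedtools_cross_check(rng, tmp_path):
    """Independent oracle: bedtools intersect -f 0.05 -r -u / -v."""
    a = random_peakset(rng, "a", n=150, chrom_len=500_000)
    b = random_peakset(rng, "b", n=150, chrom_len=500_000)
    fa, fb = tmp_path / "a.bed", tmp_path / "b.bed"
    hs.write_bed(a, fa)
    hs.write_bed(b, fb)
    res = hs.reciprocal_overlap(a, b, 0.05)
    for flag, expected in (("-u", res.n_a_overlapping), ("-v", len(res.specific_a))):
        out = subprocess.run(
            ["bedtools", "intersect", "-a", str(fa), "-b", str(fb),
             "-f", "0.05", "-r", flag],
            capture_output=True, text=True, check=True,
        )
        n_lines = len([l for l in out.stdout.splitlines() if l.strip()])
        assert n_lines == expected


class TestPartition:
    def test_ref_equals_a(self, rng):
        a = random_peakset(rng, n=30)
        common, specific = hs.partition_by_reference(a, a)
        assert len(specific) == 0 and len(common) == len(a)

    def test_ref_disjoint(self):
        a = hs.PeakSet("a", [hs.Peak("chrA", 0, 100)], whitelist=("chrA",))
        ref = hs.PeakSet("r", [hs.Peak("chrA", 500, 600)], whitelist=("chrA",))
        common, specific = hs.partition_by_reference(a, ref)
        assert len(common) == 0 and len(specific) == 1

    def test_order_preserved(self, rng):
        a = random_peakset(rng, "a", n=100)
        ref = random_peakset(rng, "r", n=100)
        common, specific = hs.partition_by_reference(a, ref)
        merged = sorted(common.peaks + specific.peaks,
                        key=lambda p: (p.chrom, p.start, p.end))
        assert tuple(merged) == a.peaks


class TestVenn:
    def test_disjoint_all_exclusive(self):
        a = hs.PeakSet("a", [hs.Peak("chrA", 0, 100)], whitelist=("chrA",))
        b = hs.PeakSet("b", [hs.Peak("chrA", 500, 600)], whitelist=("chrA",))
        counts = venn_counts([a, b])
        assert counts["a"] == {(): 1} and counts["b"] == {(): 1}

    def test_identical_all_shared(self, rng):
        a = random_peakset(rng, "a", n=20)
        b = a.subset(a.peaks, "b")
        c = a.subset(a.peaks, "c")
        counts = venn_counts([a, b, c])
        assert counts["a"] == {("b", "c"): 20}

    def test_matches_pairwise_oracle(self, rng):
        sets = [random_peakset(rng, n, n=60) for n in "abc"]
        counts = venn_counts(sets, 0.05)
        for focal in sets:
            others = [s for s in sets if s is not focal]
            masks = [brute_force_mask(focal, o, 0.05) for o in others]
            for i in range(len(focal)):
                key = tuple(o.name for o, m in zip(others, masks) if m[i])
                assert counts[focal.name].get(key, 0) > 0

    def test_more_than_three_unsupported(self, rng):
        sets = [random_peakset(rng, str(i), n=5) for i in range(4)]
        with pytest.raises(ValueError):
            venn_counts(sets)


class TestStringentVsRelaxed:
    def test_subset_gives_100(self, rng):
        b = random_peakset(rng, "relaxed", n=80)
        a = b.subset(b.peaks[:30], "stringent")
        assert hs.stringent_vs_relaxed(a, b) == 100.0


def random_annotation(rng, chroms=("chrA", "chrB"), chrom_len=100_000):
    labels = list(hs.intervals.STATE_COLOURS) if hasattr(hs, "intervals") else None
    from hoxspec.intervals import STATE_COLOURS
    intervals = {}
    for chrom in chroms:
        pos, ivs = 0, []
        while pos < chrom_len - 100:
            seg = int(rng.integers(100, 5000))
            if rng.random() < 0.85:  # leave UNKNOWN gaps
                ivs.append((pos, min(pos + seg, chrom_len),
                            STATE_COLOURS[rng.integers(0, 5)]))
            pos += seg
        intervals[chrom] = ivs
    return StateAnnotation(intervals)


class TestStatePrevalence:
    def test_fully_inside_one_state(self):
        ann = StateAnnotation({"chrA": [(0, 1000, "RED")]})
        ps = hs.PeakSet("p", [hs.Peak("chrA", 0, 100)], whitelist=("chrA",))
        prev = hs.state_prevalence(ps, ann)
        assert prev["RED"] == 1.0 and prev["UNKNOWN"] == 0.0

    def test_half_unannotated(self):
        ann = StateAnnotation({"chrA": [(0, 50, "RED")]})
        ps = hs.PeakSet("p", [hs.Peak("chrA", 0, 100)], whitelist=("chrA",))
        prev = hs.state_prevalence(ps, ann)
        assert prev["RED"] == 0.5 and prev["UNKNOWN"] == 0.5

    def test_zero_length_error(self):
        ann = StateAnnotation({"chrA": [(0, 50, "RED")]})
        with pytest.raises(ValueError):
            hs.state_prevalence(hs.PeakSet("p", [], whitelist=("chrA",)), ann)

    def test_per_base_oracle(self, rng):
        """Fractions equal base-by-base counting on a small genome."""
        chrom_len = 50_000
        ann = random_annotation(rng, chroms=("chrA",), chrom_len=chrom_len)
        ps = random_peakset(rng, n=60, chroms=("chrA",), chrom_len=chrom_len)
        labels = np.full(chrom_len, len(STATES_WITH_UNKNOWN) - 1)  # UNKNOWN
        from hoxspec.intervals import STATE_COLOURS
        for s, e, lab in ann.intervals["chrA"]:
            labels[s:e] = STATE_COLOURS.index(lab)
        counts = np.zeros(len(STATES_WITH_UNKNOWN))
        for p in ps:
            for code in labels[p.start:p.end]:
                counts[code] += 1
        expected = counts / counts.sum()
        prev = hs.state_prevalence(ps, ann)
        for i, state in enumerate(STATES_WITH_UNKNOWN):
            assert prev[state] == pytest.approx(expected[i], abs=1e-12)

    def test_fractions_sum_to_one(self, rng):
        ann = random_annotation(rng)
        ps = random_peakset(rng, n=40)
        prev = hs.state_prevalence(ps, ann)
        assert sum(prev.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_whole_genome_peak_equals_composition(self, rng):
        """A peak tiling the genome recovers the genome-wide composition."""
        chrom_len = 50_000
        ann = random_annotation(rng, chroms=("chrA",), chrom_len=chrom_len)
        whole = hs.PeakSet("whole", [hs.Peak("chrA", 0, chrom_len)],
                           whitelist=("chrA",))
        prev = hs.state_prevalence(whole, ann)
        comp = ann.genome_composition({"chrA": chrom_len})
        for state in STATES_WITH_UNKNOWN:
            assert prev[state] == pytest.approx(comp[state], abs=1e-12)
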