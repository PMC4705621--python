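"""Peak-set algebra: reciprocal overlap, common/specific partitions, Venn
counts and chromatin-colour-state prevalence.

The qualification rule follows the ``bedtools intersect -f 0.05 -r``
convention: a pair (a, b) qualifies iff the overlap covers at least fraction
``f`` of BOTH intervals. Overlap length of [s1,e1) and [s2,e2) is
``max(0, min(e1,e2) - max(s1,s2))``; the fractional requirement is applied
as ``ov >= max(1, ceil(f * len))`` so the stated minimum fraction is a true
minimum and a 1 bp overlap floor is always enforced. An A peak counts once
no matter how many B partners qualify (the ``-u`` contract); "specific"
peaks have no qualifying partner (the ``-v`` contract).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .core import Peak, PeakSet

STATE_COLOURS = ("RED", "YELLOW", "BLUE", "BLACK", "GREEN")
STATES_WITH_UNKNOWN = STATE_COLOURS + ("UNKNOWN",)


def _required(f: float, length: int) -> int:
    return max(1, math.ceil(f * length))


def pair_qualifies(a: Peak, b: Peak, f: float) -> bool:
    """Reciprocal-overlap test for a single peak pair (symmetric in a, b)."""
    if a.chrom != b.chrom:
        return False
    ov = min(a.end, b.end) - max(a.start, b.start)
    return ov >= _required(f, a.length) and ov >= _required(f, b.length)


def _build_trees(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, ps in peaks.by_chrom().items():
        trees[chrom] = IntervalTree.from_tuples((p.start, p.end, p) for p in ps)
    return trees


def _overlapping_mask(a: PeakSet, b: PeakSet, f: float) -> list[bool]:
    trees = _build_trees(b)
    mask = []
    for p in a:
        tree = trees.get(p.chrom)
        hit = False
        if tree is not None:
            for iv in tree.overlap(p.start, p.end):
                if pair_qualifies(p, iv.data, f):
                    hit = True
                    break
        mask.append(hit)
    return mask


@dataclass
class OverlapResult:
    """Two-way reciprocal-overlap summary between peak sets A and B.

    ``pct_a`` is the percentage of A peaks with at least one qualifying B
    partner (None when A is empty, reported as NA rather than 0), and
    symmetrically for ``pct_b``. ``common_a``/``specific_a`` partition A.
    """

    set_a_name: str
    set_b_name: str
    n_a: int
    n_b: int
    n_a_overlapping: int
    n_b_overlapping: int
    common_a: PeakSet
    specific_a: PeakSet

    @property
    def pct_a(self) -> float | None:
        return 100.0 * self.n_a_overlapping / self.n_a if self.n_a else None

    @property
    def pct_b(self) -> float | None:
        return 100.0 * self.n_b_overlapping / self.n_b if self.n_b else None


def reciprocal_overlap(a: PeakSet, b: PeakSet, f: float = 0.05) -> OverlapResult:
    """Count peaks of A and of B with a qualifying reciprocal-overlap partner.

    Returns an :class:`OverlapResult`; ``common_a`` and ``specific_a`` carry
    the A-side partition (B's partition is obtained by swapping arguments).
    """
    if not (0 < f <= 1):
        raise ValueError("overlap fraction must be in (0, 1]")
    mask_a = _overlapping_mask(a, b, f)
    mask_b = _overlapping_mask(b, a, f)
    common = [p for p, hit in zip(a, mask_a) if hit]
    specific = [p for p, hit in zip(a, mask_a) if not hit]
    return OverlapResult(
        set_a_name=a.name,
        set_b_name=b.name,
        n_a=len(a),
        n_b=len(b),
        n_a_overlapping=sum(mask_a),
        n_b_overlapping=sum(mask_b),
        common_a=a.subset(common, f"{a.name}_and_{b.name}"),
        specific_a=a.subset(specific, f"{a.name}_not_{b.name}"),
    )


def partition_by_reference(
    a: PeakSet, ref: PeakSet, f: float = 0.05
) -> tuple[PeakSet, PeakSet]:
    """Split A into (common, specific) against a reference set.

    Common peaks have >=1 qualifying partner in ``ref``; the two parts are
    disjoint, preserve coordinate order, and together equal A.
    """
    res = reciprocal_overlap(a, ref, f)
    return res.common_a, res.specific_a


def stringent_vs_relaxed(
    a_stringent: PeakSet, b_relaxed: PeakSet, f: float = 0.05
) -> float | None:
    """Percentage of a stringent peak set recovered in a relaxed set.

    Used to check that high-stringency peaks of one factor fall within the
    low-stringency peaks of another (e.g. a stringent set almost completely
    contained in a relaxed set supports shared binding).
    """
    return reciprocal_overlap(a_stringent, b_relaxed, f).pct_a


def venn_counts(
    sets: Sequence[PeakSet], f: float = 0.05
) -> dict[str, dict[tuple[str, ...], int]]:
    """Per-focal-set membership counts for 2 or 3 peak sets.

    Reciprocal overlap is not transitive, so no single consistent region
    partition exists; instead each set's peaks are classified by which of
    the other sets they hit, matching per-set Venn percentages. Returns
    ``{focal_set_name: {tuple_of_hit_set_names: count}}`` where the key
    ``()`` counts exclusive peaks.
    """
    if not (2 <= len(sets) <= 3):
        raise ValueError("venn_counts supports 2 or 3 peak sets")
    out: dict[str, dict[tuple[str, ...], int]] = {}
    for focal in sets:
        others = [s for s in sets if s is not focal]
        masks = [_overlapping_mask(focal, other, f) for other in others]
        counts: dict[tuple[str, ...], int] = {}
        for i in range(len(focal)):
            key = tuple(o.name for o, m in zip(others, masks) if m[i])
            counts[key] = counts.get(key, 0) + 1
        out[focal.name] = counts
    return out


class StateAnnotation:
    """Partition of the genome into the five chromatin colour states.

    The five-state classification of the Kc167 genome labels segments RED /
    YELLOW (active), BLUE (Polycomb), BLACK (repressive) and GREEN (HP1);
    bases covered by no segment are UNKNOWN. Intervals within a chromosome
    must not overlap.
    """

    def __init__(
        self, intervals: Mapping[str, Sequence[tuple[int, int, str]]]
    ) -> None:
        clean: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, ivs in intervals.items():
            ivs = sorted(ivs)
            prev_end = -1
            for start, end, label in ivs:
                if label not in STATE_COLOURS:
                    raise ValueError(
                        f"unknown state label {label!r}; expected one of {STATE_COLOURS}"
                    )
                if start >= end:
                    raise ValueError(f"{chrom}: empty state interval [{start},{end})")
                if start < prev_end:
                    raise ValueError(f"{chrom}: overlapping state intervals at {start}")
                prev_end = end
            clean[chrom] = [(int(s), int(e), lab) for s, e, lab in ivs]
        self.intervals = clean

    @classmethod
    def read_bed(cls, path) -> "StateAnnotation":
        """Read a 4-column BED whose name column is the colour label."""
        from .io import ParseError, _open_text
        intervals: dict[str, list[tuple[int, int, str]]] = {}
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                if len(fields) == 1:
                    fields = line.split()
                try:
                    chrom, start, end, label = (
                        fields[0], int(fields[1]), int(fields[2]), fields[3].upper(),
                    )
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
                intervals.setdefault(chrom, []).append((start, end, label))
        return cls(intervals)

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                for start, end, label in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")

    def genome_composition(self, chrom_lengths: Mapping[str, int]) -> "StatePrevalence":
        """Genome-wide state composition, the background for prevalence plots."""
        bases = dict.fromkeys(STATES_WITH_UNKNOWN, 0)
        for chrom, length in chrom_lengths.items():
            covered = 0
            for start, end, label in self.intervals.get(chrom, ()):
                seg = min(end, length) - start
                if seg > 0:
                    bases[label] += seg
                    covered += seg
            bases["UNKNOWN"] += length - covered
        total = sum(bases.values())
        if total == 0:
            raise ValueError("empty genome")
        return StatePrevalence({s: bases[s] / total for s in STATES_WITH_UNKNOWN})


@dataclass
class StatePrevalence:
    """Fraction of total peak length in each colour state (plus UNKNOWN).

    The six fractions sum to 1.
    """

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state fractions sum to {total}, expected 1")

    def __getitem__(self, state: str) -> float:
        return self.fractions[state]


def state_prevalence(peaks: PeakSet, ann: StateAnnotation) -> StatePrevalence:
    """Fraction of total peak length overlapping each chromatin colour state.

    For each state the numerator is the number of peak bases falling inside
    intervals of that state; bases inside no annotated interval count as
    UNKNOWN. Denominator is the total peak length.
    """
    total = peaks.total_length()
    if total == 0:
        raise ValueError("state_prevalence: zero total peak length")
    bases = dict.fromkeys(STATES_WITH_UNKNOWN, 0)
    trees: dict[str, IntervalTree] = {
        chrom: IntervalTree.from_tuples((s, e, lab) for s, e, lab in ivs)
        for chrom, ivs in ann.intervals.items()
    }
    for p in peaks:
        tree = trees.get(p.chrom)
        annotated = 0
        if tree is not None:
            for iv in tree.overlap(p.start, p.end):
                ov = min(p.end, iv.end) - max(p.start, iv.begin)
                bases[iv.data] += ov
                annotated += ov
        bases["UNKNOWN"] += p.length - annotated
    return StatePrevalence({s: bases[s] / total for s in STATES_WITH_UNKNOWN})
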