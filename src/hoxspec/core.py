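"""Core domain types shared by every analysis stage.

Coordinates are uniformly 0-based half-open (BED native): a peak spanning
``[start, end)`` covers exactly ``end - start`` bases in every base-resolved
computation downstream. narrowPeak summits are stored as absolute genome
coordinates, not offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

log = logging.getLogger("hoxspec")

#: Euchromatic chromosome arms of the D. melanogaster BDGP5 assembly used for
#: all peak-level analyses (heterochromatic scaffolds are excluded).
DEFAULT_WHITELIST: tuple[str, ...] = (
    "chr2L", "chr2R", "chr3L", "chr3R", "chr4", "chrX", "chrM",
)


@dataclass(frozen=True)
class Peak:
    """One genomic interval, the unit of all peak-set algebra.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start, end : int
        0-based half-open interval; ``start < end``.
    summit : int, optional
        Absolute coordinate of the point of highest signal,
        ``start <= summit < end``.
    score : float, optional
        Caller-assigned score (e.g. signal value or -log10 q-value).
    name : str, optional
        Peak label.
    """

    chrom: str
    start: int
    end: int
    summit: int | None = None
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"peak {self.name or ''} {self.chrom}:{self.start}-{self.end}: "
                "start must be < end"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(
                f"peak {self.name or ''} {self.chrom}:{self.start}-{self.end}: "
                f"summit {self.summit} outside interval"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def center(self) -> int:
        """Summit if annotated, else the interval midpoint.

        The midpoint fallback is logged once per call site via the module
        logger so substituted centres are visible in pipeline logs.
        """
        if self.summit is not None:
            return self.summit
        return (self.start + self.end) // 2


class PeakSet:
    """Named, chromosome-partitioned collection of peaks.

    Peaks on non-whitelisted chromosomes are rejected at construction;
    within each chromosome peaks are kept sorted by start coordinate.

    Parameters
    ----------
    name : str
        Label, e.g. ``"Ubx_exp1"``.
    peaks : iterable of Peak
    stringency : str, optional
        Peak-calling q-value tag, conventionally ``"1e-2"`` or ``"1e-10"``.
    whitelist : sequence of str
        Allowed chromosome names.
    """

    def __init__(
        self,
        name: str,
        peaks: Iterable[Peak],
        stringency: str | None = None,
        whitelist: Sequence[str] = DEFAULT_WHITELIST,
    ) -> None:
        self.name = name
        self.stringency = stringency
        self.whitelist = tuple(whitelist)
        wl = set(self.whitelist)
        kept: list[Peak] = []
        for p in peaks:
            if p.chrom not in wl:
                raise ValueError(
                    f"peak on non-whitelisted chromosome {p.chrom!r} "
                    f"(whitelist: {sorted(wl)})"
                )
            kept.append(p)
        kept.sort(key=lambda p: (p.chrom, p.start, p.end))
        self.peaks: tuple[Peak, ...] = tuple(kept)
        self._warn_overlaps()

    def _warn_overlaps(self) -> None:
        prev: Peak | None = None
        for p in self.peaks:
            if prev is not None and p.chrom == prev.chrom and p.start < prev.end:
                log.warning(
                    "peak set %s: overlapping peaks %s:%d-%d and %s:%d-%d kept unmerged",
                    self.name, prev.chrom, prev.start, prev.end,
                    p.chrom, p.start, p.end,
                )
                return
            prev = p

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.peaks == other.peaks and self.name == other.name

    def __repr__(self) -> str:
        return f"PeakSet({self.name!r}, n={len(self)}, stringency={self.stringency!r})"

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out

    def total_length(self) -> int:
        return sum(p.length for p in self.peaks)

    def subset(self, peaks: Iterable[Peak], name: str | None = None) -> "PeakSet":
        return PeakSet(
            name or self.name, peaks,
            stringency=self.stringency, whitelist=self.whitelist,
        )


class SignalTrack:
    """Per-chromosome step function with bedGraph semantics.

    ``steps[chrom]`` is a sorted list of ``(start, end, value)`` triples with
    no overlaps; bases covered by no step have implicit value 0. Values are
    assumed already normalized (per million reads for MACS2 ``-B -SPMR``
    pileups) and are never rescaled here; the ``normalization`` tag records
    the convention.
    """

    def __init__(
        self,
        name: str,
        steps: Mapping[str, Sequence[tuple[int, int, float]]],
        normalization: str = "SPMR",
    ) -> None:
        self.name = name
        self.normalization = normalization
        clean: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, ss in steps.items():
            ss = sorted(ss)
            prev_end = -1
            for start, end, value in ss:
                if start >= end:
                    raise ValueError(f"{chrom}: empty step [{start},{end})")
                if value < 0:
                    raise ValueError(f"{chrom}:{start}-{end}: negative value {value}")
                if start < prev_end:
                    raise ValueError(
                        f"{chrom}: overlapping steps at {start} (previous end {prev_end})"
                    )
                prev_end = end
            clean[chrom] = [(int(s), int(e), float(v)) for s, e, v in ss]
        self.steps = clean

    def chroms(self) -> list[str]:
        return sorted(self.steps)

    def value_at(self, chrom: str, pos: int) -> float:
        """Signal at a single base (0 where uncovered)."""
        import bisect
        ss = self.steps.get(chrom)
        if not ss:
            return 0.0
        i = bisect.bisect_right(ss, (pos, float("inf"), float("inf"))) - 1
        if i >= 0 and ss[i][0] <= pos < ss[i][1]:
            return ss[i][2]
        return 0.0

    def values_over(self, chrom: str, start: int, end: int):
        """Dense per-base value vector over ``[start, end)`` (zero-filled)."""
        import bisect

        import numpy as np
        out = np.zeros(end - start)
        ss = self.steps.get(chrom, ())
        i = max(0, bisect.bisect_right(ss, (start, float("inf"), float("inf"))) - 1)
        for s, e, v in ss[i:]:
            if e <= start:
                continue
            if s >= end:
                break
            out[max(s, start) - start: min(e, end) - start] = v
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        return self.steps == other.steps


class GenomeSequence:
    """Uppercased per-chromosome nucleotide strings over {A,C,G,T,N}."""

    def __init__(self, sequences: Mapping[str, str]) -> None:
        self.sequences = {c: s.upper() for c, s in sequences.items()}
        for chrom, seq in self.sequences.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"{chrom}: non-nucleotide characters {sorted(bad)}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.sequences:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        if start < 0 or end > len(self.sequences[chrom]):
            raise IndexError(
                f"{chrom}:{start}-{end} outside chromosome (length "
                f"{len(self.sequences[chrom])})"
            )
        return self.sequences[chrom][start:end]


@dataclass
class AnalysisConfig:
    """Tunable parameters of the full analysis, with study defaults.

    reciprocal_overlap_fraction
        Minimum fraction of BOTH intervals an overlap must cover (0.05,
        the ``bedtools intersect -f 0.05 -r`` convention).
    window_size_bp
        Genome bin width for binding-score correlation (1000).
    profile_span_bp
        Width of the summit-centred window for shape/GC profiles (2000).
    smooth_window_bp / smooth_step_bp
        Rolling-mean smoothing of summit profiles (100 / 10).
    pwm_match_pvalue
        Per-window match threshold for PWM scanning (0.001).
    """

    reciprocal_overlap_fraction: float = 0.05
    window_size_bp: int = 1000
    profile_span_bp: int = 2000
    smooth_window_bp: int = 100
    smooth_step_bp: int = 10
    pwm_match_pvalue: float = 0.001
    chrom_whitelist: tuple[str, ...] = DEFAULT_WHITELIST
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.reciprocal_overlap_fraction <= 1):
            raise ValueError("reciprocal_overlap_fraction must be in (0, 1]")
        if self.smooth_window_bp > self.profile_span_bp:
            raise ValueError("smooth_window_bp must be <= profile_span_bp")
        if self.smooth_step_bp < 1:
            raise ValueError("smooth_step_bp must be >= 1")


REVCOMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    return seq.translate(REVCOMP)[::-1]
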