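"""Track-level statistics: genome binning, binding-score correlation,
per-peak median signal, and differential Hox-vs-accessibility ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import GenomeSequence, Peak, PeakSet, SignalTrack

log = logging.getLogger("hoxspec")


@dataclass
class BinnedProfile:
    """Mean pileup per non-overlapping genome window.

    ``values[chrom]`` has ``ceil(chrom_length / window_size_bp)`` entries;
    the terminal partial window is averaged over its actual length so all
    windows are comparable. Uncovered bases contribute 0.
    """

    window_size_bp: int
    values: dict[str, np.ndarray]
    source: str

    def concatenated(self, chroms=None) -> np.ndarray:
        chroms = sorted(self.values) if chroms is None else chroms
        return np.concatenate([self.values[c] for c in chroms])


def bin_track(track: SignalTrack, genome: GenomeSequence, w: int) -> BinnedProfile:
    """Binding score (mean per-base pileup) per non-overlapping ``w`` bp window.

    Every chromosome of the genome gets a window vector, including ones the
    track does not cover (all zeros). A track chromosome absent from the
    genome is an error.
    """
    if w < 1:
        raise ValueError("window size must be >= 1")
    for chrom in track.steps:
        if chrom not in genome:
            raise KeyError(f"track chromosome {chrom!r} absent from genome")
    values: dict[str, np.ndarray] = {}
    for chrom, length in genome.chrom_lengths().items():
        n_windows = math.ceil(length / w)
        sums = np.zeros(n_windows)
        for start, end, v in track.steps.get(chrom, ()):
            end = min(end, length)
            if start >= end:
                continue
            first, last = start // w, (end - 1) // w
            if first == last:
                sums[first] += v * (end - start)
            else:
                sums[first] += v * ((first + 1) * w - start)
                sums[last] += v * (end - last * w)
                if last - first > 1:
                    sums[first + 1:last] += v * w
        widths = np.full(n_windows, w, dtype=float)
        if length % w:
            widths[-1] = length % w
        values[chrom] = sums / widths
    return BinnedProfile(window_size_bp=w, values=values, source=track.name)


def profile_correlation(
    p1: BinnedProfile, p2: BinnedProfile
) -> tuple[float, int]:
    """Pearson correlation of two binned binding profiles.

    Profiles must share the window grid (same window size and chromosome
    vector lengths). Returns ``(r, n_windows)``; r is NaN with a warning
    when either profile has zero variance.
    """
    if p1.window_size_bp != p2.window_size_bp:
        raise ValueError("profiles have different window sizes")
    if sorted(p1.values) != sorted(p2.values) or any(
        len(p1.values[c]) != len(p2.values[c]) for c in p1.values
    ):
        raise ValueError("profiles are on different window grids")
    x, y = p1.concatenated(), p2.concatenated()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("profile_correlation: zero variance, correlation undefined")
        return float("nan"), len(x)
    r, _ = stats.pearsonr(x, y)
    return float(r), len(x)


@dataclass
class PeakSignalSummary:
    """Per-peak median track value over all peak bases (zeros included).

    Bases not covered by any bedGraph step contribute 0 to the median, so a
    peak more than half uncovered has median 0 by construction.
    """

    track_name: str
    peaks: PeakSet
    medians: np.ndarray

    def quartiles(self) -> tuple[float, float, float]:
        q1, q2, q3 = np.percentile(self.medians, [25, 50, 75])
        return float(q1), float(q2), float(q3)


def peak_median_signal(peaks: PeakSet, track: SignalTrack) -> PeakSignalSummary:
    """Median bedGraph score per peak, for accessibility-distribution plots."""
    if len(peaks) == 0:
        raise ValueError("peak_median_signal: empty peak set")
    medians = np.array([
        float(np.median(track.values_over(p.chrom, p.start, p.end))) for p in peaks
    ])
    return PeakSignalSummary(track_name=track.name, peaks=peaks, medians=medians)


@dataclass
class DifferentialRanking:
    """Peaks ranked by differential signal D = log2((a + c) / (b + c)).

    ``order`` is a permutation of peak indices, highest D first, ties broken
    by (chrom, start) so the ranking is deterministic. ``top(n)`` returns the
    n highest-differential peaks as a PeakSet.
    """

    peaks: PeakSet
    scores: np.ndarray
    order: np.ndarray
    pseudocount: float
    a_name: str
    b_name: str

    def top(self, n: int, name: str | None = None) -> PeakSet:
        if n > len(self.peaks):
            raise ValueError(f"requested top {n} of {len(self.peaks)} peaks")
        chosen = [self.peaks.peaks[i] for i in self.order[:n]]
        return self.peaks.subset(
            chosen, name or f"{self.peaks.name}_top{n}_{self.a_name}_vs_{self.b_name}"
        )


def _peak_mean(track: SignalTrack, p: Peak, summit_halfwidth: int | None) -> float:
    if summit_halfwidth is None:
        start, end = p.start, p.end
    else:
        c = p.center()
        start, end = c - summit_halfwidth, c + summit_halfwidth
    return float(np.mean(track.values_over(p.chrom, start, end)))


def differential_rank(
    peaks: PeakSet,
    a: SignalTrack,
    b: SignalTrack,
    pseudocount: float = 0.1,
    summit_halfwidth: int | None = None,
) -> DifferentialRanking:
    """Rank peaks by log2 mean-pileup ratio of track a over track b.

    A transparent, deterministic stand-in for paired track differential
    callers: with both tracks normalized per million reads, the log-ratio of
    mean pileups is monotone in the same underlying signal difference. The
    pseudocount ``c`` regularises empty peaks; ``summit_halfwidth`` switches
    the per-peak signal from the full-interval mean to a window of
    +-halfwidth around the summit.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if len(peaks) == 0:
        raise ValueError("differential_rank: empty peak set")
    sig_a = np.array([_peak_mean(a, p, summit_halfwidth) for p in peaks])
    sig_b = np.array([_peak_mean(b, p, summit_halfwidth) for p in peaks])
    scores = np.log2((sig_a + pseudocount) / (sig_b + pseudocount))
    # stable sort on -score keeps the (chrom, start) order of PeakSet for ties
    order = np.argsort(-scores, kind="stable")
    return DifferentialRanking(
        peaks=peaks, scores=scores, order=order,
        pseudocount=pseudocount, a_name=a.name, b_name=b.name,
    )
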