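"""PWM scanning with exact p-value thresholds, per-peak match density, and
Poisson motif-set enrichment of peak sequences against a background.

Log-odds scores are quantized once, at PWM construction, onto a lattice of
0.01 bits. The exact null score distribution (a random width-w word drawn
from the 0-order background) is then computed by per-position convolution
over that lattice, so the p-value threshold, the scanner and the exact
distribution all live on the same score scale and agree to the lattice
resolution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import PeakSet
from .kmers import BackgroundSet

log = logging.getLogger("hoxspec")

LATTICE_BITS = 0.01  # score quantum for the exact-distribution DP
_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}


def background_frequencies(seqs: Iterable[str]) -> np.ndarray:
    """0-order nucleotide frequencies of a sequence collection (N ignored)."""
    counts = np.zeros(4)
    for seq in seqs:
        for i, b in enumerate(_BASES):
            counts[i] += seq.count(b)
    total = counts.sum()
    if total == 0:
        raise ValueError("no ACGT bases in background sequences")
    return counts / total


class Pwm:
    """Position weight matrix with log-odds scoring against a 0-order background.

    Built from a count matrix: ``p[i,j] = (count[i,j] + pseudocount * bg[j])
    / (column_total[i] + pseudocount)``. Each position's probabilities sum
    to 1; any zero probability (possible only with pseudocount 0) is an
    error because its log-odds would be -inf.
    """

    def __init__(
        self,
        name: str,
        counts: np.ndarray,
        pseudocount: float = 0.01,
        background: np.ndarray | None = None,
    ) -> None:
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must be a (width, 4) matrix")
        if counts.shape[0] < 4:
            raise ValueError(f"PWM width {counts.shape[0]} < 4")
        if (counts < 0).any():
            raise ValueError("negative counts")
        if (counts.sum(axis=1) <= 0).any():
            raise ValueError("every position needs at least one positive count")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        bg = bg / bg.sum()
        probs = (counts + pseudocount * bg) / (
            counts.sum(axis=1, keepdims=True) + pseudocount
        )
        if (probs <= 0).any():
            raise ValueError(
                "zero probability in PWM (use a positive pseudocount)"
            )
        self.name = name
        self.counts = counts
        self.background = bg
        self.probabilities = probs
        self.width = counts.shape[0]
        # quantized log-odds (bits), integer lattice units of LATTICE_BITS
        lom = np.log2(probs / bg)
        self._lattice = np.rint(lom / LATTICE_BITS).astype(np.int64)

    @property
    def log_odds(self) -> np.ndarray:
        """Log-odds matrix in bits, quantized to the score lattice."""
        return self._lattice * LATTICE_BITS

    def consensus(self) -> str:
        return "".join(_BASES[j] for j in self.probabilities.argmax(axis=1))

    def reverse_complement_lattice(self) -> np.ndarray:
        return self._lattice[::-1, ::-1]

    def score_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        """Exact null distribution of the quantized score.

        Returns ``(scores_bits, probabilities)`` for a random width-w word
        drawn i.i.d. from the background model, computed by convolving the
        per-position score distributions over the integer lattice.
        """
        lat = self._lattice
        lo = int(lat.min(axis=1).sum())
        hi = int(lat.max(axis=1).sum())
        dist = np.zeros(hi - lo + 1)
        # start with position 0
        offset_min = int(lat[0].min())
        cur = np.zeros(int(lat[0].max()) - offset_min + 1)
        for j in range(4):
            cur[lat[0, j] - offset_min] += self.background[j]
        cur_min = offset_min
        for i in range(1, self.width):
            pos_min, pos_max = int(lat[i].min()), int(lat[i].max())
            nxt = np.zeros(len(cur) + pos_max - pos_min)
            for j in range(4):
                shift = lat[i, j] - pos_min
                nxt[shift: shift + len(cur)] += self.background[j] * cur
            cur = nxt
            cur_min += pos_min
        dist[cur_min - lo: cur_min - lo + len(cur)] = cur
        scores = (np.arange(lo, hi + 1)) * LATTICE_BITS
        return scores, dist

    def score_threshold(self, p: float) -> float:
        """Smallest score s with P(null score >= s) <= p.

        With ``p = 1`` this is the minimum attainable score; a ``p`` below
        the resolution of the discrete null distribution yields the maximum
        attainable score with a warning.
        """
        if not (0 < p <= 1):
            raise ValueError("p must be in (0, 1]")
        scores, dist = self.score_distribution()
        tail = np.cumsum(dist[::-1])[::-1]  # tail[i] = P(score >= scores[i])
        ok = np.nonzero(tail <= p + 1e-15)[0]
        if len(ok) == 0:
            log.warning(
                "%s: p=%g below attainable resolution; using maximum score",
                self.name, p,
            )
            return float(scores[-1])
        return float(scores[ok[0]])


def _parse_jaspar_blocks(text: str) -> list[tuple[str, np.ndarray]]:
    """Parse JASPAR-style PFM text (one or more motifs) or a bare 4-row matrix."""
    blocks: list[tuple[str, list[list[float]]]] = []
    rows_by_base: dict[str, list[float]] = {}
    name = "pwm"

    def flush():
        nonlocal rows_by_base, name
        if rows_by_base:
            if set(rows_by_base) != set(_BASES):
                raise ValueError(f"motif {name!r}: expected rows A,C,G,T")
            mat = np.array([rows_by_base[b] for b in _BASES]).T
            blocks.append((name, mat))
            rows_by_base = {}

    bare_rows: list[list[float]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].split()[0] if line[1:].split() else "pwm"
            continue
        cleaned = line.replace("[", " ").replace("]", " ")
        parts = cleaned.split()
        if parts[0].upper() in _CODE and not _is_number(parts[0]):
            rows_by_base[parts[0].upper()] = [float(x) for x in parts[1:]]
        else:
            bare_rows.append([float(x) for x in parts])
    flush()
    if bare_rows:
        if len(bare_rows) != 4:
            raise ValueError("bare matrix must have exactly 4 rows (A, C, G, T)")
        blocks.append((name, np.array(bare_rows).T))
    widths = {m.shape[0] for _, m in blocks}
    for nm, m in blocks:
        if len({len(r) for r in m.T}) > 1:  # ragged guarded earlier by numpy
            raise ValueError(f"motif {nm!r}: ragged matrix")
    if not blocks:
        raise ValueError("no PWM found")
    return blocks


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def load_pwms(
    path: str | Path,
    pseudocount: float = 0.01,
    background: np.ndarray | None = None,
) -> list[Pwm]:
    """Load all motifs from a JASPAR-style PFM file (or a bare 4-row matrix)."""
    text = Path(path).read_text()
    try:
        blocks = _parse_jaspar_blocks(text)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    return [
        Pwm(name, counts, pseudocount=pseudocount, background=background)
        for name, counts in blocks
    ]


def load_pwm(path, pseudocount: float = 0.01, background=None) -> Pwm:
    """Load a single motif; errors if the file holds more than one."""
    pwms = load_pwms(path, pseudocount=pseudocount, background=background)
    if len(pwms) != 1:
        raise ValueError(f"{path}: expected one motif, found {len(pwms)}")
    return pwms[0]


def bundled_pwm(name: str, pseudocount: float = 0.01, background=None) -> Pwm:
    """Load a synthetic Hox-like count matrix shipped with the package."""
    import importlib.resources
    ref = importlib.resources.files("hoxspec") / "data" / "pwms" / f"{name}.jaspar"
    with importlib.resources.as_file(ref) as path:
        return load_pwm(path, pseudocount=pseudocount, background=background)


@dataclass
class MatchSet:
    """PWM matches per sequence at a fixed score threshold.

    ``matches[i]`` lists ``(position, strand, score_bits)`` for sequence i;
    positions are window starts on the forward coordinate system for both
    strands. ``n_windows`` counts every (position, strand) window actually
    evaluated (N-containing windows are skipped and not counted).
    """

    pwm_name: str
    threshold: float
    matches: list[list[tuple[int, str, float]]]
    n_windows: int

    def counts(self) -> np.ndarray:
        return np.array([len(m) for m in self.matches])

    def total(self) -> int:
        return int(self.counts().sum())


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), 4, dtype=np.int8)
    for b, i in _CODE.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return codes


def _window_scores(codes: np.ndarray, lattice: np.ndarray) -> np.ndarray:
    """Quantized score (lattice units) per window start; NaN where N present."""
    w = lattice.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0)
    ext = np.hstack([lattice.astype(float), np.full((w, 1), np.nan)])  # col 4 = N
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    return ext[np.arange(w)[None, :], windows].sum(axis=1)


def scan(
    seqs: Sequence[str],
    pwm: Pwm,
    cutoff: float,
    strands: str = "both",
) -> MatchSet:
    """All windows scoring >= cutoff on the requested strands.

    Overlapping matches are all retained; windows containing N are skipped.
    A reverse-strand match at position i means the reverse complement of
    ``seq[i:i+w]`` matches the motif.
    """
    if strands not in ("forward", "both"):
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")
    cutoff_lattice = cutoff / LATTICE_BITS - 0.5  # tolerate float fuzz on the lattice
    strand_lattices = [("+", pwm._lattice)]
    if strands == "both":
        strand_lattices.append(("-", pwm.reverse_complement_lattice()))
    matches: list[list[tuple[int, str, float]]] = []
    n_windows = 0
    for seq in seqs:
        codes = _encode(seq.upper())
        found: list[tuple[int, str, float]] = []
        for strand, lat in strand_lattices:
            sc = _window_scores(codes, lat)
            valid = ~np.isnan(sc)
            n_windows += int(valid.sum())
            hits = np.nonzero(valid & (sc >= cutoff_lattice))[0]
            found.extend((int(i), strand, float(sc[i] * LATTICE_BITS)) for i in hits)
        found.sort()
        matches.append(found)
    return MatchSet(
        pwm_name=pwm.name, threshold=cutoff, matches=matches, n_windows=n_windows
    )


@dataclass
class DensityResult:
    """Per-peak PWM match density, (matches / peak length) x 1000."""

    pwm_name: str
    peaks: PeakSet
    densities: np.ndarray

    @property
    def median(self) -> float:
        return float(np.median(self.densities))


def match_density(peaks: PeakSet, matches: MatchSet) -> DensityResult:
    """Match density per kb for each peak of the set the matches came from."""
    if len(matches.matches) != len(peaks):
        raise ValueError("match set does not correspond to this peak set")
    dens = np.array([
        len(m) / p.length * 1000.0 for p, m in zip(peaks, matches.matches)
    ])
    return DensityResult(pwm_name=matches.pwm_name, peaks=peaks, densities=dens)


def density_compare(a: DensityResult, b: DensityResult) -> float:
    """Two-sided Mann-Whitney rank-sum p-value between per-peak densities."""
    return float(stats.mannwhitneyu(a.densities, b.densities).pvalue)


@dataclass
class EnrichmentScore:
    """Motif-set enrichment of one motif: score = log10(1 / p-value)."""

    motif: str
    p_value: float
    score: float
    rank: int = 0
    fg_matches: int = 0
    fg_windows: int = 0
    bg_rate: float = 0.0


def motif_set_enrichment(
    fg_seqs: Sequence[str],
    background: BackgroundSet,
    pwms: Sequence[Pwm],
    match_pvalue: float = 0.001,
    strands: str = "both",
    score_cap: float = 16.0,
) -> list[EnrichmentScore]:
    """Rank motifs by over-representation in foreground vs background.

    For each motif the background match rate per scanned window, lambda, is
    estimated at the exact-p-value cutoff; the foreground match count m over
    n windows is tested against Poisson(lambda * n) with p = P(X >= m).
    Scores are log10(1/p), capped; motifs are ranked by score, ties broken
    by name. Absolute scores from affinity-based enrichment tools will
    differ; the ranking is the comparable output.
    """
    results = []
    for pwm in pwms:
        cutoff = pwm.score_threshold(match_pvalue)
        bg_matches = scan(background.sequences, pwm, cutoff, strands)
        fg_matches = scan(fg_seqs, pwm, cutoff, strands)
        lam = bg_matches.total() / bg_matches.n_windows if bg_matches.n_windows else 0.0
        m, n = fg_matches.total(), fg_matches.n_windows
        if m == 0:
            p = 1.0
        elif lam == 0:
            log.warning("%s: no background matches but %d foreground; capping", pwm.name, m)
            p = 10.0 ** -score_cap
        else:
            p = float(stats.poisson.sf(m - 1, lam * n))
        score = min(score_cap, math.log10(1.0 / p)) if p > 0 else score_cap
        results.append(EnrichmentScore(
            motif=pwm.name, p_value=p, score=score,
            fg_matches=m, fg_windows=n, bg_rate=lam,
        ))
    results.sort(key=lambda r: (-r.score, r.motif))
    for i, r in enumerate(results, 1):
        r.rank = i
    return results
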