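"""K-mer fingerprint statistic: frequency per kb of a fixed word panel in
peak sequences versus a background set, reported as log2 ratios.

The panel words come from in vitro SELEX-Seq fingerprints of Hox and
Exd-Hox binding preferences; the statistic characterises which of those
preferences a peak set carries in vivo. Counting is overlap-aware (every
start position is tested) and forward-strand by default, with a both-strand
mode for unstranded peak sets.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .core import GenomeSequence, PeakSet, revcomp

log = logging.getLogger("hoxspec")


@dataclass(frozen=True)
class KmerPanel:
    """Ordered panel of same-length DNA words with display labels."""

    k: int
    kmers: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        for word in self.kmers:
            if len(word) != self.k:
                raise ValueError(f"{word}: length != {self.k}")
            if set(word) - set("ACGT"):
                raise ValueError(f"{word}: contains non-ACGT characters")

    @classmethod
    def from_words(cls, words: Sequence[str], labels: Sequence[str] | None = None):
        words = tuple(w.upper() for w in words)
        if not words:
            raise ValueError("empty panel")
        labels = tuple(labels) if labels is not None else words
        return cls(k=len(words[0]), kmers=words, labels=labels)

    @classmethod
    def read(cls, path) -> "KmerPanel":
        """Read a panel file: one k-mer plus optional whitespace-separated label per line."""
        words, labels = [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            words.append(parts[0].upper())
            labels.append(parts[1] if len(parts) > 1 else parts[0].upper())
        return cls.from_words(words, labels)

    @classmethod
    def bundled(cls, name: str) -> "KmerPanel":
        """Load a panel shipped with the package (``hox_5mers``, ``exd_hox_8mers``)."""
        ref = importlib.resources.files("hoxspec") / "data" / "panels" / f"{name}.txt"
        with importlib.resources.as_file(ref) as path:
            return cls.read(path)


@dataclass
class BackgroundSet:
    """Background sequence collection (conventionally 2 kb upstream of TSSs)."""

    sequences: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.sequences or sum(len(s) for s in self.sequences) == 0:
            raise ValueError("background set is empty")

    def total_kb(self) -> float:
        return sum(len(s) for s in self.sequences) / 1000.0


def extract_peak_sequences(peaks: PeakSet, genome: GenomeSequence) -> list[str]:
    """Forward-strand uppercase sequence under each peak, in set order."""
    seqs = []
    for p in peaks:
        try:
            seqs.append(genome.fetch(p.chrom, p.start, p.end))
        except (KeyError, IndexError) as exc:
            raise ValueError(
                f"peak {p.name or ''} {p.chrom}:{p.start}-{p.end} out of genome bounds"
            ) from exc
    return seqs


def build_tss_background(
    tss: Iterable[tuple[str, int, str]],
    genome: GenomeSequence,
    span: int = 2000,
    provenance: str = "TSS_upstream",
) -> BackgroundSet:
    """Sequences of the ``span`` bases upstream of each TSS.

    ``tss`` yields (chrom, position, strand). For a + strand TSS at t the
    window is [t - span, t); for - strand it is the reverse complement of
    [t, t + span). Windows truncated by a chromosome edge are dropped with
    a warning so every background sequence has the full length.
    """
    seqs = []
    n_dropped = 0
    for chrom, pos, strand in tss:
        if chrom not in genome:
            n_dropped += 1
            continue
        length = genome.length(chrom)
        if strand == "+":
            start, end = pos - span, pos
        elif strand == "-":
            start, end = pos, pos + span
        else:
            raise ValueError(f"TSS at {chrom}:{pos}: invalid strand {strand!r}")
        if start < 0 or end > length:
            n_dropped += 1
            continue
        seq = genome.fetch(chrom, start, end)
        seqs.append(seq if strand == "+" else revcomp(seq))
    if n_dropped:
        log.warning("build_tss_background: dropped %d edge/missing TSS windows", n_dropped)
    if not seqs:
        raise ValueError("no valid TSS windows")
    return BackgroundSet(tuple(seqs), provenance=provenance)


def _count_in_seq(seq: str, word: str) -> int:
    # str.find with advancing start counts overlapping occurrences; words
    # contain no N so N positions can never match.
    n = 0
    i = seq.find(word)
    while i != -1:
        n += 1
        i = seq.find(word, i + 1)
    return n


def count_kmer(seqs: Iterable[str], kmer: str, strands: str = "forward") -> int:
    """Occurrences of ``kmer`` across a sequence collection.

    Overlapping occurrences all count. With ``strands="both"`` occurrences
    of the reverse complement are added; a palindromic word is counted once
    per position (forward and reverse-complement matches coincide).
    """
    kmer = kmer.upper()
    if set(kmer) - set("ACGT"):
        raise ValueError(f"invalid characters in k-mer {kmer!r}")
    if strands not in ("forward", "both"):
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")
    total = 0
    rc = revcomp(kmer)
    for seq in seqs:
        total += _count_in_seq(seq, kmer)
        if strands == "both" and rc != kmer:
            total += _count_in_seq(seq, rc)
    return total


@dataclass
class FingerprintResult:
    """Per-k-mer enrichment of a panel in foreground vs background sequences.

    ``enrichment[i] = log2(fg_per_kb[i] / bg_per_kb[i])``, defined only when
    both frequencies are positive; otherwise the entry is None and the word
    is flagged in ``undefined`` rather than reported as +/-inf.
    """

    panel: KmerPanel
    fg_counts: tuple[int, ...]
    fg_kb: float
    bg_counts: tuple[int, ...]
    bg_kb: float
    strands: str

    @property
    def fg_per_kb(self) -> tuple[float, ...]:
        return tuple(c / self.fg_kb for c in self.fg_counts)

    @property
    def bg_per_kb(self) -> tuple[float, ...]:
        return tuple(c / self.bg_kb for c in self.bg_counts)

    @property
    def enrichment(self) -> tuple[float | None, ...]:
        import math
        out = []
        for fg, bg in zip(self.fg_per_kb, self.bg_per_kb):
            out.append(math.log2(fg / bg) if fg > 0 and bg > 0 else None)
        return tuple(out)

    @property
    def undefined(self) -> tuple[str, ...]:
        return tuple(
            w for w, e in zip(self.panel.kmers, self.enrichment) if e is None
        )

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "kmer": self.panel.kmers,
            "label": self.panel.labels,
            "fg_count": self.fg_counts,
            "fg_per_kb": self.fg_per_kb,
            "bg_per_kb": self.bg_per_kb,
            "log2_enrichment": [e if e is not None else float("nan")
                                for e in self.enrichment],
        })


def fingerprint(
    fg_seqs: Sequence[str],
    background: BackgroundSet,
    panel: KmerPanel,
    strands: str = "forward",
) -> FingerprintResult:
    """Panel enrichment: log2(foreground frequency per kb / background frequency per kb).

    Background frequency is pooled across all background sequences (total
    counts over total kb), giving a single background number per word.
    """
    if not fg_seqs or sum(len(s) for s in fg_seqs) == 0:
        raise ValueError("fingerprint: empty foreground")
    fg_kb = sum(len(s) for s in fg_seqs) / 1000.0
    bg_kb = background.total_kb()
    fg_counts = tuple(count_kmer(fg_seqs, w, strands) for w in panel.kmers)
    bg_counts = tuple(count_kmer(background.sequences, w, strands) for w in panel.kmers)
    return FingerprintResult(
        panel=panel, fg_counts=fg_counts, fg_kb=fg_kb,
        bg_counts=bg_counts, bg_kb=bg_kb, strands=strands,
    )
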