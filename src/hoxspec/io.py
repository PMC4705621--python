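"""Readers and writers for BED/narrowPeak, bedGraph and FASTA.

All readers transparently accept gzip-compressed files. Coordinates are
passed through unchanged (all formats here are natively 0-based half-open);
narrowPeak summit offsets are converted to absolute coordinates on read and
back to offsets on write.
"""

from __future__ import annotations

import gzip
import io as _io
import logging
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from .core import DEFAULT_WHITELIST, GenomeSequence, Peak, PeakSet, SignalTrack

log = logging.getLogger("hoxspec")


class ParseError(ValueError):
    """Malformed input line; message names the file and 1-based line number."""


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_peaks(
    path: str | Path,
    format: str = "narrowPeak",
    name: str | None = None,
    stringency: str | None = None,
    whitelist: Sequence[str] = DEFAULT_WHITELIST,
) -> PeakSet:
    """Read a peak file into a :class:`PeakSet`.

    Parameters
    ----------
    format : {"narrowPeak", "bed"}
        ``narrowPeak`` expects the 10-column ENCODE extension; column 10 is
        the summit offset from ``start`` (-1 = no summit). ``bed`` accepts
        BED3/BED6.
    whitelist
        Peaks on other chromosomes are dropped (their count is logged),
        mirroring the restriction of the analysis to euchromatic arms.
    """
    if format not in ("narrowPeak", "bed"):
        raise ValueError(f"unknown peak format {format!r}")
    wl = set(whitelist)
    peaks: list[Peak] = []
    n_dropped = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                pname = fields[3] if len(fields) > 3 and fields[3] != "." else None
                score = None
                summit = None
                if format == "narrowPeak":
                    if len(fields) < 10:
                        raise ValueError("narrowPeak requires 10 columns")
                    score = float(fields[6])  # signalValue
                    offset = int(fields[9])
                    if offset >= 0:
                        summit = start + offset
                elif len(fields) > 4 and fields[4] != ".":
                    score = float(fields[4])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if chrom not in wl:
                n_dropped += 1
                continue
            try:
                peaks.append(
                    Peak(chrom, start, end, summit=summit, score=score, name=pname)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if n_dropped:
        log.info("%s: dropped %d peaks on non-whitelisted chromosomes", path, n_dropped)
    return PeakSet(
        name or Path(path).stem, peaks, stringency=stringency, whitelist=tuple(whitelist)
    )


def write_bed(peaks: PeakSet, path: str | Path, narrowpeak: bool = False) -> None:
    """Write a peak set as BED6 or, with ``narrowpeak=True``, 10-column narrowPeak."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.name or f"{peaks.name}_{i + 1}"
            score = p.score if p.score is not None else 0.0
            if narrowpeak:
                offset = p.summit - p.start if p.summit is not None else -1
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t0\t.\t{score:g}\t-1\t-1\t{offset}\n"
                )
            else:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{score:g}\t.\n")


def read_bedgraph(path: str | Path, name: str | None = None) -> SignalTrack:
    """Read a bedGraph file into a :class:`SignalTrack`.

    Overlapping intervals are rejected (MACS2 pileup output never
    overlaps); unsorted input is sorted internally with a warning; negative
    values are an error.
    """
    steps: dict[str, list[tuple[int, int, float]]] = {}
    unsorted = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            try:
                chrom, start, end, value = (
                    fields[0], int(fields[1]), int(fields[2]), float(fields[3]),
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative value {value}")
            ss = steps.setdefault(chrom, [])
            if ss and start < ss[-1][0]:
                unsorted = True
            ss.append((start, end, value))
    if unsorted:
        log.warning("%s: intervals not sorted; sorting internally", path)
        for ss in steps.values():
            ss.sort()
    try:
        return SignalTrack(name or Path(path).stem, steps)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_bedgraph(track: SignalTrack, path: str | Path, write_zeros: bool = False) -> None:
    """Write a track as bedGraph; zero-valued steps are skipped by default."""
    with open(path, "w") as fh:
        for chrom in track.chroms():
            for start, end, value in track.steps[chrom]:
                if value == 0 and not write_zeros:
                    continue
                fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a (possibly gzipped) FASTA into a :class:`GenomeSequence`.

    Sequences are uppercased; N is permitted; duplicate names are an error.
    """
    sequences: dict[str, str] = {}
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record.id in sequences:
                raise ParseError(f"{path}: duplicate chromosome name {record.id!r}")
            sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise ParseError(f"{path}: no FASTA records found")
    return GenomeSequence(sequences)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome.sequences):
            fh.write(f">{chrom}\n")
            seq = genome.sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
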