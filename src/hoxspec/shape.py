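"""Summit-centred DNA-shape (minor groove width) and GC-content profiling.

Minor groove width (MGW) is predicted per base from the local pentamer via
a lookup table (the convention of sliding-pentamer shape predictors); GC is
the 0/1 indicator per base. Profiles are averaged across peaks at each
position relative to the summit, then smoothed with a rolling mean
(default 100 bp window, 10 bp step). Narrow minor grooves at Hox summits
are the structural signature the profile is designed to expose.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import numpy as np

from .core import GenomeSequence, PeakSet, revcomp

log = logging.getLogger("hoxspec")

ALL_PENTAMERS = tuple(
    "".join(p) for p in itertools.product("ACGT", repeat=5)
)


class PentamerShapeTable:
    """Pentamer -> minor-groove-width (angstrom) lookup at the central base.

    A pentamer and its reverse complement describe the same double-helical
    context, so the table must satisfy ``value(p) == value(revcomp(p))``;
    violations are symmetrized by averaging with a warning. A table covering
    all 1024 pentamers is complete; a partial table must set
    ``missing_policy="skip"`` so absent keys yield missing values.
    """

    def __init__(
        self, values: Mapping[str, float], missing_policy: str = "error"
    ) -> None:
        if missing_policy not in ("error", "skip"):
            raise ValueError("missing_policy must be 'error' or 'skip'")
        table: dict[str, float] = {}
        asymmetric = 0
        for pent, v in values.items():
            pent = pent.upper()
            if len(pent) != 5 or set(pent) - set("ACGT"):
                raise ValueError(f"invalid pentamer key {pent!r}")
            table[pent] = float(v)
        for pent in list(table):
            rc = revcomp(pent)
            if rc in table:
                if table[rc] != table[pent]:
                    mean = 0.5 * (table[rc] + table[pent])
                    table[rc] = table[pent] = mean
                    asymmetric += 1
            else:
                table[rc] = table[pent]
        if asymmetric:
            log.warning(
                "shape table: %d pentamer pairs violated reverse-complement "
                "symmetry; symmetrized by averaging", asymmetric,
            )
        self.values = table
        self.missing_policy = missing_policy
        if not self.is_complete() and missing_policy == "error":
            missing = 1024 - len(table)
            raise ValueError(
                f"shape table covers {len(table)}/1024 pentamers; "
                "pass missing_policy='skip' to accept a partial table"
            )

    def is_complete(self) -> bool:
        return len(self.values) == 1024

    def __getitem__(self, pent: str) -> float:
        return self.values[pent]

    def minmax(self) -> tuple[float, float]:
        vals = list(self.values.values())
        return min(vals), max(vals)


def load_shape_table(path: str | Path, missing_policy: str = "error") -> PentamerShapeTable:
    """Read a 2-column TSV of pentamer and width; symmetry is enforced on load."""
    values: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'pentamer<TAB>value'")
        values[parts[0]] = float(parts[1])
    return PentamerShapeTable(values, missing_policy=missing_policy)


def write_shape_table(table: PentamerShapeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pent in sorted(table.values):
            fh.write(f"{pent}\t{table.values[pent]:g}\n")


def synthetic_shape_table() -> PentamerShapeTable:
    """Toy MGW table: width = 5.8 - 0.5 * (count of A/T in the pentamer).

    Synthetic stand-in for a real pentamer shape-query table. It keeps only
    the dominant qualitative feature of predicted minor groove width - AT
    tracts narrow the groove - mapping AT counts 0..5 onto 5.8..3.3
    angstrom, inside the physical range of real predictions. Symmetric
    under reverse complement by construction; exists so tests and demos
    need no external shape-prediction table.
    """
    return PentamerShapeTable(
        {p: 5.8 - 0.5 * sum(p.count(b) for b in "AT") for p in ALL_PENTAMERS}
    )


def mgw_predict(seq: str, table: PentamerShapeTable) -> np.ndarray:
    """Per-base minor groove width; NaN at edges, Ns and missing pentamers.

    Position i (2 <= i <= L-3) is looked up from the pentamer centred on it;
    the two bases at each end have no complete pentamer and are missing.
    """
    seq = seq.upper()
    L = len(seq)
    if L < 5:
        raise ValueError("sequence shorter than a pentamer")
    out = np.full(L, np.nan)
    get = table.values.get
    for i in range(2, L - 2):
        v = get(seq[i - 2: i + 3])
        if v is not None:
            out[i] = v
    return out


def gc_indicator(seq: str) -> np.ndarray:
    """1.0 for G/C, 0.0 for A/T, NaN for N, per base."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.where((arr == ord("G")) | (arr == ord("C")), 1.0, 0.0)
    out[arr == ord("N")] = np.nan
    return out


@dataclass
class SummitProfile:
    """Average per-base value around peak summits, raw and smoothed.

    ``positions`` run from -span/2 to span/2 - 1 relative to the summit
    (0 = summit base). ``raw_mean`` averages over peaks, ignoring missing
    values; ``n`` records how many peaks contributed at each position.
    ``smoothed`` is the rolling mean of ``raw_mean`` (window/step in bp)
    reported at window-midpoint positions.
    """

    mode: str
    span_bp: int
    window_bp: int
    step_bp: int
    positions: np.ndarray
    raw_mean: np.ndarray
    n: np.ndarray
    smoothed_positions: np.ndarray
    smoothed: np.ndarray
    n_peaks: int

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "relative_position": self.smoothed_positions,
            "smoothed_mean": self.smoothed,
        })


def _smooth(values: np.ndarray, window: int, step: int) -> np.ndarray:
    n_out = (len(values) - window) // step + 1
    return np.array([
        np.nanmean(values[i * step: i * step + window]) for i in range(n_out)
    ])


def summit_profile(
    peaks: PeakSet,
    genome: GenomeSequence,
    mode: str = "mgw",
    table: PentamerShapeTable | None = None,
    span: int = 2000,
    window: int = 100,
    step: int = 10,
) -> SummitProfile:
    """Average MGW or GC profile over ``span`` bp centred on peak summits.

    Peaks lacking a summit fall back to their midpoint (logged); peaks whose
    window would cross a chromosome edge are dropped with a warning. Missing
    per-base values (sequence edges, Ns, absent pentamers) are excluded from
    both numerator and denominator; ``n`` exposes thin positions.
    """
    if span % 2:
        raise ValueError("span must be even")
    if mode not in ("mgw", "gc"):
        raise ValueError(f"mode must be 'mgw' or 'gc', got {mode!r}")
    if mode == "mgw" and table is None:
        raise ValueError("mgw mode requires a pentamer shape table")
    half = span // 2
    total = np.zeros(span)
    n = np.zeros(span, dtype=int)
    n_dropped = n_fallback = n_used = 0
    for p in peaks:
        if p.summit is None:
            n_fallback += 1
        c = p.center()
        start, end = c - half, c + half
        if start < 0 or end > genome.length(p.chrom):
            n_dropped += 1
            continue
        seq = genome.fetch(p.chrom, start, end)
        vals = mgw_predict(seq, table) if mode == "mgw" else gc_indicator(seq)
        ok = ~np.isnan(vals)
        total[ok] += vals[ok]
        n += ok
        n_used += 1
    if n_fallback:
        log.info("summit_profile: %d peaks lack summits, used interval midpoints", n_fallback)
    if n_dropped:
        log.warning("summit_profile: dropped %d peaks at chromosome edges", n_dropped)
    if n_used == 0:
        raise ValueError("summit_profile: all peaks dropped")
    with np.errstate(invalid="ignore"):
        raw = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    positions = np.arange(-half, half)
    smoothed = _smooth(raw, window, step)
    # window midpoints: centre of [i*step, i*step + window) in relative coords
    n_out = (span - window) // step + 1
    smoothed_positions = np.array([
        -half + i * step + (window - 1) / 2 for i in range(n_out)
    ])
    return SummitProfile(
        mode=mode, span_bp=span, window_bp=window, step_bp=step,
        positions=positions, raw_mean=raw, n=n,
        smoothed_positions=smoothed_positions, smoothed=smoothed,
        n_peaks=n_used,
    )
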