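"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the statistical structure of a cultured-cell Hox
ChIP-Seq experiment: a random genome at a chosen GC content, a five-colour
chromatin-state annotation drawn as a renewal process, factor peak sets
with controlled pairwise reciprocal overlap (later sets copy and jitter
peaks of earlier sets), motif words planted by substitution inside chosen
subsets, per-million-style pileup tracks built from a triangular kernel per
peak over a low noise floor, and a stranded TSS set for background
sequences. Everything planted is recorded in a :class:`GroundTruth` so each
analysis stage can be checked against what was actually put in.

All randomness flows from a single integer seed; each generation stage uses
an independent substream derived from (seed, fixed stage offset), so adding
a stage never perturbs the draws of earlier ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from intervaltree import IntervalTree

from .core import GenomeSequence, Peak, PeakSet, SignalTrack
from .intervals import STATE_COLOURS, StateAnnotation

log = logging.getLogger("hoxspec")

_TRACK_RES = 10  # bp; pileup kernels are block-averaged at this resolution


@dataclass
class PeakSetSpec:
    """Recipe for one synthetic peak set.

    ``source_fraction`` of the peaks are copies of random peaks of the
    ``source`` set, jittered by at most ``jitter_frac`` of their length, so
    they reciprocally overlap their originals by at least
    ``1 - jitter_frac``; the remainder are placed disjoint from every peak
    placed so far (zero overlap). ``state_bias`` biases fresh-peak placement
    into segments of the given colour states. ``motif``/``at_core_bp``
    plant sequence features by substitution inside designated peaks.
    """

    name: str
    n_peaks: int
    length_min: int = 500
    length_mode: int = 1000
    length_max: int = 2000
    source: str | None = None
    source_fraction: float = 0.0
    jitter_frac: float = 0.05
    state_bias: dict[str, float] | None = None
    motif: str | None = None
    motif_prob: float = 0.0
    motif_copies: tuple[int, int] = (1, 1)
    motif_in_copied: bool = False
    at_core_bp: int = 0
    amplitude: float = 10.0


@dataclass
class ScenarioSpec:
    """Full scenario: genome layout, annotation, peak sets, TSSs, seed."""

    chrom_lengths: dict[str, int]
    peak_sets: list[PeakSetSpec]
    gc_content: float = 0.42
    n_tss: int = 300
    state_mean_bp: int = 5000
    state_weights: dict[str, float] = field(default_factory=lambda: {
        "BLACK": 0.48, "YELLOW": 0.17, "BLUE": 0.13, "RED": 0.12, "GREEN": 0.10,
    })
    state_unknown_fraction: float = 0.08
    track_noise: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must be in (0, 1)")
        genome = sum(self.chrom_lengths.values())
        # only freshly-placed peaks demand unoccupied space; copied peaks
        # deliberately reuse their source's footprint
        requested = sum(
            s.n_peaks * (1 - s.source_fraction)
            * (s.length_min + s.length_mode + s.length_max) / 3
            for s in self.peak_sets
        )
        if requested >= genome / 2:
            raise ValueError(
                f"requested ~{requested:.0f} peak bases on a {genome} bp genome; "
                "infeasible (must be < genome/2)"
            )
        seen: set[str] = set()
        for s in self.peak_sets:
            if s.source is not None:
                if s.source not in seen:
                    raise ValueError(
                        f"set {s.name!r}: source {s.source!r} not generated before it"
                    )
                if not (0 <= s.source_fraction <= 1):
                    raise ValueError(f"set {s.name!r}: source_fraction outside [0,1]")
            seen.add(s.name)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        raw = yaml.safe_load(Path(path).read_text())
        raw["peak_sets"] = [
            PeakSetSpec(**{**ps, "motif_copies": tuple(ps.get("motif_copies", (1, 1)))})
            for ps in raw["peak_sets"]
        ]
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        for ps in raw["peak_sets"]:
            ps["motif_copies"] = list(ps["motif_copies"])
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass
class GroundTruth:
    """What the generator actually planted, for parameter-recovery checks.

    ``provenance[set_name][i]`` describes peak i of that set: its source
    set (None if placed fresh), the state targeted by biased placement, and
    the absolute coordinates of every planted motif copy. Realized
    fractions are derived from these records, not re-measured by the
    analysis code under test.
    """

    provenance: dict[str, list[dict]]
    realized_overlap: dict[tuple[str, str], float]
    realized_state_target: dict[str, dict[str, float]]
    motif_positions: dict[str, list[tuple[str, int]]]

    def planted_copies_per_kb(self, set_name: str, peaks: PeakSet) -> float:
        n = sum(len(rec["motif_at"]) for rec in self.provenance[set_name])
        return n / (peaks.total_length() / 1000.0)


@dataclass
class SimulatedData:
    genome: GenomeSequence
    peak_sets: dict[str, PeakSet]
    tracks: dict[str, SignalTrack]
    states: StateAnnotation
    tss: list[tuple[str, int, str]]
    truth: GroundTruth
    spec: ScenarioSpec


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([seed, stage])


def _random_genome(spec: ScenarioSpec) -> dict[str, np.ndarray]:
    rng = _rng(spec.seed, 0)
    gc = spec.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {
        chrom: rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)
        for chrom, n in spec.chrom_lengths.items()
    }


def _random_states(spec: ScenarioSpec) -> StateAnnotation:
    rng = _rng(spec.seed, 1)
    labels = list(spec.state_weights)
    for lab in labels:
        if lab not in STATE_COLOURS:
            raise ValueError(f"unknown state label {lab!r}")
    w = np.array([spec.state_weights[lab] for lab in labels], dtype=float)
    w /= w.sum()
    intervals: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, length in spec.chrom_lengths.items():
        pos = 0
        ivs = []
        while pos < length:
            seg = max(200, int(rng.exponential(spec.state_mean_bp)))
            # a fraction of segments stays unannotated (UNKNOWN downstream)
            if rng.random() >= spec.state_unknown_fraction:
                lab = labels[rng.choice(len(labels), p=w)]
                ivs.append((pos, min(pos + seg, length), lab))
            pos += seg
        intervals[chrom] = ivs
    return StateAnnotation(intervals)


def _triangular_length(rng, s: PeakSetSpec) -> int:
    if s.length_min == s.length_max:
        return s.length_min
    return int(rng.triangular(s.length_min, s.length_mode, s.length_max))


def _place_fresh(
    rng, spec: ScenarioSpec, sspec: PeakSetSpec,
    occupied: dict[str, IntervalTree],
    segments_by_state: dict[str, list[tuple[str, int, int]]],
) -> tuple[str, int, int, str | None]:
    """One disjoint peak placement, optionally biased into a colour state."""
    chroms = list(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    bias = sspec.state_bias
    if bias:
        blabels = list(bias)
        bw = np.array([bias[lab] for lab in blabels], dtype=float)
        bw /= bw.sum()
    for _ in range(2000):
        plen = _triangular_length(rng, sspec)
        target_state = None
        if bias:
            target_state = blabels[rng.choice(len(blabels), p=bw)]
            segs = [s for s in segments_by_state.get(target_state, ())
                    if s[2] - s[1] >= plen]
            if not segs:
                continue
            seg_w = np.array([s[2] - s[1] for s in segs], dtype=float)
            chrom, s0, s1 = segs[rng.choice(len(segs), p=seg_w / seg_w.sum())]
            start = int(rng.integers(s0, s1 - plen + 1))
        else:
            chrom = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
            limit = spec.chrom_lengths[chrom] - plen - 1
            if limit <= 1:
                continue
            start = int(rng.integers(1, limit))
        if not occupied[chrom].overlap(start - 10, start + plen + 10):
            return chrom, start, start + plen, target_state
    raise RuntimeError(
        f"set {sspec.name!r}: could not place a disjoint peak after 2000 tries; "
        "the genome is too crowded for the requested design"
    )


def _plant(
    rng, genome: dict[str, np.ndarray], peak: Peak, sspec: PeakSetSpec
) -> list[tuple[str, int]]:
    """Substitute motif copies (and an AT-rich core) into the genome."""
    placed: list[tuple[str, int]] = []
    arr = genome[peak.chrom]
    if sspec.at_core_bp:
        c = peak.center()
        half = sspec.at_core_bp // 2
        lo, hi = max(peak.start, c - half), min(peak.end, c + half)
        core = rng.choice(np.frombuffer(b"AT", dtype=np.uint8), size=hi - lo)
        arr[lo:hi] = core
    if sspec.motif and rng.random() < sspec.motif_prob:
        word = np.frombuffer(sspec.motif.upper().encode(), dtype=np.uint8)
        k = len(word)
        n_copies = int(rng.integers(sspec.motif_copies[0], sspec.motif_copies[1] + 1))
        for _ in range(n_copies):
            if peak.length <= k + 10:
                break
            pos = int(rng.integers(peak.start + 5, peak.end - k - 5))
            arr[pos:pos + k] = word
            placed.append((peak.chrom, pos))
    return placed


def generate(spec: ScenarioSpec) -> SimulatedData:
    """Run the full generator; deterministic given the spec (incl. its seed)."""
    genome_arr = _random_genome(spec)
    states = _random_states(spec)
    segments_by_state: dict[str, list[tuple[str, int, int]]] = {}
    for chrom, ivs in states.intervals.items():
        for s0, s1, lab in ivs:
            segments_by_state.setdefault(lab, []).append((chrom, s0, s1))

    occupied = {chrom: IntervalTree() for chrom in spec.chrom_lengths}
    whitelist = tuple(spec.chrom_lengths)
    peak_sets: dict[str, PeakSet] = {}
    provenance: dict[str, list[dict]] = {}
    realized_overlap: dict[tuple[str, str], float] = {}
    realized_state_target: dict[str, dict[str, float]] = {}
    motif_positions: dict[str, list[tuple[str, int]]] = {}

    for i, sspec in enumerate(spec.peak_sets):
        rng = _rng(spec.seed, 10 + i)
        peaks: list[Peak] = []
        records: list[dict] = []
        planted_all: list[tuple[str, int]] = []
        n_copied = int(round(sspec.source_fraction * sspec.n_peaks))
        if sspec.source is not None and n_copied > 0:
            src = peak_sets[sspec.source]
            if n_copied > len(src):
                raise ValueError(
                    f"set {sspec.name!r}: needs {n_copied} source peaks, "
                    f"{sspec.source!r} has {len(src)}"
                )
            chosen = rng.choice(len(src), size=n_copied, replace=False)
            for idx in sorted(chosen):
                p = src.peaks[idx]
                j = max(1, int(sspec.jitter_frac * p.length))
                shift = int(rng.integers(-j, j + 1))
                start = max(1, p.start + shift)
                end = start + p.length
                if end >= spec.chrom_lengths[p.chrom]:
                    end = spec.chrom_lengths[p.chrom] - 1
                    start = end - p.length
                peak = Peak(p.chrom, start, end, summit=(start + end) // 2)
                peaks.append(peak)
                occupied[peak.chrom].addi(peak.start, peak.end)
                records.append({"source": sspec.source, "source_index": int(idx),
                                "state": None, "motif_at": []})
        n_fresh = sspec.n_peaks - len(peaks)
        state_counts: dict[str, int] = {}
        for _ in range(n_fresh):
            chrom, start, end, target_state = _place_fresh(
                rng, spec, sspec, occupied, segments_by_state
            )
            peaks.append(Peak(chrom, start, end, summit=(start + end) // 2))
            occupied[chrom].addi(start, end)
            records.append({"source": None, "source_index": None,
                            "state": target_state, "motif_at": []})
            if target_state:
                state_counts[target_state] = state_counts.get(target_state, 0) + 1
        # plant sequence features after all placements for this set
        for peak, rec in zip(peaks, records):
            if rec["source"] is not None and not sspec.motif_in_copied:
                continue
            if rec["source"] is not None and sspec.at_core_bp:
                continue  # AT cores only in fresh (specific) peaks
            rec["motif_at"] = _plant(rng, genome_arr, peak, sspec)
            planted_all.extend(rec["motif_at"])
        # PeakSet sorts by coordinate; keep provenance aligned by sorting together
        order = sorted(range(len(peaks)),
                       key=lambda k: (peaks[k].chrom, peaks[k].start, peaks[k].end))
        peaks = [peaks[k] for k in order]
        records = [records[k] for k in order]
        peak_sets[sspec.name] = PeakSet(
            sspec.name, peaks, stringency="1e-2", whitelist=whitelist
        )
        provenance[sspec.name] = records
        motif_positions[sspec.name] = planted_all
        if sspec.source is not None:
            realized_overlap[(sspec.name, sspec.source)] = n_copied / sspec.n_peaks
        if state_counts and n_fresh:
            realized_state_target[sspec.name] = {
                lab: c / n_fresh for lab, c in state_counts.items()
            }

    genome = GenomeSequence({
        chrom: arr.tobytes().decode() for chrom, arr in genome_arr.items()
    })

    tracks = {
        sspec.name: _pileup_track(spec, sspec, peak_sets[sspec.name])
        for sspec in spec.peak_sets
    }

    rng_tss = _rng(spec.seed, 2)
    tss: list[tuple[str, int, str]] = []
    chroms = list(spec.chrom_lengths)
    lens = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    for _ in range(spec.n_tss):
        chrom = chroms[rng_tss.choice(len(chroms), p=lens / lens.sum())]
        pos = int(rng_tss.integers(2000, spec.chrom_lengths[chrom] - 2000))
        strand = "+" if rng_tss.random() < 0.5 else "-"
        tss.append((chrom, pos, strand))

    truth = GroundTruth(
        provenance=provenance,
        realized_overlap=realized_overlap,
        realized_state_target=realized_state_target,
        motif_positions=motif_positions,
    )
    return SimulatedData(
        genome=genome, peak_sets=peak_sets, tracks=tracks,
        states=states, tss=tss, truth=truth, spec=spec,
    )


def _pileup_track(
    spec: ScenarioSpec, sspec: PeakSetSpec, peaks: PeakSet
) -> SignalTrack:
    """Triangular kernel per peak over a uniform noise floor, 10 bp blocks."""
    steps: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, length in spec.chrom_lengths.items():
        n_blocks = -(-length // _TRACK_RES)
        arr = np.full(n_blocks, spec.track_noise)
        for p in peaks:
            if p.chrom != chrom:
                continue
            summit = p.center()
            half = p.length / 2
            b0 = max(0, int((summit - half) // _TRACK_RES))
            b1 = min(n_blocks, int((summit + half) // _TRACK_RES) + 1)
            centres = (np.arange(b0, b1) + 0.5) * _TRACK_RES
            arr[b0:b1] += sspec.amplitude * np.maximum(
                0.0, 1.0 - np.abs(centres - summit) / half
            )
        arr = np.round(arr, 4)
        # run-length encode blocks into bedGraph steps
        change = np.nonzero(np.diff(arr))[0] + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [n_blocks]])
        steps[chrom] = [
            (int(s * _TRACK_RES), int(min(e * _TRACK_RES, length)), float(arr[s]))
            for s, e in zip(starts, ends)
        ]
    return SignalTrack(sspec.name, steps, normalization="synthetic-SPMR")


def correlated_window_tracks(
    chrom_lengths: Mapping[str, int],
    rho: float,
    window: int = 1000,
    seed: int = 0,
    mean: float = 5.0,
    sd: float = 1.0,
    names: tuple[str, str] = ("track_a", "track_b"),
) -> tuple[SignalTrack, SignalTrack]:
    """Two window-constant tracks whose per-window values have Pearson
    correlation ``rho`` by construction (bivariate normal, mean 5 sd 1, so
    negative draws are vanishingly rare and are clipped at 0)."""
    if not (-1 < rho < 1):
        raise ValueError("rho must be in (-1, 1)")
    rng = np.random.default_rng([seed, 1000])
    cov = [[sd ** 2, rho * sd ** 2], [rho * sd ** 2, sd ** 2]]
    steps_a: dict[str, list] = {}
    steps_b: dict[str, list] = {}
    for chrom, length in chrom_lengths.items():
        n = -(-length // window)
        vals = rng.multivariate_normal([mean, mean], cov, size=n)
        vals = np.clip(vals, 0.0, None)
        sa, sb = [], []
        for i in range(n):
            s, e = i * window, min((i + 1) * window, length)
            sa.append((s, e, float(vals[i, 0])))
            sb.append((s, e, float(vals[i, 1])))
        steps_a[chrom] = sa
        steps_b[chrom] = sb
    return (
        SignalTrack(names[0], steps_a, normalization="synthetic"),
        SignalTrack(names[1], steps_b, normalization="synthetic"),
    )


def study_design_spec(seed: int = 0) -> ScenarioSpec:
    """Scenario emulating the study's observed structure.

    Three Hox-like factors on a two-chromosome 0.8 Mb genome: "Ubx" and
    "AbdA" sharing ~90 % of their peaks and both sitting almost entirely in
    accessible ("DNase")-like regions of active (RED/YELLOW) chromatin;
    "AbdB" sharing ~55 % with Ubx plus a specific fraction placed in
    repressive BLUE/BLACK states with planted Exd-Hox motif words and
    AT-rich (narrow-minor-groove) summit cores.
    """
    dnase = PeakSetSpec(
        name="DNase", n_peaks=350, length_min=300, length_mode=600, length_max=1200,
        state_bias={"RED": 0.42, "YELLOW": 0.42, "BLUE": 0.04, "BLACK": 0.08,
                    "GREEN": 0.04},
        amplitude=8.0,
    )
    ubx = PeakSetSpec(
        name="Ubx", n_peaks=300, source="DNase", source_fraction=0.95,
        length_min=400, length_mode=900, length_max=1800, amplitude=10.0,
        state_bias={"RED": 0.5, "YELLOW": 0.5},
    )
    abda = PeakSetSpec(
        name="AbdA", n_peaks=300, source="Ubx", source_fraction=0.90,
        length_min=400, length_mode=900, length_max=1800, amplitude=10.0,
        state_bias={"RED": 0.5, "YELLOW": 0.5},
    )
    abdb = PeakSetSpec(
        name="AbdB", n_peaks=400, source="Ubx", source_fraction=0.55,
        length_min=400, length_mode=900, length_max=1800, amplitude=10.0,
        state_bias={"BLUE": 0.45, "BLACK": 0.45, "GREEN": 0.10},
        motif="TGATTTAT", motif_prob=0.9, motif_copies=(2, 4), at_core_bp=120,
    )
    return ScenarioSpec(
        chrom_lengths={"chr2L": 800_000, "chr2R": 800_000},
        peak_sets=[dnase, ubx, abda, abdb],
        n_tss=300,
        seed=seed,
    )


def recovery_benchmark_spec(seed: int = 0) -> ScenarioSpec:
    """Scenario with known planted quantities for parameter-recovery checks.

    Plants: a 0.89 reciprocal-overlap fraction of "probe" in "ref"; a 2x
    planted motif-copy ratio between "hi" (2 copies/kb) and "lo" (1
    copy/kb) peak sets, with a motif-free "ctrl" set to measure the scanner's
    incidental background match rate; and a BLUE/BLACK placement bias for
    the "biased" set. All peaks are exactly 1 kb so per-kb densities equal
    per-peak copy numbers.
    """
    kb = dict(length_min=1000, length_mode=1000, length_max=1000)
    word = "TTTATGAC"
    return ScenarioSpec(
        chrom_lengths={"chr2L": 3_000_000, "chr2R": 3_000_000},
        peak_sets=[
            PeakSetSpec(name="ref", n_peaks=1000, **kb),
            PeakSetSpec(name="probe", n_peaks=1000, source="ref",
                        source_fraction=0.89, **kb),
            PeakSetSpec(name="hi", n_peaks=200, motif=word, motif_prob=1.0,
                        motif_copies=(2, 2), **kb),
            PeakSetSpec(name="lo", n_peaks=200, motif=word, motif_prob=1.0,
                        motif_copies=(1, 1), **kb),
            PeakSetSpec(name="ctrl", n_peaks=200, **kb),
            PeakSetSpec(name="biased", n_peaks=150,
                        state_bias={"BLUE": 0.5, "BLACK": 0.5}, **kb),
        ],
        n_tss=200,
        seed=seed,
    )


def emulate_study_design(seed: int = 0, out_dir: str | Path | None = None) -> SimulatedData:
    """Generate the study-structure scenario; optionally write all fixtures.

    With ``out_dir`` the genome (FASTA), peak sets (narrowPeak), pileup
    tracks (bedGraph), chromatin states (BED), TSSs (BED6 with strand) and
    the scenario spec (YAML) are written in the standard formats, so the
    fixtures are indistinguishable from real pipeline inputs. Regeneration
    with the same seed is byte-identical.
    """
    data = generate(study_design_spec(seed))
    if out_dir is not None:
        write_fixtures(data, out_dir)
    return data


def write_fixtures(data: SimulatedData, out_dir: str | Path) -> dict[str, Path]:
    from .io import write_bed, write_bedgraph, write_fasta
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = out / "genome.fa"
    write_fasta(data.genome, paths["genome"])
    for name, ps in data.peak_sets.items():
        paths[f"peaks_{name}"] = out / f"{name}.narrowPeak"
        write_bed(ps, paths[f"peaks_{name}"], narrowpeak=True)
    for name, track in data.tracks.items():
        paths[f"track_{name}"] = out / f"{name}.bdg"
        write_bedgraph(track, paths[f"track_{name}"])
    paths["states"] = out / "chromatin_states.bed"
    data.states.write_bed(paths["states"])
    paths["tss"] = out / "tss.bed"
    with open(paths["tss"], "w") as fh:
        for chrom, pos, strand in data.tss:
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\ttss\t0\t{strand}\n")
    paths["scenario"] = out / "scenario.yaml"
    data.spec.to_yaml(paths["scenario"])
    from .shape import synthetic_shape_table, write_shape_table
    paths["shape_table"] = out / "pentamer_mgw_synthetic.tsv"
    write_shape_table(synthetic_shape_table(), paths["shape_table"])
    paths["config"] = out / "analysis.yaml"
    cfg = {
        "genome": "genome.fa",
        "peak_sets": [
            {"name": name, "path": f"{name}.narrowPeak", "stringency": "1e-2"}
            for name in data.peak_sets
        ],
        "tracks": [{"name": name, "path": f"{name}.bdg"} for name in data.tracks],
        "states": "chromatin_states.bed",
        "tss": "tss.bed",
        "shape_table": "pentamer_mgw_synthetic.tsv",
    }
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=False))
    return paths


def read_tss_bed(path) -> list[tuple[str, int, str]]:
    """Read a BED6 of TSS positions (start column, strand column)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        if len(f) == 1:
            f = line.split()
        out.append((f[0], int(f[1]), f[5] if len(f) > 5 else "+"))
    return out
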