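"""End-to-end orchestration: run every analysis stage over a set of input
files and collect the results in one deterministic report.

Stages run in dependency order (overlaps -> partitions -> correlations ->
differential ranking -> fingerprints -> motif statistics -> state
prevalence -> summit profiles). A failure in one branch is recorded and
does not abort independent branches; the report's ``errors`` mapping and
the CLI exit status reflect any failure. Given fixed inputs, configuration
and seed the report is identical between runs (no timestamps inside
result tables; provenance records inputs, parameters and package version).
"""

from __future__ import annotations

import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .core import AnalysisConfig, GenomeSequence, PeakSet, SignalTrack
from .intervals import (
    STATES_WITH_UNKNOWN, StateAnnotation, reciprocal_overlap, state_prevalence,
)
from .io import read_bedgraph, read_fasta, read_peaks
from .kmers import KmerPanel, build_tss_background, extract_peak_sequences, fingerprint
from .motifs import (
    bundled_pwm, load_pwms, match_density, motif_set_enrichment, scan,
)
from .shape import load_shape_table, summit_profile
from .simulate import read_tss_bed
from .tracks import bin_track, differential_rank, peak_median_signal, profile_correlation

log = logging.getLogger("hoxspec")


@dataclass
class PipelineReport:
    """All stage outputs plus a provenance block.

    Tables are pandas DataFrames keyed by stage; ``errors`` maps a stage
    name to the exception it raised (empty when everything succeeded);
    ``skipped`` maps optional stages to the reason they did not run.
    """

    provenance: dict[str, Any]
    overlaps: pd.DataFrame | None = None
    correlations: pd.DataFrame | None = None
    median_signal: pd.DataFrame | None = None
    differential: pd.DataFrame | None = None
    fingerprints: pd.DataFrame | None = None
    motif_enrichment: pd.DataFrame | None = None
    motif_density: pd.DataFrame | None = None
    state_prevalence: pd.DataFrame | None = None
    profiles: pd.DataFrame | None = None
    errors: dict[str, str] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors

    def tables(self) -> dict[str, pd.DataFrame]:
        names = ("overlaps", "correlations", "median_signal", "differential",
                 "fingerprints", "motif_enrichment", "motif_density",
                 "state_prevalence", "profiles")
        return {n: getattr(self, n) for n in names if getattr(self, n) is not None}

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary: dict[str, Any] = {"provenance": self.provenance,
                                   "errors": self.errors, "skipped": self.skipped,
                                   "tables": {}}
        for name, df in self.tables().items():
            path = out / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False, float_format="%.6g")
            summary["tables"][name] = path.name
        (out / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    base = Path(path).resolve().parent
    for key in ("genome", "states", "tss", "shape_table"):
        if cfg.get(key):
            cfg[key] = str((base / cfg[key]))
    for entry in cfg.get("peak_sets", []) + cfg.get("tracks", []):
        entry["path"] = str(base / entry["path"])
    cfg["pwms"] = [str(base / p) for p in cfg.get("pwms", [])]
    cfg["panels"] = [str(base / p) for p in cfg.get("panels", [])]
    return cfg


def _check_inputs(cfg: dict) -> None:
    missing = []
    for key in ("genome", "states", "tss", "shape_table"):
        if cfg.get(key) and not Path(cfg[key]).exists():
            missing.append(f"{key}: {cfg[key]}")
    for entry in cfg.get("peak_sets", []) + cfg.get("tracks", []):
        if not Path(entry["path"]).exists():
            missing.append(entry["path"])
    for p in cfg.get("pwms", []) + cfg.get("panels", []):
        if not Path(p).exists():
            missing.append(p)
    if missing:
        raise FileNotFoundError("missing pipeline inputs: " + ", ".join(missing))


def run_pipeline(cfg: dict) -> PipelineReport:
    """Execute every configured stage; see module docstring for semantics.

    ``cfg`` is the dictionary form of the YAML configuration: ``genome``,
    ``peak_sets`` (name/path/stringency entries), optional ``tracks``,
    ``states``, ``tss``, ``shape_table``, ``pwms``, ``panels``, an
    ``analysis`` block of :class:`AnalysisConfig` overrides, and an
    optional ``differential`` list of {peaks, a, b, top} comparisons.
    """
    _check_inputs(cfg)
    ac = AnalysisConfig(**cfg.get("analysis", {}))
    report = PipelineReport(provenance={
        "version": __version__,
        "config": {k: v for k, v in cfg.items()},
        "seed": ac.random_seed,
    })

    genome = read_fasta(cfg["genome"])
    whitelist = tuple(cfg.get("whitelist") or genome.chrom_lengths())
    peak_sets: dict[str, PeakSet] = {}
    for entry in cfg.get("peak_sets", []):
        fmt = entry.get("format", "narrowPeak")
        peak_sets[entry["name"]] = read_peaks(
            entry["path"], format=fmt, name=entry["name"],
            stringency=entry.get("stringency"), whitelist=whitelist,
        )
    tracks: dict[str, SignalTrack] = {
        entry["name"]: read_bedgraph(entry["path"], name=entry["name"])
        for entry in cfg.get("tracks", [])
    }
    set_names = list(peak_sets)

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - independent branches continue
                log.error("stage %s failed: %s", name, exc)
                log.debug("%s", traceback.format_exc())
                report.errors[name] = f"{type(exc).__name__}: {exc}"
        return deco

    @stage("overlaps")
    def _overlaps():
        rows = []
        f = ac.reciprocal_overlap_fraction
        for i, a in enumerate(set_names):
            for b in set_names[i + 1:]:
                res = reciprocal_overlap(peak_sets[a], peak_sets[b], f)
                rows.append({
                    "set_a": a, "set_b": b, "n_a": res.n_a, "n_b": res.n_b,
                    "n_a_overlapping": res.n_a_overlapping,
                    "n_b_overlapping": res.n_b_overlapping,
                    "pct_a": res.pct_a, "pct_b": res.pct_b,
                })
        report.overlaps = pd.DataFrame(rows)

    @stage("correlations")
    def _correlations():
        if len(tracks) < 2:
            report.skipped["correlations"] = "fewer than two tracks configured"
            return
        profiles = {n: bin_track(t, genome, ac.window_size_bp)
                    for n, t in tracks.items()}
        rows = []
        names = list(profiles)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                r, n = profile_correlation(profiles[a], profiles[b])
                rows.append({"track_a": a, "track_b": b, "pearson_r": r,
                             "n_windows": n, "window_bp": ac.window_size_bp})
        report.correlations = pd.DataFrame(rows)

    @stage("median_signal")
    def _median_signal():
        if not tracks:
            report.skipped["median_signal"] = "no tracks configured"
            return
        rows = []
        for sname, ps in peak_sets.items():
            for tname, track in tracks.items():
                summ = peak_median_signal(ps, track)
                q1, q2, q3 = summ.quartiles()
                rows.append({"peak_set": sname, "track": tname,
                             "q1": q1, "median": q2, "q3": q3, "n_peaks": len(ps)})
        report.median_signal = pd.DataFrame(rows)

    @stage("differential")
    def _differential():
        jobs = cfg.get("differential", [])
        if not jobs:
            report.skipped["differential"] = "no differential comparisons configured"
            return
        rows = []
        for job in jobs:
            ranking = differential_rank(
                peak_sets[job["peaks"]], tracks[job["a"]], tracks[job["b"]],
            )
            top = ranking.top(int(job["top"]))
            for rank, i in enumerate(ranking.order[: int(job["top"])], 1):
                p = ranking.peaks.peaks[i]
                rows.append({"peaks": job["peaks"], "a": job["a"], "b": job["b"],
                             "rank": rank, "chrom": p.chrom, "start": p.start,
                             "end": p.end, "log2_ratio": ranking.scores[i]})
            peak_sets[top.name] = top  # downstream stages may reference it
        report.differential = pd.DataFrame(rows)

    @stage("fingerprints")
    def _fingerprints():
        if not cfg.get("tss"):
            report.skipped["fingerprints"] = "no TSS file configured"
            return
        tss = read_tss_bed(cfg["tss"])
        background = build_tss_background(tss, genome, span=2000)
        panels = ([KmerPanel.read(p) for p in cfg["panels"]]
                  if cfg.get("panels")
                  else [KmerPanel.bundled("hox_5mers"), KmerPanel.bundled("exd_hox_8mers")])
        rows = []
        for sname, ps in peak_sets.items():
            seqs = extract_peak_sequences(ps, genome)
            for panel in panels:
                fp = fingerprint(seqs, background, panel)
                df = fp.to_frame()
                df.insert(0, "peak_set", sname)
                df.insert(1, "k", panel.k)
                rows.append(df)
        report.fingerprints = pd.concat(rows, ignore_index=True)

    @stage("motifs")
    def _motifs():
        pwms = (load_pwms(cfg["pwms"][0]) if cfg.get("pwms") else
                [bundled_pwm("hox_ubx_like_synthetic"),
                 bundled_pwm("hox_abdb_like_synthetic")])
        for extra in cfg.get("pwms", [])[1:]:
            pwms.extend(load_pwms(extra))
        dens_rows, enr_rows = [], []
        background = None
        if cfg.get("tss"):
            tss = read_tss_bed(cfg["tss"])
            background = build_tss_background(tss, genome, span=2000)
        for sname, ps in peak_sets.items():
            seqs = extract_peak_sequences(ps, genome)
            for pwm in pwms:
                cutoff = pwm.score_threshold(ac.pwm_match_pvalue)
                matches = scan(seqs, pwm, cutoff)
                dens = match_density(ps, matches)
                dens_rows.append({"peak_set": sname, "pwm": pwm.name,
                                  "median_per_kb": dens.median,
                                  "mean_per_kb": float(dens.densities.mean()),
                                  "n_peaks": len(ps)})
            if background is not None:
                for res in motif_set_enrichment(seqs, background, pwms,
                                                match_pvalue=ac.pwm_match_pvalue):
                    enr_rows.append({"peak_set": sname, "pwm": res.motif,
                                     "p_value": res.p_value, "score": res.score,
                                     "rank": res.rank})
        report.motif_density = pd.DataFrame(dens_rows)
        if enr_rows:
            report.motif_enrichment = pd.DataFrame(enr_rows)

    @stage("state_prevalence")
    def _states():
        if not cfg.get("states"):
            report.skipped["state_prevalence"] = "no chromatin-state annotation configured"
            return
        ann = StateAnnotation.read_bed(cfg["states"])
        rows = []
        genome_comp = ann.genome_composition(genome.chrom_lengths())
        rows.append({"peak_set": "genome", **genome_comp.fractions})
        for sname, ps in peak_sets.items():
            prev = state_prevalence(ps, ann)
            rows.append({"peak_set": sname, **prev.fractions})
        report.state_prevalence = pd.DataFrame(
            rows, columns=["peak_set", *STATES_WITH_UNKNOWN]
        )

    @stage("profiles")
    def _profiles():
        table = None
        if cfg.get("shape_table"):
            table = load_shape_table(cfg["shape_table"])
        rows = []
        for sname, ps in peak_sets.items():
            modes = ["gc"] + (["mgw"] if table is not None else [])
            for mode in modes:
                prof = summit_profile(
                    ps, genome, mode=mode, table=table,
                    span=ac.profile_span_bp, window=ac.smooth_window_bp,
                    step=ac.smooth_step_bp,
                )
                df = prof.to_frame()
                df.insert(0, "peak_set", sname)
                df.insert(1, "mode", mode)
                rows.append(df)
        if table is None:
            report.skipped["profiles_mgw"] = "no pentamer shape table configured"
        report.profiles = pd.concat(rows, ignore_index=True)

    return report
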