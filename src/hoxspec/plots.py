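"""Minimal plotting: fingerprint bar charts and summit-profile lines.

Tables are the primary output of the pipeline; these helpers exist for
quick visual inspection of the two panel types users most often look at.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .kmers import FingerprintResult  # noqa: E402
from .shape import SummitProfile  # noqa: E402


def plot_fingerprint(
    results: dict[str, FingerprintResult], path: str | Path
) -> None:
    """Grouped bars of log2 k-mer enrichment, one group per peak set."""
    fig, ax = plt.subplots(figsize=(7, 4))
    first = next(iter(results.values()))
    kmers = first.panel.kmers
    width = 0.8 / len(results)
    for j, (name, fp) in enumerate(results.items()):
        vals = [e if e is not None else 0.0 for e in fp.enrichment]
        ax.bar([i + j * width for i in range(len(kmers))], vals, width, label=name)
    ax.set_xticks([i + 0.4 for i in range(len(kmers))])
    ax.set_xticklabels(kmers, rotation=45, ha="right")
    ax.set_ylabel("log2 enrichment vs background")
    ax.axhline(0, color="k", lw=0.5)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_profiles(profiles: dict[str, SummitProfile], path: str | Path) -> None:
    """Smoothed summit-centred profiles, one line per peak set."""
    fig, ax = plt.subplots(figsize=(6, 4))
    mode = None
    for name, prof in profiles.items():
        ax.plot(prof.smoothed_positions, prof.smoothed, label=name)
        mode = prof.mode
    ax.set_xlabel("position relative to summit (bp)")
    ax.set_ylabel("minor groove width (Å)" if mode == "mgw" else "GC fraction")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
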