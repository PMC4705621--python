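# hoxspec

Comparative ChIP-Seq binding-specificity analysis for transcription-factor
families, built around the question the Drosophila Hox proteins pose: when
several related factors (Ubx, Abd-A, Abd-B and their Exd/Hth cofactor
complexes) bind overlapping but distinct genomic repertoires, which peaks
are shared, what DNA sequence and shape features distinguish the specific
ones, and how does binding relate to chromatin accessibility and state?

The package takes standard files — peak calls (BED/narrowPeak), normalized
pileup tracks (bedGraph), a genome (FASTA), a chromatin colour-state
annotation (BED), TSS coordinates, PWMs (JASPAR-style) and k-mer panels —
and provides:

- **Peak-set algebra** — reciprocal-overlap analysis
  (`ov ≥ f·len` on *both* peaks, default f = 0.05), common/specific
  partitions, per-focal-set Venn counts, stringent-vs-relaxed containment.
- **Track statistics** — binding score per 1 kb window with Pearson
  correlation between factors, per-peak median accessibility, and
  differential peak ranking by `D = log2((a + c)/(b + c))`.
- **K-mer fingerprints** — panel enrichment
  `log2(freq/kb in peaks / freq/kb in TSS-upstream background)`.
- **PWM analysis** — scanning with *exact* score thresholds
  (the null score distribution is computed by dynamic programming on a
  0.01-bit lattice and verified against full 4^w enumeration), per-peak
  match density `(matches/length)×1000` with rank-sum comparisons, and a
  Poisson motif-set enrichment score `log10(1/p)`.
- **Chromatin-state prevalence** — fraction of peak length in each of the
  five colour states (RED/YELLOW active, BLUE Polycomb, BLACK repressive,
  GREEN HP1) plus UNKNOWN.
- **DNA-shape and GC profiles** — summit-centred 2 kb minor-groove-width
  (pentamer lookup) and GC profiles, smoothed with a 100 bp window at
  10 bp steps.
- **A ground-truthed simulator** — genomes, peak sets with controlled
  reciprocal overlap, planted motifs, biased chromatin states, and
  correlated pileup tracks, so every stage is verifiable end to end
  without any external dataset.

See `docs/methods.md` for the statistical details and design rationale.

## Worked example

Generate a synthetic scenario that mirrors the biological structure —
"Ubx" and "AbdA" sharing ~90 % of their peaks inside accessible active
chromatin, "AbdB" sharing only ~55 % with Ubx plus a specific fraction in
repressive states carrying planted Exd-Hox words and AT-rich summit
cores — then analyse it:

```bash
hoxspec simulate --seed 1 --out fixtures/
hoxspec run --config fixtures/analysis.yaml --out report/
```

or in Python:

```python
import hoxspec as hs

data = hs.emulate_study_design(seed=1)

res = hs.reciprocal_overlap(data.peak_sets["AbdB"], data.peak_sets["Ubx"], 0.05)
print(f"{res.pct_a:.1f}% of AbdB peaks overlap Ubx")      # 55.0

common, specific = hs.partition_by_reference(
    data.peak_sets["AbdB"], data.peak_sets["Ubx"])
prev = hs.state_prevalence(specific, data.states)
print(f"AbdB-specific peaks in BLUE+BLACK: {prev['BLUE'] + prev['BLACK']:.3f}")  # 0.894

bg = hs.build_tss_background(data.tss, data.genome)
fp = hs.fingerprint(hs.extract_peak_sequences(specific, data.genome),
                    bg, hs.KmerPanel.bundled("exd_hox_8mers"))
print(f"TGATTTAT log2 enrichment: {fp.enrichment[0]:.2f}")  # 3.71
```

The printed numbers recover the scenario's ground truth: the 55 %
AbdB-in-Ubx overlap is the planted copy fraction, the 0.89 BLUE+BLACK
fraction reflects the repressive-state placement bias of the specific
peaks, and the strong TGATTTAT enrichment reflects the planted Exd-Hox
words (seed 1; other seeds give values within sampling error).

Every stage is also available as a subcommand on real files, e.g.

```bash
hoxspec overlap --a ubx.narrowPeak --b abda.narrowPeak -f 0.05
hoxspec corr --a ubx.bdg --b abda.bdg --genome dm3.fa -w 1000
hoxspec profile --peaks abdb.narrowPeak --genome dm3.fa --mode mgw --table pentamers.tsv
```

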