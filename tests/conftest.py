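import numpy as np
import pytest

import hoxspec as hs


@pytest.fixture(scope="session")
def study_design():
    """One shared realisation of the study-structure scenario."""
    return hs.emulate_study_design(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def toy_genome():
    rng = np.random.default_rng(3)
    return hs.GenomeSequence({
        "chrA": "".join(rng.choice(list("ACGT"), 100_000)),
        "chrB": "".join(rng.choice(list("ACGT"), 60_000)),
    })


def random_peakset(rng, name="peaks", n=100, chroms=("chrA", "chrB"),
                   chrom_len=100_000, min_len=50, max_len=2000):
    """Random, possibly overlapping peaks for oracle comparisons."""
    peaks = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        length = int(rng.integers(min_len, max_len))
        start = int(rng.integers(0, chrom_len - length))
        peaks.append(hs.Peak(chrom, start, start + length))
    return hs.PeakSet(name, peaks, whitelist=chroms)


def random_track(rng, chrom_lens={"chrA": 100_000, "chrB": 60_000},
                 n_steps=60, max_value=8.0):
    """Random sparse non-overlapping step function."""
    steps = {}
    for chrom, chrom_len in chrom_lens.items():
        bounds = np.sort(rng.choice(chrom_len, size=2 * n_steps, replace=False))
        ss = []
        for i in range(0, len(bounds), 2):
            if rng.random() < 0.7:  # leave gaps -> implicit zeros exercised
                val = float(np.round(rng.uniform(0, max_value), 3))
                ss.append((int(bounds[i]), int(bounds[i + 1]), val))
        steps[chrom] = ss
    return hs.SignalTrack("random", steps)
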