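"""Shared fixtures: a tiny hand-built assembly and one session-scoped
default simulation run through the full fragment -> CMBS pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from mcmchec import (
    GenomeAssembly,
    PeakCallConfig,
    SimConfig,
    build_genome,
    emit_tracks,
    sample_fragments,
)
from mcmchec.peakcall import CMBS
from mcmchec.pipeline import call_from_fragments, match_to_truth, recovery_stats

SIM_SEED = 1
SIM_MAX_PEAKS = 700


@dataclass
class SimRun:
    config: object
    assembly: object
    truth: object
    fragments: list
    cmbs: list
    matched: object
    stats: dict
    ssdna: object
    dyad: object
    brdu: object


@pytest.fixture(scope="session")
def sim() -> SimRun:
    """Default synthetic dataset run end to end once per test session."""
    config = SimConfig(seed=SIM_SEED)
    assembly, truth = build_genome(config)
    fragments = sample_fragments(config, truth)
    cmbs = call_from_fragments(
        fragments, assembly, PeakCallConfig(max_peaks=SIM_MAX_PEAKS)
    )
    matched = match_to_truth(cmbs, truth.origins)
    stats = recovery_stats(matched)
    ssdna, dyad, brdu = emit_tracks(config, truth, assembly)
    return SimRun(config, assembly, truth, fragments, cmbs, matched, stats,
                  ssdna, dyad, brdu)


@pytest.fixture
def tiny_assembly() -> GenomeAssembly:
    """Two short chromosomes without sequence, for interval/track tests."""
    return GenomeAssembly(("chr1", "chr2"), {"chr1": 1000, "chr2": 600})


def make_cmbs(chrom: str, midpoint: int, rank: int, abundance: float = 1.0,
              midpoint_signal: float | None = None) -> CMBS:
    return CMBS(chrom, midpoint, rank, abundance,
                abundance if midpoint_signal is None else midpoint_signal)


def random_smoothed_tracks(rng: np.random.Generator, lengths: dict[str, int]):
    """Random non-negative 'smoothed' track pairs for peak-caller tests."""
    from mcmchec.core_io import GenomeAssembly
    from mcmchec.coverage import FULL_LENGTH, MIDPOINT, CoverageTrack

    assembly = GenomeAssembly(tuple(lengths), dict(lengths))
    full_vals, mid_vals = {}, {}
    for chrom, n in lengths.items():
        base = rng.random(n) * (rng.random(n) < 0.05)
        # overlay a few clear peaks so the caller has structure to find
        for _ in range(max(n // 2000, 1)):
            p = rng.integers(0, n)
            w = int(rng.integers(20, 120))
            lo, hi = max(p - w, 0), min(p + w, n)
            base[lo:hi] += rng.random() * 20 * np.hanning(hi - lo)
        full_vals[chrom] = base
        mid_vals[chrom] = np.roll(base, int(rng.integers(-30, 30))) * rng.random(n)
    full = CoverageTrack(assembly, full_vals, mode=FULL_LENGTH, smoothed_window=10)
    mid = CoverageTrack(assembly, mid_vals, mode=MIDPOINT, smoothed_window=10)
    return full, mid


def naive_call_cmbs(full_track, mid_track, config):
    """Reference peak caller: literally re-scans the entire genome at every
    iteration (single concatenated argmax), independent of the cached
    production implementation."""
    order = full_track.assembly.chrom_names
    lengths = [len(full_track.values[c]) for c in order]
    offsets = np.concatenate(([0], np.cumsum(lengths)))
    full = np.concatenate([full_track.values[c] for c in order]).astype(float)
    mid = np.concatenate([mid_track.values[c] for c in order]).astype(float)

    peaks = []
    while len(peaks) < config.max_peaks:
        gi = int(np.argmax(full))
        if full[gi] <= 0:
            break
        ci = int(np.searchsorted(offsets, gi, side="right") - 1)
        chrom, seg_lo, seg_hi = order[ci], offsets[ci], offsets[ci + 1]
        lo = max(gi - config.refine_radius, seg_lo)
        hi = min(gi + config.refine_radius + 1, seg_hi)
        mi = lo + int(np.argmax(mid[lo:hi]))
        peaks.append(
            CMBS(chrom, int(mi - seg_lo), len(peaks) + 1,
                 float(full[gi]), float(mid[mi]))
        )
        zlo = max(mi - config.zero_radius, seg_lo)
        zhi = min(mi + config.zero_radius + 1, seg_hi)
        full[zlo:zhi] = 0.0
        mid[zlo:zhi] = 0.0
    return peaks
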