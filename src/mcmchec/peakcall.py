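"""Iterative identification of candidate Mcm binding sites (CMBSs).

The caller operates on two smoothed tracks built from 51-100 bp inserts:
one quantified over entire fragment lengths (wide, robust peaks) and one
quantified at fragment midpoints (sharp peaks). Each iteration

  1. takes the global argmax of the full-length track,
  2. refines it to the best midpoint-track coordinate within
     ``refine_radius`` (60 bp) of that position — this becomes the CMBS
     midpoint,
  3. zeroes both tracks within ``zero_radius`` (500 bp) of the midpoint,

and repeats until the track is exhausted or ``max_peaks`` is reached.
Abundance is recorded at selection time from the full-length track
(step-1 value); the midpoint-track value at the final coordinate is kept
alongside and is what downstream cohort analyses quantify.

Ties in either argmax break to the lowest chromosome in assembly order,
then the lowest coordinate, so output is platform-independent.

Input tracks are copied before zeroing; the caller never mutates them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import CoverageTrack


@dataclass(frozen=True)
class CMBS:
    chrom: str
    midpoint: int
    rank: int
    abundance: float
    midpoint_signal: float


@dataclass
class PeakCallConfig:
    smooth_window: int = 10
    refine_radius: int = 60
    zero_radius: int = 500
    max_peaks: int = 100_000
    exclusion_margin: int = 100
    exclusion_intervals: dict[str, list[tuple[str, int, int]]] = field(
        default_factory=dict
    )  # keys 'rdna', 'ty'

    def __post_init__(self) -> None:
        if min(self.smooth_window, self.refine_radius, self.zero_radius,
               self.max_peaks, self.exclusion_margin) <= 0:
            raise ValueError("all config values must be positive")
        if self.refine_radius >= self.zero_radius:
            raise ValueError("refine_radius must be < zero_radius")


def _global_argmax(values: dict[str, np.ndarray], chrom_order: tuple[str, ...]):
    """(chrom, pos, value) of the global maximum; ties break to the first
    chromosome in assembly order, then the lowest coordinate (np.argmax
    already returns the first occurrence within a chromosome)."""
    best = None
    for chrom in chrom_order:
        v = values[chrom]
        if len(v) == 0:
            continue
        pos = int(np.argmax(v))
        val = v[pos]
        if best is None or val > best[2]:
            best = (chrom, pos, float(val))
    return best


def call_cmbs(
    full_track: CoverageTrack,
    mid_track: CoverageTrack,
    config: PeakCallConfig | None = None,
) -> list[CMBS]:
    """Run the iterative peak caller; returns CMBSs ranked by abundance.

    Caches per-chromosome maxima so only the chromosome touched by
    zeroing is re-scanned each iteration.
    """
    config = config or PeakCallConfig()
    if full_track.smoothed_window == 0 or mid_track.smoothed_window == 0:
        raise ValueError("peak calling requires smoothed tracks")
    if full_track.assembly.chrom_names != mid_track.assembly.chrom_names:
        raise ValueError("tracks on different assemblies")

    order = full_track.assembly.chrom_names
    full = {c: full_track.values[c].copy() for c in order}
    mid = {c: mid_track.values[c].copy() for c in order}

    # per-chromosome (argmax, max) cache for the full-length track
    cache = {c: (int(np.argmax(full[c])), float(np.max(full[c], initial=0.0)))
             if len(full[c]) else (0, 0.0) for c in order}

    peaks: list[CMBS] = []
    while len(peaks) < config.max_peaks:
        # max() returns the first among ties, i.e. the earliest chromosome
        chrom = max(order, key=lambda c: cache[c][1])
        pos, val = cache[chrom]
        if val <= 0:
            break

        # refine on the midpoint track within +/- refine_radius
        n = len(mid[chrom])
        lo = max(pos - config.refine_radius, 0)
        hi = min(pos + config.refine_radius + 1, n)
        local = mid[chrom][lo:hi]
        midpoint = lo + int(np.argmax(local))
        mid_val = float(mid[chrom][midpoint])

        peaks.append(
            CMBS(chrom, midpoint, len(peaks) + 1, abundance=val,
                 midpoint_signal=mid_val)
        )

        zlo = max(midpoint - config.zero_radius, 0)
        zhi = min(midpoint + config.zero_radius + 1, n)
        full[chrom][zlo:zhi] = 0.0
        mid[chrom][zlo:zhi] = 0.0
        cache[chrom] = (int(np.argmax(full[chrom])), float(np.max(full[chrom])))
    return peaks


def _distance_to_interval(pos: int, start: int, end: int) -> int:
    """bp from a point to a half-open interval; 0 if inside."""
    if pos < start:
        return start - pos
    if pos >= end:
        return pos - (end - 1)
    return 0


def apply_exclusions(
    cmbs_list: list[CMBS], config: PeakCallConfig
) -> list[CMBS]:
    """Collapse rDNA peaks to the single best-ranked one, drop peaks within
    ``exclusion_margin`` bp (inclusive) of Ty intervals, then renumber
    ranks consecutively."""
    rdna = config.exclusion_intervals.get("rdna", [])
    ty = config.exclusion_intervals.get("ty", [])

    keep: list[CMBS] = []
    best_rdna_seen: dict[int, int] = {}  # interval index -> best rank kept
    for c in sorted(cmbs_list, key=lambda x: x.rank):
        in_rdna = None
        for i, (chrom, s, e) in enumerate(rdna):
            if c.chrom == chrom and s <= c.midpoint < e:
                in_rdna = i
                break
        if in_rdna is not None:
            if in_rdna in best_rdna_seen:
                continue  # only the best-ranked rDNA peak survives
            best_rdna_seen[in_rdna] = c.rank
        near_ty = any(
            c.chrom == chrom
            and _distance_to_interval(c.midpoint, s, e) <= config.exclusion_margin
            for chrom, s, e in ty
        )
        if near_ty:
            continue
        keep.append(c)

    return [
        CMBS(c.chrom, c.midpoint, i + 1, c.abundance, c.midpoint_signal)
        for i, c in enumerate(keep)
    ]


def rank_abundance_curve(cmbs_list: list[CMBS]) -> pd.DataFrame:
    """(rank, abundance) table; inspected on a log scale to locate the
    drop-off that marks genome exhaustion."""
    if not cmbs_list:
        raise ValueError("empty CMBS list")
    df = pd.DataFrame(
        {"rank": [c.rank for c in cmbs_list],
         "abundance": [c.abundance for c in cmbs_list]}
    ).sort_values("rank", ignore_index=True)
    return df
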