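"""GC skew of the Watson strand and its composite across site midpoints.

Skew at position x is (G - C) / (G + C) counted over Watson-strand bases
in an odd window centered at x (default 51 bp). Replication leaves a
strand-composition footprint: following either strand 5'->3' across an
origin, skew rises, because the lagging-strand template spends more time
single-stranded and its cytosines deaminate faster.

Undefined positions (window off the chromosome, or G + C = 0 after
excluding Ns) are NaN, never 0 — zero is a meaningful skew value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import GenomeAssembly, SignalTrack


def skew_track(assembly: GenomeAssembly, window: int = 51) -> SignalTrack:
    """Per-bp (G-C)/(G+C) over a centered odd window; Ns are excluded
    from both counts."""
    if window % 2 == 0:
        raise ValueError("window must be odd (the midpoint must be a base)")
    if assembly.sequence is None:
        raise ValueError("assembly carries no sequence")
    half = window // 2
    track = SignalTrack(assembly)
    for chrom in assembly.chrom_names:
        seq = np.frombuffer(
            assembly.sequence[chrom].upper().encode("ascii"), dtype=np.uint8
        )
        n = len(seq)
        g = np.concatenate(([0], np.cumsum(seq == ord("G"))))
        c = np.concatenate(([0], np.cumsum(seq == ord("C"))))
        out = np.full(n, np.nan)
        if n >= window:
            centers = np.arange(half, n - half)
            lo, hi = centers - half, centers + half + 1
            gs = (g[hi] - g[lo]).astype(float)
            cs = (c[hi] - c[lo]).astype(float)
            tot = gs + cs
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = np.where(tot > 0, (gs - cs) / tot, np.nan)
            out[half : n - half] = vals
        track.values[chrom] = out
    return track


def composite_skew(cmbs_subset, skew: SignalTrack, half_width: int = 200) -> pd.DataFrame:
    """Mean skew per offset in [-half_width, +half_width] across windows
    centered on CMBS midpoints; clipped windows dropped, NaNs excluded
    position-wise. Columns: offset, mean, n."""
    if not cmbs_subset:
        raise ValueError("empty CMBS subset")
    rows = []
    for c in cmbs_subset:
        v = skew.values[c.chrom]
        lo, hi = c.midpoint - half_width, c.midpoint + half_width + 1
        if lo < 0 or hi > len(v):
            continue
        rows.append(v[lo:hi])
    if not rows:
        raise ValueError("all windows clipped at chromosome ends")
    mat = np.vstack(rows)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(mat, axis=0)
    return pd.DataFrame(
        {
            "offset": np.arange(-half_width, half_width + 1),
            "mean": mean,
            "n": np.sum(~np.isnan(mat), axis=0),
        }
    )


def skew_reversal_stat(profile: pd.DataFrame, inner_half: int = 25) -> dict:
    """Quantify the origin signature of a composite skew profile.

    outer_step: mean over the downstream half minus mean over the upstream
    half, both excluding the central +/- inner_half window — the rise in
    skew across the site. inner_deviation: central-window mean minus the
    midpoint of the two outer means — negative when the short reversal at
    the midpoint (the two Mcm hexamers cross over before diverging) is
    present.
    """
    off = profile["offset"].to_numpy()
    m = profile["mean"].to_numpy()
    up = m[(off < -inner_half)]
    down = m[(off > inner_half)]
    inner = m[np.abs(off) <= inner_half]
    up_mean = float(np.nanmean(up)) if len(up) else float("nan")
    down_mean = float(np.nanmean(down)) if len(down) else float("nan")
    inner_mean = float(np.nanmean(inner)) if len(inner) else float("nan")
    return {
        "outer_step": down_mean - up_mean,
        "inner_deviation": inner_mean - (up_mean + down_mean) / 2.0,
    }
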