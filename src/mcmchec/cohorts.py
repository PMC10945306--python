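"""Rank-defined cohorts of CMBSs, composite profiles over external signal
tracks, and the licensing-fraction inference.

Cohorts are consecutive rank blocks (groups of 200 for the ssDNA
replication profiles, 500 for nucleosome-dyad composites, 1100 for motif
and skew composites). Cohort abundance is summarized by the median of
member midpoint-track signals, normalized so the top cohort reads 100.

Licensing: the fraction of cells in which a site carries a loaded Mcm
double hexamer. Direct measurements exist only for a handful of strong
origins; a proportional fit through those calibration points anchors the
top cohort, and every other cohort is scaled by its relative abundance
(e.g. a cohort at 1.5% of the top cohort's abundance with a 69% anchor
is licensed in ~1% of cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import SignalTrack


@dataclass
class Cohort:
    label: str
    rank_lo: int
    rank_hi: int  # inclusive
    members: list = field(default_factory=list)
    median_abundance: float = 0.0
    normalized_abundance: float = 0.0


def make_cohorts(cmbs_list, group_size: int, n_groups: int) -> list[Cohort]:
    """Split the top group_size*n_groups CMBSs into consecutive rank blocks.

    Medians come from midpoint_signal; normalization sets the top cohort
    to 100, making downstream ratios scale-invariant.
    """
    if group_size * n_groups > len(cmbs_list):
        raise ValueError(
            f"need {group_size * n_groups} CMBSs, have {len(cmbs_list)}"
        )
    ranked = sorted(cmbs_list, key=lambda c: c.rank)
    cohorts = []
    for k in range(n_groups):
        block = ranked[k * group_size : (k + 1) * group_size]
        med = float(np.median([c.midpoint_signal for c in block]))
        cohorts.append(
            Cohort(
                label=f"{block[0].rank}-{block[-1].rank}",
                rank_lo=block[0].rank,
                rank_hi=block[-1].rank,
                members=block,
                median_abundance=med,
            )
        )
    top = cohorts[0].median_abundance
    if top <= 0:
        raise ValueError("top cohort has non-positive median abundance")
    for c in cohorts:
        c.normalized_abundance = 100.0 * c.median_abundance / top
    return cohorts


def cohort_profile(cohort: Cohort, track: SignalTrack, half_width: int) -> pd.DataFrame:
    """Position-wise mean of the track over member-centered windows.

    End-clipped windows are dropped; missing values are excluded
    position-wise. Columns: offset, mean, n.
    """
    if not cohort.members:
        raise ValueError("empty cohort")
    rows = []
    for c in cohort.members:
        v = track.values[c.chrom]
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


def center_edge_contrast(profile: pd.DataFrame, center_half: int = 100) -> float:
    """Center minus edge mean of a cohort profile — the simple 'is there a
    bump at the midpoint' statistic used to judge how deep replication
    signal extends down the rank list."""
    off = profile["offset"].to_numpy()
    m = profile["mean"].to_numpy()
    center = np.nanmean(m[np.abs(off) <= center_half])
    edge = np.nanmean(m[np.abs(off) > (off.max() - center_half)])
    return float(center - edge)


def heatmap_matrix(
    cmbs_list, track: SignalTrack, half_width: int, top_n: int
) -> np.ndarray:
    """Row r = the track window centered on the rank-(r+1) CMBS midpoint.

    Rows whose window is clipped by a chromosome end are NaN-filled so row
    index always equals rank - 1.
    """
    ranked = sorted(cmbs_list, key=lambda c: c.rank)[:top_n]
    if len(ranked) < top_n:
        raise ValueError(f"need {top_n} CMBSs, have {len(ranked)}")
    width = 2 * half_width + 1
    mat = np.full((top_n, width), np.nan)
    for i, c in enumerate(ranked):
        v = track.values[c.chrom]
        lo, hi = c.midpoint - half_width, c.midpoint + half_width + 1
        if lo < 0 or hi > len(v):
            continue
        mat[i] = v[lo:hi]
    return mat


def infer_licensing(
    calibration_points: np.ndarray | list[tuple[float, float]],
    cohorts: list[Cohort],
) -> pd.DataFrame:
    """Per-cohort licensed fractions from calibration measurements.

    calibration_points: (normalized abundance, measured licensed fraction)
    pairs. A least-squares line THROUGH THE ORIGIN (zero abundance ->
    zero licensing) gives slope beta; the anchor f1 is the fit evaluated
    at the top cohort's normalized median, and cohort k is then
    f1 * (median_k / median_1). Reports beta, r2 and per-cohort estimates.
    """
    pts = np.asarray(calibration_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("need at least one (abundance, fraction) point")
    x, y = pts[:, 0], pts[:, 1]
    if np.all(x == 0):
        raise ValueError("all calibration abundances are zero")
    beta = float(np.sum(x * y) / np.sum(x * x))
    resid = y - beta * x
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0

    med1 = cohorts[0].normalized_abundance  # 100 by construction
    f1 = beta * med1
    rows = []
    for c in cohorts:
        ratio = c.median_abundance / cohorts[0].median_abundance
        rows.append(
            {
                "cohort": c.label,
                "normalized_abundance": c.normalized_abundance,
                "abundance_ratio": ratio,
                "licensed_fraction": f1 * ratio,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["beta"] = beta
    df.attrs["r2"] = r2
    df.attrs["anchor_fraction"] = f1
    return df
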