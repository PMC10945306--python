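"""End-to-end convenience layer: fragments -> smoothed tracks -> ranked
CMBS list, and evaluation of a called list against simulator ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .core_io import FragmentRecord, GenomeAssembly
from .coverage import FULL_LENGTH, MIDPOINT, make_coverage, size_filter, smooth
from .peakcall import CMBS, PeakCallConfig, call_cmbs

MCM_SIZE_RANGE = (51, 100)  # double-hexamer-protected insert window
DYAD_SIZE_RANGE = (46, 56)  # nucleosome chemical-cleavage core


def mcm_tracks(
    fragments: list[FragmentRecord],
    assembly: GenomeAssembly,
    smooth_window: int = 10,
    size_range: tuple[int, int] = MCM_SIZE_RANGE,
):
    """Size-filter fragments and build the two smoothed quantitations the
    peak caller consumes (full-length and midpoint)."""
    kept = size_filter(fragments, *size_range)
    full = smooth(make_coverage(kept, assembly, FULL_LENGTH, size_range), smooth_window)
    mid = smooth(make_coverage(kept, assembly, MIDPOINT, size_range), smooth_window)
    return full, mid


def call_from_fragments(
    fragments: list[FragmentRecord],
    assembly: GenomeAssembly,
    config: PeakCallConfig | None = None,
) -> list[CMBS]:
    config = config or PeakCallConfig()
    full, mid = mcm_tracks(fragments, assembly, config.smooth_window)
    return call_cmbs(full, mid, config)


def match_to_truth(
    cmbs_list: list[CMBS], origins: pd.DataFrame, max_dist: int = 50
) -> pd.DataFrame:
    """Pair each planted origin with the nearest CMBS within ``max_dist`` bp.

    Returns the origin table with recovered_rank / recovered_midpoint /
    distance columns (NaN-filled where unmatched).
    """
    by_chrom: dict[str, list[CMBS]] = {}
    for c in cmbs_list:
        by_chrom.setdefault(c.chrom, []).append(c)
    for v in by_chrom.values():
        v.sort(key=lambda c: c.midpoint)

    rows = []
    for row in origins.itertuples(index=False):
        cands = by_chrom.get(row.chrom, [])
        rec = dict(row._asdict())
        rec.update(recovered_rank=np.nan, recovered_midpoint=np.nan, distance=np.nan)
        if cands:
            mids = np.array([c.midpoint for c in cands])
            i = int(np.argmin(np.abs(mids - row.midpoint)))
            d = abs(int(mids[i]) - row.midpoint)
            if d <= max_dist:
                rec.update(
                    recovered_rank=cands[i].rank,
                    recovered_midpoint=cands[i].midpoint,
                    distance=d,
                )
        rows.append(rec)
    return pd.DataFrame(rows)


def recovery_stats(
    matched: pd.DataFrame, top_decades: float = 2.0, total_decades: float = 3.0
) -> dict:
    """Recovery rate of top-decade origins and the abundance/rank
    concordance of the matched set.

    top-two-decade origins are those with abundance within ``top_decades``
    decades of the largest planted abundance.
    """
    real = matched[matched.category == "origin"]
    amax = real.abundance.max()
    top = real[real.abundance >= amax / 10**top_decades]
    rec = top[~top.recovered_rank.isna()]
    recovery = len(rec) / len(top) if len(top) else float("nan")
    if len(rec) >= 3:
        rho = float(spearmanr(rec.abundance, -rec.recovered_rank).statistic)
    else:
        rho = float("nan")
    return {
        "n_top_origins": int(len(top)),
        "n_recovered": int(len(rec)),
        "recovery_fraction": recovery,
        "spearman_abundance_vs_order": rho,
        "median_distance": float(rec.distance.median()) if len(rec) else float("nan"),
    }


def pseudo_cmbs_from_truth(origins: pd.DataFrame) -> list[CMBS]:
    """Planted origins dressed as a ranked CMBS list (rank = planted rank,
    signal = planted abundance) — for exercising cohort/composite machinery
    against ground truth independently of the peak caller."""
    real = origins[origins.category == "origin"].sort_values("planted_rank")
    return [
        CMBS(r.chrom, int(r.midpoint), int(r.planted_rank),
             float(r.abundance), float(r.abundance))
        for r in real.itertuples(index=False)
    ]
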