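"""Locate CMBSs relative to gene bodies, transcription, flanking-gene
orientation, and reference site lists (known origins, ACSs).

A site is genic iff its midpoint falls inside a gene body (half-open
interval); when genes overlap, the site is genic if inside any of them
and the host expression is the maximum over covering genes. Intergenic
sites are classified by the transcription directions of the nearest gene
on each side: (+, -) converge on the site, (-, +) diverge from it, equal
strands are tandem, and a missing flank leaves the orientation undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GeneRecord

GENIC = "genic"
INTERGENIC = "intergenic"
CONVERGENT = "convergent"
DIVERGENT = "divergent"
TANDEM = "tandem"
UNDEFINED = "undefined"


@dataclass
class CmbsAnnotation:
    cmbs: object
    locus_class: str
    host_expression: float | None = None
    flank_orientation: str | None = None

    def __post_init__(self) -> None:
        if self.locus_class == GENIC and self.flank_orientation is not None:
            raise ValueError("flank orientation is defined only for intergenic sites")
        if self.locus_class == INTERGENIC and self.host_expression is not None:
            raise ValueError("host expression is defined only for genic sites")


def classify_locus(cmbs, genes: list[GeneRecord]) -> CmbsAnnotation:
    """Genic/intergenic call for one site; genic hosts carry expression."""
    covering = [
        g for g in genes
        if g.chrom == cmbs.chrom and g.start <= cmbs.midpoint < g.end
    ]
    if covering:
        return CmbsAnnotation(
            cmbs, GENIC, host_expression=max(g.expression for g in covering)
        )
    return CmbsAnnotation(cmbs, INTERGENIC,
                          flank_orientation=flank_orientation(cmbs, genes))


def flank_orientation(cmbs, genes: list[GeneRecord]) -> str:
    """Orientation of the nearest genes left and right of an intergenic site."""
    left = right = None
    left_d = right_d = None
    for g in genes:
        if g.chrom != cmbs.chrom:
            continue
        if g.end <= cmbs.midpoint:
            d = cmbs.midpoint - g.end
            if left_d is None or d < left_d:
                left, left_d = g, d
        elif g.start > cmbs.midpoint:
            d = g.start - cmbs.midpoint
            if right_d is None or d < right_d:
                right, right_d = g, d
    if left is None or right is None:
        return UNDEFINED
    if left.strand == right.strand:
        return TANDEM
    if left.strand == "+":  # and right is '-': both point at the site
        return CONVERGENT
    return DIVERGENT


def annotate_cmbs(cmbs_list, genes: list[GeneRecord]) -> list[CmbsAnnotation]:
    return [classify_locus(c, genes) for c in cmbs_list]


def sliding_rank_summary(
    annotations: list[CmbsAnnotation], window_n: int = 50
) -> pd.DataFrame:
    """Sliding-window summary over abundance rank.

    For each window of ``window_n`` consecutive ranks: counts of genic
    sites, of each orientation class among intergenic sites, and the mean
    expression of genic hosts. A window larger than the list collapses to
    one full-list window.
    """
    anns = sorted(annotations, key=lambda a: a.cmbs.rank)
    n = len(anns)
    if window_n > n:
        window_n = n
    rows = []
    for start in range(0, n - window_n + 1):
        win = anns[start : start + window_n]
        genic = [a for a in win if a.locus_class == GENIC]
        inter = [a for a in win if a.locus_class == INTERGENIC]
        counts = {k: 0 for k in (CONVERGENT, DIVERGENT, TANDEM, UNDEFINED)}
        for a in inter:
            counts[a.flank_orientation] += 1
        rows.append(
            {
                "window_start_rank": win[0].cmbs.rank,
                "window_end_rank": win[-1].cmbs.rank,
                "n_genic": len(genic),
                "n_intergenic": len(inter),
                "n_convergent": counts[CONVERGENT],
                "n_divergent": counts[DIVERGENT],
                "n_tandem": counts[TANDEM],
                "n_undefined": counts[UNDEFINED],
                "mean_host_expression": (
                    float(np.mean([a.host_expression for a in genic]))
                    if genic else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)


def proximity_to_sites(cmbs_list, site_list, max_dist: int = 100) -> dict:
    """How many reference sites have a CMBS within ``max_dist`` bp
    (inclusive of exactly max_dist), and symmetrically for CMBSs.

    Reference sites may be AcsRecords or any objects with chrom/midpoint.
    """
    cm_by_chrom: dict[str, np.ndarray] = {}
    for c in cmbs_list:
        cm_by_chrom.setdefault(c.chrom, []).append(c.midpoint)
    cm_by_chrom = {k: np.sort(np.asarray(v)) for k, v in cm_by_chrom.items()}

    site_by_chrom: dict[str, np.ndarray] = {}
    for s in site_list:
        site_by_chrom.setdefault(s.chrom, []).append(s.midpoint)
    site_by_chrom = {k: np.sort(np.asarray(v)) for k, v in site_by_chrom.items()}

    def _n_near(queries: dict, refs: dict) -> int:
        hits = 0
        for chrom, q in queries.items():
            r = refs.get(chrom)
            if r is None or len(r) == 0:
                continue
            idx = np.searchsorted(r, q)
            left = np.abs(q - r[np.clip(idx - 1, 0, len(r) - 1)])
            right = np.abs(q - r[np.clip(idx, 0, len(r) - 1)])
            hits += int(np.sum(np.minimum(left, right) <= max_dist))
        return hits

    n_sites = sum(len(v) for v in site_by_chrom.values())
    n_cmbs = sum(len(v) for v in cm_by_chrom.values())
    sites_hit = _n_near(site_by_chrom, cm_by_chrom)
    cmbs_hit = _n_near(cm_by_chrom, site_by_chrom)
    return {
        "n_sites": n_sites,
        "n_sites_with_cmbs": sites_hit,
        "fraction_sites_with_cmbs": sites_hit / n_sites if n_sites else float("nan"),
        "n_cmbs": n_cmbs,
        "n_cmbs_near_site": cmbs_hit,
        "fraction_cmbs_near_site": cmbs_hit / n_cmbs if n_cmbs else float("nan"),
    }
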