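"""ACS position-weight-matrix scoring and ACS-centric analyses.

The ACS (ARS consensus sequence) is the asymmetric ~17 bp Orc-binding
motif of budding yeast origins. A 17-mer is scored by summing, over the
17 positions, the matrix probability of the base observed on the scored
strand, read 5'->3' — a plain probability sum with no logarithms, so the
maximum achievable score is the sum of per-position maxima, 12.742.

Genome scans produce one score track per strand. Both tracks index the
score at the CENTER base of the 17-mer window, so composite-profile
offsets read directly as distances from a site midpoint to a motif
center. The Crick value at x is the Watson-rule score of the reverse
complement of the window centered at x.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import AcsRecord, GenomeAssembly, SignalTrack

PWM_WIDTH = 17
HALF_WIN = PWM_WIDTH // 2  # 8: center-base offset inside the window
BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMP = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N self


@dataclass(frozen=True)
class PWMatrix:
    """17 x 4 probability matrix; rows are positions 1..17, columns A,C,G,T."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        if self.probs.shape != (PWM_WIDTH, 4):
            raise ValueError("PWM must be 17 x 4")
        if ((self.probs < 0) | (self.probs > 1)).any():
            raise ValueError("PWM entries must lie in [0, 1]")
        rowsums = self.probs.sum(axis=1)
        if (np.abs(rowsums - 1.0) > 0.005).any():
            raise ValueError("PWM rows must sum to 1 within printed rounding")

    @property
    def max_score(self) -> float:
        """Sum of per-position maxima — the best achievable 17-mer score."""
        return float(self.probs.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        """Per-position argmax sequence (the score-12.742 17-mer)."""
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))


def load_pwm(path: str | Path | None = None) -> PWMatrix:
    """Load the packaged EACS probability matrix (or one in the same
    TSV layout: position, A, C, G, T)."""
    if path is None:
        ref = importlib.resources.files("mcmchec").joinpath("data/eacs_pwm.tsv")
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return PWMatrix(df[list(BASES)].to_numpy(dtype=float))


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else -> 4 (treated as N)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _CODE.items():
        codes[arr == ord(b)] = i
    return codes


def revcomp(seq: str) -> str:
    table = str.maketrans("ACGTN", "TGCAN")
    return seq.upper().translate(table)[::-1]


def score_17mer(seq17: str, pwm: PWMatrix) -> float:
    """Score one 17-mer on the strand it is given; NaN if any base is N."""
    if len(seq17) != PWM_WIDTH:
        raise ValueError(f"expected a 17-mer, got length {len(seq17)}")
    codes = encode(seq17)
    if (codes == 4).any():
        return float("nan")
    return float(pwm.probs[np.arange(PWM_WIDTH), codes].sum())


def scan_genome(assembly: GenomeAssembly, pwm: PWMatrix) -> tuple[SignalTrack, SignalTrack]:
    """Per-bp Watson and Crick score tracks, indexed at window centers.

    Positions whose window runs off the chromosome or contains an N are NaN.
    """
    if assembly.sequence is None:
        raise ValueError("assembly carries no sequence")
    ext = np.zeros((PWM_WIDTH, 5))
    ext[:, :4] = pwm.probs
    ext[:, 4] = np.nan  # N voids the window

    watson = SignalTrack(assembly)
    crick = SignalTrack(assembly)
    for chrom in assembly.chrom_names:
        codes = encode(assembly.sequence[chrom])
        n = len(codes)
        w = np.full(n, np.nan)
        c = np.full(n, np.nan)
        if n >= PWM_WIDTH:
            m = n - PWM_WIDTH + 1  # number of windows; centers at 8..8+m-1
            ws = np.zeros(m)
            cs = np.zeros(m)
            comp = _COMP[codes]
            for i in range(PWM_WIDTH):
                ws += ext[i, codes[i : i + m]]
                # position i of the revcomp window reads Watson base 16-i,
                # complemented
                cs += ext[i, comp[PWM_WIDTH - 1 - i : PWM_WIDTH - 1 - i + m]]
            w[HALF_WIN : HALF_WIN + m] = ws
            c[HALF_WIN : HALF_WIN + m] = cs
        watson.values[chrom] = w
        crick.values[chrom] = c
    return watson, crick


def _site_windows(track: SignalTrack, sites, half_width: int) -> np.ndarray:
    """Stack (2*half_width+1)-wide windows centered on site midpoints;
    windows clipped by a chromosome end are dropped."""
    rows = []
    for chrom, mid in sites:
        n = len(track.values[chrom])
        if mid - half_width < 0 or mid + half_width + 1 > n:
            continue
        rows.append(track.values[chrom][mid - half_width : mid + half_width + 1])
    if not rows:
        return np.empty((0, 2 * half_width + 1))
    return np.vstack(rows)


def composite_pwm_profile(
    cmbs_subset, watson: SignalTrack, crick: SignalTrack, half_width: int = 200
) -> pd.DataFrame:
    """Position-wise mean PWM score per strand across windows centered on
    CMBS midpoints. Columns: offset, watson, crick, n."""
    if not cmbs_subset:
        raise ValueError("empty CMBS subset")
    sites = [(c.chrom, c.midpoint) for c in cmbs_subset]
    w = _site_windows(watson, sites, half_width)
    c = _site_windows(crick, sites, half_width)
    if w.shape[0] == 0:
        raise ValueError("all windows clipped at chromosome ends")
    return pd.DataFrame(
        {
            "offset": np.arange(-half_width, half_width + 1),
            "watson": np.nanmean(w, axis=0),
            "crick": np.nanmean(c, axis=0),
            "n": w.shape[0],
        }
    )


def conditional_flank_test(
    cmbs_list,
    watson: SignalTrack,
    crick: SignalTrack,
    threshold: float = 10.8,
    flank: tuple[int, int] = (-60, 0),
    half_width: int = 200,
) -> dict:
    """Do sites with a strong Watson-strand ACS still show a Crick-strand
    ACS on the other flank?

    Selects CMBSs whose best Watson score in the upstream flank
    [midpoint+flank[0], midpoint+flank[1]) reaches ``threshold``, then
    returns the Crick composite of that subset next to the full-set one.
    """
    pwm_max = 12.742
    strong = []
    for c in cmbs_list:
        v = watson.values[c.chrom]
        lo = max(c.midpoint + flank[0], 0)
        hi = min(c.midpoint + flank[1], len(v))
        if hi <= lo:
            continue
        window = v[lo:hi]
        if np.all(np.isnan(window)):
            continue
        if np.nanmax(window) >= threshold:
            strong.append(c)
    if not strong:
        raise ValueError(
            f"no CMBS has an upstream Watson score >= {threshold} "
            f"(selected 0 of {len(cmbs_list)}; max possible {pwm_max})"
        )
    return {
        "n_selected": len(strong),
        "selected_crick": composite_pwm_profile(strong, watson, crick, half_width),
        "all_crick": composite_pwm_profile(list(cmbs_list), watson, crick, half_width),
    }


def downstream_orientation(
    cmbs_list, acs_list: list[AcsRecord], max_dist: int = 100
) -> tuple[int, int, float]:
    """For each ACS with a CMBS within ``max_dist`` bp (inclusive), is the
    nearest CMBS downstream of it?

    Downstream follows the ACS strand: larger coordinates for '+', smaller
    for '-'. Returns (n ACSs matched, n matched downstream, fraction).
    """
    by_chrom: dict[str, list[int]] = {}
    for c in cmbs_list:
        by_chrom.setdefault(c.chrom, []).append(c.midpoint)
    for v in by_chrom.values():
        v.sort()

    n_within = n_downstream = 0
    for acs in acs_list:
        mids = by_chrom.get(acs.chrom)
        if not mids:
            continue
        arr = np.asarray(mids)
        d = np.abs(arr - acs.midpoint)
        i = int(np.argmin(d))
        if d[i] > max_dist:
            continue
        n_within += 1
        delta = arr[i] - acs.midpoint
        if (delta > 0) == (acs.strand == "+") and delta != 0:
            n_downstream += 1
    frac = n_downstream / n_within if n_within else float("nan")
    return n_within, n_downstream, frac


def cumulative_mcm_around_acs(
    acs_list: list[AcsRecord],
    mid_track: SignalTrack,
    half_width: int = 500,
    norm_total: float = 100.0,
) -> pd.DataFrame:
    """Cumulative, ACS-oriented Mcm signal around ACSs.

    Each (2*half_width+1) bp window of the midpoint-quantified Mcm track is
    oriented by the ACS strand (minus-strand windows reversed), scaled so
    its total equals ``norm_total``, and summed position-wise. A mass
    excess at positive offsets means Mcm sits downstream of the ACS.
    """
    import logging

    profile = np.zeros(2 * half_width + 1)
    n_used = 0
    for acs in acs_list:
        v = mid_track.values[acs.chrom]
        lo, hi = acs.midpoint - half_width, acs.midpoint + half_width + 1
        if lo < 0 or hi > len(v):
            logging.getLogger(__name__).warning(
                "window at %s:%d overlaps a chromosome end; dropped",
                acs.chrom, acs.midpoint,
            )
            continue
        window = np.nan_to_num(v[lo:hi])
        if acs.strand == "-":
            window = window[::-1]
        total = window.sum()
        if total <= 0:
            continue
        profile += window * (norm_total / total)
        n_used += 1
    return pd.DataFrame(
        {
            "offset": np.arange(-half_width, half_width + 1),
            "cumulative": profile,
            "n": n_used,
        }
    )
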