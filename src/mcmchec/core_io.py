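"""Readers and writers for every external format the pipeline touches.

All coordinates are 0-based half-open, everywhere. BED and bedGraph match
this natively; tables that arrive 1-based must be converted by the caller
(``one_based=True`` on the table readers).

Fragments are unstranded: a ChEC insert is a double-stranded cut product
and carries no meaningful strand of its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from pyfaidx import Fasta

log = logging.getLogger(__name__)

VALID_STRANDS = frozenset({"+", "-"})


class FormatError(ValueError):
    """A record in an input file violates the format contract."""


@dataclass(frozen=True)
class GenomeAssembly:
    """Chromosome names, lengths and (optionally) sequence.

    ``sequence`` maps chromosome name to an uppercase A/C/G/T/N string.
    Any assembly is accepted, real or synthetic.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: Mapping[str, int]
    sequence: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        for name in self.chrom_names:
            n = self.chrom_lengths[name]
            if n <= 0:
                raise ValueError(f"non-positive length for {name}")
            if self.sequence is not None and len(self.sequence[name]) != n:
                raise ValueError(
                    f"sequence length {len(self.sequence[name])} != declared "
                    f"length {n} for {name}"
                )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def length(self, chrom: str) -> int:
        return self.chrom_lengths[chrom]


@dataclass(frozen=True, order=True)
class FragmentRecord:
    """One sequenced paired-end insert as a genomic interval."""

    chrom: str
    start: int
    end: int

    @property
    def insert_length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneRecord:
    chrom: str
    start: int
    end: int
    strand: str
    expression: float = 0.0


@dataclass(frozen=True)
class AcsRecord:
    """An ARS consensus sequence site; strand defines its 'downstream'."""

    chrom: str
    midpoint: int
    strand: str


@dataclass
class SignalTrack:
    """Per-bp real-valued signal, one vector per chromosome; NaN = missing."""

    assembly: GenomeAssembly
    values: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def zeros(cls, assembly: GenomeAssembly) -> "SignalTrack":
        return cls(
            assembly,
            {c: np.zeros(assembly.length(c)) for c in assembly.chrom_names},
        )

    def copy(self) -> "SignalTrack":
        return SignalTrack(self.assembly, {c: v.copy() for c, v in self.values.items()})

    def total(self) -> float:
        return float(sum(np.nansum(v) for v in self.values.values()))


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> GenomeAssembly:
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    names = tuple(fa.keys())
    seqs = {name: str(fa[name][:]) for name in names}
    lengths = {name: len(s) for name, s in seqs.items()}
    return GenomeAssembly(names, lengths, seqs)


def write_fasta(assembly: GenomeAssembly, path: str | Path, width: int = 70) -> None:
    if assembly.sequence is None:
        raise ValueError("assembly carries no sequence")
    with open(path, "w") as fh:
        for name in assembly.chrom_names:
            fh.write(f">{name}\n")
            seq = assembly.sequence[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED3 fragments / intervals

def read_fragments(path: str | Path, assembly: GenomeAssembly) -> list[FragmentRecord]:
    """Read fragment intervals from a 3-column BED file.

    Out-of-bounds or malformed records raise, naming the offending line;
    an empty file yields an empty list with a logged warning.
    """
    records: list[FragmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if chrom not in assembly:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if start < 0 or end > assembly.length(chrom):
                raise FormatError(
                    f"{path}:{lineno}: interval [{start},{end}) outside {chrom} "
                    f"(length {assembly.length(chrom)})"
                )
            records.append(FragmentRecord(chrom, start, end))
    if not records:
        log.warning("no fragment records read from %s", path)
    return records


def write_fragments(fragments: Iterable[FragmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")


def read_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """BED3 intervals that need not be validated against an assembly
    (exclusion lists may legitimately extend past synthetic bounds)."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            out.append((chrom, start, end))
    return out


def write_intervals(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# bedGraph

def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Run-length encode a per-bp track as bedGraph. NaN runs are omitted."""
    with open(path, "w") as fh:
        for chrom in track.assembly.chrom_names:
            v = track.values[chrom]
            if len(v) == 0:
                continue
            # boundaries where the value changes (NaN == NaN for this purpose)
            same = (v[1:] == v[:-1]) | (np.isnan(v[1:]) & np.isnan(v[:-1]))
            cuts = np.flatnonzero(~same) + 1
            starts = np.concatenate(([0], cuts))
            ends = np.concatenate((cuts, [len(v)]))
            for s, e in zip(starts, ends):
                val = v[s]
                if np.isnan(val):
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{val:.10g}\n")


def read_bedgraph(path: str | Path, assembly: GenomeAssembly,
                  missing: float = np.nan) -> SignalTrack:
    """Read a bedGraph into a per-bp track; uncovered bases get ``missing``.

    Overlapping intervals are an error: a bedGraph is a function of position.
    """
    track = SignalTrack(
        assembly,
        {c: np.full(assembly.length(c), missing) for c in assembly.chrom_names},
    )
    covered = {c: np.zeros(assembly.length(c), dtype=bool) for c in assembly.chrom_names}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, s, e, val = line.split()[:4]
            s, e = int(s), int(e)
            if chrom not in assembly:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if s >= e or s < 0 or e > assembly.length(chrom):
                raise FormatError(f"{path}:{lineno}: bad interval [{s},{e})")
            if covered[chrom][s:e].any():
                raise FormatError(f"{path}:{lineno}: overlapping intervals")
            covered[chrom][s:e] = True
            track.values[chrom][s:e] = float(val)
    return track


def read_wig(path: str | Path, assembly: GenomeAssembly) -> SignalTrack:
    """Fixed-step wiggle reader (``fixedStep chrom=... start=... step=1``).

    wig declaration lines are 1-based per the format; values are laid down
    at step intervals of span 1.
    """
    track = SignalTrack(
        assembly,
        {c: np.full(assembly.length(c), np.nan) for c in assembly.chrom_names},
    )
    chrom, pos, step = None, 0, 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                if chrom not in assembly:
                    raise FormatError(f"unknown chromosome {chrom!r} in wig header")
                pos = int(fields["start"]) - 1  # wig is 1-based
                step = int(fields.get("step", 1))
                continue
            if chrom is None:
                raise FormatError("wig data line before fixedStep header")
            track.values[chrom][pos] = float(line)
            pos += step
    return track


# ---------------------------------------------------------------------------
# TSV tables

def read_gene_table(path: str | Path, one_based: bool = False) -> list[GeneRecord]:
    """Genes as TSV: chrom, start, end, strand[, expression].

    Expression defaults to 0 when the column is absent.
    """
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 columns")
            chrom, start, end, strand = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if one_based:
                start -= 1
            if strand not in VALID_STRANDS:
                raise FormatError(f"{path}:{lineno}: malformed strand {strand!r}")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            expr = float(parts[4]) if len(parts) > 4 and parts[4] != "" else 0.0
            if expr < 0:
                raise FormatError(f"{path}:{lineno}: negative expression")
            genes.append(GeneRecord(chrom, start, end, strand, expr))
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\texpression\n")
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t{g.expression:.6g}\n")


def read_acs_table(path: str | Path, one_based: bool = False) -> list[AcsRecord]:
    """ACS sites as TSV: chrom, midpoint, strand."""
    sites: list[AcsRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            chrom, mid, strand = parts[0], int(parts[1]), parts[2]
            if one_based:
                mid -= 1
            if strand not in VALID_STRANDS:
                raise FormatError(f"{path}:{lineno}: malformed strand {strand!r}")
            sites.append(AcsRecord(chrom, mid, strand))
    return sites


def write_acs_table(sites: Iterable[AcsRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tmidpoint\tstrand\n")
        for a in sites:
            fh.write(f"{a.chrom}\t{a.midpoint}\t{a.strand}\n")


def write_cmbs_table(cmbs_list, path: str | Path) -> None:
    """Ranked CMBS list as TSV (chrom, midpoint, rank, abundance, midpoint_signal)."""
    df = pd.DataFrame(
        [
            (c.chrom, c.midpoint, c.rank, c.abundance, c.midpoint_signal)
            for c in cmbs_list
        ],
        columns=["chrom", "midpoint", "rank", "abundance", "midpoint_signal"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_cmbs_table(path: str | Path):
    from .peakcall import CMBS

    df = pd.read_csv(path, sep="\t")
    return [
        CMBS(r.chrom, int(r.midpoint), int(r.rank), float(r.abundance),
             float(r.midpoint_signal))
        for r in df.itertuples(index=False)
    ]
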