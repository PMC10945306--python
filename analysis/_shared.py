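"""Paths and loaders shared by the numbered analysis scripts."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from mcmchec.core_io import read_cmbs_table, read_fasta

RESULTS = Path(__file__).resolve().parent.parent / "results"
SIM_DIR = RESULTS / "sim"


def load_sim():
    """Genome, truth table and standard file paths of the simulated dataset
    written by 01_simulate.py."""
    if not SIM_DIR.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    assembly = read_fasta(SIM_DIR / "genome.fa")
    truth = pd.read_csv(SIM_DIR / "truth.tsv", sep="\t")
    return assembly, truth


def load_cmbs():
    path = RESULTS / "cmbs.tsv"
    if not path.exists():
        raise SystemExit("run analysis/02_call_peaks.py first")
    return read_cmbs_table(path)
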