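"""Generate the default synthetic dataset: a 2 x 300 kb genome carrying
150 planted origins (abundances spanning three decades, flanking ACS
motifs, NFRs, strand-asymmetric G/C composition), genes, nucleosomes,
ChEC-like fragments and ssDNA/BrdU/dyad tracks."""

import argparse

from _shared import SIM_DIR

from mcmchec.simulate import SimConfig, simulate

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

config = SimConfig(seed=args.seed)
paths = simulate(config, SIM_DIR)

n_frags = sum(1 for _ in open(paths["fragments.bed"]))
print(f"simulated {config.n_chroms} x {config.chrom_length:,} bp genome "
      f"with {config.n_origins} origins (seed {args.seed})")
print(f"  {n_frags:,} ChEC fragments -> {paths['fragments.bed']}")
print(f"  outputs under {SIM_DIR}")
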