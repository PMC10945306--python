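"""Locate CMBSs relative to genes: genic/intergenic fraction, host-gene
expression, and flanking-gene orientation in sliding rank windows —
the analyses that expose the transition from origin-like intergenic
sites to nucleosomal signal inside transcribed genes."""

import argparse

from _shared import RESULTS, SIM_DIR, load_cmbs, load_sim

from mcmchec.annotate import annotate_cmbs, proximity_to_sites, sliding_rank_summary
from mcmchec.core_io import read_acs_table, read_gene_table

parser = argparse.ArgumentParser()
parser.add_argument("--window", type=int, default=50)
args = parser.parse_args()

assembly, truth = load_sim()
cmbs = load_cmbs()
genes = read_gene_table(SIM_DIR / "genes.tsv")
acs = read_acs_table(SIM_DIR / "acs.tsv")

annotations = annotate_cmbs(cmbs, genes)
df = sliding_rank_summary(annotations, args.window)
df.to_csv(RESULTS / "annotation_summary.tsv", sep="\t", index=False)

first, last = df.iloc[0], df.iloc[-1]
print(f"sliding windows of {args.window} by rank -> results/annotation_summary.tsv")
print(f"  ranks {first.window_start_rank:.0f}-{first.window_end_rank:.0f}: "
      f"{first.n_genic:.0f}/{args.window} genic, "
      f"host expression {first.mean_host_expression:.1f}")
print(f"  ranks {last.window_start_rank:.0f}-{last.window_end_rank:.0f}: "
      f"{last.n_genic:.0f}/{args.window} genic, "
      f"host expression {last.mean_host_expression:.1f}")

cross = df[df.n_genic >= args.window // 2]
if len(cross):
    print(f"  genic fraction crosses 50% near rank "
          f"{cross.window_start_rank.iloc[0]:.0f}")

prox = proximity_to_sites(cmbs, acs, 100)
print(f"ACSs with a CMBS within 100 bp: {prox['n_sites_with_cmbs']}/"
      f"{prox['n_sites']} ({100 * prox['fraction_sites_with_cmbs']:.0f}%)")
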