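"""ACS motif structure around CMBSs: strand-resolved PWM composites,
the strong-Watson conditional test for double Orc sites, the
downstream-of-ACS orientation count, and the cumulative ACS-oriented
Mcm profile."""

import argparse

import pandas as pd
from _shared import RESULTS, SIM_DIR, load_cmbs, load_sim

from mcmchec.core_io import read_acs_table, read_fragments
from mcmchec.motif import (
    composite_pwm_profile,
    conditional_flank_test,
    cumulative_mcm_around_acs,
    downstream_orientation,
    load_pwm,
    scan_genome,
)
from mcmchec.pipeline import mcm_tracks

parser = argparse.ArgumentParser()
parser.add_argument("--top-ranks", type=int, default=100)
parser.add_argument("--half-width", type=int, default=150)
parser.add_argument("--strong-threshold", type=float, default=10.8)
args = parser.parse_args()

assembly, truth = load_sim()
cmbs = load_cmbs()
acs = read_acs_table(SIM_DIR / "acs.tsv")
pwm = load_pwm()
print(f"PWM loaded: width 17, max score {pwm.max_score:.3f} "
      f"(consensus {pwm.consensus})")

watson, crick = scan_genome(assembly, pwm)
top = [c for c in cmbs if c.rank <= args.top_ranks]
prof = composite_pwm_profile(top, watson, crick, args.half_width)
prof.to_csv(RESULTS / "pwm_composite.tsv", sep="\t", index=False)
w_off = prof["offset"][prof["watson"].idxmax()]
c_off = prof["offset"][prof["crick"].idxmax()]
print(f"composite over top {args.top_ranks} CMBSs: Watson maximum at "
      f"{w_off:+d} bp, Crick at {c_off:+d} bp (flanking ACSs)")

res = conditional_flank_test(top, watson, crick,
                             threshold=args.strong_threshold,
                             half_width=args.half_width)
res["selected_crick"].to_csv(RESULTS / "pwm_conditional_crick.tsv",
                             sep="\t", index=False)
print(f"{res['n_selected']} sites with Watson flank score >= "
      f"{args.strong_threshold}: Crick composite peak "
      f"{res['selected_crick'].crick.max():.2f} vs {res['all_crick'].crick.max():.2f} "
      f"for all sites (double-ACS structure)")

n_within, n_down, frac = downstream_orientation(cmbs, acs, 100)
print(f"of {len(acs)} planted ACSs, {n_within} have a CMBS within 100 bp; "
      f"in {n_down}/{n_within} ({100 * frac:.0f}%) the CMBS is downstream")

fragments = read_fragments(SIM_DIR / "fragments.bed", assembly)
_, mid = mcm_tracks(fragments, assembly)
cum = cumulative_mcm_around_acs(acs, mid, half_width=500)
cum.to_csv(RESULTS / "cumulative_mcm_around_acs.tsv", sep="\t", index=False)
down = cum.loc[cum.offset > 0, "cumulative"].sum()
total = cum["cumulative"].sum()
print(f"cumulative ACS-oriented Mcm signal: {100 * down / total:.0f}% of mass "
      f"downstream of the ACS")
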