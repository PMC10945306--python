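"""Assess replication activity at CMBSs: cohort-wise ssDNA composite
profiles centered on peak midpoints, center/edge contrasts, and the
licensing-fraction inference anchored by calibration measurements."""

import argparse

import numpy as np
import pandas as pd
from _shared import RESULTS, SIM_DIR, load_cmbs, load_sim

from mcmchec.cohorts import (
    center_edge_contrast,
    cohort_profile,
    infer_licensing,
    make_cohorts,
)
from mcmchec.core_io import read_bedgraph

parser = argparse.ArgumentParser()
parser.add_argument("--group-size", type=int, default=30)
parser.add_argument("--n-groups", type=int, default=5)
parser.add_argument("--half-width", type=int, default=2000)
args = parser.parse_args()

assembly, truth = load_sim()
cmbs = load_cmbs()
ssdna = read_bedgraph(SIM_DIR / "ssdna.bedgraph", assembly)

cohorts = make_cohorts(cmbs, args.group_size, args.n_groups)
profiles, rows = [], []
for c in cohorts:
    prof = cohort_profile(c, ssdna, args.half_width)
    prof.insert(0, "cohort", c.label)
    profiles.append(prof)
    rows.append({
        "cohort": c.label,
        "normalized_abundance": c.normalized_abundance,
        "center_edge_contrast": center_edge_contrast(prof, 100),
    })
pd.concat(profiles).to_csv(RESULTS / "ssdna_profiles.tsv", sep="\t", index=False)

summary = pd.DataFrame(rows)
print("ssDNA composite contrast by cohort (top cohort abundance = 100):")
print(summary.to_string(index=False, float_format=lambda x: f"{x:.3f}"))

# calibration points emulate direct licensing measurements at strong sites:
# licensed fraction proportional to normalized abundance, anchored at ~69%
rng = np.random.default_rng(100)
x = np.linspace(40, 100, 7)
y = np.clip(0.0069 * x + rng.normal(0, 0.03, 7), 0, 1)
lic = infer_licensing(np.column_stack([x, y]), cohorts)
lic.to_csv(RESULTS / "licensing.tsv", sep="\t", index=False)
print(f"\nproportional licensing fit: beta={lic.attrs['beta']:.5f}, "
      f"r2={lic.attrs['r2']:.2f}, anchor={100 * lic.attrs['anchor_fraction']:.0f}%")
for _, r in lic.iterrows():
    print(f"  cohort {r.cohort}: relative abundance "
          f"{r.normalized_abundance:6.2f} -> licensed in "
          f"{100 * r.licensed_fraction:.1f}% of cells")
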