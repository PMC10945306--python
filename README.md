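# mcmchec

Genome-wide mapping of replicative-helicase (Mcm) loading sites from
MCM-ChEC fragment data, and assessment of the called sites against the
classic hallmarks of DNA replication origins.

In budding yeast, a replication origin is licensed when an Mcm double
hexamer — a head-to-head pair of helicase rings protecting ~61 bp of
DNA — is loaded next to the ARS consensus sequence (ACS) in G1. In a
ChEC experiment the Mcm subunit carries a micrococcal-nuclease fusion,
so licensed sites release short protected fragments whose 51–100 bp size
class and midpoints report the helicase position at base-pair
resolution. This package implements, as a reusable library plus a set of
narrative analysis drivers:

* **Coverage** — size-filtered per-bp quantitation of paired-end
  fragment intervals, either over full insert lengths or at insert
  midpoints, with box smoothing and sample pooling.
* **Peak calling** — an iterative caller for candidate Mcm binding
  sites (CMBSs): repeatedly take the global maximum of the smoothed
  full-length track, refine the coordinate on the sharper midpoint track
  within ±60 bp, zero both tracks within ±500 bp, and rank the sites by
  selection-time abundance; then collapse rDNA peaks to one, drop peaks
  within 100 bp of Ty-like exclusion intervals, and renumber ranks.
* **Hallmark analyses** — rank-cohort composite profiles over ssDNA /
  BrdU replication tracks and nucleosome-dyad coverage; genic/intergenic
  and flanking-gene-orientation annotation in sliding rank windows; ACS
  position-weight-matrix scanning of both strands (additive probability
  scores; maximum 12.742 = sum of per-position maxima); downstream-of-ACS
  orientation counting; GC skew ((G−C)/(G+C), 51 bp window) composites
  across site midpoints; and a proportional licensing-fraction inference
  anchored on calibration measurements.
* **Synthetic data** — a seeded generator that plants all of the above
  structure (origins spanning three decades of abundance, flanking ACS
  motifs, NFRs, phased nucleosomes, expression-coupled background
  cleavage, strand-asymmetric G/C composition, ssDNA-like bumps) in a
  small genome with a complete ground-truth table.

## Worked example

The numbered drivers under `analysis/` run the whole study on the
default synthetic dataset (2 × 300 kb, 150 planted origins, seed 1) and
write tables under `results/`:

```
cd analysis
python 01_simulate.py
python 02_call_peaks.py
```

```
called 700 peaks; 699 after rDNA/Ty exclusions
recovery of top-two-decade origins: 107/107 (100.0%) within 50 bp (median offset 1 bp)
Spearman(planted abundance, recovered order) = 0.996
rank-abundance span: 2,709x over 699 sites -> results/rank_abundance.tsv
```

All 107 planted origins within two decades of the strongest one are
recovered to ~1 bp, the recovered rank order tracks planted abundance,
and the rank–abundance curve spans about three orders of magnitude.
Continuing (`03`–`07`) reproduces the hallmark analyses; e.g. the ACS
and GC-skew structure around the called sites:

```
composite over top 100 CMBSs: Watson maximum at -36 bp, Crick at +35 bp (flanking ACSs)
of 244 planted ACSs, 240 have a CMBS within 100 bp; in 193/240 (80%) the CMBS is downstream
GC skew (51 bp window) across cohort midpoints:
  ranks      1-50: rise across midpoint +0.4560, central deviation -0.0210
```

The Watson/Crick composite maxima at ∓35 bp recover the planted ACS
offsets; the 80% downstream fraction matches the configured loading
geometry; and GC skew rises across the midpoints of the strongest
cohort, the footprint expected of repeated replication initiation.
`04_nucleosome_landscape.py` shows the called sites sitting in
nucleosome-free regions for origin-dominated ranks and on nucleosomes
below them, and `03_replication_cohorts.py` converts cohort abundances
into licensed fractions (e.g. a cohort at 2.4% of the top cohort's
abundance is licensed in ~1.7% of cells under a ~70% anchor).

## Layout

```
src/mcmchec/      library: core_io, coverage, peakcall, motif, gcskew,
                  annotate, cohorts, simulate, pipeline
analysis/         numbered narrative drivers (simulate -> call -> assess)
tests/            unit, property and end-to-end suites
docs/methods.md   models, parameters, design choices, limitations
```
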