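# Methods

## Coordinate and data model

All coordinates are 0-based half-open throughout the library; BED and
bedGraph match natively and 1-based tables are converted at read time by
an explicit flag. Fragments are unstranded intervals (a ChEC insert is a
double-stranded cut product). Signal tracks are per-chromosome per-bp
vectors in which missing is NaN, never 0 — for GC skew in particular,
zero is a meaningful value and is kept distinct from undefined.

## Coverage quantitation

Fragments are size-filtered inclusively; the Mcm analysis window is
51–100 bp (the double-hexamer footprint) and nucleosome-dyad mapping
uses 46–56 bp chemical-cleavage cores. Two quantitations are built from
the same fragments: *full-length* (each fragment adds one to every
covered bp) and *midpoint* (one count at floor((start+end)/2); a 61 bp
fragment has an exact central bp). Two conservation identities hold
exactly and are asserted in tests: the midpoint track sums to the
fragment count, the full-length track to the summed insert lengths.
Smoothing is a centered box mean that truncates at chromosome ends (no
padding — no invented signal); an even window takes its extra base on
the left, a fixed, documented asymmetry. Samples are pooled by raw
element-wise summation with no depth normalization, since pooling
precedes peak calling.

## Peak calling

The caller alternates: (1) global argmax of the smoothed full-length
track — wide peaks are robust for detection; (2) argmax of the smoothed
midpoint track within ±60 bp — sharp peaks are precise for placement;
(3) zeroing of both tracks within ±500 bp of the chosen midpoint to
prevent redundant calls; repeat until the maximum is zero or `max_peaks`
is reached. Abundance is recorded at selection time from the full-length
track, so it is non-increasing in rank by construction; the midpoint-
track value at the final coordinate is stored alongside and is the
quantity cohort analyses summarize, since Mcm signal is quantified from
midpoints downstream. Argmax ties break to the earliest chromosome in
assembly order, then the lowest coordinate, making output platform-
independent. Tracks are copied before zeroing. The geometry implies a
provable separation bound: two same-chromosome midpoints are always more
than zero_radius − refine_radius = 440 bp apart, asserted on random and
synthetic inputs. Termination is by `max_peaks` or track exhaustion; the
exported rank–abundance curve lets the analyst locate the drop-off that
marks genome coverage, a judgment we do not automate. The production
caller caches per-chromosome maxima and re-scans only the chromosome
modified by zeroing; the test suite holds it to exact equivalence with a
reference that re-scans the entire genome every iteration.

rDNA-like exclusion intervals retain only the best-ranked overlapping
peak; Ty-like intervals remove peaks whose midpoint is within 100 bp
(inclusive, measured to the nearest contained base) of the interval;
ranks are then renumbered consecutively.

## ACS scoring

The 17×4 ACS probability matrix ships as a packaged TSV. A 17-mer score
is the plain sum of per-position probabilities of the observed bases on
the scored strand — no logarithms or background correction, which is the
only rule under which the maximum achievable score equals the sum of
per-position maxima, 12.742 (verified at load time). Any N voids the
window. Genome scans produce Watson and Crick tracks indexed at the
*center* base of each window: the Crick value at x is the Watson-rule
score of the reverse complement of the window centered at x. Center
assignment (rather than the window's left edge) was chosen so that
composite-profile offsets read directly as distances from a site
midpoint to a motif center; with ACS centers planted 35 bp from Mcm
midpoints, the composite maxima fall at ∓35 rather than being shifted by
half a window. The conditional double-ACS test selects sites whose best
Watson score in the upstream flank [midpoint−60, midpoint) reaches a
threshold (default 10.8) — the 60 bp window brackets the ~35 bp flank
offset — and compares the Crick composite of that subset to the full
set's. ACS–CMBS pairing for the downstream-orientation count takes the
nearest CMBS per ACS within 100 bp, one-to-one not enforced (the minimal
assumption); downstream follows the ACS strand, and a CMBS exactly at
the ACS midpoint counts as not downstream.

## GC skew

Skew at x is (G−C)/(G+C) over Watson-strand bases in an odd centered
window (default 51 bp; an even window has no central base and is
rejected). Ns are excluded from both counts; windows with G+C = 0 or
running off the chromosome are undefined. Composites average defined
values position-wise across site-centered windows. The reversal
statistic summarizes a composite by the rise across the midpoint (mean
of the downstream half minus the upstream half, excluding a central
±25 bp window) and the central deviation (central-window mean minus the
midpoint of the two flank means), which is negative when the short
midpoint inversion — the signature of Mcm hexamers crossing over before
diverging — is present. Composites are aligned on CMBS midpoints;
ACS-centered alignment is available as the negative control that
destroys the signal.

## Annotation

A site is genic iff its midpoint lies in a gene body (half-open). With
overlapping genes, any cover makes it genic and host expression is the
maximum over covering genes — the conservative choice for detecting
signal inside transcribed genes. The gene table is taken as given;
filtering dubious features is a data-preparation concern. Intergenic
sites are classed by the strands of the nearest flanking genes:
(+, −) convergent, (−, +) divergent, equal tandem. Sliding summaries
over rank windows (default 50) report genic counts, orientation classes
(which partition the intergenic subset) and host expression.
"Within 100 bp" is inclusive of exactly 100 everywhere.

## Cohorts and licensing

Cohorts are consecutive rank blocks summarized by the median of member
midpoint signals, normalized so the top cohort reads 100; all downstream
ratios are therefore scale-invariant. Composite profiles are means
(position-wise, missing excluded); the cumulative ACS-oriented Mcm
profile instead scales each window to a fixed total (100) before
summation, so every ACS contributes equally regardless of abundance.
Licensing inference fits licensed_fraction = β·abundance by least
squares *through the origin* — zero abundance must mean zero licensing,
so proportionality is the physically forced model; the fit anchors the
top cohort and other cohorts scale by relative median abundance. r² is
reported against the centered total sum of squares.

## Synthetic data

The generator emulates the statistical structure the analyses assume,
with one strength scalar per origin — log10(abundance)/decades — tying
motif sharpness and planted skew amplitude to abundance so that every
hallmark decays together down the rank list.

Defaults (all configurable on `SimConfig`): 2 chromosomes × 300 kb with
150 origins, one per equal slot with ≥ 2.5 kb spacing; abundances
log-uniform over 3 decades; ~61 ± 4 bp Mcm fragments, Poisson counts at
3 per abundance unit, centers jittered ± 8 bp; ACS 17-mers sampled
position-wise from strength·PWM + (1−strength)·uniform with centers
35 bp from the Mcm midpoint, pointed so the Mcm site is downstream with
probability 0.8, and a mirrored opposite-strand ACS with probability
0.6; 150 bp NFRs (no nucleosome dyads within 145 bp of a midpoint) in a
165 bp-phased nucleosome background; G/C composition within ±200 bp of
each midpoint biased C-rich upstream / G-rich downstream on Watson with
amplitude 0.3·strength (A/T positions untouched, so GC content is
preserved); genes of ~1.5 kb tiling the remaining sequence with
lognormal expression; nucleosomal background fragments at Poisson rate
3·(1 + 0.2·expression) per dyad, drawn mostly at ~167 bp with a 15%
subnucleosomal ~80 bp tail from partial digestion — the tail is what
lets background cleavage inside expressed genes produce the low-rank
genic, nucleosomal site class that the annotation and dyad-composite
transitions detect; ssDNA/BrdU tracks as baseline-1 Gaussian bumps
(σ = 500 bp) with amplitude proportional to the planted licensed
fraction (0.9 at the top origin) plus iid noise (sd 0.05); the dyad
track as a compact triangular kernel (half-width 30 bp) at each dyad, so
NFR centers are exactly zero. An rDNA-like interval containing planted
decoy peaks is dropped into the widest inter-origin gap, and a Ty-like
interval is emitted, to exercise the exclusion rules without disturbing
genuine origins. All randomness derives from the seed through per-stage
generators; fixed seed gives byte-identical files.

What the generator does *not* emulate: mappability and GC amplification
bias, replication-fork gradients in the ssDNA track, rDNA repeat arrays,
chromosome-end effects beyond simple margins, correlated noise, or
sequence evolution (the deamination footprint is planted directly in
present-day composition). Passing recovery tests therefore demonstrate
correctness of the analysis machinery under the model's assumptions, not
performance on real libraries.

## Problem sizes and numerical choices

Desk-scale runs use the default 600 kb genome; the analysis drivers call
up to 700 peaks (~one per kb) and form cohorts of 30 (ssDNA, 5 groups)
or 50 (dyad/PWM/skew composites), scaled-down analogues of the groups of
200/500/1100 appropriate to 150 planted origins. The peak-caller
equivalence suite uses ≤ 50 kb random tracks; oracle comparisons are
exact (integer positions) or within 1e-12 relative tolerance for
floating-point means. Degenerate inputs are defined behavior: empty
fragment files yield empty lists with a warning, all-zero tracks yield
empty peak lists, empty cohorts and empty composite subsets raise.

## Known limitations

The caller's 500 bp zeroing radius caps achievable site density at about
one per kb, which matches its design target but undercounts genuinely
closer double sites. Abundance ranks use the full-length selection-time
value; analyses preferring midpoint quantitation read the stored
midpoint signal, and the two orderings can differ for asymmetric peaks.
The licensing inference assumes strict proportionality and inherits any
bias in the calibration points. GC-skew composites on short synthetic
chromosomes have higher variance at large offsets because end-clipped
windows are dropped.
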