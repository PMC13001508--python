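# Methods

This note records the models implemented in `g4coop`, the conventions and
numerical choices behind them, what the synthetic-data generators do and do
not emulate, and the design decisions taken where the published description
left the details open.

## Equilibrium model of HNRNPH binding to an unfolded rG4

An rG4 with `n_sites` G-runs (default 4) is either folded or unfolded.  Each
bound HNRNPH protein engages a contiguous block of 1..`max_qrrm` G-runs
(default 3, one per qRRM); every contact beyond the first is a backfolding
event.  With the unfolded, unbound RNA as reference (weight 1), a state with
proteins making contacts (k_1, …, k_m) has weight

    multiplicity · (c/c0)^m · exp[(Σ k_i·g_bind − Σ (k_i−1)·g_backfold) / RT]

where the multiplicity counts ordered placements of the unlabeled proteins on
the linear G-run array (so 2^22 — two proteins with two contacts each — has
multiplicity 1, and 2^31 has multiplicity 2).  The folded, unbound state has
weight exp(g_rG4/RT); an optional helper state 1^F (one protein bound to the
still-folded rG4) has weight (c/c0)·exp[(g_rG4 + g_rG4_bind)/RT].  All
weights are accumulated in log space.  Energies are in kcal/mol
(R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹), T = 298 K, and the reference concentration
is c0 = 1 mol/l; with these conventions −RT·ln(0.2 µM) = 9.2 kcal/mol, which
fixes the per-contact binding energy from the measured dissociation constant.

Derived quantities: the bound fraction (states with m ≥ 1, helper included),
the transition concentration K (bound fraction = 1/2, found by bisection of
log-concentration on [10⁻³⁰, 10¹⁰] mol/l to near machine precision), and the
Hill coefficient n_H = log 81 / log(EC90/EC10) of the min–max-normalized
binding curve on a log-spaced grid of 121 points spanning 6 decades centered
on K (both grid parameters are exposed).  EC10/EC90 are located by
piecewise-linear interpolation — the simplest monotone choice.

### Statistical-weight convention audit

The published account does not fully specify the statistical weights, and two
natural conventions differ in testable ways:

* **Bare multiplicities (default).**  The three qRRMs are treated as fully
  equivalent and a protein's weight carries no combinatorial factor for
  *which* qRRMs engage.  Under this convention 2^31 outweighs 2^22 two-to-one
  (equal energies, higher placement multiplicity).
* **qRRM-combination degeneracy (`qrrm_degeneracy=True`).**  Each protein's
  weight gains a factor C(max_qrrm, k) for choosing its k engaged qRRMs.
  Under this convention 2^22 : 2^31 = 9 : 6, i.e. 2^22 dominates, matching
  the reported dominance order at the fitted energies.

The inversion of the backfolding penalty from the observed transition
(K = 3×10⁻⁶ mol/l at g_rG4 = 23, g_bind = 9.2 kcal/mol) gives
−0.29 kcal/mol under the bare convention and +0.17 kcal/mol with the
degeneracy factor, versus the published 0.8 kcal/mol — a residual
discrepancy of order 1 kcal/mol attributable to the unspecified weight
conventions (multiplicity rules, reference concentration, and possibly a
nonlinear backfolding cost).  Both values are reported rather than tuned.
The qualitative model behavior is convention-independent: n_H → 4 without
backfolding, n_H ≈ 2 with free backfolding, helper states below
~4 kcal/mol leave n_H unchanged while strong folded-rG4 binding collapses
cooperativity toward 1.

A boundary caveat: with g_backfold = 0 the claim "n_H ≤ 2 for all
K < 0.1 mol/l" is approximate near the upper end.  The three-protein state
(1,1,2) carries the same total contact energy as the dominant two-protein
states and a relative weight of order K/c0 regardless of g_bind, so n_H
creeps above 2 (to ≈2.1 in the continuum limit) as K approaches 0.1 mol/l.
On the standard sweep (g_rG4 ∈ [15, 35] × g_bind ∈ [8, 15] kcal/mol, 5×5)
with the standard Hill grid the measured maximum over K < 0.1 is 2.018.

The reduced "double-backfolding" model keeps only 2^31 and 2^22 (plus the
unbound and folded states); it tracks the full model to within 0.05 in bound
fraction for penalties below ~7 kcal/mol, beyond which the full model's
Hill coefficient rises toward 4 and the reduction loses validity.

## Dose–response fitting and classification

ΔPSI observations are fitted pointwise (no replicate averaging) with
f(x) = min + (max − min) / (1 + exp(b·(log x − log ec50))) under box
constraints min ∈ [−max(PSI_KD, PSI_OE), 0], max ∈ [0, 1 − min(PSI_KD,
PSI_OE)], ec50 ≥ 0, b unbounded.  The optimizer is bounded least squares
(trust-region reflective, tolerances 10⁻¹⁴) restarted from
b ∈ {±1, ±5, ±15} × ec50 ∈ {0.7, 1.0, 1.3}; the best SSE wins and ties go to
the smallest |b|.  The reported n_H is |b|; the direction (enhanced vs
repressed) is the sign of f(x_max) − f(x_min).  Goodness of fit is the
pseudo-R² = 1 − SS_res/SS_tot against the observation mean (may be
negative); events below 0.75 are excluded, the rest are classified
cooperative iff n_H ≥ 2.  Degenerate inputs (fewer than five distinct
levels; an all-constant response) raise or are excluded explicitly.

## Splicing cascade

Three algebraic steady-state levels map the HNRNPH level H to exon
inclusion:

1. bound = H^n1 / (H^n1 + K1^n1)
2. E = (1 + (α−1)·bound)^n2 / ((1 + (α−1)·bound)^n2 + K2)  — K2 enters
   un-exponentiated, exactly as printed in the source description.
3. PSI = 1 − [k_CE / (k_CE + k_AE·E)] · exp(−k_AE·E·τ)

The printed expression for level 3 is typographically ambiguous; the parse
adopted here is kinetic competition between inclusion and skipping times the
probability that no commitment to skipping survives the window τ.  It is
monotone in H for α > 1 and sigmoidal, as the model requires; the literal
alternative parse (the exponential inside the denominator), which is not
monotone, is available via `literal_level3=True`.

Hill coefficients (per level and overall) use the same EC10/EC90 estimator
on min–max-normalized curves; the H grid spans 8 decades around K1 (801
points).  Responses with a PSI dynamic range below 10⁻³ are reported as
flat rather than assigned a coefficient — normalizing a saturated curve
would amplify numerical noise into a spurious n_H.  Population sampling
draws every parameter independently from log-normal distributions
(median·exp(N(0, log-sd))) and records non-monotone or flat runs as excluded
rather than dropping them.

Default medians: n_H1 = 2 (the in vitro binding cooperativity), K1 = 1
(levels are relative to control), n_H2 = 2 (HNRNPH acts on both U1 and U2
recruitment), K2 = 25, α = 10, k_CE = 2, k_spl_AE = 4, τ = 1, log-sd 0.5.
K2, k_CE and k_spl_AE were chosen so the baseline PSI response actually
traverses its range (≈0.2 → 0.98) with all three levels mildly sigmoidal; a
parameterization with the decision level saturated (PSI pinned near 1,
dynamic range ~10⁻³) would make the cascade's output insensitive to HNRNPH
and the Hill analysis meaningless.  These are documented stand-ins — the original
parameter values were not published alongside the model description — and
are fully configurable.

The amplification bound is checked constructively: for three pure Hill
stages with fixed exponents, the overall n_H of the composite (on a grid
where the response traverses ≥99.9 % of its dynamic range) is maximized
over the two downstream thresholds by coarse log-grid search plus
Nelder–Mead refinement; for exponents (2,2,2) the optimum reaches 7.9999,
i.e. the product bound n1·n2·n3 = 8 is approached but not exceeded.

## iCLIP binding-site definition

Significant crosslink positions at most 3 nt apart are merged into regions;
regions shorter than 2 nt are discarded.  Sites are placed iteratively: the
position with the most crosslink events (leftmost on ties) is extended ±2 nt
into a 5-nt site, then the site plus 4 nt on either side is cut out and the
procedure recurses into the remainders.  Cut-out positions are gone for
good: a placement whose 5-nt footprint would reuse them is discarded (its
position is still excised so iteration terminates).  This reading enforces a
≥4 nt edge-to-edge gap between sites; the naive alternative (allowing
footprints to reach back into excised territory) admits gaps of 2 nt.
Cleanup removes sites whose center is neither a significant position nor the
in-site count maximum (the OR reading; the stricter AND is available via
`removal="and"`), and sites with fewer than 3 covered positions.
Coordinates are 0-based half-open internally, BED6/bedGraph on disk, strands
independent.  Sites whose ±2 nt extension would leave the contig are
discarded.

## RT-stop rG4 calling

Per 200-nt construct and salt condition, read starts are summed over
replicates; positions 19..200 with ≥6 stacked read starts seed 3-nt peaks
(positions 1–18 are excluded because full-length cDNAs pile there).  Peaks
are assembled greedily from the strongest seed down, kept when ≥2 of 3
positions carry signal, windows clamped to 19..200 at the boundaries.  KCl
and NaCl peak sets are merged; partial overlaps are re-centered on the
maximum combined coverage.  Constructs with <100 normalized reads
(median-of-ratios size factors) or a strong, significant between-condition
total-count change (|L2FC| ≥ 1, BH p < 0.05) are excluded.  The printed
description of the variability filter invokes a "lessAbs" test, whose
significant outcome actually marks *stable* constructs; the implementation
follows the stated intent (exclude high-variability constructs) and the
literal behavior is available via `literal_lessabs=True`.

Differential testing is a self-contained negative-binomial Wald test:
size-factor-normalized means per condition, method-of-moments dispersion
pooled across conditions with a floor of 0.01, a pseudocount of 0.5
normalized reads, and a delta-method standard error on the log2 fold change;
p-values are BH-corrected at α = 0.05 and fold changes are shrunk toward
zero by a normal empirical-Bayes prior whose variance is the cross-peak
L2FC spread in excess of sampling noise.  A peak is an rG4 when adjusted
p < 0.05 and the shrunken L2FC (NaCl relative to KCl) is negative.  The test
is validated by simulation (power, type-I error) and cross-checked against
an independent DESeq2 analysis in the test suite; bit-compatibility with any
particular external package is not a goal.  Regions (four barcoded
constructs each) are rG4 with ≥2 rG4 constructs, non-rG4 with zero, and
inconsistent otherwise; the representative construct has the highest read
count.  Propensity scores are ratios of in-peak read starts over total
construct reads: the representative peak maximizes the ratio, the
g4-propensity sums ratios over rG4 peaks, and the total construct ratio
divides that sum by the number of peaks.

## Splice maps

Windows open at the four splice sites of the cassette-exon triplet, up to
50 nt into exons and 300 nt into introns (truncated at short features;
missing positions are NaN and averaged over available events).  Each window
is min–max normalized (all-equal windows map to zero) so heavily crosslinked
events cannot dominate, then averaged position-wise per group and smoothed
with locally-weighted regression (lowess; span 0.2 by default — the source
does not state one).  Profiles are reported in transcript orientation.

Control events are PSI-matched: the target group's PSI quantiles at
(0, 5, 70, 80, 100) % for enhanced and (0, 10, 65, 90, 100) % for repressed
events define four bins; ceil(target/4) controls are sampled per bin
(with replacement plus a warning when a bin is short).  Differential binding
uses overlapping 10-nt windows (step 1): per-event window means, two-sample
Wilcoxon (Mann–Whitney) tests, BH correction, significance at FDR ≤ 0.01;
all-tied windows get p = 1.  Junction PSI is inclusion/(inclusion+skipping)
when the junction support is ≥25 reads (otherwise missing); the variant for
an exon whose skipping makes an NMD substrate is (i1+i2)/(i1+i2+2·s).

## Synthetic data

Generators are deterministic functions of the configuration seed and emulate:

* **Titrations** — 12 protein levels log-spaced on [0.46, 1.76] (the printed
  extremes of the knockdown/overexpression series; intermediate levels are a
  stand-in), LL.4 ground truth, Gaussian ΔPSI noise (default sd 0.02),
  3 replicates.
* **Crosslink tracks** — Poisson background plus triangular signal kernels of
  half-width 2 nt (matching 5-nt site geometry); "significant" positions are
  counts above the 99.9th percentile of the background, a surrogate for an
  HMM peak caller's output.
* **Oligo library** — 18-nt T7 promoter + 146-nt insert + 15-nt barcode +
  21-nt L3 linker; barcodes pairwise Hamming ≥5 without GGG (vectorized
  rejection sampling); planted canonical rG4s (four G-triplets, 1–7-nt
  non-G loops) start at construct position 51; background sequence is
  G-run-free so planted quadruplexes are the only consensus matches.
* **RT-stop counts** — uniform Poisson background, a 5'-end pileup over
  positions 1–18, and, only under KCl+GTP for rG4 constructs, a
  negative-binomial stall pileup at the position immediately 3' of the
  planted rG4 (fractions 0.7/0.2/0.1 over the stall position and the two
  positions further 3', emulating slight RT stutter so stop peaks have the
  2-of-3 coverage real stops show).  NaCl and 7dGTP abolish the stall.
* **In vitro binding** — the equilibrium model's bound fraction plus
  Gaussian noise.

What the generators do **not** emulate: sequencing reads (UMIs, mapping,
sequencing error), crosslinking sequence bias, partial or kinetically slow
rG4 folding, inter-replicate batch effects beyond NB dispersion, and genomic
context (real introns/exons, expression differences between events).
Passing recovery tests therefore demonstrates that the *analysis rules* are
implemented faithfully and have the claimed statistical behavior under the
stated noise models — not that the pipeline is robust to every artifact of
real libraries.

## Problem sizes and numerics

The test suite and the reproduction script run at desk scale by design:
titration recovery uses tens of events, site-caller recovery ~130 planted
sites over kilobase tracks, the RT-stop end-to-end checks 15–20 regions
(60–80 constructs) per seed, the null FDR checks 40–50 simulated
profile sets, and the equilibrium sweeps 25-point energy grids.  These sizes
were chosen so each property is measured with comfortable statistical margin
while the whole suite stays fast; all of them are parameters, not limits.

Known numerical choices collected in one place: log-sum-exp partition sums;
bisection tolerances ~10⁻⁹ relative for K and 10⁻⁶ for the penalty
inversion (bracket −10..20 kcal/mol); 121-point/6-decade Hill grids for the
equilibrium model and 801-point/8-decade grids for the cascade; LL.4
multistart as above; lowess span 0.2; NB dispersion floor 0.01 and
pseudocount 0.5; flat-response threshold 10⁻³ PSI.
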