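# Methods

## Logistic growth and the iterated map

The package treats logistic growth in two distinct roles that must not be
conflated.  The *population envelope* of the simulator is the closed-form
solution N(t) = C·N0 / (N0 + (C−N0)·e^{−rt}) on time normalized to [0, 1],
which is smooth and monotone for every r.  The *iterated map*
x' = r·x·(1−x) is the qualitative argument about predictability: its
attractor is a fixed point for r < 3, splits into cycles at r = 3 and
1+√6 ≈ 3.4495, and becomes chaotic near 3.57.  Fitted growth rates are
interpreted against the map's bifurcation structure (`growth_regime`), but
simulated trajectories always follow the closed form.  A consequence worth
stating explicitly: in this package mutation accumulation rises *smoothly*
with r (more growth → more divisions → more mutations), so the increase
across r = 3 is a monotone difference, not a literal discontinuity; a
genuine jump would require the population itself to follow the map's
oscillatory dynamics, which is outside this model.

### Attractor-period detection

Naive period detection (iterate, discard a fixed burn-in, test whether the
window repeats with period p) fails near bifurcation points: convergence
slows critically, and just below r = 3 the decaying alternation passes a
strict period-2 test while the period-1 test fails, which would misplace
the first onset below 3.0.  The scanner therefore confirms a candidate
period only when the same minimal p is found, with cycle values stable to
`tol`, on two consecutive windows separated by a doubling burn-in (start
x0 = 0.5, first stage burn-in 1000, window 512, tol 1e−6, cap 2²¹ total
iterations; all configurable).  Orbits whose best residual stops shrinking
with no fitting period resolve to "aperiodic".  Onset queries can return
the bracket midpoint between the last sub-threshold and first
super-threshold grid points (`refine=True`), which halves the
discretization bias; on the 0.001-step grid this locates the onsets at
2.9995 and 3.4495.

## The clone-table simulator

Cells are grouped into clones — genotype classes carrying a set of driver
mutation IDs, a neutral-mutation count k, a selection coefficient s, and a
cell count.  This abstracts the spatial automaton picture into a logistic
envelope, which is what makes C = 10⁵–10⁷ tractable on a desktop; spatial
niche effects are deliberately out of scope (see Limitations).

Per generation (G equipartition steps of normalized time):

1. target N_{g+1} from the closed form;
2. the net increment is allocated as divisions by multinomial draw with
   weights count·b·(1+s) — fitter clones divide more under the same
   envelope;
3. each division mutates with probability m; a mutation is a driver draw
   with probability p (uniform over the catalog's pathogenic partition),
   else neutral.  Drivers found a child clone with s' = s + α·(score−0.5)
   (additive, order-independent, a Markov update in s); neutral mutations
   found a child in class k+1.  Neutral dynamics depend only on k, but
   distinct IDs are drawn for the registry so surviving-mutation counts are
   meaningful;
4. baseline deaths (probability d per cell), then ratchet enforcement: the
   capacity of neutral class k is the Poisson mass n_k = N·e^{−θ}·θ^k/k!
   with N the logistic target, and any excess is removed uniformly at
   random (multivariate hypergeometric) — burden-dependent apoptosis, the
   Muller's-ratchet channel;
5. re-normalization to the target by multinomial resampling proportional to
   clone counts, so the realized trajectory is exactly logistic
   (conservation is asserted in tests).

### The θ convention and the ratchet selection coefficient

Classical Muller's-ratchet theory (Haigh) puts the fittest-class equilibrium
at n0 = N·e^{−u/s} with u the deleterious mutation rate and s the selection
coefficient, i.e. θ = u/s; the inverse ratio also circulates in the
literature.  Both are implemented (`theta_convention="haigh" | "paper"`).
The default is the classical one, because only θ increasing in m yields the
qualitative behavior the simulator exists to show — the ancestor fraction
*decreasing* with mutation rate; with the inverted ratio the least-loaded
class's capacity collapses as m shrinks, which is biologically backwards
here.  The convention used is echoed in every result.

The selection coefficient `ratchet_s` entering θ has no principled value in
a model whose neutral mutations are fitness-neutral by construction, so it
was fixed once by analysis: with trim-to-cap followed by proportional
refill, the ancestor-class fraction equilibrates at e^{−m/s}/(1−d) (the
cap is enforced against the logistic target after deaths removed a fraction
d, hence the inflation factor).  Matching that equilibrium to ancestor
fractions of roughly 0.9 at m = 0.01 and 0.35–0.45 at m = 0.04 — the range
reported for simulations of this design — gives s in [0.036, 0.053];
the default is the round midpoint **s = 0.04**, a standard magnitude in the
ratchet literature.  Defaults elsewhere: b = 1, d = 0.1 per generation,
α = 0.1 (driver scores above 0.5 convert to percent-scale selection
coefficients), G = 50, one PCG64 stream per run seeded by `seed`.

At the sweep conditions used throughout (r = 2.0, N0 = 10³, C = 10⁵,
p = 0.01, 100 seeds), mean MRCA fractions are ≈ 87 / 66 / 54 / 40% for
m = 0.01 / 0.02 / 0.03 / 0.04 — strictly decreasing and strongly nonlinear
in m, since θ enters through an exponential.

## Clonal-landscape metrics

End-state cells are clustered by total mutational burden with **exact 1-D
k-means**: dynamic programming over contiguous partitions of the distinct
burden values weighted by cell counts (optimal in one dimension,
deterministic — unlike Lloyd's algorithm there is nothing to seed).  The
number of clusters is chosen in 1..6 by the cell-weighted mean silhouette,
ties toward fewer clusters; single-valued populations return one cluster.
The MRCA fraction is the cell percentage of the smallest-centroid cluster —
a *cluster*-based definition, so late ancestors carrying one or two
mutations can legitimately fall in the MRCA cluster.

Growth-rate scans are reduced with a three-section convention mirroring the
bifurcation structure: r < 3 replicate means ("grey"), 3 ≤ r ≤ 3.5 cluster
centroids of replicate values ("black", one value per branch, same 1-D
k-means), r > 3.5 all replicates ("red").  Both boundaries are assigned to
the black section (the convention is tested explicitly).

## Growth-curve fitting

Series are affinely mapped to normalized time (first point → 0, last → 1;
idempotent) and fitted by bounded nonlinear least squares in (N0, C, r),
multi-started at r ∈ {0.5, 1, 3, 10, 30} to span the rates observed across
model systems; the winner minimizes the residual sum of squares, ties to
the smaller rate.  The logistic/non-logistic call is `converged ∧ r² ≥ 0.9`
(threshold configurable and reported) — a deliberate operationalization,
since published analyses rarely state theirs.  Capacity bounds default to
the experimental context (1500–5000 mm³ in vivo, 1.5–2×10⁸ cells in vitro)
and double whenever the observed maximum exceeds them.  Recovery at the
defaults: noiseless series return r to well under 0.1%; with 5%
multiplicative log-normal noise on 8 points the median relative error is
4–8% for r ∈ {1, 10, 31}.  Cohort summaries report medians both over
logistic fits and over all converged fits, because published pooled medians
are ambiguous about which set they use.

## Variant filtering and statistics

Exclusion rules, read literally: depth ≤ 10 in every culture sample
(strict at 10, kept at 11); VAF < 0.1 in all culture samples; and the
baseline rule — strict mode drops variants found in more than 1% of the
seeding sample's reads, relaxed mode *replaces* that criterion with a seed
VAF allowance up to 0.1 (for seed fractions in (0.01, 0.1] the two modes
deliberately disagree; the relaxed set is a superset).  Filtering is
idempotent.

The "two-way ANOVA" is a fixed-effects serum-group × time-point
decomposition (type-II sums of squares via OLS), the interaction included
when every design cell has ≥ 2 observations; week-3 and week-6 samples are
treated as independent (unpaired), the layout matching a 2 × 2 × 3 design.
Degenerate inputs are defined: an all-identical response gives F = 0,
p = 1; an empty design cell raises an error naming the cell.  The
chromosome-wise variant keeps chromosomes with ≥ 4 detected variants
(boundary included) and runs the same ANOVA per chromosome.  VAF
distributions are summarized per (group, timepoint) (mean, KDE mode,
SD) with a two-sided Mann–Whitney comparison between groups — a rank test,
chosen because no distributional form is defensible for filtered VAFs.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the analyses assume:
catalog scores uniform within class bands; growth curves from the closed
form with multiplicative log-normal noise (σ = 0.05) and a configurable
fraction of non-monotone artifact series (abrupt collapse-and-recovery, the
kind of measurement artifact that breaks logistic fits); variant tables
with Poisson per-sample novel-SNV counts (defaults 6/6 at week 3, 7/20 at
week 6), truncated-Beta(2.5, 7.5) VAFs unimodal near 0.25, depths
11 + negative-binomial (~30×) quantized to whole read counts so TSV, VCF AF
and AD agree exactly, seed contamination planted on both sides of the 1%
and 10% thresholds, and chromosome labels guaranteeing both passing and
failing cases for the ≥ 4-variant rule.  Every generator is
byte-deterministic given its seed (PCG64, fixed formatting) and emits a
planted-truth sidecar.

What passing tests on these data do **not** show: recovery of published
cohort percentages or controlled-access WGS statistics (those inputs are
not redistributable); robustness to caller-specific artifacts, mapping
bias, or copy-number-distorted VAFs (not simulated); spatial clonal
structure (not modeled).

## Problem sizes and numerical choices

Tests and the acceptance script run the simulator at C = 10⁵, N0 = 10³,
G = 50 with 100 seeds per condition, and the map scan at grid step 0.001 —
sizes chosen so the full suite completes in well under a minute of compute
while keeping Monte-Carlo error far below the tolerances asserted.
Clustering ties break toward fewer clusters; map-scan ties toward smaller
periods; fitting ties toward smaller rates.  Extinction (a population
reaching zero) terminates a run early with a flagged, still-valid result.

## Known limitations

* No spatial structure: niche protection, boundary-driven selection, and
  spatially segregated subclones are absent, so the MRCA fraction may
  understate heterogeneity relative to spatial models.
* The growth envelope is exactly logistic by construction; feedback of
  fitness on the *global* growth rate is not modeled (fitness only shifts
  division shares between clones).
* Muller's-ratchet enforcement uses equilibrium Poisson capacities each
  generation rather than explicit deleterious fitness, an intentional
  simplification consistent with fitness-neutral "burden" mutations.
* Logistic-only fitting: Gompertz or accelerated-time alternatives are not
  compared.
* The simulator's clone table merges neutral lineages only through their
  class index for dynamics; linkage between co-occurring neutral mutations
  is not tracked beyond the clone genealogy.
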