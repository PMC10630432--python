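# Methods

## The statistic

The core object is the shared-fraction profile. Let a *SASV* be an ASV whose
exact sequence occurs both in a sediment-trap sample and in the water column
at depth *Z*. Two directions of the statistic are computed for every (trap
interval, depth) pair:

* **water-column fraction** — the summed relative abundance, in the
  water-column reference at depth *Z*, of the ASVs shared with that trap
  sample. It measures how much of the suspended community at *Z* is entrained
  in particles reaching the trap.
* **trap fraction by origin depth** — the summed relative abundance, in the
  trap sample, of the ASVs shared with depth *Z*. It measures how much trap
  material originates from (or is colonized by taxa resident at) depth *Z*.
  Because one ASV can be resident at several depths, these fractions can sum
  to more than one across depths; this is intentional multi-membership, not
  double counting.

Presence means relative abundance strictly greater than zero (configurable
floor, `min_presence`). Sequence identity is exact full-length string
equality after uppercasing and U→T mapping. Datasets produced with a
uniformly masked low-quality position carry the mask as an `N` in every
sequence, so literal equality still matches; for mixed datasets an optional
N-wildcard mode treats `N` as matching any base at that position
(equal-length sequences only; no other fuzziness is supported).

## Water-column reference: monthly climatology

Moored-trap time series span years while water sampling is roughly monthly,
so each trap interval is compared against a *monthly climatology*: for every
(depth, calendar month), replicates at one date are averaged, then dates
within a (year, month), then years — an unweighted mean of normalized
vectors, which stays normalized. A trap interval spanning a month boundary is
assigned the month of its midpoint. Missing (depth, month) entries are filled
with the elementwise mean of the two calendar-adjacent observed months
(December and January adjacent); if a neighbor is also missing this is a hard
error naming the entry, unless the nearest-month fallback is explicitly
enabled. The default target is all twelve months; callers can restrict it to
the months the trap record actually needs. For expedition data where water
casts are contemporaneous with the trap deployment, a *direct* mode pools the
same-period water samples per depth and bypasses the climatology.

An open choice documented here: the water-column fraction's denominator is
the full normalized climatology vector at (depth, month), not a vector
restricted to taxa observed in any particular subset.

## Power-law fits

Profiles of per-depth means are fit to S_Z = S_ref (Z/Z_ref)^b by unweighted
nonlinear least squares *on the linear scale* with both parameters free,
initialized from ordinary log–log regression (which is already exact on
noiseless power-law data). The defaults anchor the upper-ocean fit at
Z_ref = 75 m over 75–250 m — 75 m approximates the base of the mixed layer,
below which net community production is small, so it serves as the reference
depth of particle export — and the deep fits at 250 m over 250–4000 m.
Numerical conventions:

* R² = 1 − SS_res/SS_tot on the linear scale; undefined (reported null) for a
  zero-variance profile, which returns b = 0 exactly.
* p-value: two-sided t test of b = 0 using SE(b) from the NLS covariance with
  df = n − 2. This replaces an unrecoverable third-party recipe and is
  flagged in every fit's output metadata. A perfect fit with nonzero slope
  reports the smallest positive float rather than 0 so that p ∈ (0, 1].
* 95% CI on b as b ± 2·SE(b) (two-sigma convention).
* Two points: closed-form exact solution; no uncertainty estimate (p = 1,
  infinite CI).
* Fits are scale-equivariant: multiplying a profile by c > 0 scales S_ref by
  c and leaves b, R² and p unchanged. Fractions are used internally; outputs
  also report S_ref in percent.

Per-interval fits produce the b time series; intervals with fewer than two
usable in-window depths are skipped with a warning. Covariate correlations
use Spearman rank correlation by default (Pearson optional),
pairwise-complete, with constant covariates flagged undefined.

## Depth-zone classification

Abundant SASVs (time-averaged water-column profile maximum ≥ 0.1%, boundary
inclusive) are classified by their depth maxima into six zones: Surface
5–75 m, DCM 100–150 m, Lower Euphotic 175–200 m, Upper Mesopelagic
225–500 m, Lower Mesopelagic 770–1000 m, Bathypelagic 2000–4000 m. Peak
conventions are explicit: an interior peak is strictly greater than both
neighbors; an equal-valued plateau flanked by smaller values is one peak at
its shallowest depth; a boundary value strictly greater than its single
neighbor is a peak when `edge_peaks` is on. `edge_peaks` defaults to *on*,
deliberately differing from common peak-finder defaults that ignore
boundaries: taxa maximal at the shallowest or deepest sampled depth (surface
picocyanobacteria, abyssal clades) must be classifiable; the
boundary-excluding behavior is available behind the flag. Bimodal profiles
are retained only if exactly one maximum exceeds the profile's depth-averaged
mean (zone of that maximum) or both maxima fall in one zone; other bimodal
profiles and >2-peak profiles are excluded with a recorded reason. The
depth-averaged mean uses all grid depths, including zeros. On a grid with
depths between zone bounds, the nearest zone-midpoint rule applies (the
standard grid has no such depths; a strict mode errors instead). Zone
composition groups retained SASVs by taxon; a zone's coverage is the whole
retained set's abundance at that zone's depths as a fraction of all profiled
SASV abundance there.

## SEP flagging and enrichment

A trap interval belongs to the summer export pulse when both its particulate
carbon and particulate nitrogen flux ratios (flux over the long-term annual
reference mean) are ≥ 1.5, boundary inclusive; an `--any` relaxation accepts
either ratio. Intervals without a flux record are flagged unknown and
excluded. Enrichment uses Welch's unequal-variance t test per ASV (explicit
Welch–Satterthwaite formulas; groups of fewer than two intervals or zero
variance in both groups are flagged undefined rather than raising) with a
two-sided p-value plus a direction gate: enriched ⇔ p < α and
mean_SEP > mean_non-SEP. The direction gate makes the null rate of the
*enriched verdict* α/2 while the test itself calibrates to α; both rates are
verified by permutation in the test suite. No multiple-testing correction is
applied by default, matching the uncorrected p < 0.05 convention of the
field analysis this mirrors; Benjamini–Hochberg q-values are available
behind a flag and always yield a subset of the uncorrected calls.

## Synthetic data: what it emulates and what it does not

The generator's defaults reproduce the study design the package targets: a
19-depth grid from 5 to 4000 m, two years of monthly water-column sampling
(so every calendar month averages two years), 58 twelve-day abyssal-trap
intervals starting in March, and July/August SEP pulses.

Planted structure:

* the water-column shared fraction follows
  S(Z) = S_75 (Z/75)^b_upper for 75 ≤ Z ≤ 250 m (defaults S_75 = 0.829,
  b_upper = −1.34), an increasing power law with b_deep = +0.31 below 250 m,
  and a constant S_75 shallower than 75 m (observed upper-ocean profiles are
  roughly flat above the export reference depth; extending the power law
  upward would exceed 1). The curve is continuous at both junctions and the
  generator refuses configurations where S(Z) > 1 anywhere.
* ecotypes are Gaussian bumps on log10-depth (σ = 0.12 by default, truncated
  at 3σ), one or two peaks, 19 default taxa patterned on the dominant clades
  of each zone. A per-depth *shared filler* ASV tops the shared mass up to
  exactly S(Z) and a per-depth *unshared filler* carries 1 − S(Z), so in
  noiseless mode the pipeline's water fraction equals the planted curve to
  machine precision.
* the trap column allocates mass so the trap fraction attributable to origin
  depth Z equals a planted power law T(Z) = T_250 (Z/250)^0.31. Because the
  generator's origin-depth masses are disjoint (depth-specific fillers), the
  anchor is T_250 = 0.04 — smaller than a real trap community's, whose
  origin-depth fractions overlap and can sum past one — which is immaterial
  to exponent recovery since the fit is scale-equivariant.
* eight copiotroph ASVs resident at 4000 m are multiplied five-fold in SEP
  trap columns (then renormalized); flux records exceed 1.5× both reference
  means exactly in SEP intervals. The renormalization slightly perturbs the
  4000 m point of the trap-side profile, so the trap-side exponent is
  recovered exactly only with the pulse disabled (`sep_multiplier = 1`); the
  water-side curve is unaffected.
* with `reads_per_sample` set, counts are multinomial draws per sample from
  the exact compositions; all randomness (including the unique 250-nt random
  ASV sequences and flux draws) flows from one seed, and identical
  configurations are bit-identical.

What the generator does **not** emulate: compositional correlation between
taxa beyond the multinomial constraint, seasonality of the water column,
sequencing error and chimeras, overlapping origin-depth trap mass, particle
sinking dynamics, and realistic phylogenetic sequence structure. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated sampling model, not robustness to artifacts upstream of ASV
tables (read QC, denoising and taxonomy are out of scope; the pipeline
consumes finished ASV tables).

## Problem sizes used in tests and the acceptance script

Noiseless recovery runs the full default design (19 depths × 24 water
months, 58 trap intervals). Stochastic recovery uses 20 seeded datasets at
10⁵ reads per sample (planted b_upper = −0.75; mean recovered b within
±0.05, every per-dataset fit significant at p < 0.05). The fit oracle checks
50 random ≤ 6-point profiles against a dense grid search over b with the
closed-form optimal S_ref per candidate (|Δb| ≤ 0.01). Classification
recovery plants 100 unimodal and 20 bimodal profiles (10 rule-1, 5 rule-2,
5 ambiguous) and requires exact counts and zones. Null calibrations use
1000 permutation replicates. These sizes were chosen so every recovery
check is well-powered while the whole suite completes in about a minute on
one CPU.

## Known limitations

* The water-fraction denominator choice (full climatology vector) and the
  midpoint-month convention for straddling trap intervals are defensible
  but not uniquely determined by the field protocol they mirror.
* The p-value for b assumes approximate normality of the NLS estimate at
  small n; with 7–9 depth points it is indicative, and the per-interval b
  confidence intervals (±2σ) should be preferred for inference.
* Exact-sequence matching treats a single-nucleotide variant as a different
  taxon; the N-wildcard mode only addresses uniformly masked positions.
* Enrichment testing is performed on relative abundances without
  compositional (log-ratio) adjustment, matching the convention of the
  analysis it mirrors; strong pulses of a few taxa necessarily depress the
  remaining fractions.
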