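# Methods

## The problem

Fossil-calibrated molecular dating is usually assumed to be *most* reliable
for recently diverged clades: rates are closer to clock-like, and multiple
substitutions at the same sites (saturation) have had little time to
accumulate. `satclock` encodes the opposite concern: when the loci are
saturated at depth and the calibrations sit on deep nodes, the inferred
clock rate is an *apparent* rate — distance at the calibrated node divided
by its age — which under-states the true rate. Young, unsaturated nodes are
then dated too old, and the bias grows with the temporal depth of the
calibration used. Conversely, calibrating only on shallow nodes recovers the
true rate but compresses the ages of saturated deep nodes, to the point of
rejecting well-established fossil minima.

The package lets this mechanism be studied end to end at desk scale: a
closed-form saturation model, a synthetic data generator shaped like a
17-taxon aquatic-bird (flamingo-anchored) study system, a strict-clock
distance dating engine with minimum-age calibrations, and a 45-run
sensitivity harness over locus, taxon and calibration subsets.

## The saturation model

Expected percent distance after `t` MY of divergence is piecewise linear:
slope `r` (default 1 %/MY) up to an onset `T0` (default 20 MY), after which
the k-th window of width `w` (default 10 MY) has slope `r·f^k` with decay
`f` (default 0.5) — the first post-onset window is already halved. With the
defaults: d(20)=20, d(30)=25, d(60)=29.375, asymptote 30. The convention
that the first post-onset window uses slope `r·f` (rather than the halving
starting one window later) is deliberate and is what makes the worked
values above hold.

Single-calibration dating at a node of true age `a` estimates ages as
`d(t)/(d(a)/a)`. Several calibrations pool into one rate by through-origin
least squares of distance on age, `Σ a·d(a) / Σ a²`; ages enter
quadratically, so deep calibrations dominate — matching the observation
that results respond more to calibration *depth* than to calibration
*number*. An equal-weight mean of apparent rates is available as an
alternative pooling.

Deviation classes (−/0/+) use a 5 % relative tolerance by default; the
source of the sign convention gives no numeric threshold, so this is a
package choice, shared across the analytic module and the sweep harness.

## Synthetic data

**Chronogram.** Seventeen taxa: six flamingos in two genera, two grebes,
nine outgroup waterbirds. Anchored ages: youngest split 0.5 MY, crown
flamingos 4.4 MY, the seven calibrated splits at their fossil minima (the
penguin–tubenose divergence at 62 MY, just above its 60.5 MY minimum), root
at 64 MY. Uncalibrated node ages are interpolated between anchors; they are
a modelling choice, not data. The fixture is deterministic — the `seed`
argument exists for interface uniformity.

**Sequences (mechanistic mode).** Kimura two-parameter evolution along the
tree under a strict clock. The nuclear panel is seven 1,000-bp loci at a
1 %/MY pairwise rate (κ=2); the mitochondrial partition is 1,500 bp at 5×
that rate (κ=4). The mitochondrial multiplier is not quantified by the study
system and is configurable; 5× puts mtDNA deep into saturation at ordinal
timescales (p-distance ≈ 73 % at 62 MY against a 75 % ceiling) while nuclear
loci are only mildly bent (≈ 42 % observed vs 62 % linear), which is the
regime the analyses assume. Lengths were fixed once so that binomial noise
does not mask the bias at desk scale.

**Distances (stylized mode).** Pairwise distances drawn directly from a
saturation-model expectation at each pair's MRCA age, with optional binomial
noise for a finite length. This mode has no sequences and isolates the
piecewise law from substitution-process detail; the fossil-rejection
analysis uses it noise-free so its numbers are exactly the model's.

**What the generator does not emulate:** rate variation across lineages or
sites, incomplete lineage sorting, indels/alignment error, base-composition
heterogeneity, and the Bayesian joint-prior machinery. Passing tests
therefore demonstrate the saturation mechanism under clock-like conditions,
not the full error budget of real multi-locus data sets.

## Dating engine

Node heights are half the mean cross-pair distance between the two
descendant sides of each split, computed on uncorrected p-distances by
default (rationale: the package's premise is that available corrections do
not fully remove homoplasy; a Jukes–Cantor correction is available behind
`correction="jc"` but off by default). Multi-locus data are combined by
length-weighted averaging, equivalent to concatenation; per-locus dating
with post-hoc pooling is available via the grid's `pooled_loci` proxy.
Heights are clamped top-down so a child never exceeds its parent; clamped
nodes are flagged.

**Rate fitting.** `point_min` (default) regresses node distance on the
calibration minimum ages through the origin. `soft` minimizes the summed
negative log prior of the implied calibrated-node ages over a deterministic
rate grid with local refinement; lognormal priors place the offset above
the minimum with log-SD `spread` (default 1) and a location chosen so the
95 % offset quantile is ~12.5 MY (or `soft_max − min_age` when a soft
maximum is supplied); uniform priors are flat between minimum and maximum,
and a flat penalty surface resolves to the point-minimum rate. Soft mode is
an approximation of prior-shape experiments, not a posterior: interactions
among joint priors in a full Bayesian analysis are outside this proxy.

**Minimum-age flooring.** After `age = distance/rate`, every node carrying a
*used* calibration is floored at its minimum age and parent ≥ child
monotonicity is restored upward. This is the point-minimum reading of
posteriors hugging their minimum priors, and it is what allows a fully
calibrated analysis to be consistent with the fossil record even on
saturated data, while held-out fossils (never floored) retain their power
to reject under-estimated ages. Nodes that were floored are flagged in the
output.

**Calibration attachment.** Taxon-set MRCA semantics, robust to pruning; a
calibration whose clade retains a single tip attaches to that tip's parent
(its stem divergence), the standard reading of a stem-group fossil. The
8-outgroup reference taxon set resolves all six standard constraints this
way (the 33.0 MY stem-Sulidae minimum lands on the 51.8 MY Fregatidae
split, an age-consistent placement).

**Uncertainty.** Nonparametric bootstrap (default 100 replicates) resampling
alignment columns within each locus, re-running the whole pipeline per
replicate; 95 % CIs are the 2.5/97.5 percentiles, forced to bracket the
point estimate. `relative_ci` = CI range / point age × 100. Distance-only
input cannot be resampled, so CIs collapse to the point estimate with a
warning.

## Sensitivity harness

The 45-run grid varies loci (4–8, mtDNA in/only/out), ingroup sampling
(2 vs 6 flamingos, grebes excluded), outgroup count (3/8/9/10, realized as
a deterministic keep-priority list), calibration subsets (0–7 constraints,
youngest-two vs oldest-four, single deep constraints) and prior shape
(uniform / widened lognormal via soft mode). Runs whose original meaning is
Bayesian-only (joint-prior tests with zero constraints, unpartitioned
likelihood) map to the nearest distance-engine proxy and are flagged
`approximate`; the zero-constraint runs are carried undated, since a
distance engine has no prior to sample.

Deviations are percent differences from the reference run per named node,
using a both-sides-survive rule: a node's row is emitted only if taxa from
both sides of its original split remain in the run. The factor summary
reports each factor's maximum-magnitude deviation (with sign class) for a
representative young node (crown flamingos) and old node (penguin–tubenose
split). Outgroup-factor contrasts compare each reduced-outgroup run with
its matching full-outgroup run (16↔12 … 19↔15) so the outgroup effect is
isolated from the calibration subset those runs share.

Known limitation: ingroup-subsampling and locus-number effects reported for
the real system arise from node-density and joint-prior behaviour that a
distance engine does not possess (a 2-taxon crown has the same expected
cross-pair distance as a 6-taxon crown), so the harness computes those rows
but their signs are not claims of this package.

## Numerical and scale choices

* The parameter-recovery experiment runs on the fixture scaled by 0.3
  (root 19.2 MY) at a 0.25 %/MY pairwise rate: expected pairwise divergence
  stays ≤ 0.05 subs/site, the regime where multiple hits are well below
  binomial sampling noise — the package's working definition of
  "unsaturated". Twenty seeds × 100 bootstrap replicates complete in a few
  seconds.
* Inverse of the distance law: exact piecewise inversion; distances at or
  beyond the asymptote (30 % by default) are rejected as non-invertible.
* Ties in the soft-mode penalty surface break toward the point-minimum
  rate; the grid spans a 25-fold rate range in 801 log-spaced steps before
  bounded local refinement, making soft mode deterministic.
* Degenerate inputs: zero evolutionary rate yields identical sequences and
  all-zero heights (rate fitting then fails with an explicit error);
  negative times, rates, ages and malformed trees raise `ValueError`.
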