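# Methods

This note documents the statistical procedures, the simulation models, the
numerical choices behind them, and what the test suite does and does not
demonstrate.

## Trajectory model and units

A trajectory is a mutation's population frequency sampled at a host's
sampling days.  Frequencies live in [0, 1]; a reported 0 means *sampled but
below the detection floor* of the variant calls (default 5%, the usual
retention rule for ~300× pool-seq), and is treated downstream as a censored
value, not a measurement of zero.  Days convert to generations linearly;
the default 15 generations/day is the ribosomal-content estimate for
*E. coli* growing in the mouse gut.  All test statistics are computed in
generations, but the two headline statistics p and τ are ratios in which
the unit cancels.

## The p–τ selection test

For the family of *established* trajectories of one population (those ever
exceeding x₀ = 0.01, i.e. past the drift-dominated regime) we estimate:

* **G(x)** — the fraction of established trajectories whose maximum ever
  reaches x.  Since trajectories are interpolated between samples by
  monotone segments, the maximum is attained at a sampled point.
* **T(x)** — the mean, over trajectories reaching x, of the time from
  origination at x₀ to the first crossing of x.

and summarise them as p = G(0.95)/G(0.3) and τ = T(0.95)/T(0.3).  The
thresholds avoid the noisy extremes of pool-seq trajectories; the test is
insensitive to their exact values.

**Origination.**  With a 5% floor the sample preceding the first detection
is 0, so the crossing of x₀ must be reconstructed.  The default (`segment`)
interpolates the segment from the preceding (zero) sample to the first
detection and clips the crossing to that segment; the alternative
(`extrapolate`) extrapolates the first *detected* segment backwards,
clipped to one sampling interval.  Both were validated against densely
sampled noise-free simulations; the segment rule tracks the dense reference
more closely and is the default.  When the preceding sample is a genuine
detection (dense data), both rules simply interpolate the observed segment.

**Interpolation.**  Crossing times between detected samples are
interpolated on the logit scale (default), which represents sigmoid
(constant-selection) trajectories exactly at any sampling interval.
Piecewise-linear interpolation in frequency is available
(`interpolation="linear"`) but overestimates τ badly when the sampling
interval is comparable to the sweep time: on a noise-free logistic with
s = 0.05 sampled every 100 generations the linear chord gives τ = 3.8
against the true 2.0, because the chord crosses the near-fixation level too
late on the concave top and the intermediate level too early on the convex
bottom.  The logit rule is exact in that setting (this is a unit test).
Saturated samples (reported frequency exactly 1.0, i.e. every read mutant)
are clamped to 1 − 1/(2·300) before the logit, reflecting the frequency
resolution of depth-300 sequencing; segments touching a censored 0 fall
back to linear interpolation.

**No-fixation lower bound.**  When no trajectory reaches x_f, p is the
observed 0 and τ is reported as a lower bound:
(end-of-observation − mean origination of the x_m-reachers) / T(x_m), with
`tau_is_lower_bound=True`.  This is conservative: every unfixed trajectory
had at least that long to fix and did not.

**Classification.**  The descriptive regimes overlap, so the classifier
uses fixed, overridable cuts: diversifying if p < 0.5 and τ > 3 (bound
included); periodic sweeps if p ≥ 0.9 and |τ − 2| ≤ 0.5; clonal
interference if 0.2 ≤ p < 0.9 and τ ≤ 2.5; otherwise undetermined.
Observation spans under 2 000 generations are always undetermined — too
short to separate the modes.  Because single-host cohorts are small (often
< 20 established trajectories), pooling replicate hosts
(`pool_sets`) before computing p–τ is recommended; per-host τ is a ratio
of small-sample means and is upward-biased (Jensen).

**A caveat on the mean.**  T(x) is a mean, and under directional selection
with similar selection coefficients a small fraction of trajectories stalls
at intermediate frequency (two co-established clones of equal fitness are
mutually neutral until a further mutation breaks the tie).  These stallers
give T(0.95) a heavy right tail, so measured τ in sweep regimes typically
sits 10–20% above the logistic reference value 2.0 unless sweeps are
strictly non-overlapping.

## Simulators

Both simulators are discrete-generation Wright–Fisher models over genotypes
(full asexuality, no recombination; a mutation's trajectory is the summed
frequency of all genotypes carrying it, so hitchhiking and genetic
backgrounds arise naturally), followed by a pool-seq observation layer:
frequencies at scheduled days are replaced by Binomial(depth, x)/depth with
depth 300 by default, zeroed below the 5% floor, and mutations never
detected are dropped (the retention rule of pooled sequencing).  Everything
is reproducible from a single integer seed; replicate r of a cohort uses
seed + r.

**Directional model.**  Each generation the genotype counts are
multinomially resampled with weights count × Π(1+s_i); Poisson(N·U) new
beneficial mutations each found a child genotype with an extra coefficient
drawn from the configured distribution (fixed s, or exponential with mean
s).  N·U sets the regime: N·U ≈ 0.001 per generation with s = 0.05 keeps
sweeps non-overlapping (periodic sweeps; fixation fraction of a single copy
matches the 2s diffusion prediction, a unit test); N·U ≈ 1 with
exponential s̄ = 0.03 produces pervasive clonal interference.  Populations
are simulated at desk scale (N = 10⁵, 8 000 generations); larger natural
populations are emulated by scaling s and U, since the dynamics depend on
the products N·U and N·s.

**Resource-competition (ecotype) model.**  Each genotype carries an
allocation vector α over R substitutable resources (rows sum to 1).  With
supply rates K_r and population consumption c_r = Σ_g x_g α_gr, fitness is
w_g = Σ_r K_r α_gr / c_r: the marginal value of a resource is inversely
proportional to how heavily it is consumed, so rare types feeding on
underused resources gain an advantage — negative frequency-dependent
selection without any explicit frequency term.  Mutations perturb α by a
truncated Gaussian and renormalize.  The default conditions model an
invader arriving maladapted to a uniform two-resource environment
(ancestor allocation (0.7, 0.3), supply (0.5, 0.5)): mutants grabbing the
underused resource rise quickly and plateau where consumption balances
supply, forming stable coexisting ecotypes.  Defaults N = 10⁴,
μ = 5×10⁻⁵ (N·μ = 0.5/generation), allocation-mutation scale 0.5 were
chosen so that ecotypes form in essentially every 8 000-generation run and
persist against drift (at N ≈ 2×10³ drift extinguishes an ecotype within
the horizon; with small allocation steps early mutants displace the
ancestor instead of splitting the niche).  R = 1 reduces the model to
neutral Wright–Fisher dynamics exactly (all w = 1), which the suite uses as
a null.

## Supporting statistics

* **Sweep calls**: interpolated maximum > 0.95 and every later sampled
  point at or above the maintenance floor (default = threshold; a strict
  mode requires strictly above).  With depth-300 noise a truly fixed
  mutation occasionally samples below 0.95, so analyses of noisy data may
  prefer a floor of ~0.90.
* **M(t)** is the plain sum of allele frequencies per sampled day; its rate
  is the least-squares slope against generations with free intercept (the
  first sample may postdate colonization).  Fixed mutations keep
  contributing 1.0.
* **dN/dS** is a raw count ratio (dS = 0 yields an undefined marker, not
  infinity).  It is *not* site-normalized — that would require the
  reference annotation — so values are comparable across hosts of the same
  organism but are not an absolute ω.
* **NFDS Pearson test**: pairs (x_t, Δx_t) over consecutive detected
  samples, for trajectories detected at ≥ 4 time points; zeros are censored
  values and break pair formation.  A per-generation-rate variant of Δx is
  a flag.  Important limitation: trajectories conditioned to appear and
  later vanish have negative r *under pure neutrality* (rise-and-fall
  selection effect), so a negative r alone is not proof of NFDS; the
  statistic is comparative, and the neutral null that does hold (and is
  tested) is the pooled ensemble correlation of (x, Δx) including
  extinction steps.
* **Rare-type advantage**: least-squares slope of logit(x) vs generations
  over detected samples in the rare range; for logistic dynamics the slope
  is the selection coefficient.  Points sitting at the detection floor are
  upward-censored and attenuate the slope, so the estimate is most accurate
  when the fitted range sits clear of the floor.
* **Lineage nesting** is a deterministic greedy operationalization of the
  rule that a mutation arising on an existing background can never exceed
  it and fluctuates with it: descending order of maximum frequency (ties:
  earlier origination, then id), attach to the deepest placed node that
  dominates the candidate (child ≤ parent + ε at every day, ε = 0.05) and
  correlates positively with it over shared detected days.  Mutations never
  exceeding ε are flagged low-confidence.  In the Muller table a
  parent–child dominance violation beyond ε is an error; sibling
  over-counting (noise, or co-segregating clades the greedy rule failed to
  nest) is clipped with a warning and each day renormalized to sum to 1.
  Like the manual procedure it formalizes, the result is a presentation
  device, not an inference of the true genealogy.
* **OD kinetics**: maximum sliding-window least-squares slope of ln OD600
  (growth) or of ln(OD_mitomycin/OD_control) (induction; the steepest
  decline reported as a positive rate).  Window default 4 points (1.5 h at
  30-min sampling); 2 gives pairwise differences.

## What the synthetic data do and do not show

The simulators reproduce the *statistical structure* the test relies on —
stochastic establishment, sweeps, interference, NFDS plateaus, sparse
sampling, binomial depth noise, detection censoring — so green tests show
the estimators recover known ground truth under realistic observation.
They do not emulate: horizontal gene transfer and phage dynamics (HGT
trajectories are analysed like any others), host-to-host transmission,
changing population size, mutation-rate evolution, or linkage breakup by
recombination.  Real-data conclusions inherit those assumptions.

## Problem sizes

Default validation cohorts are 20 replicate hosts × 8 000 generations at
N = 10⁴–10⁵ with 80 sampling points each, chosen to give a few hundred
established trajectories per regime; the full test suite and the
acceptance script each complete in about half a minute on one CPU.
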