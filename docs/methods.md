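# Methods

## The measurement process being modelled

An automatic water sampler hidden on a urinal drainpipe draws one sample
per urination event into the next free slot of a 24-slot cassette. The
suction tubing retains a residual volume of liquid — up to about 4 ml
against a mean collected volume of 67 ml — so a fraction of the previous
sample's mixed concentration is carried into the next draw. Cassettes are
swapped and the tube rinsed between collection nights, so carryover never
crosses a cassette boundary and slot 1 of every cassette is carryover-free.
Samples are assayed for a multi-substance panel; each substance has a
reporting limit (LOD) below which it is recorded as not detected.

## The conservative classification rule

Within one cassette, for one substance, ordered by slot:

* not detected (concentration 0 or `< lod`) → **negative**;
* detected, previous slot also detected, and current concentration `<=`
  previous measured concentration → **contaminated**;
* detected otherwise → **positive**.

Numerical choices: the comparison is an exact `<=` on stored values — ties
are contaminated (conservative), no floating-point tolerance. The
comparison is always against the previous slot's *measured* value,
regardless of that slot's own status, so a sample following a contaminated
one is positive iff its concentration rises above the previous measurement.
A detected sample after an undetected one is positive: carryover from a
source with no measurable signal cannot explain it. Per-cassette reset is
assumed because the tube is rinsed when cassettes change; timestamps are
carried through the pipeline but play no role in classification.

Sample level: positive if ≥ 1 substance positive (contamination of other
substances does not demote a sample), negative if nothing was detected and
nothing contaminated, contaminated otherwise. Metabolite links
(prednisone→prednisolone, codeine→morphine, metoprolol→metoprolol acid)
fold a co-detected pair into the primary substance before combination
counts, so a pair counts once; the fold is idempotent and leaves a
metabolite detected on its own untouched.

## Estimators

**Adjusted prevalence** of substance *s*:
`100 · n_positive / (n_total − n_contaminated,s)` — contaminated samples
leave both numerator and denominator. Intervals are Wald
(`p ± z·sqrt(p(1−p)/n_eff)`), computed from the unrounded proportion,
clipped to [0, 100] and rounded only for display; with n_positive = 0 the
interval collapses to (0, 0). No continuity correction and no exact
(Clopper–Pearson) option: the large-sample normal approximation is part of
the method itself, and the z quantile is taken exactly (1.959964…), with tests
confirming the hard-coded 1.96 reproduces the same design statement.
Whole-sample shares use the unadjusted denominator and sum to 100% before
rounding. Class-level estimates use the any-member rule: a sample is
class-positive if any member is positive, class-contaminated if no member
is positive and at least one is contaminated. Combination percentages are
shares of the unadjusted total.

**A-priori precision**: half-width `z·sqrt(p(1−p)/n)`; at n = 400 and
p ≤ 0.4 it stays below 0.05 (0.0480 at p = 0.4). The inverse,
`min_n_for_half_width`, returns the boundary-exact smallest n.

## The synthetic campaign generator

What it emulates, and the defaults (all overridable):

* **Sites and cassettes** — the default two-hut campaign reproduces the
  study scale exactly: 274 + 156 = 430 samples (12 and 7 cassettes, the
  last of each site partially filled). `events_per_cassette` may also be a
  fixed count or a Poisson mean truncated to [1, 24].
* **Latent use** — each visitor independently uses each panel substance
  with probability `use_probability`; flags are fixed per visitor and
  independent of slot position. The default panel's probabilities are the
  published adjusted prevalences of the more common substances
  (acetazolamide 0.206, zolpidem 0.084, …).
* **Concentrations** — log-normal per substance, one draw per event. The
  printed among-user concentration ranges span three to four orders of
  magnitude, which a log-normal captures with σ ≈ (log max − log min)/6
  centred on the geometric midpoint; defaults are calibrated so simulated
  ranges bracket the printed min–max spans.
* **Carryover** — measured(k) = true(k) + f · measured(k−1) within a
  cassette, measured(1) = true(1). Applying f to the previous *measured*
  (not true) concentration makes chains decay geometrically, matching a
  tube that retains the previous mixed draw. The default
  f = 4/71 ≈ 0.056 is the volumetric ratio residual/(residual + draw). A
  `uniform` mode draws f ~ Uniform(0, 2f̄) per transfer for the titration
  emulation. The titration levels behind the published per-drug carryover
  rates (0.0–12.8%) are not known, so f and the LOD stay free parameters
  rather than being fitted to those rates.
* **Detection limits** — measured concentrations below the substance LOD
  are recorded as 0 with an explicit below-LOD flag, so "no signal" is
  distinguishable from a measured zero. The latent truth keeps the
  uncensored value.
* **Redundancy** — a visitor contributes Geometric(1/`revisit_mean`)
  samples on consecutive nights at one site, at most one per cassette,
  with the same latent flags. Default `revisit_mean` = 1 (no revisits),
  reflecting the study's argument that redundancy was low; revisits are
  *not* correlated with drug use. Consequence: redundancy leaves the
  per-sample prevalence centred on the per-visitor rate but inflates its
  variance (fewer independent visitors), which is what the sensitivity
  grid shows. The generator has no sex covariate (the sampled population
  was male-only by construction of the collection hardware).
* **Determinism** — one `numpy` Generator seeded from the config; the
  random event stream does not depend on the carryover fraction, so
  raising f with the seed held fixed changes measured concentrations
  monotonically (the basis of the monotonicity property test).

What it does **not** emulate: water flushes and conductivity detection,
assay chemistry and cross-reactivity, pharmacokinetics (a concentration is
a single draw, not a dose–time curve), non-stationary arrival patterns, or
any association between drug use and urination frequency. Passing tests
therefore show the estimator behaves correctly *given* this idealised
measurement model, not that the published field numbers are unbiased.

## Monte-Carlo experiments

`run_recovery` simulates R campaigns (replicate r reseeded with
base + r), classifies each, and compares three estimators per substance:
adjusted (the conservative rule), naive (every detection positive, nothing
discarded) and oracle (the latent use share). Aggregates are mean bias,
RMSE, 95%-interval coverage of the latent use probability, and the mean
contaminated share, each with Monte-Carlo standard errors. Given the same
classification, adjusted ≤ naive holds deterministically
(P/(N−C) ≤ (P+C)/N ⇔ P+C ≤ N), so the "conservative" direction is
structural; the experiments quantify its size. Default experiment scale —
430 samples per replicate, 200–500 replicates — keeps a full experiment in
tens of seconds on one core.

### A property worth knowing: bias without carryover

The sequential rule flags the second of two consecutive *detected* samples
whenever its concentration is less than or equal to the previous one. For
two consecutive true users with iid continuous concentrations that happens
with probability 1/2 — no physical carryover required. At use probability
p ≈ 0.21 and 430 samples in 24-slot cassettes this censors
≈ (430 − 19)·p²/2 ≈ 9 true positives per campaign, biasing the adjusted
estimator by about −1.7 percentage points and pushing its nominal-95%
coverage down to roughly 85–89%, while the naive and oracle estimators sit
at ~95%. The conservative estimator is therefore *not* an unbiased
binomial share even in the best case; this is the computational face of
the method's own admission that it underestimates prevalence.

The direction of the adjusted estimator's bias also depends on the
detection limit relative to carried concentrations. When the LOD is far
below them (e.g. 20 ng/ml against median ~3,000 ng/ml), heavy carryover
marks many *non-users* contaminated; removing them shrinks the denominator
and the adjusted estimate can overshoot the latent truth even while staying
well below the (grossly inflated) naive estimate. With the LOD near the
carried concentration — the regime the published titration rates of
0–12.8% suggest — contaminated samples are mostly declining true users and
the bias is downward. A literal LOD of zero is degenerate: every
infinitesimal trace of the geometric carryover chain counts as a
detection, and the contaminated share explodes.

## Known limitations

* The rule's false-contamination effect above makes interval coverage for
  the adjusted estimator fall short of nominal at realistic prevalences;
  use the experiments module to calibrate expectations for a given panel.
* Per-substance contaminated counts of the original campaign were never
  published, so published per-substance CIs can be checked only to
  rounding tolerance, and published class rows cannot be reconciled
  exactly from printed substance rows; the any-member class rule here is
  one consistent choice.
* The generator's visitors are exchangeable; it cannot express
  use-correlated revisiting or oversampling of frequent urinators
  (e.g. diuretic users), both of which would bias a real campaign.
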