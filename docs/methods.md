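# Methods

## Model

Two species (S1, the spent-medium producer; S2, the responder) grow in batch
on four compounds. The state is (S1, S2, c1…c4) with

    dSᵢ/dt = Sᵢ Σⱼ r[i,j] · cⱼ/(K[i,j]+cⱼ) · gate
    dcⱼ/dt = Σᵢ [ −(r[i,j]/y[i,j]) · Sᵢ · cⱼ/(K+cⱼ) · gate − u[i,j]·Sᵢ·cⱼ + p[i,j]·Sᵢ ]

Assumptions: Monod uptake is the consumer–resource closure; there is no
death or maintenance term, so biomass is non-decreasing; filtration removes
cells but no compounds; each species consumes a single supplied carbon
source. Compound roles: C1/C2 are the two species' carbon niches (identical
under exploitative competition), C3 is the inhibitor, C4 a cross-fed
by-product (always zero in fresh media). Interference competition is
secretion of the same inhibitor (p[1,3] > 0); cross-detoxification is
growth-independent uptake of it (u[1,3] > 0), deliberately orthogonal to
cross-feeding (p[1,4] > 0, r[2,4] > 0) so the two positive mechanisms can be
compared cleanly.

**Lag rule.** The inhibitor does not slow growth; it delays it. Growth of
species *i* on compound *j* is gated off before T[i,j] = Σₖ l[i,j,k]·cₖ(0),
evaluated on the medium at inoculation. A hard time gate is the simplest
rule that is linear in the initial inhibitor level; a dynamic lag-state
variant could be added behind the same interface. Because the right-hand
side is discontinuous at lag times, the integrator (LSODA, rtol 1e-8,
atol 1e-10) runs piecewise between lag breakpoints; trajectories are
interpolated onto the regular output grid. Negative excursions below −1e-9
raise an error; smaller ones are clamped to zero.

**Stationary criterion.** Harvest happens at the first time from which the
relative biomass change stays below 1e-4 per unit time through the end of
the horizon (default 96 a.u.); if never reached, a warning is recorded and
the end state is harvested, mirroring a fixed-time harvest.

## Parameter choices

Units are arbitrary but hour/mM/OD-like. Shared defaults: r = 0.5, y = 1,
inoculum 0.05 per species, MM carbon c1 = 15, c2 = 10 (mirroring 15 mM
glucose and 10 mM citric acid), inhibitory C3 = 3.5.

* **K = 0.05.** The half-saturation sits well below the carbon pools so
  growth is rate-limited rather than affinity-limited. This keeps substrate
  switches sharp (visible diauxic bumps) and makes growth insensitive to
  the 0.5×–1.5× carbon differences that the mixing arithmetic creates
  between conditions — which is what lets niche separation read as "no
  effect in any condition".
* **Benign assay window t_end = 8.** Chosen inside the interaction-limited
  regime: no condition exhausts its carbon within the window, so the only
  AUC differences are those caused by the partner's consumption, secretion
  or inhibition. (With linear AUC and a carbon-exhausting window, SM/2+NC
  and SM/2+MM would differ from MM by their 0.5× / 1.5× carbon loads even
  under niche separation, which is an artifact of the protocol arithmetic,
  not an interaction.)
* **Inhibitory window t_end = 72 with l[2,j,3] = 14.** The responder's lag
  at C3 = 3.5 is then 49 a.u. — most of the window — so the replenished
  conditions (C3 = 5.25, lag beyond the window) lose more AUC to the extra
  inhibitor than they gain from extra carbon, reproducing the anomalous
  pattern: pure SM above MM, both replenished conditions below it. Curves
  do reach their carbon-limited plateaus here, which the final-yield
  comparison needs.
* **Exchange rates.** Interference p[1,3] = 0.1 puts ~3.3–3.5 units of
  secreted inhibitor into the spent medium (a lag comparable to the benign
  window at l = 0.8). Cross-feeding p[1,4] and r[2,4] are per-scenario
  (0.009–0.09 and 0.3–0.5) so the by-product is depleted within the window
  (the bump needs a first growth phase that ends) while lifting the SM
  yield ~30% above MM in the inhibitory case. Cross-detox u[1,3] = 0.03
  removes about two-thirds of the inhibitor by harvest: partial
  detoxification is the interesting regime, since complete removal would
  make SM/2+MM carbon-rich at MM-level inhibition and mask the pattern.
  All registry values are overridable from a scenario config (YAML/JSON).

## Features and statistics

AUC is the trapezoidal integral of blank-corrected linear OD (log-scale AUC
is a configuration away but not the default). Relative AUC is the affine
map NC → 0, MM → 1; values above 1 are diagnostic for cross-feeding. Lag
time — nowhere defined operationally in the assay literature we follow — is
the first time the smoothed OD exceeds 1.5× its initial value; the
convention is recorded in output metadata. Final yield is the mean over the
last 5% of time points. Smoothing is a centered moving average, window 5
samples (50 min at 10-min sampling).

**Bump detection** works on the smoothed log-OD rate: a bump is an interior
interval where the rate falls below 0.2× the preceding running-max rate for
at least 30 min and later recovers above 0.5× of it, with meaningful growth
(≥ 15% of the OD span) both before the dip and after the recovery — the
last condition is what excludes the terminal plateau. The running-max rate
is accumulated only where the OD has risen ≥ 5% of its span above the
start, because the log-derivative is noise-dominated near the detection
floor and would otherwise inflate the reference rate. At plate-reader noise
(additive sd 0.005 OD) the false-positive rate on single-phase curves is
below 5% (measured at 0/200 in the suite).

**Condition comparisons** are two-sample equal-variance t-tests of each SM
condition against MM and against NC, Bonferroni-corrected over the
six-comparison family of one producer/responder pair, α = 0.05. Zero
variance in both groups with equal means reads as "≈"; with unequal means
it is flagged degenerate and called by sign.

**CF vs CD** combines two evidence bits on pure-SM vs MM curves: a raised
final yield (one-sided t-test, and the ratio must exceed 1.02) and a
majority-of-replicates bump absent from MM. Concordant bits give CF or CD;
conflicting bits give "ambiguous". The 2% practical-equivalence margin on
the yield ratio is a minimum-effect-size guard: under true detoxification
the yields are exactly equal, and a bare t-test at α would spuriously call
a "significant" microscopic difference in a fixed fraction of experiments
regardless of noise level; requiring a ≥ 2% effect makes the call depend on
the biology (cross-fed carbon raises the yield by tens of percent) rather
than on the test's false-positive rate.

## Classification

The decision tree reads the comparison symbols: SM ≈ NC with no SM/2+NC
benefit → EC (replenishment restoring MM-level growth) or EC+IC (it does
not); SM ≈ MM → NS; SM > MM → NS+CF in a benign medium, and in an
inhibitory medium a CF-or-CD leaf resolved by the yield/bump evidence;
intermediate SM → the confusable EC+CF / NS+IC pair, separated by whether
carbon replenishment restores MM-level growth, with both labels retained in
the ambiguity set. A producer growing better in its own SM/2+MM than in MM
flags residual carbon, which demotes partner cross-feeding calls. When no
rule fires, the call falls back to the nearest noise-free reference pattern
simulated from the registry, so the classifier can never drift away from
the model that motivated it.

## Synthetic data

The curve generator emulates a plate reader: 10-min sampling, biomass → OD
identity plus a 0.04 blank (no calibration curve — only relative
comparisons matter downstream), multiplicative (sd 0.02) plus additive
(sd 0.005) Gaussian noise truncated at zero. It does not emulate plate
edge effects, evaporation, OD saturation at high density, or
non-exponential lag physiology; passing closed-loop tests therefore shows
that the *pipeline logic* is sound under instrument-like noise, not that
real organisms obey the model. The metabolome generator puts log-normal
baselines (median 1000, σ 0.5) under three conditions and spikes cross-fed
(up 20× then back down), produced-only and consumed-only compounds, with
mean-corrected log-normal replicate noise at cv 0.2 and nuisance wobble
≤ 2×; the spike pattern, not LC-MS physics, is what it reproduces.

## Numerical and testing notes

Problem sizes throughout (20 noise seeds × 9 scenarios for the closed loop,
100 tables for metabolomics recovery, 200 curves for the bump
false-positive rate) were chosen as the smallest grids at which the
binomial uncertainty of the estimated rates is clearly below the margins
being tested. Determinism: the model is deterministic; all stochasticity
lives in the seeded generators, and identical seeds reproduce files
byte-for-byte (CSV floats are written at %.17g and parsed with round-trip
precision). Known limitations: no cocultures of more than two species, no
spatial structure, no death or pH/osmolarity chemistry, no multi-carbon
generalization of the tree, and the conflation of the environmental
inhibitor with the interference compound — in reality a producer likely
secretes a different inhibitory molecule.
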