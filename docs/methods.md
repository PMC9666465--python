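# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `auxokit`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Growth curves and the deviation criteria

### The measurement model

The depletion experiment is a semi-continuous batch culture: optical density
is read every 10 minutes, and the well is transferred into fresh medium
after every 2 doublings so that readings stay inside the detector's linear
range and growth stays exponential. Two arms are run per strain × vitamin:
a supplemented control and a vitamin-depleted condition. The quantity of
interest is the number of doublings the depleted culture performs before it
deviates from the control — the coenzyme storage, with fold excess
2^doublings (coenzymes are diluted by growth, not consumed by catalysis).

All doubling accounting works on the dilution-corrected log OD: cumulative
doublings at reading *k* are Σ log₂(OD_{k+1}/OD_k) plus log₂(factor) for
every logged dilution event, so transfers never reduce the count. Growth
rates are OLS slopes on (t, ln OD_corrected); a rate is only reported when
the fitted window spans ≥ 2 doublings (sliding-window search maximising r²,
ties broken toward the earliest, then shortest window; flagged points —
outside the linear range or non-positive after blank subtraction — never
enter a fit).

### The deviation call

A strain deviates for a vitamin when

1. some depleted replicate falls ≥ 0.25 doublings behind the **mean** of the
   three control replicates' doubling curves (the mean, rather than paired
   wells, because replicates are technical), and
2. the post-separation growth rate — fitted from the separation time over a
   window of max(2 h, 6 readings) — is reduced by ≥ 25 % relative to the
   replicate's own pre-separation exponential-phase rate in ≥ 2 of 3
   replicates, and by ≥ 10 % in the remaining one.

The pre-separation baseline is the best ≥ 2-doubling window fit restricted
to [start, t_sep]; when the pre-separation stretch is too short for that
(storage ≈ 1 doubling), a plain OLS over the stretch is used. The baseline
is each depleted replicate's own rate, not the control's, so systematic
well effects cancel. Replicates that never separate contribute a rate
reduction of 0, which the 2-of-3 rule then handles uniformly.

Storage is the **median** across replicates of each replicate's depleted
cumulative doublings at its own separation time (robust to one outlier
replicate), and the reported deviation time is the median separation time.
The first-crossing time defines separation (rather than the gap at the end
of the run) — this also gives the deviation time a natural definition.

Because the control keeps growing at μ_max after the depleted arm arrests,
the gap crosses 0.25 doublings about 0.25·ln2/μ after arrest, at which
point the depleted count still equals the true storage (arrest rate 0), so
the estimator is unbiased up to one sampling interval; the acceptance suite
measures median recovery error ≤ 0.03 doublings over a 1–9 doubling grid at
the default noise.

## The synthetic plate reader

The generator produces the closed-form piecewise exponential: rate μ_max
until cumulative doublings reach the per-vitamin storage, then `arrest_rate`
(default 0; an optional linear ramp over `arrest_ramp_h` makes harder test
cases). Dilutions fire exactly when cumulative doublings cross multiples of
the trigger (default 2), reset OD to od0 exactly, and are logged with their
exact factor (2^trigger), so doubling accounting on generated data is
lossless. Noise is multiplicative log-normal on OD (plate-reader noise is
roughly proportional to signal; an additive option exists), default
sd = 0.02 on log-OD — the magnitude and the linear-range bounds
[0.01, 1.0] are conventions, configurable, since real instruments vary.
Readings outside the linear range are clipped to the bound and flagged,
not dropped; filtering is the analysis stage's job.

Randomness: one RNG stream per (seed, crc32(strain), replicate), so adding
replicates never perturbs existing ones; the depleted and control arm of a
replicate replay the *same* stream. This paired-well noise makes a
prototroph's two arms byte-identical — convenient for identity tests —
at the cost of slightly understating between-arm variance relative to real
plates.

## Comparative genomics

Per vitamin, every pathway-mapped COG is tested on the 2×2 table
(auxotrophs/prototrophs × present/absent) with Pearson's χ² without
continuity correction (a config flag enables Yates for tool-compatible
output); p-values are Benjamini–Hochberg adjusted over all pathway-mapped
COGs of that vitamin's analysis (one FDR family per vitamin). COGs constant
across all strains get p = 1 by convention and are flagged, as are records
with any expected cell count < 1 (flagged but tested). Pathway-level
summaries: completeness is the fraction of a pathway's mapped COGs present
per strain; a pathway is differential when strictly more than 20 % of its
tested genes are significant at q < 0.05, with the majority direction of
the significant records as the enriched group.

Classifiers are sklearn decision trees, depth ≤ 3, trained on binary COG
presence with a stratified 60/40 train/test split; the random-feature
baseline redraws features (from the pathway-mapped universe, without
replacement) and the split 500 times and reports the metric distribution.
On balanced classes with label-independent features its mean held-out
accuracy is ~0.5, which the suite checks to 3 standard errors.

Coenzyme usage: reaction counts per strain × coenzyme come from an exported
reaction → cofactor table (a reaction may count toward several coenzymes);
group comparison reports the percent difference of group means (relative to
prototrophs) and a χ² p-value on the 2×2 of summed counts (this coenzyme vs
all others, by group).

The label-shuffle randomization control deserves a calibration note: with
BH at α = 0.05, a fully clean shuffle occurs with probability ≈ 0.95 *by
construction* (family-wise error under the global null), so "≥ 95 of 100
shuffles clean" is the expectation itself, not a conservative bound. The
acceptance suite therefore asserts the clean count at two binomial standard
deviations below expectation plus the sharper content: corrected
discoveries average ≈ 0 per shuffle while uncorrected p < 0.05 hits average
≈ α·m ≈ 4.

## Consumer-resource models

State: per-strain abundances N_i (CFU/ml), glucose S (mM), by-product S₂
(mM). Between dilution events,

- μ_i = μ_max,i · S/(S + K_i), with K_i = max yield / own yield. This
  yield-ratio affinity is dimensionless but sits in the mM slot of the
  Monod term — a unit inconsistency inherited from the model's
  construction, kept as-is because the strain ranking it encodes (better
  yield → better substrate affinity) is the model's point.
- dN_i/dt = μ_i N_i (1 − N_i/C_i) — the standard logistic form; C_i =
  yield (OD) × CFU per OD.
- dS/dt = −Σ_i(10·μ_i·N_i/C_i)·S — consumption, so S is non-increasing
  between events; the flux coefficient 10 converts a realized growth rate
  into a glucose consumption rate.

At t ∈ {24, 48, 72, 96} h: N_i → N_i/dilution_factor (200), S → s0 (20 mM),
and S₂ → S₂/200 (the transfer is into fresh medium; the printed dilution
procedure the model follows mentions only strains and glucose, so the S₂
treatment is this implementation's choice — it barely matters because S₂ is
regenerated within hours each cycle). Growth-rate "reset" at dilutions is
automatic: μ is a function of S, which is reset.

Initial abundances are stationary CFU/ml ÷ 4: mixing 20 strains dilutes
each 1/20, the mix is inoculated 1/200, and a ×1000 volume-unit conversion
nets ÷4.

Numerics: RK45 (`solve_ivp`) restarted at each dilution with the reset
state applied exactly between segments (no in-solver event detection);
rtol 1e-8, absolute tolerance 1e-3 CFU/ml for abundances and 1e-12 mM for
resources; hourly output grid t ∈ {0, 1, …, 120} storing the pre-dilution
state at dilution times and the exact post-dilution state separately;
states are clipped at 0 with a warning if they undershoot −atol. Halving
tolerances moves stored trajectories by < 1e-4 relative (tested). The
single-strain model with flux_coeff = 0 (glucose pinned) is exactly
logistic with rate μ_max·s0/(s0+K), which the suite checks to 1e-6
relative; with consumption on, no closed form exists because S feeds back
into μ.

### Carbon cross-feeding

Strains with μ_max ≥ 0.3 h⁻¹ (the secretion threshold; sensitivity grid to
0.6) secrete S₂ at 50 % of their glucose consumption flux:
dS₂/dt = +Σ_secreters(10·0.5·μ_i·N_i/C_i)·S. The production term is
proportional to concurrent glucose consumption; a form multiplied by [S₂]
itself would freeze S₂ at its zero initial condition, so it cannot be what
generated by-product pools of a few mM. Secreters and consumers are
disjoint: strains below the threshold (the slow growers, gated on μ_max,
i.e. on strain identity rather than the instantaneous realized rate) grow
on S₂ at μ₂ = μ_max·scaling·S₂/(S₂+K_S2) with logistic term (1 − N/C_S2).
Scaling is 1/3 for the equal-efficiency scenario and 1 for auxotrophs in
the preferential scenario; both sensitivity conventions for this parameter
(a 1/2–2 absolute grid, and a 2–5-fold auxotroph/prototroph ratio) are
exposed, and neither is asserted as canonical. K_S2 defaults to K_i.

C_S2 is printed as 70 in the source model with no usable units (a literal
70 CFU/ml capacity would make the by-product term a death term at any
realistic abundance). It is implemented as `c_s2` (70) × `c_s2_unit`
(1e8 CFU/ml) = 7e9 CFU/ml — comparable to the glucose-derived carrying
capacities, matching the stated rationale that growth on by-products can
rival growth on glucose. Both factors are configurable.

Peak S₂ has a closed-form supremum in this production-only model:
0.5·s0·f/(f−1) ≈ 10.05 mM (half of the glucose routed through secreters,
plus the 1/200 carry-over); runs sit near 10 mM, i.e. single-digit-to-ten
mM by-product pools, the biologically sensible range.

### Richness and what the scenarios can and cannot show

A strain is "detected" at a time point when its share of total abundance is
≥ the presence threshold (default 0.5 %, the midpoint of the 0.1–1 %
sensitivity range); group richness is detected/introduced. Richness is
monotone non-increasing in the threshold, which is what makes the
presence-threshold envelope in `sensitivity_bands` exact at its grid ends.

On the calibrated community (below), the default model washes every
auxotroph out by 72 h while most prototrophs persist. Equal-efficiency
carbon cross-feeding retains auxotrophs at that 72 h checkpoint — the
deadline by which the default model has lost them all — but cannot retain
a consumer indefinitely, for a structural reason: a consumer has
μ_max < 0.3 h⁻¹ and by-product efficiency 1/3, so its per-cycle log-growth
is bounded by μ_max·(t_glc + (24 − t_glc)/3) < 3.2, far below the
ln 200 ≈ 5.3 needed to replace a daily 1/200 dilution; every consumer is
therefore washed out at ≥ e² per cycle *at any parameter values* under
these equations, and late-time coexistence of the equal-efficiency scenario
only appears at the other ends of the sensitivity grids (secretion
threshold 0.6, which makes the fast auxotrophs consumers, or scaling ≳ 1).
The preferential scenario (auxotroph scaling 1) lifts the bound to
μ_max·24 > ln 200 for μ_max near 0.3 and keeps part of the auxotroph group
to 120 h. The package evaluates "retention" at the 72 h checkpoint and
"preferential ≥ equal" at the final time point, and reports all of these
quantities explicitly in the acceptance output.

## The synthetic community

`CommunitySpec` defaults encode the study conditions: 20 strains, half
auxotrophic; growth rates U(0.15, 0.45) h⁻¹ for auxotrophs and
U(0.30, 0.70) h⁻¹ for prototrophs — in expectation 15 strains at or above
the 0.3 h⁻¹ secretion threshold and ~3 at or above 0.6 h⁻¹; yields
U(0.3, 0.7) OD vs U(0.6, 1.2) OD; CFU per OD U(5e8, 2e9) ml⁻¹ (the "order
of 1e9/ml" plate-count range). Stationary CFU/ml is yield × CFU/OD ×
U(0.9, 1.1): in batch monoculture the stationary density *is* the carrying
capacity up to measurement scatter, and drawing it independently can place
an inoculum far above the strain's own capacity, which distorts the first
cycle artifactually.

`spacing="quantile"` replaces the uniform draws of rates and yields with
evenly spaced class quantiles (pairing permuted by seed): this emulates a
single fixed, experimentally characterized community and reproduces the
threshold counts exactly (15 and 3 of 20) at every seed. The acceptance
measurements use five quantile-spaced communities and report medians, so
they measure the study condition rather than one draw's tail behaviour.

What the generator does *not* emulate: lag phases, aggregation,
non-exponential growth (no Gompertz/Baranyi structure), instrument drift,
correlated noise, cross-contamination, or any sequencing/LC-MS readout.
Passing tests therefore demonstrate the correctness of the analysis logic
under the stated generative assumptions, not robustness to every artifact
of real plate data.

## Known limitations

- The deviation detector assumes 3 + 3 replicates with overlapping time
  ranges (a relaxation flag exists) and a detectable post-separation window
  of ≥ 3 readings.
- The CRM inherits the source model's unit shortcuts (yield-ratio affinity
  in mM; opaque C_S2 scale); its outputs are qualitative group-level
  richness patterns, not calibrated abundances.
- FDR families are per-vitamin over all pathway-mapped COGs; an alternative
  per-pathway family definition would give different q-values.
- The decision-tree classifier is intentionally tiny (depth ≤ 3) and is
  evaluated on a 35–63-strain scale; its metrics are not estimates of
  performance on large genome collections.
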