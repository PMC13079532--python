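# Methods

This note documents the models, numerical choices and design decisions behind
`docseer`, and what the synthetic experiments do and do not demonstrate.

## Calendar and horizon

All internal computation uses a 365-day ("noleap365") calendar: every year has
identical month lengths, so a 5-year warm-up plus the fixed 215-day prediction
horizon is always exactly 2040 daily steps and lead-month boundaries are
integers. Lead 1 is the initialization month itself; leads are calendar
months. The 215-day horizon covers seven lead months for every initialization
month (212–215 days depending on the month); where it truncates the seventh
month, monthly means use the available days and carry a completeness flag,
and the few days that spill into an eighth calendar month inherit the lead-7
skill parameters in the generator and are ignored by the aggregation. A
Gregorian mode exists for user-supplied observations only.

## Synthetic weather truth

The truth generator emulates the statistical features of a Mediterranean
mid-latitude catchment pair that the downstream chain depends on, not any
specific reanalysis product:

* temperature: annual harmonic (mean 13 °C, semi-amplitude 8.5 °C, late-July
  peak) plus AR(1) anomalies (ρ = 0.7, innovation σ = 1.4 °C), shared between
  sub-catchments; the upstream sub-catchment C1 is 5 °C colder (elevation),
  which produces a seasonal snowpack there;
* precipitation: per-calendar-month wet-day occurrence (autumn and spring
  maxima near 0.4–0.46, a dry summer near 0.12) and gamma-distributed wet-day
  intensities (shape 0.7; wettest months average 12–14 mm per wet day);
  C1 receives 1.3× (orographic enhancement).

These defaults were chosen once, from climatological orders of magnitude for
such catchments, and produce ~1000 mm yr⁻¹ downstream with the bimodal flow
regime the catchment model should exhibit.

What the generator does **not** emulate: spatial rainfall structure within a
sub-catchment, multi-day storm clustering beyond AR(1) temperature memory,
trends, or the heavy hourly intensities that drive event-scale DOC flushing.
Passing tests therefore demonstrate the correctness and the qualitative
behaviour of the chain, not site-specific skill on real data.

## Forecast ensembles

A member's temperature anomaly (against the truth's per-calendar-month
climatology) is λ·(truth anomaly) + √(1−λ²)·ε with ε ~ N(0, noise_sd²) and
λ = λ(lead) ∈ [0, 1]; an additive bias per lead may follow. Precipitation is
generated in a transformed Gaussian space: each month's truth sample defines
an empirical probability transform (Hazen plotting positions, ties collapsed
to their mean position, linear interpolation), the truth value is mapped to a
Gaussian score, mixed with independent noise by the same λ-rule, and mapped
back through the month's empirical quantiles — members therefore stay ≥ 0 and
keep the dry-day mass — before a multiplicative bias. The transform's
tie-collapsed construction makes it exactly invertible on sample values, so
λ ≡ 1 with neutral bias reproduces truth bitwise (asserted in tests); this
invertibility is why this construction was chosen over alternatives.

## Catchment model

The simulator is deliberately minimal: a stand-in with the same I/O contract
as a coupled rainfall-runoff → in-soil carbon model chain (temperature and
precipitation in; HER, SMD, streamflow, DOC out) and the two properties the
forecasting workflow exploits — fast hydrology mediated by HER/SMD and slow
carbon-pool memory. It does not attempt process fidelity of any published
catchment model.

Per land-cover unit (urban, agriculture, broad-leaved forest, coniferous
forest, small/no vegetation), daily explicit-Euler steps:

**Hydrology.** Precipitation falls as snow below `t_snow` (0 °C); melt is
degree-day (`ddf` = 3 mm °C⁻¹ d⁻¹) capped by the pack. PET = `a_pet`·max(0,T)
(0.22 mm °C⁻¹ d⁻¹ ≈ 1000 mm yr⁻¹ at 13 °C); actual ET scales with relative
soil moisture S/C and is capped by available water. Water exceeding the soil
capacity C (50–180 mm by land cover) becomes HER, split β_q (0.4–0.9) to a
quick linear reservoir (τ_q = 3 d) and the rest to a slow one (τ_s = 70 d);
SMD = C − S. With AET capped at S+W the update never needs clamping, so the
water balance closes to round-off by construction (asserted at 1e-6 relative
on every run).

**Carbon.** The organic pool receives a litter flux `i_litter` (0.002–0.026
g C m⁻² d⁻¹ by land cover) representing the carbon entering the
dissolved-producing pathway — not gross litterfall, most of which is respired
without ever passing through the dissolved pool. Production moves carbon to
the dissolved pool at k_p·SOC_o·Q10^((T−T_ref)/10)·(S/C) (k_p = 2×10⁻⁴ d⁻¹,
Q10 = 2, T_ref = 10 °C), giving the organic pool a multi-year turnover — the
memory that drives DOC predictability. The dissolved pool loses to sorption
(k_sorb = 0.005 d⁻¹ → mineral pool), mineralization (k_min = 0.01 d⁻¹, out of
the system) and hydrological export D·min(1, HER/(S+ε)) with ε = 0.1 mm to
regularize dry soil. If demanded outflows exceed a pool, all its outflows
scale down proportionally, so pools never go negative (property-tested under
random forcing); a final max(·, 0) clears ~1e-16 arithmetic residue. The
mineral pool is a slowly accumulating sink (sorption in, nothing out); its
relative growth rate decays as it fills, which is what the spin-up drift
diagnostic measures. The carbon balance Δ(SOC_o+SOC_m+D) = Σlitter −
Σmineralization − Σexport closes to round-off.

**Routing.** Reach streamflow = area-share-aggregated unit runoff
(mm d⁻¹·km² → m³ s⁻¹ via ×1000/86400) + upstream flow + point sources; reach
DOC load (g s⁻¹ = mg L⁻¹ × m³ s⁻¹) = terrestrial export + groundwater DOC
(c_gw ~1–3 mg L⁻¹ times slow flow) + upstream load·(1−k_instream), with
k_instream = 0.05 in-transit loss, + point-source loads; concentration =
load/flow, flagged missing when flow is zero. No routing lag between the two
reaches at daily resolution. The demonstration catchment places a continuous
12 mg L⁻¹ × 0.13 m³ s⁻¹ treated-wastewater source on the downstream reach.

Initial pools (soil at 70% capacity, organic carbon 15–180 g C m⁻² by land
cover, mineral at twice organic, dissolved 0.8 g C m⁻²) sit near the model's
own equilibria so spin-up converges quickly. The fixture parameters were
chosen for qualitative realism — summer low flow, an autumn DOC concentration
peak near 4 mg L⁻¹, a secondary late-winter peak, mean DOC ≈ 3 mg L⁻¹ — not
to reproduce any gauged catchment.

## Calibration

GOF metrics use their standard definitions; logNSE uses ln(x+ε) with ε = 1%
of the mean observed value to survive near-zero flows; KGE is the 2009 form
with untransformed ratios. Monthly aggregation drops months with missing
days; DOC grab samples are compared as within-month sample means against
monthly means of the daily simulation, accepting the sampling-density
mismatch that entails. The Monte-Carlo search perturbs each named parameter
by a single multiplicative factor drawn uniformly in ±25%, applied to every
land-cover unit so relative structure is preserved; the objective is a
configurable weighted mean of monthly NSE for streamflow and DOC (default
0.5/0.5 — the weighting across variables is a genuine free choice).
Candidates whose carbon pools drift more than 1%/yr over the final simulated
year are excluded as unstable; if all are, the base set is returned flagged.
Calibration uses the full record (no split), with robustness instead probed
by the hindcast verification stage.

## Bias correction

Empirical quantile mapping with 99 equally spaced probabilities, linear
interpolation between matched quantile nodes, and constant-shift
extrapolation beyond the fitted range. Pooling: all ensemble members and all
days of one lead *calendar month* within one initialization month form the
training sample (the natural reading of daily-scale correction conditioned by
calendar month; pooling by lead-day index was the alternative). Leave-one-
year-out: the target year's days never enter its own training sample, for
either the forecast or the observation side. Precipitation uses a 0.1 mm d⁻¹
dry threshold; sub-threshold values are dried before fitting and after
mapping, a fully dry observed training climate maps everything to zero, and
output is clamped ≥ 0. Degenerate (constant) training samples fall back to a
constant shift. Both raw and corrected archives are first-class paths through
the pipeline (`bias_correct=` flag): bias correction fixes marginal errors
but cannot add correlation skill, so the raw path is not a fallback but an
alternative the verification stage can prefer.

## Hindcasting

Warm-up forcing always comes from the truth record (never from forecast
members), with the model state reset from the truth-forced reference run at
the warm-up start. Because the warm-up forcing *is* the reference forcing,
the state at the initialization date equals the stored reference state there
exactly — the engine therefore computes it once per initialization and shares
it across members, which tests assert is bit-identical to running each
member's warm-up explicitly (`explicit_warmup=True` keeps the literal path).
Restart equivalence — rerunning from a stored state reproduces the reference
run bitwise — is the discrete form of a smooth warm-up/prediction transition
and is an acceptance property. Members run as one batched simulation (the
state and forcing arrays carry a member axis). Failed jobs are reported with
their identity and excluded from ensemble statistics, never imputed.

## Verification

CRPS uses the standard energy (NRG) estimator, which equals the integral of
(F−H)² for the empirical CDF; an independent exact piecewise-integration
oracle guards it in tests (agreement to 1e-12), and a "fair"
ensemble-size-adjusted variant is available as an option. The climatology
reference for a verification instance is the ensemble of that calendar
month's monthly means over the reference years, excluding the verifying year
by default (including it would reward the reference with the answer; the
non-LOO mode exists as an option). A cell's CRPSS is 1 − (mean forecast CRPS
over years)/(mean climatology CRPS over years) — the skill of the system, not
a mean of per-year ratios. Cells with fewer than two scorable years, or a
degenerate (zero-CRPS) climatology, are flagged missing. Negative CRPSS is
floored at zero only in the optional heatmap rendering, never in stored
values. Boundary semantics of the traffic-light classes and action levels are
exact as printed (0.6 and 0.2 are acceptable; 0.80 escalates).

## Products

Tercile bounds are empirical 33.33%/66.67% percentiles per calendar month
(linear interpolation between order statistics); an all-equal sample is
flagged degenerate. Members exactly on a bound count as normal; the
most-probable label resolves ties toward normal, then toward below-normal.
The tercile reference window is configurable separately for climate variables
and for streamflow/DOC, so a flux reference can start later than the climate
reference when a catchment's management regime shifted. The monthly report is
static, machine-readable JSON with a deterministic Markdown rendering, covers
exactly four lead months, and carries "no skill information" (never a
fabricated class) where the verification grid is missing.

## Problem sizes in the test suite

The statistical experiments run at reduced scale chosen to keep Monte-Carlo
conclusions stable: skill-decay and memory checks use 20 replicate archives
of 10 members × 10 years × 4 initialization months; bias-removal uses a
10-year, 5-member archive; conservation properties use five randomized
10-year simulations. The memory experiment sets λ = (0.8, 0.4, 0, 0, 0, 0, 0)
so meteorological skill is gone by lead 3, and verifies that DOC CRPSS
exceeds precipitation CRPSS at leads 2–4 in at least 80% of replicates — the
qualitative signature of carbon-pool memory as a predictability source.

## Known limitations

* The catchment model is a behavioural stand-in; its parameters are not
  transferable to a real catchment without calibration against observations.
* One Monte-Carlo factor per parameter name across all land covers cannot
  re-balance land covers against each other.
* The mineral carbon pool only accumulates; on century scales this is wrong,
  but over the ≤ 40-year horizons simulated here it only contributes a slow,
  explicitly diagnosed drift.
* Ensemble λ controls daily anomaly correlation; the induced monthly-mean
  correlation is somewhat higher (averaging suppresses the independent
  noise), so λ values are not directly CRPSS targets.
* No spatial weather structure, no reservoir or in-stream temperature
  processes, no nutrient coupling.
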