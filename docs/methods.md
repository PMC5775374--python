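# Methods

## The multimedia fate model

The fate metrics come from a closed, evaluative three-compartment model
(air, water, soil) in the fugacity tradition: linear first-order exchange
and degradation, solved directly at steady state, `(T − diag(k_deg)) m + e
= 0`. "Closed" means no advective loss terms in the persistence
calculation — at steady state the emission is exactly balanced by
degradation, which is the premise of an overall-persistence metric, and
the solver asserts that closure to a relative error below 1e-9.

Fugacity capacities are expressed relative to water (Z_water = 1), since
only capacity ratios enter rate constants:

- air: Z = K_AW for the gas phase, with aerosol sorption from the
  octanol–air absorption model log K_p = log K_OA + log f_OM − 11.91
  (K_p in m³/µg), φ = K_p·TSP / (1 + K_p·TSP);
- water: dissolved fraction 1 / (1 + K_OC · f_OC,ss · SS) with
  K_OC = 0.35 · K_OW (L/kg);
- soil: volume-weighted pore air (0.2), pore water (0.3) and solids (0.5,
  density 2.4 kg/L, K_d = K_OC · f_OC,soil). The sub-phase composition of
  soil is a fixed constant of the evaluative world, not a user parameter.

Process inventory: air–water two-film diffusion, rain dissolution, wet and
dry aerosol deposition; air–soil boundary-layer diffusion (which also
carries soil volatilization, damped by the bulk soil fugacity capacity)
and deposition; soil-to-water runoff of water and solids. There is no
sediment compartment, no temperature dependence, no spatially resolved
transport and no degradation products.

**Environment parameterization.** Defaults (in
`EnvironmentParameters`) describe a generic 10⁵ km²-scale region: 6000 m
atmosphere, 70 % water surface 100 m deep, 10 cm soil, 4 m/s wind,
0.02 m/s current, 30 µg/m³ TSP with 10 % organic matter, 0.85 m/yr rain
with a 2×10⁵ scavenging ratio. The absolute values matter little for the
final outputs because priority scores are percentile ranks computed with
the same parameterization for screened and reference chemicals; the
parameterization fingerprint carried by every reference set enforces that
consistency and turns a mismatch into a hard error rather than a silent
bias.

**Metric definitions and conventions.**

- Pov is reported as the *maximum* over the three single-medium emission
  scenarios — a conservative screening convention, switchable by calling
  `solve_steady_state` per mode.
- CTD uses the emission-to-that-medium scenario: velocity × mobile mass
  fraction × overall residence time, in km.
- TE is built from two identical regions: region 1 receives the air
  emission and loses chemical by advective air outflow at rate
  wind_speed / L with L = √(total area); that outflow is the sole input to
  region 2 (same outflow sink), and TE is the net air→surface deposition
  flux in region 2 per unit region-1 emission, in percent.
- Half-lives are accepted in hours (the property-estimation convention)
  and converted internally; Pov is reported in days, CTDs in km.
- Half-lives ≥ 1e14 h are treated as non-degrading. If *all* three are
  non-degrading, the closed-system steady state does not exist and the
  record is flagged as a batch error (Pov would be infinite).

**Numerical choices.** The steady state is a deterministic 3×3 direct
solve (`numpy.linalg.solve`); there is no iteration and no randomness
anywhere in the metric path. Tests verify the solve against long-horizon
ODE integration (relative tolerance 1e-6) and against a dynamic two-region
simulation for TE (1e-5). Degenerate limits (zero mobile mass, φ → 1)
are guarded by floors of 1e-15 on phase fractions, which is far below any
value that can influence a percentile rank.

**Insensitivity beyond the clipped domain.** Partition ratios are clipped
to log K_OW ∈ [−4, 10], log K_AW ∈ [−12, 3] before screening. Pov and
CTD_water change by well under 1 % when a ratio moves beyond those bounds.
CTD_air and TE depend on the aerosol-bound fraction φ, whose absorption
transition is not fully saturated at the domain edge, so they can still
move by up to ~20–25 % between log K_OW 10 and 12 at unfavourable K_AW;
the regression test uses a 25 % band there (and treats metric values that
are negligible on the screening scale as equal). On the percentile scale
this movement is at most a bin or two, which is why domain clipping is
safe for ranking purposes.

## The bioaccumulation metric

BAF comes from a single mid-trophic-level fish at steady state:

    BAF = (k1 + kD · L_diet · K_OW) / (k2 + kE + kG + kM)

with gill uptake k1 = E_W·G_V/W (E_W = 1/(1.85 + 155/K_OW), ventilation
G_V = 1400·W^0.65 / C_O₂ L/d), gill elimination k2 = k1/(L_fish·K_OW),
dietary uptake kD = E_D·G_D/W (E_D = 1/(3×10⁻⁷·K_OW + 2), feeding
G_D = 0.022·W^0.85 kg/d), egestion kE = 0.125·kD, growth dilution
kG = 5×10⁻⁴ /d and biotransformation kM (default 0 — conservative for
screening). The diet is assumed in lipid equilibrium with the water. The
default fish is a 0.2 kg, 5 % lipid forage fish in 8 mg/L dissolved
oxygen.

This is deliberately *not* a three-trophic-level food-web QSAR: the B
metric's role in the scores is to respond to hydrophobicity and to
biotransformation potential, and both sensitivities are reproduced (tests
sweep both). Users holding full food-web BAF estimates attach them as
`log_baf_override`, which takes absolute precedence and is recorded in the
`baf_source` provenance column. There is no bioavailability correction of
the dissolved concentration and no laboratory-BCF variant.

## Curation rules

Ionizability: a record is removed iff pKa < 5 (present) or pKb > 8
(present); comparisons are strict, so boundary values stay. The pKb
convention is taken as printed; records lacking both estimates are kept
and flagged `ionization_unknown` — a screening tool has to tolerate gaps
even though curated inventories usually carry predictions for all records.
Clipping bounds and thresholds are exposed as function arguments
defaulting to the standard values. Curation is idempotent and
filter/clip order-independent, both property-tested.

## Scoring and benchmarking

Raw profile scores are products of linear-scale metrics (Pov days × BAF
L/kg × TE % for POP, etc.). Percentile rank = 100 × (number of reference
chemicals with raw score *strictly* below) / N_ref: ties count as not
exceeding, the conservative choice. With N_ref = 148 there are exactly
149 attainable scores; self-benchmarking the reference set returns the
uniform grid {0, 100/148, …, 100·147/148}. Because the scores are ranks
of products of positive quantities, any jointly applied strictly
increasing transform (log scale, unit changes) leaves them unchanged —
property-tested with exact power-of-two scalings.

Priority selection: over-90 and under-10 flags per profile (strict
inequalities), with spatial-coverage classes assigned by precedence
near-field (vPvB fit) > far-field (POP fit without vPvB) > global (APC or
WPC fit without POP). Summary counts include the exclusive and
cross-profile combinations used for the coverage scheme.

## The synthetic data generator

The generator emulates the statistical shape of a large
chemicals-in-commerce inventory with software-estimated properties, so the
pipeline is fully testable without redistribution of any database:

- log K_OW ~ N(3, 2.5²) clipped to [−4, 10]; log K_AW ~ N(−4, 3²) clipped
  to [−12, 3] (clipping mass at the bounds mirrors what domain conversion
  does to real estimates);
- half-lives log-normal with medians 100 h (air), 900 h (water), 1800 h
  (soil) — right-skewed, a realistic ordering of media reactivity;
- 31.5 % of records ionizable (pKa ~ U(0,5) or pKb ~ U(8,14), half each),
  5 % with no ionization estimate;
- formulas assembled from a log-normal carbon count (median 12),
  heteroatoms present with inventory-like prevalences (O 81.6 %, N 36.3 %,
  Cl 13.1 %, S 10.1 %, F 3.8 %, …) and per-element count distributions
  shaped like real inventories (fluorination mode at 3 atoms — the
  terminal –CF₃ signature; chlorination mode at 2 with 4 second; Br and I
  mostly single-atom).

Property correlations (e.g. K_OW with soil half-life) are *not* modelled;
the joint distribution is independent by default. Consequently the
synthetic set reproduces marginal distributions and pipeline behaviour,
not the clustering of real chemical classes — passing tests demonstrate
the method's correctness and invariants, not recovery of any particular
real inventory's counts.

The reference fixture draws 148 records uniformly over the reference
property space (log K_OW ∈ (−2, 10), log K_AW ∈ (−10, 2)) with longer,
widely spread half-lives (medians 300/2000/4000 h, log-sd 1.4–1.6), runs
the full metric pipeline on them and keeps records with strictly positive
raw scores; the resulting raw-score spread exceeds three orders of
magnitude per profile, as a set of legacy contaminants would show. It is
labelled synthetic in its provenance and is a stand-in for benchmarking
demonstrations; a real reference list is supplied through
`ReferenceSet.load`, transparently.

## Problem sizes

The test suite uses 100–1000 random chemicals for the conservation,
bracketing and oracle suites, 50×148 batches for the rank-oracle check and
a 500-chemical end-to-end screen; the acceptance script screens 2000
synthetic chemicals against a 148-member fixture. These sizes give stable
statistics for every asserted property while a full run stays in the
seconds-to-minutes range on one CPU; all of them scale linearly if larger
demonstrations are wanted.

## Known limitations

- The multimedia world is a fixed two-surface box model: no sediment
  burial, no temperature or seasonality, no spatial resolution beyond the
  two-region TE construction.
- The fish model is a single organism; trophic magnification through a
  food web is out of scope, as are ionizable chemicals (which curation
  removes precisely because these models do not apply to them).
- Scores are exposure-hazard ranks, not risk: no toxicity term, no
  emissions weighting, and the percentile is only as meaningful as the
  reference set it is computed against.
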