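# Methods

`heterowheat` analyses multi-location hybrid wheat trials: canopy NDVI
dynamics in thermal time, adjusted means and broad-sense heritability from
augmented designs, mid-/best-parent heterosis, and trait associations. This
note records the models, the parameters that matter, the design choices made
where the literature left the procedure open, and what the synthetic trial
generator does and does not emulate.

## Canopy phenology model

NDVI observation dates are converted to thermal time: cumulative
`max((tmin+tmax)/2 − Tbase, 0)` from the sowing day with `Tbase = 0 °C`,
then centred so the heading date sits at 0 °C days. Heading dates come from
the plot-level HD trait (days from January 1, rounded to a calendar day).

Each plot's cycle is modelled in three phases:

* growing: `f(TT) = a1·TT + b1`, from sowing to the NDVI maximum;
* flowering plateau: `g(TT) = a2·TT + b2`;
* senescence: `h(TT) = NDVI_final + NDVI_amplitude / (1 + e^(a3·TT + b3))`.

`NDVI_final` is fixed at the lowest post-peak observation, and
`NDVI_amplitude` at `g(TT_breakpoint) − NDVI_final`; only `(a3, b3)` are
free in the nonlinear fit. Stay-green statistics are the logistic quantiles
`TFN90 = (−ln 9 − b3)/a3`, `TFN50 = −b3/a3`, `TFN10 = (ln 9 − b3)/a3`,
`TFN1 = (ln 99 − b3)/a3` (thermal time at which 90/50/10/1 % of the
amplitude remains). Phase areas integrate the fitted curves: GPA over
[TT_sowing, TT_Nmax], FPA over [TT_Nmax, TT_breakpoint], SPA from the
breakpoint to TFN1 via the closed-form antiderivative
`H(t) = final·t + amplitude·(t − ln(1 + e^(a3 t + b3))/a3)`, and
DPA = FPA + SPA.

Open points resolved here:

* **Phase boundary.** How post-peak points split between flowering and
  senescence is not standardised. Default: exhaustive search over candidate
  split indices minimising the joint SSE of (line left, logistic right),
  deterministic with ties broken toward the earlier split; an alternative
  rule (`logistic_all`: fit all post-peak points, cut at the 99 % quantile)
  sits behind `boundary_rule`. Each side keeps ≥ 3 points where the series
  allows; with 3–4 post-peak points the flowering line degrades to a
  peak-anchored stub rather than discarding the senescence fit, and < 3
  post-peak points (or < 8 observations in total) leaves the plot flagged
  unavailable rather than silently dropped.
* **FPA upper bound.** FPA ends at the fitted breakpoint and SPA runs from
  there to TFN1, which preserves DPA = FPA + SPA exactly.
* **Total area.** TA defaults to the trapezoid area under the *measured*
  points from sowing to the last observation (`ta_mode="measured"`);
  `ta_mode="modelled"` returns GPA + DPA. The two differ because the
  measured curve includes the pre-emergence and post-TFN1 tails.
* **Fit quality.** R per phase is the absolute Pearson correlation between
  fitted and observed values (identical to √R² for a simple regression).

Numerical choices: the logistic is evaluated through `expit` and
`logaddexp` (no overflow); the fit uses bounded least squares (`a3 > 0`)
with `ftol = xtol = gtol = 1e−14`, initialised at `a3 = 4/span`,
`b3 = −a3·median(TT)`, with five deterministic restarts scaling `a3` by
(1, 0.5, 1.5, 0.75, 1.25) before failure is declared. A converged fit whose
midpoint `−b3/a3` falls more than half the senescence-window span outside
that window is rejected as a runaway (flat-tail) solution and the plot is
flagged — without this guard a handful of noisy plots return essentially
unbounded TFN values that would dominate downstream variance components.

## Adjusted means and heritability

Per location, `Y_ij = μ + α_i + β_j + ε_ij` with sum-to-zero fixed effects;
the genotype adjusted mean (BLUE) is the marginal mean over blocks,
computed by averaging model predictions over the full genotype × block
grid (the emmeans construction). Across locations the additive fixed model
`μ + α_i + β_j(k) + L_k` is used; with one plot per genotype × location
cell the full interaction is saturated, so it is only estimated as a random
component. Block-within-location absorbs the location main effect, and
genotypes missing from a location keep estimable means through the additive
structure (logged). Rank-deficient (aliased) designs raise an error naming
the confounded terms.

Variance components are REML estimates from a linear mixed model (random
genotype intercept; in the combined scope also a genotype × location
variance component; blocks and locations fixed), fitted with lbfgs and
powell/cg fallbacks. A noiseless-data degenerate case (saturated fixed
model with zero residual) is detected and returns the limit directly. A
balanced-design method-of-moments estimator is provided as an independent
oracle for tests. Broad-sense heritability:

    single site : h² = σ²G / (σ²G + σ²res / n̄)
    combined    : h² = σ²G / (σ²G + σ²GxL / l + σ²res / (n̄·l))

`n̄` is the average number of replicates per genotype **per location**
(plots/genotypes at one site; plots/(genotypes·l) combined), so that `n̄·l`
is the total replicate count — the only reading under which the combined
formula reduces to the single-site one at l = 1. In the emulated design
n̄ ≈ 1.21 (checks are replicated 8×, everything else once).

## Heterosis

For hybrid i with parents F, M: mid-parent heterosis
`100·(HYB − (F+M)/2)/((F+M)/2)` and best-parent heterosis
`100·(HYB − max(F, M))/max(F, M)`, computed on combined-environment BLUEs
by default (per-location behind a flag). Records require the hybrid and
both parents; zero mid-parent values are flagged undefined and excluded
from summaries. The per-trait summary reports n, mean, min, max, σ/μ, the
share of positive records, and a p-value from a two-sided one-sample t-test
of the per-hybrid values against zero — the reading of "Student test"
consistent with summarising a distribution of per-hybrid heterosis values;
a two-sample hybrids-vs-parents Welch test is available behind
`test="two_sample"`. p-values are reported raw (no multiplicity
correction, α = 0.05 convention). The top-k subset ranks hybrids by their
yield BLUE with ties broken by id.

## Trait associations

Pairwise-complete Pearson correlations with two-sided p-values and
0.05/0.01/0.001 stars, traits ordered measured → estimated → modelled.
Grain protein deviation is the residual of GPC regressed on YLD over the
whole panel (hybrids and lines jointly); the hybrid-vs-line offset comes
from the joint model `GPC ~ YLD + group`. Group ANCOVAs fit
`response ~ covariate + group` (offset test) and
`response ~ covariate × group` (slope-difference test) for TKW | GPSM,
TFN90 | HD and YLD | HD. Check varieties are excluded from the
hybrid-vs-line contrasts by default (they are neither parents nor hybrids);
`include_checks` restores them.

## Synthetic trial generator

The generator emulates the study design end to end: 19 females × 16 males,
92 hybrids sampled so every male has ≥ 3 and every female ≥ 2 crosses, 35
parents, 4 replicated + 1 unreplicated checks, 8 blocks × 20 entries at
three sites with realistic sowing/harvest windows, sinusoidal-plus-noise
weather calibrated to a ~10.4 °C cycle mean and 2700–3000 °C-day cycle
sum, and 13–14 NDVI timepoints per plot following the three-phase curve.

Genetic architecture is additive + dominance. Parents draw additive values
per trait; hybrids are mid-parent plus a dominance deviation proportional
to their own mid-parent, so the configured percent *is* the expected
per-hybrid mid-parent heterosis (the additive-shift alternative leaves a
ratio-estimator bias of a few tenths of a point). Trait means, G×L and
residual variances, and per-trait dominance targets default to the source
trial's reported values. Three deliberate calibrations depart from the
reported genetic variances and are labelled as such in the code: the
YLD/GPC additive SDs (0.9) and the TFN90 additive SD (12 °C days) are set
above the reported components because, with the reported values, noise
attenuation leaves the observable adjusted-mean GPC–YLD correlation and
the hybrid protein-deviation offset far weaker than the trial reports;
likewise the latent-factor loadings (±0.894, genetic r ≈ −0.8) and the
genetic HD–TFN correlation (−0.85) are set so the *observed* correlations
land near −0.57 and −0.78 after attenuation. These are calibrations of the
generator, not estimates about wheat.

Correlations are induced by one shared latent factor per genotype (YLD
loads +, GPC −); senescence onset is generated from heading date with the
configured negative correlation; GPSM and GPY are derived (GPSM =
YLD·10⁵/TKW), which automatically yields the TKW–GPSM trade-off and a
hybrid GPSM deficit of ≈ −3 % (the YLD and TKW dominance targets imply it;
no separate density-penalty knob). NDVI curve parameters (Nmax, final
NDVI, a3) have genotype-level draws plus plot-level jitter; senescence
observations sit at the 93/75/50/25/7 % amplitude quantiles plus one at
harvest, mirroring weekly late-season visits. Everything is deterministic
per seed (sub-streams by fixed offsets; byte-identical CSV bundles), and
the ground truth (genotype values, variance components, per-plot curve
parameters) is written under `truth/` — read by tests, never by the
pipeline.

What the generator does **not** emulate: spatial field trend, correlated
weather across sites, missing-data patterns beyond fit failures, marker
genotypes, or any mechanistic crop physiology. Passing tests show the
estimators recover a faithful statistical emulation of the design — not
that real wheat behaves this way.

## Problem sizes and tolerances used in the test suite

Formula oracles run at 1000 random parameter draws (TFN vs bisection,
1e−6 °C days) and 200 draws (areas vs adaptive quadrature, 1e−6 relative).
Noiseless logistic refits recover (a3, b3) to 1e−6. End-to-end noiseless
recovery through segmentation is limited by estimating `NDVI_final` from
the last observation (the logistic tail at harvest is ~1e−4 above the
asymptote), so pipeline-level recovery is asserted at 0.5 °C days on TFN50
and 1 % relative on a3. Heritability recovery uses 200 simulated
study-shaped trials (480 plots, known components; mean ĥ² within ±0.05 of
the formula truth); heterosis recovery 100 simulated panels (2 SE);
null-uniformity of the ANCOVA slope-difference p-value 1000 replicates
(KS). The full pipeline on the default bundle runs in about a minute on
one CPU.

## Known limitations

* GPA heterosis on synthetic data comes out slightly negative: hybrids
  head earlier, which shortens the growing phase in heading-centred
  thermal time; the source trial reports a small positive value, so the
  growing-phase area is emulated only qualitatively.
* The reported per-trait variance components are not mutually consistent
  with the reported h² under the stated formula for any plausible n̄; h²
  defaults are therefore calibrated to land in the reported ranges rather
  than reproduced exactly.
* Whether reported phase "areas" are areas or durations is ambiguous in
  the source material; both conventions are emitted (`ta_mode`), neither
  is treated as a ground truth.
* REML on a single unreplicated location identifies σ²res only through the
  replicated checks; estimates for traits with tiny check replication
  variance are accordingly unstable.
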