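# Methods

## The capacity model

`thyrocap` treats the pituitary–thyroid axis at equilibrium. The thyroid's
maximum stimulated secretion rate GT (pmol/s) is inferred from one paired
serum measurement as

    GT = β_T (D_T + TSH) (1 + K41·[TBG] + K42·[TBPA]) [FT4] / (α_T · TSH)

The factor (1 + K41·[TBG] + K42·[TBPA]) converts free to
protein-bound-equivalent T4 at equilibrium with thyroxine-binding globulin
and transthyretin; with the default constants it equals 6901 exactly.
D_T is the EC50 of TSH at the gland: the term (D_T + TSH)/TSH = 1 + D_T/TSH
makes GT strictly decreasing in TSH at fixed FT4, with a finite asymptote
β_T·6901·FT4/α_T as TSH → ∞. That asymptote is the feasibility floor used by
the algebraic inverse: a capacity at or below it cannot sustain the given FT4
at any finite TSH, and `invert_gt` raises an error stating the minimum.

Constants and their defaults (all overridable through `SpinaConstants` or
the YAML config):

| constant | meaning | default | unit |
|---|---|---|---|
| α_T | dilution factor for T4 | 0.1 | L⁻¹ |
| β_T | clearance exponent for T4 | 1.1·10⁻⁶ | s⁻¹ |
| D_T | TSH damping constant (EC50) | 2.75 | mIU/L |
| K41 | T4 dissociation at TBG | 2·10¹⁰ | L/mol |
| K42 | T4 dissociation at TTR | 2·10⁸ | L/mol |
| [TBG] | standard TBG concentration | 300·10⁻⁹ | mol/L |
| [TBPA] | standard TTR concentration | 4.5·10⁻⁶ | mol/L |

Units are fixed at the API boundary — TSH in mIU/L (≡ µIU/mL), FT4 in
pmol/L, GT in pmol/s — with the pmol↔mol conversion internal. Source
material for this model family mixes µIU/L, mIU/L and µIU/mL; mIU/L is used
throughout because it is the unit attached to the printed constants and
group statistics. The dissociation constants are secretion-rate–dependent in
the underlying physiology but only fixed values are published; they are
implemented as fixed, overridable defaults. The GT reference range
(1.4–8.7 pmol/s, inclusive) derives from adult data; its use in children is
exactly the extrapolation this kind of analysis interrogates.

## The population curve

Predicted TSH at a subject's FT4 comes from a two-branch negative-sigmoid
population fit of ln TSH on FT4 (4-parameter logistics:
offset + span/(1 + e^{−(center−FT4)/width})); low branch
(1.4, 3.5, 7.0, 1.0) below 12 pmol/L, high branch (−3.7, 5.3, 20.6, 3.0)
above. Both parameter sets are exposed in the config. Two deliberate
numerical choices:

- **The boundary.** The published fit defines the branches on FT4 < 12 and
  FT4 > 12, leaving 12 itself unassigned; `thyrocap` assigns FT4 ≥ 12 to the
  high branch, since pediatric euthyroid/SH FT4 lies almost entirely above
  12 pmol/L.
- **The discontinuity.** The branches do not meet at the boundary
  (ln TSH ≈ 1.423 from below vs ≈ 1.315 at 12). This step is a property of
  the published model and is preserved, not smoothed; a regression test
  asserts it stays.

Predicted GT is the capacity formula evaluated at (predicted TSH, FT4) — a
function of FT4 only. A single curve pair is used; age- and sex-specific
variants exist in the source population model but are out of scope.

## Cohort pipeline

Classification: euthyroid TSH ≤ 4.5 mIU/L, mild SH 4.5 < TSH ≤ 10, severe
SH > 10 (SH strictly above 4.5). Euthyroid TSH quartiles use linear
interpolation between order statistics (the numpy default); boundary ties go
to the lower bin. Antibody positivity is TG-Ab and/or TPO-Ab > 34 IU/mL
(strict); with one assay missing the available one decides, with both
missing the subject is indeterminate and excluded from positivity numerators
and denominators. Stratum percentages follow the two-significant-figure
convention in the stratum table and one decimal in the group table
(configurable). The t-test defaults to Welch's form, robust to unequal
group variances; ANOVA uses Tukey's HSD for multiplicity-adjusted pairwise
p-values (scipy); chi-squared is Pearson's without continuity correction.
Significance is read at 0.05.

## Synthetic cohorts

No real cohort ships with the package; the generator produces cohorts with
the statistical structure the analysis assumes, built on the set-point
concept — each individual owns a characteristic TSH–FT4 equilibrium:

1. draw true FT4 ~ Normal(μ_F, σ_F), truncated to the group's admissible
   window (SH: 10.43–24.5 pmol/L) and to positivity;
2. draw true GT from a lognormal (median m, log-scale σ_G), optionally
   correlated with log FT4 (correlation ρ); reject infeasible (GT, FT4)
   pairs;
3. set true TSH by the exact algebraic inverse of the capacity formula;
4. apply unit-mean multiplicative lognormal assay noise (CV 5% for both
   TSH and FT4, typical immunoassay imprecision; configurable);
5. reject-and-redraw whole subjects until measured TSH lands in the group's
   half-open window (euthyroid (0.6, 4.5], SH (4.5, 15]); rejection rather
   than clipping avoids probability atoms at the boundaries.

Ages are uniform in the group's observed range, sex is Bernoulli at the
group's male fraction, BMI-SDS is normal at the group's published moments,
and antibody values are drawn below the 34 IU/mL threshold for negatives and
above it for positives (TPO-only : TG-only : both ≈ 2:1:1).

**Calibration.** The study conditions are two groups, 313 euthyroid and
183 SH children, with published TSH/FT4 group moments (euthyroid TSH
3.01 ± 0.95 mIU/L, FT4 16.3 ± 2.19 pmol/L; SH TSH 6.7 ± 2.05, FT4
15.7 ± 2.32). FT4 means/SDs enter the generator directly. The GT lognormal
parameters were calibrated once against the TSH moments and frozen:
euthyroid m = 2.0 pmol/s, σ_G = 0.20, ρ = 0; SH m = 1.75, σ_G = 0.15,
ρ = 0.7. The positive GT–FT4 correlation in the SH group is a deliberate
mechanistic choice: with independent GT and FT4 the inversion amplifies FT4
variability ~3.4-fold into ln TSH, over-dispersing SH TSH and inflating the
severe-SH fraction far beyond what is observed; correlated set-points
(higher-capacity glands running higher FT4) restore a realistic dispersion.
Resulting accepted-cohort moments: euthyroid TSH ≈ 3.02 ± 0.82, SH TSH
≈ 6.9 ± 2.1, severe-SH fraction ≈ 10%.

**What the generator does not emulate.** Range rejection conditions the
accepted marginals: the accepted euthyroid FT4 mean sits ≈ 0.9 pmol/L below
the input mean, and the moment-convergence test therefore runs with the TSH
window disabled (it checks the sampling machinery, not the truncation). The
empirical within-group TSH–FT4 correlation of real cohorts is unknown; here
it is induced mechanistically via shared set-points. Real features not
modeled: assay interference, age- and sex-dependent reference shifts,
longitudinal set-point drift, hysteresis after treatment, and any occult
autoimmune effect linking antibody status to capacity (antibody status is
drawn independently of GT). Passing tests therefore show that the *pipeline*
recovers what this mechanism generates — not that the mechanism is the true
data-generating process of any clinical cohort.

## Recovery experiment

`recovery_experiment` generates replicate cohorts, runs the full pipeline on
each, and scores per-stratum estimated capacity medians against the
per-replicate truth — the median of noise-free GT among the subjects the
pipeline assigned to that stratum. (The configured lognormal median is not
used as truth: TSH-window rejection tilts the accepted GT distribution, so
the realized cohort's truth is the honest yardstick.) It also reports how
often the qualitative stratum ordering Q1 > Q2 ≥ Q3 ≥ Q4 > mild SH >
severe SH is recovered, and the fraction of SH subjects whose actual GT
falls below their predicted GT. The six-stratum recipe `strata_spec` uses
the published stratum sizes, TSH windows, antibody rates and capacity
medians (3.21/2.53/2.20/1.70/1.77/1.29 pmol/s) as generator inputs.

Problem sizes used by the shipped experiments — 200 replicate two-group
cohorts (496 subjects each) for ordering recovery and 100 six-stratum
cohorts for parameter recovery — give Monte-Carlo standard errors of about
1% on the recovery rate and well under 1% on stratum-median bias.

## Degenerate inputs and tie-breaks

Non-positive TSH/FT4 raise a domain error naming the field; cohort-file rows
violating invariants are excluded with logged line numbers rather than
aborting the run. Quartile binning requires ≥ 4 distinct euthyroid TSH
values. An empty stratum yields an n = 0 row with absent aggregates.
Comparisons on all-identical constant groups raise instead of returning a
meaningless p-value. Generator configurations whose acceptance rate falls
below 1% raise an error describing the feasible GT–FT4 region.

## Known limitations

- GT is one structure parameter; deiodinase activity (which needs T3) and
  other composite indices are out of scope, so peripheral compensation is
  invisible to this analysis.
- The constants (in particular D_T and the dissociation constants) were
  estimated in adults; pediatric re-estimation would shift absolute GT
  values, though intra-cohort contrasts are less sensitive.
- The population curve is a single published fit; no uncertainty in its
  parameters is propagated.
- Synthetic-cohort results validate pipeline correctness and noise
  robustness only, for the reasons above.
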