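# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer should know.

## Calibration

The standard curve is the ordinary least-squares line of Cq on
log10(copies) over the detected wells of a serial dilution — the classic
calibration orientation, under which amplification efficiency is
E = (10^(−1/slope) − 1) × 100 %. Non-detect standard wells are excluded
from the fit rather than imputed at the cycle limit: imputation drags the
slope toward zero at the low end, and a non-amplified well carries no Cq
information. At least three distinct concentrations are required; fewer
is a calibration error. Efficiency outside 90–110 % raises a warning, not
an error — an out-of-range assay can still be examined, but its
quantities should not be trusted. Back-calculation of unknowns permits
extrapolation below the lowest standard (field samples routinely sit
there); `is_extrapolated` flags it.

The ng→copies utility assumes double-stranded DNA at 660 g/mol/bp and
takes the construct length (plasmid plus insert) as user input, since
standards prepared gravimetrically need that length to become copy
numbers.

## Limit of detection

The LOD is defined as the copy number at which the fitted detection
probability reaches `lod_probability` (default 0.95). Two monotone
candidates are fitted by maximum binomial likelihood and compared by AIC:

* **poisson_cloglog** — p(Q) = 1 − exp(−cQ). This is the physical model
  of single-molecule sampling: a reaction with mean Q template copies
  contains zero copies with probability e^(−cQ), where c ≤ 1 absorbs
  per-molecule capture/amplification efficiency. It is fitted as a
  binomial GLM with complementary log-log link and log Q offset, so the
  single parameter is log c. Solving p = 0.95 at c = 1 gives the
  theoretical floor −ln(0.05) ≈ 2.996 ≈ 3 copies.
* **logistic_log10** — a two-parameter logistic in log10 Q, covering
  assays whose detection falls off on a different scale than Poisson
  sampling predicts.

Two candidates suffice to cover saturating detection shapes; a
non-increasing fit is discarded with a warning and the other candidate
used. If the fitted probability at the lowest tested concentration
already meets the target (including the degenerate all-detected case,
where the curve is unidentifiable), the LOD is censored at that
concentration and flagged. No concentration with any detection at all is
an error, not a censored value.

## Limit of quantification

CV is computed on back-calculated copy estimates among detected
replicates (≥ 2 required per concentration) — a quantification limit
bounds the precision of the quantity actually reported, and non-detects
have no copy estimate. Three candidate curves are fitted by least
squares: exponential decay a·e^(−bQ) against copies, and linear and
quadratic polynomials against log10 copies (the decay model is the one
that usually wins on real dilution series; the polynomials catch
flat-then-falling and non-monotone shapes). Selection is by
RSS-based AIC with the residual floored at 1e−12 so that exactly
interpolating fits of different sizes still order by parameter count;
a saturated fit (parameters ≥ points) is ineligible. The LOQ is the
first downward crossing of the fitted curve through `loq_cv_threshold`
(default 0.35), located by a 512-point log-spaced scan refined with
Brent's method — a scan rather than a single root-find because the
quadratic model can be non-monotone. Crossing below the lowest standard
censors at that standard; never crossing censors at the highest with a
warning.

The report enforces LOD ≤ LOQ by raising the LOQ to the LOD with a
diagnostic note when the fits disagree (quantification cannot be more
sensitive than detection). This also covers the censored-LOQ case: at
very low copies the back-calculated estimates quantize to small integer
template counts, so the empirical CV can dip under the threshold at the
lowest standard even though detection itself is unreliable there.

## Inhibition

ΔCq is the spiked IPC's delay in the environmental extract relative to
the clean control, ΔCq = Cq_sample − Cq_control, so that inhibition is
positive and the 2^ΔCq correction inflates copy numbers back toward
their uninhibited values. Negative ΔCq (apparent facilitation) is
applied as-is by default — shrinking copies — with a
`clip_negative_delta` switch to floor it at zero. ΔCq > 3 cycles
(strictly greater) or a non-amplifying spiked IPC is significant
inhibition; the latter gets a +∞ sentinel and the sample is excluded
from quantification, since no finite correction exists. Control wells
are averaged per season when a season column is present (each sampling
event treated as its own run), otherwise globally; site-level ΔCq is the
mean over the site's replicate IPC wells. Plates whose no-template
controls amplify are rejected outright.

## Gating, units, aggregation

Normalization precedes gating: detection status is assigned to
inhibition-corrected copies. The three-way gate (negative ≤ LOD <
detected_below_loq < LOQ ≤ quantifiable) partitions every replicate.
Copies/reaction × (elution/template) / filtration gives copies/L (×50 by
default). Group means average quantifiable replicates with negative
replicates entering as zeros (`negative_fill="zero_fill"`): a
non-detection is evidence of at-most-trace concentration, and omitting
it would bias sparse groups upward. The alternative `omit` rule is
config-exposed because either convention is defensible; detections below
the LOQ are excluded from means under both rules but still count as
detections. Fold changes are ratios of linear-scale mean copies/L, not
of log-transformed values. Reports round ratios and factors to 2
decimals and concentrations to 3 significant figures.

## Comparisons

Pairwise Wilcoxon rank-sum tests run within three families — species
within each season, seasons within each species, stream classes within
each species — each family Holm-adjusted separately (`p_adjust` also
accepts bonferroni or none). The exact null distribution is used when
both groups have ≤ 10 observations and no ties; otherwise the normal
approximation with tie correction and a signed continuity correction
(sign(U − nm/2)·0.5, so a centered statistic gives p = 1 exactly). Tests
run on log10(x + 1) values; being rank-based they are invariant to that
transform, which a test asserts. The seasonal ΔCq comparison is a Welch
t-test (two-sided): seasonal inhibition variances are visibly unequal,
and Welch costs essentially nothing when they are equal. Spearman's ρ
uses average ranks with an exact permutation p for n ≤ 8 and the
t-approximation above. Significance stars use the strict thresholds
0.05/0.01/0.001/0.0001 on adjusted p-values.

## Synthetic data

The generator produces the structure the estimators assume, not a
mechanistic river model. Each well draws its template count
k ~ Poisson(Q·e) where e is the per-molecule detection efficiency; k = 0
is a non-detect, otherwise Cq = b + m·log10(k) + N(0, σ_Cq). Poisson
sampling alone yields the falling detection probability (LOD structure)
and the 1/√Q rise in CV (LOQ structure) at low copies; no separate
amplification-efficiency stochasticity is modeled. σ_Cq defaults to 0.2
cycles, a typical TaqMan replicate scatter. Dilution series default to a
10-fold ladder, 1–10⁷ copies × 10 replicates.

The default survey (`yangyang-default`) has six sites — three mainstem
(higher concentrations, brackish salinity toward the mouth), three on
two tributaries — two seasons and three field replicates per site. The
four assays use efficiencies of 96.26/95.15/100.67/106.33 % and
per-molecule efficiencies chosen as 2.996/LOD for LODs of
4.11/8.44/4.65/10.38 copies, i.e. the sensitivities of a validated
salmon panel. Species mean concentrations anchor to the dominant chum
assay at 1.09×10⁶ copies/L (spawning) and 1.71×10⁴ (non-spawning), with
the minor species set from the observed between-species ratios
(626.10-, 77.11- and 42.74-fold below chum in the spawning season) and
masu at 1.96×10³ copies/L off-season; off-season coho and steelhead
means are not constrained by any reported ratio and are set to a low
1.5×10³ copies/L, consistent with year-round trace presence. Replicate
variation is lognormal with σ = 0.3 on the log10 scale (a typical
within-site eDNA dispersion; no empirical value was available).
Site/season inhibition deltas span −0.33 to 1.33 cycles with seasonal
means 0.44 (spawning) and 0.07 (off-season), rising with salinity so the
ΔCq–salinity correlation is positive by construction; the same delta
shifts both the species wells and the site's spiked IPC wells, which is
what makes the correction recoverable. The reaction→liter factor 50 is
reused inversely so simulated and analyzed units round-trip exactly.

What the generator does **not** emulate: eDNA shedding, decay and
transport dynamics; between-assay competition in multiplexed reactions;
amplification-efficiency drift across a plate; pipetting error beyond
the lognormal replicate term. Passing recovery tests therefore show the
estimators are correct for Poisson-limited, lognormally dispersed data —
not that field surveys meet those assumptions.

## Problem sizes and tolerances

Simulated recovery tests use sizes chosen to make their Monte-Carlo
error small relative to the asserted tolerance: LOD recovery uses 1000
replicates per concentration (tolerance ±0.5 copies around the analytic
2.996); ΔCq recovery on the default survey tolerates 0.65 cycles — a
4-standard-error bound on the maximum over 12 site/season cells, each
cell's error being ~N(0, 0.163) from a 3-replicate mean against a 3-well
control at σ_Cq = 0.2; the end-to-end seasonal fold change must land
within a factor 1.7 of the injected 63.7 (≈2.5 SE of a ratio of
lognormal means at 18 replicates per season). Exact-test checks
(Wilcoxon vs. full enumeration for n+m ≤ 10, Spearman permutation for
n ≤ 8) are tolerance-free.

## Known limitations

* The LOD model family is fixed to two candidates; heavily overdispersed
  detection data (extra-binomial variation between plates) would need a
  beta-binomial extension.
* CV model selection with few concentrations (3–4 usable levels) leans
  on the AIC small-model preference; with exactly three levels the
  quadratic is never eligible.
* Inhibition correction assumes the IPC and target assays are equally
  inhibited; matrix effects that differ by amplicon are not identifiable
  from a single IPC.
* The pipeline treats each plate table as one run; cross-plate
  calibration transfer (different enzymes, instruments) is out of scope
  and assays should be re-validated per run configuration.

## Worked output

The README example was produced with:

```python
from ednaquant import PipelineConfig, run_pipeline, simulate_scenario

plate, truth = simulate_scenario("yangyang-default", seed=7)
result = run_pipeline(PipelineConfig(seed=7, out_dir="demo-out"), plate=plate)
cal = result["calibration"]["O_keta"]
sens = result["sensitivity"]["O_keta"]
means = result["group_means"]["mean_copies_per_liter"]
comp = result["comparisons"]
row = comp[comp["family"] == "season|O_keta"].iloc[0]
print(f"O. keta curve: slope {cal['slope']:.3f}, efficiency "
      f"{cal['efficiency_pct']:.2f}%, r2 {cal['r_squared']:.4f}")
print(f"O. keta LOD {sens['lod_copies']:.2f} copies ({sens['lod_model']}), "
      f"LOQ {sens['loq_copies']:.2f} copies ({sens['loq_model']})")
print(f"O. keta spawning mean {means['O_keta|spawning']:.3g} copies/L, "
      f"non-spawning {means['O_keta|non_spawning']:.3g} copies/L")
print(f"seasonal fold change "
      f"{means['O_keta|spawning']/means['O_keta|non_spawning']:.1f}")
print(f"season comparison (Wilcoxon): U={row['statistic']:.1f}, "
      f"p_adj={row['p_adjusted']:.2e} {row['stars']}")
```
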