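# ednaquant

Standardized quantification of species-specific environmental DNA (eDNA)
from qPCR plate data.

Species-specific qPCR assays are the workhorse of aquatic eDNA
surveillance: water is filtered, extracted DNA is amplified with a TaqMan
assay, and the quantification cycle (Cq) of each reaction is converted to
a copy number of the target's marker gene. Raw Cq values are not
comparable across samples, sites or studies until they pass through a
calibration and standardization pipeline. `ednaquant` implements that
pipeline for multi-assay surveys (its defaults mirror a four-species
salmon monitoring panel on a spawning river), together with a synthetic
plate generator so every stage is testable without instrument data.

## The model

**Standard curve.** For each assay, serial plasmid dilutions with known
copy numbers Q fit the calibration line

    Cq = b + m · log10(Q),      E = (10^(−1/m) − 1) × 100 %

where m is the slope (≈ −3.32 for perfect per-cycle doubling, E = 100 %).
Unknowns back-calculate as Q = 10^((Cq − b)/m). Efficiencies outside
90–110 % are flagged.

**Limit of detection (LOD).** The smallest copy number detected with 95 %
probability, from binomial fits of monotone detection curves to the
replicated dilution series: a Poisson single-molecule model
p(Q) = 1 − e^(−cQ) (complementary log-log link) and a logistic curve in
log10 Q, selected by AIC. With perfect per-molecule detection the Poisson
model gives the theoretical floor −ln(0.05) ≈ 3 copies/reaction.

**Limit of quantification (LOQ).** The smallest copy number whose
replicate-to-replicate coefficient of variation (CV of back-calculated
copies) stays below 35 %, from the best of three CV-vs-copies models
(exponential decay, linear and quadratic in log10 Q, selected by AIC).

**Inhibition normalization.** An internal positive control (IPC) spiked
into each extract measures inhibition as ΔCq = Cq_sample − Cq_control;
raw copies are corrected by ×2^ΔCq (a 1.33-cycle delay ≈ 2.51-fold
underestimation), and ΔCq > 3 cycles or a non-amplifying spiked IPC marks
significant inhibition.

**Gating and units.** Corrected copies ≤ LOD are negative; LOD < copies <
LOQ are detections excluded from quantitative summaries; copies ≥ LOQ are
quantifiable. Copies/reaction convert to copies per liter of water via
the template/elution/filtration volumes (×50 with the default
2 µL / 50 µL / 0.5 L), and group comparisons run on log10(x + 1)
concentrations: pairwise Wilcoxon rank-sum tests (exact for small
tie-free samples, Holm-adjusted) among species, seasons and stream
classes, a Welch t-test for seasonal ΔCq, and Spearman's correlation of
ΔCq with salinity.

## Worked example

```python
from ednaquant import PipelineConfig, run_pipeline, simulate_scenario

plate, truth = simulate_scenario("yangyang-default", seed=7)
result = run_pipeline(PipelineConfig(seed=7, out_dir="demo-out"), plate=plate)

cal = result["calibration"]["O_keta"]
sens = result["sensitivity"]["O_keta"]
means = result["group_means"]["mean_copies_per_liter"]
```

With seed 7 this prints (via the snippet in `docs/methods.md` § worked
output):

```
O. keta curve: slope -3.378, efficiency 97.72%, r2 0.9965
O. keta LOD 3.26 copies (poisson_cloglog), LOQ 15.41 copies (polynomial2)
O. keta spawning mean 1.09e+06 copies/L, non-spawning 2.11e+04 copies/L
seasonal fold change 51.5
season comparison (Wilcoxon): U=0.0, p_adj=3.23e-07 ****
```

Reading: the chum-salmon assay calibrates with near-perfect efficiency;
its modeled detection limit is ~3 copies/reaction (the Poisson floor,
since the simulated assay captures nearly every template molecule); the
recovered spawning-season concentration is ~50-fold the off-season one
(the generator injected a 63.7-fold difference; the gap is replicate
sampling noise), and the seasonal contrast is maximally significant.

The same pipeline runs from the shell:

```sh
ednaquant simulate --scenario yangyang-default --seed 7 --out-dir sim
ednaquant run --input sim/plate.tsv --seed 7 --out-dir out
```

writing `calibration.json`, `sensitivity.json`, `inhibition.tsv`,
`quantified.tsv`, `site_summary.tsv`, `comparisons.tsv`,
`group_means.json` and a run log with the config hash.

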