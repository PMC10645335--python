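# peaquant

Quantitative processing of multiplex Proximity Extension Assay (PEA) panels
and case-cohort prognostic modelling of the resulting biomarker
concentrations.

PEA panels read out protein levels by qPCR: paired oligonucleotide-labelled
antibodies form an amplicon only when both bind their antigen, and the cycle
threshold (Ct) falls as protein concentration rises. Turning a plate of Ct
values into clinically interpretable pg/mL — and those concentrations into
validated risk models — takes a chain of steps that this package implements
end to end:

1. **Normalization** (`normalize`). Per well, the internal extension-control
   Ct is subtracted (`dCt = Ct − Ct_ext`), cancelling within-run technical
   variation. Per plate and assay, the median of each calibrator triplicate
   (High/Middle/Low) is taken and the three medians averaged
   (`dCt_cal`); `ddCt = dCt − dCt_cal` cancels between-run shifts exactly.
   `NPX = cf − ddCt` is the log2-scale Normalized Protein eXpression, with a
   per-assay correction factor `cf`; larger NPX means more protein.
2. **Calibration and quantification** (`quantify`). A four-parameter
   logistic `NPX(x) = d + (a − d)/(1 + (x/c)^b)` is fit to standard curves;
   LOD is the blank mean + 3 SD mapped through the inverse curve, and
   LLOQ/ULOQ bound the contiguous run of standards whose back-calculated
   accuracy and precision are both ≤ 30%. Sample NPX is inverted to
   concentration, multiplied by the ten-fold predilution, and flagged
   (`in_range`, `below_lloq`, `above_uloq`, `below_lod`). Standard-curve
   concentrations can be value-reassigned (a single multiplicative rescale)
   to agree with a clinically validated reference assay, and censored values
   can be imputed from a censored-ML lognormal fit.
3. **Analytical validation** (`validate_assay`). Linearity of dilution
   (relative error against the mixing-theoretical concentration), QC
   accuracy (replicate mean / reference, accepted within 75–125%) and
   intra-assay CV, dynamic-range coverage, and method comparison on the
   log2 scale (Spearman ρ, regression r², Bland–Altman mean ± 1.96 SD).
4. **Risk modelling** (`risk_models`). Case-cohort weighted Cox regression
   (all cases weight 1, sampled non-cases inverse sampling fraction) with
   Breslow ties, damped-Newton optimisation, and a robust sandwich variance
   from weighted score residuals; four-knot restricted cubic splines (knots
   at the 5/35/65/95th percentiles); Q3-vs-Q1 hazard ratios; weighted
   Harrell's C; the fraction of new information
   `FNI = 1 − χ²(reduced)/χ²(full)`; bootstrap optimism correction; and a
   multi-model comparison harness with paired-bootstrap CIs for C-index
   differences.
5. **Synthetic data** (`simulate`). Because real plasma panels are not
   public, a generator produces plate tables (triplicate calibrators, QC
   pools and negative controls; Ct-level noise; per-plate run offsets;
   lognormal sample concentrations) and case-cohort survival data with
   known hazard coefficients, so every stage is testable against hidden
   truth.

## Worked example

```python
import numpy as np
import peaquant as pq

panel = pq.PanelConfig("demo", (pq.AssayDefinition("IL6"), pq.AssayDefinition("NTproBNP")))
truth = pq.default_panel_truth(panel, ct_noise_sd=0.05)
tmap = {t.assay_id: t for t in truth}
series = {a.assay_id: tmap[a.assay_id].fourpl[2] * 10 * 2.0 ** (np.arange(12) - 6.0)
          for a in panel.assays}
table, truth_df = pq.simulate_plates(panel, truth, 2, 12, seed=42, sample_concs=series)
npx = pq.normalize_plates(table)

conc, ny = pq.extract_standards(npx.values, truth_df, "IL6")
curve = pq.fit_4pl(conc, ny, assay_id="IL6")
curve = pq.determine_lod(curve, ny[conc == 0], predilution=10.0)
curve = pq.determine_loq(curve, conc, ny, predilution=10.0)
print(f"IL6 4PL: a={curve.a:.3f} d={curve.d:.3f} c={curve.c:.2f} b={curve.b:.3f}")
print(f"IL6 LOD={curve.lod_conc:.3g} pg/mL  LLOQ={curve.lloq_conc:.3g}  ULOQ={curve.uloq_conc:.3g}")

v = npx.values
res = pq.quantify_samples(v[v["role"] == "sample"],
                          curves={"IL6": curve, "NTproBNP": curve}, panel=panel)
for _, r in res[res.assay_id == "IL6"].head(3).iterrows():
    print(f"{r.sample_id}: NPX={r.npx:.3f} -> {r.conc:.1f} pg/mL [{r.flag}]")
```

prints

```
IL6 4PL: a=4.987 d=-5.018 c=49.53 b=-1.000
IL6 LOD=5.88 pg/mL  LLOQ=7.81  ULOQ=1.6e+04
S01_001: NPX=-4.841 -> 8.9 pg/mL [in_range]
S01_002: NPX=-4.730 -> 14.7 pg/mL [in_range]
S01_003: NPX=-4.435 -> 30.7 pg/mL [in_range]
```

The fitted inflection (49.5) recovers the generating truth (50) despite
Ct-level noise; the slope is negative because NPX rises with concentration.
LLOQ and ULOQ sit at the extreme standards (ten-fold predilution applied),
and the three samples — a two-fold dilution series — quantify close to
their true 7.8 / 15.6 / 31.2 pg/mL.

A command-line interface mirrors the stages
(`peaquant validate | simulate-plates | simulate-cohort | normalize |
fitcurves | quantify | qc | range | compare | risk-fit`); run
`peaquant --help` for details.

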