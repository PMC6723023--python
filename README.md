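# pulpcolor

Chemometric prediction of fruit biocompound contents from internal pulp
color.

Standard quantification of anthocyanins, carotenoids and polyphenols in
fruit requires extraction and UV-VIS spectrophotometry — accurate, but slow
and solvent-hungry. For routine quality control, a cheaper surrogate is a
handheld colorimeter reading of the pulp in CIELAB coordinates, calibrated
once against the wet-chemistry assays. `pulpcolor` implements that
calibration workflow end to end for six tropical and Andean fruits (araza,
blackberry, Andean blueberry, naranjilla, tamarillo, goldenberry), and is
aimed at food-quality labs and researchers building similar color-based
screening models.

## The model

Each analyte content `Y` (total anthocyanins TAC, mg cyanidin-3-glucoside
chloride/100 g DW; total carotenoids TCC, µg β-carotene/g DW; total
polyphenols TPC, mg GAE/100 g DW) is modeled as linear in the pulp color
coordinates:

```
Y = b0 + b1·L* + b2·a* + b3·b* + ε
```

fit per fruit by solving the normal equations `(XᵀX)b = XᵀY` on
replicate-level data (15 samples × 3 replicates). Data homogeneity is
enforced by a 2σ residual filter: rows whose |residual| exceeds two
residual standard deviations of the initial fit are removed and the model
is refit. Partial coefficients are tested with `tᵢ = bᵢ/√(Pᵢᵢ·S²)` at
n − 4 degrees of freedom, where `P = (XᵀX)⁻¹` and `S²` is the residual
variance. Method precision is judged by coefficients of variation of the
experimental replicates (CV_E) and of the model predictions (CV_P) against
Horwitz-style limits (16% for µg/g-scale analytes, 8% for mg/100 g-scale
analytes, or the continuous curve `CV% = 2^(1 − 0.5·log₁₀ C)`).

The package also ships the upstream assay arithmetic (pH-differential TAC,
Beer–Lambert TCC, Folin–Ciocalteu TPC with A/B-fraction interference
correction, ABTS/DPPH Trolox equivalents, maturity index, chroma/hue) and a
synthetic-data generator that emulates the study design so the whole
pipeline is testable without laboratory data.

## Worked example

Predict blackberry anthocyanin content from its mean pulp color using the
bundled calibration:

```
$ pulpcolor predict --fruit Blackberry --analyte TAC
Blackberry TAC at (L*=10.68, a*=13.8, b*=4.95): 1417.82
```

1417.82 mg/100 g is within 0.3% of that fruit's measured mean anthocyanin
content (1416.69 mg/100 g) — a dark, red-dominant pulp (low L*, positive
a*) maps to a high anthocyanin load.

Simulate a calibration campaign under the study conditions, fit, filter and
validate:

```
$ pulpcolor simulate --fruit Blackberry --analyte TAC --seed 7 --out bb.csv
wrote 45 rows to bb.csv
$ pulpcolor fit --samples bb.csv
Blackberry/TAC: b = (1620.35, -11.54, -12.22, 18.10), R2 = 0.936, n = 44
$ pulpcolor run --samples bb.csv --out-dir report --seed 7
$ cat report/validation.csv
fruit,analyte,experimental_mean,cv_e,predicted_mean,cv_p,horwitz_limit,passes_horwitz,relative_error
Blackberry,TAC,1420.68...,3.69,1422.80...,3.47,8.0,True,0.149
```

The recovered coefficients sit close to the generating truth
(1644.47, −13.53, −12.56, 18.42); one of the 45 rows was trimmed by the 2σ
filter; both CVs clear the 8% band, so the synthetic method validates.

The same operations are available as library calls
(`pulpcolor.fit_linear_model`, `pulpcolor.predict_content`,
`pulpcolor.run_pipeline`, ...); see `docs/methods.md` for the modeling
details and design choices.

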