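# ircut

Reference-anchored diagnostic cutoff selection for surrogate indices of
insulin resistance.

## The problem

Insulin resistance (IR) precedes type 2 diabetes and cardiovascular
disease, but the reference measurements — the euglycemic–hyperinsulinemic
clamp, or the OGTT-derived Matsuda index — are too costly for routine
screening. Cheap surrogate indices exist (HOMA-IR, QUICKI, the TyG family,
TG/HDL-c, LAP, VAI, leptin/adiponectin ratio, plain anthropometrics), yet
their published diagnostic cutoffs vary widely across populations. `ircut`
implements a computational procedure that, given a cohort with OGTT
glucose/insulin, lipids, adipokines and anthropometrics, selects an
optimal cutoff with its sensitivity and specificity for each surrogate
index, using the Matsuda index

&nbsp;&nbsp;&nbsp;&nbsp;Matsuda = 10000 / √(G₀·I₀·Ḡ·Ī)

as the reference that defines the IR / non-IR groups. It is aimed at
biostatisticians and clinical researchers evaluating IR screening tools.

## The method

For each candidate variable *y* against the Matsuda reference *x*:

1. z-score both variables;
2. form the *separation/overlap window* on each axis — the interval between
   the IR-group extreme and the non-IR-group extreme — and take its midpoint
   (x_w, y_w);
3. build a spatial weight matrix **W** from inverse pairwise distances in
   the (x_z, y_z) plane raised to a power *p*, min–max scaled, then
   row-standardized;
4. smooth the coordinates with the squared Spearman correlation as weight:
   x₀ = r²**W**x_z + (1−r²)x_z (likewise y₀);
5. sweep *p* from 0.50 to 2.50 in steps of 0.01 and keep the candidate whose
   smoothed-coordinate means (x̄₀, ȳ₀) lie closest to (x_w, y_w); the cutoff
   is ȳ₀ back-transformed to original units;
6. wrap everything in a first-order jackknife and return the replicate whose
   cutoff maximizes the Youden index J = sensitivity + specificity − 1 on
   the full sample.

The Matsuda reference cutoff itself is refined iteratively from the
midpoint of its separation window, so the Matsuda report row is
self-consistent (J = 1) by construction. A truncated-normal, one-factor
copula simulator generates cohorts with the two-group structure of the
emulated study (48 insulin-sensitive / 45 insulin-resistant young men) for
testing and calibration. See `docs/methods.md` for the full model
description and design rationale.

## Worked example

```python
import ircut

result = ircut.run_pipeline(ircut.RunConfig(seed=1))
print(f"Matsuda reference cutoff: {result.matsuda_cutoff:.4f}")
print(result.report[["variable", "cutoff", "sensitivity", "specificity"]]
      .head(6).round(2).to_string(index=False))
```

prints

```
Matsuda reference cutoff: 4.0167
variable  cutoff  sensitivity  specificity
 matsuda    4.02          1.0          1.0
     bmi   28.98          1.0          1.0
      wc   93.01          1.0          1.0
    whtr    0.54          1.0          1.0
 tfm_pct   31.60          1.0          1.0
  af_pct   40.69          1.0          1.0
```

The refined Matsuda cutoff (≈ 4.02) splits the simulated cohort into 45 IR
and 48 non-IR subjects; BMI, waist circumference, WHtR and the DXA fat
fractions separate those groups perfectly, so their selected cutoffs (e.g.
BMI 29.0 kg/m², WC 93.0 cm) classify every subject correctly — while
glucose-only predictors score much lower Youden indices (run the full
report to see them). The same pipeline is available from the shell:

```sh
ircut simulate --seed 1 -o cohort.csv
ircut indices cohort.csv -o panel.csv
ircut run cohort.csv --out-dir results/
```

`ircut run` writes the cutoff report, the Spearman correlation matrix, the
Matsuda correlation vector ordered by magnitude, and tidy per-subject plot
data for violin/scatter figures.

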