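# Methods

## Problem and scope

`ircut` selects diagnostic cutoff values for surrogate indices of insulin
resistance (IR) in a two-group cohort, using the OGTT-derived Matsuda index
as the reference standard. The package covers four stages: (i) calculators
for the surrogate indices, (ii) refinement of the Matsuda reference cutoff
that defines the IR / non-IR labels, (iii) a cutoff-selection engine for
every candidate variable, and (iv) a synthetic cohort generator that
reproduces the two-group statistical structure of the emulated study (93
young adult men: 48 insulin-sensitive, 45 insulin-resistant) so that the
whole pipeline can be exercised and calibrated without access to raw
patient data.

## Surrogate indices

All calculators are pure functions with strict unit contracts (glucose
mg/dL, insulin µIU/mL, lipids mg/dL, leptin ng/mL, adiponectin µg/mL;
mmol/L conversions use TG/88.57 and HDL/38.67):

- Matsuda = 10000 / √(G₀·I₀·Ḡ·Ī), with Ḡ, Ī the arithmetic means over the
  four sampled OGTT timepoints (0/30/60/120 min, equal weights — these are
  the only samples drawn);
- HOMA-IR = G₀·I₀/405; QUICKI = 1/(log₁₀ I₀ + log₁₀ G₀);
- TyG = ln(TG·G₀)/2 and the composites TyG·WC, TyG·BMI, TyG·WHtR;
- TG/HDL-c; BMI = weight/height²; WHtR = WC/height;
- LAP (male) = (WC − 65)·TG[mmol/L]; requires WC > 65 cm;
- VAI (male) = (WC/(39.68 + 1.88·BMI)) · (TG[mmol/L]/1.03) · (1.31/HDL[mmol/L]);
- LAR = leptin/adiponectin.

Only the male LAP/VAI variants are implemented (the emulated cohort is all
men). No winsorizing or outlier handling is applied anywhere: indices are
deterministic functions of their inputs, and out-of-domain inputs raise
errors rather than being clamped.

Known discrepancy: the standard male VAI formula evaluated at the non-IR
group means of the emulated study gives ≈ 1.0, whereas the study tabulates
a non-IR VAI mean of 2.3. The exact VAI variant behind that figure could
not be resolved; the standard formula is used.

## Cutoff-selection engine

For a reference variable x (Matsuda; low values indicate IR), a candidate
variable y, and binary labels:

1. **Standardization.** Both variables are z-scored with the sample SD
   (n−1), because the variables differ in variance by orders of magnitude.
   Back-transform parameters are retained per replicate.
2. **Windows.** On each axis the *window* is the interval between the
   IR-group extreme and the non-IR-group extreme: for an IR-low variable,
   [max(IR), min(non-IR)]. When those ranges are disjoint it is a
   *separation* window, otherwise an *overlap* window; either way its
   midpoint (arithmetic mean of the extremes) anchors the search. The
   candidate axis's direction is taken from the sign of the Spearman
   correlation r(x, y): r < 0 means high y indicates IR.
3. **Spatial weights.** W is built from pairwise Euclidean distances in
   the (x_z, y_z) plane: raw weights (1/d_ij)^p with zero diagonal, then
   min–max scaling of the off-diagonal entries to [0, 1], then row
   standardization to unit row sums. The construction order (power first,
   then scaling, then row normalization) keeps the family monotone in p
   and every member row-stochastic. Coincident points receive the largest
   finite raw weight (the "closest points weigh most" contract without
   infinities); a completely flat off-diagonal falls back to uniform
   weights 1/(n−1), as does any row whose scaled weights sum to zero.
4. **Smoothing.** x₀ = r²·W·x_z + (1−r²)·x_z and y₀ = r²·W·y_z +
   (1−r²)·y_z. The squared Spearman correlation weights how much each
   coordinate is pulled toward its spatially smoothed version. (The
   y-equation uses W·y_z; the parallel structure is the only reading under
   which y enters the smoothing at all.)
5. **Power sweep.** p runs over 0.50–2.50 in steps of 0.01 (201 values).
   For each p the distance d(p) = √((x̄₀−x_w)² + (ȳ₀−y_w)²) between the
   smoothed-coordinate means and the window midpoints is evaluated; the
   minimum-distance candidate wins (ties to the smaller p). Its cutoff is
   ȳ₀ back-transformed to original units.
6. **Jackknife + Youden.** Steps 1–5 are repeated n times leaving each
   observation out in turn (first-order jackknife). Each replicate's
   candidate cutoff is scored by its confusion matrix **on the full n
   rows** (so replicates are comparable and reported sensitivity/
   specificity refer to the whole cohort), and the candidate with the
   largest Youden index J = sensitivity + specificity − 1 is returned
   (ties: smaller distance, then smaller replicate index). Replicates that
   empty a label group or make a variable constant are skipped with a
   warning.

Classification rule: IR is the positive class everywhere; IR is predicted
for y ≥ cutoff when r < 0 and for y ≤ cutoff when r ≥ 0, with ties at the
cutoff classified as IR.

**Reference refinement.** The Matsuda reference cutoff is the midpoint of
its own separation window, refined by progressive iteration: labels start
from a configurable threshold (default 4.0), each pass recomputes the
leave-one-out window midpoints, keeps the maximum-Youden one (scored on
the full sample), relabels by the new cutoff, and repeats until the cutoff
moves by less than 1e-6 (cap 100 passes). On bimodal data the refined
cutoff lands inside the inter-group gap and the returned labels are exactly
the classification by the returned cutoff, which forces the Matsuda report
row to sensitivity = specificity = 1. The window midpoint — not the
smoothed-coordinate mean — is the right estimator here because the
reference must reproduce its own labels; the smoothed-coordinate mean is
anchored near the pooled mean and is generally not a fixed point of the
relabeling iteration.

**Numerical implementation.** The power sweep never materializes the 201
weight matrices: because x ↦ x^p is monotone, the off-diagonal min/max of
the powered weights are the powered min/max, and W_p acts on a vector v as
((R v)_i − mn·(Σv − v_i)) / (rowsum(R)_i − (n−1)·mn) with R the powered
inverse distances, built by cumulative multiplication along the grid. The
engine additionally factors the jackknife into a label-independent part
(per-replicate standardization, Spearman r, smoothed-mean curves over the
p-grid) and a cheap label-dependent part (windows, candidate choice,
confusion matrices). Label-permutation calibration and reference
refinement reuse the precomputed part; the result is numerically identical
to rerunning the engine from scratch per labeling (asserted in the test
suite). The engine contains no randomness.

## Synthetic cohort generator

The generator is the package's stand-in for the study data, which is not
publicly deposited. Design:

- **Marginals.** Every raw variable (anthropometrics, blood pressures,
  DXA fat fractions, OGTT glucose/insulin at the four timepoints, lipids,
  leptin, adiponectin) is drawn per group from a truncated normal whose
  mean, SD and truncation bounds are the published group summaries — the
  only distributional facts available. The printed mean/SD are used
  directly as the pre-truncation location/scale; for asymmetric ranges the
  realized (truncated) mean therefore shifts slightly away from the
  printed mean (quantified by the quadrature oracle in the tests). OGTT
  series are drawn per timepoint; no parametric glucose-curve model is
  imposed. The age row prints no SD; 3.0 years is assumed. Weight is
  back-solved from drawn BMI and height (weight = BMI·height²), since BMI
  and height are what the study tabulates.
- **Dependence.** A one-factor Gaussian copula: each subject has a latent
  standard-normal severity s, and each variable's copula normal score is
  λ·s + √(1−λ²)·ε with λ = ±latent_rho — positive for variables elevated
  under IR, negative for HDL and adiponectin, zero for age. The default
  latent_rho = 0.8 is calibrated so that at n = 93 at least 19 of the 20
  candidate predictors reach |Spearman r| > 0.5 with the computed Matsuda
  index (on the default seed all 20 do). It is a documented, overridable
  spec field.
- **Derived-index consistency.** In the study the groups are *defined* by
  the Matsuda cutoff, so the tabulated per-group ranges of the derived
  indices (Matsuda, HOMA-IR, TyG and composites, LAP, VAI, LAR, TG/HDL)
  hold by construction. A copula draw from the raw marginals alone does
  not respect them — e.g. an IR-group subject drawn at the 2nd severity
  percentile computes a Matsuda near 6, well inside the non-IR range. The
  generator therefore redraws any subject whose computed derived indices
  leave the group's observed range (rejection sampling, vectorized,
  deterministic under the seed). Indices whose printed ranges carry only
  one decimal of resolution (WHtR, QUICKI) are not constrained. The flag
  `index_consistent=False` disables the redraw; the moment-recovery and
  independence property tests run in that configuration, because those
  invariants describe the raw truncated-normal machinery, which the
  consistency conditioning deliberately distorts.

What the generator does **not** emulate: within-group correlation
*structure* beyond a single factor (real OGTT curves are serially
correlated in time in ways one factor cannot express); measurement error;
the exact group means of derived composites (a mean of products is not the
product of printed means — generated TyG-WC group means run ≈ 2–3% above
the study's, see Limitations); covariate effects of age. Passing tests on
synthetic cohorts therefore demonstrate correctness and calibration of the
*procedure*, not clinical validity of any particular cutoff.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `latent_rho` | 0.8 | copula loading; strength of the shared severity factor |
| `initial_matsuda` | 4.0 | starting threshold for reference refinement |
| `p_min`, `p_max`, `p_step` | 0.50, 2.50, 0.01 | power grid of the weight-matrix sweep |
| `n_ir`, `n_nonir` | 45, 48 | group sizes of the emulated cohort |
| `seed` | — | single source of randomness (generator only) |

## Design choices where the design was open

- Confusion matrices of jackknife candidates are evaluated on all n rows,
  not the n−1 retained rows: replicates become comparable and the reported
  operating characteristics describe the whole cohort.
- W is built from joint distances in the (x_z, y_z) plane rather than
  per-axis; "distances between all points" of a bivariate scatter most
  naturally means the plane.
- Orientation and the candidate axis's window direction come from the sign
  of the pooled Spearman correlation with the reference, recomputed per
  replicate.
- Standardization and r are pooled (both groups), per replicate;
  back-transformation uses the replicate's own parameters.
- Ties: sweep ties go to the smaller p; jackknife ties to smaller
  distance, then smaller replicate index; brute-force oracle ties to the
  smaller cutoff, high-is-IR first.

## Known limitations

- The candidate cutoff is the back-transformed smoothed y-coordinate
  mean, which is anchored near the pooled mean of y. When the two groups
  are strongly unbalanced and separated, the pooled mean can sit inside
  the larger group's range, and the selected cutoff then underperforms
  the exhaustive-search oracle. With near-balanced groups (as in the
  emulated 48/45 design, group fraction ~0.4–0.6) the engine matches the
  oracle on separated data; the acceptance tests probe exactly that
  regime.
- Generated group means of multiplicative composites (TyG-WC, TyG-BMI)
  exceed the study's printed means by ≈ 2–3%: the printed composite means
  embed within-subject covariance that marginal draws cannot reproduce,
  truncation asymmetry inflates the TG/insulin means, and the
  derived-range conditioning trims the composites' lower IR tail. The
  selected cutoffs for those composites land just above the printed
  non-IR/IR gap even though sensitivity/specificity remain at or near
  1.00.
- Cutoffs carry no confidence intervals (none are defined by the
  procedure); the jackknife here stabilizes selection, it does not
  estimate variance.

## Problem sizes used in the tests

Acceptance-level checks run the full 93-subject pipeline across 100 seeds
for separation recovery, 1000 random instances of n ≤ 30 against the
exhaustive oracle, 1000 label permutations of the default cohort, and
10,000-per-group cohorts for moment recovery — sizes chosen to bound
Monte-Carlo error well below the asserted margins.
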