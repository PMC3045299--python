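# kernelcc

Kernel-perceptron statistical learning versus logistic regression on
simulated two-risk-factor case-control data, with a KDE-based transformation
of classifier scores into **continuous odds-ratio curves**.

## The problem

Epidemiologic case-control analyses lean on logistic regression (LR) because
its coefficients are log odds ratios. But LR's separation boundary in
risk-factor space is a hyperplane; when the true exposure/disease
relationship is nonlinear, the fitted coefficients summarize an average
effect and the boundary misclassifies structurally. Kernel statistical
learning (SL) methods capture nonlinearity without a parametric form, at the
cost of losing the odds-ratio interpretation. This package implements both
sides of that trade, plus the bridge back:

1. **Simulator** — subjects carry x1 ~ U(0, 1) and x2 = (x1 + z1)/10 with
   z1 ~ N(5, 1). Disease status follows a stochastic nonlinear boundary:
   a subject is a case iff x2 > g(x1), where

   g(x1) = (1/c0) · [ x1²/(x1² + (1−x1)²) + exp(−(a0·x1 − m0)²) ]

   is a parabola-built sigmoid plus a movable Gaussian bulge. A dataset is
   the first m cases and first m controls from a 20 000-subject pool. The
   shipped constants (a0, c0, m0) = (4.5, 1.6, 0.25) were calibrated once so
   that, at m = 200, the raw marginals give Az(x2) ≈ 0.77, Az(x1) ≈ 0.49 and
   pooled Pearson R(x1, x2) ≈ 0.25.

2. **Kernel mapping** — the universal kernel k(x, xj) = c_x·exp(−D(x, xj))
   with the per-component weighted distance
   D = sqrt(s1·Δx1²/σ1² + s2·Δx2²/σ2²). Each subject becomes the 2m-vector
   of its kernel values against the training set (a row of **K**).

3. **Perceptron** — a Rosenblatt perceptron on kernel rows with fixed bias
   b = 1, trained by bootstrap-ordered updates with the training-set ROC
   area (Az) as convergence criterion, then fine-tuned by raising the Az
   criterion in 0.005 steps until non-convergence. Sigma-weights come from a
   grid search maximizing training Az. Three variants are fitted: both
   factors (k), x1 only (k_x1), x2 only (k_x2).

4. **Evaluation** — Mann–Whitney Az (with tie correction), 10×150 stratified
   bootstrap on the training set, 10 independent validation datasets, and
   operating points set by the *mean-sensitivity rule* (threshold where
   sensitivity equals Az, which equals the ROC's mean sensitivity).

5. **Odds-ratio transformation** — Gaussian KDEs h1, h0 of the case/control
   normalized scores give p_r(z) = h1/(h1+h0) = Pr(case | z), and with
   p_1(z) = p_r(z + Δz),

   OR(z) = [p_1/(1−p_1)] · [(1−p_r)/p_r],   Δz = 0.10.

   For LR scores ln OR(z) is constant (the coefficient); for the kernel
   models it is a genuine curve showing where in score space the odds climb.

## Worked example

```sh
kernelcc run-study --m 200 --seed 0 --out study/
```

runs the whole pipeline (one training dataset, sigma search over
{0.25, 0.5, 1, 2, 3, 4, 5, 6}², three SL variants, two LR fits, bootstrap and
validation evaluation, OR curves and boundary exports) in a few seconds and
prints the validation summary:

```
{"table2": [
 {"method": "LR",     "az": 0.779480, "sd": 0.017041, "se": 0.005389},
 {"method": "LR_int", "az": 0.776540, "sd": 0.017252, "se": 0.005456},
 {"method": "k",      "az": 0.996402, "sd": 0.001361, "se": 0.000430},
 {"method": "k_x1",   "az": 0.860000, "sd": 0.023929, "se": 0.007567},
 {"method": "k_x2",   "az": 0.774678, "sd": 0.019273, "se": 0.006095}]}
```

Reading: the full kernel model (k) nearly separates the classes because the
simulated status is a deterministic function of (x1, x2) and the kernel
mapping renders the nonlinear boundary linearly separable. x1 *alone* is
uninformative marginally (raw Az ≈ 0.49) yet the kernel variant k_x1 reaches
Az ≈ 0.86 — the case/control x1 distributions differ in shape, not location,
and that is exactly what LR cannot exploit (LR ≈ 0.78 rides almost entirely
on x2, whose coefficient is strongly positive). `study/report.json` also
records the fitted LR coefficients — e.g. (β0, β1, β2) ≈ (−7.2, +0.2, +13.3)
for the standard model at this seed — the operating points (standard LR:
sensitivity 0.78 at false-positive fraction 0.44), and `study/or_curve_*.csv`
holds the continuous ln-OR curves per SL variant.

Individual stages are available as `simulate`, `calibrate`, `fit`,
`evaluate`, `odds` and `boundary` subcommands; see `kernelcc --help`.

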