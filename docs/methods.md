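# Methods

## Model overview

`agepbpk` simulates the disposition of four CYP3A4-metabolized drugs
(midazolam, fentanyl, alfentanil, sufentanil) with a whole-body,
flow-limited physiologically based pharmacokinetic (PBPK) model whose every
physiological coefficient is a deterministic function of age. The body is
represented as venous blood → lung → arterial blood feeding heart, brain,
muscle, adipose, skin, kidney, spleen, five gut-wall segments (duodenum,
jejunum, ileum, cecum, colon), liver and a residual tissue, all drained
back to venous blood; spleen and gut walls drain through the portal vein
into the liver. The gut lumen is a serial transit chain (stomach →
duodenum → … → colon → feces) with first-order transfer at 1/mean
residence time. Absorption (first-order rate 2·P_eff/r, with r the
age-dependent intestinal radius) and gut-wall CYP3A metabolism occur in
duodenum, jejunum and ileum only. The liver eliminates by the well-stirred
model in intrinsic-clearance form (rate `fu_b·CL_int,l·C_liver,venous-ref`),
the kidney at a renal clearance referenced to its emergent venous
concentration. The stomach wall is not an explicit compartment; its small
volume and perfusion are folded into the residual tissue.

All processes are linear, so the state equation is `dy/dt = A·y + u(t)`
with constant `A`; cumulative hepatic, intestinal and renal elimination and
fecal loss are carried as extra states so the mass balance is checkable to
solver precision. Key consequences used throughout: exposures scale
linearly with dose, responses to multiple dose events superpose, and
exposure-matched doses follow from a single probe simulation.

### Assumptions

- perfusion-limited (not permeability-limited) tissue distribution;
- linear (non-saturable) metabolism and renal excretion;
- no enterohepatic recirculation, no metabolite kinetics, no CYP3A5
  polymorphism, no transporters;
- sex-agnostic physiology (an explicit modelling choice; the field's
  evidence for these four drugs shows no consistent sex effect);
- intravenous boluses are represented as 0.5-min infusions to avoid the
  distributional artifact of instantaneous mixing (configurable).

## Age-dependent physiology

**Body size.** Body weight and height follow rational growth curves
`Y = (a + b·A)/(1 + c·A + d·A²)`. A single coefficient set cannot track
infancy, the adolescent spurt and senescence simultaneously, so three sets
per quantity are packaged (0–3 y, 3–18 y, ≥18 y), fitted to sex-averaged
reference anthropometry (max error ≈ 2 %). Body surface area uses the
classical adult power law above 15 kg and the infant/child law below;
exactly 15 kg resolves to the adult branch.

**Organ volumes and perfusion.** Tissue volumes are age-interpolated
fractions of body weight and perfusion age-interpolated fractions of an
allometric cardiac output (CO ∝ BW^0.75), anchored at newborn, 1, 5, 10,
15 y and adult reference values from standard reference-anatomy
compilations. Beyond age 40, cardiac output declines 0.7 %/y, with small
hepatic and renal extras such that hepatic perfusion reaches ~57 %, renal
perfusion ~70 % and liver volume ~70 % of the young-adult value by ~age
90 — the senescence endpoints the source clinical literature reports. The
residual tissue absorbs the flow difference so the perfusion balance
closes exactly at every age.

**CYP3A activity** (fraction of the healthy-adult level):

| regime | span | form |
|---|---|---|
| neonatal/preterm | PNA < 1 mo (term) or < 6 mo (preterm) | `0.003 + 0.1331·PMA` (PMA in years) |
| pediatric | to 20 y | `A^0.83/(0.31 + A^0.83)` |
| adult | 20–40 y | 1 |
| elderly | > 40 y | `0.92^((A−40)/10)` |

Switches are hard; the largest jump (≈4-fold at the 1-month boundary for a
term newborn) is a property of the source functions, and the logger reports
the regime per subject. Intestinal CYP3A ontogeny uses
`0.639·A/(2.36+A) + 0.42`: the printed source form is typographically
ambiguous, and this reading both matches the token order and converges to
≈1 at adult ages, which the alternative Hill reading (plateau 0.639) does
not; the alternative remains selectable.

**Microsomal protein (MPPGL).** Pediatric log₁₀-cubic curve below 20 y,
a cubic polynomial from 20–80 y, and a late-life quadratic above 80 y that
reproduces the reported rebound in the oldest old. Regime jumps are < 1 %.
PBSF (whole-liver microsomal protein, mg) = MPPGL × liver weight.

**Plasma proteins and binding.** Albumin: Hill curve in postmenstrual age
(neonatal), `1.1287·ln A + 33.746` (pediatric), `51.4 − 0.107·A` (from age
20). AAG: adult 0.61 g/L scaled by the percentage `0.01137·days + 53.4`
capped at 100 % in childhood; 0.58 g/L from age 60. The subject's unbound
plasma fraction follows the competitive-binding rescaling
`fu = 1/(1 + P·(1−fu_ad)/(P_ad·fu_ad))` using the drug's dominant binding
protein (albumin for midazolam, AAG for the three opioids). Tissue:plasma
partition coefficients are rescaled by the subject/adult fu ratio
(restricted binding: unbound tissue affinity age-invariant); blood unbound
fraction is fu_p/R_b with R_b age-invariant.

**Clearance scaling.** Whole-liver intrinsic clearance =
per-mg adult value × CYP3A ratio × MPPGL × liver weight (the single
µL/min → L/h conversion happens here). Whole-gut intrinsic clearance is
stored as an adult aggregate (the product of per-pmol activity and total
mucosal abundance) split across duodenum/jejunum/ileum by abundance
fractions (0.20/0.57/0.23); pediatric subjects scale it by the product of
the hepatic maturation ratio and the intestinal ontogeny fraction — the
literal reading of the source scaling relation, in which the pediatric
intestinal clearance is defined through the maturing pediatric enzyme
activity — while elderly subjects keep adult activity corrected by relative
body weight. Renal clearance scales with relative renal perfusion.

## Adult drug parameters and calibration

Drug records (permeability, fu, R_b, binding protein, partition
coefficients, renal clearance) are assembled from published clinical
pharmacology of healthy adults. The whole-liver and whole-gut intrinsic
clearances are *in-vivo* calibrated values: they are set so that the
reference adult (30 y for physiology, 39 y — the 19–59-band midpoint — for
dose work) reproduces published systemic clearance and, for midazolam,
oral bioavailability (model: CL ≈ 33 L/h ≈ 7.8 mL/min/kg, F ≈ 0.30; both
inside the published ranges). This mirrors standard PBPK practice of
developing the adult model against clinical data before extrapolating, and
these values are never revisited afterwards. In-vitro-scaled intrinsic
clearances would be several-fold lower (the well-known IVIVE gap).

## Virtual populations

Six parameters carry inter-individual variability: P_eff, f_u,b, CL_int,l,
CL_int,i, R_b and PBSF. Each subject's multiplier is exp(η),
η ~ N(0, σ²), resampled until it lies in [0.67, 1.5]; σ = ln(1.5)/1.96 ≈
0.207 places ≈95 % of the untruncated mass inside the bounds, which are
log-symmetric (0.67 ≈ 1/1.5). A log-uniform alternative is available. The
f_u,b multiplier is additionally clipped so the unbound fraction cannot
exceed 1. One seeded generator drives the whole population in a fixed
draw order, so (base, n, seed) is fully reproducible. Percentile bands
(5/50/95) are pointwise empirical percentiles with linear interpolation
between order statistics.

Because the six multipliers enter the exposure nonlinearly, the population
median AUC sits a few percent above the typical individual's; population
medians (not typical-subject values) are therefore used wherever the
analysis specifies medians.

## Validation statistics

AFE = 10^(mean log₁₀(pred/obs)) with bands satisfactory [0.8, 1.25],
passable [0.5, 0.8) ∪ (1.25, 2], else poor. PE% = geometric mean of
|pred−obs|/obs × 100 with bands < 25 / 25–50 / ≥ 50. Exact predictions
produce zero error terms, for which the geometric mean is undefined; such
terms are excluded with a warning and an all-exact vector returns 0 —
finite and conservative. AUC(0–t) uses the linear trapezoid (a
linear/log-linear hybrid is available); Cmax takes the first attainment of
the maximum. Two-fold coverage counts ratios in [0.5, 2] inclusive.
Predicted NCA values for validation come from the 50th-percentile curve.

## Sensitivity analysis

Local analysis re-simulates the typical adult with one parameter scaled by
0.5/1/2 (Q_l, f_u,b, K_t:p jointly, P_eff) or 0.1/1/10 (PBSF, CL_int,l).
Scaling Q_l scales all liver-inflow paths; total perfusion (the lung flow)
re-balances to the new sum. Global analysis estimates Sobol indices of
AUC(0–24) with a Saltelli scheme on scrambled Sobol sequences
(`scipy.stats.qmc`), Saltelli-2010 estimator for S1 and Jansen for ST,
200-resample bootstrap CIs, factors sampled log-uniformly over the local
ranges (two of which span two decades — log-uniform matches their
multiplicative semantics). Default n_base = 1024 (8192 model runs,
≈1 min). The estimator is verified against the analytic Ishigami indices.
A mildly relaxed solver tolerance (rtol 1e-6) is used inside the Sobol
loop; AUC is insensitive to it at that level.

## Dose optimization

Age bands follow the clinical grouping (0–1 mo, 1–6 mo, …, ≥85 y). Each
band is represented by one age: the upper edge for the newborn band (its
members are conventionally described as 1-month-olds), the geometric
midpoint for bands entirely within infancy/toddlerhood (physiology changes
log-linearly there), the arithmetic midpoint otherwise; both conventions
are available explicitly. The matched per-kg dose is
`probe_dose · reference_metric / probe_metric` on population medians
(reference: 0.75 mg iv over 2 min in the adult band), exact under
linearity and optionally re-verified by an explicit re-simulation against
the 15 % deviation criterion.

## Numerical choices

- LSODA with the exact constant Jacobian; defaults rtol 1e-8, atol 1e-10
  (mass-balance closure < 1e-6 of the dose; dose-linearity < 0.01 %).
- Output grid: 481 uniform points over 24 h, refined to 0.01 h around dose
  events so that infusion-end peaks are captured.
- Oral doses are impulses into the stomach lumen; the snapshot exactly at
  the event time is pre-impulse, and the administered-amount bookkeeping
  uses the same convention.
- Simulation sizes: populations of n = 300 in the acceptance script and
  n = 200 in population-level tests; bounded-multiplier medians are stable
  at these sizes (seed-to-seed dose variation < 5 % at n = 150).
- Ages are real years throughout; "days" in the AAG percentage uses
  365.25 d/y; gestational weeks convert at 52 w/y.

## What the synthetic fixtures do and do not show

`generate_fixtures` emulates digitized clinical profiles by subsampling the
typical-individual curve at 8–12 geometrically spaced times and adding
truncated-at-zero noise proportional to the local concentration. Fixtures
therefore share the model's own structure: self-validation (AFE ≈ 1 at low
noise) demonstrates the statistics pipeline and I/O round-tripping, not
clinical predictive accuracy. Real profiles differ by assay error,
sampling-time misrecording, inter-study population differences and model
misspecification, none of which the fixtures emulate.

## Known limitations

- The neonatal→pediatric ontogeny switch at 1 month is a hard 4-fold step
  for a term newborn; exposure predictions for the first weeks of life are
  the least certain, consistent with the high reported variability in
  preterm/term neonates.
- Gut-wall metabolism referenced to wall venous concentration couples
  pre-systemic and systemic intestinal extraction; the calibration anchors
  the oral route (midazolam F ≈ 0.30), so the systemic intestinal
  contribution is likely overstated relative to enterocyte-limited
  reality.
- Partition coefficients scale only through plasma binding; age-dependent
  body-composition effects on tissue affinity (e.g., infant adipose
  composition) are not modelled.
- No disease states, surgery/bypass effects, pharmacodynamics, or
  safety-bounded dosing logic.
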