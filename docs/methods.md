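# Methods

`mvamep` models isopentenyl diphosphate (IPP) and dimethylallyl diphosphate
(DMAPP) biosynthesis in rice seed tissue across four genotypes: wild type
(WT) and three engineered types that carry a plastid-targeted ectopic MVA
pathway of increasing completeness (Type I: HMGR; Type II: + HMGS, MVK;
Type III: + PMK, MVD). This note records the model, its assumptions, the
numerical choices, and what the synthetic data can and cannot establish.

## Kinetic formalism

Every process is approximated by a saturating rational rate law

v = V · ∏ᵢ xᵢ / ( ∏ᵢ (Kᵢ + xᵢ) + ∏_b (x_b + K_b) ),

with apparent saturation rate constant `V` (mM per model-time unit),
substrate binding constants `Kᵢ` and inhibitor constants `K_b` (mM). With
a single substrate and no inhibitors this is exactly Michaelis–Menten; the
inhibitor product is added to the denominator only when inhibitors are
declared, so the classical reduction holds without a spurious constant term.
No reaction of the pathway models declares inhibitors or activators, but the
law supports them. Time is a dimensionless "model time" inherited from the
V scale; all concentrations are mM.

## Network

WT carries 14 dynamic pools: the cytosolic MVA chain
(HMG-CoA → MVA → MVP → MVPP → IPP, HMGS condensation upstream, IDI
isomerisation to DMAPP) and the plastidic MEP chain
(G3P + pyruvate → DXP → MEP → CDP-ME → CDP-MEP → MEcPP → HMBPP → IPP/DMAPP,
plus a plastidic IDI). Acetyl-CoA, acetoacetyl-CoA, G3P and pyruvate are
held at fixed concentrations (the plant maintains their homeostasis), so
they drive rates but carry no equation. HDR is written as two parallel
reactions (HMBPP → IPP and HMBPP → DMAPP, both tagged to the HDR gene) with
a 5:1 basal flux split, the canonical product ratio of this enzyme. IPP and
DMAPP cross the plastid envelope in both directions with the export rate
constant fixed at exactly ten times the import rate constant
(export-dominant transport). Both compartments drain IPP/DMAPP through
simple single-substrate sink reactions — no downstream isoprenoid chemistry
is modelled, which is why sensitivity analysis flags these pools as the
least well-determined part of the model.

Variants extend WT monotonically: Type I adds plastidic HMGR with slow
HMG-CoA/MVA exchange (16 pools), Type II plastidic HMGS and MVK with MVP
exchange (17), Type III plastidic PMK and MVD with MVPP exchange (18). The
dynamic-pool counts are asserted at construction. The "very slow"
MVA-intermediate exchange is quantified as: export V = 1% of the
corresponding cytosolic chain V, import at a quarter of the export rate, so
the plastidic ectopic pools always have a net outward drain.

## Parameter provenance and calibration

Measured basal constants are not available to the package, so the default
provenance is **calibrated**: binding
constants are drawn log-uniformly within half a decade of the basal
concentration of their pool (each step neither saturated nor first-order);
a self-consistent steady-state flux is assigned to every WT reaction (MVA
chain flux 1, MEP chain flux 2 in model units, HDR split 5:1, half the
plastidic IPP isomerised by IDI, 40% of the remaining plastid surplus
exported, sinks as residuals); and each V is solved from
V = flux / ∏ qᵢ with qᵢ = xᵢ/(Kᵢ+xᵢ) at the reference concentrations. The
reference state is therefore an **exact** fixed point of the calibrated WT
model, and its stability is checked by the Jacobian spectrum. Ectopic
constants reuse the corresponding cytosolic V, except the plastidic HMGS
entry flux, which is capped well below the narrowest downstream exit of the
variant's ectopic chain (Type II exits only through the slow MVP exchange;
Type III runs through plastid MVD into IPP). A draw is accepted only when
all four variant basal models are stable, including under a doubled
transgene dosage stress test; rejected draws are redrawn deterministically
from the seed.

## Steady states, stability, sensitivities

Steady states are found by a Newton-type root solve in log-concentration
space (positivity by construction, analytic Jacobian), falling back to
LSODA integration towards quasi-stationarity (relative tolerance 1e-9)
followed by a root polish; convergence requires a residual below 1e-8
mM/time. When no positive fixed point exists the trajectory diverges; a
pool is reported "accumulating" when it exceeds 10³× its basal value and is
still growing, or rises monotonically by more than 50% over the final decade
of the horizon (the relative-growth clause distinguishes true divergence
from slow relaxation toward a large but finite steady state). Stability is
strict negativity of all Jacobian eigenvalue real parts; the Jacobian is
assembled from hand-coded analytic partials of the rational rate law and is
validated against central finite differences (1e-6 relative) in the tests.

Logarithmic sensitivities S(X,p) = ∂logX/∂logp are computed by re-solving
the steady state at p·(1±δ) with δ = 1% centered in log space — not by
local linearization — so they capture the full nonlinear response. The
aggregate indices are the Euclidean norm of a row or column divided by the
number of its components (norm-over-count, which makes the indices
comparable between variants of different size). Entries whose perturbed
re-solve loses stability are flagged NaN and excluded from aggregates with
a warning. Eigenvalue sensitivities track the spectrum sorted by real part
and are flagged when the base spectrum is near-degenerate.

## Stabilization

Line-personalized mutant models can lose their steady state: a consuming
capacity below the incoming flux makes DXP, CDP-MEP, MEcPP (or combinations)
accumulate. The stabilization scan multiplies the V of the reactions
consuming these pools (the DXR, MDS, HDS steps) by log₂-spaced factors 2ᵏ,
k ∈ {−3…6}, over all 1-D, 2-D and 3-D subsets, pools every stable candidate,
and selects the minimum normalized distance ‖log₂ m‖₂ / √(#scanned axes),
ties broken by fewest changed parameters then lexicographically. The chosen
candidate is re-verified with a full solve and reported with a stability
certificate (the largest eigenvalue real part). An empty candidate set is an
explicit error status, never silent. For workflows that need many related
solves (per-line states, hormone sweeps) a cheap directed top-up doubles the
already-chosen axes until stability returns, emulating deeper
post-transcriptional upregulation of the same consumers; the reported
minimal distances always come from the full scan, never from the top-up.

## Hormone coupling

Hormone levels are screened against responses (gene-expression ratios;
model steady-state metabolite concentrations) by OLS on log₁₀–log₁₀ axes.
Pairs with slope p < 0.05 become links; no multiple-testing correction is
applied (recorded in the link table), so at a panel of 11 hormones a handful
of spurious links per type is expected and the downstream validation treats
them as such. Each link is rendered as a multiplicative rate modifier,
power-law (H/H_ref)^g or saturating [(H/(K+H)) / (H_ref/(K+H_ref))]^g, the
saturating form being chosen when |R²_adj/g| ≤ 0.5 (a steep exponent
explaining little variance indicates saturation over the observed range).
K is the median observed level; both forms equal 1 at the reference level,
so the basal model is preserved by construction, and hormones below their
detection limit revert the affected terms to basal (piecewise handling).
Gene links multiply the reactions tagged with the gene. Metabolite links
attach to all producers and consumers of the pool; note that such a uniform
multiplier cancels in the pool's own balance, which is why the sign
validation couples the model through the *gene* links and uses the
metabolite links as the assessed correlations: each hormone is swept over
its observed range (uniform capacity within a sweep), the coupled model is
re-solved, and the simulated trend sign is compared with the fitted slope
sign. Sweeps that lose stability at any level, or that show no dependence
(the expected outcome for spurious links), count as "ambiguous or none
observed".

## Phenotype models

Macroscopic traits (height, leaf count, leaf length/width, chlorophyll) are
regressed per mutant type on typed predictors — gene-expression ratios,
hormone levels, and *model* steady-state metabolite concentrations (the
multilevel chaining: metabolites enter from the stabilized line models, not
from measurements). Forward stepwise selection: single-predictor fits gated
on coefficient significance (α = 0.05) and adjusted R² > 0.2; the winner is
the highest adjusted R², with AICc (small-sample-corrected) breaking ties
within 0.02 R², and R² breaking AICc ties within 2; extensions exclude
collinear pairs (|Pearson r| ≥ 0.7) and stop when no addition gains 0.02
adjusted R² with a significant coefficient. Leaf-count predictions are
rounded to the nearest integer. Leaf area is 0.75 × length × width. The
package also ships the study's fitted type-specific models as evaluable
objects (typed predictors, printed coefficients) for prediction and for the
type-specificity comparison.

## Synthetic cohorts

The generator emulates the study conditions, not any particular dataset:
cohorts of 6 (WT) and 12/10/12 (Types I/II/III) lines; endogenous
expression ratios log-normal with ln-SD 0.3 around 1; exogenous transgenes
(present only in the matching variant) log-normal with ln-SD 0.6,
reflecting non-targeted integration; hormones log-normal on a log₁₀ scale
(panel of 11, SD 0.3 decades) censored at per-hormone detection limits
(jasmonic acid deliberately ~30% censored to exercise the piecewise
handling); phenotypes from planted affine models with Gaussian noise scaled
to an R² of 0.7. Two planted structures tie the cohorts to the pipeline:
(i) hormone→gene modulations (iP→DXS g = +0.8, ABA→MCT g = −0.5) that
create recoverable log-log correlations, and (ii) consumer deficits — the
DXR (Type I), DXR+MDS (Type II) and DXR+MDS+HDS (Type III) expression
centers are placed at γ = 0.7/0.3/0.2 of the calibrated capacity threshold
q = x/(K+x), the exact point below which the consuming flux can no longer
carry the pathway input. This makes the personalized mutant models lose
their steady state with the matching pools accumulating, makes the expected
stabilizing multiplier ≈ 1/γ, and deepens the required intervention from
Type I to Type III, so the magnitude ordering (II, III) > I is a property
of the planted conditions. All draws are deterministic in the seed; the
TSV outputs are byte-identical across repeat runs on the same platform
(floating-point text round-trips exactly).

What passing tests on these cohorts show: that the pipeline's estimators
recover planted structure at the study's sample sizes. What they do not
show: anything about the real measured rice data (absent here), the true
kinetic constants, or hormone-metabolite biology beyond sign consistency.

## Cross-variant rank properties

The robustness ordering (WT least robust, Type III most) is asserted on the
fraction of sensitivity entries with |S| > 1 — the summary this comparison
is usually reported with — averaged over three replicate cohorts, because
single-cohort medians at n ≈ 10–12 lines are noisy (the analysis script
prints the single-cohort values and says so). The stabilization-magnitude
ordering (II, III) > I uses the median-model normalized distances and holds
per cohort.

## Problem sizes and runtime choices

Default analyses use the median-line model per variant (one scan each, ~5 s)
rather than per-line scans; per-line steady states reuse the median
multiplier with the doubling top-up. The stepwise recovery property uses
200 replicates at n = 30 with 5 decoy predictors; hormone sign recovery uses
100 replicates at n = 30, CV 20%. The full test suite runs in a few minutes
on one CPU.

## Known limitations

- Flux magnitudes are in model units; with calibrated (not measured)
  constants, eigenvalue magnitudes and the |S| > 1 counts are not
  comparable to values obtained under measured constants.
- IPP/DMAPP consumption is a structureless sink; sensitivities of these
  pools are accordingly the largest and least mechanistic.
- The hormone-coupling validation inherits the no-correction α = 0.05
  screen: many assessed pairs are expected to be spurious and show no
  model dependence.
- Metabolite-response hormone links attached to all producers+consumers of
  a pool shift neighbouring pools, not the pool itself; a finer attachment
  (per correlated enzyme) would need per-term evidence the data here do not
  provide.
- No oscillation or bifurcation analysis: fixed points only.
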