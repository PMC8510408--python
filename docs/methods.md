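# Methods

This note records the models implemented in `bilemix`, the numerical
choices behind them, what the synthetic generators do and do not emulate,
and the known limitations.

## Regular-solution theory of binary mixed micelles

The Rubingh/Rosen regular-solution treatment models the mixed micelle as a
regular solution of the two surfactants: the excess free energy of mixing
is βx₁(1−x₁)RT with a single composition-independent interaction parameter
β. Equating monomer chemical potentials at the mixed CMC gives the two
component equations αC₁₂ = x₁f₁C₁ and (1−α)C₁₂ = (1−x₁)f₂C₂ with
f₁ = exp(β(1−x₁)²), f₂ = exp(βx₁²); eliminating β yields the implicit
equation for x₁ solved by `solve_micellar_composition`, and the ideal limit
β = 0 recovers the Clint equation. Assumptions inherited from the theory:
a single micellar pseudo-phase, composition-independent β, no explicit
counter-ion binding, and activity effects confined to the micelle (the
aqueous monomers are treated as ideal).

Numerics. Roots are bracketed on a 2001-point grid over (ε, 1−ε),
ε = 10⁻¹⁰, and polished by Brent's method to xtol 10⁻¹⁵; exact grid hits
are kept (the symmetric case lands on x₁ = 0.5 exactly). β is evaluated
from whichever component equation is better conditioned — component 1 for
x₁ ≤ 0.5, component 2 otherwise — because the discarded expression divides
by (1−x₁)² (resp. x₁²) and amplifies root error without bound near the
boundary; the gap between the two estimates is reported as
`beta_consistency`. Compositions within 10⁻⁸ of a boundary raise an
ill-conditioning error rather than returning an unreliable β.

Branch convention for strong antagonism. For β larger than about +2 the
chemical-potential balance develops three roots: a fully mixed composition
and two near-demixed ones (the regular solution's miscibility gap). The
forward model `predict_mixed_cmc` returns the fully mixed branch — the
root with the highest mixed CMC, which is the continuous continuation of
the β = 0 solution and keeps C₁₂ strictly increasing in β, so the map
β ↦ C₁₂ stays invertible. The inverse correspondingly selects, among all
roots of the defining equation, the one whose implied β reproduces the
measured C₁₂ through the forward model. A naive tie-break on the
β-consistency residual cannot work here: at any exact root the two
component equations agree identically, so all roots look equally
"consistent". With this convention the forward–inverse round trip recovers
β to better than 10⁻¹⁰ across α ∈ (0.05, 0.95), C ∈ (0.5, 20) mM,
β ∈ (−8, 8). Near-demixed micelle populations, if physically present, are
outside the model.

`classify_interaction` labels |β| ≤ 0.05 as ideal by default; the
threshold separates genuine interaction from measurement and solver noise
and is configurable.

## Phillips CMC detection

The Phillips criterion defines the CMC as the concentration where the
third derivative of conductivity with respect to concentration vanishes —
implemented as the extremum of the second derivative, whose location is
numerically far stabler than a zero crossing of a thrice-differentiated
noisy signal. The second derivative is estimated by moving local-polynomial
(degree 3) least squares, which handles non-uniform concentration grids;
the discrete extremum is refined by a three-point parabolic vertex. The
reported uncertainty is half the local concentration step — the resolution
limit of the grid — since the parabola's curvature-based width is undefined
for near-flat peaks.

Window choice. The default window is adaptive: the odd integer nearest
max(9, n/6). A small fixed window on densely sampled curves places few
points across the breakpoint region relative to the noise bandwidth, and
spurious second-derivative spikes (largest at the high-concentration end,
where multiplicative noise is biggest) then capture the argmax; scaling the
window with n keeps the estimator's localisation stable from 20-point to
120-point curves (noiseless error < 0.05%, mean error ≤ 0.4% at 0.5%
relative noise). An explicit odd `window` overrides the rule.

Significance guard. An extremum only counts as a breakpoint if the slope
change it implies, |d²κ/dC²|·ΔC, exceeds 10⁻⁶ of the curve's overall slope
scale; a straight line (no micellization in range) therefore raises a
no-breakpoint error rather than returning numerical noise. The guard is
invariant under affine conductivity rescaling and concentration unit
changes, as is the estimate itself.

The segmented estimator scans every interior split with at least 3 points
per side, fits independent lines, and intersects the SSE-optimal pair.
Equal slopes or an out-of-range intersection are flagged in diagnostics
rather than raised — the two-line picture may still be informative. The
post/pre slope ratio is the classical conductometric estimate of the
micellar counter-ion ionization degree, clipped to [0, 1] with a warning.

## Molar solubilization ratio

MSR is the OLS slope of solubilizate vs surfactant concentration strictly
above the CMC (the breakpoint itself is excluded: the micellar regime is
defined above it), with the slope's standard error from the regression.
A free intercept is fitted, making the estimate invariant to the aqueous
baseline solubility. Orthogonal regression was deliberately not used: the
surfactant concentration is the controlled variable in the source
experiments. Pearson correlations use the exact t-transform p-value.

## PLS, VIP and group comparisons

PLS1 is fitted by classical NIPALS on autoscaled data (centred, unit
sample SD with ddof = 1, matching the scikit-learn convention used as a
cross-check oracle in the tests): per component, weight w ∝ X'y, score
t = Xw, loadings p = X't/t't, q = y't/t't, then deflation of both blocks.
Standardized coefficients are W(P'W)⁻¹q. Extraction stops early with a
warning when the design's rank is exhausted. Scores are mutually orthogonal
by construction (verified to 10⁻⁸), and fitted values are invariant to
affine rescaling of input columns since autoscaling absorbs it.

All one-hot levels are kept — no reference level is dropped — because PLS
tolerates the collinearity and importance is wanted for every bile-salt
class; binary-mixture records set two indicator columns, which also breaks
the all-rows-sum-to-one degeneracy. The default of A = 2 components suits
the small descriptor sets this package targets (four class indicators plus
a handful of covariates) and keeps VIP stable; VIP_j =
√(p·Σ_a SSY_a(w_ja/‖w_a‖)² / Σ_a SSY_a) with SSY_a = q_a²t_a't_a, so
ΣVIP² = p identically and VIP > 1 marks above-average influence.

Group summaries report the arithmetic mean, sample SD (n−1) and count;
singleton groups report an undefined (NaN) SD. Welch's unequal-variance
t-test with Satterthwaite degrees of freedom handles the unbalanced group
sizes typical of literature collations; one-tailed variants are exposed
because directional hypotheses (e.g. conjugated releases more FFA) are the
norm in this setting. The conventional p < 0.05 threshold is used where a
binary significance call is needed.

## pH-stat lipolysis

%FFA(t) = 100·V(t)·c_NaOH·M_lipid / (2·m_lipid), with V in mL converted to
litres internally. The factor 2 reflects sn-1,3-specific pancreatic lipase
(two titratable fatty acids per triacylglycerol), the standard convention
for duodenal pH-stat protocols; it is a parameter (`ffa_per_tag=3` for
complete hydrolysis). The default triacylglycerol molar mass is 880 g/mol,
the conventional value for sunflower oil, and is user-overridable. No
back-titration correction for un-ionized FFA is applied — the conversion
reports raw titration stoichiometry. The first-order summary
Φ(t) = Φ_max(1 − e^(−kt)) is fitted by Levenberg–Marquardt with
Φ_max initialised at the observed plateau and k at initial slope / plateau;
an all-zero profile returns a flagged degenerate fit instead of failing.
Condition comparisons interpolate replicate profiles to a common time
point (warning when grids differ) and delegate to the Welch test.

## Synthetic generators

The generators emulate the structure of the real inputs, not their full
messiness: conductivity curves are piecewise-linear with an optional
softplus-rounded kink (default width 0 for exact tests; real curves are
never perfectly sharp), mixed CMCs come from the forward regular-solution
model with multiplicative lognormal noise (positivity-preserving),
meta-tables are linear in planted category/covariate effects with additive
Gaussian noise, lipolysis runs invert the first-order release model through
the titration stoichiometry (noise added in %FFA units, then monotonized so
every run remains a valid cumulative titration), and solubility series are
flat below the CMC with slope MSR above it. Default study conditions
mirror the target protocols: conductometric curves of ~60 points spanning
0.5–10 mM around a 4.16 mM breakpoint (a modern deoxycholate-scale value)
at 310.15 K, mixture tables on the α ∈ {0.2, 0.4, 0.6, 0.8} composition
grid, 0.1 M NaOH / 0.075 g oil / triplicate lipolysis runs at 310.15 K,
and 100-record meta-tables over the four bile-salt classes with effect
−2.0 on the secondary-conjugated indicator and residual SD 0.3 where an
effect is planted. Identical seeds give identical bytes.

What passing recovery tests therefore shows is that each estimator is
correct under its own model with realistic noise magnitudes — not that it
is robust to the systematic heterogeneity of real literature data
(method-dependent CMC offsets, temperature drift, correlated descriptor
errors), which no generator here attempts to model.

## Pipeline and I/O

Canonical units are mM, K, µS/cm, min, mL, %. Concentration columns may be
given in M, mM or µM through the column-name suffix and are converted on
read; schema violations report the offending column and line. The pipeline
driver runs stages in a fixed order (simulate → cmc → beta → msr →
meta_pls → lipolysis), records per-stage status in `manifest.json`, skips
stages whose upstream inputs failed, and embeds the full configuration in
the manifest so a rerun from the manifest alone reproduces byte-identical
outputs (no timestamps are written).

## Limitations

- Ternary and higher mixtures, temperature-dependent β, and counter-ion
  binding corrections are out of scope.
- Only conductometric CMC determination is implemented; surface-tension or
  fluorescence values are accepted as inputs but never computed.
- logK_ow and molecular volumes are inputs (external descriptor tools),
  never computed.
- The meta-analysis pools datapoints unweighted; no study-precision
  weighting or random-effects model is offered.
- Exact numerical agreement with proprietary PLS implementations is not
  claimed; the implementation is validated against OLS in the full-rank
  limit, against scikit-learn's PLS on random designs, and by
  planted-effect sign/rank recovery.
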