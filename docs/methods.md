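# Methods

This note documents the statistical model behind `paleomet`, the choices
that were genuinely open, the numerical conventions, and what the
synthetic experiments do and do not demonstrate.

## Model and assumptions

The pipeline predicts `y = log₁₀(MMR/M^b)` (mass-independent maximal
metabolic rate) from phylogeny and `z = log₁₀ Q̇` (femoral nutrient-artery
blood flow).  Working on base-10 logs is a structural choice: metabolic
and hemodynamic quantities are log-normally distributed across amniotes,
the flow calibration is itself a polynomial in log radius, and
back-transformed intervals become log-symmetric about the point estimate
(a property the intervals this package reports always satisfy by
construction).

**Hemodynamics.**  `Q̇ = 10^(−0.20 t² + 1.91 t + 1.82)` with
`t = log₁₀ r_i`, `r_i = sqrt(area·lumen_fraction/π)` in mm, `Q̇` in mL s⁻¹.
The quadratic term is read as `(log r)²` — the curved-polynomial reading —
not `log(r²)`: the latter collapses to a straight line and implies
sub-micron arteries at the flow magnitudes this calibration is used for.
The derivative `1.91 − 0.40·t` is positive for all `r < 10^4.775` mm, so
the map is strictly increasing and invertible (closed form, monotone
branch) on any biological domain.  The lumen fraction is a parameter
(default 0.20) because it is an approximation, not a constant of nature.

**Allometry.**  Clade exponents (defaults 0.829 / 0.87 / 1.02 for
non-avian sauropsids / synapsids / birds, config-overridable) are
reconciled by treating them as a tip character under Brownian motion and
taking the maximum-likelihood root state — the GLS mean under the
shared-path covariance, equivalent to weighted squared-change parsimony.
This closed form was chosen over iterative reconstruction because it is
exactly reproducible and provably lies inside the clade-exponent range.
The reconciled exponent applies to extant and fossil taxa alike (fossils
have no clade regression of their own).  Reports carry `b` at full
precision together with the 2-decimal value used in unit labels.

**Eigenvector basis.**  The PEM basis is the thin SVD of the
column-centered weighted influence matrix (tips × edges, entry = edge on
the root-to-tip path, weight `ψ·ℓ^((1−a)/2)`).  Defaults `a = 0, ψ = 1`
make the uncentered weighted Gram matrix equal the Brownian covariance
`C` (asserted in the tests to 1e-8), so the default basis is exactly the
Brownian-motion limit; an optional grid search over
`a ∈ {0, 0.1, …, 0.9}` selects by the downstream model's AICc.
Eigenvectors are numbered 1-based by descending singular value; singular
values below `1e-10` of the largest are dropped (for a binary n-tip tree
exactly `n−1` remain).  Sign convention: each eigenvector's
largest-magnitude element is made positive, with magnitude ties broken by
tip label, so results are identical across linear-algebra backends and
tip orderings.

**Fossil scoring.**  A fossil is grafted at a dated position (attachment
point on an edge, stem length, optional declared tip age checked for
consistency to 1e-6 Myr).  Grafting never alters distances among
pre-existing tips: the attachment edge splits into collinear pieces that
keep the original edge's identity.  The fossil's influence row over the
*extant* basis edges applies the weight rule to the traversed length of
each original edge; the row is centered with the extant column means
(fossils must not shift the basis) and projected,
`u = b_c V diag(d)⁻¹`.  The fossil's private stem has no basis column and
therefore cannot move the scores; its effect belongs in the prediction
variance (below).  Scores are invariant to ψ because ψ scales `b_c` and
`d` identically.

**Regression and selection.**  OLS of `y` on intercept + selected
eigenvectors + `z`.  AICc uses the Gaussian ML convention with the
residual variance counted among the k parameters:
`AICc = −2ℓ̂ + 2k + 2k(k+1)/(n−k−1)`.  Selection is greedy forward: the
intercept and co-predictor are always in; each step adds the eigenvector
that most decreases AICc; stopping when no addition decreases it; ties go
to the smaller index.  The greedy path is computed by incremental
orthogonalization (one matrix product per step) and the selected model is
then refit exactly.  An RSS below `1e-12·max(1, ‖y‖²)` is flagged as a
perfect fit rather than reported as −∞ AICc.  A known property of this
procedure, inherited from sequential AICc selection generally: with many
orthonormal candidates the best-of-m selection bias admits spurious
eigenvectors (a pure-noise response at n = 40 typically retains ~10), so
selected-set size should not be over-interpreted; the calibration
experiment shows the resulting *predictions* remain well calibrated.

## Intervals

Two interval types are available per config:

- `confidence` (default): `x₀β̂ ± t·s·sqrt(x₀ᵀ(XᵀX)⁻¹x₀)` for the
  conditional mean, with `df = n − #coefficients` — the conventional
  confidence interval reported for retrodicted values in this literature.
- `prediction`: adds the residual variance for a single new observation
  *plus a stem-variance term* `σ̂²_BM·ψ²·ℓ_stem^(1−a)`, where `σ̂²_BM` is
  the GLS Brownian rate of the response on the extant tree and `ℓ_stem`
  the fossil's private (unrepresented) branch length.  Trait evolution
  along the private stem is invisible to the eigenvector scores, and
  without this term prediction intervals for grafted tips undercover
  badly (measured ~78% instead of 95% under the generator's conditions);
  with it, coverage is 96–97%.  The term is mildly conservative: the
  co-predictor explains part of the stem variation, and tip noise
  inflates the rate estimate.

Back-transformation is `10^(·)`, so natural-scale intervals are
log-symmetric about the point estimate.  A retrodiction whose selected
scores fall outside 1.5× the extant score range logs an extrapolation
warning (not fatal).

## Cross-validation

For each extant taxon the basis is rebuilt on the remaining tips, the
selection is re-run, and the held-out taxon is scored at its true tree
position — implemented as prune-then-regraft, which restores every
pairwise distance exactly.  One geometric special case: pruning a direct
child of a bifurcating root collapses the root, so the taxon re-attaches
at the new root with the collapsed edge folded into its stem; distances
are preserved but a tip age is no longer representable.  The paired
two-sided t-test (Wilcoxon optional) compares observed and predicted
values; a zero-variance difference vector is reported as p = 1 with a
flag.  Note that LOOCV differences are negatively correlated through the
shared intercept (intercept-only algebra makes them sum to exactly zero),
so this test is structurally conservative: under a correctly specified
model its rejection rate is near 0, far below the nominal 5%.  A high
LOOCV p-value is therefore necessary but weak evidence of calibration;
the coverage experiment below is the sharper check.  Shapiro–Wilk is
applied to the full-model residuals.

## Synthetic data: what it emulates and what it does not

The generator produces pure-birth (Yule) ultrametric trees (default 43
tips, birth rate 0.0125 Myr⁻¹ giving amniote-like root ages near 300 Myr,
clade labels in 15/14/14 blocks), bivariate Brownian `(y, z)` with rates
0.001 per Myr per trait, cross-correlation 0.8, and independent Gaussian
tip noise of 0.1 log₁₀ units; body masses are log-normal
(log₁₀ mass ~ N(3, 1)) and dress the response back into raw MMR with
b = 0.87.  Fossils are masked tips (optionally aged by truncating their
terminal branch); their flow is re-encoded as a foramen area by inverting
the hemodynamic chain, so a pipeline run on synthetic data exercises
every stage, including area → flow.  All generators are bit-reproducible
under a seed.

What passing synthetic tests cannot show: that real clade exponents are
correct, that the flow calibration transfers across taxa and ontogeny
(juveniles have relatively enlarged foramina), that real trees and fossil
placements are right, or that trait evolution is Brownian.  The
experiments validate the machinery under its own assumptions, nothing
more.

## Calibration experiment

200 replicates at 40 tips, 4 masked tips per replicate, contrast
correlation 0.8, noise 0.1: 95% prediction intervals cover the realized
(noise-inclusive) masked values 96–97% of the time; mean LOOCV bias is
below 0.001 log₁₀ units; the LOOCV paired-test rejection rate is ~0
(see above — structural, not a bug).  The experiment runs in ~30 s;
`scripts/acceptance.py` repeats it at 50 replicates.

## Numerical conventions and degenerate inputs

Branch lengths are required on every non-root edge (missing lengths are
errors, never defaulted); zero lengths are allowed and contribute zero
covariance/weight.  Polytomies are handled natively.  Singular Brownian
covariances (zero-length twins) fall back to pseudo-inverse GLS.  Config
files are strictly validated — unknown keys are rejected, never silently
defaulted.  Reports are written only after the whole pipeline succeeds,
and the manifest contains no timestamps, so a rerun with the same seed
and config is byte-identical.

## Known limitations

- Selected eigenvector lists are unstable under resampling (selection
  bias, above); compare models by AICc and prediction error, not by which
  indices appear.
- The stem-variance term treats the response's Brownian rate as
  homogeneous across the tree and ignores the co-predictor's partial
  explanation of stem evolution (conservative).
- The steepness grid search shares data with the final fit; its AICc
  values are mildly optimistic.
- Only trees are supported (no reticulation), and tree/fossil dating is
  taken as given.
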