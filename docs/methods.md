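# Methods

This note documents the statistical models, defaults, and numerical
choices behind `txpod`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Study design and units

All doses are administered doses in mg/kg body weight per day (mkd), kept
on the natural dose scale everywhere (no log-dose transform).  The
emulated design is 4 dose groups (0/2/4/8 mkd) with 4 biological
replicates per dose for sequencing-like data and 5/5/4/5 for
microarray-like data.  Expression enters the models on a log2 scale:
log2 intensities directly, counts as log2 counts-per-million (see
*Normalization*), and qPCR ΔCt negated (expression ∝ −ΔCt).

## Continuous benchmark-dose model

Per gene, replicate measurements `y_ij` at dose `d_i` are modeled as
`y_ij ~ Normal(f(d_i), σ²)` with constant variance.  The five mean
functions are linear, quadratic, cubic, power (`γ + β d^δ`, δ restricted
to ≥ 1) and Hill (`γ + ν dⁿ/(kⁿ + dⁿ)`, n ≥ 1).  Maximum likelihood under
this model is least squares with `σ̂² = SSE/N`; the log-likelihood has the
closed form `−N/2·[ln(2π σ̂²) + 1]`.  Parameter counts include σ (3 for
linear, … 5 for Hill and cubic), and `AIC = 2p − 2·loglik`.

Fitting is exact for the polynomial family (weighted least squares on the
dose-group means, which are sufficient statistics together with the
within-group sum of squares).  Power and Hill profile their linear
parameters (γ and the amplitude) in closed form and optimize only the
shape parameters: power by a bounded 1-D search over δ ∈ [1, 18]; Hill by
a (log k, n) grid (28 × 12, k spanning 1/50 of the lowest positive dose
to 10× the top dose, n ∈ [1, 18]) refined with Nelder–Mead (cap 250
iterations, matching the published optimizer cap).  With four distinct
doses the Hill and cubic mean functions can interpolate the group means;
identifiability of the *model label* is therefore limited at this design
(the fitted *curve* is still well determined at the doses), and AIC ties
are broken deterministically by fewest parameters then a fixed model
order.

**Goodness of fit** is a likelihood-ratio lack-of-fit test against the
saturated group-means model with the same variance structure:
`2(loglik_sat − loglik_model) ~ χ²` with df = (#groups) − (#mean
parameters); df ≤ 0 gives p = 1.  A parametric-bootstrap check in the
test suite confirms the χ² calibration is adequate at n = 5/dose.

**Selection.** A step-up likelihood-ratio chain (cutoff 0.05) picks
linear vs 2° vs 3° polynomial; the nested winner, power, and Hill then
compete on AIC among models with fit p > 0.1.  A winning Hill with
k < (lowest positive dose)/3 is flagged: the next-lowest-AIC candidate
with fit p > 0.05 is used instead; if none exists the Hill is kept and
its BMD replaced by 0.5 × the lowest positive dose.  (The alternative
literal reading — halving the Hill's own BMD — is available behind
`hill_flag_literal_halving`; the dose-based rule is the default because
it is the established remediation in the reference tooling and is not
self-referential.)

**BMD.** The benchmark response is 1.349 σ̂ in units of the modeled
residual SD (≈ a 10% shift of the response distribution).  The modeled σ̂
(not the raw control-group SD) defines the benchmark-response band, for
continuity with the constant-variance likelihood.  The BMD is the
smallest d > 0 with |f(d) − f(0)| equal to the band — closed-form for
linear/power/Hill, first sign crossing (8193-point scan + Brent
refinement) for possibly non-monotone polynomials — searched up to 10×
the top dose, beyond which it is reported undefined.  σ̂ = 0 (an exact
fit) leaves the BMD undefined.

**BMDL.** One-sided 95% profile-likelihood bound: the smallest b such
that the maximum log-likelihood constrained to BMD = b is within
χ²₁(0.90)/2 ≈ 1.353 of the unconstrained maximum.  The constraint is
imposed by eliminating the amplitude parameter (it is a function of b, σ,
and the shape parameters), profiling the remaining parameters by
Nelder–Mead inside a bisection on b (40 iterations, stopping at 10⁻⁴
relative width).  Both amplitude signs are tried except for the linear
model, where the opposite-sign branch cannot improve the fit.  A
simulation in the test suite shows 98% one-sided coverage over 500
linear-gene datasets at n = 5/dose (nominal 95%, accepted band 93–99%).

## Pre-filtering

Present calls: counts need ≥ 0.5 cpm (count/sample-total × 10⁶,
inclusive threshold) in ≥ 3 samples of at least one dose group;
intensities must clear background mean + 3 background SD in all but one
sample of at least one dose group (the quorum mirrors the counts rule;
the boundary is inclusive, compared on the stored log2 scale to avoid
round-trip error).

Differential expression uses classical one-way ANOVA across all dose
groups (the omnibus reading of "significant in at least one dose") with
Benjamini–Hochberg adjustment; per-dose Welch t-tests versus control are
computed for bookkeeping only.  This deliberately replaces
platform-specific moderated statistics (shrinkage-t, permutation Fs):
those estimators are not reproducibly specified and the downstream
BMD/PoD machinery consumes gene lists, not moderation machinery.  The
practical consequence is somewhat lower power at small n than a moderated
test would give; filter-tier comparisons remain internally consistent.
Filter tiers are nested by construction: `fdr` additionally requires the
omnibus p to pass, so FDR ⊆ ANOVA ⊆ unfiltered on every input.  A DEG
further requires |signed FC| ≥ 1.5 at some dose, with the signed
convention −2 ⇔ halving.

### Normalization

Inputs are assumed normalized (TMM/LOWESS-style normalization is out of
scope).  When raw-ish counts are supplied, the modeling-scale conversion
uses a median-of-ratios effective library size rather than the raw
column total: a handful of strongly responding genes can otherwise shift
the totals and make every non-responding gene appear dose-responsive — a
compositional artifact, not expression change.  The present-call cpm
keeps the literal per-sample-total definition.

## Dichotomous (DEG-count) benchmark dose

The number of DEGs at each dose, over the **total unique DEG count**
as denominator, is treated as quantal incidence (this denominator —
rather than the sum of per-dose counts — is the convention under which
the published per-dose percentages reproduce; a switch selects the
literal summed denominator).  Dose 0 enters with 0 affected, since a DEG
is defined relative to control.  Eight standard quantal forms are fitted
by binomial ML with conventional restrictions (multistage β ≥ 0,
Weibull/gamma power ≥ 1, log-logistic slope ≥ 1); the multistage family
is included up to degree 3 = (#dose groups − 1), its degree-1 case being
quantal-linear.  Extra risk `[P(d) − P(0)]/[1 − P(0)] = 0.10` inverts in
closed form for every model.  The Pearson χ² fit statistic uses
df = #groups − #parameters-not-at-a-bound (p = 1 when df ≤ 0); counting
bounded parameters as estimated would let a 4-parameter multistage on 4
groups pass trivially.

Selection is lowest AIC among models with fit p > 0.1, with a flag when
the candidate BMDs span a ≥ 3-fold range.  When **no** model reaches
p > 0.1 — which happens for DEG-count profiles with very large
denominators, where even mild lack-of-fit is overwhelming — the selector
falls back, flagged, to the lowest-AIC multistage-family fit: the
multistage is the conventional default family for cancer-type incidence
data, and the apical endpoints this analysis parallels are multistage
fits.  BMDLs are one-sided 95% profile bounds computed by bisection with
an equality-constrained (SLSQP) inner maximization; a near-feasible
start is built by stretching the fitted dose response so its BMD moves to
the candidate bound.

## Synthetic data

The generator draws, per responder gene, a true model (Hill/power/linear,
default mix 0.4/0.3/0.3), a true BMD from a log-uniform distribution on
[0.5, 6] mkd (inside the dose range so recovery is assessable), a
direction (±), and shape parameters (Hill k log-uniform on [1, 8], n on
[1, 4]; power δ on [1, 3]).  The amplitude is then solved so the mean
curve crosses the benchmark-response band 1.349 × noise_sd exactly at
the drawn BMD — the recorded truth is a closed-form property of the
generative curve, tied to the generative residual SD so that estimation
error is attributable to estimation alone.  Amplitudes implying a
top-dose effect above 8 log2 units (fold change 256) are capped and the
true BMD re-derived in closed form.  Defaults: 20% responders, residual
SD 0.25 log2 units, 2 × 10⁶ expected baseline counts per sample for the
sequencing-like platform (a scaled-down depth appropriate to the
simulated gene-panel size), microarray compression factor 0.7.

Counts are Poisson with lognormal gene means (baseline log2 levels
N(7, 2²)); expected counts are scaled by a *fixed* baseline factor, not
renormalized per sample, so the generator emulates already-normalized
data.  Microarray-like output multiplies all log2 effects by a single
global compression factor (no dose-dependent compression, no dye bias);
qPCR-like output stores −(log2 expression) as ΔCt.  noise_sd = 0 is
allowed for exact-arithmetic checks (e.g. the compression-slope
property); the true BMD is then undefined because the
benchmark-response band has zero width.

What passing these tests shows: the estimators recover known truth under
the model class they assume (normal residuals, constant variance, smooth
monotone-ish curves, independent genes).  What they do not show:
robustness to batch effects, outlier arrays, correlated genes,
count overdispersion beyond Poisson-lognormal, or probe-level artifacts —
none of which the generator emulates.

## Pathway aggregation and PoD selection

Pathway summaries are arithmetic means and medians (even counts:
midpoint) of member genes' BMDs, over genes with a defined BMD not above
the top dose; matching is case-insensitive and a gene contributes to
every set that contains it.  Summaries require ≥ 3 modeled genes; PoD
derivation applies the stricter ≥ 4.  Genes with a BMD but a failed BMDL
profile contribute to BMD statistics only, with the BMDL gene count
reported separately (how such genes should enter BMDL means is not
standardized; reporting the separate n makes the choice auditable).

The distribution-based PoD (approach 3) computes the mode on a log10
histogram with fixed 0.1-unit bins (configurable); the bin midpoint is
clamped to the observed value range.  When two near-tallest peaks are
separated by a valley the distribution is flagged multimodal and the
lowest-dose peak is reported — the most sensitive peak is the
conservative choice.  Cross-platform validation (approach 2) requires
only that the pathway be *modeled* (≥ 4 genes) on a second platform, not
that the BMDs agree.

## Cross-platform statistics

Fold-change regressions run on the log2 effect scale (signed fold
changes are mapped back through their definition), avoiding the
discontinuity of the signed scale at ±1; the gene universe is the union
of the platforms' DEG lists restricted to genes measured on both.  The
filtering-shift test is Welch's t (the unequal-variance default is the
safer reading of an unspecified "t-test").  The percent-in-PoD-range
statistic uses the inclusive interval [2.6, 5.13] mkd.

## Problem sizes used in the test suite

Simulation-based checks run at deliberately modest sizes chosen as the
package's own test design: 500 datasets for BMDL coverage, 20 replicates
of a 2 000-gene study for the filtering-direction property, 100 studies
of 400 genes for PoD recovery, and 10⁶-point grids for BMD-inversion
oracles.

## Known limitations

- Constant-variance normal likelihood only; no non-constant variance or
  exponential models, and no model averaging.
- With 4 dose groups the Hill/cubic label is weakly identified (curves,
  BMDs, and fits are fine; the *name* of the winner can be arbitrary
  between interpolating models).
- The quantal engine reports a flagged fallback rather than refusing when
  no model passes the fit threshold; treat flagged selections with the
  same caution a risk assessor would apply to a "questionable" fit.
- Pathway aggregation is unweighted; no enrichment testing is performed.
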