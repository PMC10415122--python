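# Methods

## Pseudobulk negative-binomial model

Cells are aggregated by (animal, cell type): target UMIs and total UMIs are
summed exactly and the cell count recorded. The aggregate target counts are
modelled as NB(μ, θ) with variance μ + μ²/θ and log link,

    log μ = β_ct + β_ct:trt · 1[treated] + log(total_umi),

one baseline per cell type and one treatment interaction per cell type
present in the treated arm; vehicle is the reference level. exp(β_ct:trt) is
the mean residual target fraction, with 95% CI exp(β ± 1.96·SE). One model
is fitted per dataset (region/timepoint/condition); multi-condition designs
are compared downstream rather than pooled, and no multiple-testing
correction is applied (nominal p < 0.05).

**Fitting.** β is estimated by IRLS at fixed θ (working weights
μθ/(θ+μ)); θ maximizes the profile log-likelihood via Newton steps in
log θ initialized by method of moments, with bisection as fallback; the two
are alternated until max|Δβ| < 1e-8 and |Δlog θ| < 1e-8 (cap 100 outer
iterations). θ is bounded to [1e-4, 1e6]; the upper cap is the
quasi-Poisson limit, reported when the data are under-dispersed. Standard
errors are Wald SEs from the weighted least-squares information at the
converged (β, θ), i.e. conditional on the fitted dispersion — the
convention of standard NB GLM software, against which the fitter is
verified to ~1e-6 (coefficients, SEs, θ, log-likelihood) on frozen fixtures
and against derivative-free joint ML on small tables.

**Degenerate inputs.** Cell types with zero target counts in both arms are
dropped with a warning; cell types absent from the treated arm get no
interaction term and are omitted from estimates (warned). A group whose
counts are all zero in one arm makes the interaction diverge; the fit is
returned flagged `converged=False` rather than raising. Treated animals with
zero target UMIs get a per-animal point estimate of exactly 0 (the
group-level estimate is unaffected, being based on sums).

**Per-animal points.** "Adding the animal's link-scale residual to the
interaction coefficient and exponentiating" reduces algebraically to the
animal's observed target rate divided by the fitted vehicle rate of its cell
type, which is how it is computed; this identity is specific to the
link-scale (working) residual — deviance or Pearson residuals would not
exponentiate to a rate ratio. Vehicle animals' points are also emitted
(scatter around 1.0) for plotting control spread.

**A note on closed forms.** In this saturated design the interaction MLE
equals the pooled-rate ratio (Σ target_trt/Σ total_trt)/(Σ target_veh/Σ
total_veh) exactly whenever exposures are equal within each (cell type, arm)
group, for any θ — the NB mean MLE is then the group sample mean. With
unequal exposures the NB score weights observations by θ/(θ+μ) and the
identity holds only in the Poisson limit θ→∞; at θ ≈ 5 the discrepancy can
reach a couple of percent relative. The same caveat applies to rescaling
counts and totals by a common factor: the NB family is not closed under
scaling, so estimates are exactly scale-invariant only in the
balanced-exposure regime. In practice aggregate totals are large and fitted
θ is usually in the hundreds, making the pooled-rate ratio an excellent
mental model.

## Single-cell mechanism discrimination

Two extreme single-cell accounts of a bulk residual r: *uniform scaling*
(every cell's NB mean × r) and *all-or-none silencing* (fraction 1−r of
cells set to zero, the rest unchanged). Both have mean r·μ; the all-or-none
model has variance r·σ² + r(1−r)·μ² versus r·μ + r²μ²/θ for scaling, a
strict excess for 0 < r < 1 and μ > 0.

The control NB is fitted to raw per-cell counts of vehicle cells by ML (the
mean MLE is the sample mean; θ by 1-D profile maximization, capped at 1e6
when variance ≤ mean). r̂ is the treated/control mean ratio clipped to
[0, 1] — self-contained, though callers may inject the GLM estimate. The
treated counts' exact (unbinned) log-likelihood is computed under both
candidates; Δ = logL(scale) − logL(zero) decides the verdict when |Δ| ≥ 2
(roughly "strong evidence" on the log scale; both candidates have the same
number of fitted parameters, so the raw gap is a fair comparison), otherwise
"inconclusive". Predicted distributions for reporting/plotting are
tabulated on 0..K with K the 1−1e-6 control quantile plus an exact tail
bucket (mass and partial mean), so tabulated means are exact; likelihoods
never use binning.

Because evidence per cell grows with expression, discrimination power rises
steeply with basal μ: at μ ≈ 300 (a highly expressed target like a nuclear
lncRNA) 1000 cells/arm give essentially perfect verdicts, while at μ ≈ 1 (a
typical protein-coding gene in single-nucleus data) the same cell count
yields much weaker evidence — with small samples the test correctly returns
"inconclusive" rather than guessing.

An exposure-adjusted variant (per-cell means rate·total_umi, rate and θ fit
jointly) is available by passing per-cell totals, since much of the count
spread simply tracks library size; the default matches the unadjusted
marginal construction.

Per-cell rate regressions (target on total UMIs, least squares through the
origin, per arm) provide an independent residual estimate as the
treated/vehicle slope ratio. The origin is structural: a cell with no UMIs
can have no target UMIs.

## Profile comparison

Weighted Pearson correlations use weighted moments with weights normalized
to sum to the number of observations n; p-values come from the t statistic
with n−2 df — the convention of the R helper the field uses, documented
here as a convention. Weighted SDs default to the same normalization (equal
weights of any size reduce exactly to the sample SD); a `frequency=True`
mode treats weights as repeat counts (equal to the SD of the weight-expanded
sample). The two conventions coincide at unit weights; both are exposed
because each underlies a different invariant one might reasonably want.

"Difference from overall" subtracts the all-cells pooled residual from each
cell type's residual, in percentage points. The pooled overall weights cell
types by their share of *target expression* (vehicle rate × sequencing
depth), so the cell-count-weighted mean of differences is ≈ 0 only when
basal expression is comparable across cell types; with strongly unequal
basal expression the overall is pulled toward high-expressing cell types.

Washout/recovery is residual(t2) − residual(t1) in percentage points,
antisymmetric under timepoint swap. Cross-dataset correlogram weights are
the summed per-cell-type cell counts of the two datasets (min available as
an option). Dose arithmetic is exact closed form
(molecules = N_A · mass / MW), reported at full precision and rounded to one
significant figure.

## Bulk qPCR

ΔCt = mean(target Ct) − mean(housekeeping Ct) after averaging duplicate
wells; ΔΔCt subtracts the arithmetic mean vehicle ΔCt (the standard
convention; the vehicle group then centers at 1.0 on the log2 residual
scale by construction); residual = 2^−ΔΔCt with amplification efficiency
fixed at 2.0. Ct values are validated to (0, 45). Concordance against
aggregated single-cell residuals reports per-axis means with 95% t-based
CIs, the paired mean difference, and Pearson correlation when n ≥ 3.

## Synthetic data generator

The generator emulates the structure the estimators assume: cell types drawn
multinomially with configured proportions; per-cell total UMIs log-normal
(default meanlog = log 7650, sdlog 0.5 — heavy-tailed like droplet data),
rounded and floored at 100 (QC'd droplet data contain no smaller cells);
per-cell target counts NB(basal_upm × total/1e6 × animal factor, θ) with a
shared θ (default 10); treated cells knocked down by either mechanism;
animal-level variability as a multiplicative log-normal(0, sdlog 0.1)
factor on the target rate only (the simplest structure that gives the GLM
real animal-level residuals — per-animal variance components are a modeling
choice, not an estimate from data); 4 animals per arm and 2000 cells per
animal by default. Target counts are capped at the cell's total (binding
with negligible probability at realistic UPM). All randomness flows from
one seeded generator; outputs are byte-identical for a fixed seed.

What it deliberately does not model: full transcriptomes and gene–gene
correlation, ambient RNA, doublets, empty droplets, batch effects, or
per-cell drug-exposure heterogeneity. Passing tests therefore demonstrate
estimator correctness under the stated model — unbiasedness, CI behaviour,
mechanism discrimination — not robustness to QC failures upstream, which
are out of scope.

## Verification sizes and observed behaviour

Parameter recovery uses the reference design (1 cell type, 4 animals/arm,
2000 cells/animal, basal 300 UPM, θ=10, animal sdlog 0.1) at true residuals
25/50/75%. Estimates are unbiased to ~0.3 percentage points. Nominal 95%
Wald CIs cover the truth ~85–87% of the time in this design: with 4 animals
per arm the CI uses ±1.96·SE (a normal quantile, per the estimation
convention) while the animal-level variance is estimated from 8 aggregate
observations, so mild undercoverage is expected — the test suite checks
coverage pooled over 9000 replicates against an 85% floor. Mechanism
discrimination is checked at 100 replicates per generating mechanism
(μ=300, θ=5, r=0.5, 1000 cells/arm) and its power monotonicity across
μ ∈ {1, 30, 300}.

## Known limitations

- The GLM treats aggregate counts per animal as NB draws; it has no explicit
  animal random effect, so animal-level variability is absorbed into θ and
  CIs are mildly anticonservative in small cohorts (see above).
- The mechanism test compares two point hypotheses built from the control
  fit and the observed mean; intermediate mixtures (partial silencing in a
  fraction of cells) are not modelled.
- ΔΔCt assumes perfect doubling per cycle; no amplification-efficiency
  correction is applied.
- The 10x reader handles MatrixMarket triplets (plain or gzipped), not HDF5.
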