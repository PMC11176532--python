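# Methods

## Model and assumptions

mrkit implements two-sample summary-data Mendelian randomization. The
structural model for instrument j is

    β_yj = θ · β_xj + α_j + ε_j ,

where β_xj is the variant's true effect on the exposure, θ the causal
effect of exposure on outcome, α_j a horizontal-pleiotropy term (a path to
the outcome not through the exposure), and ε_j sampling noise with the
outcome GWAS's standard error. The instrumental-variable assumptions are
the usual three: relevance (β_xj ≠ 0, enforced by the p-value and
F-statistic filters), independence from confounders (supported by the
confounder-association exclusion step), and exclusion restriction
(α_j = 0, probed rather than assumed — by Cochran's Q, the Egger
intercept, and MR-PRESSO).

All effects are on the scale the source GWAS reports: log-odds per allele
for binary traits, trait-SD per allele for quantitative traits. Exposure
betas are treated as measured without error when forming ratio SEs
(first-order delta method; the NO-Measurement-Error approximation).
Second-order terms are out of scope.

## Estimators

**IVW (random effects).** Weighted least squares of β_y on β_x through the
origin with weights β_x²/σ_y². The fixed-effect SE (Σw)^(-1/2) is inflated
by √(Q/(k−1)) when Cochran's Q exceeds its k−1 degrees of freedom
(multiplicative random effects, floored at 1 so the CI never narrows below
the fixed-effect CI). P-values are normal. The floor makes the test
slightly conservative — measured null rejection is ≈0.040 at α = 0.05
with k = 50 — which we accept in exchange for never anti-conservative
intervals. A single-instrument set degrades to the Wald ratio, flagged.

**MR-Egger.** The same regression with a free intercept, rows first
oriented so every β_x ≥ 0 (both betas negated together; pleiotropy is
defined on the exposure-increasing allele, so orientation is what makes a
directional mean detectable). Slope and intercept SEs carry the
√(Q/(k−2)) inflation (floored at 1) and use t references with k−2 df. The
intercept p-value is the pleiotropy test that drives the primary-method
rule.

**Weighted median.** Ratio estimates sorted ascending; with normalized
weights w_j the cumulative midpoints p_j = Σ_{i≤j} w_i − w_j/2 define a
step function whose linear interpolation at p = 0.5 is the estimate. SE by
parametric bootstrap: both betas resampled from normal(observed, SE),
1,000 draws by default, seed mandatory. Unpenalized weights.

**MR-PRESSO.** Observed residual sum of squares uses leave-one-out IVW
predictions, weighted 1/σ_y²; its null distribution is simulated by
redrawing outcome betas around those predictions (1,000 simulations by
default). The global p is the simulated exceedance fraction; per-SNP
outlier p-values compare each SNP's observed weighted squared residual
with its own simulated distribution, Bonferroni-adjusted across k, flagged
below 0.05. The corrected estimate is IVW without the flagged SNPs. One
degenerate regime needs care: a sufficiently dominant outlier corrupts
*every* leave-one-out prediction and the single-pass test flags all SNPs,
leaving nothing to correct with. In exactly that case the implementation
peels iteratively — drop the most extreme flagged SNP, re-test the
remainder, stop when the test is quiet — and reports the peeled set as the
outliers. The distortion test compares the corrected-minus-raw
displacement against displacements from removing random subsets of the
same size (two-sided).

**Multivariable IVW.** Weighted regression of β_y on the m exposure-beta
columns without intercept, weights 1/σ_y², SE inflation √(Q/(k−m)) floored
at 1, normal p-values (matching the univariable IVW convention). An
Egger-style intercept diagnostic refits with a constant after orienting
rows to the first exposure. Instruments are the union of each exposure's
own selection, jointly harmonized, complete-case across all tables.

## Instrument processing

Selection keeps rows with p below the trait's threshold (default 5e-8;
a configurable relaxed 5e-6 list). Clumping is greedy by ascending p (ties
broken lexicographically by variant id for determinism): a candidate is
accepted iff no already-accepted same-chromosome variant within 10 Mb has
r² ≥ 0.001 with it. Instrument strength is the squared Wald z, F = (β/SE)²
(per-SNP R² and sample sizes are not required); a trait whose surviving
instruments have mean F ≤ 10 (or none survive) is marked `outcome_only`
and produces no exposure-side estimates.

Harmonization aligns outcome records to the exposure's effect allele:
direct match kept; swapped alleles negate β_y and flip the frequency;
strand complements are resolved first. Palindromic variants (A/T, C/G) are
oriented by allele frequency and dropped as ambiguous when either side's
frequency is missing or inside [0.42, 0.58] (the de-facto standard
window). No proxy-variant substitution. Every exclusion is recorded as
(variant, stage, reason) in an audit trail.

## Pipeline rules

Primary method: IVW, switched to MR-Egger when the intercept p < 0.05
(strict); pairs too small for Egger fall back to IVW with a flag.
Significance labels: `significant` below 0.05/n_tests (default divisor 5,
i.e. 0.01), `nominal` below 0.05, else `null`. Both estimates (raw and
MR-PRESSO-corrected) are reported when outliers are flagged. The matrix
runner analyses every ordered pair in both directions, re-selecting
instruments from each direction's own exposure table, and isolates
per-pair failures. All stochastic components draw per-stage seeds derived
from one root seed by hashing the stage name and trait names, so reruns
are byte-identical. A sample-overlap confirmation column is emitted as NA
placeholder so report shapes match studies that run such a check; the
correction itself (which needs external LD-score data) is out of scope.

In the mediation screen, the four criteria are: (1) the candidate affects
the outcome in univariable MR; (2) its direct effect on the outcome
controlled for the exposure (MVMR) is nonzero; (3) the exposure affects
the candidate but not vice versa; (4) the indirect path's sign matches the
total effect's. Criteria short-circuit in order and every verdict is
audited. The univariable criteria are judged on the IVW p-value rather
than the per-pair pleiotropy-switching rule: a screen across many
candidate pairs needs one uniformly calibrated test, and the intercept
test's inflated type-I error under winner's curse (below) would otherwise
route individual pairs through the underpowered Egger estimate. The
*reported* total effect still follows the primary-method rule. The
mediated proportion a·b/total uses the delta-method SE
√(a²SE_b² + b²SE_a²) for the indirect effect and treats the total as
fixed in the CI; the lower endpoint is floored at 0% for reporting when
the point estimate is positive. Alpha for all criteria is the nominal
0.05.

## Synthetic data

The generator works entirely at the summary level; no individual-level
data is simulated. Per variant, SE(β) = 1/√(2·n·maf(1−maf)) — the
large-sample value for a standardized trait, with n read as effective
sample size for binary traits. True instrument effects are drawn
N(0, σ_x²) and rejection-sampled to pass genome-wide significance at the
exposure sample size; observed betas add sampling noise, so downstream
re-selection on observed p reproduces a mild winner's curse, visible as
the Egger intercept's inflated type-I error on selected instruments.
Defaults: 50 instruments, n = 100,000 per GWAS (large-biobank scale),
maf ∈ (0.05, 0.5), σ_x = 0.05 (acceptance probability well away from the
infeasibility guard).

Pleiotropy α_j ~ N(μ_α, σ_α²) is applied on the exposure-increasing
allele orientation; under InSIDE violation it correlates 0.7 with
instrument strength. Scenario presets plant: a null (θ = 0); an effect
(θ = 0.3); balanced and directional pleiotropy; 40% invalid instruments
with sign-aligned pleiotropy (k = 25, and the invalid subset is redrawn
until the valid instruments hold the >50% weight majority that is the
weighted median's stated validity condition — without this ~18% of
replicates measure breakdown instead of robustness); and a single
10×-ratio outlier measured twice as precisely (variance-wise) as its
peers so it carries real weight. Full-table generation adds, per
instrument, an LD block of satellite tags whose z-scores are attenuated
copies of the index variant's (√r² times a factor < 1, so clumping must
pick the index), null filler variants, ~16% palindromic allele pairs, and
randomized outcome allele orientation (swap/complement/both) so
harmonization is genuinely exercised. The mediation scenario plants
exposure → mediator → outcome effects (a, b) plus a direct effect, with
outcome effects (direct + a·b)·β_x at exposure instruments and b·β_m at
mediator instruments, so total = direct + a·b exactly; decoys with a = 0
and with a reverse mediator→exposure path (kept weak per-SNP so it never
enters the exposure's instrument set, but detectable by the aggregated
reverse UVMR) exercise the screen.

What the generator does **not** emulate: realistic human LD maps and
allele-frequency spectra, polygenicity beyond the planted instruments,
population stratification, sample overlap between the two GWAS, and
binary-trait liability-scale subtleties. Passing tests therefore
demonstrate the estimators' statistical behaviour under the stated
generative model, not performance guarantees on any particular real GWAS
pair.

## Numerical choices

Generated p-values are floored at 1e-300; input p-values of exactly 0 are
clamped to the smallest positive float with a warning. Clumping ties break
lexicographically. MR-PRESSO global p is the plain exceedance fraction
(granularity 1/n_sim). Results TSVs print 6 significant digits;
odds-ratio columns are filled only for binary outcomes. Collinear MVMR
designs raise an error naming the exposures. Simulation sizes in the test
suite (10,000 null replicates; 500 recovery and robustness replicates; 200
outlier replicates; 100 mediation replicates; bootstrap 200–1,000; PRESSO
200–500 simulations) were chosen so each check's Monte-Carlo error is
small against the property it asserts.

## Known limitations

Sample-overlap correction, proxy-variant lookup, liability-scale
conversion, penalized/mode-based estimators and plot rendering are not
implemented. The F-statistic is the single-SNP squared z, not the
multi-SNP conditional F used in some MVMR work. The mediated-proportion
CI ignores uncertainty in the total effect (a deliberate reporting
convention; with a strongly estimated total the difference is small). The
Egger intercept test's type-I error is inflated on instruments selected
with winner's curse — inherent to applying it after selection, and the
reason the mediator screen pins its criteria to IVW.
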