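# Methods

## Analysis model

For a quantitative phenotype y (heel broadband ultrasound attenuation, BUA,
in dB/MHz) and a pair of biallelic SNPs with minor-allele dosages d₁, d₂ ∈
{0, 1, 2}, the scan fits, per pair and on that pair's complete cases,

y = β₀ + β_sex·sex + β_age·age + β_bmi·BMI + β_pa·PA + β_ca·Ca
  + β₁·only1 + β₂·only2 + β_obs·both + ε,   ε ~ N(0, σ²) i.i.d.

Carrier coding (default): only1 = 1{d₁≥1, d₂=0}, only2 = 1{d₁=0, d₂≥1},
both = 1{d₁≥1, d₂≥1}; the reference class carries neither minor allele.
The interaction statistic is the departure from additivity,
β_int = β_obs − β₁ − β₂, estimated as the contrast c′β̂ with
c = (0,…,0, −1, −1, +1). Because the three indicators are a full
parameterisation of the non-reference carriage cells, c′β̂ equals the
coefficient of a carrier₁×carrier₂ product term in the reparameterised model;
the test suite verifies the identity to 1e-8. Under additive coding the
genotype terms are d₁, d₂ and d₁·d₂ and β_int is the product-term
coefficient. Reported results always name the coding: carrier-scale and
additive-scale interactions are different estimands and are not comparable.

Inference: Wald t-test of c′β = 0 with covariance s²(XᵀX)⁻¹ (homoskedastic
errors assumed; fitting is delegated to statsmodels OLS), 95% CI =
β_int ± t₀.₉₇₅(df_resid)·se. t rather than normal quantiles: at n ≈ 575 with
9 fitted terms the difference is small but the t interval is exact under the
model. Family-wise error over all k(k−1)/2 pairs is controlled by Bonferroni;
the per-test threshold divides α by the number of *enumerated* pairs (the
field's convention, e.g. 0.05/435), with the count of estimable pairs
reported alongside.

Estimability rules: a pair is flagged non-estimable — carried in the output
with a recorded reason, never raised — if any carriage cell is empty (the
contrast would extrapolate), the design is rank-deficient (collinear columns
are named via QR with column pivoting), or complete cases number fewer than
the coefficient count plus two. p-values are floored at the smallest positive
float so a reported p is never exactly 0. Ties in the p-ranked output are
broken by |β_int| descending, then by rsID pair, making the table ordering
deterministic.

## Quality control

- MAF: folded coded-allele frequency, min(f, 1−f), missing calls excluded
  from numerator and denominator; a marker passes at MAF ≥ 0.01 (the boundary
  passes).
- Missingness: fails above 0.05 (the boundary passes).
- HWE: Pearson goodness-of-fit χ² on the three genotype classes against
  expectations n·p̂², 2n·p̂q̂, n·q̂² at the observed allele frequency, upper
  tail of χ²₁, no continuity correction and no exact test. Monomorphic
  markers report (χ²=0, p=1) with a flag instead of dividing by zero. HWE is
  report-only by default — candidate panels are typically pre-vetted — with
  an optional exclusion α for reuse.

## LD pruning

Pairwise LD is the composite estimate for unphased data: the squared Pearson
correlation of the two dosage columns over pairwise-complete samples. It
requires no haplotype phase or EM and is deterministic; it can differ
slightly from haplotype-based r². Markers are pruned greedily in panel order:
a marker is excluded at the first already-kept marker with r² above the
threshold (default 0.90), so the earlier-listed marker always represents a
redundant group and the kept set never contains a pair above threshold
(pruning is idempotent). Which member of a redundant pair survives is this
package's convention; published analyses rarely state theirs. Non-estimable
pairs (constant column, < 3 complete pairs) are warned about and treated as
unlinked. Cross-chromosome pairs are checked too — at panel scale it is
cheap, and high cross-chromosome r² signals a data artifact.

## Synthetic cohorts

The generator emulates the data structure of a young-adult candidate-gene
bone study. Defaults: n = 575 with 400/575 female; age 20.41 ± 2.36 y; BMI
22 ± 3 kg/m²; physical activity 2500 ± 1500 (IPAQ-style MET·min/week);
calcium 900 ± 300 mg/day (BMI/activity/calcium moments are plausible
young-adult values — they are adjustment variables, not estimation targets);
the packaged 32-marker panel at its published MAFs; two built-in LD pairs
(rs2707466–rs2908004 and rs7988338–rs2148073 at target r² 0.95) mirroring
the panel's known redundancies; genotype missingness 1%; intercept 35 dB/MHz
with covariate slopes (−6 female, +0.9/y, +1.1 per kg/m², +0.0015 per
MET·min/week, +0.004 per mg/day) and residual SD 16 dB/MHz, giving mean BUA
near 80 dB/MHz; no genetic effects unless planted.

Genotypes: independent markers are the sum of two Bernoulli(MAF) allele
draws, so HWE holds by construction. LD pairs use a Gaussian copula per
allele copy: each of an individual's two copies draws a latent bivariate
normal (ρ) thresholded at Φ⁻¹(MAF) for each locus; marginal HWE is preserved
and the genotype correlation equals the allele-indicator correlation, which
is computed analytically from the bivariate normal CDF and calibrated to
√(target r²) by bisection (realised r² within about ±0.03 at n ≥ 5,000).
Unequal MAFs cap the attainable correlation at
r_max = (min(p₁,p₂) − p₁p₂)/√(p₁q₁p₂q₂); a target exceeding r_max² by more
than the 0.03 calibration slack raises an error reporting the attainable
maximum, while a target within the slack is clamped to the boundary — the
built-in rs7988338–rs2148073 pair (MAFs 0.19/0.18, cap ≈ 0.936) relies on
this and still prunes comfortably at r² > 0.90.

Covariates are independent truncated normals (age > 0, BMI > 10, activity
and calcium ≥ 0); sex is Bernoulli. The phenotype is generated by exactly
the analysis model — linear in covariates, planted main effects and planted
pairwise interactions on their stated coding scale, plus Gaussian noise.
This circularity is deliberate: it makes parameter-recovery, type-I-error
and CI-coverage experiments well-posed. It also bounds what passing tests
show about real data, which can feature non-Gaussian phenotypes,
covariate–genotype correlation, population structure, haplotype-block LD and
informative missingness, none of which the generator produces. The phenotype
is computed from the complete genotypes before missingness is applied, so
planted effects are exact. One root seed spawns independent substreams for
genotypes, missingness, covariates and phenotype noise; identical configs
give byte-identical outputs, and changing phenotype parameters leaves the
genotype draw untouched.

## Pipeline

`run_pipeline` fixes the stage order QC → prune → scan, with every threshold
in one config (YAML or in code) and all randomness from one seed; each stage
is also callable alone. Outputs: QC report, two-section pruning report,
p-ranked scan table (publication rendering to 3 decimals plus full-precision
columns), human-readable summary and a config echo. Missing covariate or
phenotype values drop the sample at alignment (complete-case); per-pair
genotype missingness only shrinks that pair's n, which is reported per row.
Minor-allele orientation comes from the panel table, never from observed
frequency; a column whose coded-allele frequency exceeds 0.5 is surfaced by
the folded MAF in QC rather than silently flipped.

## Verification problem sizes

Stochastic guarantees are exercised at these scales (chosen to give tight
Monte-Carlo error at interactive runtimes): type-I error of the interaction
test over 1,000 replicates of a null two-marker cohort with active main and
covariate effects at n = 575 (empirical α within [0.035, 0.065]); 95% CI
coverage of a planted 8 dB/MHz interaction over 1,000 replicates at
n = 2,000 (within [0.93, 0.97]); bias of the same estimand over 200
replicates (mean within ±0.5); and rank-first power for a planted 15 dB/MHz
pair in a 10-marker, 45-pair scan over 20 replicates. LD calibration and
pruning checks use n = 5,000–10,000.

## Known limitations

Two-locus interactions only; no permutation-based family-wise control; no
relatedness or population-structure adjustment (fixed-effects OLS assumes
unrelated individuals); homoskedastic inference by default; composite r²
rather than haplotype r²; the carrier dichotomy discards the 1-vs-2 dosage
distinction, trading power under truly additive interaction for a
well-defined cell contrast.
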