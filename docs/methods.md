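# Methods

## Study design and canonical scales

The design crosses two inbred mouse strains, B6 (C57BL/6J) and D2 (DBA/2J),
with both reciprocal F1 hybrids (B6D2F1 = B6 mother, D2B6F1 = D2 mother).
The default `StrainDesign` is 4 genotypes × 2 sexes × 1 animal = 8 samples,
one TMT channel each — the layout of an 11-plex run with two biological
replicates per genotype. Protein abundance matrices are on the log₂ scale
throughout; PSM tables are linear (reporter-intensity-like). All tables move
between stages as TSV with `%.10g` float formatting, which is what makes
fixed-seed runs byte-identical.

## TMT quantification

Order is enforced: impurity correction → intensity filter → loading
normalization → protein roll-up.

* **Isotope impurity.** The impurity matrix M (entry i,j = fraction of
  channel j's signal observed in channel i) is inverted exactly per PSM;
  negative solutions are clipped to 0 and flagged rather than failing, the
  standard practice for impurity deconvolution. A singular matrix is a hard
  error. Missing reporter values are treated as zero during the solve and
  restored as missing afterwards.
* **Filter.** A PSM is removed iff its cross-channel minimum < 1000 or its
  median < 5000 (both configurable); PSMs missing in more than half the
  channels are dropped. Missing values are excluded from medians and means,
  never imputed.
* **Loading normalization.** Channels are scaled so trimmed medians of log₂
  intensity agree; the trim fraction (default 0.1 per tail) is configurable.
  The operation is on the log₂ scale (the raw-vs-log choice is not forced by
  the procedure's definition; log₂ is chosen and documented here). Note that
  with symmetric trimming the trimmed median equals the plain median unless
  missingness is asymmetric; the trim mainly guards channels with partially
  missing extremes. Normalization assumes equal-loading ("most proteins
  unchanged"): on a finite simulated proteome the channel medians carry some
  real biological signal, so profile recovery after normalization is
  approximate, while the roll-up itself is exact (see tests).
* **Roll-up.** Protein relative profile = mean of its PSMs' mean-centered
  log₂ profiles (row means are 0 by construction); absolute scalar = grand
  mean of the three most intense PSMs by summed cross-channel intensity,
  ties broken by PSM id so output is deterministic.

## Differential expression

The moderated t-test shrinks per-feature pooled variances (d = nₐ + n_b − 2
degrees of freedom) toward a prior estimated by moment-matching a
scaled-inverse-χ² model on log sample variances: with
e = log s² − ψ(d/2) + log(d/2), solve ψ′(d₀/2) = Var(e) − ψ′(d/2) and
s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)); the moderated t uses s²_post with
d₀ + d degrees of freedom. The implementation agrees with Bioconductor
limma's eBayes to machine precision on heteroscedastic fixtures (tested via
Rscript). Zero-variance features receive the prior variance s₀² instead of
being dropped. The pooled-variance (equal-variance) two-group model is used —
with n = 2 per genotype a group-specific variance is not estimable anyway.
BH adjustment is delegated to statsmodels and checked against the literal
step-up definition.

Thresholds: DEPs at adjusted p < 0.05 and |log₂FC| > 1.5 (the 4-fold/1 % and
2-fold/5 % figure presets are available via the same function arguments);
the reciprocal-hybrid screen uses raw p < 0.01 and |log₂FC| > 0.3 — the
fold-change threshold is read on the log₂ scale, since a raw fold change of
0.3 would itself be a ~1.7-fold decrease and could not describe both up- and
down-regulated candidates. The CV screen works on back-transformed linear
abundances (CV is scale-invariant, so the relative-abundance matrix
suffices); high variation is CV > mean + 2·SD. Single-parent expression
z-scores each parental strain's mean log₂ abundance across proteins and
requires one strain above its 25th-percentile cutoff with the other below
its 5th-percentile cutoff; the per-strain-across-proteins z construction is
one of two possible readings of "z-score transformed relative expression"
and is the one implemented.

## Inheritance

D/A divides the dominance deviation (mean of the two F1 genotype means minus
mid-parent) by the additivity (high parent minus mid-parent, always > 0 when
the parents differ); equal parents are flagged undefined and excluded from
the D/A distribution. The class boundaries (|D/A| ≤ 0.25 additive, ≤ 1.25
dominant, else over/under-dominant) are an artifact convention for
summarizing the distribution, not an empirical claim.

The mixed model is y = μ + A + D + S + ε with A ~ N(0, σ²ₐR₁),
D ~ N(0, σ²_dR₂), ε ~ N(0, σ²_eI) and sex S fixed. The strain-level R₁/R₂
are pedigree expectations (R₁: parents mutually 0, parent–F1 0.5, F1–F1 0.5;
R₂: all off-diagonal 0 except F1–F1 0.25); sample-level expansion sets
same-genotype animal pairs to 1 in both matrices because inbred and F1
animals of a genotype are isogenic. That expansion is rank-deficient with
replicate animals, so a ridge of 1e-8 is added to the covariance diagonal
before factorization.

REML maximizes the restricted likelihood over log variances by Nelder–Mead
from three fixed starting points (balanced, genetic-heavy, residual-heavy),
convergence tolerance 1e-8 on the restricted log-likelihood; the response is
divided by its standard deviation internally and components rescaled by
var(y), which makes the estimator exactly scale-equivariant. Components
pinned at the numerical floor are reported as 0 with a boundary flag;
non-convergence is flagged and the best point reported.

Although sex enters as a fixed effect, V_s appears in the H² denominator;
V_s is therefore defined as the variance across samples of the fitted sex
term (β̂²/4 with balanced sexes and 0/1 coding) — the only reading that makes
the printed H² computable from the fixed-effect model. A flag-switchable
variant treats sex as a fourth random component (same-sex relatedness 1) and
uses its estimated variance instead; no claim is made about which variant
matches any particular external table. H² = (Vₐ + V_d)/(Vₐ + V_d + V_s +
V_e), with 0/0 flagged degenerate and reported as 0.

## Proteogenomics and protein ASE

The B allele is the reference (GRCm38/UniProt) sequence; the D allele
carries the missense substitutions — matching the use of D2 variants called
against the mouse reference. Digestion cleaves after K/R, suppressed before
proline, ≤ 2 missed cleavages; peptide length bounds default to 6–50
residues (the MS-observable range; only the missed-cleavage limit is forced
by the upstream search convention). All variants of a protein are
substituted together, so peptides spanning several variants form
multi-variant pairs. A substitution that creates or destroys a cleavage site
leaves the alternate peptide without a same-span reference counterpart; such
peptides are emitted as singletons with reason `site_change`. I/L-only pairs
are mass-identical and flagged MS-indistinguishable rather than dropped.
Modification strings in identified-peptide input are stripped by a fixed
pattern (bracketed/parenthesized annotations and non-uppercase characters)
before matching.

Allelic ratios are r_P = mean log₂(B-allele in B6) − mean log₂(D-allele in
D2) and r_F1 = mean over F1 samples of log₂(B) − log₂(D) within the sample.
The five-way classifier partitions the (r_P, r_F1) plane with τ = 1 log₂
unit on both axes (the one printed threshold): both super-threshold with the
same sign → cis; parental only → trans; F1 only → compensatory; neither →
conserved; opposite signs → unexpected bias. "F1 ratio similar to parental"
is operationalized as same-sign super-threshold rather than a |r_F1 − r_P|
band because the published scatter partitions the plane, not the diagonal; a
band-mode variant is available by flag. Significance gating (require the
moderated between-allele test to be significant before calling a change) is
available but off by default, since the classification is defined on ratios.
Ionization-efficiency differences between allele peptides are not corrected:
absolute B/D signals are never compared, only ratios across genotypes, where
the per-peptide efficiency cancels.

## Transcript ASE and cross-level comparison

Allele counts are pooled (summed) across hybrid samples and tested with an
exact two-sided binomial test against p₀ = 0.5 using the minimum-likelihood
convention (sum of all outcome probabilities ≤ the observed one), BH across
genes; genes under 10 pooled reads are skipped (a documented default — no
depth filter is forced by the test itself). Mapping-bias correction is
upstream of this artifact and enters only through the counts. Transcript
ratios reuse the protein-level classifier verbatim (single implementation);
r_F1 uses a 0.5 pseudocount per allele, which changes r_F1 by < 0.05 at
totals ≥ 100. The protein/transcript comparison builds a 2×2 ASE/non-ASE
table over shared genes and applies a two-sided Fisher exact test, plus a
5×5 category crosstab.

## Synthetic-data generator

`simulate_proteome` draws per-protein additive effects a ~ N(0, σ²ₐ),
dominance d ~ N(0, σ²_d), and sex effects, and sets genotype means
μ + a·g + d·h with additive code g = (−1, +1, 0, 0) for (B6, D2, F1, F1) and
heterozygosity h = (0, 0, 1, 1); samples add N(0, σ²_e) residual noise on
the log₂ scale. Defaults (σₐ = 1, σ_d = 0.5, σ_sex = 0.2, σ_e = 0.5, 30 %
null proteins) put genetic effects at or above the residual scale, as
expected for a deep TMT experiment on divergent inbred strains; the real
experiment's residual magnitude is not published, so these are stated
emulation conditions, not claims about the deposited data. PSM intensities
are linear lognormal draws around 2^y with per-PSM ionization efficiency,
channel loading biases, configurable reporter CV (default 0.1), and an
isotope-impurity mix (defaults 3 % into ±1, 0.5 % into ±2 channels).

Note the generator's additive code places the F1 mean at mid-parent (the
additive-inheritance expectation), whereas the R₁ expansion models F1
additive values as full-variance draws correlated 0.5 with each parent; the
REML fit of one protein therefore recovers the generating variances only in
distribution across proteins, and small-sample H² estimates at n = 8 are
noisy and bounded, so the distribution-level recovery checks use medians and
generous (documented) tolerances.

`simulate_variant_peptides` plants pairs under the five categories (parental
and F1 ratio = ±effect per the category pattern), with the B-allele peptide
missing in D2 samples and vice versa, mirroring detection only in carrier
strains; a configurable per-cell log₂ noise (default 0.25) is roughly the
replicate spread of well-quantified peptides. Category counts follow the
requested mix exactly (largest-remainder allocation). `simulate_allele_counts`
draws per-sample totals Poisson(depth) and B-allele counts
Binomial(n, 2^r/(1 + 2^r)). `simulate_reference_fasta` emits a small random
proteome with realistic K/R density plus a missense table so the enumeration
stage can run end to end. What passing tests show: the pipeline recovers the
structure it assumes (planted effects, categories, calibrated nulls). What
they cannot show: robustness to real-data pathologies the generator omits —
co-eluting interference beyond the impurity model, shared peptides,
non-lognormal noise, alignment mapping bias, batch structure.

## Problem sizes and numerics

Test problem sizes (2000 proteins for variance-component recovery and null
calibration, 500 variant pairs, depth-100 counts for 2000 genes, a
250-protein end-to-end demo) are chosen so the whole suite runs in minutes
on one core while Monte-Carlo error stays well inside the asserted
tolerances. Ties, degenerate inputs and boundaries are handled explicitly:
zero-variance proteins (degenerate H², D/A undefined), empty PSM tables
(warn), all-missing channels (error naming the channel), singular impurity
matrices (error), NaN p-values (error listing indices).
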