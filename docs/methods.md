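# Methods notes

This note records the models implemented, the defaults and why they were
chosen, and the places where a genuine design choice had to be made.

## Synthetic study generator (`simdata`)

The generator emulates the *product* of a reduced-representation (GBS-like)
SNP study of river salmon populations, not the sequencing process itself.

**Drift down a tree.** Ancestral allele frequencies are drawn on
[maf_floor, 1 − maf_floor] and evolve down a rooted tree under
Balding–Nichols sampling: child ~ Beta(p(1−F)/F, (1−p)(1−F)/F) per branch
with drift parameter F ∈ (0,1). Expected differentiation accumulates
approximately additively along paths for small F, so a tree with branch
kilometres proportional to branch F encodes a true isolation-by-distance
relation that the inference side can recover. The default eight-population
tree has two river complexes, a nearly panmictic sister pair (F = 0.002 per
branch), one strongly drifted in-complex population, and one old isolate;
realized pairwise θ spans roughly 0.002–0.15.

**Ancestral frequency spectrum.** The default spectrum is a symmetric
Beta(0.2, 0.2) truncated to [0.01, 0.99] by inverse-CDF sampling. A uniform
spectrum (`ancestral_beta=None`) puts mean expected heterozygosity at
≈ 0.35, which is unlike any SNP panel that passed minor-allele-count
filters and would make every simulated fish fail the fixed Ho > 0.3 QC
cutoff; the truncated-Beta default gives mean He ≈ 0.24 ancestrally and
≈ 0.20 at the leaves, in line with river-scale salmonid panels, and
produces a realistic excess of low-MAF loci for the MAC filters to act on.

**Life-history tactic signal.** The tactic signal lives in
`tactic_regions` (default 2) linked blocks, mimicking association signals
concentrated in chromosomal regions (e.g. on a chromosome fusion). Each
region has a latent diallelic haplotype state with base frequency
p_state ~ U(0.35, 0.65); estuarine and marine fish draw their two copies at
state frequencies shifted so that the marginal per-locus allele-frequency
difference between tactic groups equals δ (default 0.25 at 20 loci).
Planted loci tag the latent state with per-copy error ε = 0.1, giving
within-block correlation r ≈ (1−2ε)² ≈ 0.64. The block structure matters:
20 *independent* loci shifted by δ = 0.25 in a 3000-locus, 270-sample panel
sit exactly at the spiked-covariance detection edge (spike strength
π(1−π)Σd² ≈ √(L/n)), so no PCA-based scan can recover them reliably, while
correlated blocks form a clear principal component — which is also how such
signals present in real data. Tactic loci are shared across populations
(no river structure), matching the "tactics differ, rivers don't" pattern
the scan is meant to isolate.

**Artifacts.** Per-genotype depth is NegBin(mean 20, dispersion 5);
genotypes under 3 reads become missing (≈ 0.5% missingness). Heterozygote
allele balance is Beta(20, 20). Collapsed paralogs are simulated by
read-wise merging two loci (the merged genotype is re-called from the
pooled reads at 0.2/0.8 allele-fraction cutoffs), drawn from loci with
MAF ≥ 0.15 — a merge of two near-monomorphic loci is both unrealistic as a
detectable artifact and invisible to HDplot. Kin pairs are planted as
duplicates with a 2% genotype redraw; at 2% the Yang statistic of planted
pairs stays near 1 (above the 0.9 removal threshold), whereas larger
redraw fractions interact with the low-MAF spectrum (rare-allele loci carry
most of the statistic's weight) and push pairs under the threshold.

**What the generator does not emulate.** Read-level errors, mapping and
locus-assembly artifacts beyond the paralog merge, linkage within
chromosomes outside the tactic blocks, temporal drift between the two
mixture years, environmental covariates, and pedigree structure beyond the
planted twins. Passing tests therefore demonstrate the *inference chain* is
correct under the stated genetic model, not that it is robust to every
real-data pathology.

## QC cascade (`genio`)

Order: genotype depth ≥ 3 → locus pass 1 (group missingness ≤ 40%, rare
allele in ≥ 3 carriers) → sample missingness ≤ 5% (strict) → locus pass 2
(≤ 50%, ≥ 5) → relatedness (Yang A_jk ≥ 0.9 drops the missing-heavier
member; ties break on sample id) → heterozygosity (Ho > 0.3 strict) →
locus pass 2 again → HDplot (drop H > 0.6 or |D| > 7) → LD pruning
(r² > 0.5 within ≤ 100 kb, first-SNP-kept forward scan). Notes:

- "Rare allele in ≥ k samples" counts **carrier samples** (het or
  homozygote for the globally rarer allele), boundary inclusive.
- The depth filter sets genotypes missing rather than dropping loci, so the
  downstream missingness filters see its effect.
- Missing data are handled pairwise-complete in r² and A_jk; no imputation
  happens inside QC.
- HDplot D is summed over heterozygous calls only and defined as 0 for loci
  without heterozygotes. The H/|D| thresholds are configuration with the
  defaults above.
- The identity-by-missingness check is a PCA of the missingness indicator
  plus a 2-means silhouette; > 0.5 flags batch-structured missingness.

## Structure statistics (`structure`)

- **WC-84 θ**: two-allele variance components per locus; multilocus value
  is the ratio of sums; loci monomorphic across the compared groups, or
  with fewer than two populations called, are excluded. The estimator is
  invariant to locus order and ref/alt swaps (tested).
- **Bootstrap**: resamples loci (matching common F_ST bootstrap practice);
  CI is the 2.5–97.5 percentile interval, clamped to contain the point
  estimate; the default p-value is the one-sided fraction of replicates
  ≤ 0, with a two-sided option.
- **PCA**: per-locus mean imputation of missing dosages, centering, unit
  variance scaling, SVD; zero-variance loci dropped.
- **IBD**: response θ/(1−θ) per pair; models are OLS linear-in-distance,
  the literal zero-mean null, and an intercept-only reference; AICc =
  n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1) with k counting coefficients plus the
  residual variance (3 / 1 / 2). A θ = 1 pair makes the response infinite
  and is rejected with a message.
- **AMOVA**: squared-Euclidean distances on mean-imputed dosage vectors;
  sums of squares via the centroid identity (verified against the pairwise
  distance form); unbalanced-design coefficients n', n'', n''' for the
  variance components; secondary strata are nested as (primary, secondary)
  pairs. Permutations: whole secondary units across primary groups for the
  among-primary test, samples across secondary units within each primary
  for the among-secondary test. With few secondary units the among-primary
  permutation space is small and its p-value is conservatively bounded away
  from zero — a property of the scheme, not a bug.
- **Directional migration**: per pair, a hypothetical migrant pool with
  per-allele *normalized geometric-mean* frequencies; multilocus Nei G_ST
  (ratio of sums) from pool to each member; raw flow out of a population is
  ((1/g) − 1)/4 (capped when g ≤ 0); the matrix is normalized by its
  maximum. The geometric-mean pool is essential: with an arithmetic
  (equal-weight) pool both members are equidistant from the pool in
  frequency and the *recipient* of gene flow — whose drift is partially
  undone by admixture, raising its diversity — systematically ends up
  closer, inverting the origin rule. Under the geometric pool the source is
  closer in 20/20 simulated directional scenarios.

## Diversity and Ne (`divstats`)

Ho_i is the heterozygous fraction of a sample's called loci; He_i averages
2p(1−p) over the same loci with p from the sample's own group (itself
included — the simplest convention; alternatives differ by O(1/n));
F_i = 1 − Ho_i/He_i. Groups of size one get NaN He with a warning.

LD-Ne: in-group MAF > 0.05 (strict); Burrows composite Δ with the S/(S−1)
correction, r̂² = Δ²/(p_x q_x p_y q_y), pairs restricted to different
chromosomes; unweighted mean over pairs; E[r²_S] evaluated at each pair's
own S; harmonic-mean S reported. Ne from the random-mating quadratic
inversion; r²_drift ≤ 0 reports +∞ with a warning — the correct outcome
when loci are truly independent (only sampling LD present). The CI is a
delete-one-chromosome jackknife on r²_drift mapped through the Ne
transform; a parametric χ²-style CI is not reproduced (its
effective-independence heuristic is tool-specific), so CIs here are wider
than tool-reported ones. All-pairs r̂² is quadratic in loci; `max_loci`
randomly thins loci without biasing the mean r².

## Outlier scan (`outliers`)

K is chosen by an automated scree elbow (largest second difference of
eigenvalues), with the scree table returned for manual override. The scan
regresses standardized dosages on an orthonormalized basis of the first K
score vectors; per-locus z-vectors are summarized by Mahalanobis distance
under the **standard** covariance estimate with genomic-inflation-factor
rescaling (λ = median D² / median χ²_K), rather than a robust covariance:
at 10³–10⁴ loci with a correct K the two agree closely, and the standard
estimate is deterministic. Null calibration (no planted signal) gives
λ ∈ [0.95, 1.01] and ≈ 0 flags at q < 0.01 in simulation. Storey q-values
use the λ-grid 0.05…0.90 with cubic extrapolation to λ = 1 for π₀ and the
usual step-down minimum.

## Genetic stock identification (`gsi`)

- **Panels**: per-pair AFD rankings consumed greedily by the pair with the
  smallest running Σ AFD², so pair sums stay balanced within one appended
  AFD²; the stopping rule counts the *deduplicated union* against the
  target; a locus already in the union still accrues to other pairs' lists.
  All ties break deterministically (pair name, then locus order). Weakly
  differentiated pairs end up with longer lists, which is the point of the
  balancing.
- **Self-assignment classifier**: per-population HWE genotype
  log-likelihood with +0.5 per-allele count smoothing — deterministic, no
  tuning, standard in GSI software. Stratified train/test splits, optional
  random locus subsets, accuracy and confusion accumulated per iteration.
- **Panel size choice**: lexicographic — maximize the minimum
  per-population mean accuracy, then minimize the mean across-iteration SD,
  then prefer the smaller panel.
- **Mixture model**: priors π ~ Dirichlet(1), reference frequencies
  Dirichlet(1/2) posterior means; 2000 sweeps with 100 burn-in by default
  (the chain mixes in tens of sweeps at study scale; these defaults are
  conservative). Individuals with no called panel genotypes keep a flat
  likelihood and are flagged.
- **Odds rule**: keep iff top posterior ≥ 10 × second largest, inclusive at
  exactly 10×. Note (0.91, 0.09) is kept (ratio 10.1) and (0.9, 0.1) is
  dropped (ratio 9); the true two-population boundary case is
  (10/11, 1/11).
- **χ² homogeneity** tests use no continuity correction; expected counts in
  study-scale tables are far above 5.

## Problem sizes

The test suite and the acceptance script run the study at reduced scale —
1500–3000 loci on 6–12 chromosomes, bootstraps and permutations of 50–200,
10–20 seeds per Monte-Carlo check — chosen so the whole suite completes in
about a minute while every statistic is estimated far above its noise
floor. Parameter-recovery margins (mixture proportions within 0.05,
LD-Ne within a factor two, outlier FDR ≤ 0.05) were set from the
statistics' known sampling behavior at those sizes, and the full-scale
defaults (5000 loci, 29 chromosomes, 1000 bootstraps, 2000 sweeps) remain
the package defaults.

## Known limitations

- The HDplot variant uses fixed default thresholds (H > 0.6, |D| > 7); the
  exact "modified" criteria of the upstream tooling are unpublished.
- LD pruning treats "within 100 kb" as distance ≤ 100,000 bp inclusive;
  loci exactly 100,001 bp apart are not compared (boundary tested).
- The AMOVA among-primary permutation is conservative with few secondary
  units (see above).
- The Ne CI type differs from NeEstimator's parametric interval; point
  estimates agree in recovery simulations but CIs are not comparable.
- The mixture model is the unconditional one-level sampler; reporting-unit
  aggregation and parametric-bootstrap bias correction are out of scope.
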