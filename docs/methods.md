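# Methods

This note documents the models, numerical choices and limitations behind
`quinoaphs`. It is the design record; the README covers usage.

## Problem setting

Preharvest sprouting (PHS) — seeds germinating on the mother plant under
rain or humidity before harvest — is scored in quinoa by misting intact
panicles and recording visible sprouting daily for 7 days on an ordinal
scale. A diversity panel is screened on two planting dates (PD1, PD2) in
batches, each batch carrying tolerant and susceptible control genotypes.
The package turns those raw scores into quantitative tolerance phenotypes,
ranks genotypes, and runs a structure-adjusted genome scan that integrates
both planting dates in a single design.

## Scoring scale

Six ordinal levels {0, 1, 3, 5, 7, 9} stand for percent-sprouted bands:
0 ↔ {0}, 1 ↔ (0, 20), 3 ↔ [20, 40), 5 ↔ [40, 60), 7 ↔ [60, 80),
9 ↔ [80, 100]. The printed field scale uses integer ranges (1–19, 20–39,
…); we take intervals half-open at the upper bound so any *real*
percentage (e.g. a count ratio from an image) maps to exactly one level.
Two boundary decisions: exact 0% is the only percentage mapping to level 0
(any positive sprouting means radicle emergence, level ≥ 1), and 80% maps
to level 9. Missing observations are absent rows, never zeros.

## Temporal phenotypes

From a genotype's 7-day mean-score trajectory S₁..S₇ (replicates averaged
per day; missing panicles ignored; a day with no observation is missing,
optionally filled by linear interpolation between adjacent observed days):

* **Sprouting index** SI = Σᵢ (8−i)·Sᵢ / (7·n_max) with n_max = 9 the
  maximum scale level, so SI ∈ [0, 4]. Early sprouting is up-weighted
  (day 1 carries weight 7, day 7 weight 1). n_max is the *maximum possible
  score*, not the number of days.
* **Slope**: OLS slope (intercept included) through the 8 points
  (0, 0), (1, S₁), …, (7, S₇). The anchored day-0 zero encodes "no
  sprouting before misting starts"; it deliberately makes the slope
  sensitive to overall level, not just to within-window trend.
* **Sigmoid parameters**: nonlinear least squares of the logistic
  y(t) = a / (1 + exp(−b·(t − c))) — a the upper asymptote (score units),
  b the growth rate (day⁻¹), c the day of maximum growth. The logistic is
  the form consistent with all three parameter meanings; a Gompertz
  alternative (a·exp(−exp(−b(t−c)))) sits behind `form="gompertz"`.

Sigmoid fitting uses `scipy.optimize.least_squares` (trf) with bounds
a ∈ [0, 9.5], b ∈ (0, 10], c ∈ [−2, 14] and initialisation a₀ = max(S),
b₀ = 1, c₀ = first day S crosses a₀/2 (3.5 if never). Zero-variance
trajectories are degenerate: `converged=False`, a carries the last-day
mean, b and c are NaN; such genotypes are kept for scans on a but dropped
from scans on b and c. b is weakly identified from 7 daily points and is
reported but not used as a headline recovery metric.

Rankings are ascending (rank 1 = most tolerant) by slope or SI; ties break
on the other metric, then on genotype id, so ranks are always a
permutation of 1..N. No tolerant/susceptible threshold is imposed: PHS is
treated as a continuous spectrum.

## Genotype QC and structure covariates

Markers are biallelic SNPs coded 0/1/2 (non-reference allele count), read
from HapMap or VCF; multiallelic records are dropped with a logged count,
and marker ids are regenerated as `Cq{chrom}_{pos}` (1-based) so naming is
uniform across formats. Filters: missing rate ≤ 20% and MAF ≥ 5%, with
MAF computed on non-missing calls *before* imputation. Imputation is
modal ("major allele", ties to the lower code) by default because the
downstream hom/het recode needs the integer alphabet; mean-dosage
imputation exists for comparison runs only and is rejected by the recode.

Structure covariates are the first three PCs of the column-centred dosage
matrix plus a binary indicator = 1 where PC1 ≥ 0 (a hard two-cluster
assignment). Explained-variance percentages are 100·λᵢ/Σλ over all
components. PC signs are fixed by making the largest-|loading| entry of
each component positive, which makes the indicator reproducible across
runs and libraries. A constant indicator (single-cluster data) is logged
and dropped from the design as collinear with the intercept.

## The additive–additive (AA) design and scan

Genotypes are recoded hom → 1, het → 0 (collapsing the two homozygote
classes), and the PD1 and PD2 recoded matrices are placed block-diagonally
with exact zero off-blocks, so each marker contributes two pseudo-marker
columns, one per planting date. Phenotypes are stacked; fixed covariates
are [intercept, PC1..PC3, indicator, planting-date column]. Accessions
present in both planting dates contribute two rows that the model treats
as independent — a simplification (their residuals share a genotype).

For each marker: least-squares fit of y ~ covariates + x_PD1 + x_PD2,
implemented by residualising y and the pseudo-columns against the
covariates once (QR) and solving each marker's 2×2 normal equations
vectorised. Per-PD p-values are t-tests; the marker-level p-value is the
joint 2-df F-test; significance is Bonferroni at α/m (α = 0.05). A
pseudo-column that is constant after residualisation degrades to a 1-df
test ("single_pd"); a marker constant in both PDs gets p = 1 ("constant").
PVE is the incremental R² of the marker's pseudo-columns on the
covariate-adjusted total sum of squares, ×100.

**A structural property worth knowing:** the hom/het contrast is
orthogonal to an *additive* allele-dosage effect at allele frequency 0.5
(cov(x_AA, dosage) ∝ (2q−1)(1−q)q) and regains correlation only as
frequency leaves 0.5. An additive QTN can therefore be invisible to the
AA scan at common frequencies while remaining trivially detectable under
the standard 0/1/2 coding, available as `encoding="dosage"` for
comparison runs. The acceptance script reports detection under both
codings for exactly this reason.

The multi-locus option iterates: scan → take Bonferroni-significant
markers ordered by p → greedily drop any with r² > 0.7 (on the
concatenated recoded columns) to an already-kept one → keep the
BIC-minimising prefix as pseudo-QTNs → rescan conditioning on them,
excluding from each marker's conditioning set any pseudo-QTN in LD with
it → repeat until the set stabilises (or flag non-convergence). The
Bonferroni entry gate before BIC is deliberate: BIC alone
(penalty 2·ln n per pseudo-marker pair) is weaker than the best null
statistic among thousands of markers (≈ 2·ln p), and without the gate the
null selection rate is far above what an iterative-conditioning scan
should show. This is a documented approximation of BLINK-style methods,
not a reimplementation.

## Synthetic-data generator

The generator is the exact inverse of the analysis model so parameter
recovery is well-posed. Defaults are the study conditions; tests scale
sizes down but do not change the conditions.

* **Genotypes**: Balding–Nichols with F_ST = 0.2 between two equal
  clusters, ancestral frequencies uniform on (0.05, 0.5), 5% missing
  entries, ~300 accessions × 20 000 markers over 18 chromosomes.
* **QTNs** (default 3) are sampled among markers with MAF ≥ 0.1, each
  targeting one of (a, b, c) in rotation, with additive effects on
  centred dosage; effect SDs scale as 1.0 / 0.25 / 0.5 score-, rate- and
  day-units respectively. Truth records the clamped values (a ∈ [0, 9],
  b ≥ 0.1).
* **Baselines** (a, b, c) = (9, 1.2, 3.5): the panel's susceptible
  majority saturates the scale within the week, mean scores cross
  half-maximum near day 3–3.5, and tolerance alleles pull a and c away
  from that baseline. PD2 shifts c by −0.5 days (slightly earlier
  sprouting, matching its higher observed scores).
* **Trajectories**: latent percent pct(t) = (100/9)·a/(1+exp(−b(t−c)))
  + batch offset + N(0, 8²) percent noise, truncated (not re-drawn) to
  [0, 100], then discretised through the scale. 4 replicates per
  planting date; 4 batches per planting date with offsets N(0, 0.3²)
  score units applied on the percent scale via the same 100/9 map; the
  first two accessions are controls whose replicates rotate through every
  batch, all other accessions sit in one batch (contiguous maturity
  groups). Replicate noise of 8 percent points is a free choice —
  replicate-to-replicate variance is not estimable from published
  summaries — picked as a plausible visual-scoring error of under one
  scale band.

What the generator does **not** emulate: inbreeding (genotypes are
Hardy–Weinberg, so heterozygotes are far commoner than in a real selfing
quinoa panel — which matters for the AA recode, see above), linkage
disequilibrium beyond population structure, dominance or epistasis,
scorer-to-scorer drift, molding/seed-set failures, and read-level
sequencing error. Passing tests therefore validate the statistical
machinery under the stated generative model, not field performance.

Discretising the latent percent through the ordinal scale makes the
*expected observed score* at plateau ≈ pct/10 rather than 9·pct/100, a
+11% compression-of-scale bias that is largest for true a around 6–8 and
vanishes at the saturated (a = 9) and low ends. With the default
saturating panel the median recovery error stays well inside half a score
unit; a panel parked mid-scale would not. The bias is monotone, so
rank-based checks (Spearman of true extent vs SI) are unaffected.

## Problem sizes used in validation

Scan-level simulations use 280 accessions × 2 planting dates; error
control uses 200 null panels of 500 markers with a cluster mean shift of
1 phenotype SD; power uses 50 panels of 2 000 markers with one QTN
planted at 30% covariate-adjusted PVE (the planted value is defined on
the same residualised scale the estimator reports, so calibration is a
like-for-like comparison). Sigmoid recovery uses 200 genotypes × 2
planting dates with 8 replicates and 8-point noise. The acceptance script
reruns the same measurements (smaller replicate counts for the Monte
Carlo loops) plus a full pipeline pass on a written 280 × 3000 dataset.

## Known limitations

* Fixed-effect structure correction only; no kinship/mixed model, no
  genomic-control inflation factor.
* Rows shared between planting dates are treated as independent.
* The multi-locus scan is a deliberately simple approximation; it should
  be read as "iterative conditioning with LD exclusion", nothing more.
* GAPIT/BLINK internals (its imputation choice, its PVE definition) are
  not reproduced; modal imputation and incremental-R² PVE are this
  package's documented choices.
* PCA "explained variance" here is genotype variance; published
  phrasing sometimes calls the same quantity phenotype variance.
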