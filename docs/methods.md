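# Methods

## Scope and data model

`serumdia` implements the statistical side of a paired serum DIA study.
The quantitative unit is the fragment-ion intensity per run; lineage
(fragment → peptide → protein) is taken as given, and no protein inference
from shared peptides is attempted. Runs are either subject runs (one
convalescent case and one matched healthy control per pair, acquired in
succession) or pooled-QC injections interleaved within each batch. All
tables are plain tab-separated text.

## Synthetic cohort generator

The generator exists so every downstream stage can be validated against a
known truth; its defaults encode the study design it emulates.

**Run layout.** `n_pairs` = 29 pairs are spread over `n_batches` = 4
batches (remainder to the earliest batches); each batch opens with a QC
run, gets another QC after every `qc_interval` = 6 subject runs and one at
the batch end, giving 16 QC + 58 subject = 74 runs at the defaults. Case
and control of a pair are adjacent in run order (random within-pair
order).

**Demographics.** Pairs share age (uniform 22–61 y), sex (male fraction
0.545) and race (white 0.50, black 0.40, asian 0.05, hispanic 0.05).
Cases are symptomatic with probability 0.52; days since diagnosis are
drawn from N(59, 11²) for symptomatic and N(32, 6²) for asymptomatic
cases, rounded and clipped to 9–70 d. Latent log10 antibody titer is
1.5 + 0.05·days + ε; ε is orthogonalized against days and rescaled so the
in-sample R² equals the target 0.44 exactly before discretization. Titers
snap down to a 2-fold dilution ladder starting at 1:100; 28% of cases are
non-responders, and latent titers below the lowest dilution also count as
non-detections (sentinel value 1, i.e. log10 = 0). Because R² is then
evaluated on the ~21 detected titers, its sampling sd is ≈ 0.13, and the
generator declares a ±0.30 band around the target.

**Intensities.** On the log2 scale, a fragment's value is
protein baseline N(17, 3²) + peptide offset N(0, 1) + fragment offset
N(0, 1) + batch offset N(0, 0.3²) + s_f · drift_b(t) + subject deviation +
cohort effect + run noise N(0, `noise_sd_log2` = 0.3²). The drift curve per
batch is a random centered cubic scaled to peak-to-trough
`drift_amplitude` = 1.0 log2 units, shared by all fragments up to a
per-fragment sensitivity s_f ~ N(1, 0.2²) — i.e. instrument-level drift a
kernel smoother can capture. Subject deviations are N(0, (0.15·log2 10)²)
per protein (≈ 0.15 log10 units of biological variation, a typical serum
protein CV). Differential proteins (fraction 0.11 of the panel → 37 of
334) add ±|N(0.2, 0.05²)| log10 units to convalescent runs, positive with
probability 0.6. QC runs share one pooled latent profile: no subject or
cohort terms, so their within-batch variation is exactly drift + noise.

**Missingness.** An observation is removed with probability
`missing_rate` = 0.05 plus a logistic low-intensity component centered two
sd below the mean log2 intensity. This left-censoring is intensity-biased
on purpose (DIA missingness is): it attenuates observed fold changes by
roughly a quarter at the default settings, which real pipelines also
suffer. Recovery guarantees are therefore quoted on complete data; tests
on the default design use recovery criteria that tolerate the
attenuation.

**PTM channel.** 55 hexose-modified peptides with baseline occupancy
logit-normal (−1.5, 0.7²); 3 peptides gain +1.5 logits of occupancy in
convalescents. Modified/unmodified intensities are total × occupancy and
total × (1 − occupancy) with subject- and run-level jitter.

**What the generator does not emulate:** retention-time structure,
interference between co-eluting fragments, correlated missingness across
fragments of one peptide, vaccination status or longitudinal sampling.
Passing tests show the pipeline recovers what it injects under this model
— not that any biological conclusion transfers to a real cohort.

## Normalization chain

Fixed order, recorded step-by-step in a provenance log: missingness filter
(fragments missing in > 1/2 of all runs removed; exactly half is kept) →
log2 (non-positive intensities become missing; zero intensity is an
absence call in DIA exports) → per-batch drift fit and subtraction →
cross-batch median equalization → back-transform → fragment selection →
rollup → log10. No step imputes: the missingness pattern is preserved
throughout.

**Drift model.** Nadaraya–Watson regression on run order with a Gaussian
kernel of sd 5 runs and full support (no truncation), fitted per fragment
per batch over its observed runs only; QC runs participate like any other
run — they are interleaved precisely to capture drift. Subtraction is
re-centered by adding back the mean fitted trend over the fragment's
observed runs in the batch, so drift removal does not itself shift batch
levels; batch alignment is the median-equalization step's job. A fragment
observed fewer than 2 times in a batch gets a constant trend (its mean);
unobserved fragments are left untouched.

**Median equalization** shifts each batch additively (log2) so its median
over all observed values — QC runs included — equals the grand median of
the pre-shift batch medians. The operation is idempotent.

**Fragment selection and rollup.** A transparent stand-in for black-box
rollup tools: fragments are scored by the Pearson correlation of their
log2 profile with the protein's per-run median fragment profile (≥ 3
shared observed runs required; undefined scores rank last; ties break by
fragment id), the top `max_fragments` = 5 are kept, proteins with fewer
than `min_fragments` = 2 fragments keep all and are flagged. The protein
level per run is log10 of the sum of the selected fragments' linear
intensities present in that run; if all are missing the level is missing.
QC runs are split into a parallel matrix so the analysis matrix never
contains QC columns.

## Quality control

CoV = 100·sd/mean of linear-scale (10^log10) QC protein levels per batch,
with the sample (n−1) sd because QC counts per batch are small; batches
with < 2 observed QC levels contribute no CoV. The average CoV pools
defined batches; a protein is flagged when the average is strictly above
50%. CoV is computed on the linear scale — the conventional definition;
whether the emulated study used linear or log scale is not stated in its
methods, so the flagged-protein count is sensitive to this choice.
QC run agreement is additionally reported as pairwise-complete Pearson
correlations of raw linear fragment intensities. Ordinations (PCA and
PLS-DA with a 0/1 cohort response) drop proteins with any missing value,
report per-component X-variance, and fix axis signs by forcing the
largest-magnitude loading positive.

## Statistical testing

**Paired comparison.** Pairwise-complete analysis: pairs with either
member missing are dropped per protein, `min_pairs` = 3 required. t =
mean(d)/(sd(d)/√n) with n−1 df, two-tailed. Zero-variance difference
vectors get p floored at the smallest positive float and a flag, rather
than an exact zero that would break −log10 displays. BH adjustment treats
all tested proteins as one family (one volcano plot); missing p-values
are excluded and restored as missing. The directed value is +(1 − p_adj)
for positive log10 fold change, −(1 − p_adj) for negative, and 0 for an
exactly zero fold change (the two-branch rule leaves ties undefined).

**Covariate models.** Datasets: CONTROL (levels of the 29 controls),
COVID (levels of the 29 cases), RATIO (case − control log10 differences
per pair). Controls carry the matched case's Symptoms and
Days-since-diagnosis as negative-control covariates. Encodings: Sex and
Symptoms as 0/1 indicators, Race as indicator contrasts against the most
frequent level with all levels retained, Age and Days untransformed.
Titer is never a covariate (collinear with Symptoms/Days). Six families:
univariate (each variable separately) and multivariate per dataset, the
RATIO multivariate adding Age×Sex. Coefficient p-values are two-tailed
t-tests from OLS; BH runs within each (model, term) family across
proteins — a finer family than (model, variable), chosen so multi-level
Race contrasts are corrected like any other coefficient. Designs that
become rank-deficient after per-protein row dropping are skipped with a
logged reason. The display grid shows the overall directed value plus
each variable's multivariate directed value per cohort; for multi-term
variables the smallest-p_adj term represents the variable.

**Clustering.** Rows are median-centered (idempotent; missing preserved).
Distance is 1 − Pearson on pairwise-complete observations (≥ 3 shared
runs; rows that cannot reach that overlap with the others are dropped and
reported). Zero-variance rows, where Pearson is undefined, get the
maximal distance 2 so they remain placeable. Complete-linkage
agglomeration is cut to exactly k = 20 flat clusters (k fixed, as in the
emulated study; no automatic selection). Cluster ids are renumbered by
first-member row order so labels are deterministic. A hypergeometric
over-representation utility (BH across sets) replaces web-service
function annotation for cluster interpretation.

**PTM occupancy.** level = log2(mod/(mod + unmod)), defined only when
both channels are observed and mod > 0: a zero modified intensity is
indistinguishable from a detection failure, so it yields missing rather
than −∞. The level is scale-invariant and monotone in occupancy. Peptides
with > 20% missing levels across the 58 subject runs are removed (subject
runs, not all 74 — the PTM tables carry no QC channel here). Testing
reuses the paired machinery; the fold change is in log2 level units.

**Preranked enrichment.** Ranking: descending directed value, ties by
protein id (deterministic nulls require a total order). ES is the
weighted Kolmogorov–Smirnov running-sum extreme with weight exponent 1 on
|directed|; hit steps w_i/Σw, miss steps −1/(N − N_h). A set equal to the
whole universe carries no information and scores 0; a set whose hits all
have zero weight falls back to equal hit steps. The null is n_perm = 1000
random member-position draws, shared across sets of equal size.
p is the same-sign null tail with add-one smoothing; NES divides ES by
the mean |same-sign null|; FDR q is the pooled normalized-null ratio
estimator with monotonicity enforced (q may not increase as |NES| grows)
and capped at 1 — preranked FDR variants differ, so the estimator is
fixed and documented here. Nodes pass q < 0.01 (the stricter of the two
cutoffs the emulated study quotes; a parameter), edges require Jaccard
≥ 0.80 inclusive on universe-intersected member sets.

## Problem sizes and determinism

Default analyses run a 334-protein, 74-run cohort (~3000 fragments) in
seconds; the validation suite uses 10 default-design seeds for the
drift-correction check, 50 thin null cohorts (one fragment per protein)
for the FDR check, and 200–1000 permutations for enrichment — sizes
chosen so the whole suite completes in well under a minute per check
while keeping the binomial/KS assertions meaningful. Every random draw
flows from explicit integer seeds; rerunning any stage with the same
configuration reproduces byte-identical output files.

## Known limitations

- The fragment-selection + sum rollup is a documented transparent
  stand-in; published rollup tools apply additional variance filters
  whose exact criteria are not public, so protein-level values are not
  expected to match theirs numerically.
- Whether median equalization should include QC runs is a judgment call;
  all runs are used here.
- No moderated variance estimators, mixed models, robust regression or
  unpaired fallback; proteins observed in < 3 complete pairs are
  reported missing.
- Missing values are never imputed; intensity-biased censoring therefore
  attenuates fold-change estimates on incomplete data (see the generator
  section).
- The enrichment FDR is a permutation-ratio estimate; with few candidate
  sets its resolution is limited by the pooled null size.
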