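# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `dynqtl`.

## Study design being modelled

A multi-parent mapping population of 647 doubled-haploid (DH) lines in
four partially connected biparental families (131/120/200/196 lines) from
six elite founder parents; families 1–2 share one parent and families 3–4
another, so allele effects are linked across families without a full
diallel. Lines carry dominant-scored biallelic markers (coded 0/1; DH
homozygosity makes the dominant coding effectively codominant) on a
multi-linkage-group centimorgan map. The phenotype is a developmental
score (BBCH-like) recorded on the same field plots at three time points
DS1/DS2/DS3, in partially replicated trials across four environments
(two locations × two years abstracted to environment labels E1–E4).

## Phenotypic layer

**BLUEs.** Per stage, plot values are fitted with the two-way
fixed-effects model `y = line + environment` (sum-to-zero environment
effects, line effects absorbed via within-line centering). The line
coefficient is its expected value in an average environment; with balanced
data it equals the raw line mean. No spatial or check-based adjustment is
attempted (out of scope).

**Variance components.** The random model
`y = mu + env + line + line:env + eps` (environment fixed; line and
line-by-environment random) is fitted by REML. After collapsing plots to
line-by-environment cell means, the marginal covariance is block diagonal
with one small block per line,
`V_i = sigma2_G J + diag(sigma2_GxE + sigma2_eps / r_ij)`, so each
restricted-likelihood evaluation costs O(n_lines); the pooled within-cell
sum of squares enters the likelihood exactly, keeping full-data REML
equivalence. Optimisation is Nelder–Mead on log variances with a relative
floor of 1e-10 times the data variance (this floors, i.e. effectively
clamps, boundary solutions at zero). Significance of each random term uses
a REML likelihood-ratio test against the model without the term, with the
p value halved for the boundary constraint. The entry-mean heritability is

    h2 = sigma2_G / (sigma2_G + sigma2_GxE / E + sigma2_eps / (E * r_bar)),

with E the number of environments and r_bar the harmonic mean of the
replicate counts per observed line-environment cell, both taken from the
realized design. With a single environment, sigma2_GxE is inestimable and
h2 falls back to the reduced formula without the GxE term.

## Main-effect scan

The scan model per tested marker q is

    Y = l mu + X_f M_f + X_q b_q + sum_{c != q} X_c b_c + eps

on the line BLUEs, with X_f the family incidence matrix (spans the
intercept) and cofactors X_c selected beforehand by forward–backward
stepwise regression minimising `SBC = n ln(RSS/n) + k ln n` (k counts the
intercept/family parameters plus selected markers; constant terms of the
criterion are omitted, which is affine-equivalent for model comparison).
Ties are broken by the larger RSS reduction (equivalently smaller p), then
by map order, making the search deterministic. Selection runs on a
family-mean-imputed genotype copy — a deliberate screening shortcut; every
inferential fit afterwards is strictly complete-case per marker.

For each marker the F test compares the full model against the reduced
model without b_q, on lines complete for the marker and its active
cofactors: `F = (RSS_red - RSS_full) / (RSS_full / (n - p_full))` with p
from F(1, n - p_full). Cofactors are dropped from a marker's fit when they
are the marker itself, share its exact genotype vector, or lie within a
configurable exclusion window (default 10 cM, same linkage group) — the
standard composite-mapping practice; window 0 reproduces the literal
`c != q` rule. Perfectly duplicated marker columns are collapsed to one
representative whose statistics the duplicates inherit (flagged), and the
Holm step-down correction runs over the representatives actually tested
(m recorded in the result metadata). Markers perfectly confounded with the
family structure are reported with p = 1 and an inestimable effect.

## Epistasis scan

Every unordered marker pair is tested by the F test of
`Y = X_f M_f + X_q b_q + X_q' b_q' + X_qq' b_qq' + eps` against the model
without the interaction, where X_qq' is the elementwise product of the 0/1
vectors (reference-allele flips change the sign of b_qq', not the p
value). Cofactors are not included (minimal extension of the base model).
Pairs missing one of the four two-locus classes, or whose interaction
column is collinear with the main effects, are skipped and counted. The
genome-wide threshold divides alpha by the number of independent pairwise
interactions between chromosome regions assuming two regions per linkage
group: `alpha / C(2L, 2)`; L = 22 and alpha = 0.05 give 0.05/946 ≈ 5.3e-5.
An optional thinning parameter (one marker per w cM) bounds the quadratic
cost on dense maps; default is no thinning.

## Explained genotypic variance

For a detected marker set, the simultaneous fit `family + markers` on
complete cases yields `R2_D = (RSS_family - RSS_full) / RSS_family`,
adjusted relative to the family-only baseline:
`R2_adj = 1 - (1 - R2_D)(n - F)/(n - F - k)` with k the independent marker
columns. Then `p_G = 100 R2_adj / h2`. Family effects are treated as
design structure, not explained genotypic variance. Values above 100 % are
flagged, never clamped — the estimator's selection bias is meant to stay
visible, and the cross-validation module quantifies it. Per-marker shares
are sequential partial R2 values (markers entered smallest scan p first,
ties by map order), rescaled proportionally so they sum to p_G. The same
machinery produces per-region temporal p_G profiles across stages, each
region represented by its member marker with the smallest p at that stage.

## Cross-validation

Per run, lines are split into five folds stratified by family (every fold
within one line of exact proportionality, so all families appear in every
estimation set). Each estimation set (ES) undergoes the full pipeline —
cofactor selection, scan, Holm, p_G — and its fitted model (family means
plus marker effects) predicts the held-out test set (TS). The TS estimate
is `p_G-TS = 100 max(r2_adj, 0) / h2` from the squared
prediction-observation correlation adjusted for test-set size
(`1 - (1 - r2)(n-1)/(n-2)`); an unadjusted variant is available
(`ts_estimator="corr"`) since the literature's exact TS estimator varies.
Folds with zero detected QTL contribute p_G-ES = p_G-TS = 0 and are
counted, not dropped. The heritability is estimated once on the full data
and reused in every fold (re-estimating per fold would conflate phenotypic
and genotypic cross-validation). Default 20 runs (100 ES sets),
configurable. The relative bias `100 (p_G-ES - p_G-TS) / p_G-ES`
summarises selection optimism.

## Dynamic layer

Significant markers of all stages are clustered per linkage group by
single linkage with a ±5 cM window (a 10-cM interval surrounding the QTL;
the phrasing is ambiguous between ±5 and ±10, so the window is a
parameter). Single linkage was chosen so chains of overlapping windows
merge, which is order-independent; region representatives are the members
with the smallest p across stages. Each region's Venn class is the set of
stages at which it is significant; both region-level and marker-level Venn
counts are produced because per-marker and per-region tallies need not
agree on dense maps. Progression scans run the full association pipeline
on the per-line stage difference (a QTL with equal effects at both stages
cancels; a sign-switching QTL appears with roughly the doubled effect); a
difference that is identically zero aborts, and one that is constant
across lines scans to p = 1 everywhere. The sign-change report lists
regions significant at two stages with opposite effect signs.

## Synthetic-study generator

**Genotypes.** Founder parents are fully homozygous; alleles are drawn per
marker and resampled (capped retries) until every marker segregates in at
least one family. Markers carrying preset QTL are assigned alleles that
segregate within *every* family, so their allele frequency is 1/2
everywhere and the genetic variance they generate is analytically
predictable. Each DH line is one recombinant F1 gamete doubled: crossovers
between adjacent markers occur with Haldane probability
`r = 0.5 (1 - e^(-2d/100))`, independently across intervals and lines (no
interference) — the simplest model consistent with cM input. Missing
genotype calls (default 2 %) are injected after phenotype simulation, so
phenotypes always derive from the complete calls.

**Phenotypes.** For line i, environment j, stage t:

    y_ijt = stage_mean_t + family_mean_f(i),t + sum_q x_iq b_q(t)
            + sum_(q,q') x_iq x_iq' b_qq'(t) + polygenic_i(t)
            + ge_ij(t) + eps_ijt.

The polygenic deviation is multivariate normal across stages; its
covariance matrix supplies the between-stage genetic correlation that the
finite QTL set cannot. G×E and plot-error deviations are also correlated
across stages (rho = 0.6) because the *same plot* is scored repeatedly in
time — without this, the target BLUE correlations (up to 0.84) would
require between-stage genetic correlations above what any positive
semidefinite polygenic covariance can deliver. Scores are kept continuous
(plot-level scores of many plants average out); integer rounding is an
optional flag, off by default, because the scan assumes a continuous
response. A fraction of lines (default 0.2) is observed twice per
environment, emulating partial replication (harmonic-mean replication
r_bar = 1/0.9 ≈ 1.11 with E = 4).

**Default preset.** 21 nominal chromosomes (1A–7A, 1B–7B, 1R–7R) of
140 cM with 48 evenly spaced markers each; chromosome 5R is represented as
two linkage groups (5R.1/5R.2), giving L = 22 — the group count consistent
with the printed epistasis threshold (C(44,2) = 946; L = 21 would give
5.8e-5). The total of 1008 markers is a free design choice (the marker
count used in the original mapping is not stated); ~1000 markers at ~3 cM
spacing is typical of DArT consensus maps. The QTL set covers all three
temporal classes plus one epistatic pair (table in
`default_study_preset`'s docstring); effects are in BBCH units, sized so
that every class-defining QTL has high detection power at the Holm
threshold while leaving most genotypic variance to the polygenic
background — mirroring a trait where detected QTL explain roughly half the
genotypic variance. Family means are small (±0.15–0.25 BBCH) because the
founder parents are all adapted elite material with similar phenotypes.

**Calibration.** Targets: sigma2_G = (2.5, 2.0, 1.8) BBCH², h2 =
(0.90, 0.85, 0.72), BLUE correlations (0.84, 0.74, 0.69), E = 4, plot
error twice the G×E variance. The calibrator computes the marker-genetic
covariance across stages exactly (enumeration over two-locus classes for
epistatic blocks; QTL are unlinked by construction), sets the error
variances from the entry-mean identity, and solves for the polygenic
covariance that meets the variance and correlation targets, validating
positive semidefiniteness. Twenty-seed recovery (the acceptance check)
reproduces h2(DS1) to within ±0.01 and r(DS1,DS2) to within ±0.01 of
target in practice.

**What the generator does not emulate.** Field spatial trends, check
plots and trial-design effects; DArT hybridisation chemistry and map
construction; selection during DH production; vernalisation/photoperiod
physiology; linkage disequilibrium between founder genomes beyond the
simulated meiosis. Passing tests therefore demonstrate correctness and
calibration of the statistical machinery under the stated generative
model, not robustness to spatial artefacts or map errors in real data.

## Problem sizes used in the test suite

The suite runs the full 647-line preset where the property demands it
(calibration recovery, temporal-class recovery: 20 seeds each; the
cross-validation bias study: 20 runs × 5 folds on a 396-marker map — a
thinned map keeps the repeated scans cheap without changing the
phenomenon). Error-control nulls use 300 lines × 500 markers × 200
replicates for the Holm scan and 300 × 100 × 100 for the epistasis scan.
Oracle-equivalence checks run on 100 randomised small instances against
statsmodels OLS (used nowhere in the implementation).

## Known limitations

* Cofactors within ~10–12 cM outside the exclusion window can partially
  absorb a tested QTL on dense maps, occasionally costing a detection of a
  moderate-effect locus; this is inherent to composite marker regression
  with a fixed window.
* The epistasis scan's complete-case pair loop is O(m²) Python-level when
  missing calls are present; with complete data a vectorised path is used.
  Thinning is recommended beyond ~1500 markers with missing data.
* p_G and its cross-validated counterpart assume the entry-mean h2 is
  known; its estimation error is not propagated.
* The stepwise SBC search admits a small number of spurious cofactors
  under a pure-noise trait (about 1.5 on average for 100 lines × 50
  markers) — consistent with BIC-stopped forward selection, and harmless
  for the scan, whose error control is established separately.
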