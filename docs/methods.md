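# Methods

This note records the models, defaults and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
design decisions that were genuinely open.

## Study design

The analysis compares carcinomas with mucinous differentiation ("mucinous")
against non-mucinous controls of the same cancer type, stratum by stratum,
across expression, methylation and genomic layers. Cohort construction has
two steps: keyword triage of pathology-report text, then 1:k
nearest-neighbour selection of matched controls. All group comparisons are
non-parametric (Mann–Whitney U for continuous metrics, Fisher/χ² for 2×2
frequencies) with Benjamini–Hochberg control of the false-discovery rate;
the multiple-testing family is the set of features within one comparison run
(the genes of one stratum's recurrent-alteration screen, or the ten
pathways), a choice recorded in each output.

## Report mining

Matching is case-insensitive substring search after NFKC unicode
normalization, with the default keyword list `mucin`, `mucous`, `colloid` —
so "mucinous" and "MUCIN-producing" both hit. No stemming and no negation
detection: a negated phrase ("no mucinous features identified") is flagged,
and the ±40-character context strings exist precisely so a human reviewer
can resolve such cases, mirroring a manual-review triage. Substring (rather
than token) matching and case-insensitivity are documented behaviour, not a
claim about how any particular study implemented its search.

## Matched-control selection

Greedy sequential nearest-neighbour matching without replacement: cases in
input order, each taking its `ratio` (default 3) nearest compatible unused
controls. Compatibility = exact equality on the categorical covariates
(sex, composite pTNM stage, plus cancer-type extras: ER/PR/HER2 for breast,
smoking for lung, site and laterality for colorectal). Distance = Euclidean
over continuous covariates (age, year of diagnosis) z-scored over the
combined case+pool table (SD with ddof=1; a constant covariate contributes
zero distance). Ties break toward the smaller pool index, making the
procedure deterministic. Optimal (global) matching and propensity scores
are out of scope; greedy is the common default and its order dependence is
inspectable through the balance table, which reports
SMD = (mean_case − mean_ctrl) / √((s²_case + s²_ctrl)/2) for continuous and
per-level proportion differences for categorical covariates. Zero pooled SD
yields SMD 0 when the means agree and a flagged undefined value otherwise.
A `strict` design raises when a case cannot fill its quota; best-effort
mode records the shortfall instead (small strata need this).

## Statistical kernel

* Fisher's exact test: two-sided by summation of tables with point
  probability ≤ the observed table's (scipy's convention).
* Pearson χ²: no Yates continuity correction.
* `auto` policy: Fisher when any expected cell < 5, χ² otherwise — an
  explicit encoding of "χ² or Fisher when appropriate". Degenerate tables
  (a zero row/column margin) return p = 1 with an undefined odds ratio and
  a flag rather than an error.
* Mann–Whitney U: exact null up to n = 25 per group for tie-free samples,
  otherwise normal approximation with tie and continuity correction; two
  identical constant samples return p = 1.
* Spearman rho: average ranks, t-approximation p; constant input is
  undefined (NaN, flagged), not an error.
* BH adjustment preserves input order and satisfies q ≥ p. Note that
  re-adjusting q-values is *not* a no-op: it can only raise them, so the
  significance set can shrink (tested in that direction).
* Empirical Monte-Carlo p = (r+1)/(n+1), computed in exact rational
  arithmetic before conversion to float; it is never 0 and never exceeds 1.

## Differential expression

A deliberately simple, fully specified two-group engine: median-of-ratios
size factors (computed over genes expressed in every sample, rescaled to
geometric mean 1), log₂(normalized + 1), per-gene two-sided Welch t, BH
across tested genes. Genes with zero counts everywhere are excluded and
flagged. The cross-cancer intersection consumes only the q < 0.05 sets and
fold-change signs, which any calibrated two-group test supplies; dispersion
shrinkage, GLM offsets and covariates are intentionally out of scope.
log₂FC > 0 means higher in the mucinous group.

Mucin signatures are the per-sample mean RPKM
(count / (length/10³) / (libsize/10⁶)) over the signature genes, centered
to mean 0 and scaled to SD 1 (ddof = 1) across samples. Signature genes
missing from a matrix are dropped with a warning — annotation differences
make this common — and at least one must remain.

## Monte-Carlo intersection test

The null draws, per stratum, mᵢ genes uniformly without replacement from a
universe of G genes (default universe: genes tested in all strata) and
intersects across strata; r counts simulations whose intersection reaches
at least the observed N, and p = (r+1)/(n+1). Implementation: instead of
materialising gene sets, each simulated intersection size is produced by a
sequential hypergeometric chain — |A₁∩A₂| ~ HG(G, m₁, m₂), then
conditionally |A₁..ₖ∩Aₖ₊₁| ~ HG(G, |A₁..ₖ|, mₖ₊₁) — which is exactly the
distribution of intersecting uniform draws (exchangeability of the
universe) and vectorises 10⁵ simulations to milliseconds. A test
cross-checks it against a brute-force set-intersection simulation on a
small universe, and against the closed-form null mean G·∏(mᵢ/G).
Direction-concordant intersection ("consistently differentially expressed")
is available via `require_direction`; the default intersects on
significance alone, with both modes exposed because the stricter reading is
ambiguous.

## Differential methylation

One-way ANOVA F per probe on beta values; for two groups without shrinkage
F equals the squared pooled-variance t statistic exactly (regression test
at 10⁻⁹). The optional moderation replaces the per-probe residual variance
s² by (d₀·s̄² + df·s²)/(d₀ + df) with prior df d₀ = 3 and s̄² the mean
residual variance across probes, leaving the residual df unchanged. This is
an explicit, testable stand-in for empirical-Bayes variance shrinkage — no
equivalence to any specific external implementation is claimed, and both
moderated and plain F are available. Betas are consumed as-is
(normalization upstream); M-value transforms and region-level calling are
out of scope. Probe→gene maps must be single-valued; gene-level summaries
report the minimum-q probe and the count of significant probes.

## Genomic landscape

* TMB = non-synonymous mutations / bases sequenced (reported per base and
  per Mb).
* FGA uses strict inequalities (|log₂| > 0.2; a segment at exactly 0.2 does
  not count) and length-weighting. The denominator is the sample's total
  segmented length by default, switchable to a fixed genome size, because
  "percentage of genome" is ambiguous when segmentation does not tile the
  genome. Overlapping segments within a sample are an error naming the pair.
* SEG coordinates are 1-based inclusive and kept that way internally;
  length = end − start + 1. Round-tripping through SEG files is lossless.
* CNA calls: per fixed-width bin, the overlapping segment covering the
  largest share of the bin decides gain/loss/neutral at the same ±0.2
  thresholds; uncovered bins are missing and excluded from frequency
  denominators.
* Recurrent oncogenic alterations: oncogenic flag (consumed as an input
  boolean, never computed here) and carrier frequency ≥ 1 % ("at least 1 %"
  ⇒ exactly 1 % qualifies).
* Pathway matrix: a sample alters a pathway iff ≥ 1 member gene carries an
  oncogenic event; a gene in two templates flags both. The bundled default
  templates are compact curated member lists for the ten canonical pathways;
  full templates can be supplied as GMT. Driver-alteration counts include
  all oncogenic event types, with epigenetic silencing switchable off, since
  its inclusion in driver tallies is a convention choice.
* MSI step: 2×2 test of MSI-H against histology group, then exclusion of
  MSI-H samples from downstream genomic analyses (they are hypermutated and
  would dominate burden comparisons).

## Synthetic cohorts

The generator emulates the *statistical structure* the analysis assumes,
with defaults that define the package's study conditions:

| parameter | default | rationale |
|---|---|---|
| strata | CRC, BRCA, LUAD, STAD | the four largest cohorts of the design |
| n per stratum / mucinous fraction | 120 / 0.25 | 30 cases : 90 controls — the 1:3 design |
| genes / probes | 2000 / 1000 | desk-scale but large enough for FDR behaviour |
| count model | negative binomial, dispersion 0.15 | standard bulk RNA-seq count model; moderate overdispersion |
| planted log₂FC | MUC2 +4; MUC5B, MUC5AC +2; MUC6 +1; SEC16A, CRACR2A +1.5 | strong MUC2 up-regulation with companions; magnitudes are calibration choices, not published values |
| methylation coupling | Spearman ρ = −0.6 at the MUC2 promoter probe | negative methylation–expression association, moderate strength |
| FGA means | 0.10 mucinous vs 0.25 control (Beta, concentration 30) | quieter copy-number landscape in mucinous tumours |
| TMB | log-normal per Mb, μ 0.7/1.3 (muc/ctrl), σ 0.5; MSI-H ×10 | lower burden in mucinous; hypermutated MSI-H |
| alteration frequencies | published fractions (e.g. CRC TP53 0.25 vs 0.772, SMAD4 0.354 vs 0.074, BRCA PIK3CA 0.094 vs 0.459) + 2 % background over pathway genes | group-specific oncogenic landscapes |
| MSI-H rates | CRC 0.356 vs 0.126; 0.04/0.02 elsewhere | enrichment concentrated in colorectal |
| decoy keyword rate | 0.10 | negated keyword phrases in control reports |

Mechanics worth knowing: planted genes get baselines drawn uniform(30, 100)
so fold changes act on detectable signal; the MUC2 promoter probe is coupled
to MUC2 expression through a Gaussian copula (target Spearman ρ converted to
a Pearson latent correlation by ρ_P = 2·sin(πρ_S/6), applied to the normal
scores of within-stratum expression ranks), which hits the target ρ
approximately and guarantees the monotone-decreasing relationship; segments
realise each sample's Beta-drawn altered fraction exactly (up to 1 bp
rounding) by allocating altered stretches across a 22-chromosome toy genome
(5 Mb each) at random offsets, neutral elsewhere, never overlapping;
alteration events are independent Bernoulli draws. One master seed spawns
per-layer child generators, so layers are independently reproducible and
the whole bundle is byte-identical for a fixed (config, seed).

What it does **not** emulate — hence what passing tests show and do not
show: no read-level noise or mapping bias, no probe-level 450K artifacts or
cell-composition effects, no correlation structure between genes, no
linkage between layers beyond the planted couplings, no realistic report
prose beyond keyword placement, and no confounding between covariates and
omics layers (so matching is exercised structurally, not for its
bias-reduction value). Parameter-recovery results on these cohorts
demonstrate the code paths are correct and calibrated, not that the method
would behave identically on real tumour data.

## Problem sizes

Default end-to-end runs use 4 strata × 120 samples, 2000 genes, 1000
probes, and 10⁴ intersection simulations (10⁵ in the library default and
CLI); the full pipeline completes in a few seconds on one CPU and the
acceptance script, which also simulates 20 default cohorts, in well under a
minute.

## Known limitations

* The DE engine is a calibrated stand-in, not a negative-binomial GLM;
  genes with strong mean–variance coupling may rank differently than under
  a dedicated RNA-seq model.
* Greedy matching is order-dependent by construction; only the documented
  tie-break makes it deterministic.
* The Monte-Carlo universe defaults to genes tested in all strata; other
  universes change p and must be chosen deliberately.
* The moderation prior df is fixed (d₀ = 3) rather than estimated from the
  data.
* Pathway conclusions inherit the template definitions; the compact bundled
  templates are for structural use and small-scale analyses.
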