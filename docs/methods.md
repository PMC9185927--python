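# Methods

`ocproteo` implements the analysis chain of an ex vivo osteochondral model of
post-traumatic osteoarthritis (PTOA): cartilage–bone explants from several
human donors are cultured for 21 days under four arms — untreated control
(N), 100 nM dexamethasone (D), single mechanical impact plus TNF-α/IL-6/sIL-6R
cytokines (IC), and injury+cytokines+dexamethasone (ICD) — and profiled by
label-free LC-MS/MS of the culture media and extracted tissue alongside sGAG
biochemistry. The package consumes identified peptide tables; spectra,
database searching and FDR control are upstream and out of scope.

## Synthetic experiments

Because raw study data are not required, a generator produces complete
ground-truthed experiments. Its defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_donors` / `n_replicates` | 7 / 3 | donors × biological replicates per arm |
| `treatments` | N, D, IC, ICD | treatment arms |
| `n_batches` | 2 | media samples split into two donor collections |
| `tissue_donors` | 4 | donors contributing tissue samples |
| `donor_sd`, `batch_sd`, `residual_sd` | 0.5, 0.5, 0.4 log2 | variance components |
| `effect_size_ic` | 2.0 log2 | planted IC shift; ICD shift is `effect_size_ic·(1−att/100)` |
| `n_planted_semitryptic` / `n_background_semitryptic` | 20 / 80 | severity-associated vs null semitryptic peptides |
| `missing_total_frac` / `censor_weight` | 0.10 / 0.5 | overall missingness; fraction that is left-censored |
| `sgag_baseline_pct` / `sgag_ic_pct` | 20 / 54 | expected cumulative % sGAG loss, N and IC |
| `attenuation_true` | 66.7 | % of IC-excess loss removed by Dex |

Intensities are log-normal: log2 y = feature baseline (N(20, 2.5)) + donor
effect + batch offset (media batch 2 only) + treatment effect (planted
features only) + residual. The donor effect is drawn per feature × donor and
shared across arms, so planted fold changes are estimated against residual
noise only, as in a paired design. Missingness mixes completely-at-random
dropout with probit left-censoring of low intensities; `censor_weight`
interpolates between the two while preserving the overall fraction.

Noise scales have no published values; they were fixed once at magnitudes
typical of label-free explant media profiling (residual CV ≈ 30%,
donor-to-donor spread comparable). Planted peptides get a ~2 log2-unit lower
baseline so they are enriched toward the censoring margin in control arms
("predominantly present" under IC/ICD) while still passing the 70% presence
filter. The background semitryptic panel (80 peptides) makes the top-50
extraction a genuine selection.

Biochemistry: per explant, nine media collections (days 2–21) plus one final
tissue digest. Per donor, expected losses are N = baseline + noise,
IC = 54% + noise, D ≈ N, and ICD = IC − att_d/100·(IC − N) with per-donor
attenuation att_d ~ N(66.7, 10). Per-explant percent-loss noise is 1.5
points. IC-type arms release sGAG front-loaded (geometric day weights);
untreated arms release evenly; only cumulative totals carry ground truth.

What the generator does not emulate: retention-time structure, interference
or shared-peptide quantification artifacts, correlated protein modules,
donor-specific attenuation signal in the proteome (the planted ICD shift uses
the population attenuation), or identification error. Passing tests therefore
validate the statistical machinery on a well-specified data-generating
process, not robustness to every pathology of real MS data.

## Peptidomics

Trypsin cleaves after K/R except before P; protein termini are valid
boundaries. Terminus classification applies the same rule to both peptide
ends: both tryptic → fully tryptic; exactly one → semi-tryptic, named for the
tryptic side; neither → non-tryptic. Semitryptic peptides mark endogenous
protease activity and are the biomarker candidates. Modifications are carried
as annotations only. Peptides whose sequence occurs at more than one protein
position are dropped from position-resolved analyses with a warning. Domain
mapping assigns a peptide to the domain containing its midpoint residue
(closed intervals; boundary midpoints belong to the domain).

Protein quantification is the top-3 roll-up: per protein per sample, the mean
of the three largest raw intensities among unique, quantified peptides (all
present if fewer than three; missing if none). Uniqueness means
unique-to-protein; shared peptides are excluded.

## Preprocessing

Presence filter: keep features observed in ≥ ceil(0.70 · n samples), after
removing exogenous accessions. Tissue matrices are divided by DNA content per
wet weight (cell-density adjustment) before the log step; media never are.
Imputation runs on the log2 scale (the raw-scale alternative is a flag):
features are the neighbour objects; the distance between two features is the
plain Euclidean distance over samples where both are observed; candidates are
restricted to features observed at the target sample; the imputed value is
the unweighted mean of the k = 10 nearest candidates (all, if fewer), with
distance ties broken by feature order. k = 10 is a common proteomics default;
the value is exposed. Scaling standardizes each feature to mean 0, unit
sample variance (ddof 1); constant features raise an error by default.

Batch correction fits, per feature, value ~ design + batch with sum-to-zero
batch coding and subtracts only the fitted batch terms, so treatment-
attributable variation survives; it refuses designs where batch is aliased
with treatment. Correction is applied before ordination/regression analyses
only; differential contrasts instead carry batch as a model covariate. Zeros
in input files are observed values, not missingness (warned).

## Biochemistry statistics

Cumulative percent sGAG loss is 100·Σmedia/(Σmedia + tissue). Dexamethasone
attenuation per donor is 100·(loss_IC − loss_ICD)/(loss_IC − loss_N),
reported with flags rather than exceptions: undefined when IC shows no excess
over control, out-of-range (value still returned) when outside [0, 100] —
donors may respond negatively or not at all. Treatment significance uses a
REML linear mixed model on per-explant day-21 cumulative losses with a donor
random intercept (a repeated-measures day-covariate variant is available but
off by default). LS-means are the marginal treatment means; all pairwise
differences are tested with SEs from the fixed-effect covariance, containment
degrees of freedom (N − n_treatments − n_donors + 1; simpler than
Satterthwaite and exact for these balanced designs), and Tukey
studentized-range adjustment (Bonferroni optional). A donor variance on the
boundary is flagged, not an error — fixed effects then equal OLS.

## Differential abundance

Per feature, OLS on the log2 matrix with cell-means treatment coding (+
batch covariate for media; donor covariate optional, off by default since the
generator's donor effects cancel in treatment contrasts). Empirical-Bayes
moderation: the prior (d0, s0²) is estimated by moment-matching log s² — 
var(log s²) = ψ′(d/2) + ψ′(d0/2) inverted with a Newton trigamma inverse, and
the bias-corrected mean gives s0². Posterior variances
s̃² = (d0·s0² + d·s²)/(d0 + d) enter the t statistic on d + d0 df. When the
observed variances show no excess dispersion the prior df is infinite and s0²
is taken as the geometric mean of s² (the empirical variances are treated as
the common value; with literally identical s² this returns that value
exactly). FDR is Benjamini–Hochberg. Default contrasts: D/N, IC/N, ICD/N,
ICD/IC.

Condition-unique classification works on the pre-imputation mask: a feature
is unique to ≤ 2 conditions when each of those conditions detects it in
enough donors (media: all but one donor; tissue: every donor) and no donor
detects it elsewhere.

## Multivariate analysis and ranking

PCA is an SVD of the centered samples × features matrix; percent variance
sums to 100 over components, and each component's largest-magnitude loading
is made positive for determinism. For regression against severity,
replicates are averaged within donor × treatment and the response vector is
aligned per group: total percent sGAG loss, or per-donor Dex attenuation
(constant across that donor's arms). PLS regression is PLS1 NIPALS — per
component w ∝ Xᵀy (unit norm), t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt, deflate —
with X standardized upstream and y centered internally (not scaled, so scores
keep response units; the ranking is unaffected).

The biomarker score of a feature is its first-two x-loadings dotted with the
y-loadings, XL₁·YL₁ + XL₂·YL₂ — the projection of the feature onto the
response direction in latent space. This is the default reading of a
"loading dot product"; the alternative XL₁·XL₂ per feature is available
behind a flag but mixes component signs and is not recommended. Ranking is
descending with lexicographic tie-breaks; the top 50 are extracted. The
attenuation regression runs on all batch-corrected media samples or on
control samples only (two presets); the control-only preset asks which
baseline proteins predict a donor's later drug response.

## Enrichment

Preranked enrichment uses the weighted KS running sum (hit increments ∝
|score|^p, p = 1 by default, the standard preranked weighting; misses
decrement 1/(N−|S|)); ES is the signed maximum deviation, evaluated only at
hit-adjacent positions. The null permutes the score-to-feature assignment
(1000 draws); NES divides ES by the mean same-sign null ES and p is the
fraction of same-sign null ES at least as extreme. Over-representation is a
hypergeometric upper tail with BH across sets. Gene sets come from GMT
files; the synthetic pipeline builds random protein groupings plus the set of
proteins carrying planted peptides.

## Problem sizes and determinism

Default simulated experiments carry ~600 peptides (100 semitryptic, 20
planted) over 84 media + 48 tissue samples — a deliberately reduced scale at
which every stage's behaviour is measurable within seconds while keeping the
full design structure. All randomness flows from one top-level seed through
`numpy.random.SeedSequence` spawning, and deterministic stages are
byte-identical across reruns. Validation is property-based: imputation against
an exhaustive brute-force oracle, PLS against OLS at full rank and against an
independent implementation, hyperparameter recovery on the generating
hierarchy, attenuation recovery within 5 points of the planted truth, and
permutation-p uniformity under the null.

## Known limitations

- The mixed-model df approximation is containment, not Satterthwaite; for
  heavily unbalanced designs adjusted p-values will be conservative or
  liberal relative to lmerTest-style output.
- The attenuation PLSR on synthetic data is a null analysis (the generator
  plants no donor-attenuation-predictive proteins); it demonstrates the
  procedure, not recovery.
- Protein-level signal for planted peptides is diluted by the top-3 roll-up
  because planted semitryptic peptides are low-intensity by construction.
- kNN imputation is O(F² · S) in features and samples; matrices far beyond
  10⁴ features would need a truncated neighbour search.
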