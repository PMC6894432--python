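# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic cohort does and does
not emulate, and the numerical conventions that make runs reproducible.

## Cohort model (synthetic data)

The generator emulates a paired tumor/normal bulk RNA-seq cohort of
`n_pairs` patients (default 50, with a flag to drop one pair from the miRNA
matrix for cohorts where the miRNA assay covered one pair fewer).

**Counts.** Each gene has a log-normal baseline mean
(`exp(N(log 150, 1))`, floored at 10 counts) and per-sample counts are
negative binomial with `var = μ + φμ²`, dispersion `φ = 0.1` — a standard
marginal model for bulk RNA-seq at moderate depth. The floor keeps the
log2-CPM noise close enough to Gaussian that the paired t-test is calibrated
(its null p-values pass a Kolmogorov–Smirnov uniformity check in the test
suite); very-low-count genes, which a real analysis would filter, are simply
not generated.

**Differential expression.** A fraction `frac_de = 0.15` of each role's
genes shifts its tumor mean by `±de_log2fc` (default 2) on the log2 scale.
Candidate lncRNAs and their partner mRNAs are forced into the DE set
(up-regulated); the candidates' miRNAs get magnitude `de_log2fc + 1` so they
always rank inside the top/bottom-10 fold-change window that defines the
miRNA universe.

**Modules.** `n_modules = 5` disjoint sets of `module_size = 50` lncRNAs
each follow a per-sample latent factor `f_m(s) ~ N(0,1)` added to the log2
mean, plus gene-level noise `N(0, module_noise_sd = 0.3)`. For the first
("trait") module the tumor-sample factor is
`trait_effect·z(stage) + √(1−trait_effect²)·ε` with `trait_effect = 0.8`,
where `z(stage)` is the standardized ordinal TNM code; stages are uniform
over {I, II, III} on tumor samples, matching a cohort where stage IV is
absent.

**ceRNA triplets.** Eight candidate lncRNAs are drawn from the trait module.
Each gets 2 private miRNAs and 5 private partner mRNAs; all
(candidate, miRNA, partner) combinations are planted as triplets (80 by
default). Realization: the miRNA→candidate and miRNA→partner edges enter the
target table; the partners' log2 means follow the trait factor (positive
lncRNA–mRNA correlation in tumors); the miRNAs' tumor means follow
`−0.8·f` (anti-correlation with both partners — sponge-style depletion).
Decoy edges (uniformly random miRNA→gene, `targets_per_mirna = 10` per
miRNA) give the hypergeometric test a non-degenerate null. The decoy rate is
a deliberate compromise: with the miRNA universe fixed at 20 by the
top/bottom-10 rule, each extra decoy edge from a universe miRNA inflates a
planted pair's margins K/n, and the m = 2 upper tail crosses p = 0.05 once
the margins reach roughly (3, 4); ~10 decoy targets per miRNA keeps the
expected extra universe edges per gene below 0.1 so planted pairs pass with
high probability while random pairs essentially never do.

**Survival.** Exponential event times with rate
`λ_i = (ln 2 / 700 days) · HR^(k_i/8)` where `k_i` counts the risk lncRNAs
for which patient *i* sits in the top expression half, `HR = 6`, censoring
uniform on 1000–3000 days. These are testability choices (they give the
median-split log-rank screen ~0.9 power at n = 50), not estimates of any
real cohort; the source data offered no effect sizes to emulate.

**What passing tests do not show.** The generator has no batch effects, no
library-composition bias beyond what TMM corrects, no isoform structure, no
sequence-level miRNA binding (the edge table is an *input*, as in a real
analysis where it comes from a binding-site predictor), and module/triplet
structure far cleaner than real co-expression. Recovery results on it
validate the *implementation*, not the biological power of the method on
real data.

## Differential expression

TMM (trimmed mean of M-values) scaling follows the standard algorithm:
reference = sample whose upper-quartile relative abundance is closest to the
mean; M and A computed on genes positive in both libraries; 30% of M
extremes and 5% of A extremes trimmed by rank-window intersection; factor =
2^(precision-weighted mean M) with weights equal to inverse asymptotic
variances; factors rescaled to geometric mean 1. The implementation is
checked against reference values from an established implementation on a
fixed matrix.

log2-CPM uses a pseudo-count `prior = 0.5` scaled per sample in proportion
to its effective library size, which makes the transform exactly invariant
to a pure depth change.

The DE test is a paired two-sided t-test on per-pair tumor−normal log2
differences (log2FC = mean difference, df = pairs − 1), *not* a
negative-binomial exact test: the screen's thresholds, not its exact tail
behavior, drive everything downstream, and the paired design matches the
cohort. An unpaired Welch variant is available (`paired: false`).
Zero-variance genes get p = 1 with a warning. FDR is Benjamini–Hochberg.
Thresholds are strict inequalities (FDR < 0.01, |log2FC| > 1), and the miRNA
top/bottom-k rule breaks fold-change ties lexicographically by id so results
are order-independent.

## ceRNA inference

The miRNA universe is the DE-selected miRNA set intersected with the target
table — the natural sampling frame when DE genes are the input to target
prediction. Edges to non-universe miRNAs are ignored everywhere. The test is
one-sided (enrichment); p-values are computed through the log-space survival
function. No multiple-testing correction is applied across pairs by default
(raw p < 0.05, matching the method's published form); a BH option exists.
Correlations use tumor samples only by default — ceRNA competition is a
tumor-state claim — with an all-samples variant behind `tumor_only: false`.
Both the sign filter (PCC > 0) and the significance filter (p < 0.05) are
applied and independently toggleable, since descriptions of the method vary
on whether significance is part of the cutoff.

The emitted network may include the shared miRNAs as nodes, but centralities
for candidate selection are computed on the lncRNA–mRNA pair graph only, so
the top-degree rule measures ceRNA partnership intensity. Betweenness is the
unnormalized undirected Brandes count; closeness is
(reachable − 1)/Σdistances within the component, 0 for isolated nodes.

## Co-expression modules

Signed adjacency `((1 + cor)/2)^β`; Pearson correlation throughout (the
robust biweight variant is out of scope). TOM similarity
`(Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)` with unit diagonal.

**Power selection.** The scale-free fit index bins log10(k) (10 bins),
regresses log10(frequency) on log10(mean k), and reports −sign(slope)·R² so
genuine power-law decay scores +R². The chosen power is the smallest with
fit ≥ `r2_min = 0.85`. When nothing qualifies the operation's default
fallback is the argmax of the fit, but the *pipeline* falls back to the
conventional signed-network power 12: on data whose degree distribution has
no power-law tail (including the block-structured synthetic cohort) the fit
index is near zero for every power and its argmax is noise — in practice it
landed on extreme powers that crushed the adjacency and destroyed module
detection.

**Module detection.** Average-linkage clustering of 1 − TOM with a *static*
cut at `cut_height = 0.9`; clusters below `min_module_size = 30` become
`unassigned`; modules whose eigengene dissimilarity (1 − correlation) is
below `merge_diss_max = 0.25` merge iteratively, closest pair first. The cut
height was set from the geometry of TOM dissimilarities — within-module
heights fall around 0.6–0.8, between-module and background heights around
0.95–1.0 — so 0.9 sits in the separating gap. (The familiar 0.995 default
from the reference tool belongs to its *dynamic* tree-cut algorithm, which
cuts variable-height branches; under a static cut it merges everything.)
Labels are deterministic: M1, M2, … by size descending, ties by smallest
member id; color names are presentation only.

**Eigengenes and traits.** Eigengene = first principal component of the
standardized member×sample matrix, scaled to unit sample variance, sign
aligned with the module's mean standardized expression. Module–trait
correlation uses one binary indicator per observed TNM stage (an ordinal
single-column mode is available), Pearson r with a two-sided t-test on
n − 2 df, restricted to staged tumor samples. The pipeline clusters tumor
samples only by default: with paired samples, the tumor/normal mean shift of
DE genes otherwise dominates the correlation structure and clustering
recovers disease state rather than co-regulation.

## Candidate selection

Three conditions, each strict about its own threshold: top-20% ceRNA-degree
(empirical quantile with all boundary ties kept and at least
⌈fraction·count⌉ nodes returned), membership in a module whose best trait
p < 0.05, and ≥ 1 co-expression edge at PCC ≥ 0.7 (inclusive — the
published cutoff names the value without strictness, and inclusivity is the
deterministic reading). "High correlation support" is operationalized as a
single qualifying edge since no edge-count threshold is published. The
candidate→target table reports the union of ceRNA partners and lncRNA–mRNA
co-expression partners with per-evidence labels (`cerna`, `coexp`, `both`),
so either narrower definition of "targeted genes" can be recovered from the
output.

## Survival and enrichment

Median split assigns ties to the low group (configurable quantile); patients
without survival data are excluded before the median is taken; multiple
tumor samples per patient are averaged. Kaplan–Meier is the plain
product-limit estimator; the log-rank statistic is (Σ(O−E))²/ΣV on 1 df with
the hypergeometric variance at each event time. A candidate is flagged when
the high group has both the smaller restricted-mean survival and log-rank
p < 0.05. No covariate adjustment — the claim validated is the unadjusted KM
contrast.

Enrichment is a plain hypergeometric-tail ORA over user-supplied GMT sets,
BH-corrected across sets; the universe defaults to all genes of the supplied
expression matrix (expression-filtered universes avoid detection bias) and
is overridable. Fuzzy-clustering enrichment scores tied to hosted annotation
databases are out of scope.

## Reproducibility and numerics

One integer seed drives a single root generator; all simulation stages draw
from it in fixed order. Every writer emits deterministically ordered rows
with fixed float formatting, the manifest contains no timestamps, and two
runs with identical config + seed are byte-identical. Hypergeometric tails
are computed in log space; correlations of exactly collinear vectors report
r = ±1, p = 0; the empirical-quantile degree cutoff uses linear
interpolation. Degenerate inputs fail loudly with named offenders
(all-zero libraries, constant genes, unpaired samples, malformed files)
rather than being coerced.

Default problem sizes used by the test suite and the acceptance script —
50 pairs, 2,000/500/150 genes, three seeds for recovery checks, 500
simulations for log-rank calibration, 200 replicates for module–trait
calibration — were chosen so the full suite exercises every stage at the
cohort scale the method is described at while remaining comfortable on a
single CPU.

## Known limitations

The DE stage substitutes a paired t-test for a count-model test and will be
anticonservative for very low counts (mitigated here by the generator's
baseline floor; on real data, filter low-count genes first). The static tree
cut is simpler and more predictable than dynamic branch cutting but needs a
cut height matched to the TOM scale of the data. The ceRNA test conditions
only on margins over a small miRNA universe, so its resolution is coarse
(with N = 20, the smallest attainable p at m = 2 is ~5×10⁻³). Sequence-based
binding prediction, annotation databases, and external web services are
deliberately outside the package boundary.
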