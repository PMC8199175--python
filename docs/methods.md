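# Methods

## Problem and model

The pipeline identifies *oncofetal* miRNAs: miRNAs active during fetal lung
development and reactivated in lung adenocarcinoma, but silent in the healthy
adult lung. Operationally the definition is presence/absence, not fold
change: a hit must be statistically overexpressed in tumour and fetal tissue
relative to adult non-neoplastic lung in two independent cohorts **and**
essentially undetectable (< 10% of samples with ≥ 1 RPM) in the adult
non-neoplastic group of both cohorts. The three criteria are deliberately
conjunctive; relaxing any one of them can only enlarge the hit set.

## Normalization and detection

RPM is computed against the sample's total miRNA-assigned reads (the matrix
column sum), not the sequencer's total read count, so normalization is
self-contained in the expression matrix; the `total_reads` metadata is used
only for the 5-million-read depth filter (strict less-than). Replicate
libraries are averaged on raw counts before normalization, and the result is
renormalized. The detection rule is inclusive on both bounds: exactly 1 RPM
counts as positive, and exactly 10% of a group counts as expressed. Only
miRNAs detected in at least one group of *both* cohorts enter differential
expression — note that this removes genuinely fetal-only miRNAs whenever the
validation cohort lacks fetal samples, which is a property of the study
design, not a bug.

## Differential expression

Tests run on log₂(RPM+1); the pseudocount of 1 maps absence to 0 and is
config-exposed. Fold change is the ratio of *untransformed* group mean RPM
with ε = 0.01 RPM added to both means: the quantity of interest is often a
presence/absence contrast whose denominator mean is ~0, and ε makes the
ratio finite without materially changing any ratio between expressed groups.
The discovery scheme is a one-way fixed-effects ANOVA with Fisher's LSD
post-hoc (pairwise t on the pooled error variance and its df, reported only
when the omnibus p < 0.05, otherwise set to 1); Tukey's HSD is available via
`posthoc: tukey`. The validation scheme is Welch's t with Benjamini–Hochberg
step-up applied across all miRNAs of that single comparison. "Under" is
defined symmetrically to "over" (FC < 0.5); both FC comparisons are strict,
both p comparisons strict at α = 0.05.

## Congruence test

Status congruence between the LUAD vs ANL and FL vs ANL contrasts is a
two-sided exact test of independence on the 3×3 over/under/ns table (a 2×2
significant/ns collapse is config-exposed). The implementation enumerates
every margin-fixed table (Freeman–Halton) whenever the total is ≤ 500 and
the composition bound on the number of tables stays below 2×10⁶ — status
margins are heavily skewed towards *ns*, so real tables enumerate quickly —
and otherwise falls back to a seeded Patefield Monte Carlo (≥ 10⁶ tables,
add-one estimator) with the method recorded in the result. "Two-sided"
sums the probability of all tables no more probable than the observed one,
with a 1e-7 relative log-probability tolerance against float ties.

## Cluster localization

Membership of a hit in a genomic cluster region uses full containment
(start ≥ region start and end ≤ region end, same chromosome, strand
ignored): mature-miRNA loci are ~22 nt, so containment and overlap almost
never differ, and containment is deterministic at region edges. The default
region, chr14:100,800,000–101,100,000 (hg38), covers the C14MC imprinted
cluster at 14q32; it is a config value because the cluster has no canonical
printed boundary. Locus strings accept both the ASCII hyphen and the
Unicode minus for the reverse strand (published tables mix the two) and are
always emitted in ASCII.

## Panel classifier

The classifier is a soft-margin linear SVM (hinge loss, L2 penalty, C = 1,
tol = 1e-6 — unreported upstream, so documented assumptions) on
log₂(RPM+1) features of the oncofetal panel, trained on discovery ANL+LUAD
only; fetal samples are never classifier inputs. The solution of the convex
problem is deterministic. The published 13-weight score is shipped as a
literal formula with intercept 0 and no cutoff (none was published); its
feature convention in this package is log₂(RPM+1) so that an absent miRNA
contributes exactly 0 to the score. AUC is the Mann–Whitney rank statistic
with mid-ranks for ties, identical to trapezoidal integration of the
empirical ROC curve.

## Survival

Per miRNA, LUAD patients are positive at RPM ≥ 1 (inclusive) and negative
below. Kaplan–Meier uses the product-limit estimator; the log-rank test
uses pooled at-risk sets with the hypergeometric variance and processes
events before censorings at tied times. The screen is univariate at
p < 0.05 with no multiplicity correction by default (an optional BH switch
exists): the panel is small and the screen mirrors how candidate prognostic
markers are triaged. MiRNAs whose dichotomization yields a single stratum
are reported untestable rather than flagged. Patients without survival rows
are dropped with a logged count.

## Synthetic cohorts

The generator emulates the targeted two-cohort study design: discovery
FL=25/ANL=77/LUAD=63 and validation ANL=38/LUAD=389; planted classes
oncofetal (13, matching the reported panel size), fetal-only (20),
tumour-only (20), under-in-both (15), ubiquitous (30), silent (20), plus 50
high-abundance *background* miRNAs. Counts are negative-binomial
(dispersion k = 10, variance m + m²/k) around mean RPM × library size/10⁶,
with library sizes uniform on [5×10⁶, 2×10⁷] and a fixed per-miRNA
lognormal factor (σ = 0.4) scattering the "on" mean of 50 RPM; "off" cells
sit at 0.05 RPM. The background class closes the composition so each
sample's expected RPM total is 10⁶ — without it, column-sum normalization
would inflate the planted scale ~300-fold and destroy the presence/absence
ground truth; it mimics the bulk miRNome that dwarfs any deregulated panel
in real libraries.

Tumour heterogeneity: miRNAs reactivated in LUAD (oncofetal and
tumour-only classes) are expressed in each LUAD patient only with
probability 0.5 (`tumour_positive_fraction`), matching the low LUAD group
means and partial patient positivity seen for reported oncofetal panels;
this is also what makes RPM ≥ 1 dichotomization a non-trivial
stratification. Survival times are exponential with hazard
0.01 × HR^(positive), HR default 3, under independent exponential censoring
at rate 0.01 (≈ 50% events under the null). A 5/13 fraction of oncofetal
loci is planted inside the C14MC default region; all other loci are placed
outside it. One global seed feeds independent substreams for counts, loci
and survival, so adding one output never perturbs another.

What the generator does **not** emulate: batch effects, isomiR structure,
GC/length biases, correlated miRNA co-regulation, non-exponential hazards,
or covariate-dependent censoring. Passing planted-truth tests therefore
demonstrates the correctness and calibration of the procedure under a clean
overdispersed-count model, not its robustness to those real-data artifacts.

## Problem sizes and numerical choices

Planted-truth recovery and classifier transfer are evaluated over 20
simulated seeds at the full default cohort sizes (tests) and 10 seeds in
the acceptance script; survival calibration uses 1000 (tests) or 500
(acceptance) null replicates and 200 replicates at HR = 3 with 379
informative patients. Degenerate inputs are pinned: identical values in all
ANOVA groups give F = 0, p = 1; zero variance in both Welch groups with
equal means gives t = 0, p = 1; a survival comparison with no events gives
χ² = 0, p = 1; a zero-total-count sample is a normalization error rather
than NaN. Score accumulation is fixed left-to-right in panel order for
bit-reproducibility, and every writer emits tab-separated, '.'-decimal,
LF-terminated text so that pipeline runs are byte-identical under a fixed
config and seed.

## Known limitations

* The exact congruence test's enumeration bound is conservative; very
  balanced 3×3 margins at a few hundred observations route to Monte Carlo
  even though enumeration might be feasible.
* The ANOVA post-hoc and test transformation upstream of this package were
  not fully specified; both are config switches (`posthoc`, `pseudocount`)
  rather than a single guessed truth, and results can shift slightly
  between LSD and Tukey.
* The published scorer is treated as a literal formula; whether its
  coefficients were produced with feature standardization is unknown, so
  scores are comparable within a matrix but not calibrated probabilities.
* Survival analysis is deliberately univariate (no Cox regression or
  hazard-ratio confidence intervals).
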