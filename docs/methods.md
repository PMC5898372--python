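# Methods

## Data model

A cohort is an N × L matrix of categorical states. Every variable declares
an ordered alphabet (its states), one of which may be a reserved
missing/not-applicable label. Missingness is therefore an explicit state,
not a deleted row: the coupling analysis needs a rectangular matrix, and
column-level quality control — not row deletion — is the mechanism that
removes unreliable genotypes. Continuous covariates (age, BMI, weight,
height in cm, blood pressures, diagnosis age, disease duration) are
quantized into half-open decade bins [10k, 10(k+1)); the half-open
convention makes boundary values deterministic (60.0 → [60,70)). Raw values
are retained beside the binned states for descriptive summaries. Genotypes
are unordered allele pairs normalized to hom-ref / het / hom-alt; drugs are
absent/present indicators tagged with their therapy line (an optional
dose-class mode {absent, low, high} exists behind per-drug thresholds). The
response variable has exactly the states {Res, NonRes}, with Res meaning
HbA1c ≤ 7.0 % ("treat to target"); the boundary itself is a responder.

## Quality control

A SNP column is kept only if it passes three tests, all strict inequalities:
call rate > 0.90 (typed / total records); Hardy-Weinberg equilibrium
p > 0.05; minor allele frequency > 0.01. The HWE test is a goodness-of-fit
chi-square with maximum-likelihood allele frequencies and **one** degree of
freedom (three genotype classes, minus one estimated frequency, minus one),
which gives the closed forms χ² = 0 for exact HWE proportions and χ² = n
under complete heterozygote deficit. Missing cells count against the call
rate only; HWE and MAF see typed calls. An exact conditional test
(enumeration of heterozygote counts given allele counts, two-sided by
probability ordering) is available for small expected homozygote counts,
but the chi-square drives the pass/fail flag. Consequence worth knowing:
with nine clean SNPs, all pass HWE in only ≈ 0.95⁹ ≈ 63 % of cohort draws —
the surviving count has its mode, not its fixed value, at nine.

## Association stage

Genetic contrasts: dominant (het + hom-alt vs hom-ref), recessive (hom-alt
vs rest), over-dominant (het vs both homozygote classes), additive (allele
dosage 0/1/2, tested by the Cochran-Armitage score trend). Two-level
contrasts are tested by Pearson chi-square without continuity correction
(a flag enables Yates), falling back to Fisher's exact test when any
expected cell is below 5. Odds ratios are ad/bc with Woolf log-normal 95 %
intervals; zero cells get the Haldane-Anscombe 0.5 adjustment, always
flagged. Bonferroni m defaults to the number of tests actually run and is
exposed explicitly, because no principled universal m exists once model
families overlap. Group comparisons of continuous covariates gate on
Shapiro-Wilk normality at α = 0.05 per group: t-test / ANOVA on the
parametric branch, Mann-Whitney / Kruskal-Wallis otherwise, with the branch
reported.

## Mean-field coupling analysis and direct information

Frequencies are pseudocount-regularized:
f_i = (1−λ) f̂_i + λ/q_i and f_ij = (1−λ) f̂_ij + λ/(q_i q_j) for i ≠ j,
with the same-site joint diagonal by construction. The default λ = 0.5 is
the canonical mean-field choice; any λ > 0 guarantees an invertible
correlation matrix. No sample reweighting is applied — patients are
distinct individuals, so the sequence-similarity reweighting of protein
applications has no analogue here (a uniform-weight hook exists).

The connected correlation matrix C_ij(x,y) = f_ij(x,y) − f_i(x) f_j(y) is
assembled on reduced state spaces: each variable drops one reference state
(by default the last in schema order), contributing q_i − 1 rows. Couplings
are e_ij = −(C⁻¹)_ij on reduced states, gauge-completed with zero reference
rows/columns; fields follow from the mean-field consistency relation
h_i(x) = ln f_i(x)/f_i(ref) − Σ_j e_ij(x,·)·f_j. The partition function Z
is never computed — it cancels out of everything downstream. Alphabets are
heterogeneous throughout: all block indexing carries an explicit offset
map rather than assuming a fixed q.

For each pair, the two-site distribution
P_ij ∝ exp(e_ij + h̃_i + h̃_j) is fitted so its marginals match f_i, f_j:
alternating scaling of the auxiliary fields until the worst marginal
residual is below 1e-6, with a 500-iteration budget. On near-degenerate
blocks (extreme couplings from nearly collinear columns) that iteration
stalls at a sublinear rate, so a damped Newton refinement of the convex
dual (logsumexp(e + h̃_i + h̃_j) − f_i·h̃_i − f_j·h̃_j, whose gradient is
exactly the marginal mismatch) finishes the fit; residuals are always
recorded and unconverged pairs flagged. Direct information is the KL
divergence of P_ij from f_i ⊗ f_j in nats, with 0·ln 0 = 0 and clipping of
negative rounding residue above −1e-10. DI is gauge-independent (tested to
1e-8 under reference-state changes); at L = 2 the whole pipeline agrees
with independent exact enumeration of the inferred two-site model to
better than 1e-4. Note what that equivalence does *not* claim: the
mean-field two-site model reproduces the empirical pair distribution only
to O(coupling²), so agreement with the empirical joint is a weak-coupling
statement, not a general one.

## Network construction and ranking

The Chow-Liu step finds the spanning tree maximizing summed pairwise
dependence. Classically the weights are mutual information; here they are
DI, which discounts transitively induced correlation. "Maximum-weight over
DI" and "minimum spanning tree over negated DI" are the same tree; the
maximization phrasing is the one that matches the Chow-Liu objective.
Kruskal with deterministic tie-breaking ((−weight, name, name) ordering on
lexicographically sorted pairs) makes the output reproducible under equal
weights. Edges stay undirected; no orientation or conditional-probability
tables are estimated. Factor-response connectivity is reported as the rank
of each factor's DI-with-response inside the pool of all L(L−1)/2 pairwise
DI values (rank 1 = strongest pair in the whole model). Export formats:
edge-list TSV, GraphML, DOT (drug nodes hexagonal, everything else oval).

## Response prediction

Score_Res(patient) = Σ_i e_{i,resp}(x_i, Res) and analogously Score_NonRes,
summing over every profile factor except the response itself. The
prediction compares the two scores **after adding the response variable's
own field h_resp to each** — the model's log class prior. The pure coupling
sums carry no prevalence information: with no signal they are symmetric
noise and would predict at chance, whereas a cohort with a 71 % majority
class should fall back to that majority. Including h_resp restores exactly
that behavior (null and label-permuted cohorts score at the majority rate),
and with the reference gauge on the response it reduces to a single scalar
offset. Exact ties predict NonRes, the majority class, and are counted.

Leave-one-out cross-validation refits the full mean-field model for every
fold on the remaining N−1 profiles. The refit is implemented by downdating
the one-hot Gram matrix by the held-out row — arithmetically identical to
recounting from scratch, and verified against a from-scratch refit in the
tests — so the held-out label never touches its fold's frequencies. Each
fold costs one block-matrix inversion (dimension Σ(q_i − 1) ≈ 110 for the
default cohort), keeping 495 refits at desk scale. A fold that loses a
state entirely is carried by the pseudocount mass, which is why LOOCV
requires λ > 0. Reported rates: plain accuracy, per-class recalls, their
mean (balanced accuracy) and maximum, majority baseline, and tie count —
both accuracy readings are emitted because "average prediction rate" can
mean either.

## Synthetic cohort generator

The generator emulates the study conditions, not any particular dataset:
N = 495 patients; fourteen SNPs — nine clean ones at the minor-allele
frequencies recoverable from the published genotype tables (0.02–0.39),
two HWE violators, three near-monomorphic (MAF < 0.01) — so nine survive
QC in the modal draw; 21 drug-line indicator columns at the published
usage rates; normal covariates at the published means/SDs, clipped and
decade-binned; per-column call rate 0.97 (the study does not quantify its
missingness; this is a free choice). HWE violation is parameterized by the
inbreeding coefficient F via genotype probabilities
(p² + Fpq, 2pq(1−F), q² + Fpq) — a one-parameter, sign-definite
heterozygote deficit, the simplest mechanism that fails the HWE test.

The response is logistic over planted state indicators. The intercept is
solved by bisection so the expected responder fraction matches the study's
28.7 % split. The planted effect set couples the two K-ATP-channel SNPs at
the modest published odds-ratio magnitudes (1.33, 1.27) and puts the bulk
of the signal on treatment-line indicators (strong negative weights on
insulin escalation — confounding by indication — positive on first-line
metformin) and on diagnosis age / duration / BMI. The set was calibrated
once so the planted Bayes-optimal accuracy is ≈ 0.86 against a ≈ 0.71
majority baseline, giving the mean-field classifier measurable headroom;
the published real-cohort prediction rates are not a reproducible target
and are not used for tuning. HbA1c values are drawn from truncated normals
around the published responder / non-responder means, consistent with the
class labels by construction.

Tree-structured cohorts come from an explicit tree-factorized joint
(root marginal plus row-stochastic child-given-parent tables along a
root-to-leaf orientation), with a helper that draws uniform random
topologies (Prüfer sequences) and state-copying conditionals of chosen
strength. Everything is reproducible from (config, seed).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: linkage disequilibrium between SNPs (beyond an
optional identical-copy pairing), correlation among clinical covariates
(age and diagnosis age are drawn independently), treatment-assignment
dynamics, longitudinal HbA1c trajectories, and any non-logistic response
mechanism. Structure-recovery results on tree-generated cohorts say the
method recovers trees when the truth is a tree, not that patient data is
tree-distributed.

## Numerical choices and problem sizes

- Pseudocount λ = 0.5 default everywhere; network/structure tests use
  λ = 0.05 because structure recovery benefits from lighter damping at
  large N.
- Two-site tolerance 1e-6 on the marginal residual; Newton fallback
  targets 1e-9; DI negativity tolerance 1e-10.
- Frequency-model invariants (normalization, marginal consistency,
  symmetry) are asserted at 1e-12.
- Reference states default to the last schema state; DI's gauge
  independence makes the choice inconsequential and tested.
- Validation problem sizes: two-variable oracles at N = 2000–10000;
  Chow-Liu brute-force enumeration up to 7 nodes (Prüfer enumeration of
  n^(n−2) trees, 100 instances); structure recovery on 8-variable trees at
  N ∈ {200, 1000, 5000} over 10–20 seeds; planted-OR recovery over 200
  study-scale replicates; null calibration over 1000 cohorts of n = 200;
  LOOCV regimes at n = 200–495. These sizes make every suite a
  desk-scale run while keeping Monte-Carlo standard errors well inside the
  asserted tolerances.

## Known limitations

- Mean-field inversion is a weak-coupling estimator; couplings on nearly
  collinear columns are damped by the pseudocount rather than resolved.
- The additive score ignores factor-factor couplings at prediction time;
  it is a main-effects read-out of a pairwise model.
- Bonferroni correction treats all tests as exchangeable; no FDR option.
- The HWE chi-square is anticonservative when expected homozygote counts
  fall below ~1 (near-monomorphic SNPs); the exact test exists but does
  not drive the default flag.
- `origin` is a free categorical variable; the package imposes no
  geographic granularity.
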