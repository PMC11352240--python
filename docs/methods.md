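# Methods

## Problem setting

The input is a cohort of tumor samples with somatic mutation calls, a scored
gene-interaction network, and a clinical table with overall-survival
endpoints. Binary mutation profiles are extremely sparse (98–99.5% zeros in
typical exome cohorts) and mutations in different members of the same
pathway are effectively synonyms, so distance in raw mutation space is
nearly useless for subtype discovery. The pipeline addresses both problems:
network diffusion shares each mutation's signal with its interaction
neighborhood, and the autoencoder compresses the smoothed profiles into a
dense latent space where resampling-based clustering is stable.

## Mutation matrix

Variant calls (MAF-style or bare patient/gene pairs) collapse into a binary
patients × genes matrix: 1 iff the patient carries ≥1 retained variant in
the gene, regardless of multiplicity. Nonsense mutations are excluded by
default; the exclusion set is fully configurable because the biologically
surprising choice (truncating variants are usually *kept*) should not be
hard-wired. Patients and genes are sorted lexicographically at
construction, which makes every downstream artifact order-deterministic.

## Network and propagation operator

Edge lists are canonicalized (undirected, self-loops dropped, duplicate
pairs keep the maximum score). The confidence filter retains edges scoring
at or above the (1 − keep_fraction) quantile — default top 10% — with all
threshold ties kept, so the result is deterministic across platforms at the
cost of occasionally exceeding the nominal fraction. An optional
`prefilter_min_score` reproduces the two-stage convention of databases that
publish a "medium confidence" cutoff. After filtering the network is
unweighted.

The propagation operator is the row-stochastic random-walk normalization
W = D⁻¹A restricted to the analysis gene universe; genes with no edge
inside the universe get a unit self-loop, so W remains row-stochastic and
their signal passes through unchanged. Symmetric normalization
D^(−1/2)AD^(−1/2) is available as a sensitivity switch. Mutation-matrix
genes absent from the network are dropped by default (`intersect` policy,
with a logged report), since diffusion is undefined for them; `keep_unmapped`
retains them as self-loop nodes.

## Diffusion

The random walk with restart

    F_{t+1} = α F_t W + (1 − α) F0,  α = 0.7 (default)

is provided in three modes. `one_step` (the pipeline default) applies the
update once. `iterative` iterates to the fixed point with a Frobenius-norm
stopping rule (tolerance 1e-6, max 100 iterations; non-convergence sets a
flag rather than raising). `closed_form` solves
F (I − αW) = (1 − α) F0 densely and serves as the verification oracle; it
is guarded to ≤2000 genes. Because W is row-stochastic, both update terms
preserve each patient's total mutation mass, giving a sharp invariant
(row sums conserved to 1e-9) that the tests exploit. One-step and converged
diffusion differ substantially entrywise (max |Δ| ≈ 0.5 on the default
synthetic cohort) but yield equivalent downstream stratifications, which is
why the cheap variant is the default.

## Autoencoder

Architecture 500–100–500 (ReLU hidden layers, sigmoid output), latent
dimension 100, loss L = (1/n) Σᵢ ‖xᵢ − x̂ᵢ‖² (mean over patients of the
squared reconstruction-residual norm), Adam with learning rate 1e-4, batch
size 32, at most 150 epochs, seeded 90/10 train/validation shuffle split.
The implementation is plain numpy — forward pass, backpropagation and Adam
— which keeps training exactly reproducible under a seed (two identical
seeds agree to machine precision) and removes any framework dependency.

Because the sigmoid output layer can only produce values in (0, 1), inputs
are min-max scaled per gene to [0, 1] before training (constant genes map
to 0); the scaling record is stored with the encoder. Weights are
initialized fan-in uniform, U(−1/√fan_in, 1/√fan_in), biases at zero.

Early stopping is **off by default**. On desk-scale cohorts (a few hundred
patients) the validation loss traces a long noisy plateau between roughly
epochs 20 and 100 — the network first learns the per-gene means, then
slowly reorganizes the bottleneck — and any short patience window reliably
halts inside the plateau, yielding a latent space that has not yet
separated the cohort structure (planted-subtype recovery drops from
ARI ≈ 1 to ≈ 0). Training the full 150-epoch budget is cheap (~20 s at
300 × 2000 on one CPU) and robust; patience-based stopping with
best-weights restoration remains available via
`EncoderConfig(early_stopping_patience=...)` for larger cohorts.

Latent features carry no intrinsic order or meaning and are not
identifiable across retrains; downstream code treats the EM as an opaque
embedding.

## Consensus clustering

Monti-style consensus over K-means: per repetition, ⌊0.8·n⌋ patients and
⌊0.8·d⌋ features are sampled without replacement (the same subsample is
reused across k, as in the standard implementation), K-means (k-means++,
best of 10 restarts) partitions the subsample for each k ∈ [2, 6], and the
consensus matrix entry is #co-clustered / #co-sampled — pairs never
co-sampled get 0. EM features are z-scored first ("appropriate scaling";
range scaling is available via config). Final labels cut an
average-linkage tree on the distance 1 − CM at k; empty clusters are
recorded as warnings, never silently merged. Each repetition draws its RNG
as master seed + repetition index, so the whole procedure is reproducible
bit-for-bit and individual repetitions are independently re-derivable.

Diagnostics per k: PAC (fraction of off-diagonal consensus entries inside
(0.1, 0.9)), consensus CDFs, mean within- and between-cluster consensus.
No k is selected automatically — in this method the choice is made by
clinical association, so the diagnostics inform but do not decide.

Heatmaps order patients by final label, then dendrogram leaf order within
label, on a white-to-blue scale.

## Survival and clinical evaluation

Kaplan–Meier and the k-group log-rank test are implemented natively: the
product-limit estimator, and the observed-minus-expected event vector with
the multivariate-hypergeometric covariance, χ² on k − 1 df (pseudo-inverse
for the reduced covariance, making the statistic invariant to group
relabeling). The native implementation is cross-checked against lifelines
in the test suite.

Cox proportional-hazards models use lifelines (Efron tie handling, Wald
95% CIs); the proportional-hazards assumption is checked with the
scaled-Schoenfeld rank test and reported alongside. Multi-level terms get
a global Wald χ² p-value. Collinear or separated designs are refit with a
tiny ridge (1e-4) and flagged, so that degenerate subtypes (e.g. a
two-patient cluster with zero events) are reported with warnings rather
than dropped — rare tiny subtypes are a real output of stratification and
should stay visible. The covariate-free null model's partial likelihood is
computed in closed form (Efron: the j-th of d tied events contributes
−log(n_t − j)), so likelihood-ratio tests against an empty baseline are
exact counterparts of the lifelines fits.

The multivariate procedure: univariate screen at p < 0.2; backward
elimination removes the largest-p term while any p > 0.05 (on correlated
covariates other removal orders could select differently — the iterative
largest-p rule is the standard choice); the baseline (selected covariates)
and full (baseline + subtype) models are fit on the complete-case rows of
the *full* design so the likelihood-ratio test compares nested models on
identical data.

Association tests dispatch by variable type: continuous → Kruskal–Wallis
(>2 groups) or Wilcoxon rank-sum (2 groups); categorical → Fisher's exact
for 2×2 tables with any expected count ≤ 5, otherwise Pearson's χ².
Exact tests for r×c tables beyond 2×2 are not available in the scipy
backend; such tables fall back to χ² with an explicit note on the result.
Missing values are excluded listwise per variable and the non-missing N is
reported.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes, at
desk scale:

- **Network**: genes partitioned into modules of 25 (default); in-module
  edges drawn with probability 0.3, background edges with probability
  0.0325 across module boundaries. Confidence scores are uniform draws,
  but in-module edges score in [0.9, 1] and background edges in [0, 0.9],
  with background edges outnumbering module edges ≈9:1 — so the default
  top-10% filter genuinely selects the interaction skeleton, mimicking how
  curated confidence scores concentrate on true interactions. A filter fed
  scores uncorrelated with structure would keep a uniformly random tenth of
  the edges and no network method could work, so score–structure
  correlation is a modeling requirement, not a convenience.
- **Mutations**: each of the k subtypes owns 2 disjoint driver modules
  (50 genes); a patient mutates driver genes with p_driver = 0.2 and all
  other genes with a background rate derived from the target sparsity
  (default 0.99 → p_bg ≈ 0.005 at 2000 genes). Infeasible targets raise an
  error stating the implied bound. Patients left with zero mutations
  receive one forced driver mutation, since real cohorts condition on
  having mutation calls.
- **Survival**: exponential event times with per-subtype hazards (default
  0.04/0.02/0.01 per month — 2-fold spread), independent uniform censoring
  on [0, 60] months, plus neutral covariates (age ~ N(65, 10), sex) that
  carry no survival signal.

Defaults (300 patients × 2000 genes, 3 subtypes) keep the full pipeline
around a minute of CPU. What the generator does **not** emulate: mutational
signatures, gene-length effects, hypermutators, subtype-specific mutation
burden, inter-database identifier noise, or covariate–survival
confounding. Passing tests therefore demonstrate the machinery recovers
planted modular-driver structure under realistic sparsity — not that any
particular real cohort will stratify.

Setting p_driver = p_bg severs the signal entirely and is used for null
calibration: recovered labels then have |ARI| ≈ 0 against the planted
subtypes and log-rank p-values are uniform.

## Problem sizes used in the tests

Unit and property tests run on fixtures from a few genes up to 80 × 600.
The end-to-end recovery check runs the full default cohort (300 × 2000,
200 consensus repetitions). Null calibration uses 20 replicates of a
reduced instance (120 × 400, small encoder, 60 repetitions, k ≤ 4), chosen
because null-ARI behavior does not depend on scale. The acceptance script
regenerates the default cohort and reruns the complete pipeline from a
user-supplied seed.

## Known limitations

- The one-step diffusion is a deliberate approximation; its entrywise
  values are not comparable across networks with different degree
  distributions (only the downstream stratification is).
- Min-max input scaling makes the autoencoder sensitive to single outlier
  patients in a gene column; quantile normalization of the smoothed matrix
  is intentionally not applied but may help on heavy-tailed real data.
- K-means consensus assumes roughly isotropic latent clusters; elongated
  or nested structures would need a different base clusterer.
- Fisher's exact test beyond 2×2 is unavailable; sparse large contingency
  tables are tested by χ² with a warning.
- The backward-stepwise selection inherits the usual instability of
  stepwise procedures on strongly correlated covariates.
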