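# d3ns — network-smoothed stratification of tumor mutation profiles

Somatic mutation calls are a poor direct substrate for discovering tumor
subtypes: the binary patient × gene mutation matrix is ~99% sparse, and two
patients with the same disrupted pathway rarely share the same mutated gene.
`d3ns` stratifies patients by first *smoothing* each mutation profile over a
gene-interaction network, then *compressing* the smoothed profiles with a
deep autoencoder, and finally *clustering* the latent features with
resampling consensus K-means. Recovered subtypes are scored against overall
survival and clinical covariates. It is aimed at computational
oncologists working with cohort-level mutation calls (MAF-style exports) and
public interaction databases (STRING, HumanNet, Mentha edge lists).

## Method

1. **Mutation matrix.** Variant calls collapse into a binary matrix
   `F0` (patients × genes); an entry is 1 if the patient has at least one
   retained variant in that gene. Nonsense variants are excluded by default
   (configurable).
2. **Network smoothing** (random walk with restart). With `W` the
   degree-normalized adjacency of the top-10%-confidence interaction
   network,

   `F_{t+1} = α F_t W + (1 − α) F0`,   α = 0.7.

   The pipeline default applies the update once
   (`F = α F0 W + (1 − α) F0`); the iterated fixed point and the closed form
   `(1 − α) F0 (I − αW)^{-1}` are available for verification.
3. **Autoencoder.** The smoothed matrix, min-max scaled per gene, is
   compressed by a 500–100–500 fully connected autoencoder (ReLU hidden,
   sigmoid output), trained to minimize the per-patient reconstruction error
   `L = (1/n) Σᵢ ‖xᵢ − x̂ᵢ‖²` with Adam (lr 1e-4, batch 32, ≤150 epochs,
   90/10 train/validation split). The 100-unit bottleneck output is the
   encoded matrix (EM).
4. **Consensus clustering.** For each k = 2..6, K-means is run on 1000
   resamples of 80% of patients and 80% of (z-scored) latent features; the
   consensus matrix holds the fraction of co-sampled runs in which each
   patient pair co-clustered. Final labels cut an average-linkage tree on
   1 − CM at k. PAC and within/between-consensus diagnostics are reported;
   k is chosen by the analyst (typically by clinical association).
5. **Evaluation.** Kaplan–Meier curves with the k-group log-rank test,
   univariate and backward-stepwise multivariate Cox models (baseline vs
   baseline + subtype compared by likelihood-ratio test), and
   Kruskal–Wallis / Wilcoxon / Fisher / chi-squared association tests.

## Worked example

Generate a synthetic cohort (300 patients × 2000 genes, 3 planted subtypes
with 2-fold hazard spread, ~99% sparsity) and run the full pipeline:

```sh
d3ns simulate --out cohort/ --patients 300 --genes 2000 --k-true 3 --seed 1
d3ns build-matrix --mutations cohort/mutations.tsv --dialect pairs --out mm.tsv
d3ns smooth --matrix mm.tsv --network cohort/network.tsv --alpha 0.7 --out nsm.npz
d3ns encode --nsm nsm.npz --latent-dim 100 --seed 2 --out em.tsv
d3ns cluster --em em.tsv --k-min 2 --k-max 6 --reps 200 --seed 3 --outdir clusters/
d3ns evaluate --labels clusters/labels_k3.tsv --clinical cohort/clinical.tsv --out eval.csv
```

Along the way the tools print the realized cohort characteristics
(`300 patients x 1619 genes, sparsity 0.9877` — genes never mutated in any
patient carry no information and are dropped at matrix construction), and
the final step prints:

```
log-rank chi2=25.255 (df=2), p=3.28e-06
```

meaning the three recovered subtypes separate overall survival far beyond
chance — expected here, because the cohort was planted with per-subtype
exponential hazards of 0.04/0.02/0.01 per month. `clusters/diagnostics.csv`
reports PAC per k (0.0 at k = 3 on this cohort: every patient pair is
either always or never co-clustered), and comparing
`clusters/labels_k3.tsv` with `cohort/truth.tsv` gives an adjusted Rand
index of 0.99.

The same run is available as a single call (`d3ns run --config run.yaml`)
or through the Python API (`d3ns.pipeline.run_all`), which writes every
intermediate artifact plus a manifest with checksums, timings and seeds.

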