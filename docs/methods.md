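# Methods

## Model

`dazzle` infers a gene regulatory network (GRN) from a cells × genes
single-cell expression matrix X (natural-log scale) under a linear
structural equation model (SEM):

    X = X A + Z,

where A ∈ ℝ^{m×m} is a weighted adjacency matrix (entry (i, j): influence of
regulator gene i on target gene j, diagonal fixed at 0) and Z is per-cell,
per-gene Gaussian noise. Rearranged,

    Z = X (I − A)        and        X = Z (I − A)^{-1},

the residual Z acts as a latent variable and the two rearrangements form an
encoder/decoder pair, trained as a variational autoencoder: the encoder
produces a posterior mean and log-variance per cell, gene and latent
channel; the decoder reconstructs the input from a reparameterized sample
by solving a linear system against (I − A) (never an explicit inverse — a
failed solve aborts with an advisory, since it signals divergence).
Small neural nets, *shared across genes*, wrap both sides: a feature net
lifts each expression value to d channels before the (I − A) mixing, and an
output net maps the decoded channels back to expression space. They are
residual around an exact linear path (their final layers initialize at
zero), so at initialization the model is exactly the linear SEM, and with
`identity_nets=True`, exactly so forever. The latent prior is a closed-form
standard normal.

### Dropout augmentation

Single-cell data is zero-inflated by dropout. At every optimizer step a
fresh Bernoulli(p) mask M is drawn over all positions and the noise term
E = −X ⊙ M is added, i.e. masked entries are temporarily zeroed on the log
scale; the model only ever sees the corrupted X′ = X + E, so it cannot
memorize any particular realization of the dropout pattern. An auxiliary
classifier — a narrow 3-layer tanh MLP over the latent state followed by a
sigmoid — predicts which entries were masked; its binary cross entropy
joins the objective, encouraging the latent space to segregate
dropout-like values. Default p = 0.1.

### Objective

    L = recon + α Σ|A| + β KL + γ BCE

- recon: squared reconstruction error summed over genes, averaged over
  cells (Gaussian likelihood with unit variance).
- KL: mean over cells of Σ over gene-channels of
  ½(exp(log σ²) + μ² − 1 − log σ²).
- Σ|A|: L1 over off-diagonal entries, held at **zero for the first
  `sparse_delay` = 5 iterations**. Introducing sparsity only after the
  adjacency gradients have stabilized prevents the failure mode where the
  L1 term is prioritized early and the whole adjacency collapses to zero.
- BCE: classifier cross entropy, averaged over all entries (so γ is
  resolution-independent).

One Adam optimizer updates everything, with learning rate 2e-5 on A and
1e-4 on all nets; batch size 64; 120 iterations (full passes); cells are
shuffled each iteration with the seeded generator. The adjacency diagonal
is re-zeroed after every step. Ensembling (`ensemble_runs=k`) averages |A|
over k runs seeded consecutively; ranking uses |weight| throughout, since
the model does not sign regulatory effects.

### Gradient machinery

Training runs on a small reverse-mode automatic-differentiation core
(`dazzle.autodiff`) over float64 numpy arrays. It implements exactly the
operations the model needs, including the gene-axis product with (I − A)
and its inverse via linear solves, with analytic vector-Jacobian rules
(checked against central finite differences in the test suite). Float64 on
CPU makes seeded runs bitwise reproducible.

## Numerical and design choices

These were genuinely open (no printed values to follow) and were fixed
once, from mechanism pilots on the reference synthetic world, before the
acceptance experiments were frozen:

- **Internal standardization.** Each gene is z-scored inside `train`
  (means/sds kept on the returned parameters). Log expression has large
  positive per-gene means; without centering, the adjacency gradient is
  dominated by a uniform mean-offset component and every entry grows at
  the same rate, destroying the ranking. Augmentation masks are applied
  *before* standardization, so a synthetic dropout lands at the same
  standardized value (−μ/σ) as a real one.
- **α default 0.01.** The L1 term is a sum, so its per-entry gradient is α
  itself. The data-term gradient per entry at these learning rates is
  O(0.01–0.3); α ≥ 0.1 makes the L1 pull dominant for every entry and
  collapses A to zero regardless of the delay. α is exposed (and a
  `--alpha-small` preset sets 0.01 explicitly, mirroring the advice to use
  very small sparsity pressure for hard, celltype-specific references).
  β = γ = 1.
- **Posterior log-variance initialized at −4** (std ≈ 0.14). A unit-variance
  initial posterior injects latent noise of the same magnitude as the
  standardized data and drowns the covariance signal during the short
  training schedule; the head remains fully learned.
- **Classifier head**: width 16 (its input is d = 1 channels; a wide MLP
  adds cost, not capacity), random hidden biases (a bias-free tanh net is
  an odd function and cannot express the even "magnitude ≈ dropout point"
  feature), output weights zero and output bias at logit(p) (starting
  calibrated to the base rate removes the transient that otherwise
  consumes the whole schedule).
- **Adjacency init** ~ N(0, 1e-4): (I − A) starts well conditioned and the
  L1 subgradient is silent until data moves entries.
- Ties in edge rankings break lexicographically by (regulator, target);
  metric tie handling is the block rule (AUPRC) and pro-rata (early
  precision).

## Synthetic data

The generator (`dazzle.synthetic`) realizes exactly the model's
assumptions: a sparse signed adjacency (off-diagonal entries present with
probability `density`, weights uniform ±[0.5, 1] × `weight_scale`,
globally rescaled to spectral radius ≤ 0.8), expression X = Z(I − A)^{-1}
with Z ~ N(0, noise_scale²) generated directly on the log scale, shifted
by the global minimum and floored at zero (so dropout zeros sit at the
matrix minimum, as in real data), and i.i.d. Bernoulli dropout on the
observed matrix. Cycles are allowed — only the spectral-radius bound is
enforced, matching the model's lack of an acyclicity constraint.

The reference study condition used throughout the tests is m = 50 genes,
n = 500 cells, density 0.05, unit weight and noise scales, 20% dropout,
generator seed 7. These sizes keep every experiment (including the 20-run
stability suite and the 300-iteration over-training comparison)
desk-scale; they are the package's own choice of a small but
non-trivial recovery problem.

What the generator does **not** emulate: count-level (negative binomial)
noise, library-size variation, batch effects, pseudotime or branching
trajectories, and TF-biased network topology. Passing recovery tests
therefore show that the estimator recovers the structure its own model
assumes under dropout corruption — a necessary condition — not that it
matches its measured performance on real benchmark data.

## Evaluation

Candidates are all ordered (TF, gene) pairs *including TF self-pairs*
(e.g. 410 TFs × 1,410 genes = 578,100 candidates); the inferred network
scores each candidate by |weight| and the reference labels it. Metrics:
average precision (non-interpolated, block tie rule) and its ratio to the
positive-class fraction (AUPRC ratio); early precision within the top-k
(k = number of true edges, pro-rata at a tied k-th score) and its ratio to
edge density (EPR); Mann–Whitney AUROC. Predictions outside the candidate
universe are dropped with a logged count; reference edges with endpoints
missing from the expression matrix are dropped before k is computed.

## Known limitations

- Memory and time scale with m² through the adjacency; very large gene
  sets (10⁴+) are slow on pure CPU.
- The model ranks |weight| but cannot sign effects, and enforces no
  acyclicity.
- At the benchmarked learning rates the adjacency stays small in
  magnitude (the reporting threshold is 0.001); weights are rankings, not
  effect-size estimates.
- The L1 weight α interacts with data scale; the 0.01 default assumes
  standardized input (which `train` guarantees internally).
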