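# Methods

## Model

`spotdecon` treats spot deconvolution as supervised fraction regression on
simulated mixtures, transferred to real spots by adversarial domain
adaptation (an ADDA-style scheme with a *shared* feature embedder).

**Pseudospot simulation.** From an annotated single-cell reference subset
to the marker panel, each pseudospot draws `k` cells uniformly without
replacement (with replacement across pseudospots) and weights
`w_i = u_i / Σ u_j`, `u_i ~ Uniform(0,1)` i.i.d. The composite profile is
`Σ w_i · x_i` computed on log-normalized expression, and the label is the
weight mass per cell type. The normalized-uniform weight law is an
assumption (a Dirichlet(α₀) alternative is exposed via `weight_law`);
mixing in log space rather than count space is deliberate — real spots mix
transcripts before log transformation, and this discrepancy is part of the
domain gap the adversarial phase is meant to absorb.

**Architecture.** Embedder `f`: genes → 1024 → 64, each stage affine +
batch normalization + ELU (α = 1.0). Source head `S`: one affine layer
64 → K with softmax. Domain head `D`: 64 → 32 affine + batch-norm + ELU +
dropout (rate 0.5) → 1 with sigmoid. The embedder parameters are literally
shared by both heads. Initialization: Glorot-uniform weights, zero biases,
batch-norm γ = 1, β = 0. The network and its backpropagation are
implemented directly in numpy (float32 internally).

**Losses.** With ε = 1e−8 clipping inside logs and 0·log 0 ≡ 0:

* `L_s = mean_s Σ_k Y_{k,s} log(Y_{k,s} / S_k)` (KL divergence),
* `L_adv,1 = mean(−log D(f(X_p)) − log(1 − D(f(X_r))))` (inverted labels),
* `L_total = L_s + α·L_adv,1`,
* `L_adv,2 = mean(−log D(f(X_r)) − log(1 − D(f(X_p))))`.

`D` outputs a single sigmoid probability; with scalar targets the two
binary cross-entropy forms above are exactly the printed losses.

## Training procedure

Pretraining minimizes `L_s` alone for `pretrain_epochs` (default 10)
epochs over the pseudospot set. Each subsequent iteration then performs:

1. **Phase A, source step** — one Adam step on `L_s` over a pseudospot
   minibatch, updating `f` and `S`.
2. **Phase A, adversarial step** — one Adam step on `α·L_adv,1` over the
   pseudospot minibatch plus an equal-size real-spot minibatch, updating
   `f` only; gradients flow through the frozen `D`.
3. **Phase B** — one Adam step on `L_adv,2` over the concatenated
   minibatch, updating `D` only, at its own learning rate.

The two phase-A objectives use *independent* Adam states. This mirrors
training the source and adversarial paths as separately compiled models
and matters empirically: folding both terms into a single optimizer lets
the adversarial gradient contaminate the source-loss moment estimates, and
in our benchmarks that variant erased the adaptation benefit and degraded
no-shift recovery. Real spots are sampled with replacement when fewer than
`batch_size` exist.

**Freeze semantics.** A frozen block forwards with the current minibatch's
batch-norm statistics and active dropout, but its parameters and running
statistics are never written (asserted by content hashes each iteration
when `check_freeze` is on). Inference always uses running statistics, so
predictions are independent of batch composition.

**Batch normalization.** ε = 1e−5; running statistics are exponential
moving averages with momentum 0.9, updated only in the phases that train
the block owning them (the embedder's statistics therefore see both
domains during phase A, which itself contributes a mild covariate-shift
correction).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `l` (`n_markers`) | 20 | markers per cluster (10 suits smaller panels) |
| `k` (`k_cells`) | 8 | cells per pseudospot (2 for bead-scale data, ~10 for dense tissue) |
| `n` (`n_pseudospots`) | 20 000 | pseudospots (up to 5×10⁵ for very large spot sets) |
| `iterations` | 3000 | adversarial iterations |
| `batch_size` | 512 | minibatch per domain |
| `lr_domain` | 0.005 | Adam rate for `D` |
| `lr_main` | 0.001 | Adam rate for pretraining and phase A |
| `α` | 0.6 | adversarial loss weight (1.0 for the lung-style setting) |
| `pretrain_epochs` | 10 | epochs of `L_s`-only pretraining |
| `target_sum` | 1e4 | per-sample count normalization target |

`lr_main`, `pretrain_epochs` and the dropout rate are our choices where the
training scheme leaves them open; all are exposed.

## Preprocessing

Fixed order, enforced by a layer-tag state machine: per-sample total-count
normalization to `target_sum` → log1p → subset to the pooled marker panel
(intersected with the spatial gene set, panel order, exact string match) →
per-sample min–max scaling to [0, 1]. Scaling happens after subsetting,
since the model only sees panel genes; a constant sample maps to all
zeros. Marker selection uses a one-sided (enrichment) Wilcoxon rank-sum
test per gene with tie-corrected variance and 0.5 continuity correction on
log-normalized values, BH adjustment within each cluster comparison, and
deterministic tie-breaks (adjusted p, then descending rank-sum statistic,
then gene id). No fold-change or detection-rate filter is applied.

## Evaluation

`roc_auc` is the Mann–Whitney statistic (half credit for ties);
`auc_significance` is the one-sided rank-sum p-value (exact enumeration
when both groups have ≤ 25 spots and no ties, tie-corrected normal
approximation otherwise), Bonferroni-corrected by the caller across
(cell type × slide) tests at 0.05. Spots labelled `unknown` are excluded
from both sides. The tissue-domain ranking scales each type's fraction to
[0, 1] across spots, ranks types within a region by in/out mean ratio
(infinite ratios first, ties by BH-adjusted p), drops types with in-region
scaled mean < 0.2, and reports the top 7.

## Synthetic data

`make_reference` draws counts from a gamma–Poisson (negative binomial,
dispersion θ = 2) with per-gene log-normal baseline means, per-cell
log-normal library factors (σ = 0.3), and a disjoint marker block per type
multiplied by `fold_change`. `make_spatial` composes spots exactly like
pseudospots but on raw counts, optionally with region-specific type priors
(allowing region-restricted types with exactly zero out-of-region truth),
then applies the domain shift: global library scaling, per-entry
multiplicative log-normal noise, independent dropout.

The generator reproduces the statistical skeleton the method relies on —
cluster-separated references, mixture spots, a pseudospot/real-spot gap —
but not spatial autocorrelation, cell-size differences, segmentation
noise, or platform-specific gene-detection biases. Passing benchmarks here
demonstrates correct mechanics and that adaptation helps under a
controlled shift; it does not certify accuracy on any particular tissue.

## Benchmark scale and observed behavior

Tests and the acceptance script run a reduced-scale benchmark chosen so
training completes in minutes on one CPU: 5 types × 250 cells, 200 genes
(panel ≈ 100 after marker pooling), 500 spots of k = 8 cells, 8000
pseudospots, 500 iterations at batch 256. At this scale the pretrained
baseline recovers true fractions at mean per-type Pearson ≈ 0.9 with no
domain shift, and under a strong shift (library ×5, noise sd 0.5, 30%
dropout) adversarial adaptation improves the localization AUC of a
region-restricted type over the no-adaptation baseline on every seed
tried. The improvement is modest because per-sample min–max scaling
already absorbs much of this synthetic shift; unstructured dropout noise
is information-destroying and no alignment can fully undo it.

## Numerical and degenerate-input choices

* All-zero samples pass normalization unchanged with a warning.
* Constant gene vectors receive rank-sum p = 1.
* Softmax and sigmoid are computed in numerically stable forms; losses
  clip probabilities at ε = 1e−8.
* Batches of fewer than 2 samples are skipped during pretraining (batch
  normalization is undefined there).
* Checkpoints round-trip through a single `.npz` file; save → load →
  predict agrees to 1e−6.
* With a fixed seed and single-threaded BLAS, runs are bitwise
  reproducible end to end.

## Known limitations

* Spot composition is modelled with a fixed `k` per pseudospot; varying
  local cell density is only absorbed indirectly by the adaptation.
* Rare cell types can be masked by dominant ones; rerunning on subclusters
  with their own markers is the intended workaround.
* The adversarial game is not guaranteed to converge; loss trajectories
  (`history_`) should be inspected, and `NN_wo_da` provides a sanity
  baseline.
* Min–max scaling per spot discards absolute expression scale by design;
  types distinguished mainly by total transcript abundance lose signal.
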