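# Methods

## Model and assumptions

The pipeline assumes that the evolutionary profile of a protein — the
L×20 position-specific scoring matrix (PSSM) a PSI-BLAST search produces —
carries enough signal to decide whether two proteins interact, and that
this signal survives compression to a fixed-size summary. Three modelling
commitments follow:

1. **Gram-matrix compression.** `P̂ = PᵀP` (20×20) removes length
   dependence. It is invariant to row (position) order, so positional
   information is deliberately discarded: what remains is the co-occurrence
   structure of amino-acid propensities across positions. The zero-padding
   alternative (keep the N-terminal 20 rows, zero-fill short proteins)
   retains raw positional scores for a tiny prefix and is kept only as an
   ablation arm. Truncation takes the N-terminal end; either choice is
   defensible and only consistency matters for the comparison.
2. **Denoising autoencoder features.** The flattened matrix is min-max
   scaled into [0,1] *per matrix* (a constant matrix maps to 0.5), because
   every layer, including the output, is sigmoid-bounded. Corruption is
   additive Gaussian with standard deviation `noise_sigma` (masking noise
   is available behind a config switch); noise is resampled every epoch;
   inference always encodes clean inputs. Per-matrix (rather than
   training-set) scaling keeps featurisation free of dataset statistics,
   at the cost of discarding overall profile magnitude.
3. **Pair encoding.** Concatenation of the two protein vectors. Since
   concatenation is order-sensitive while interaction is not, training
   augments each pair in both orders and prediction averages both
   orientations. This halves the symmetry error rather than eliminating
   it; a symmetric pooling (sum/product) would eliminate it but discards
   which-protein-carries-what information.

## Parameters

| Parameter | Default | Units / range | Why |
|---|---|---|---|
| DAE layer sizes | 400→256→128 | neurons | gentle two-step compression; latent 128 keeps ~1/3 of the input width |
| `noise_sigma` | 0.1 | input units (inputs are in [0,1]) | visible but non-destructive corruption |
| epochs / batch / lr | 100 / 64 / 1e-3 | — | Adam on a network this small converges well within this budget |
| GBDT | 500 trees, depth 6, lr 0.05 | — | standard boosted-tree operating point for a few thousand rows |
| HOG | 5-px cells, 2×2 blocks, 9 unsigned bins, L2 block norm | — | the standard published HOG recipe, which divides the 20×20 grid evenly |
| CV folds | 5 | — | the conventional protocol for PPI benchmarks |
| decision threshold | 0.5 | probability | no calibration argument favours another fixed value |

The optimiser is Adam; one seed drives weight initialisation, batch
shuffling and noise draws, so training is bit-reproducible on one machine.
The autoencoder is trained end to end (no layer-wise pretraining): at this
scale the joint optimisation is stable and simpler to reason about.

The ordered target statistic is implemented exactly as the prefix target
mean with an additive prior: item *i* at position *p* of permutation σ
receives `(Σ_{j<p, same category} Y_j + α·p₀) / (count + α)`. It is exposed
as a standalone encoder; the main pipeline's features are continuous, so
the boosted-tree library consumes them directly and the encoder is covered
as a unit of its own.

## The synthetic benchmark

`synthetic_data` emulates the structure of curated PPI benchmarks (an
interaction database plus localisation-based negatives) without their
data. Each protein gets a cluster (localisation stand-in) and a latent
vector `u = separation · (cluster centre + 0.25·noise)`; cluster centres
are orthonormal. Amino-acid composition is `softmax(M u)` for a fixed
random 20×4 mixing matrix, sequences are drawn i.i.d. from it (length
uniform on [50, 300], mirroring the usual ≥50-residue filter), and
pseudo-PSSMs are BLOSUM62 row lookups plus seeded Gaussian noise — so the
signal genuinely flows through composition into Gram-matrix statistics
rather than being injected downstream.

Positive pairs are same-cluster pairs drawn by Gumbel top-k on latent
compatibility `u·u′` (at `separation=0` this reduces to a uniform draw);
negatives always span two clusters and are drawn to *balance each
protein's positive and negative degree*. The balance matters: proteins
recur across training and held-out pairs, and an unbalanced design lets a
classifier score well by memorising which proteins are "positive-heavy"
rather than learning pair compatibility. With balance, the permuted-label
and zero-separation nulls sit at chance.

What the generator does **not** emulate: homology structure and
sequence-identity redundancy, realistic PSI-BLAST alignment statistics,
position-dependent conservation (composition is i.i.d. per position), and
hub-dominated degree distributions. Passing the planted-signal tests
therefore shows the pipeline recovers a composition-borne signal through
profile statistics; it does not certify performance on real interactomes,
where the signal is weaker and confounded by homology.

A quirk worth knowing: linear/marginal classifiers (LDA, naive Bayes) can
score *below* chance on this benchmark. Same-cluster compatibility is a
relation between the two halves of the concatenated feature vector
(XOR-like), which linear models cannot express; what they can fit are
per-protein marginals, which degree balancing makes actively misleading
out of fold. Tree ensembles, k-NN and the RBF SVM capture the relation and
score near ceiling.

## Numerical choices

- Sigmoid is computed branch-wise (separate forms for positive and
  negative arguments) and saturates cleanly at |x| ≈ 10³.
- The Gram transform runs on raw (unscaled) profile scores; scaling
  happens once, after the transform.
- Min-max scaling of a constant matrix returns all 0.5 (no range to
  normalise; the sigmoid midpoint is the least-informative value).
- Metric ratios with zero denominators (e.g. precision with no positive
  predictions) return NaN, flagged rather than raised; fold aggregation
  uses NaN-skipping means.
- AUC is trapezoidal integration over the full ROC threshold sweep, which
  equals the Mann–Whitney pair-counting statistic with ties counted ½
  (asserted exactly in tests).
- Ranking output breaks score ties lexicographically on (id_a, id_b) so
  results are deterministic.
- The PSSM writer emits integers bare and non-integral scores via `repr`,
  so write→parse round-trips are bit-exact; the parser reads the log-odds
  block (the first 20 columns) and re-maps any file whose header order
  differs from the PSI-BLAST standard.

## Evaluation protocol

Cross-validation is stratified over pair labels and retrains the feature
extractor *within each fold* on training-fold proteins only. Held-out
proteins are encoded with the fold's trained encoder at test time — that
is inference, not leakage; what is avoided is the held-out matrices
influencing the learned representation. Problem sizes used by the test
suite and acceptance script (120 proteins, 400+400 pairs, 5 folds; the
ablation grid shares one extractor fit per fold across all six
classifiers) were chosen so a complete run finishes in minutes on one CPU
while keeping per-fold test sets large enough (160 pairs) for stable
metrics.

## Known limitations

- Log-odds columns feed the transform; profiles built from the percentage
  block would need their own calibration.
- The boosted-tree arm uses a standard GBDT library; ordered boosting's
  permutation-driven training scheme itself is not re-implemented, only
  its categorical encoder (the ordered target statistic) is.
- `signed_gradients` in the HOG config is rejected rather than
  implemented (the backing implementation is unsigned-only).
- Ambiguous residues (B, Z, X, U, J, O) are rejected by default;
  `allow_ambiguous` maps them to a zero profile row, which slightly
  dilutes composition signal for sequences rich in them.
- Everything is sized for CPU; there is no GPU path.
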