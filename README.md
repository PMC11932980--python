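# evoppi

Predicting protein–protein interactions (PPIs) from the evolutionary
information in protein sequences. Experimental PPI detection (yeast
two-hybrid, AP-MS) is slow and noisy, so sequence-based classifiers are a
standard complement; this package implements a profile-based pipeline for
computational biologists who want a complete, testable reference
implementation that runs end to end without external databases.

## The method

1. **Evolutionary profile.** Each protein of length *L* is represented by a
   position-specific scoring matrix (PSSM) `P ∈ ℝ^{L×20}`, where `x_{i,j}`
   scores amino acid *j* at position *i*. Real profiles come from PSI-BLAST
   (`-out_ascii_pssm`); the package parses that format and also provides a
   database-free *pseudo-PSSM* generator (BLOSUM62 row lookups with seeded
   noise) so everything runs offline.
2. **Fixed-size transform.** Sequence lengths vary, so each profile is
   compressed to the 20×20 Gram matrix `P̂ = PᵀP`, which is symmetric,
   positive semi-definite and independent of *L*. A zero-padding/truncation
   transform (keep the first 20 rows) is included as an ablation baseline.
3. **Denoising autoencoder (DAE).** The flattened, min-max-scaled matrix
   `x ∈ [0,1]^{400}` is corrupted (`x̃ = x + g`, `g ~ N(0, σ²I)`), encoded
   `y = s(Wx̃ + b)` and decoded `z = s(W′y + b′)` with sigmoid activations,
   minimising `‖x − z‖²` against the clean input. The deepest encoder
   activations (default 400→256→128) are the learned per-protein features.
   A histogram-of-oriented-gradients (HOG) descriptor is the non-learned
   ablation baseline.
4. **Pair classification.** A pair is the concatenation of its two protein
   feature vectors (trained in both orders, scored as the average of both
   orientations). The flagship classifier is gradient-boosted decision
   trees; NB, LDA, SVM, decision tree and k-NN are comparison arms. The
   ordered target statistic used by ordered boosting to encode categorical
   features without target leakage is exposed as a standalone encoder.
5. **Evaluation.** Stratified 5-fold cross-validation with per-fold feature
   learning (the DAE never sees held-out proteins' matrices during
   training), reporting ACC, precision (PE), sensitivity (SN), Matthews
   correlation coefficient (MCC) and ROC AUC as mean ± std across folds.

Because curated PPI datasets and PSI-BLAST runs are not bundled, the
package ships a synthetic benchmark generator that plants a recoverable
signal: proteins carry latent vectors and cluster labels (a stand-in for
subcellular localisation); amino-acid composition is biased by the latent,
positives are latent-compatible same-cluster pairs, negatives always span
clusters, and per-protein positive/negative degrees are balanced so protein
identity alone predicts nothing. At `separation=0` the benchmark is an
exact null.

## Worked example

```python
from evoppi import PipelineConfig, SyntheticSpec, cross_validate, generate_benchmark

bench = generate_benchmark(SyntheticSpec(
    n_proteins=60, n_positive_pairs=100, n_negative_pairs=100,
    separation=2.0, seed=7))
report = cross_validate(bench.pairs, {p.protein_id: p for p in bench.pssms},
                        PipelineConfig(), k=5, seed=7)
print(report.format_table())
```

```
Testing set                ACC                PE                SN               MCC               AUC
1                       0.9250            0.9048            0.9500            0.8511            0.9625
2                       0.9500            0.9500            0.9500            0.9000            0.9800
3                       0.9750            1.0000            0.9500            0.9512            0.9500
4                       0.8750            0.8261            0.9500            0.7586            0.9750
5                       0.9500            0.9091            1.0000            0.9045            0.9475
Average        0.9350 ± 0.0339   0.9180 ± 0.0574   0.9600 ± 0.0200   0.8731 ± 0.0654   0.9630 ± 0.0130
```

Each row is one held-out fold: ACC is the fraction of pairs classified
correctly at the 0.5 threshold, PE/SN are precision and sensitivity of the
interacting class, MCC is the label/prediction correlation, and AUC is the
probability a random interacting pair outscores a random non-interacting
one. A mean AUC of 0.96 on this small benchmark means the pipeline
recovers most of the planted latent compatibility from profile statistics
alone. More walkthroughs live in `examples/`.

The same pipeline is available from the shell:

```bash
evoppi simulate --out bench/ --seed 7
evoppi evaluate --data bench/ --out eval/ --seed 7
evoppi train --data bench/ --out model/ --seed 7
evoppi predict --model-dir model/ --data bench/ --pairs bench/pairs.tsv --out ranked.tsv
```

To use real data instead, place `proteins.fasta`, one PSI-BLAST ASCII PSSM
per protein under `pssms/<id>.pssm` (e.g. from
`psiblast -query seq.fasta -db <protein_db> -num_iterations 3
-evalue 0.001 -out_ascii_pssm pssms/<id>.pssm`), and a `pairs.tsv` with
columns `id_a  id_b  label`.

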