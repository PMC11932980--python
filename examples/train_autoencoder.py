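"""Train the denoising autoencoder on synthetic profiles and inspect it.

Generates a small planted benchmark, trains the autoencoder on the scaled
Gram matrices, and prints the loss trajectory and the latent feature width.
A falling loss and a compact latent code are what the downstream
classifier consumes.
"""

from evoppi import (
    DAEConfig,
    SyntheticSpec,
    equal_size_transform,
    extract_features,
    generate_benchmark,
    scale_matrix,
    train_dae,
)

bench = generate_benchmark(SyntheticSpec(
    n_proteins=60, n_positive_pairs=80, n_negative_pairs=80, seed=1))
matrices = [scale_matrix(equal_size_transform(p)) for p in bench.pssms]

config = DAEConfig(layer_sizes=(256, 128), noise_sigma=0.1, epochs=60, seed=1)
model = train_dae(matrices, config)

hist = model.training_loss_history
print(f"epoch   1 mean loss: {hist[0]:.3f}")
print(f"epoch {len(hist):3d} mean loss: {hist[-1]:.3f}")
# the loss is the mean squared reconstruction error of clean inputs from
# noise-corrupted ones; it should fall substantially over training

features = extract_features(model, matrices)
print(f"{len(features)} proteins encoded to {features[0].values.shape[0]} "
      "latent features each (down from 400 inputs)")
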