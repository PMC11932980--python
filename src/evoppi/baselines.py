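"""Baseline feature extractors for the ablation arm.

The histogram-of-oriented-gradients (HOG) descriptor treats the scaled
20 x 20 profile matrix as a tiny grayscale image and summarises local
gradient directions — a deliberately generic, non-learned competitor to the
autoencoder features.  Backed by scikit-image's reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import hog as _skimage_hog

from .dae import FeatureVector
from .transforms import FixedMatrix

_SIDE = 20  # FixedMatrix edge length in "pixels"


@dataclass(frozen=True)
class HOGConfig:
    """Standard HOG recipe: 5-px cells, 2x2 blocks, 9 unsigned bins, L2 norm."""

    cell_size: int = 5
    block_size: int = 2
    n_orientations: int = 9
    signed_gradients: bool = False

    def __post_init__(self) -> None:
        if self.cell_size < 1 or _SIDE % self.cell_size != 0:
            raise ValueError(f"cell_size must divide {_SIDE}, got {self.cell_size}")
        n_cells = _SIDE // self.cell_size
        if not (1 <= self.block_size <= n_cells):
            raise ValueError(f"block_size {self.block_size} does not fit the {n_cells}-cell grid")
        if self.n_orientations < 1:
            raise ValueError("n_orientations must be positive")
        if self.signed_gradients:
            raise ValueError("signed gradients are not supported (unsigned 0-180 degree bins only)")

    @property
    def descriptor_length(self) -> int:
        """Number of values: blocks x cells-per-block x orientation bins."""
        n_cells = _SIDE // self.cell_size
        n_blocks_1d = n_cells - self.block_size + 1
        return n_blocks_1d**2 * self.block_size**2 * self.n_orientations


def hog_features(m: FixedMatrix, config: HOGConfig | None = None) -> FeatureVector:
    """HOG descriptor of a scaled 20 x 20 matrix; deterministic, fixed length."""
    if config is None:
        config = HOGConfig()
    if not m.scaled:
        raise ValueError(f"matrix for {m.protein_id!r} must be scaled before HOG extraction")
    desc = _skimage_hog(
        m.values,
        orientations=config.n_orientations,
        pixels_per_cell=(config.cell_size, config.cell_size),
        cells_per_block=(config.block_size, config.block_size),
        block_norm="L2",
        feature_vector=True,
    )
    assert desc.shape == (config.descriptor_length,)
    return FeatureVector(protein_id=m.protein_id, values=desc)
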