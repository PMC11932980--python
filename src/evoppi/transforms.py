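"""Fixed-size transforms of variable-length PSSMs.

Protein sequences have unequal lengths, so their L x 20 profiles cannot feed
a fixed-width model directly.  Two remedies are provided:

* **equal-size transform** — the Gram matrix ``P.T @ P`` (20 x 20), which is
  independent of sequence length and of row order, and summarises pairwise
  column covariation of the profile;
* **zero-padding** — keep the first 20 rows, zero-filling when L < 20, a
  deliberately lossy baseline.

Matrices destined for a sigmoid-bounded autoencoder must first pass through
:func:`scale_matrix` (per-matrix min-max to [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pssm_io import PSSM

EQUAL_SIZE = "equal_size"
ZERO_PAD = "zero_pad"


@dataclass
class FixedMatrix:
    """A 20 x 20 per-protein feature matrix plus provenance flags."""

    protein_id: str
    values: np.ndarray
    method: str
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20, 20):
            raise ValueError(f"FixedMatrix must be 20 x 20, got {self.values.shape}")
        if self.method not in (EQUAL_SIZE, ZERO_PAD):
            raise ValueError(f"unknown transform method {self.method!r}")

    def flat(self) -> np.ndarray:
        """Row-major 400-vector view used as model input."""
        return self.values.ravel()


def equal_size_transform(pssm: PSSM) -> FixedMatrix:
    """Compress an L x 20 PSSM into its 20 x 20 Gram matrix ``P.T @ P``.

    The output is symmetric positive semi-definite and invariant under any
    permutation of the profile's rows.
    """
    if pssm.length < 1:
        raise ValueError(f"empty PSSM for {pssm.protein_id!r}")
    values = pssm.scores.T @ pssm.scores
    return FixedMatrix(protein_id=pssm.protein_id, values=values, method=EQUAL_SIZE)


def zero_pad_transform(pssm: PSSM) -> FixedMatrix:
    """Truncate or zero-pad a PSSM to its first 20 rows (N-terminal)."""
    if pssm.length < 1:
        raise ValueError(f"empty PSSM for {pssm.protein_id!r}")
    values = np.zeros((20, 20))
    n = min(pssm.length, 20)
    values[:n] = pssm.scores[:n]
    return FixedMatrix(protein_id=pssm.protein_id, values=values, method=ZERO_PAD)


def scale_matrix(m: FixedMatrix) -> FixedMatrix:
    """Min-max scale a matrix into [0, 1] (per matrix, not per dataset).

    A constant matrix maps to all 0.5 — there is no range to normalise, and
    0.5 sits at the sigmoid's centre.
    """
    if m.scaled:
        raise ValueError(f"matrix for {m.protein_id!r} is already scaled")
    if not np.all(np.isfinite(m.values)):
        raise ValueError(f"matrix for {m.protein_id!r} contains non-finite entries")
    lo, hi = m.values.min(), m.values.max()
    if hi > lo:
        values = (m.values - lo) / (hi - lo)
    else:
        values = np.full_like(m.values, 0.5)
    return replace(m, values=values, scaled=True)
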