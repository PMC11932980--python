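"""From a protein sequence to a fixed-size evolutionary feature matrix.

Builds a pseudo-PSSM for a short sequence (BLOSUM62 row lookups with seeded
noise, a database-free stand-in for a PSI-BLAST profile), compresses it to
a length-independent 20 x 20 Gram matrix, and scales it for the
autoencoder.
"""

import numpy as np

from evoppi import ProteinRecord, pseudo_pssm, equal_size_transform, scale_matrix

record = ProteinRecord(id="demo", sequence="MKVLITGAGSGIGLEAAKQFLAEGAKVVLIDRS")
pssm = pseudo_pssm(record, seed=42)
print(f"profile shape: {pssm.scores.shape}  (one row per residue, 20 amino-acid columns)")

gram = equal_size_transform(pssm)
print(f"Gram matrix: {gram.values.shape}, symmetric: "
      f"{np.allclose(gram.values, gram.values.T)}")
# the Gram matrix is length-independent: any protein yields 20 x 20

scaled = scale_matrix(gram)
print(f"scaled range: [{scaled.values.min():.1f}, {scaled.values.max():.1f}]")
# entries now fit the sigmoid-bounded autoencoder input range
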