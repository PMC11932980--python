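"""Synthetic interaction benchmarks with planted structure.

Real PPI benchmarks pair an interaction database with profile searches
against a large sequence database — neither is bundled here.  Instead this
module plants a recoverable signal: every protein gets a latent vector and
a cluster (a stand-in for subcellular localisation); its amino-acid
composition is biased by the latent with tunable strength, so pseudo-PSSM
row statistics genuinely carry the signal through the Gram-matrix
transform.  Positive pairs are same-cluster pairs with high latent
compatibility (u . u'); negative pairs always span two clusters, mirroring
the differing-localisation heuristic real negative sets use.  At
``separation=0`` the data carry no signal at all, giving a null benchmark.

A ground-truth sidecar (latents + clusters) is written for test assertions
but never read by the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .pssm_io import (
    AA_ORDER,
    PSSM,
    ProteinRecord,
    parse_pssm,
    pseudo_pssm,
    read_fasta,
    write_fasta,
    write_pssm,
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Benchmark shape and signal strength.

    ``separation`` scales the latent vectors (and hence the composition
    bias): 0 means no signal, 2 a strongly recoverable one.  Sequence
    lengths stay at or above 50 residues, matching the usual short-protein
    filter applied to curated PPI sets.
    """

    n_proteins: int = 120
    n_positive_pairs: int = 400
    n_negative_pairs: int = 400
    latent_dim: int = 4
    separation: float = 2.0
    n_clusters: int = 3
    length_range: tuple[int, int] = (50, 300)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 2 or self.n_clusters < 2:
            raise ValueError("need at least 2 proteins and 2 clusters")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be positive")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if self.length_range[0] < 50 or self.length_range[1] < self.length_range[0]:
            raise ValueError("length_range must satisfy 50 <= min <= max")
        if self.n_positive_pairs < 1 or self.n_negative_pairs < 1:
            raise ValueError("pair counts must be positive")
        max_pairs = self.n_proteins * (self.n_proteins - 1) // 2
        if self.n_positive_pairs + self.n_negative_pairs > max_pairs:
            raise ValueError(
                f"{self.n_positive_pairs}+{self.n_negative_pairs} pairs requested "
                f"but only {max_pairs} unordered pairs exist"
            )


@dataclass
class Benchmark:
    """Everything one benchmark run produces, including the hidden truth."""

    records: list[ProteinRecord]
    pssms: list[PSSM]
    pairs: list[tuple[str, str, int]]
    latents: np.ndarray
    clusters: np.ndarray
    spec: SyntheticSpec


def _cluster_centres(rng: np.random.Generator, latent_dim: int, n_clusters: int) -> np.ndarray:
    """Well-separated unit vectors; orthonormal when the dimension allows."""
    raw = rng.normal(size=(latent_dim, max(n_clusters, 2)))
    if n_clusters <= latent_dim:
        q, _ = np.linalg.qr(raw[:, :n_clusters])
        return q.T
    norms = np.linalg.norm(raw, axis=0)
    return (raw / norms).T[:n_clusters]


def generate_benchmark(spec: SyntheticSpec | None = None) -> Benchmark:
    """Generate proteins, pseudo-PSSMs and a labelled pair list.

    Fully reproducible from ``spec.seed``; no pair appears twice in either
    orientation and no protein is paired with itself.
    """
    if spec is None:
        spec = SyntheticSpec()
    rng = np.random.default_rng(spec.seed)

    clusters = np.arange(spec.n_proteins) % spec.n_clusters
    centres = _cluster_centres(rng, spec.latent_dim, spec.n_clusters)
    noise = rng.normal(scale=0.25, size=(spec.n_proteins, spec.latent_dim))
    latents = spec.separation * (centres[clusters] + noise)

    # composition bias: softmax(uniform logits + M u), M fixed per benchmark
    mixing = rng.normal(scale=1.0, size=(20, spec.latent_dim))
    logits = latents @ mixing.T
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)

    alphabet = np.array(list(AA_ORDER))
    width = len(str(spec.n_proteins - 1))
    records, pssms = [], []
    for i in range(spec.n_proteins):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = "".join(rng.choice(alphabet, size=length, p=probs[i]))
        rec = ProteinRecord(id=f"P{i:0{width}d}", sequence=seq)
        records.append(rec)
        pssms.append(pseudo_pssm(rec, seed=int(rng.integers(2**31))))

    same, cross = [], []
    for i, j in combinations(range(spec.n_proteins), 2):
        (same if clusters[i] == clusters[j] else cross).append((i, j))
    if spec.n_positive_pairs > len(same):
        raise ValueError(
            f"{spec.n_positive_pairs} positives requested but only "
            f"{len(same)} same-cluster pairs exist"
        )
    if spec.n_negative_pairs > len(cross):
        raise ValueError(
            f"{spec.n_negative_pairs} negatives requested but only "
            f"{len(cross)} cross-cluster pairs exist"
        )

    # positives: favour latent-compatible same-cluster pairs via Gumbel
    # top-k (reduces to a uniform draw when separation is 0, so the null
    # benchmark stays null)
    compat = np.array([latents[i] @ latents[j] for i, j in same])
    keys = compat + rng.gumbel(size=len(same))
    positives = [same[i] for i in np.argsort(-keys)[: spec.n_positive_pairs]]

    # negatives: cross-cluster pairs chosen to balance each protein's
    # positive and negative degree, so protein identity alone carries no
    # label signal (memorising who a protein is must not predict labels)
    deficit = np.zeros(spec.n_proteins)
    for i, j in positives:
        deficit[i] += 1
        deficit[j] += 1
    cross_arr = np.array(cross)
    available = np.ones(len(cross), dtype=bool)
    negatives = []
    for _ in range(spec.n_negative_pairs):
        scores = deficit[cross_arr[:, 0]] + deficit[cross_arr[:, 1]]
        scores = np.where(available, scores + 0.5 * rng.gumbel(size=len(cross)), -np.inf)
        best = int(np.argmax(scores))
        available[best] = False
        i, j = cross[best]
        negatives.append((i, j))
        deficit[i] -= 1
        deficit[j] -= 1

    ids = [r.id for r in records]
    pairs = [(ids[i], ids[j], 1) for i, j in positives]
    pairs += [(ids[i], ids[j], 0) for i, j in negatives]
    return Benchmark(records=records, pssms=pssms, pairs=pairs,
                     latents=latents, clusters=clusters, spec=spec)


def write_benchmark(bundle: Benchmark, out_dir: str | Path) -> dict[str, Path]:
    """Write a benchmark as FASTA + per-protein ASCII PSSMs + pairs TSV.

    A ``ground_truth.json`` sidecar records latents and clusters for test
    assertions; the pipeline itself never reads it.
    """
    if not bundle.records:
        raise ValueError("empty benchmark bundle")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pssm_dir = out / "pssms"
    pssm_dir.mkdir(exist_ok=True)

    fasta = out / "proteins.fasta"
    write_fasta(bundle.records, fasta)
    for pssm in bundle.pssms:
        write_pssm(pssm, pssm_dir / f"{pssm.protein_id}.pssm")
    pairs_tsv = out / "pairs.tsv"
    with open(pairs_tsv, "w") as fh:
        fh.write("id_a\tid_b\tlabel\n")
        for a, b, label in bundle.pairs:
            fh.write(f"{a}\t{b}\t{label}\n")
    truth = out / "ground_truth.json"
    truth.write_text(json.dumps({
        "latents": bundle.latents.tolist(),
        "clusters": bundle.clusters.tolist(),
        "spec": asdict(bundle.spec),
    }))
    return {"fasta": fasta, "pssm_dir": pssm_dir, "pairs": pairs_tsv, "ground_truth": truth}


def read_pairs(path: str | Path) -> list[tuple[str, str, int]]:
    """Read a pair list TSV with header ``id_a  id_b  label``."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t")[:3] != ["id_a", "id_b", "label"]:
        raise ValueError(f"{path}: expected header 'id_a\\tid_b\\tlabel'")
    pairs = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3 or fields[2] not in ("0", "1"):
            raise ValueError(f"{path}: line {lineno}: malformed pair row")
        pairs.append((fields[0], fields[1], int(fields[2])))
    if not pairs:
        raise ValueError(f"{path}: no pairs found")
    return pairs


def read_benchmark(out_dir: str | Path) -> tuple[list[ProteinRecord], list[PSSM], list[tuple[str, str, int]]]:
    """Re-read a written benchmark with the package's own readers."""
    out = Path(out_dir)
    records = read_fasta(out / "proteins.fasta")
    pssms = [parse_pssm(out / "pssms" / f"{r.id}.pssm") for r in records]
    pairs = read_pairs(out / "pairs.tsv")
    return records, pssms, pairs
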