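"""Protein sequence and PSSM input/output.

A position-specific scoring matrix (PSSM) is an L x 20 profile giving, for
each position of a protein sequence, a log-odds score per standard amino
acid.  PSI-BLAST emits these as ASCII files (``-out_ascii_pssm``); this
module parses that dialect, writes it back bit-exactly for fixtures, and
provides a database-free *pseudo-PSSM* generator so the whole pipeline can
run without a homology search: each row is the substitution-matrix row of
the residue at that position, optionally perturbed with seeded noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

#: PSI-BLAST's native column order for the 20 standard amino acids.
AA_ORDER: str = "ARNDCQEGHILKMFPSTWYV"

#: Ambiguity / non-standard letters tolerated on read when allowed.
AMBIGUOUS_AA: frozenset = frozenset("BZXUJO")

_PSSM_HEADER = (
    "Last position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative "
    "weight of gapless real matches to pseudocounts"
)


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence, the unit that interaction pairs reference."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"protein id must be non-empty and whitespace-free: {self.id!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for protein {self.id!r}")


@dataclass
class PSSM:
    """An L x 20 evolutionary profile with a fixed amino-acid column order."""

    protein_id: str
    scores: np.ndarray
    column_order: str = AA_ORDER
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"PSSM for {self.protein_id!r} must be L x 20, got {self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise ValueError(f"PSSM for {self.protein_id!r} has no rows")
        if sorted(self.column_order) != sorted(AA_ORDER):
            raise ValueError(f"column_order is not the 20 standard amino acids: {self.column_order!r}")
        if self.sequence is not None and len(self.sequence) != self.scores.shape[0]:
            raise ValueError(
                f"PSSM for {self.protein_id!r}: {self.scores.shape[0]} rows but "
                f"sequence length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return self.scores.shape[0]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased; record order is preserved.  Raises on an
    empty file, duplicate ids, or letters outside the extended amino-acid
    alphabet.
    """
    allowed = set(AA_ORDER) | AMBIGUOUS_AA | {"*"}
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = sorted(set(seq) - allowed)
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains non-amino-acid characters: {''.join(bad)}"
            )
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _fmt_score(v: float) -> str:
    # integers are written bare, as PSI-BLAST does; non-integral scores use
    # repr so that write -> parse round-trips bit-exactly
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_pssm(pssm: PSSM, path: str | Path) -> None:
    """Write a PSSM in the PSI-BLAST ASCII dialect.

    The log-odds block carries ``pssm.scores``; the percentage block and the
    two trailing per-row statistics are written as zeros (they are ignored
    on read).  Requires ``pssm.sequence`` so residue letters can be emitted.
    """
    if pssm.sequence is None:
        raise ValueError(f"cannot write PSSM for {pssm.protein_id!r}: sequence unknown")
    cols = " ".join(f"{a:>6s}" for a in pssm.column_order)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(_PSSM_HEADER + "\n")
        fh.write("          " + cols + " " + cols + "\n")
        for i, (letter, row) in enumerate(zip(pssm.sequence, pssm.scores), start=1):
            vals = " ".join(f"{_fmt_score(v):>6s}" for v in row)
            pct = " ".join(f"{0:>6d}" for _ in range(20))
            fh.write(f"{i:>5d} {letter} {vals} {pct}  0.00 0.00\n")
        fh.write("\n")


def parse_pssm(path: str | Path) -> PSSM:
    """Parse a PSI-BLAST ASCII PSSM, keeping the first (log-odds) block.

    The 20 header letters of the first block define the column order; files
    whose order differs from PSI-BLAST's native order are re-mapped to
    :data:`AA_ORDER`.  The residue letters of the rows are concatenated into
    the query sequence.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_idx = None
    column_order = None
    for idx, line in enumerate(lines):
        tokens = line.split()
        if len(tokens) >= 20 and all(t in set(AA_ORDER) for t in tokens[:20]):
            column_order = "".join(tokens[:20])
            header_idx = idx
            break
    if header_idx is None:
        raise ValueError(f"{path}: no PSSM column header found")
    if sorted(column_order) != sorted(AA_ORDER):
        raise ValueError(f"{path}: header amino-acid order is not a permutation of the standards")

    rows: list[np.ndarray] = []
    letters: list[str] = []
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        tokens = line.split()
        if not tokens:
            break
        if not tokens[0].isdigit():
            break
        # position, residue, 20 log-odds, then optionally 20 percentages + 2 stats
        if len(tokens) < 22:
            raise ValueError(f"{path}: line {lineno}: truncated PSSM row ({len(tokens)} fields)")
        if len(tokens) not in (22, 42, 44):
            raise ValueError(
                f"{path}: line {lineno}: unexpected field count {len(tokens)} in PSSM row"
            )
        letters.append(tokens[1])
        try:
            rows.append(np.array([float(t) for t in tokens[2:22]], dtype=float))
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric score: {exc}") from None
    if not rows:
        raise ValueError(f"{path}: PSSM contains no residue rows")

    scores = np.vstack(rows)
    if column_order != AA_ORDER:
        perm = [column_order.index(a) for a in AA_ORDER]
        scores = scores[:, perm]
    protein_id = path.stem
    return PSSM(protein_id=protein_id, scores=scores, column_order=AA_ORDER,
                sequence="".join(letters))


def default_substitution_table() -> np.ndarray:
    """BLOSUM62 log-odds restricted to the 20 standard residues, in :data:`AA_ORDER`."""
    blosum = substitution_matrices.load("BLOSUM62")
    idx = [blosum.alphabet.index(a) for a in AA_ORDER]
    return np.asarray(blosum)[np.ix_(idx, idx)].astype(float)


def pseudo_pssm(
    record: ProteinRecord,
    substitution_table: np.ndarray | None = None,
    seed: int | None = None,
    noise_sigma: float = 0.5,
    allow_ambiguous: bool = False,
) -> PSSM:
    """Build a stand-in PSSM without running a homology search.

    Row *i* is the substitution-table row of residue *i* (so row statistics
    reflect amino-acid composition, the same signal a real profile's
    background carries).  With a seed, i.i.d. Gaussian perturbations of
    scale ``noise_sigma`` are added reproducibly.

    Parameters
    ----------
    record:
        The protein to profile.
    substitution_table:
        20 x 20 log-odds table indexed by :data:`AA_ORDER`; defaults to
        BLOSUM62.
    seed:
        ``None`` for the deterministic table-lookup profile; an integer for
        reproducible perturbed profiles.
    allow_ambiguous:
        Map ambiguity codes (B, Z, X, U, J, O) to an all-zero row instead of
        raising.
    """
    if substitution_table is None:
        substitution_table = default_substitution_table()
    table = np.asarray(substitution_table, dtype=float)
    if table.shape != (20, 20):
        raise ValueError(f"substitution_table must be 20 x 20, got {table.shape}")
    aa_index = {a: i for i, a in enumerate(AA_ORDER)}
    rows = np.zeros((len(record.sequence), 20))
    for pos, letter in enumerate(record.sequence):
        if letter in aa_index:
            rows[pos] = table[aa_index[letter]]
        elif allow_ambiguous and letter in AMBIGUOUS_AA:
            pass  # zero row
        else:
            raise ValueError(
                f"protein {record.id!r}: residue {letter!r} at position {pos + 1} "
                "is not a standard amino acid"
            )
    if seed is not None and noise_sigma > 0:
        rng = np.random.default_rng(seed)
        rows = rows + rng.normal(0.0, noise_sigma, size=rows.shape)
    return PSSM(protein_id=record.id, scores=rows, sequence=record.sequence)
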