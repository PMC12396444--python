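"""Sequence-level immunogenicity metrics for designed proteins.

Three views of how "human-like" and how visible to CTLs a design is:

* ``self_kmer_fraction`` — per length k, the fraction of the design's kmer
  windows found in the reference proteome;
* ``presented_nonself_fraction`` — the fraction of all 8-10mer windows that
  are both absent from the proteome and predicted presented by the genotype
  (these are the potentially immunogenic peptides; a constrained decode that
  finished without fallback contains exactly zero);
* BLOSUM62 dissimilarity — for each non-self 8-10mer, the gap between its
  ungapped BLOSUM62 self-score and the best ungapped score achievable against
  any same-length proteome kmer.  Zero means some proteome peptide matches it
  at full score; larger values mean the peptide is more foreign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .presentation import (
    PEPTIDE_LENGTHS,
    Genotype,
    PresentationModel,
    encode_peptides,
    is_presented,
)
from .proteome import STANDARD_AA, KmerIndex, is_self

_AA_TO_IDX = {a: i for i, a in enumerate(STANDARD_AA)}


def load_blosum62() -> np.ndarray:
    """BLOSUM62 as a 20x20 integer array over :data:`STANDARD_AA` order.

    Validated on load: symmetric, and each diagonal entry is at least as
    large as every off-diagonal entry in its row (which makes the
    dissimilarity non-negative).
    """
    mat = substitution_matrices.load("BLOSUM62")
    out = np.empty((20, 20), dtype=np.int64)
    for i, a in enumerate(STANDARD_AA):
        for j, b in enumerate(STANDARD_AA):
            out[i, j] = int(mat[a, b])
    if not np.array_equal(out, out.T):
        raise ValueError("substitution matrix is not symmetric")
    if np.any(np.diag(out)[:, None] < out):
        raise ValueError("substitution matrix rows are not diagonal-dominant")
    return out


def _windows(sequence: str, k: int) -> list[str]:
    return [sequence[i : i + k] for i in range(len(sequence) - k + 1)]


def self_kmer_fraction(sequence: str, index: KmerIndex, k: int) -> float:
    """Fraction of the sequence's length-k windows present in the proteome.

    Windows containing ``X`` are excluded from the denominator (self-ness is
    undefined for them, matching the index's own exclusion rule).
    """
    if len(sequence) < k:
        raise ValueError(f"sequence shorter than k={k}")
    windows = [w for w in _windows(sequence, k) if "X" not in w]
    if not windows:
        return 0.0
    return sum(is_self(index, w) for w in windows) / len(windows)


def presented_nonself_fraction(
    sequence: str,
    index: KmerIndex,
    model: PresentationModel,
    genotype: Genotype,
) -> float:
    """Presented non-self 8-10mers over all 8-10mer windows of the design."""
    if len(sequence) < min(PEPTIDE_LENGTHS):
        raise ValueError("sequence shorter than the minimum peptide length (8)")
    total = 0
    bad = 0
    for k in PEPTIDE_LENGTHS:
        for w in _windows(sequence, k):
            if "X" in w:
                continue
            total += 1
            if not is_self(index, w) and is_presented(model, genotype, w):
                bad += 1
    if total == 0:
        return 0.0
    return bad / total


class Blosum62Dissimilarity:
    """Exhaustive ungapped nearest-self search, vectorised per kmer length.

    The proteome's same-length kmers are encoded once into an (N, k) integer
    matrix; a query's best score is then a single fancy-indexed reduction.
    """

    def __init__(self, index: KmerIndex, matrix: np.ndarray | None = None) -> None:
        self.index = index
        self.matrix = load_blosum62() if matrix is None else np.asarray(matrix)
        self._encoded: dict[int, np.ndarray] = {}

    def _members(self, k: int) -> np.ndarray:
        enc = self._encoded.get(k)
        if enc is None:
            members = sorted(self.index.members[k])
            if not members:
                raise ValueError(f"proteome holds no kmers of length {k}")
            enc = encode_peptides(members, k)
            self._encoded[k] = enc
        return enc

    def __call__(self, kmer: str) -> int:
        k = len(kmer)
        if not min(PEPTIDE_LENGTHS) <= k <= max(PEPTIDE_LENGTHS):
            raise ValueError("dissimilarity is defined for 8-10mers")
        query = np.array([_AA_TO_IDX[a] for a in kmer])
        members = self._members(k)
        scores = self.matrix[members, query[None, :]].sum(axis=1)
        best = int(scores.max())
        self_score = int(self.matrix[query, query].sum())
        return self_score - best


def blosum62_dissimilarity(
    kmer: str, index: KmerIndex, matrix: np.ndarray | None = None
) -> int:
    """Self-score minus best ungapped score against any same-length proteome kmer."""
    return Blosum62Dissimilarity(index, matrix)(kmer)


@dataclass
class DesignReport:
    """Per-design immunogenicity metrics."""

    sequence_id: str
    self_fraction_by_k: dict[int, float]
    presented_nonself_fraction: float
    dissimilarities: list[tuple[str, int]] = field(default_factory=list)


def evaluate_design(
    sequence: str,
    sequence_id: str,
    index: KmerIndex,
    model: PresentationModel,
    genotype: Genotype,
    dissimilarity: Blosum62Dissimilarity | None = None,
    self_fraction_lengths: Sequence[int] = (5, 6, 7, 8, 9, 10),
) -> DesignReport:
    """Full report for one design; dissimilarities cover every non-self 8-10mer."""
    fractions = {
        k: self_kmer_fraction(sequence, index, k)
        for k in self_fraction_lengths
        if len(sequence) >= k
    }
    pnf = presented_nonself_fraction(sequence, index, model, genotype)
    dissimilarities: list[tuple[str, int]] = []
    if dissimilarity is not None:
        for k in PEPTIDE_LENGTHS:
            for w in _windows(sequence, k):
                if "X" not in w and not is_self(index, w):
                    dissimilarities.append((w, dissimilarity(w)))
    return DesignReport(
        sequence_id=sequence_id,
        self_fraction_by_k=fractions,
        presented_nonself_fraction=pnf,
        dissimilarities=dissimilarities,
    )
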