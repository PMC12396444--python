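"""Synthetic inputs: proteomes, anchored alleles, and toy sequence models.

Everything the other modules consume can be generated here, seeded and
bit-reproducible, so the whole pipeline runs without any downloaded data:

* :func:`generate_proteome` — i.i.d.-residue protein records (optionally
  with planted motifs) standing in for a reference proteome;
* :func:`generate_synthetic_allele` — an *anchored* MHC-I allele whose
  ground-truth presentation rule ("anchor residues at anchor positions") is
  known exactly, with a labelled peptide set to train PWMs from;
* :func:`toy_sequence_model` — a deterministic autoregressive model placing
  a concentration-weighted mass on a target sequence over a seeded
  first-order background, exposing its exact probability table so tests can
  brute-force decode oracles.

Restricted alphabets (4-6 letters) are supported solely to keep exhaustive
enumeration feasible in tests; the engine itself is alphabet-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .decoder import SequenceModelContract
from .proteome import STANDARD_AA, ProteinRecord


@dataclass(frozen=True)
class AlleleSpec:
    """Anchored presentation rule: residues required at given positions.

    Positions may be negative (Python-style; -1 anchors the C-terminus, as
    real MHC-I motifs do, so one rule applies across lengths 8-10).
    ``sharpness`` in (0, 1] is the probability a peptide's label follows the
    rule; 1 means noise-free labels.
    """

    anchor_positions: tuple[int, ...]
    anchor_residues: tuple[str, ...]
    sharpness: float = 1.0

    def __post_init__(self) -> None:
        if len(self.anchor_positions) != len(self.anchor_residues):
            raise ValueError("one residue set per anchor position")
        if not 0 < self.sharpness <= 1:
            raise ValueError("sharpness must be in (0, 1]")

    def matches(self, peptide: str) -> bool:
        return all(
            peptide[p] in residues
            for p, residues in zip(self.anchor_positions, self.anchor_residues)
        )


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_proteins: int = 100
    protein_length_range: tuple[int, int] = (200, 400)
    alphabet: str = STANDARD_AA
    allele_specs: tuple[AlleleSpec, ...] = ()
    residue_freqs: tuple[float, ...] | None = None  # uniform if None
    planted_motifs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.alphabet:
            raise ValueError("alphabet must be non-empty")
        if set(self.alphabet) - set(STANDARD_AA):
            raise ValueError("alphabet must be standard residues")


def generate_proteome(spec: FixtureSpec) -> list[ProteinRecord]:
    """Seeded i.i.d.-residue proteome; planted motifs are embedded verbatim.

    Each motif is written into a deterministic position of one protein so
    tests can force specific kmers to be self.
    """
    if spec.n_proteins < 0:
        raise ValueError("n_proteins must be >= 0")
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(spec.alphabet))
    if spec.residue_freqs is None:
        p = None
    else:
        p = np.asarray(spec.residue_freqs, dtype=float)
        if len(p) != len(letters):
            raise ValueError("residue_freqs length must match the alphabet")
        p = p / p.sum()
    lo, hi = spec.protein_length_range
    records = []
    for i in range(spec.n_proteins):
        n = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=n, p=p))
        records.append(ProteinRecord(id=f"syn{i:05d}", sequence=seq))
    for m, motif in enumerate(spec.planted_motifs):
        if not records:
            raise ValueError("cannot plant motifs into an empty proteome")
        rec = records[m % len(records)]
        seq = rec.sequence
        if len(motif) > len(seq):
            seq = motif
        else:
            start = (m * 7919) % (len(seq) - len(motif) + 1)
            seq = seq[:start] + motif + seq[start + len(motif) :]
        records[m % len(records)] = ProteinRecord(id=rec.id, sequence=seq)
    return records


def random_peptides(
    n: int, k: int, rng: np.random.Generator, alphabet: str = STANDARD_AA
) -> list[str]:
    """n i.i.d. uniform peptides of length k (background panels, test panels)."""
    letters = np.array(list(alphabet))
    block = rng.choice(letters, size=(n, k))
    return ["".join(row) for row in block]


def generate_synthetic_allele(
    spec_entry: AlleleSpec,
    k: int,
    n_peptides: int,
    seed: int,
    alphabet: str = STANDARD_AA,
) -> tuple[list[tuple[str, bool]], AlleleSpec]:
    """Labelled peptides for one anchored allele plus its ground-truth rule.

    Labels follow ``spec_entry.matches`` and are flipped independently with
    probability ``1 - sharpness``.  The returned rule is the oracle tests use
    independently of any trained PWM.
    """
    if any(p >= k or p < -k for p in spec_entry.anchor_positions):
        raise ValueError("anchor position out of range for peptide length")
    rng = np.random.default_rng(seed)
    peptides = random_peptides(n_peptides, k, rng, alphabet)
    labelled = []
    for pep in peptides:
        label = spec_entry.matches(pep)
        if spec_entry.sharpness < 1 and rng.random() > spec_entry.sharpness:
            label = not label
        labelled.append((pep, label))
    return labelled, spec_entry


def anchored_peptides(
    spec_entry: AlleleSpec,
    k: int,
    n: int,
    rng: np.random.Generator,
    alphabet: str = STANDARD_AA,
) -> list[str]:
    """Peptides drawn uniformly, then forced to satisfy the anchor rule."""
    peptides = random_peptides(n, k, rng, alphabet)
    out = []
    for pep in peptides:
        chars = list(pep)
        for p, residues in zip(spec_entry.anchor_positions, spec_entry.anchor_residues):
            chars[p] = residues[int(rng.integers(len(residues)))]
        out.append("".join(chars))
    return out


def synthetic_presentation_model(
    allele_specs: "dict[str, AlleleSpec]",
    seed: int,
    n_train: int = 1000,
    n_background: int = 20000,
    target_presented_fraction: float = 0.02,
    alphabet: str = STANDARD_AA,
) -> "PresentationModel":
    """Train and calibrate one PWM per (named allele, length 8-10).

    Positives are anchor-conforming peptides; thresholds are calibrated on a
    uniform background at the given target fraction (default the 2%
    "weak binder" convention).
    """
    from .presentation import (
        PEPTIDE_LENGTHS,
        Allele,
        PresentationModel,
        calibrate_threshold,
        train_pwm,
    )

    pwms = []
    for a_i, (name, spec_entry) in enumerate(sorted(allele_specs.items())):
        for k in PEPTIDE_LENGTHS:
            rng = np.random.default_rng([seed, a_i, k])
            positives = anchored_peptides(spec_entry, k, n_train, rng, alphabet)
            pwm = train_pwm(positives, allele=Allele(name))
            background = random_peptides(n_background, k, rng, alphabet)
            pwms.append(
                calibrate_threshold(pwm, background, target_presented_fraction)
            )
    return PresentationModel.from_pwms(pwms)


class ToySequenceModel:
    """Deterministic position-wise autoregressive model for fixtures.

    Position p's distribution is ``(concentration * onehot(target[p]) + bg)
    / (concentration + 1)`` where the background ``bg`` blends a uniform
    distribution with a seeded first-order (previous-residue conditioned)
    table, weighted by ``markov_blend``.  The exact probability table is
    exposed via :meth:`probability_row` so brute-force oracles can be
    computed outside the decoder.
    """

    def __init__(
        self,
        target: str,
        concentration: float = 1.0,
        markov_blend: float = 0.0,
        seed: int = 0,
        alphabet: str | None = None,
    ) -> None:
        if not target:
            raise ValueError("target must be non-empty")
        if concentration < 0:
            raise ValueError("concentration must be >= 0")
        if not 0 <= markov_blend <= 1:
            raise ValueError("markov_blend must be in [0, 1]")
        self.target = target
        self.concentration = concentration
        self.markov_blend = markov_blend
        self.alphabet = alphabet or STANDARD_AA
        if set(target) - set(self.alphabet):
            raise ValueError("target uses letters outside the alphabet")
        self.tokens: tuple[str, ...] = tuple(self.alphabet)
        self._tok_idx = {t: i for i, t in enumerate(self.tokens)}
        rng = np.random.default_rng(seed)
        v = len(self.tokens)
        markov = rng.random((v, v)) + 0.1
        self._markov = markov / markov.sum(axis=1, keepdims=True)

    def probability_row(self, prev: Optional[str], position: int) -> np.ndarray:
        """Exact next-token probabilities given the previous residue."""
        v = len(self.tokens)
        uniform = np.full(v, 1.0 / v)
        if prev is None or prev not in self._tok_idx:
            bg = uniform
        else:
            bg = (
                (1 - self.markov_blend) * uniform
                + self.markov_blend * self._markov[self._tok_idx[prev]]
            )
        onehot = np.zeros(v)
        if position < len(self.target):
            onehot[self._tok_idx[self.target[position]]] = 1.0
        else:
            onehot = uniform
        probs = (self.concentration * onehot + bg) / (self.concentration + 1.0)
        return probs / probs.sum()

    def log_probs(
        self, assignment: Sequence[Optional[str]], position: int
    ) -> np.ndarray:
        prev = assignment[position - 1] if position > 0 else None
        return np.log(self.probability_row(prev, position))


def toy_sequence_model(
    target: str,
    concentration: float = 1.0,
    markov_blend: float = 0.0,
    seed: int = 0,
    alphabet: str | None = None,
) -> ToySequenceModel:
    """Factory matching the sequence-model contract; see :class:`ToySequenceModel`."""
    return ToySequenceModel(target, concentration, markov_blend, seed, alphabet)
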