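"""Fast approximate MHC-I presentation classifier built on PWMs.

External presentation predictors are far too slow to be queried once per
candidate kmer during constrained decoding, so designs are screened with a
position weight matrix (PWM) trained per allele and per peptide length
(8, 9, 10).  A peptide's score is the sum of per-position log-odds weights

    w[a, p] = log2( (count(a at p) + pseudocount) / (n + 20 * pseudocount)
                    / background_freq[a] )

estimated from peptides labelled *presented* for that allele.  The score
threshold is calibrated so that a target fraction of background peptides
(default 2%, mirroring the conventional "weak binder" rank cutoff) scores at
or above it; a peptide is *presented by a genotype* when at least one of its
alleles' PWMs scores it at or above threshold.

Also implemented here: presentation-profile distances between alleles (the
percentage of a shared peptide panel on which two alleles' verdicts differ)
and max-min selection of an alternative genotype that is maximally dissimilar
to a primary genotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .proteome import STANDARD_AA

PEPTIDE_LENGTHS = (8, 9, 10)

_AA_TO_IDX = {a: i for i, a in enumerate(STANDARD_AA)}


@dataclass(frozen=True, order=True)
class Allele:
    """An MHC-I allele, e.g. ``HLA-A*02:01``."""

    name: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("allele name must be non-empty")

    @property
    def gene(self) -> str:
        """Gene prefix (``HLA-A``/``HLA-B``/``HLA-C``) used for genotype grouping."""
        return self.name.split("*")[0]


@dataclass(frozen=True)
class Genotype:
    """1..6 MHC-I alleles of one individual; duplicates mark homozygosity."""

    alleles: tuple[Allele, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.alleles) <= 6:
            raise ValueError("a genotype carries between 1 and 6 alleles")

    @property
    def unique_alleles(self) -> tuple[Allele, ...]:
        seen: dict[Allele, None] = {}
        for a in self.alleles:
            seen.setdefault(a)
        return tuple(seen)


def encode_peptides(peptides: Sequence[str], k: int) -> np.ndarray:
    """Encode equal-length peptides as an (n, k) int matrix; ``X`` -> -1."""
    out = np.empty((len(peptides), k), dtype=np.int64)
    for i, pep in enumerate(peptides):
        if len(pep) != k:
            raise ValueError(f"peptide {pep!r} has length {len(pep)}, expected {k}")
        for p, aa in enumerate(pep):
            out[i, p] = _AA_TO_IDX.get(aa, -1)
    return out


@dataclass
class PWM:
    """Per-allele, fixed-length position weight matrix with a score cutoff."""

    allele: Allele
    k: int
    weights: np.ndarray  # (20, k) log2 odds
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (20, self.k):
            raise ValueError(
                f"weights shape {self.weights.shape} != (20, {self.k})"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("PWM weights must be finite (use a pseudocount)")

    def score(self, peptide: str) -> float:
        return score_peptide(self, peptide)

    def score_many(self, peptides: Sequence[str]) -> np.ndarray:
        """Vectorised scoring; peptides containing ``X`` score -inf."""
        enc = encode_peptides(peptides, self.k)
        valid = (enc >= 0).all(axis=1)
        scores = np.full(len(peptides), -np.inf)
        if valid.any():
            idx = enc[valid]
            scores[valid] = self.weights[idx, np.arange(self.k)].sum(axis=1)
        return scores


def train_pwm(
    presented_peptides: Sequence[str],
    background_freqs: Sequence[float] | None = None,
    pseudocount: float = 0.5,
    allele: Allele | None = None,
) -> PWM:
    """Estimate log2 frequency-over-background weights from presented peptides.

    ``background_freqs`` is a 20-vector over :data:`STANDARD_AA` order summing
    to one (uniform by default).  Deterministic and order-invariant.
    """
    if not presented_peptides:
        raise ValueError("need at least one presented peptide")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    k = len(presented_peptides[0])
    if background_freqs is None:
        bg = np.full(20, 1 / 20)
    else:
        bg = np.asarray(background_freqs, dtype=float)
        if bg.shape != (20,):
            raise ValueError("background_freqs must have 20 entries")
        if np.any(bg <= 0):
            raise ValueError("background frequencies must be positive")
    enc = encode_peptides(presented_peptides, k)
    if (enc < 0).any():
        raise ValueError("training peptides must use standard residues only")
    n = len(presented_peptides)
    counts = np.zeros((20, k))
    for p in range(k):
        counts[:, p] = np.bincount(enc[:, p], minlength=20)
    freqs = (counts + pseudocount) / (n + 20 * pseudocount)
    weights = np.log2(freqs / bg[:, None])
    return PWM(allele=allele or Allele("synthetic"), k=k, weights=weights)


def score_peptide(pwm: PWM, peptide: str) -> float:
    """Additive PWM score; any non-standard residue makes the score -inf."""
    if len(peptide) != pwm.k:
        raise ValueError(f"peptide length {len(peptide)} != PWM length {pwm.k}")
    total = 0.0
    for p, aa in enumerate(peptide):
        i = _AA_TO_IDX.get(aa)
        if i is None:
            return -math.inf
        total += pwm.weights[i, p]
    return total


def calibrate_threshold(
    pwm: PWM,
    background_peptides: Sequence[str],
    target_presented_fraction: float = 0.02,
) -> PWM:
    """Set the cutoff to the nearest-rank (1 - target) background quantile.

    After calibration roughly ``target_presented_fraction`` of the background
    peptides score at or above the threshold.  Requires >= 1000 background
    peptides so the quantile is resolved.
    """
    if not 0 < target_presented_fraction < 1:
        raise ValueError("target_presented_fraction must be in (0, 1)")
    n = len(background_peptides)
    if n < 1000:
        raise ValueError(
            f"need >= 1000 background peptides to calibrate, got {n}"
        )
    scores = np.sort(pwm.score_many(background_peptides))
    rank = math.ceil((1 - target_presented_fraction) * n)  # 1-based, ceiling
    threshold = float(scores[rank - 1])
    return replace(pwm, weights=pwm.weights.copy(), threshold=threshold)


@dataclass
class PresentationModel:
    """One calibrated PWM per (allele, peptide length) pair."""

    pwms: dict[tuple[str, int], PWM]
    lengths_covered: tuple[int, ...] = PEPTIDE_LENGTHS

    @classmethod
    def from_pwms(cls, pwms: Iterable[PWM]) -> "PresentationModel":
        table: dict[tuple[str, int], PWM] = {}
        for pwm in pwms:
            table[(pwm.allele.name, pwm.k)] = pwm
        return cls(pwms=table)

    def pwm_for(self, allele: Allele, k: int) -> PWM:
        try:
            return self.pwms[(allele.name, k)]
        except KeyError:
            raise KeyError(
                f"no PWM for allele {allele.name} at length {k}: model incomplete"
            ) from None


def is_presented(model: PresentationModel, genotype: Genotype, peptide: str) -> bool:
    """OR over alleles: presented if any allele's PWM scores >= its threshold."""
    k = len(peptide)
    if k not in PEPTIDE_LENGTHS:
        raise ValueError(f"presentation is defined for lengths {PEPTIDE_LENGTHS}")
    for allele in genotype.unique_alleles:
        pwm = model.pwm_for(allele, k)
        if pwm.threshold is None:
            raise ValueError(
                f"PWM for {allele.name} length {k} has no calibrated threshold"
            )
        if score_peptide(pwm, peptide) >= pwm.threshold:
            return True
    return False


# ---------------------------------------------------------------------------
# presentation profiles and alternative-genotype selection


@dataclass
class PresentationProfile:
    """Boolean presented/hidden verdicts of one allele over a fixed panel."""

    allele: Allele
    verdicts: np.ndarray

    def __post_init__(self) -> None:
        self.verdicts = np.asarray(self.verdicts, dtype=bool)
        if self.verdicts.ndim != 1 or len(self.verdicts) < 1:
            raise ValueError("verdicts must be a non-empty 1-D boolean vector")


def profile_for_allele(
    model: PresentationModel, allele: Allele, panel: Sequence[str]
) -> PresentationProfile:
    """Evaluate one allele's verdicts over a shared peptide panel."""
    single = Genotype(alleles=(allele,))
    verdicts = np.fromiter(
        (is_presented(model, single, pep) for pep in panel), dtype=bool, count=len(panel)
    )
    return PresentationProfile(allele=allele, verdicts=verdicts)


def allele_distance(a: PresentationProfile, b: PresentationProfile) -> float:
    """Percent of panel peptides on which the two verdict vectors disagree."""
    if len(a.verdicts) != len(b.verdicts):
        raise ValueError(
            f"panel length mismatch: {len(a.verdicts)} vs {len(b.verdicts)}"
        )
    return 100.0 * float(np.count_nonzero(a.verdicts != b.verdicts)) / len(a.verdicts)


def select_alternative_genotype(
    candidates_by_gene: Mapping[str, Sequence[Allele]],
    primary: Genotype,
    distances: Mapping[tuple[str, str], float],
) -> Genotype:
    """Max-min genotype selection: per gene, the two candidates whose minimum
    distance to any primary allele is largest.

    ``distances[(candidate_name, primary_name)]`` is the presentation-profile
    distance in percent.  Ties are broken by lexicographic allele name, genes
    are emitted in sorted order, so the result is deterministic.
    """
    chosen: list[Allele] = []
    for gene in sorted(candidates_by_gene):
        candidates = candidates_by_gene[gene]
        if len(candidates) < 2:
            raise ValueError(f"gene {gene}: need at least 2 candidate alleles")

        def min_dist(c: Allele) -> float:
            return min(distances[(c.name, p.name)] for p in primary.unique_alleles)

        ranked = sorted(candidates, key=lambda c: (-min_dist(c), c.name))
        chosen.extend(ranked[:2])
    return Genotype(alleles=tuple(chosen))


# ---------------------------------------------------------------------------
# PWM persistence: one TSV per (allele, length)

def save_pwm(pwm: PWM, path: str | Path) -> None:
    """Write a PWM as TSV: header line with allele/k/threshold, 20 weight rows."""
    with open(path, "w") as fh:
        thr = "NA" if pwm.threshold is None else format(pwm.threshold, ".12g")
        fh.write(f"#allele\t{pwm.allele.name}\tk\t{pwm.k}\tthreshold\t{thr}\n")
        fh.write("residue\t" + "\t".join(f"pos{p + 1}" for p in range(pwm.k)) + "\n")
        for i, aa in enumerate(STANDARD_AA):
            row = "\t".join(format(w, ".12g") for w in pwm.weights[i])
            fh.write(f"{aa}\t{row}\n")


def load_pwm(path: str | Path) -> PWM:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 6 or header[0] != "#allele":
            raise ValueError(f"{path}: not a PWM file")
        allele, k, thr = Allele(header[1]), int(header[3]), header[5]
        fh.readline()  # column header
        weights = np.empty((20, k))
        for i, aa in enumerate(STANDARD_AA):
            fields = fh.readline().rstrip("\n").split("\t")
            if fields[0] != aa:
                raise ValueError(f"{path}: expected residue row {aa}, got {fields[0]}")
            weights[i] = [float(x) for x in fields[1:]]
    threshold = None if thr == "NA" else float(thr)
    return PWM(allele=allele, k=k, weights=weights, threshold=threshold)
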