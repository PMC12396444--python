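"""Kmer permissibility rules for constrained decoding.

Every kmer of a design, up to ``max_checked_kmer_len`` (10, the longest
canonical MHC-I peptide), must be *permissible*:

* length <= ``min_self_kmer_len``: the kmer must occur in the reference
  proteome (SELF), otherwise it is FORBIDDEN;
* longer lengths: the kmer may be SELF, or — if it is absent from the
  proteome — it must be predicted *not presented* by the patient's genotype
  (HIDDEN_NONSELF).  A presented non-self 8-10mer is FORBIDDEN.

Non-self kmers of lengths between ``min_self_kmer_len`` and 8 are classified
HIDDEN_NONSELF: MHC-I presentation is modelled only for 8-10mers, so there is
no predictor to consult, but they still count toward the hidden penalty.

When a position is filled, only the windows that *became fully filled at that
step* need to be checked; for strict left-to-right decoding these are exactly
the suffixes ending at the new position.  The general form (some positions
pre-filled out of order) is handled by :func:`completed_windows`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from .presentation import PEPTIDE_LENGTHS, Genotype, PresentationModel, is_presented
from .proteome import KmerIndex, is_self


class KmerClass(enum.Enum):
    SELF = "self"
    HIDDEN_NONSELF = "hidden_nonself"
    FORBIDDEN = "forbidden"


@dataclass(frozen=True)
class PermissibilityPolicy:
    """Rule-set parameters: which lengths must be self, which merely hidden.

    ``non_self_prob_factor`` in [0, 1] is the multiplicative penalty applied
    (per lookahead step) to the estimated future probability of extensions
    that rely on hidden non-self kmers; 1 disables the penalty, 0 makes it
    absolute.
    """

    min_self_kmer_len: int = 6
    max_checked_kmer_len: int = 10
    non_self_prob_factor: float = 0.9

    def __post_init__(self) -> None:
        if not 1 <= self.min_self_kmer_len <= self.max_checked_kmer_len:
            raise ValueError(
                "require 1 <= min_self_kmer_len <= max_checked_kmer_len"
            )
        if not 0.0 <= self.non_self_prob_factor <= 1.0:
            raise ValueError("non_self_prob_factor must be in [0, 1]")


@dataclass
class ExtensionVerdict:
    """Outcome of checking all newly formed kmers of a candidate extension."""

    permissible: bool
    hidden_nonself_count: int
    checked_kmers: list[tuple[str, KmerClass]]


def window_spans(
    filled: Sequence[bool], pos: int, max_len: int
) -> list[tuple[int, int]]:
    """Half-open spans ``[s, e)`` of windows newly completed by filling ``pos``.

    A window qualifies if it has length 1..max_len, contains ``pos``, every
    position in it is filled (with ``pos`` counted as filled), and it was not
    fully filled before.  Sorted shortest-first, then left-to-right.
    """
    n = len(filled)
    if not 0 <= pos < n:
        raise ValueError(f"position {pos} out of range 0..{n - 1}")
    spans: list[tuple[int, int]] = []
    for length in range(1, max_len + 1):
        for s in range(max(0, pos - length + 1), min(pos, n - length) + 1):
            e = s + length
            if all(filled[i] or i == pos for i in range(s, e)):
                spans.append((s, e))
    return spans


def completed_windows(
    assignment: Sequence[Optional[str]], pos: int, max_len: int
) -> list[str]:
    """The kmers that became fully determined when ``pos`` was filled.

    ``assignment`` holds one residue per position, ``None`` where still
    unfilled; ``assignment[pos]`` must already carry the new residue.  For
    strict left-to-right decoding this returns the suffixes ending at ``pos``
    of lengths 1..min(max_len, pos + 1).
    """
    if assignment[pos] is None:
        raise ValueError(f"position {pos} is not filled")
    filled = [r is not None and i != pos for i, r in enumerate(assignment)]
    spans = window_spans(filled, pos, max_len)
    return ["".join(assignment[s:e]) for s, e in spans]  # type: ignore[arg-type]


def classify_kmer(
    kmer: str,
    index: KmerIndex,
    model: PresentationModel | None,
    genotype: Genotype | None,
    policy: PermissibilityPolicy,
) -> KmerClass:
    """SELF / HIDDEN_NONSELF / FORBIDDEN classification of a single kmer.

    ``model``/``genotype`` may be None only when no 8-10mer can reach the
    presentation check (e.g. max_checked_kmer_len < 8).
    """
    k = len(kmer)
    if k < 1 or k > policy.max_checked_kmer_len:
        raise ValueError(
            f"kmer length {k} exceeds max_checked_kmer_len "
            f"{policy.max_checked_kmer_len}"
        )
    self_kmer = is_self(index, kmer)
    if k <= policy.min_self_kmer_len:
        return KmerClass.SELF if self_kmer else KmerClass.FORBIDDEN
    if self_kmer:
        return KmerClass.SELF
    if k not in PEPTIDE_LENGTHS:
        return KmerClass.HIDDEN_NONSELF
    if model is None or genotype is None:
        raise ValueError("a presentation model is required to classify 8-10mers")
    if is_presented(model, genotype, kmer):
        return KmerClass.FORBIDDEN
    return KmerClass.HIDDEN_NONSELF


def extension_verdict(
    assignment: Sequence[Optional[str]],
    pos: int,
    candidate_residue: str,
    index: KmerIndex,
    model: PresentationModel | None,
    genotype: Genotype | None,
    policy: PermissibilityPolicy,
    stop_on_forbidden: bool = False,
) -> ExtensionVerdict:
    """Classify every window newly completed by placing ``candidate_residue``.

    The unknown token ``X`` is never SELF (the index holds no X kmers), so it
    is FORBIDDEN at lengths <= min_self_kmer_len — effectively impermissible
    once any context exists.  With ``stop_on_forbidden`` the scan short-cuts
    at the first FORBIDDEN window (used by the decoder's hot path);
    ``checked_kmers`` then lists only the windows examined.
    """
    trial = list(assignment)
    trial[pos] = candidate_residue
    kmers = completed_windows(trial, pos, policy.max_checked_kmer_len)
    checked: list[tuple[str, KmerClass]] = []
    hidden = 0
    permissible = True
    for kmer in kmers:
        cls = classify_kmer(kmer, index, model, genotype, policy)
        checked.append((kmer, cls))
        if cls is KmerClass.FORBIDDEN:
            permissible = False
            if stop_on_forbidden:
                break
        elif cls is KmerClass.HIDDEN_NONSELF:
            hidden += 1
    return ExtensionVerdict(
        permissible=permissible, hidden_nonself_count=hidden, checked_kmers=checked
    )


class PermissibilityChecker:
    """Caching wrapper binding (index, model, genotype, policy).

    Classification of a kmer is pure, so results are memoised — the decoder
    re-examines the same windows many times during lookahead.
    """

    def __init__(
        self,
        index: KmerIndex,
        model: PresentationModel | None,
        genotype: Genotype | None,
        policy: PermissibilityPolicy,
    ) -> None:
        if index.max_len < policy.max_checked_kmer_len:
            raise ValueError(
                f"index max_len {index.max_len} < policy max_checked_kmer_len "
                f"{policy.max_checked_kmer_len}"
            )
        self.index = index
        self.model = model
        self.genotype = genotype
        self.policy = policy
        self._cache: dict[str, KmerClass] = {}

    def classify(self, kmer: str) -> KmerClass:
        cls = self._cache.get(kmer)
        if cls is None:
            cls = classify_kmer(kmer, self.index, self.model, self.genotype, self.policy)
            self._cache[kmer] = cls
        return cls

    def verdict_for_spans(
        self,
        sequence: Sequence[Optional[str]],
        spans: Sequence[tuple[int, int]],
        stop_on_forbidden: bool = True,
    ) -> ExtensionVerdict:
        """Verdict over precomputed window spans (decoder hot path)."""
        checked: list[tuple[str, KmerClass]] = []
        hidden = 0
        permissible = True
        for s, e in spans:
            kmer = "".join(sequence[s:e])  # type: ignore[arg-type]
            cls = self.classify(kmer)
            checked.append((kmer, cls))
            if cls is KmerClass.FORBIDDEN:
                permissible = False
                if stop_on_forbidden:
                    break
            elif cls is KmerClass.HIDDEN_NONSELF:
                hidden += 1
        return ExtensionVerdict(
            permissible=permissible, hidden_nonself_count=hidden, checked_kmers=checked
        )
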