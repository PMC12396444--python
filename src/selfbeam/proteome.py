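"""Reference-proteome kmer index: the "self" oracle.

A designed peptide that also occurs somewhere in the reference proteome is a
*self* kmer: central tolerance should keep cytotoxic T-lymphocytes from
reacting to it.  This module builds an exact per-length membership structure
over all kmers of a proteome (up to a configurable length, 10 by default to
cover the canonical MHC-I peptide lengths) and answers membership queries.

Sequences are uppercased on ingest; ``*`` stop characters split a record into
independent segments so windows never span a stop; rare or ambiguous residue
codes (U, B, Z, J, O) are mapped to ``X``, and any window overlapping an ``X``
is excluded from the self set — self-ness is simply not defined for ambiguous
residues, and exclusion is the conservative choice.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

#: The 20 standard amino-acid one-letter codes, in canonical order.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Unknown / ambiguous residue token.
UNKNOWN = "X"
#: Full ingest alphabet: 20 standard residues plus the unknown token.
ALPHABET = STANDARD_AA + UNKNOWN

_STANDARD_SET = frozenset(STANDARD_AA)
_ALPHABET_SET = frozenset(ALPHABET)
# Rare / ambiguous codes treated like 'X' on FASTA ingest.
_RARE_CODES = "UBZJO"


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: an identifier and a sequence over the 21-letter alphabet.

    ``*`` is additionally tolerated as an in-sequence stop marker (Ensembl
    protein FASTA contains it in some records); kmer windows never cross it.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _ALPHABET_SET - {"*"}
        if bad:
            raise ValueError(
                f"protein {self.id!r}: characters outside the 21-letter "
                f"alphabet: {sorted(bad)!r}"
            )


@dataclass(eq=False)
class KmerIndex:
    """Per-length exact sets of all proteome kmers up to ``max_len``."""

    max_len: int
    members: dict[int, frozenset[str]]
    source_digest: str = ""

    def __post_init__(self) -> None:
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")

    def count(self, k: int) -> int:
        return len(self.members[k])


def _normalize(sequence: str) -> str:
    seq = sequence.upper()
    for code in _RARE_CODES:
        seq = seq.replace(code, UNKNOWN)
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (possibly line-wrapped, multi-record) protein FASTA.

    Rare residue codes are mapped to ``X``; sequences are uppercased.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(id=rec.id, sequence=_normalize(str(rec.seq))))
    return records


def build_kmer_index(proteins: Iterable[ProteinRecord], max_len: int) -> KmerIndex:
    """Index every X-free kmer window of length 1..max_len of the proteome.

    Windows never span two records nor a ``*`` stop character.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    members: dict[int, set[str]] = {k: set() for k in range(1, max_len + 1)}
    digest = hashlib.sha256()
    for rec in proteins:
        seq = _normalize(rec.sequence)
        bad = set(seq) - _ALPHABET_SET - {"*"}
        if bad:
            raise ValueError(
                f"protein {rec.id!r}: characters outside the 21-letter "
                f"alphabet: {sorted(bad)!r}"
            )
        digest.update(rec.id.encode())
        digest.update(b"\x00")
        digest.update(seq.encode())
        digest.update(b"\x00")
        for segment in seq.split("*"):
            n = len(segment)
            # positions of 'X' let us skip overlapping windows cheaply
            x_pos = [i for i, c in enumerate(segment) if c == UNKNOWN]
            for k in range(1, min(max_len, n) + 1):
                target = members[k]
                if not x_pos:
                    for i in range(n - k + 1):
                        target.add(segment[i : i + k])
                else:
                    next_x = 0
                    for i in range(n - k + 1):
                        while next_x < len(x_pos) and x_pos[next_x] < i:
                            next_x += 1
                        if next_x < len(x_pos) and x_pos[next_x] < i + k:
                            continue
                        target.add(segment[i : i + k])
    return KmerIndex(
        max_len=max_len,
        members={k: frozenset(v) for k, v in members.items()},
        source_digest=digest.hexdigest(),
    )


def is_self(index: KmerIndex, kmer: str) -> bool:
    """Exact membership: is this kmer a substring of the reference proteome?"""
    k = len(kmer)
    if k < 1 or k > index.max_len:
        raise ValueError(
            f"kmer length {k} outside the indexed range 1..{index.max_len}"
        )
    return kmer in index.members[k]


# ---------------------------------------------------------------------------
# serialization (plain text, round-trips exactly)

_MAGIC = "#selfbeam-kmer-index\tv1"


def save_index(index: KmerIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{_MAGIC}\n")
        fh.write(f"max_len\t{index.max_len}\n")
        fh.write(f"digest\t{index.source_digest}\n")
        for k in range(1, index.max_len + 1):
            kmers = sorted(index.members[k])
            fh.write(f"k\t{k}\t{len(kmers)}\n")
            for kmer in kmers:
                fh.write(kmer + "\n")


def load_index(path: str | Path) -> KmerIndex:
    with open(path) as fh:
        if fh.readline().rstrip("\n") != _MAGIC:
            raise ValueError(f"{path}: not a kmer index file")
        _, max_len_s = fh.readline().split("\t")
        _, digest = fh.readline().rstrip("\n").split("\t")
        max_len = int(max_len_s)
        members: dict[int, frozenset[str]] = {}
        for k in range(1, max_len + 1):
            tag, k_s, count_s = fh.readline().rstrip("\n").split("\t")
            if tag != "k" or int(k_s) != k:
                raise ValueError(f"{path}: malformed length block for k={k}")
            members[k] = frozenset(
                fh.readline().rstrip("\n") for _ in range(int(count_s))
            )
    return KmerIndex(max_len=max_len, members=members, source_digest=digest)


def write_index_summary(index: KmerIndex, path: str | Path) -> None:
    """TSV with one row per kmer length: length, member count."""
    with open(path, "w") as fh:
        fh.write("length\tmember_count\n")
        for k in range(1, index.max_len + 1):
            fh.write(f"{k}\t{index.count(k)}\n")
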