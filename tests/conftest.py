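"""Shared fixtures: synthetic proteomes, anchored alleles, toy models.

Session scope keeps index construction and PWM training out of individual
test timings; everything is seeded so the suite is reproducible.
"""

from __future__ import annotations

import numpy as np
import pytest

import selfbeam as sb

SMALL_ALPHABET = "ACDE"


@pytest.fixture(scope="session")
def proteome_records():
    spec = sb.FixtureSpec(seed=7, n_proteins=120, protein_length_range=(150, 250))
    return sb.generate_proteome(spec)


@pytest.fixture(scope="session")
def index(proteome_records):
    return sb.build_kmer_index(proteome_records, 10)


@pytest.fixture(scope="session")
def allele_specs():
    return {
        "HLA-A*01:01": sb.AlleleSpec((1, -1), ("LM", "KR")),
        "HLA-B*01:01": sb.AlleleSpec((2, -1), ("FY", "DE")),
    }


@pytest.fixture(scope="session")
def pres_model(allele_specs):
    return sb.synthetic_presentation_model(
        allele_specs, seed=3, n_train=500, n_background=5000
    )


@pytest.fixture(scope="session")
def genotype():
    return sb.Genotype((sb.Allele("HLA-A*01:01"), sb.Allele("HLA-B*01:01")))


def _flat_model(threshold: float) -> sb.PresentationModel:
    """All-zero-weight PWMs: every standard peptide scores 0."""
    pwms = []
    for name in ("HLA-A*01:01", "HLA-B*01:01"):
        for k in sb.PEPTIDE_LENGTHS:
            pwms.append(
                sb.PWM(sb.Allele(name), k, np.zeros((20, k)), threshold=threshold)
            )
    return sb.PresentationModel.from_pwms(pwms)


@pytest.fixture(scope="session")
def never_presenting_model():
    """Thresholds above any achievable score: nothing is ever presented."""
    return _flat_model(threshold=1.0)


@pytest.fixture(scope="session")
def always_presenting_model():
    """Thresholds below any achievable score: every standard peptide presented."""
    return _flat_model(threshold=-1.0)


@pytest.fixture(scope="session")
def tiny_records():
    spec = sb.FixtureSpec(
        seed=13, n_proteins=6, protein_length_range=(25, 35), alphabet=SMALL_ALPHABET
    )
    return sb.generate_proteome(spec)


@pytest.fixture(scope="session")
def tiny_index(tiny_records):
    return sb.build_kmer_index(tiny_records, 10)
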