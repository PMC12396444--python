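"""Beam search: lookahead scoring, pruning, dedupe, fallback, and oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

import selfbeam as sb
from tests.conftest import SMALL_ALPHABET

NO_DEDUPE = 99  # suffix length longer than any test sequence disables dedupe


def seq_logprob(model, seq: str) -> float:
    """Independent accumulation of the model's per-position log-probs."""
    assignment: list = [None] * len(seq)
    total = 0.0
    for pos, aa in enumerate(seq):
        lp = model.log_probs(assignment, pos)
        total += float(lp[model.tokens.index(aa)])
        assignment[pos] = aa
    return total


def sequence_is_permissible(seq: str, index, pres_model, genotype, policy) -> bool:
    """Brute-force re-scan: no window of any checked length may be FORBIDDEN."""
    for k in range(1, policy.max_checked_kmer_len + 1):
        for s in range(len(seq) - k + 1):
            cls = sb.classify_kmer(seq[s : s + k], index, pres_model, genotype, policy)
            if cls is sb.KmerClass.FORBIDDEN:
                return False
    return True


def enumerate_permissible(model, length, index, pres_model, genotype, policy):
    out = []
    for letters in itertools.product(model.tokens, repeat=length):
        seq = "".join(letters)
        if sequence_is_permissible(seq, index, pres_model, genotype, policy):
            out.append(seq)
    return out


@pytest.fixture(scope="module")
def tiny_policy():
    return sb.PermissibilityPolicy(
        min_self_kmer_len=3, max_checked_kmer_len=6, non_self_prob_factor=0.9
    )


class TestFutureLogprob:
    def test_depth_zero_equals_own_logprob(self, tiny_index, tiny_policy):
        model = sb.toy_sequence_model(
            "ACDA", concentration=1.0, seed=2, alphabet=SMALL_ALPHABET
        )
        cfg = sb.DecodeConfig(depth=0, policy=tiny_policy)
        a: list = [None] * 4
        residue = next(
            t for t in model.tokens
            if sb.extension_verdict(a, 0, t, tiny_index, None, None, tiny_policy).permissible
        )
        own = float(model.log_probs(a, 0)[model.tokens.index(residue)])
        got = sb.future_logprob(model, a, 0, residue, cfg, tiny_index, None, None)
        assert got == pytest.approx(own)

    def test_unit_factor_is_penalty_free_greedy_sum(self, tiny_index):
        policy = sb.PermissibilityPolicy(
            min_self_kmer_len=3, max_checked_kmer_len=6, non_self_prob_factor=1.0
        )
        model = sb.toy_sequence_model(
            "ACDADC", concentration=0.8, markov_blend=0.4, seed=3,
            alphabet=SMALL_ALPHABET,
        )
        cfg = sb.DecodeConfig(depth=2, policy=policy)
        a: list = ["A", "C"] + [None] * 4
        # independent greedy walk over permissible residues
        def greedy_expected(residue):
            trial = list(a)
            trial[2] = residue
            total = float(model.log_probs(a, 2)[model.tokens.index(residue)])
            for pos in (3, 4):
                lp = model.log_probs(trial, pos)
                best = None
                for i in np.argsort(-np.asarray(lp), kind="stable"):
                    tok = model.tokens[i]
                    v = sb.extension_verdict(trial, pos, tok, tiny_index, None, None, policy)
                    if v.permissible:
                        best = (tok, float(lp[i]))
                        break
                assert best is not None
                trial[pos] = best[0]
                total += best[1]
            return total

        for residue in model.tokens:
            v = sb.extension_verdict(a, 2, residue, tiny_index, None, None, policy)
            if not v.permissible:
                continue
            got = sb.future_logprob(model, a, 2, residue, cfg, tiny_index, None, None)
            assert got == pytest.approx(greedy_expected(residue))

    def test_hidden_extension_charged_depth_log_factors(self):
        # proteome of one protein; min_self=1 so single letters are self, but
        # the 2-mer "CA" is absent -> extension relies on a hidden kmer
        idx = sb.build_kmer_index([sb.ProteinRecord("p", "ACD")], 10)
        policy = sb.PermissibilityPolicy(
            min_self_kmer_len=1, max_checked_kmer_len=2, non_self_prob_factor=0.5
        )
        model = sb.toy_sequence_model("CAAA", concentration=0.0, alphabet="ACD")
        cfg = sb.DecodeConfig(depth=2, policy=policy, penalize_lookahead=False)
        a: list = ["C"] + [None] * 3
        own = float(model.log_probs(a, 1)[model.tokens.index("A")])
        got = sb.future_logprob(model, a, 1, "A", cfg, idx, None, None)
        # greedy lookahead from "CA": uniform model ties resolved by token
        # order; every continuation log-prob is log(1/3)
        expected = own + 2 * math.log(1 / 3) + 2 * math.log(0.5)
        assert got == pytest.approx(expected)


class TestStep:
    def test_beam_count_and_suffix_uniqueness(self, tiny_index, tiny_policy):
        model = sb.toy_sequence_model(
            "ACDADC", concentration=0.5, markov_blend=0.3, seed=5,
            alphabet=SMALL_ALPHABET,
        )
        cfg = sb.DecodeConfig(width=3, depth=0, dedupe_suffix_len=2, policy=tiny_policy)
        beams = [sb.Beam(residues=(None,) * 6, cum_logprob=0.0)]
        filled: list[int] = []
        for pos in range(4):
            beams = sb.step(beams, pos, model, cfg, tiny_index, None, None)
            filled.append(pos)
            assert len(beams) <= cfg.width
            suffixes = [b.suffix_key(filled, cfg.dedupe_suffix_len) for b in beams]
            assert len(suffixes) == len(set(suffixes))

    def test_same_suffix_beams_collapse_to_most_likely(self, tiny_index, tiny_policy):
        model = sb.toy_sequence_model(
            "AC", concentration=0.5, seed=6, alphabet=SMALL_ALPHABET
        )
        cfg = sb.DecodeConfig(width=10, depth=0, dedupe_suffix_len=1, policy=tiny_policy)
        beams = [sb.Beam(residues=(None, None), cum_logprob=0.0)]
        beams = sb.step(beams, 0, model, cfg, tiny_index, None, None)
        beams = sb.step(beams, 1, model, cfg, tiny_index, None, None)
        # with a suffix length of 1, at most |alphabet| beams may survive and
        # each last letter appears once, carried by its best-scoring prefix
        last = [b.residues[1] for b in beams]
        assert len(last) == len(set(last))
        for b in beams:
            siblings = [
                c for c in beams if c.residues[1] == b.residues[1] and c is not b
            ]
            assert not siblings

    def test_fallback_when_nothing_is_permissible(self):
        # proteome letters are disjoint from the model's alphabet
        idx = sb.build_kmer_index([sb.ProteinRecord("p", "FGHIKFGHIK")], 10)
        model = sb.toy_sequence_model("ACDA", concentration=2.0, alphabet=SMALL_ALPHABET)
        cfg = sb.DecodeConfig(width=2, depth=0)
        seq, beam, report = sb.decode(
            model, sb.TemplateContext(4), cfg, idx, None, None
        )
        assert report["fallback_positions"] == [0, 1, 2, 3]
        # raw most-probable residues still chosen deterministically
        assert seq == "ACDA"


class TestDecode:
    def test_length_one_returns_most_probable_self_letter(self, tiny_index, tiny_policy):
        model = sb.toy_sequence_model("C", concentration=3.0, alphabet=SMALL_ALPHABET)
        cfg = sb.DecodeConfig(depth=0, policy=tiny_policy)
        seq, _, report = sb.decode(
            model, sb.TemplateContext(1), cfg, tiny_index, None, None
        )
        assert seq == "C" and report["fallback_positions"] == []

    def test_recovers_concentrated_permissible_target(self, tiny_records, tiny_index, tiny_policy):
        target = tiny_records[0].sequence[:12]  # a genuine proteome substring
        model = sb.toy_sequence_model(target, concentration=50.0, alphabet=SMALL_ALPHABET)
        cfg = sb.DecodeConfig(policy=tiny_policy)
        seq, _, report = sb.decode(
            model, sb.TemplateContext(len(target)), cfg, tiny_index, None, None
        )
        assert seq == target and report["fallback_positions"] == []

    @pytest.mark.parametrize("seed", range(8))
    def test_exhaustive_argmax_oracle_on_tiny_instances(self, seed, tiny_index, tiny_policy):
        """Width >= #permissible and depth 0 must find the global argmax."""
        model = sb.toy_sequence_model(
            "".join(np.random.default_rng(seed).choice(list(SMALL_ALPHABET), 6)),
            concentration=1.5, markov_blend=0.5, seed=seed, alphabet=SMALL_ALPHABET,
        )
        cfg = sb.DecodeConfig(
            width=5000, depth=0, dedupe_suffix_len=NO_DEDUPE, policy=tiny_policy
        )
        seq, beam, report = sb.decode(
            model, sb.TemplateContext(6), cfg, tiny_index, None, None
        )
        permissible = enumerate_permissible(model, 6, tiny_index, None, None, tiny_policy)
        assert permissible, "fixture must admit at least one permissible sequence"
        best = max(permissible, key=lambda s: (seq_logprob(model, s), s))
        assert report["fallback_positions"] == []
        assert seq == best
        assert beam.cum_logprob == pytest.approx(seq_logprob(model, best))

    def test_no_fallback_decode_has_zero_forbidden_windows(self, index, pres_model, genotype):
        """Safety guarantee: brute-force re-scan finds no forbidden kmer."""
        policy = sb.PermissibilityPolicy(min_self_kmer_len=5)
        for seed in range(3):
            target = "".join(
                np.random.default_rng(100 + seed).choice(list(sb.STANDARD_AA), 45)
            )
            model = sb.toy_sequence_model(
                target, concentration=2.0, markov_blend=0.5, seed=seed
            )
            cfg = sb.DecodeConfig(policy=policy, seed=seed)
            seq, _, report = sb.decode(
                model, sb.TemplateContext(45), cfg, index, pres_model, genotype
            )
            if report["fallback_positions"]:
                continue
            # independent scan, not going through the permissibility module
            for k in range(1, policy.min_self_kmer_len + 1):
                for s in range(len(seq) - k + 1):
                    assert sb.is_self(index, seq[s : s + k])
            for k in (8, 9, 10):
                for s in range(len(seq) - k + 1):
                    window = seq[s : s + k]
                    if not sb.is_self(index, window):
                        assert not sb.is_presented(pres_model, genotype, window)

    def test_unresolved_positions_are_presampled_and_reported(self, tiny_index, tiny_policy):
        model = sb.toy_sequence_model(
            "ACDADC", concentration=1.0, seed=9, alphabet=SMALL_ALPHABET
        )
        cfg = sb.DecodeConfig(policy=tiny_policy, seed=4)
        ctx = sb.TemplateContext(6, unresolved=frozenset({5}))
        seq1, _, rep1 = sb.decode(model, ctx, cfg, tiny_index, None, None)
        seq2, _, rep2 = sb.decode(model, ctx, cfg, tiny_index, None, None)
        assert seq1 == seq2  # seeded presampling is reproducible
        assert rep1["presampled_positions"] == [5]
        assert len(rep1["position_logprobs"]) == 6

    def test_lower_penalty_factor_does_not_raise_hidden_usage(self, index, pres_model, genotype):
        """Statistical trend across seeds, not a per-instance guarantee."""
        totals = {}
        for factor in (1.0, 0.5):
            policy = sb.PermissibilityPolicy(
                min_self_kmer_len=5, non_self_prob_factor=factor
            )
            total = 0
            for seed in range(4):
                target = "".join(
                    np.random.default_rng(200 + seed).choice(list(sb.STANDARD_AA), 40)
                )
                model = sb.toy_sequence_model(
                    target, concentration=1.0, markov_blend=0.5, seed=seed
                )
                cfg = sb.DecodeConfig(policy=policy, seed=seed)
                _, beam, _ = sb.decode(
                    model, sb.TemplateContext(40), cfg, index, pres_model, genotype
                )
                total += beam.hidden_kmer_count
            totals[factor] = total
        assert totals[0.5] <= totals[1.0]


class TestBaselineSample:
    def test_tiny_temperature_is_greedy(self, tiny_index):
        model = sb.toy_sequence_model("ACDA", concentration=3.0, alphabet=SMALL_ALPHABET)
        ctx = sb.TemplateContext(4)
        assert sb.baseline_sample(model, ctx, temperature=1e-9) == "ACDA"

    def test_same_seed_reproducible(self):
        model = sb.toy_sequence_model("ACDADC", concentration=0.5, alphabet=SMALL_ALPHABET)
        ctx = sb.TemplateContext(6)
        a = sb.baseline_sample(model, ctx, temperature=1.0, seed=7)
        b = sb.baseline_sample(model, ctx, temperature=1.0, seed=7)
        assert a == b

    def test_nonpositive_temperature_rejected(self):
        model = sb.toy_sequence_model("AC", alphabet=SMALL_ALPHABET)
        with pytest.raises(ValueError, match="temperature"):
            sb.baseline_sample(model, sb.TemplateContext(2), temperature=0.0)

    def test_temperature_one_matches_model_frequencies(self):
        model = sb.toy_sequence_model("A", concentration=1.0, alphabet="ACD")
        ctx = sb.TemplateContext(1)
        n = 10000
        counts = {t: 0 for t in model.tokens}
        for seed in range(n):
            counts[sb.baseline_sample(model, ctx, temperature=1.0, seed=seed)] += 1
        probs = model.probability_row(None, 0)
        for i, tok in enumerate(model.tokens):
            p = probs[i]
            sigma = math.sqrt(n * p * (1 - p))
            assert abs(counts[tok] - n * p) <= 3 * sigma
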