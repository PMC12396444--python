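"""Constrained beam-search decoding with permissibility-aware lookahead.

The engine decodes from any autoregressive sequence model satisfying a small
contract (normalised per-position log-probabilities over its token set).  At
each step every beam proposes all candidate residues; a candidate survives
only if every kmer it newly completes is permissible (see
:mod:`selfbeam.permissibility`).  Candidates are ranked by an estimated
*future log-probability*: the candidate's own log-probability plus a greedy,
permissibility-constrained lookahead of ``depth`` further steps, penalised by
``log(non_self_prob_factor)`` terms wherever hidden non-self kmers are relied
upon.  The top ``width`` candidates survive; beams sharing their last few
residues are then collapsed to the single most likely one to prevent beam
convergence.  If no candidate is permissible for any beam the decoder falls
back to unconstrained extension and flags the position.

The safety property this buys: any decode that finishes without fallback
yields a sequence in which every kmer up to ``min_self_kmer_len`` occurs in
the reference proteome and no non-self 8-10mer is predicted presented by the
genotype's presentation model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np

from .permissibility import (
    ExtensionVerdict,
    KmerClass,
    PermissibilityChecker,
    PermissibilityPolicy,
    window_spans,
)
from .presentation import Genotype, PresentationModel
from .proteome import KmerIndex, UNKNOWN


@runtime_checkable
class SequenceModelContract(Protocol):
    """What the decoder needs from an autoregressive sequence model.

    ``tokens`` is the model's residue vocabulary; ``log_probs`` returns one
    finite-or ``-inf`` natural-log probability per token (exponentials summing
    to one), deterministically for a given partial assignment and position.
    """

    tokens: tuple[str, ...]

    def log_probs(
        self, assignment: Sequence[Optional[str]], position: int
    ) -> np.ndarray: ...


@dataclass(frozen=True)
class TemplateContext:
    """Decoding target: total length plus positions lacking template support.

    Positions in ``unresolved`` (e.g. residues with missing backbone
    coordinates) are pre-sampled unconstrained before beam search begins, as
    inverse-folding pipelines conventionally do.
    """

    length: int
    unresolved: frozenset[int] = frozenset()
    name: str = "design"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if any(not 0 <= p < self.length for p in self.unresolved):
            raise ValueError("unresolved positions out of range")


@dataclass(frozen=True)
class DecodeConfig:
    """Beam-search hyperparameters.

    ``depth`` defaults to twice ``policy.min_self_kmer_len``.  The hidden-kmer
    penalty has two configurable contributions: ``depth`` factors of
    ``non_self_prob_factor`` when the immediate extension introduces a hidden
    non-self kmer, and one factor per lookahead step that itself does; either
    can be switched off.  ``lookahead_floor_logprob`` is charged per missing
    step when the greedy lookahead dead-ends (default log(1/21), the
    uniform-over-vocabulary floor).
    """

    width: int = 10
    depth: int | None = None
    dedupe_suffix_len: int = 5
    policy: PermissibilityPolicy = field(default_factory=PermissibilityPolicy)
    seed: int = 0
    penalize_immediate: bool = True
    penalize_lookahead: bool = True
    lookahead_floor_logprob: float = math.log(1.0 / 21.0)

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("width must be >= 1")
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.dedupe_suffix_len < 1:
            raise ValueError("dedupe_suffix_len must be >= 1")

    @property
    def resolved_depth(self) -> int:
        if self.depth is not None:
            return self.depth
        return 2 * self.policy.min_self_kmer_len


@dataclass(frozen=True)
class Beam:
    """A partial assignment with its penalty-free cumulative log-probability."""

    residues: tuple[Optional[str], ...]
    cum_logprob: float
    hidden_kmer_count: int = 0
    fallback_positions: tuple[int, ...] = ()
    position_logprobs: tuple[tuple[int, float], ...] = ()

    @property
    def sequence(self) -> str:
        if any(r is None for r in self.residues):
            raise ValueError("beam is not fully decoded")
        return "".join(self.residues)  # type: ignore[arg-type]

    def suffix_key(self, filled_order: Sequence[int], n: int) -> tuple[str, ...]:
        """Residues at the last ``n`` filled positions (position order)."""
        tail = sorted(filled_order)[-n:]
        return tuple(self.residues[p] for p in tail)  # type: ignore[return-value]


@dataclass
class Candidate:
    parent: Beam
    position: int
    residue: str
    own_logprob: float
    verdict: ExtensionVerdict
    future_estimate: float
    lookahead_truncated: bool = False

    def child(self, fallback: bool = False) -> Beam:
        residues = list(self.parent.residues)
        residues[self.position] = self.residue
        return Beam(
            residues=tuple(residues),
            cum_logprob=self.parent.cum_logprob + self.own_logprob,
            hidden_kmer_count=self.parent.hidden_kmer_count
            + self.verdict.hidden_nonself_count,
            fallback_positions=self.parent.fallback_positions
            + ((self.position,) if fallback else ()),
            position_logprobs=self.parent.position_logprobs
            + ((self.position, self.own_logprob),),
        )


def _log_factor(factor: float) -> float:
    return math.log(factor) if factor > 0 else -math.inf


class _Decoder:
    """One decoding run; caches window spans per (position, fill pattern step)."""

    def __init__(
        self,
        model: SequenceModelContract,
        checker: PermissibilityChecker,
        config: DecodeConfig,
        length: int,
    ) -> None:
        self.model = model
        self.checker = checker
        self.config = config
        self.length = length
        self.policy = checker.policy
        self.log_pen = _log_factor(self.policy.non_self_prob_factor)
        self.tokens = model.tokens if UNKNOWN in model.tokens else model.tokens + (UNKNOWN,)
        self._span_cache: dict[tuple[int, frozenset[int]], list[tuple[int, int]]] = {}

    def model_logprobs(self, residues: Sequence[Optional[str]], pos: int) -> np.ndarray:
        lp = np.asarray(self.model.log_probs(residues, pos), dtype=float)
        if UNKNOWN not in self.model.tokens:
            lp = np.append(lp, -np.inf)
        return lp

    def spans(self, pos: int, filled: frozenset[int]) -> list[tuple[int, int]]:
        key = (pos, filled)
        got = self._span_cache.get(key)
        if got is None:
            mask = [i in filled for i in range(self.length)]
            got = window_spans(mask, pos, self.policy.max_checked_kmer_len)
            self._span_cache[key] = got
        return got

    # -- lookahead ---------------------------------------------------------

    def future_logprob(
        self, cand_residues: list[Optional[str]], pos: int, own_logprob: float,
        verdict: ExtensionVerdict, filled: frozenset[int],
    ) -> tuple[float, bool]:
        """Greedy permissible lookahead estimate for one candidate extension."""
        cfg = self.config
        depth = cfg.resolved_depth
        est = own_logprob
        if cfg.penalize_immediate and verdict.hidden_nonself_count > 0:
            est += depth * self.log_pen
        if depth == 0:
            return est, False
        trial = list(cand_residues)
        trial_filled = filled | {pos}
        next_positions = [
            p for p in range(pos + 1, self.length) if p not in trial_filled
        ][:depth]
        truncated = False
        steps_taken = 0
        for lp_pos in next_positions:
            spans = self.spans(lp_pos, trial_filled)
            logprobs = self.model_logprobs(trial, lp_pos)
            best_tok: str | None = None
            best_lp = -math.inf
            best_hidden = 0
            for tok_i in np.argsort(-logprobs, kind="stable"):
                tok = self.tokens[tok_i]
                if tok == UNKNOWN:
                    continue  # never SELF, so never permissible with context
                trial[lp_pos] = tok
                v = self.checker.verdict_for_spans(trial, spans)
                if v.permissible:
                    best_tok = tok
                    best_lp = float(logprobs[tok_i])
                    best_hidden = v.hidden_nonself_count
                    break
            trial[lp_pos] = best_tok
            if best_tok is None:
                truncated = True
                break
            est += best_lp
            if self.config.penalize_lookahead and best_hidden > 0:
                est += self.log_pen
            trial_filled = trial_filled | {lp_pos}
            steps_taken += 1
        if truncated:
            est += (len(next_positions) - steps_taken) * cfg.lookahead_floor_logprob
        return est, truncated

    # -- one beam-search step ----------------------------------------------

    def step(self, beams: list[Beam], pos: int, filled: frozenset[int]) -> list[Beam]:
        if not beams:
            raise ValueError("empty beam list")
        cfg = self.config
        spans = self.spans(pos, filled)
        candidates: list[Candidate] = []
        fallback_pool: list[Candidate] = []
        for beam in beams:
            logprobs = self.model_logprobs(beam.residues, pos)
            trial = list(beam.residues)
            per_beam_fallback: list[Candidate] = []
            for tok_i, tok in enumerate(self.tokens):
                own_lp = float(logprobs[tok_i])
                trial[pos] = tok
                verdict = self.checker.verdict_for_spans(trial, spans)
                if verdict.permissible:
                    fut, trunc = self.future_logprob(
                        trial, pos, own_lp, verdict, filled
                    )
                    candidates.append(
                        Candidate(beam, pos, tok, own_lp, verdict, fut, trunc)
                    )
                else:
                    per_beam_fallback.append(
                        Candidate(beam, pos, tok, own_lp, verdict, own_lp)
                    )
            trial[pos] = None
            per_beam_fallback.sort(key=lambda c: (-c.own_logprob, c.residue))
            fallback_pool.extend(per_beam_fallback[: cfg.width])

        if candidates:
            candidates.sort(
                key=lambda c: (-c.future_estimate, -c.own_logprob, c.residue)
            )
            survivors = [c.child() for c in candidates[: cfg.width]]
        else:
            # no permissible extension anywhere: accept the most probable
            # unconstrained residues and flag the position
            full = [
                replace(
                    c,
                    verdict=self.checker.verdict_for_spans(
                        self._with(c), spans, stop_on_forbidden=False
                    ),
                )
                for c in fallback_pool
            ]
            full.sort(key=lambda c: (-c.own_logprob, c.residue))
            survivors = [c.child(fallback=True) for c in full[: cfg.width * len(beams)]]
            survivors.sort(key=lambda b: (-b.cum_logprob, b.residues))
            survivors = survivors[: cfg.width]

        new_filled_order = sorted(filled | {pos})
        deduped: dict[tuple[str, ...], Beam] = {}
        for b in survivors:
            key = b.suffix_key(new_filled_order, cfg.dedupe_suffix_len)
            cur = deduped.get(key)
            if (
                cur is None
                or b.cum_logprob > cur.cum_logprob
                or (b.cum_logprob == cur.cum_logprob and _seq_key(b) < _seq_key(cur))
            ):
                deduped[key] = b
        return list(deduped.values())

    def _with(self, c: Candidate) -> list[Optional[str]]:
        trial = list(c.parent.residues)
        trial[c.position] = c.residue
        return trial


def _seq_key(beam: Beam) -> tuple[str, ...]:
    return tuple(r if r is not None else "" for r in beam.residues)


def future_logprob(
    model: SequenceModelContract,
    assignment: Sequence[Optional[str]],
    position: int,
    residue: str,
    config: DecodeConfig,
    index: KmerIndex,
    pres_model: PresentationModel | None,
    genotype: Genotype | None,
) -> float:
    """Penalised greedy-lookahead ranking score for one candidate extension.

    The candidate's own log-probability, plus the log-probabilities of the
    greedily chosen most-probable *permissible* residue over the next
    ``depth`` unfilled positions, plus ``depth * log(non_self_prob_factor)``
    if the immediate extension introduces a hidden non-self kmer and one
    ``log`` factor per lookahead step that does.  The candidate extension
    itself must be permissible.
    """
    checker = PermissibilityChecker(index, pres_model, genotype, config.policy)
    dec = _Decoder(model, checker, config, len(assignment))
    filled = frozenset(i for i, r in enumerate(assignment) if r is not None)
    if position in filled:
        raise ValueError(f"position {position} is already filled")
    spans = dec.spans(position, filled)
    own_lp = float(dec.model_logprobs(assignment, position)[dec.tokens.index(residue)])
    trial = list(assignment)
    trial[position] = residue
    verdict = checker.verdict_for_spans(trial, spans, stop_on_forbidden=False)
    if not verdict.permissible:
        raise ValueError("candidate extension is not permissible")
    est, _ = dec.future_logprob(trial, position, own_lp, verdict, filled)
    return est


def step(
    beams: list[Beam],
    position: int,
    model: SequenceModelContract,
    config: DecodeConfig,
    index: KmerIndex,
    pres_model: PresentationModel | None,
    genotype: Genotype | None,
) -> list[Beam]:
    """One public beam-expansion step (all beams share their fill pattern)."""
    if not beams:
        raise ValueError("empty beam list")
    filled = frozenset(i for i, r in enumerate(beams[0].residues) if r is not None)
    for b in beams:
        if frozenset(i for i, r in enumerate(b.residues) if r is not None) != filled:
            raise ValueError("beams disagree on which positions are filled")
    checker = PermissibilityChecker(index, pres_model, genotype, config.policy)
    dec = _Decoder(model, checker, config, len(beams[0].residues))
    return dec.step(beams, position, filled)


def presample_unresolved(
    model: SequenceModelContract,
    context: TemplateContext,
    rng: np.random.Generator,
) -> tuple[list[Optional[str]], list[tuple[int, float]]]:
    """Unconstrained temperature-1 sampling of the unresolved positions."""
    residues: list[Optional[str]] = [None] * context.length
    logprobs: list[tuple[int, float]] = []
    for pos in sorted(context.unresolved):
        lp = np.asarray(model.log_probs(residues, pos), dtype=float)
        probs = np.exp(lp - lp.max())
        probs /= probs.sum()
        tok_i = int(rng.choice(len(model.tokens), p=probs))
        residues[pos] = model.tokens[tok_i]
        logprobs.append((pos, float(lp[tok_i])))
    return residues, logprobs


def decode(
    model: SequenceModelContract,
    template_context: TemplateContext,
    config: DecodeConfig,
    index: KmerIndex,
    pres_model: PresentationModel | None,
    genotype: Genotype | None,
) -> tuple[str, Beam, dict]:
    """Run the full constrained beam search and return the selected design.

    Unresolved template positions are pre-sampled (seeded, unconstrained);
    remaining positions are then decoded in increasing order.  Among completed
    beams the one with the highest penalty-free cumulative log-probability is
    returned, ties broken lexicographically by sequence.
    """
    checker = PermissibilityChecker(index, pres_model, genotype, config.policy)
    dec = _Decoder(model, checker, config, template_context.length)
    rng = np.random.default_rng(config.seed)
    residues, pre_logprobs = presample_unresolved(model, template_context, rng)
    pre_lp = sum(lp for _, lp in pre_logprobs)
    root = Beam(
        residues=tuple(residues),
        cum_logprob=pre_lp,
        position_logprobs=tuple(pre_logprobs),
    )
    filled = frozenset(template_context.unresolved)
    beams = [root]
    for pos in range(template_context.length):
        if pos in filled:
            continue
        beams = dec.step(beams, pos, filled)
        filled = filled | {pos}
    best = min(beams, key=lambda b: (-b.cum_logprob, b.sequence))
    report = {
        "name": template_context.name,
        "sequence": best.sequence,
        "cum_logprob": best.cum_logprob,
        "hidden_kmer_count": best.hidden_kmer_count,
        "fallback_positions": list(best.fallback_positions),
        "position_logprobs": [
            {"position": p, "logprob": lp}
            for p, lp in sorted(best.position_logprobs)
        ],
        "presampled_positions": sorted(template_context.unresolved),
    }
    return best.sequence, best, report


def baseline_sample(
    model: SequenceModelContract,
    template_context: TemplateContext,
    length: int | None = None,
    temperature: float = 0.1,
    seed: int = 0,
) -> str:
    """Unconstrained autoregressive sampling — the comparison baseline.

    Logits are scaled by 1/temperature; temperatures below 1e-6 switch to
    greedy argmax decoding.  Unresolved positions are sampled first, then the
    rest in increasing order, all from the same seeded generator.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    n = length if length is not None else template_context.length
    if n != template_context.length:
        raise ValueError("length disagrees with the template context")
    rng = np.random.default_rng(seed)
    residues: list[Optional[str]] = [None] * n
    order = sorted(template_context.unresolved) + [
        p for p in range(n) if p not in template_context.unresolved
    ]
    greedy = temperature < 1e-6
    for pos in order:
        lp = np.asarray(model.log_probs(residues, pos), dtype=float)
        if greedy:
            tok_i = int(np.argmax(lp))
        else:
            scaled = lp / temperature
            probs = np.exp(scaled - scaled.max())
            probs /= probs.sum()
            tok_i = int(rng.choice(len(model.tokens), p=probs))
        residues[pos] = model.tokens[tok_i]
    return "".join(residues)  # type: ignore[arg-type]
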