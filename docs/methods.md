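# Methods

## Model and procedure

`selfbeam` treats protein design as constrained decoding from an
autoregressive sequence model. The model supplies normalised per-position
log-probabilities over its residue vocabulary (plus an `X` unknown token);
the decoder supplies the constraint logic. The constraint is local and
exhaustive: whenever a position is filled, every kmer window that became
fully determined at that step — up to `max_checked_kmer_len` — is classified

* **SELF** if it occurs in the reference proteome,
* **HIDDEN_NONSELF** if it is absent from the proteome but predicted not
  presented by the genotype (or has a length, 7 and below `min_self` < k < 8,
  for which MHC-I presentation is not defined — only 8–10mers are canonical
  MHC-I ligands),
* **FORBIDDEN** if it is a non-self kmer of length ≤ `min_self_kmer_len`, or
  a presented non-self 8–10mer.

An extension is permissible iff no newly completed window is FORBIDDEN.
Because each window is checked exactly once over the course of a decode
(shown by the incremental/batch-equivalence property test), a decode that
finishes without fallback yields a sequence whose *global* re-scan contains
no forbidden window. This is the package's central guarantee and is asserted
by brute-force re-scans that bypass the decoder entirely.

Assumptions: kmer windows never span chain breaks or `*` stop characters;
self-ness is undefined for ambiguous residues (any window containing `X` is
excluded from the self set and from metric denominators); presentation of a
genotype is the disjunction over its (deduplicated) alleles.

## Decoding

Standard beam search with three modifications:

1. **Permissibility filtering** — of the 21 candidate tokens per beam (20
   residues plus unknown) only permissible ones enter the ranking. The
   unknown token is never self, so it can only ever survive through fallback.
2. **Penalised greedy lookahead** — candidates are ranked by their own
   log-probability plus the log-probabilities of the greedily chosen most
   probable *permissible* residue over the next `depth` unfilled positions.
   If the immediate extension introduced a hidden non-self kmer, the
   estimate is charged `depth · ln(non_self_prob_factor)`; each lookahead
   step that itself introduces one is charged one further `ln` factor. The
   stated penalty exponent could also be read as applying only to the
   immediate extension, so both contributions are independently switchable
   (`penalize_immediate`, `penalize_lookahead`); defaults enable both. A
   lookahead that dead-ends is truncated and charged a floor of `ln(1/21)`
   per missing step (`lookahead_floor_logprob`) — it must be penalised
   without aborting the search. Lookahead never extends past the sequence
   end; missing steps there are not charged.
3. **Suffix dedupe** — after the top-`width` cut, beams sharing their last
   `dedupe_suffix_len` (default 5) filled residues are collapsed to the one
   with the highest cumulative log-probability. Cutting before deduping may
   leave fewer than `width` beams; the alternative order is a one-line
   change and was not observed to matter on fixtures.

Final selection is by the highest penalty-free sum of per-residue
log-probabilities; ties break lexicographically so runs are reproducible.
Positions without template support are pre-sampled unconstrained at
temperature 1 (seeded) before beam search, mirroring standard
inverse-folding practice; the generalized window rule ("windows that became
fully filled at this step") means their constraint checks happen when
neighbouring positions are later filled. Fallback — no permissible extension
for any beam — extends each beam with its most probable raw residues and
records the position; downstream consumers (CLI exit code, evaluation) treat
flagged designs as constraint-infeasible.

## Presentation model

Per allele and per length k ∈ {8, 9, 10}, a position weight matrix with
weights `w[a,p] = log2((count(a,p) + 0.5) / (n + 10) / bg[a])` trained on
presented peptides; the background `bg` is uniform (1/20) by default and can
be overridden with proteome-derived frequencies. A peptide's score is the
sum of its k weights; `X` scores −∞. The threshold is the nearest-rank
(ceiling) empirical (1 − t) quantile of background scores, with t = 0.02 by
default so that ~2% of background peptides classify presented — mirroring
the conventional "weak binder" percentile-rank cutoff used by neural
presentation predictors. Score ≥ threshold counts as presented (ties
included), fixed so tests are exact. Nearest-rank rather than interpolated
quantiles avoids any interpolation ambiguity; thresholds are monotone
non-increasing in the target, so raising the target can only enlarge the
presented set.

Allele distance is the percentage of a fixed peptide panel on which two
alleles' verdicts differ; alternative-genotype selection picks, per gene,
the two candidate alleles with the largest minimum distance to any allele in
the primary genotype, ties broken by allele name.

## Evaluation metrics

* `self_kmer_fraction(seq, k)` — fraction of X-free length-k windows found
  in the proteome. Non-increasing in k by substring closure of the index.
* `presented_nonself_fraction` — presented non-self 8–10mer windows over all
  8–10mer windows. Exactly 0 for every unflagged decode when evaluated with
  the decode-time presentation model.
* BLOSUM62 dissimilarity — for a non-self 8–10mer, its ungapped BLOSUM62
  self-score minus the best ungapped score against any *same-length*
  proteome kmer (ungapped alignment forces equal lengths). Non-negative by
  diagonal dominance of BLOSUM62 over the standard residues (validated at
  load); zero iff some proteome kmer attains the full score, in particular
  for every self kmer. The search is vectorised (per-length integer
  encoding of the proteome's kmer sets); tests compare it against a plain
  Python scan.

## Synthetic data

The generators define the conditions under which the package is exercised:

* **Proteomes** — i.i.d. residues (uniform by default, overridable
  frequencies), 500 proteins of 200–400 residues in the end-to-end runs; at
  this size ~1.5·10⁵ distinct kmers exist per length, so 6-mer constraints
  are binding but satisfiable. Motif planting forces chosen kmers to be
  self for targeted tests. Real proteomes have repeat structure, domain
  families, and biased composition that i.i.d. sequences lack, so passing
  tests demonstrate the *machinery*, not design quality on the human
  proteome.
* **Anchored alleles** — ground-truth presentation is "anchor residues at
  anchor positions" (position 2 and C-terminal anchors, as in real MHC-I
  motifs; negative indices make one rule apply across lengths). Labels can
  be flipped with probability 1 − sharpness. Because the rule is known
  exactly, trained PWMs can be scored against it: at matched calibration
  the agreement exceeds 0.99, the surrogate-fidelity property the fast
  classifier is built on. Real presentation predictors have graded,
  length-dependent motifs this caricature does not.
* **Toy sequence models** — position p's distribution mixes a point mass on
  a target sequence (weight `concentration`) with a background blending
  uniform and a seeded first-order Markov table (`markov_blend`). The exact
  table is exposed, so exhaustive-enumeration decode oracles are computable
  on 4-letter, length-6 instances (50 seeded instances in the acceptance
  suite; the decoder matches the enumerated argmax on all of them).

## Numerical and interface choices

* Rare residue codes (U, B, Z, J, O) map to `X` on FASTA ingest; `*` splits
  records into independent segments. Sequences are uppercased.
* The kmer index stores exact per-length hash sets (no probabilistic
  filters), serialised to a sorted plain-text format keyed by a SHA-256
  digest of the source records; round-trips are exact.
* PWMs persist as one TSV per (allele, length) with the threshold in the
  header, 12-significant-digit weights.
* Default decode configuration: width 10, `min_self_kmer_len` 6,
  `max_checked_kmer_len` 10, `non_self_prob_factor` 0.9, depth
  2 × `min_self_kmer_len`, dedupe suffix 5. Lowering `min_self_kmer_len` to
  5 loosens the constraint; factor 0 makes the hidden-kmer penalty absolute
  (−∞ ranking score), pushing the search to pure-self paths and to fallback
  when none exists.
* End-to-end runs use 20 designs of length 60; brute-force comparisons use
  4-letter alphabets at length 6 (4⁶ = 4096 sequences), sizes chosen so the
  exhaustive oracles stay exact.

## Limitations

* The PWM classifier is additive per position; it cannot express pairwise
  residue couplings real predictors capture. It is the decode-time
  predictor, not an evaluation-grade one — the zero-leakage guarantee is
  relative to whatever presentation model is supplied.
* Only canonical 8–10mer MHC-I ligands are modelled; longer presented
  peptides are covered only insofar as they contain an 8–10mer core.
* The i.i.d. synthetic proteome overstates kmer-graph connectivity compared
  to a real proteome at equal size; feasibility of the 6-mer constraint on
  real data depends on proteome scale.
* The external inverse-folding adapter is an integration stub; shipped
  models are the toy fixtures.
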