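# selfbeam

Constrained beam-search decoding for autoregressive protein sequence models
that keeps designs invisible to cytotoxic T-lymphocytes (CTLs).

## The problem

Intracellular protein therapeutics are degraded into short peptides
(mostly 8–10 residues) that the MHC class I pathway presents on the cell
surface, where CTLs inspect them. Two kinds of peptide should not trigger a
CTL response:

* **self kmers** — subsequences of the host (reference) proteome, covered by
  central tolerance;
* **hidden kmers** — peptides predicted *not* to be presented by any of the
  patient's (up to six) MHC-I alleles.

`selfbeam` decodes a sequence from any autoregressive protein model (an
inverse-folding model, or the toy models shipped here) under the hard
constraint that **every kmer of the design, up to length 10, is either self
or hidden**. Concretely, for a window of length *k*:

* *k* ≤ `min_self_kmer_len` (default 6): the kmer **must** occur in the
  reference proteome;
* `min_self_kmer_len` < *k* ≤ `max_checked_kmer_len` (default 10): the kmer
  may be non-self only if the presentation model predicts it hidden for the
  genotype; such kmers are allowed but penalised.

The search keeps `width` beams. Each candidate extension is ranked by its
*future log-probability*: its own log-probability plus a greedy,
permissibility-constrained lookahead of `depth` steps, with
`depth · log(non_self_prob_factor)` charged when the extension relies on a
hidden non-self kmer (and one factor per offending lookahead step). Beams
sharing their last 5 residues are collapsed to the most likely one. If no
permissible extension exists anywhere, the decoder falls back to
unconstrained extension and *flags the position* — so a design that finishes
unflagged carries a hard guarantee: re-scanning it with the decode-time
presentation model finds zero presented non-self 8–10mers.

Presentation is judged by a fast per-allele position weight matrix (PWM)
classifier: for each allele and each length *k* ∈ {8, 9, 10} the weights are
log2 position-specific frequency over background (pseudocount 0.5), and the
score threshold is calibrated so that 2% of background peptides score above
it — the conventional "weak binder" rank cutoff. A peptide is presented by a
genotype if any allele's PWM scores it at or above threshold.

## Worked example

```python
import numpy as np
import selfbeam as sb

# 1. reference proteome and self-kmer index
proteome = sb.generate_proteome(
    sb.FixtureSpec(seed=11, n_proteins=500, protein_length_range=(200, 400))
)
index = sb.build_kmer_index(proteome, max_len=10)

# 2. per-allele PWM presentation model, calibrated at the 2% convention
alleles = {
    "HLA-A*01:01": sb.AlleleSpec((1, -1), ("LM", "KR")),
    "HLA-B*01:01": sb.AlleleSpec((2, -1), ("FY", "DE")),
}
pres_model = sb.synthetic_presentation_model(alleles, seed=3)
genotype = sb.Genotype(tuple(sb.Allele(n) for n in alleles))

# 3. constrained decode of a length-60 design from a toy sequence model
target = "".join(np.random.default_rng(0).choice(list(sb.STANDARD_AA), 60))
model = sb.toy_sequence_model(target, concentration=2.0, markov_blend=0.5, seed=5)
config = sb.DecodeConfig(seed=1)   # width 10, min_self 6, factor 0.9, depth 12
sequence, beam, report = sb.decode(
    model, sb.TemplateContext(60), config, index, pres_model, genotype
)

# 4. re-evaluate with the same presentation model
print("design:", sequence)
print("fallback:", report["fallback_positions"],
      "hidden kmers:", report["hidden_kmer_count"])
print("self 6-mer fraction:", sb.self_kmer_fraction(sequence, index, 6))
print("presented non-self fraction:",
      sb.presented_nonself_fraction(sequence, index, pres_model, genotype))
```

prints

```
design: VQMGYICDFSLFMTVRHYMWPTVDYPKGVVDACISDHIMRSFSDWKEYIIPMRVCDCEMC
fallback: [] hidden kmers: 20
self 6-mer fraction: 1.0
presented non-self fraction: 0.0
```

Every 6-mer of the design occurs in the reference proteome; the 20 longer
non-self kmers the design uses are all predicted hidden for this genotype,
so no presented non-self peptide remains.

## Command line

```bash
selfbeam build-index proteome.fasta --max-len 10 --out index.txt
selfbeam train-pwms --presented-dir peptides/ --out-dir pwms/
selfbeam design config.yaml            # nonzero exit if any design needed fallback
selfbeam evaluate designs.fasta config.yaml --out metrics.tsv
selfbeam genotype-distance --profiles-dir profiles/ --out dist.tsv \
    --primary "HLA-A*02:01,HLA-A*24:02"
```

`design` reads a flat YAML config (proteome path, PWM store, genotype,
decoding hyperparameters, seed) and writes designs as FASTA, per-design
JSON-line reports, and the resolved config next to the outputs.

## Scope

The package covers sequence-space design and evaluation only: no structure
prediction, no external presentation predictors (an adapter seam accepts
externally produced verdict panels), and no model fine-tuning. Substitution
scores come from biopython's BLOSUM62.
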