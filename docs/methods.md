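# Methods

This note records the models, conventions, numerical choices and known
limitations of `thermotrans`, in the spirit of a statistical package's
methods documentation. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from
external experiments.

## The translation framing

Proteins from thermophilic organisms are under selection to remain folded
and functional near their host's optimal growth temperature (OGT). Pairs of
homologs — one member from a mesophile (OGT < 313 K here), one from a
thermophile (OGT ≥ 333 K) — therefore carry a weak, distributed signal of
what "the same protein, adapted to heat" looks like. The package treats
learning this mapping as sequence-to-sequence translation: an encoder
consumes the mesophilic sequence, a causal decoder emits a thermophile-like
homolog residue by residue, and the decoder's token probabilities double as
a zero-shot *thermophilicity* score for arbitrary variants.

## Curation rules

A pair is kept iff all of the following hold, evaluated in this fixed order
for rejection attribution: OGT difference strictly greater than 20 K;
thermophile OGT ≥ 333 K; mesophile OGT strictly below 313 K; alignment
coverage of each member strictly above 0.95 (the minimum of the two stored
coverages is compared); relative length difference at most 10%. The length
denominator is the mesophilic length — the mesophile is the model's input
and the natural reference. Boundary strictness follows the definitions
above literally and is unit-tested at the exact boundary values
(ΔOGT = 20 K rejected, coverage = 0.95 rejected, length difference = 10%
kept).

### Clustering and splits

Sequences are clustered greedily: visited in order of descending length
(ties by id), each sequence joins the first cluster whose representative
reaches the identity threshold (default 0.50), else founds a new cluster.
This is a deterministic desk-scale stand-in for MMSeqs2-style clustering;
an external MMSeqs2 run (parameters such as min-seq-id 0.5, c 0.95,
cov-mode 0) can replace it upstream without changing any downstream code,
since splits consume only the cluster assignment.

Two identity definitions coexist deliberately:

* **Alignment-span identity** (`align_pair.identity`): exact matches over
  the columns between the first and last position where both sequences are
  aligned. This is the right notion for judging how well a *generated*
  sequence recapitulates a target, and is what the evaluation metrics
  report.
* **Clustering identity** (`clustering_identity`): exact matches divided by
  the shorter sequence's length. With free end gaps, two unrelated
  sequences can align as a 2–3-residue exact-match island, giving a span
  identity of 1.0 over a meaningless core; normalizing by sequence length
  removes that pathology. Clustering tools impose a coverage requirement
  for exactly this reason. Clustering and the split-leakage audit use this
  definition.

Splits assign whole clusters: clusters are shuffled by seed, then fill the
train split until its sequence-count quota (fraction × total sequences) is
met, then validation, remainder to test. The 80/10/10 fractions are
interpreted over sequence counts, not cluster counts. Test-set subsampling
draws at most one random member from each of n random test clusters,
reducing the weight of large clusters in evaluation.

## The conditional-model contract

All scoring and decoding depend only on: *(source, target_prefix) → a
probability vector over 21 tokens* (20 residues + end token), deterministic
for fixed inputs and model state, non-negative, summing to 1 within 1e-6.
A conformance suite runs against every bundled implementation.

End-of-sequence handling: the end token is explicit in the alphabet.
Teacher-forced scoring over a full sequence includes the end-token term
only when requested (`include_end`, default off), so per-residue averages
stay comparable across lengths. The uniform baseline spreads mass over the
20 residues only, which makes ln(1/20) ≈ −2.996 analytics exact.

### TinyTranslator

The bundled trainable model is a compact numpy encoder–decoder: the
"encoder context" for target position *i* is a one-hot window of source
residues at positions i−1, i, i+1 (padding outside), the decoder state is
the previous target token (start symbol at i=0), and a linear-softmax layer
maps these features to next-token logits. This is deliberately the smallest
model that satisfies the contract, learns position-aligned substitution
rules essentially perfectly, and trains deterministically in under a second
on one CPU. It is described as what it is — a minimal causal translator for
desk-scale experiments — and makes no claim to transformer-scale capacity;
insertions/deletions break its positional alignment assumption, which is
acceptable for substitution-rule fixtures.

Training is teacher-forced per-token categorical cross entropy with Adam
under a linear ramp-up/ramp-down schedule (`warmup_fraction` of total
steps, default 10%). Early stopping evaluates validation loss once per
epoch and halts after `patience` (default 4) evaluations without an
improvement of at least `improvement_threshold` (default 0.1) nats over the
best seen; the best-validation weights are returned. The default peak
learning rate (1e-4) suits fine-tuning regimes of large pretrained models;
for the linear-softmax TinyTranslator the tests and acceptance script use
0.05, an ordinary Adam step size for a convex model of this size.
Determinism: all randomness flows through one seeded generator; identical
data + config + seed reproduce bit-identical weights.

### Beam search

Standard breadth-limited best-first decoding over cumulative log
probability. Completed hypotheses (end token emitted) are kept in a
separate pool and do not consume beam slots; after the length budget is
exhausted, surviving beams are offered one final end-token completion. The
returned score includes the end-token term. Ties break lexicographically.
Width 1 reduces to greedy rollout; for position-profile models of length
≤ 4 with width ≥ alphabet size, the output provably and empirically equals
exhaustive-search maximum likelihood (verified against broadcast
enumeration of every complete sequence). If no hypothesis ever reaches the
end token the decode is flagged `collapsed` and the best partial sequence
is returned — callers should treat collapsed outputs as unusable
translations.

## Scoring conventions

* The 1/|M| prefactor means L is always a *mean* over scored positions, so
  sequences and mutation sets of different sizes are comparable, and
  CCE = −L(all positions) holds identically (asserted to 1e-12).
* Substitution-only variants (equal length) are scored at differing
  positions only; each sequence is conditioned on its own prefix by
  default. Conditioning the variant's tokens on the wild-type prefix
  instead is available (`prefix_mode="wt"`); for prefix-independent models
  the two agree, and the default reflects the causal contract — the model
  sees the sequence actually being evaluated.
* Indel variants switch to whole-sequence mode; both scores are
  length-normalized means before subtraction, so ΔL is antisymmetric under
  argument swap.
* Zero-probability target residues yield −inf with a warning, not an
  exception: a hard zero is informative (the model forbids the residue) and
  should propagate as an extreme score, not crash a scan.
* MSA column profiles count non-gap canonical residues per reference
  column plus a pseudocount (default 1e-3) per residue: small enough to
  perturb observed columns negligibly, large enough to keep unobserved
  residues finite.

## Structure and stability analyses

Disulfide labeling uses the Cα-distance heuristic with a strict < 7.5 Å
threshold. When more than two cysteines have sub-threshold contacts,
pairs are accepted greedily by ascending distance with each cysteine in at
most one pair — deterministic and locally optimal. The causal label marks
the *later* cysteine of each pair: a left-to-right generator can only
"complete" a bond whose first member it has already emitted. Labels are
invariant under rigid motions (distances only). The bias test is a
one-sided Welch (unequal-variance) two-sample t-test, H1: bonded mean
log-likelihood exceeds non-bonded; Welch is chosen because the two position
populations have no reason to share a variance.

Stability estimates divide the ensemble-mean energy score by residue count
(default ensemble size 25), making variants with indels comparable; lower
is more stable. Variant comparisons use a seeded percentile bootstrap
(default 2,000 resamples) on the difference of per-residue means;
"confidently stabilizing" requires the 95% interval to exclude zero on the
negative side. On Gaussian ensembles of size 25 the empirical coverage of
these intervals measures 93–95% over 2,000 trials (percentile bootstrap
mildly undercovers at small ensemble sizes); this is computed fresh by the
acceptance script. Spearman rank correlation (mid-ranks for ties) is
provided for benchmarking scores against measured melting temperatures;
constant inputs are reported as undefined rather than raising.

## Synthetic data: what it emulates and what it does not

The pair-table generator emulates the *statistical envelope* of a curated
homolog-pair table: OGT labels drawn from mesophile/thermophile ranges,
pairwise identity set by explicit substitution counts, single contiguous
indels of length 1–3, and terminal overhangs steering alignment coverage.
Stored coverage/length statistics follow from the exact edits applied, so
brute-force re-derivation agrees with them. Defaults: lengths 60–120,
identity 0.60–0.90, indel rate 0.10, coverage 0.96–1.0, meso OGT
280–312 K, thermo OGT 333–363 K — chosen to resemble a strongly filtered
homolog-pair table while keeping alignments unambiguous at desk scale.
Residues are drawn from a configurable frequency table (default uniform),
which makes frequency-shift analytics exactly predictable.

Rule pairs apply a deterministic substitution map (optionally an insertion
motif) to random mesophiles; the thermophilic member is the rule image
exactly, so learnability, ΔL direction, beam recovery, and amino-acid
shift all have closed-form expectations.

Toy structures place residues on straight backbone segments at the
canonical 3.8 Å consecutive Cα spacing; a constrained cysteine pair bridges
two parallel segments so its distance is exact (to the float) while every
other inter-Cα distance stays ≥ 3.5 Å. Straight segments were chosen over
a helical trace because they make every pairwise distance provable by
arithmetic; the geometry is a labeling fixture, not a protein model. The
boundary construction nudges the offset upward by ulps so a requested
boundary distance never rounds below itself under the strict threshold.

None of this emulates real evolutionary covariation, realistic indel
processes, compositional bias of thermophilic proteomes, or actual protein
geometry. Passing tests therefore demonstrate the *correctness of the
machinery* — filters, splits, likelihood algebra, decoding, labeling,
calibration — not biological performance of a trained translator on real
homolog data, which requires the full-scale dataset, a large pretrained
model, and structure/energy oracles that are consumed here only as inputs.

## Known limitations

* The greedy clusterer checks identity against cluster representatives
  only; highly chained families could in principle split across clusters.
  The leakage audit (exhaustive pairwise check over fixtures, multiple
  seeds) is the guard that matters for split hygiene.
* The TinyTranslator cannot represent long-range or prefix-history
  dependence beyond the previous token; it is a contract-exercising model,
  not a design tool.
* Sequences containing X are accepted by I/O and curation but X is
  excluded from frequency analyses and cannot be scored by models.
* Beam search explores the top-k frontier only; for prefix-dependent
  models global optimality is guaranteed only on the small instances the
  tests enumerate.
* Problem sizes throughout (500-pair tables, 60–120-residue sequences,
  50-model decoding sweeps, 2,000 bootstrap trials) are the package's
  chosen desk-scale study conditions; all scale linearly if enlarged.
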