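# Methods

## Corpus curation

Raw SMILES records (plain `.smi` streams and molecules harvested from
`reactants>agents>products` reaction strings) are sanitized and
canonicalized with RDKit. Sanitization keeps the largest fragment by heavy
atoms (ties broken by canonical string) and strips explicit hydrogens;
parse failures, valence violations and empty records are rejected with a
reason code rather than silently dropped, and every manifest satisfies
`retained + rejected == input` per source.

Duplicate-frequency analysis counts occurrences per canonical form across
all sources under one uniform rule. Molecules occurring more than once are
ranked by `(count desc, canonical asc)` — the lexicographic tie-break makes
the selection deterministic — and the top fraction (default 0.2) of that
duplicated set is re-emitted `ceil(count · r)` times (ratio `r`
configurable, default 1), split evenly between canonical copies and
randomized SMILES produced by RDKit's seeded random graph traversal. All
other molecules appear exactly once. Sequences longer than 512 content
tokens are removed, measured with the trained unigram tokenizer when one
is supplied and with the atom-level regex tokenizer during bootstrap.

The output order is a seeded chunked merge-shuffle: fixed-size chunks are
Fisher–Yates shuffled, then drained by sampling a chunk with probability
proportional to its remaining size. This is linear-time and bounded-memory,
exact Fisher–Yates when one chunk suffices, and byte-reproducible under
the seed.

## Tokenization

SMILES has no whitespace word boundaries, so the tokenizer treats each
line as a raw character stream. Training is the unigram language-model
recipe: a seed pool of the most frequent substrings (up to 8 characters,
ranked by count × length, pool ≈ 8× the target size) plus every observed
character is refit by EM and pruned to exactly the requested vocabulary
size. The E-step uses hard Viterbi counts rather than full
forward–backward expected counts, and pruning drops the lowest-probability
multi-character pieces rather than re-scoring each candidate's
log-likelihood loss; both are standard simplifications that preserve the
properties downstream code relies on, since *encoding* is exact Viterbi
maximum-likelihood segmentation under the fitted log-probabilities
(property-tested against exhaustive enumeration of all segmentations of
short strings). Single characters are never pruned, so every string over
the training alphabet encodes with zero `[UNK]`; unseen characters fall
back to `[UNK]` at a floor score instead of failing.

Special ids are fixed: `[PAD]`=0, `[CLS]`=1, `[SEP]`=2, `[UNK]`=3,
`[MASK]`=4. Content is truncated to 512 tokens and wrapped in
`[CLS]`…`[SEP]`, so every sequence has between 2 and 514 ids; content-token
character offsets tile the input exactly. Vocabulary presets: 500 for
desk-scale work, 2417 for the full-scale configuration. The regex baseline
is the widely used atom-level SMILES pattern (bracket atoms, two-letter
halogens, `@@`, `%nn` ring closures and single symbols as one token each);
it is configurable because published variants differ in detail, and its
tokens must tile the input or the offending span is reported.

## Encoder and pre-training

The encoder is the standard post-LayerNorm bidirectional transformer:
learned word and absolute-position embeddings (514 positions) with an
embedding LayerNorm, then per layer multi-head self-attention
(4 × (H² + H) projection parameters), residual + LayerNorm, and a GELU
feed-forward block H → I → H. The MLM head is dense H → H + GELU +
LayerNorm with the output projection weight-tied to the embedding table
plus a per-vocabulary bias. Tying is the convention of this architecture
family and is what makes the full-scale count come out right: at 12
layers / 12 heads / hidden 768 / intermediate 3072 / 514 positions /
vocabulary 2417 the model has 87,901,553 trainable scalars (tied tensors
counted once), i.e. ~88 M.

Masking selects content tokens independently at probability 0.15
(`[CLS]`/`[SEP]`/`[PAD]` are never corrupted), with the 80/10/10
mask/random/keep split; random replacements are drawn from content ids.
Loss is mean cross-entropy over corrupted positions only; a batch with no
corrupted positions scores 0 and is flagged by its zero count.

The learning-rate schedule ramps linearly from 0 to the peak (full-scale
peak 6 × 10⁻⁴; desk default 10⁻³) over the warmup, then decays
polynomially (default power 1, i.e. linearly) to the end rate (default 0).
The warmup length defaults to 6% of total steps — the schedule family is
standard but the published warmup length is not, so this is a documented
package default. The optimizer is AdamW (β = 0.9/0.999, decoupled weight
decay 0.01, not applied to 1-D parameters).

Gradient accumulation reproduces large-batch data-parallel semantics in
one process: the effective batch is `per_device × accum_steps ×
world_size` (the 8 × 32 × 16 = 4096 full-scale plan survives as
arithmetic; multi-device execution is out of scope). The macro-batch's
corrupted positions are counted first and each micro-batch loss is
weighted by its share, so the accumulated gradient equals the one-big-batch
mean-loss gradient; with float64 arithmetic the relative error is ~10⁻⁹,
tested against 10⁻⁵. Training aborts on a non-finite loss and restores the
last checkpoint.

## Fingerprints

Fingerprint dimensionality always equals the encoder's hidden size. Mean
pooling averages final hidden states over non-padding positions and by
default *includes* `[CLS]`/`[SEP]` (the embeddings are "all token
embeddings"); a flag restricts to content tokens, and both modes are
tested. `[CLS]` pooling returns row 0. Fingerprints are stored
unnormalized; cosine similarity normalizes internally and rejects
zero-norm vectors. Batch fingerprinting is deterministic (eval mode, no
dropout), equals the per-molecule loop, is invariant to padding, and flags
RDKit-unparseable inputs as NaN rows rather than dropping them.

## Fine-tuning

Single-branch: the dropout-regularized (default 0.2) mean-pooled embedding
feeds a one-layer head; sigmoid + binary cross-entropy for classification,
identity + MSE for regression; default 10 epochs on an 80/10/10 split.
The full encoder is updated by default — the alternative frozen-encoder
mode trains only the head on detached features. Fine-tuning always clones
the input encoder, so shared pre-trained weights are never mutated.
Stripping the head exposes the specialized encoder for fingerprinting and
is idempotent.

Siamese classification pairs each molecule with a seeded random SMILES
permutation of itself (the pairing seed is derived from the run seed and
the molecule, so it is deterministic); both strings pass through the *same*
encoder object — weight sharing by identity, not by copy — and the head
consumes `[fp1 | fp2 | |fp2 − fp1|]` (3 × hidden inputs). The latent
strategy needs no labels: it minimizes `(cos(fp1, fp2) − 1)²` over such
pairs and reports held-out mean pair cosine before and after training.
Whether Siamese classification should update the encoder is left
configurable (the same freeze flag); the default updates it, matching the
single-branch default.

Classical heads (SVM, random forest, feed-forward network; scikit-learn
implementations) fit frozen fingerprint matrices on a seeded train split
and report held-out AUCROC or RMSE. Scaffold splitting groups molecules by
Bemis–Murcko scaffold and packs whole groups, largest first, into
train/valid/test, so held-out chemotypes are unseen.

## Screening evaluation

Library compounds are scored by fused cosine similarity to the query
actives — maximum over queries by default (the convention of similarity
benchmarking platforms; mean fusion by flag) — and sorted descending with
ties broken by input index. AUCROC is the probability a random active
outranks a random decoy (ties ½). BEDROC follows the standard
exponentially weighted, min–max-normalized definition (the formula is
transcribed in the code and cross-checked in tests against RDKit's
independent implementation as well as a hand-transcribed evaluation):
perfect early ranking gives 1, worst approaches 0, promoting an active
never decreases it, and as α → 0⁺ it flattens to a linear rank statistic.

The benchmark harness redraws the 5 queries per repetition (default 50
repetitions; the desk-scale directional tests use 20) and reports
mean ± std per target plus an across-target aggregate. Cluster evaluation
projects fingerprints to 2 principal components, runs K-means with k =
number of classes, maps clusters to classes by the best label permutation,
and reports the AUCROC of the mapped hard assignments together with the
silhouette coefficient of the cluster assignment — computed in the 2-D
projection by default (flag for the full-dimensional space), since hard
assignments carry no ranking information beyond the mapping.

## Attention attribution

The full (layer, head, from, to) attention tensor is extracted in eval
mode; every row is a distribution. Functional groups from a pluggable
SMARTS catalog (a deliberately small 15-pattern default, so results do not
depend on any external catalog version) are matched as substructures;
matched atom indices map to character spans through the atom-level
tokenization (the i-th atom token corresponds to RDKit atom i — this
round trip is verified per molecule and the group is skipped with a
warning if it fails), and spans map to the subword tokens overlapping
them. The attention proportion of a token set is the mean over all layers
and heads of the column-sum share it *receives* (row normalization makes
the total L, so proportions lie in [0, 1] and are additive over disjoint
sets); per-layer/per-head and emitted-attention variants are flags. The
published analysis does not fix the reduction or the pairing unit of its
rank-sum comparison, so the report adopts one defensible convention: each
matched group in each molecule contributes one observation, and each
group's proportion sample is tested against the pooled sample of all other
groups with a two-sided Mann–Whitney U — exact when both samples have ≤ 8
untied observations (verified against full permutation enumeration),
normal approximation with tie correction otherwise, and p = 1 with a flag
for fully tied input.

## Synthetic data

The generators assemble molecules from a closed grammar — alkyl chains
with optional branches, benzene/cyclohexane/pyridine/THF/thiophene cores,
and ~14 functional-group decorations — validated with RDKit, so every
emitted string is chemically valid and no database download is needed.
The corpus generator plants Zipf-distributed duplicate multiplicities
(rank-r molecule appears `max(1, round(30 / (r+1)^1.2))` times, first copy
canonical, later copies alternating canonical/randomized) and records the
ground-truth counts in a manifest. The screening generator embeds the
planted scaffold (indole by default) as one fragment of a larger random
molecule and builds decoys identically around near-miss aromatic cores,
verified scaffold-free — early versions that used structurally disjoint
decoys were rejected because every fingerprint, including random
projections, solved them at ceiling, leaving the benchmark unable to
discriminate. The labeled generator plants a nitro group on half the
molecules (classification; labels optionally flipped at the noise rate) or
uses the heavy-atom count plus Gaussian noise (regression), with noiseless
truth stored alongside.

What the fixtures do *not* emulate: drug-like property distributions,
stereochemistry-rich or macrocyclic chemistry, realistic functional-group
frequencies, or billion-scale corpus statistics. Passing the directional
tests shows the pipeline's machinery orders representations correctly
under controlled conditions; it does not certify performance on real
screening libraries.

## Desk-scale study conditions

The test suite's shared conditions: ~5,000 corpus lines from ~4,935 unique
molecules; unigram vocabulary 500; encoder 2 layers / 4 heads / hidden
64 / intermediate 128; one MLM epoch with effective batch 32 (8 × 4
accumulation); screening target of 30 actives vs 300 decoys with 5 queries
and 20 repetitions; fine-tuning 500 labeled molecules for 10 epochs;
Siamese latent training 600 molecules for 2 epochs at LR 5 × 10⁻⁴. These
sizes were chosen once as the smallest at which the directional effects
(pre-training beats random initialization, mean beats `[CLS]`, fine-tuning
sharpens clusters, latent training raises pair cosine) are comfortably
reproducible on one CPU core in minutes.

## Numerical choices and degenerate inputs

All training arithmetic is float64. Softmax and log-softmax subtract the
detached row maximum; BCE clips probabilities at 10⁻¹²; cosine rows in the
latent loss add 10⁻¹² inside the norms. Attention masking adds −10⁹ to
padded key scores. Ranking ties break by input index everywhere a sort
occurs. Degenerate cases are contracts, not crashes: single-atom molecules
augment to repeats; an empty string encodes to `[CLS][SEP]`; a batch with
no maskable tokens contributes zero loss; single-class training sets,
zero-norm vectors, all-identical fingerprint matrices and empty rank-sum
samples raise informative errors.

## Known limitations

The Viterbi-EM tokenizer is not bit-compatible with reference unigram
implementations (segmentation optimality, coverage and size contracts are
what is guaranteed). The NumPy training stack is single-process and
CPU-bound — full-scale (88 M parameter, billion-molecule) pre-training is
far outside its envelope; full-scale settings survive as configuration
presets and arithmetic. Attention attribution quantifies where attention
mass sits; it makes no causal interpretability claim.
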