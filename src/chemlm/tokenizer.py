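"""Unigram subword tokenization of SMILES strings.

SMILES has no whitespace word boundaries, so the tokenizer treats each line
as a raw character stream.  Training follows the unigram language-model
recipe: a large frequency-seeded candidate vocabulary of substrings is
refit by EM (hard Viterbi counts) and pruned by unigram probability until
exactly ``vocab_size`` entries remain, always keeping every single
character seen in training so that any string over the training alphabet is
encodable with zero ``[UNK]``.  Encoding is exact maximum-likelihood
(Viterbi) segmentation under the fitted token log-probabilities.

Content is truncated to ``MAX_CONTENT_TOKENS`` (512) tokens and wrapped in
``[CLS]`` ... ``[SEP]``, giving sequences of at most 514 ids.

A character-level regular-expression tokenizer (the atom-level SMILES
pattern widely used in chemistry language models) is provided as the
comparison baseline.
"""

from __future__ import annotations

import json
import math
import re
from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "SPECIAL_TOKENS", "PAD_ID", "CLS_ID", "SEP_ID", "UNK_ID", "MASK_ID",
    "MAX_CONTENT_TOKENS", "MAX_SEQUENCE_LENGTH", "DESK_VOCAB_SIZE",
    "FULL_VOCAB_SIZE", "DEFAULT_SMILES_REGEX", "TokenSequence",
    "UnigramTokenizer", "train_unigram", "regex_tokenize",
    "compare_token_counts",
]

# fixed special-token ids (reserved, dense, never overlapping content)
SPECIAL_TOKENS = ("[PAD]", "[CLS]", "[SEP]", "[UNK]", "[MASK]")
PAD_ID, CLS_ID, SEP_ID, UNK_ID, MASK_ID = range(5)

MAX_CONTENT_TOKENS = 512
MAX_SEQUENCE_LENGTH = MAX_CONTENT_TOKENS + 2  # [CLS] + content + [SEP]

DESK_VOCAB_SIZE = 500    # desk-scale preset
FULL_VOCAB_SIZE = 2417  # full-scale preset

# Atom-level SMILES pattern: bracket atoms, two-letter halogens, stereo
# marks, ring-closure escapes and single organic-subset symbols are each
# one token.
DEFAULT_SMILES_REGEX = (
    r"\[[^\]]+\]|Br|Cl|@@|%\d{2}"
    r"|[BCNOSPFIbcnosp]"
    r"|[0-9]|\(|\)|\.|=|#|-|\+|\\|/|:|~|@|\?|>|\*|\$"
)


@dataclass
class TokenSequence:
    """Encoded sequence: ids bracketed by [CLS]/[SEP], plus content offsets.

    ``offsets[i]`` is the half-open, 0-based character span of content token
    ``i`` (sequence position ``i + 1``); specials carry no span.
    ``truncated`` marks inputs whose segmentation exceeded the content limit.
    """

    ids: list[int]
    offsets: list[tuple[int, int]] = field(default_factory=list)
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def content_ids(self) -> list[int]:
        return self.ids[1:-1]


class UnigramTokenizer:
    """Unigram vocabulary with log-probabilities and fixed special tokens."""

    def __init__(self, logprobs: dict[str, float]):
        if any(s in logprobs for s in SPECIAL_TOKENS):
            raise ValueError("special tokens may not appear as content pieces")
        self.logprobs = dict(logprobs)
        self.vocab: dict[str, int] = {t: i for i, t in enumerate(SPECIAL_TOKENS)}
        for piece in sorted(self.logprobs):
            self.vocab[piece] = len(self.vocab)
        self.id_to_token = {i: t for t, i in self.vocab.items()}
        self._max_piece_len = max((len(p) for p in self.logprobs), default=1)
        # unknown characters score well below any real piece so they are
        # only used when no in-vocabulary segmentation exists
        self._unk_logprob = min(self.logprobs.values(), default=-10.0) - 10.0

    # -- properties -----------------------------------------------------------

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)

    @property
    def max_content_length(self) -> int:
        return MAX_CONTENT_TOKENS

    # -- encoding -------------------------------------------------------------

    def segment(self, text: str) -> list[tuple[str, int, int]]:
        """Viterbi max-likelihood segmentation into (piece, start, end).

        Unknown characters become single-character pieces scored at the UNK
        floor; ties between equal-likelihood segmentations break toward the
        longest last piece (deterministic).
        """
        n = len(text)
        if n == 0:
            return []
        NEG = -math.inf
        best = [NEG] * (n + 1)
        back: list[tuple[int, str] | None] = [None] * (n + 1)
        best[0] = 0.0
        for j in range(1, n + 1):
            lo = max(0, j - self._max_piece_len)
            for i in range(lo, j):
                if best[i] == NEG:
                    continue
                piece = text[i:j]
                lp = self.logprobs.get(piece)
                if lp is None:
                    if j - i == 1:
                        lp = self._unk_logprob
                    else:
                        continue
                score = best[i] + lp
                # >= prefers the longer final piece among ties
                if score >= best[j]:
                    best[j] = score
                    back[j] = (i, piece)
            if back[j] is None:  # unreachable: single chars always allowed
                raise RuntimeError("untokenizable position")  # pragma: no cover
        pieces: list[tuple[str, int, int]] = []
        j = n
        while j > 0:
            i, piece = back[j]
            pieces.append((piece, i, j))
            j = i
        pieces.reverse()
        return pieces

    def encode(self, smiles: str) -> TokenSequence:
        pieces = self.segment(smiles)
        truncated = len(pieces) > MAX_CONTENT_TOKENS
        if truncated:
            pieces = pieces[:MAX_CONTENT_TOKENS]
        ids = [CLS_ID]
        offsets = []
        for piece, start, end in pieces:
            ids.append(self.vocab.get(piece, UNK_ID))
            offsets.append((start, end))
        ids.append(SEP_ID)
        return TokenSequence(ids=ids, offsets=offsets, truncated=truncated)

    def decode(self, seq: TokenSequence | list[int]) -> str:
        ids = seq.ids if isinstance(seq, TokenSequence) else list(seq)
        parts = []
        for i in ids:
            if i not in self.id_to_token:
                raise KeyError(f"unknown token id {i}")
            if i < len(SPECIAL_TOKENS):
                continue
            parts.append(self.id_to_token[i])
        return "".join(parts)

    def n_content_tokens(self, smiles: str) -> int:
        return len(self.segment(smiles))

    # -- serialization --------------------------------------------------------

    def save(self, path) -> None:
        payload = {
            "format": "chemlm-unigram-v1",
            "specials": list(SPECIAL_TOKENS),
            "logprobs": self.logprobs,
            "vocab": self.vocab,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "UnigramTokenizer":
        with open(path) as fh:
            payload = json.load(fh)
        tok = cls(payload["logprobs"])
        if tok.vocab != {k: int(v) for k, v in payload["vocab"].items()}:
            raise ValueError("corrupt tokenizer file: vocab/id mismatch")
        return tok


def _candidate_counts(lines: list[str], max_piece_len: int) -> Counter:
    """Frequencies of all substrings up to ``max_piece_len`` characters."""
    counts: Counter = Counter()
    for line in lines:
        n = len(line)
        for i in range(n):
            for j in range(i + 1, min(i + max_piece_len, n) + 1):
                counts[line[i:j]] += 1
    return counts


def train_unigram(corpus, vocab_size: int, seed: int = 0,
                  max_piece_len: int = 8, n_em_rounds: int = 4,
                  seed_multiplier: int = 8) -> UnigramTokenizer:
    """Fit a unigram tokenizer on an iterable of SMILES lines.

    The candidate pool is the ``seed_multiplier * vocab_size`` most frequent
    substrings (frequency-weighted by length, the usual seeding heuristic)
    plus every single character.  Each EM round re-segments the corpus by
    Viterbi under current probabilities and refits piece probabilities from
    the resulting hard counts; between rounds the pool is pruned toward the
    target size, never dropping single characters.

    Raises ``ValueError`` if ``vocab_size`` cannot cover the character set
    plus specials, or exceeds what the corpus can support.
    """
    lines = [l for l in (line.rstrip("\n") for line in corpus) if l]
    if not lines:
        raise ValueError("empty corpus")
    charset = sorted({c for line in lines for c in line})
    n_content = vocab_size - len(SPECIAL_TOKENS)
    if n_content < len(charset):
        raise ValueError(
            f"vocab_size={vocab_size} below character coverage: need at least "
            f"{len(charset) + len(SPECIAL_TOKENS)}")

    counts = _candidate_counts(lines, max_piece_len)
    if len(counts) < n_content:
        raise ValueError(
            f"corpus supports only {len(counts) + len(SPECIAL_TOKENS)} distinct "
            f"pieces; vocab_size={vocab_size} is unreachable")

    # seed pool: singles always in; multis ranked by count * length
    multis = [p for p in counts if len(p) > 1]
    multis.sort(key=lambda p: (-counts[p] * len(p), p))
    pool = set(charset) | set(multis[: max(n_content, seed_multiplier * n_content)])

    total = sum(counts[p] for p in pool)
    logprobs = {p: math.log(counts[p] / total) for p in pool}
    tok = UnigramTokenizer(logprobs)

    target_schedule = []
    size = len(pool)
    while size > n_content:
        size = max(n_content, int(size * 0.6))
        target_schedule.append(size)
    if not target_schedule:
        target_schedule = [n_content]

    for rnd in range(max(n_em_rounds, len(target_schedule))):
        # E-step: hard counts from Viterbi segmentation
        piece_counts: Counter = Counter()
        for line in lines:
            for piece, _, _ in tok.segment(line):
                piece_counts[piece] += 1
        # M-step with light smoothing so unused singles survive
        for c in charset:
            piece_counts[c] += 1e-3
        total = sum(piece_counts.values())
        logprobs = {p: math.log(piece_counts[p] / total)
                    for p in tok.logprobs if piece_counts.get(p, 0) > 0}
        # prune multi-character pieces with the lowest probability
        target = target_schedule[min(rnd, len(target_schedule) - 1)]
        if len(logprobs) > target:
            singles = {p: lp for p, lp in logprobs.items() if len(p) == 1}
            ranked = sorted(
                ((p, lp) for p, lp in logprobs.items() if len(p) > 1),
                key=lambda kv: (-kv[1], kv[0]))
            keep = dict(ranked[: target - len(singles)])
            keep.update(singles)
            logprobs = keep
        tok = UnigramTokenizer(logprobs)

    # top up if pruning + zero-count loss undershot the target
    if len(tok.logprobs) < n_content:
        extra = [p for p in multis if p not in tok.logprobs]
        floor = min(tok.logprobs.values()) - 1.0
        for p in extra[: n_content - len(tok.logprobs)]:
            tok.logprobs[p] = floor
        tok = UnigramTokenizer(tok.logprobs)

    assert tok.vocab_size == vocab_size, (tok.vocab_size, vocab_size)
    return tok


def regex_tokenize(smiles: str, pattern: str = DEFAULT_SMILES_REGEX) -> list[str]:
    """Tokenize with an atom-level pattern; tokens must tile the string.

    Raises ``ValueError`` naming the offending span if any character is not
    covered by the pattern.
    """
    tokens = []
    pos = 0
    rx = re.compile(pattern)
    for m in rx.finditer(smiles):
        if m.start() != pos:
            raise ValueError(
                f"untokenizable span {smiles[pos:m.start()]!r} at position {pos}")
        tokens.append(m.group(0))
        pos = m.end()
    if pos != len(smiles):
        raise ValueError(f"untokenizable span {smiles[pos:]!r} at position {pos}")
    return tokens


def compare_token_counts(corpus, model: UnigramTokenizer,
                         pattern: str = DEFAULT_SMILES_REGEX) -> dict:
    """Total content-token counts under both tokenizers (no specials/padding)."""
    total_unigram = 0
    total_regex = 0
    n = 0
    for line in corpus:
        line = line.rstrip("\n")
        if not line:
            continue
        n += 1
        total_unigram += model.n_content_tokens(line)
        total_regex += len(regex_tokenize(line, pattern))
    if n == 0:
        raise ValueError("empty corpus")
    return {
        "total_unigram": total_unigram,
        "total_regex": total_regex,
        "n_smiles": n,
        "mean_diff_per_smiles": (total_regex - total_unigram) / n,
    }
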