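"""Transformer encoder and masked-language-model pre-training.

The encoder is the standard bidirectional-encoder family configuration:
learned absolute position embeddings, pre-norm-free (post-LN) attention
blocks with GELU feed-forward layers, and an MLM head whose output
projection is weight-tied to the input embedding table.  At the full-scale
preset (12 layers, 12 heads, hidden 768, intermediate 3072, 514 positions,
vocabulary 2417) the tied-head parameter count is ~88 million.

Pre-training uses the usual MLM recipe: 15% of content tokens are selected
for corruption, of which 80% become ``[MASK]``, 10% a random content token
and 10% stay unchanged; cross-entropy is taken over corrupted positions
only.  Gradient accumulation reproduces large-batch semantics exactly: the
macro-batch's corrupted positions are counted first, and every micro-batch
loss is weighted by its share, so accumulated gradients equal the
one-big-batch mean-loss gradient to floating-point precision (the
single-process counterpart of all-reduce data parallelism).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import Tensor
from .tokenizer import (CLS_ID, MASK_ID, PAD_ID, SEP_ID,
                        MAX_SEQUENCE_LENGTH, UnigramTokenizer)

__all__ = [
    "EncoderConfig", "TransformerEncoder", "MlmHead", "MlmConfig", "Schedule",
    "BatchPlan", "desk_config", "full_config", "count_parameters",
    "mask_tokens", "mlm_loss", "lr_at_step", "effective_batch_size",
    "collate", "pretrain", "save_checkpoint", "load_checkpoint",
]

_N_SPECIALS = 5  # [PAD],[CLS],[SEP],[UNK],[MASK]


@dataclass
class EncoderConfig:
    vocab_size: int
    n_layers: int = 12
    n_heads: int = 12
    hidden: int = 768              # fingerprint dimensionality
    intermediate: int = 3072
    max_positions: int = MAX_SEQUENCE_LENGTH
    dropout: float = 0.1
    layer_norm_eps: float = 1e-12

    def __post_init__(self):
        if self.hidden % self.n_heads != 0:
            raise ValueError("hidden must be divisible by n_heads")
        if self.max_positions < 3:
            raise ValueError("max_positions must be >= 3")
        if self.vocab_size <= _N_SPECIALS:
            raise ValueError("vocab_size must exceed the special-token count")


def desk_config(vocab_size: int, **overrides) -> EncoderConfig:
    """Small configuration for laptop-scale experiments and tests."""
    base = dict(n_layers=2, n_heads=4, hidden=64, intermediate=128,
                max_positions=MAX_SEQUENCE_LENGTH, dropout=0.1)
    base.update(overrides)
    return EncoderConfig(vocab_size=vocab_size, **base)


def full_config(vocab_size: int = 2417, **overrides) -> EncoderConfig:
    """Full-scale configuration: 12x12, hidden 768, intermediate 3072."""
    base = dict(n_layers=12, n_heads=12, hidden=768, intermediate=3072,
                max_positions=MAX_SEQUENCE_LENGTH, dropout=0.1)
    base.update(overrides)
    return EncoderConfig(vocab_size=vocab_size, **base)


class _SelfAttention(nn.Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        H = cfg.hidden
        self.n_heads = cfg.n_heads
        self.head_dim = H // cfg.n_heads
        self.q = nn.Linear(H, H, rng)
        self.k = nn.Linear(H, H, rng)
        self.v = nn.Linear(H, H, rng)
        self.out = nn.Linear(H, H, rng)
        self.dropout_p = cfg.dropout

    def __call__(self, x: Tensor, pad_mask: np.ndarray,
                 rng: np.random.Generator, collect):
        B, L, H = x.shape
        nh, dh = self.n_heads, self.head_dim

        def split(t: Tensor) -> Tensor:  # (B,L,H) -> (B,nh,L,dh)
            return t.reshape(B, L, nh, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        # additive mask: padded keys get -inf-like scores
        bias = np.where(pad_mask[:, None, None, :], 0.0, -1e9)
        attn = nn.softmax(scores + Tensor(bias), axis=-1)
        if collect is not None:
            collect.append(attn.data.copy())
        attn = nn.dropout(attn, self.dropout_p, rng, self.training)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, H)
        return self.out(ctx)


class _EncoderLayer(nn.Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.attention = _SelfAttention(cfg, rng)
        self.attn_norm = nn.LayerNorm(cfg.hidden, cfg.layer_norm_eps)
        self.ff_in = nn.Linear(cfg.hidden, cfg.intermediate, rng)
        self.ff_out = nn.Linear(cfg.intermediate, cfg.hidden, rng)
        self.ff_norm = nn.LayerNorm(cfg.hidden, cfg.layer_norm_eps)
        self.dropout_p = cfg.dropout

    def __call__(self, x, pad_mask, rng, collect):
        a = self.attention(x, pad_mask, rng, collect)
        a = nn.dropout(a, self.dropout_p, rng, self.training)
        x = self.attn_norm(x + a)
        h = self.ff_out(nn.gelu(self.ff_in(x)))
        h = nn.dropout(h, self.dropout_p, rng, self.training)
        return self.ff_norm(x + h)


class TransformerEncoder(nn.Module):
    """Maps id sequences to per-token hidden states (and attention maps)."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        self.word_emb = nn.Embedding(config.vocab_size, config.hidden, rng)
        self.pos_emb = nn.Embedding(config.max_positions, config.hidden, rng)
        self.emb_norm = nn.LayerNorm(config.hidden, config.layer_norm_eps)
        self.layers = [_EncoderLayer(config, rng) for _ in range(config.n_layers)]
        self.dropout_p = config.dropout
        self._rng = np.random.default_rng(rng.integers(2**31))

    def reseed(self, seed: int) -> None:
        """Reset the dropout stream (for reproducible training runs)."""
        self._rng = np.random.default_rng(seed)

    def forward(self, ids: np.ndarray, pad_mask: np.ndarray | None = None,
                collect_attention: bool = False):
        """``ids``: int array (B, L); ``pad_mask``: bool (B, L), True = real.

        Returns ``(hidden_states, attentions)`` where ``hidden_states`` is a
        (B, L, hidden) tensor and ``attentions`` (when requested) a list of
        per-layer (B, n_heads, L, L) arrays whose rows sum to 1.
        """
        ids = np.asarray(ids)
        if ids.ndim == 1:
            ids = ids[None, :]
        B, L = ids.shape
        if L > self.config.max_positions:
            raise ValueError(
                f"sequence length {L} exceeds max_positions "
                f"{self.config.max_positions}")
        if pad_mask is None:
            pad_mask = ids != PAD_ID
        x = self.word_emb(ids) + self.pos_emb(np.broadcast_to(np.arange(L), (B, L)))
        x = self.emb_norm(x)
        x = nn.dropout(x, self.dropout_p, self._rng, self.training)
        collected = [] if collect_attention else None
        for layer in self.layers:
            x = layer(x, pad_mask, self._rng, collected)
        return x, collected

    __call__ = forward


class MlmHead(nn.Module):
    """Dense + GELU + LayerNorm, then projection tied to the embedding table."""

    def __init__(self, encoder: TransformerEncoder):
        super().__init__()
        cfg = encoder.config
        rng = np.random.default_rng(1)
        self.dense = nn.Linear(cfg.hidden, cfg.hidden, rng)
        self.norm = nn.LayerNorm(cfg.hidden, cfg.layer_norm_eps)
        self.decoder_weight = encoder.word_emb.weight   # tied (same Tensor)
        self.decoder_bias = Tensor(np.zeros(cfg.vocab_size), requires_grad=True)

    def __call__(self, hidden: Tensor) -> Tensor:
        h = self.norm(nn.gelu(self.dense(hidden)))
        return h @ self.decoder_weight.transpose(1, 0) + self.decoder_bias


class MlmModel(nn.Module):
    def __init__(self, encoder: TransformerEncoder):
        super().__init__()
        self.encoder = encoder
        self.head = MlmHead(encoder)


def count_parameters(model: nn.Module) -> int:
    """Trainable scalar count; tied tensors are counted once (by identity)."""
    return model.n_parameters()


@dataclass
class MlmConfig:
    mask_prob: float = 0.15
    mask_split: tuple[float, float, float] = (0.8, 0.1, 0.1)  # mask/random/keep
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.mask_prob <= 1.0:
            raise ValueError("mask_prob must be in [0, 1]")
        if abs(sum(self.mask_split) - 1.0) > 1e-9:
            raise ValueError("mask_split must sum to 1")


IGNORE_INDEX = -100
_SPECIAL_IDS = frozenset({PAD_ID, CLS_ID, SEP_ID})


def mask_tokens(ids: np.ndarray, cfg: MlmConfig, vocab_size: int,
                rng: np.random.Generator | None = None):
    """BERT-style corruption of a padded id batch.

    Content tokens ([CLS]/[SEP]/[PAD] excluded) are selected independently
    with probability ``mask_prob``; selected positions become ``[MASK]``,
    a random content token, or stay, per ``mask_split``.  Returns
    ``(corrupted, labels, positions)`` where labels hold original ids at
    corrupted positions and ``IGNORE_INDEX`` elsewhere.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ids = np.asarray(ids)
    corrupted = ids.copy()
    labels = np.full_like(ids, IGNORE_INDEX)
    content = ~np.isin(ids, (PAD_ID, CLS_ID, SEP_ID))
    selected = content & (rng.random(ids.shape) < cfg.mask_prob)
    if selected.any():
        labels[selected] = ids[selected]
        p_mask, p_rand, _ = cfg.mask_split
        u = rng.random(ids.shape)
        to_mask = selected & (u < p_mask)
        to_rand = selected & (u >= p_mask) & (u < p_mask + p_rand)
        corrupted[to_mask] = MASK_ID
        n_rand = int(to_rand.sum())
        if n_rand:
            corrupted[to_rand] = rng.integers(_N_SPECIALS, vocab_size, size=n_rand)
    return corrupted, labels, selected


def mlm_loss(logits: Tensor, labels: np.ndarray) -> tuple[Tensor, int]:
    """Mean cross-entropy over corrupted positions.

    ``logits``: (..., vocab) tensor; ``labels``: matching int array with
    ``IGNORE_INDEX`` at uncorrupted positions.  Returns ``(loss, n)`` where
    ``n`` is the number of scored positions; with no corrupted positions the
    loss is defined as 0 (n == 0 is the caller's warning flag).
    """
    labels = np.asarray(labels)
    flat_logits = logits.reshape(-1, logits.shape[-1])
    flat_labels = labels.reshape(-1)
    keep = flat_labels != IGNORE_INDEX
    n = int(keep.sum())
    if n == 0:
        return Tensor(0.0), 0
    idx = np.nonzero(keep)[0]
    sel = flat_logits[idx]                      # (n, vocab)
    logp = nn.log_softmax(sel, axis=-1)
    picked = logp[np.arange(n), flat_labels[idx]]
    return -picked.mean(), n


@dataclass
class Schedule:
    """Linear warmup to ``peak_lr``, then polynomial decay to ``end_lr``."""

    peak_lr: float = 6e-4
    warmup_steps: int = 0
    total_steps: int = 1
    power: float = 1.0
    end_lr: float = 0.0

    def __post_init__(self):
        if not 0 <= self.warmup_steps <= self.total_steps:
            raise ValueError("need 0 <= warmup_steps <= total_steps")


def lr_at_step(s: Schedule, step: int) -> float:
    if not 0 <= step <= s.total_steps:
        raise ValueError(f"step {step} outside [0, {s.total_steps}]")
    if s.warmup_steps > 0 and step < s.warmup_steps:
        return s.peak_lr * step / s.warmup_steps
    if s.total_steps == s.warmup_steps:
        return s.peak_lr
    frac = (step - s.warmup_steps) / (s.total_steps - s.warmup_steps)
    return s.end_lr + (s.peak_lr - s.end_lr) * (1.0 - frac) ** s.power


@dataclass
class BatchPlan:
    per_device: int = 8
    accum_steps: int = 32
    world_size: int = 1


def effective_batch_size(plan: BatchPlan) -> int:
    if min(plan.per_device, plan.accum_steps, plan.world_size) < 1:
        raise ValueError("batch plan fields must be positive")
    return plan.per_device * plan.accum_steps * plan.world_size


def collate(seqs: list[list[int]], pad_to: int | None = None):
    """Pad id lists to a rectangle; returns (ids, pad_mask)."""
    L = pad_to if pad_to is not None else max(len(s) for s in seqs)
    ids = np.full((len(seqs), L), PAD_ID, dtype=np.intp)
    mask = np.zeros((len(seqs), L), dtype=bool)
    for i, s in enumerate(seqs):
        ids[i, :len(s)] = s
        mask[i, :len(s)] = True
    return ids, mask


@dataclass
class TraceEntry:
    step: int
    lr: float
    loss: float


def _macro_batch_step(model: MlmModel, optimizer: nn.AdamW, seqs: list[list[int]],
                      mlm_cfg: MlmConfig, plan: BatchPlan, lr: float,
                      mask_rng: np.random.Generator) -> float:
    """One optimizer step over ``seqs`` with gradient accumulation.

    Masking is planned for the whole macro-batch first; each micro-batch
    loss is weighted by its corrupted-position share so the accumulated
    gradient equals the single large-batch mean-CE gradient.
    """
    ids, pad = collate(seqs)
    corrupted, labels, _ = mask_tokens(ids, mlm_cfg, model.encoder.config.vocab_size,
                                       rng=mask_rng)
    total_n = int((labels != IGNORE_INDEX).sum())
    optimizer.zero_grad()
    if total_n == 0:
        return 0.0
    loss_total = 0.0
    micro = plan.per_device
    for lo in range(0, len(seqs), micro):
        sl = slice(lo, lo + micro)
        lengths = pad[sl].sum(axis=1)
        Lmax = int(lengths.max())
        hidden, _ = model.encoder(corrupted[sl, :Lmax], pad[sl, :Lmax])
        logits = model.head(hidden)
        loss, n = mlm_loss(logits, labels[sl, :Lmax])
        if n == 0:
            continue
        weighted = loss * (n / total_n)
        weighted.backward()
        loss_total += float(weighted.data)
    optimizer.step(lr=lr)
    return loss_total


def pretrain(corpus_lines: list[str], tokenizer: UnigramTokenizer,
             encoder: TransformerEncoder, mlm_cfg: MlmConfig | None = None,
             schedule: Schedule | None = None, plan: BatchPlan | None = None,
             epochs: int = 1, seed: int = 0, weight_decay: float = 0.01,
             checkpoint_dir=None, checkpoint_every: int = 0,
             shuffle: bool = False) -> tuple[TransformerEncoder, list[TraceEntry]]:
    """MLM pre-training; returns the trained encoder and the loss trace.

    The corpus is consumed in order (curation already shuffles it) unless
    ``shuffle`` is set.  On a NaN loss the run aborts and the last
    checkpointed weights are restored.
    """
    mlm_cfg = mlm_cfg or MlmConfig(seed=seed)
    plan = plan or BatchPlan(per_device=8, accum_steps=4, world_size=1)
    macro = plan.per_device * plan.accum_steps
    seqs = [tokenizer.encode(l.rstrip("\n")).ids for l in corpus_lines
            if l.strip()]
    if not seqs:
        raise ValueError("empty corpus")
    steps_per_epoch = max(1, (len(seqs) + macro - 1) // macro)
    total = steps_per_epoch * epochs
    schedule = schedule or Schedule(peak_lr=1e-3,
                                    warmup_steps=max(1, int(0.06 * total)),
                                    total_steps=total)
    model = MlmModel(encoder)
    model.train()
    encoder.reseed(seed + 1)
    optimizer = nn.AdamW(model.parameters(), weight_decay=weight_decay)
    mask_rng = np.random.default_rng(mlm_cfg.seed)
    order_rng = np.random.default_rng(seed + 2)
    trace: list[TraceEntry] = []
    last_good: dict | None = None
    step = 0
    for _ in range(epochs):
        order = list(range(len(seqs)))
        if shuffle:
            order_rng.shuffle(order)
        for lo in range(0, len(seqs), macro):
            batch = [seqs[i] for i in order[lo:lo + macro]]
            step += 1
            lr = lr_at_step(schedule, min(step, schedule.total_steps))
            loss = _macro_batch_step(model, optimizer, batch, mlm_cfg, plan,
                                     lr, mask_rng)
            if not np.isfinite(loss):
                if last_good is not None:
                    model.load_state_dict(last_good)
                raise FloatingPointError(
                    f"training diverged at step {step}; restored last checkpoint")
            trace.append(TraceEntry(step=step, lr=lr, loss=loss))
            if checkpoint_every and step % checkpoint_every == 0:
                last_good = {k: v.copy() for k, v in model.state_dict().items()}
                if checkpoint_dir is not None:
                    save_checkpoint(checkpoint_dir, encoder, trace)
    model.eval()
    if checkpoint_dir is not None:
        save_checkpoint(checkpoint_dir, encoder, trace)
    return encoder, trace


def save_checkpoint(ckpt_dir, encoder: TransformerEncoder,
                    trace: list[TraceEntry] | None = None) -> None:
    """Config JSON + weights (npz) + loss trace CSV in ``ckpt_dir``."""
    os.makedirs(ckpt_dir, exist_ok=True)
    with open(os.path.join(ckpt_dir, "config.json"), "w") as fh:
        json.dump(asdict(encoder.config), fh, indent=2)
    np.savez(os.path.join(ckpt_dir, "weights.npz"), **encoder.state_dict())
    if trace is not None:
        with open(os.path.join(ckpt_dir, "trace.csv"), "w") as fh:
            fh.write("step,lr,loss\n")
            for t in trace:
                fh.write(f"{t.step},{t.lr:.8g},{t.loss:.8g}\n")


def load_checkpoint(ckpt_dir) -> TransformerEncoder:
    with open(os.path.join(ckpt_dir, "config.json")) as fh:
        cfg = EncoderConfig(**json.load(fh))
    encoder = TransformerEncoder(cfg)
    with np.load(os.path.join(ckpt_dir, "weights.npz")) as npz:
        encoder.load_state_dict(dict(npz))
    encoder.eval()
    return encoder
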