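"""Masked-language-model pre-training of a desk-scale encoder.

15% of content tokens are corrupted (80% [MASK] / 10% random / 10% kept)
and the encoder learns to recover them; the loss trace shows learning
within a single epoch.  Gradient accumulation gives large effective
batches on one process.
"""

from chemlm.fixtures import FixtureSpec, gen_corpus
from chemlm.model import (BatchPlan, TransformerEncoder, desk_config,
                          effective_batch_size, pretrain)
from chemlm.tokenizer import train_unigram

lines = gen_corpus(FixtureSpec(n_molecules=1500, seed=7)).lines
tok = train_unigram(lines, vocab_size=300, seed=0)

plan = BatchPlan(per_device=8, accum_steps=4, world_size=1)
print("effective batch size:", effective_batch_size(plan))

encoder = TransformerEncoder(desk_config(tok.vocab_size), seed=0)
encoder, trace = pretrain(lines, tok, encoder, epochs=1, seed=1, plan=plan)

first = sum(t.loss for t in trace[:5]) / 5
last = sum(t.loss for t in trace[-5:]) / 5
print(f"{len(trace)} optimizer steps; "
      f"mean MLM loss first 5 steps {first:.3f} -> last 5 steps {last:.3f}")
# the drop in cross-entropy shows the model is learning SMILES statistics.
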