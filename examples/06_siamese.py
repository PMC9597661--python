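"""Siamese training strategies over paired canonical/randomized SMILES.

Latent strategy: pull the cosine similarity of a molecule's canonical and
permuted fingerprints toward 1 (MSE loss).  Classification strategy: feed
[fp1 | fp2 | |fp2 - fp1|] of the pair through a single head; both branches
share one weight set.
"""

from chemlm.adapt import (FineTuneConfig, siamese_classify, siamese_features,
                          siamese_latent_loss, siamese_latent_train)
from chemlm.fixtures import (FixtureSpec, gen_corpus, gen_labeled_dataset,
                             gen_molecules)
from chemlm.model import TransformerEncoder, desk_config, pretrain
from chemlm.tokenizer import train_unigram

lines = gen_corpus(FixtureSpec(n_molecules=1500, seed=11)).lines
tok = train_unigram(lines, vocab_size=300, seed=0)
encoder = TransformerEncoder(desk_config(tok.vocab_size), seed=0)
encoder, _ = pretrain(lines, tok, encoder, epochs=1, seed=1)

print("feature layout for fp1=(1,0), fp2=(0,1):",
      siamese_features([1.0, 0.0], [0.0, 1.0]))
print("latent loss at cosine 1 / 0 / -1:",
      siamese_latent_loss([1.0, 0.0], [1.0, 0.0]),
      siamese_latent_loss([1.0, 0.0], [0.0, 1.0]),
      siamese_latent_loss([1.0, 0.0], [-1.0, 0.0]))

molecules = gen_molecules(400, seed=33)
_, report = siamese_latent_train(encoder, tok, molecules,
                                 FineTuneConfig(epochs=2, seed=3, lr=5e-4))
print(f"held-out canonical/permuted cosine: "
      f"{report['holdout_cosine_before']:.3f} -> "
      f"{report['holdout_cosine_after']:.3f}")

dataset = gen_labeled_dataset(250, "nitro", 0.0, seed=8)
bundle = siamese_classify(encoder, tok, dataset,
                          FineTuneConfig(epochs=5, seed=2))
print("Siamese classifier held-out accuracy:",
      bundle.metrics[-1]["test_metric"])
# after latent training, SMILES permutations of one molecule land close
# together in cosine space.
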