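"""Curate raw SMILES streams into a pre-training corpus.

Two synthetic sources (a molecule stream with planted duplicates and a
small reaction stream) are canonicalized, duplicate frequencies analyzed,
the most common duplicates re-emitted in canonical and randomized form,
and the result shuffled deterministically.
"""

import json
import tempfile
from pathlib import Path

from chemlm.corpus import (CurationConfig, build_pretraining_corpus,
                           extract_molecules_from_reaction)
from chemlm.fixtures import FixtureSpec, gen_corpus

reactions = [
    "CCO.CC(=O)O>>CC(=O)OCC",      # esterification
    "CCO.CC(=O)Cl>>CC(=O)OCC",     # same product, different route
    "c1ccccc1.CC(=O)Cl>>CC(=O)c1ccccc1",
]
reaction_molecules = [m for rxn in reactions
                      for m in extract_molecules_from_reaction(rxn)]

fixture = gen_corpus(FixtureSpec(n_molecules=400, seed=7))

out = Path(tempfile.mkdtemp()) / "corpus.txt"
manifest = build_pretraining_corpus(
    {"molecules": fixture.lines, "reactions": reaction_molecules},
    CurationConfig(top_fraction=0.2, shuffle_seed=0), out)

print(json.dumps({k: manifest[k] for k in
                  ("n_unique", "n_duplicated", "top_set_size",
                   "n_augmented_emitted", "n_lines")}, indent=2))
print("first corpus lines:", out.read_text().splitlines()[:3])
# n_unique molecules each appear once, except the top 20% most duplicated,
# which are re-emitted count-proportionally (half of those as randomized
# SMILES); n_lines is the final shuffled stream length.
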