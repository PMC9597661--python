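"""Seeded synthetic SMILES generation.

Molecules are assembled from a closed grammar — alkyl / aryl backbones with
functional-group decorations — and validated with RDKit, so every emitted
string is chemically valid and no external database is needed.  Three
generators emulate the statistical structure of the data the toolkit
consumes:

* :func:`gen_corpus` — a pre-training stream containing duplicates in
  canonical and randomized form whose multiplicities follow a Zipf law,
  with a manifest of planted ground-truth counts;
* :func:`gen_screening_target` — actives sharing a planted scaffold versus
  scaffold-free decoys;
* :func:`gen_labeled_dataset` — labels from a deterministic structural rule
  (plus optional noise) for classification, or a computable scalar for
  regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.rdBase import BlockLogs

from .corpus import augment, sanitize_and_canonicalize, SmilesRejection

__all__ = [
    "FixtureSpec", "CorpusFixture", "ScreeningTarget", "LabeledDataset",
    "random_molecule", "gen_molecules", "gen_corpus",
    "gen_screening_target", "gen_labeled_dataset", "DEFAULT_SCAFFOLD",
]

DEFAULT_SCAFFOLD = "c1ccc2[nH]ccc2c1"  # indole: distinctive, easy to decorate

# grammar pieces --------------------------------------------------------------
# suffix groups: valid when appended after a chain/ring atom
_SUFFIX_GROUPS = [
    "O", "N", "Cl", "F", "Br", "C#N", "C(=O)O", "C(=O)OC", "C(=O)N",
    "[N+](=O)[O-]", "S", "OC", "C=C", "C(C)=O",
]
# branch groups: valid inside parentheses on a chain carbon
_BRANCH_GROUPS = ["O", "N", "Cl", "F", "C", "CC", "C#N", "C(=O)O", "OC"]
# prefix groups: valid as the opening fragment, bonding rightward
_PREFIX_GROUPS = ["O", "N", "OC", "C(=O)O", "NC(=O)", "CC(=O)", "C#C"]
_RINGS = ["c1ccccc1", "C1CCCCC1", "c1ccncc1", "C1CCOC1", "c1ccsc1"]


def _random_chain(rng: np.random.Generator, min_len: int = 1,
                  max_len: int = 7, branch_p: float = 0.25) -> str:
    n = int(rng.integers(min_len, max_len + 1))
    parts = []
    for i in range(n):
        parts.append("C")
        if 0 < i < n - 1 and rng.random() < branch_p:
            parts.append(f"({rng.choice(_BRANCH_GROUPS)})")
    return "".join(parts)


def random_molecule(rng: np.random.Generator, allow_nitro: bool = True,
                    allow_aromatic_n: bool = True) -> str:
    """One raw SMILES from the grammar (not yet validated)."""
    suffixes = [g for g in _SUFFIX_GROUPS
                if allow_nitro or g != "[N+](=O)[O-]"]
    rings = [r for r in _RINGS if allow_aromatic_n or "n" not in r]
    kind = rng.random()
    chain = _random_chain(rng)
    if kind < 0.35:  # decorated chain
        s = chain
        if rng.random() < 0.8:
            s += rng.choice(suffixes)
        if rng.random() < 0.3:
            s = rng.choice(_PREFIX_GROUPS) + s
    elif kind < 0.7:  # chain + ring
        s = chain + rng.choice(rings)
        if rng.random() < 0.4:
            s = rng.choice(_PREFIX_GROUPS) + s
    else:  # substituted benzene
        sub = rng.choice(suffixes)
        s = f"c1ccc({sub})cc1"
        if rng.random() < 0.5:
            s = _random_chain(rng, 1, 4) + s
    return s


def gen_molecules(n: int, seed: int, allow_nitro: bool = True,
                  allow_aromatic_n: bool = True,
                  exclude: set[str] | None = None,
                  max_attempts_factor: int = 200) -> list[str]:
    """``n`` distinct valid canonical molecules from the grammar."""
    rng = np.random.default_rng(seed)
    exclude = set(exclude or ())
    out: list[str] = []
    seen: set[str] = set(exclude)
    attempts = 0
    budget = max_attempts_factor * n
    while len(out) < n:
        attempts += 1
        if attempts > budget:
            raise RuntimeError(
                f"grammar exhausted: produced {len(out)}/{n} molecules")
        raw = random_molecule(rng, allow_nitro=allow_nitro,
                              allow_aromatic_n=allow_aromatic_n)
        try:
            canon = sanitize_and_canonicalize(raw)
        except SmilesRejection:
            continue
        if canon in seen:
            continue
        seen.add(canon)
        out.append(canon)
    return out


@dataclass
class FixtureSpec:
    """Conditions for synthetic corpus generation."""

    n_molecules: int = 1000          # unique molecules
    zipf_exponent: float = 1.2       # duplicate-frequency skew
    top_count: int = 30              # multiplicity of the most frequent molecule
    scaffold: str = DEFAULT_SCAFFOLD
    label_rule: str = "nitro"
    noise_rate: float = 0.0
    seed: int = 0


@dataclass
class CorpusFixture:
    """Generated stream plus the ground truth needed to verify it."""

    lines: list[str]                      # raw SMILES, shuffled
    counts: dict[str, int]                # planted canonical -> multiplicity
    spec: FixtureSpec

    def canonical_set(self) -> set[str]:
        return set(self.counts)


def gen_corpus(spec: FixtureSpec) -> CorpusFixture:
    """Zipf-duplicated SMILES stream in canonical and randomized forms.

    Molecule at frequency rank r (0-based) is planted
    ``max(1, round(top_count / (r+1)**zipf_exponent))`` times; the first
    copy is canonical, further copies alternate canonical / randomized.
    """
    rng = np.random.default_rng(spec.seed)
    molecules = gen_molecules(spec.n_molecules, seed=int(rng.integers(2**31)))
    counts: dict[str, int] = {}
    lines: list[str] = []
    for rank, canon in enumerate(molecules):
        m = max(1, int(round(spec.top_count / (rank + 1) ** spec.zipf_exponent)))
        counts[canon] = m
        n_canon = math.ceil(m / 2)
        emitted = [canon] * n_canon
        if m > n_canon:
            emitted += augment(canon, m - n_canon, seed=int(rng.integers(2**31)))
        lines.extend(emitted)
    rng.shuffle(lines)
    return CorpusFixture(lines=lines, counts=counts, spec=spec)


@dataclass
class ScreeningTarget:
    """One retrieval experiment: actives share a scaffold, decoys do not."""

    name: str
    actives: list[str]
    decoys: list[str]
    n_queries: int = 5

    def __post_init__(self):
        if self.n_queries >= len(self.actives):
            raise ValueError("n_queries must be < number of actives")
        overlap = set(self.actives) & set(self.decoys)
        if overlap:
            raise ValueError(f"actives and decoys overlap: {sorted(overlap)[:3]}")


# near-miss cores for decoys: aromatic rings that are not the scaffold
_DECOY_RINGS = ["c1cc[nH]c1", "c1ccncc1", "c1ccc2ccccc2c1", "c1ccsc1", "c1ccoc1"]


def _decorated(rng: np.random.Generator, core: str) -> str:
    """Embed ``core`` in a larger random molecule so it is a minor fragment."""
    return (_random_chain(rng, 3, 8, branch_p=0.35)
            + rng.choice(["c1ccccc1", "C1CCCCC1", ""])
            + _random_chain(rng, 1, 4)
            + core
            + rng.choice(["O", "Cl", "C", "CC", "OC", ""]))


def gen_screening_target(n_actives: int, n_decoys: int,
                         scaffold: str = DEFAULT_SCAFFOLD,
                         seed: int = 0, n_queries: int = 5,
                         name: str = "planted") -> ScreeningTarget:
    """Planted-scaffold retrieval target.

    Actives embed ``scaffold`` as one fragment of a larger, diverse
    molecule; decoys are built identically around near-miss aromatic cores
    (pyrrole, pyridine, naphthalene, ...) and verified scaffold-free, so
    retrieval requires recognizing the scaffold rather than gross
    composition.  Disjointness of the canonical sets is guaranteed.
    """
    with BlockLogs():
        patt = Chem.MolFromSmiles(scaffold)
    if patt is None:
        raise ValueError(f"invalid scaffold {scaffold!r}")
    rng = np.random.default_rng(seed)
    actives: list[str] = []
    seen: set[str] = set()
    attempts = 0
    with BlockLogs():
        while len(actives) < n_actives:
            attempts += 1
            if attempts > 500 * n_actives:
                raise RuntimeError("could not generate enough distinct actives")
            raw = _decorated(rng, scaffold)
            try:
                canon = sanitize_and_canonicalize(raw)
            except SmilesRejection:
                continue
            mol = Chem.MolFromSmiles(canon)
            if canon in seen or mol is None or not mol.HasSubstructMatch(patt):
                continue
            seen.add(canon)
            actives.append(canon)

        decoys: list[str] = []
        attempts = 0
        while len(decoys) < n_decoys:
            attempts += 1
            if attempts > 500 * n_decoys:
                raise RuntimeError("could not generate enough scaffold-free decoys")
            raw = _decorated(rng, str(rng.choice(_DECOY_RINGS)))
            try:
                canon = sanitize_and_canonicalize(raw)
            except SmilesRejection:
                continue
            mol = Chem.MolFromSmiles(canon)
            if canon in seen or mol is None or mol.HasSubstructMatch(patt):
                continue
            seen.add(canon)
            decoys.append(canon)
    return ScreeningTarget(name=name, actives=actives, decoys=decoys,
                           n_queries=n_queries)


_NITRO_SMARTS = "[NX3+](=O)[O-]"


@dataclass
class LabeledDataset:
    frame: pd.DataFrame                  # columns: smiles, label
    rule: str
    noise_rate: float
    truth: dict[str, float] = field(default_factory=dict)  # noiseless rule value

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def gen_labeled_dataset(n: int, label_rule: str = "nitro",
                        noise_rate: float = 0.0, seed: int = 0) -> LabeledDataset:
    """Labeled molecules.

    ``label_rule='nitro'`` — binary: presence of a nitro group (planted on
    half the molecules), flipped with probability ``noise_rate``.
    ``label_rule='heavy_atoms'`` — regression: heavy-atom count plus
    Gaussian noise of standard deviation ``noise_rate``.
    """
    rng = np.random.default_rng(seed)
    if label_rule == "nitro":
        n_pos = n // 2
        negatives = gen_molecules(n - n_pos, seed=int(rng.integers(2**31)),
                                  allow_nitro=False)
        positives: list[str] = []
        seen = set(negatives)
        attempts = 0
        with BlockLogs():
            patt = Chem.MolFromSmarts(_NITRO_SMARTS)
            while len(positives) < n_pos:
                attempts += 1
                if attempts > 500 * n_pos:
                    raise RuntimeError("could not generate enough nitro molecules")
                base = _random_chain(rng, 1, 6)
                if rng.random() < 0.4:
                    base += rng.choice(["c1ccccc1", "C1CCCCC1"])
                raw = base + "[N+](=O)[O-]"
                try:
                    canon = sanitize_and_canonicalize(raw)
                except SmilesRejection:
                    continue
                mol = Chem.MolFromSmiles(canon)
                if canon in seen or not mol.HasSubstructMatch(patt):
                    continue
                seen.add(canon)
                positives.append(canon)
        smiles = negatives + positives
        truth = {s: 0.0 for s in negatives}
        truth.update({s: 1.0 for s in positives})
        labels = [truth[s] for s in smiles]
        if noise_rate > 0:
            flips = rng.random(len(labels)) < noise_rate
            labels = [1.0 - y if f else y for y, f in zip(labels, flips)]
    elif label_rule == "heavy_atoms":
        smiles = gen_molecules(n, seed=int(rng.integers(2**31)))
        truth = {}
        with BlockLogs():
            for s in smiles:
                truth[s] = float(Chem.MolFromSmiles(s).GetNumHeavyAtoms())
        labels = [truth[s] + (rng.normal(0.0, noise_rate) if noise_rate > 0 else 0.0)
                  for s in smiles]
    else:
        raise ValueError(f"unknown label rule {label_rule!r}")

    order = rng.permutation(len(smiles))
    frame = pd.DataFrame({
        "smiles": [smiles[i] for i in order],
        "label": [labels[i] for i in order],
    })
    return LabeledDataset(frame=frame, rule=label_rule,
                          noise_rate=noise_rate, truth=truth)
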