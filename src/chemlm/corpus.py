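"""SMILES corpus curation for pre-training.

Pipeline: sanitize and canonicalize every record (RDKit), pool records
across sources, run a duplicate-frequency analysis, keep one copy of every
unique molecule, and re-emit the most frequently duplicated molecules
count-proportionally in canonical and randomized (graph-traversal
permuted) forms.  Over-length sequences are dropped and the output is
shuffled with a seeded chunked merge so the result is byte-reproducible.

Molecules are also harvested from reaction strings
(``reactants>agents>products``) so that reaction corpora contribute their
component molecules to the frequency analysis.
"""

from __future__ import annotations

import json
import math
import zlib
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.rdBase import BlockLogs

from .tokenizer import UnigramTokenizer, regex_tokenize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "RejectionReason", "SmilesRejection", "SmilesRecord", "CurationConfig",
    "sanitize_and_canonicalize", "extract_molecules_from_reaction",
    "frequency_analysis", "select_top_fraction", "augment",
    "build_pretraining_corpus", "functional_group_profile",
    "chunked_shuffle", "DEFAULT_GROUP_CATALOG",
]


class RejectionReason(str, Enum):
    PARSE_ERROR = "parse_error"
    SANITIZATION_ERROR = "sanitization_error"
    EMPTY = "empty"


class SmilesRejection(ValueError):
    """Invalid chemistry: parse failure, valence violation, empty record."""

    def __init__(self, smiles: str, reason: RejectionReason, detail: str = ""):
        self.smiles = smiles
        self.reason = reason
        self.detail = detail
        super().__init__(f"{reason.value}: {smiles!r}" + (f" ({detail})" if detail else ""))


@dataclass
class SmilesRecord:
    """One molecule: raw string, canonical fixed point, origin, multiplicity."""

    raw: str
    canonical: str
    source: str = ""
    count: int = 1


@dataclass
class CurationConfig:
    top_fraction: float = 0.2          # fraction of the duplicated set to augment
    max_token_length: int = 512        # sequence-length filter
    augment_ratio: float = 1.0         # emitted copies per duplicate count
    shuffle_seed: int = 0
    chunk_size: int = 100_000          # chunked-shuffle working-set bound

    def __post_init__(self):
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.max_token_length < 3:
            raise ValueError("max_token_length must be >= 3")
        if self.augment_ratio < 0:
            raise ValueError("augment_ratio must be >= 0")
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")


def sanitize_and_canonicalize(smiles: str, keep_largest_fragment: bool = True) -> str:
    """Canonical SMILES of a sanitized molecule, or raise :class:`SmilesRejection`.

    Salt/fragment handling: by default only the largest fragment (most heavy
    atoms; ties broken by canonical string) is kept and explicit hydrogens
    are stripped.  Idempotent: the output canonicalizes to itself.
    """
    if not smiles or not smiles.strip():
        raise SmilesRejection(smiles, RejectionReason.EMPTY)
    smiles = smiles.strip()
    with BlockLogs():
        mol = Chem.MolFromSmiles(smiles, sanitize=False)
        if mol is None:
            raise SmilesRejection(smiles, RejectionReason.PARSE_ERROR)
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:  # valence, kekulization, aromaticity errors
            raise SmilesRejection(
                smiles, RejectionReason.SANITIZATION_ERROR, str(exc)) from exc
        mol = Chem.RemoveHs(mol)
        if keep_largest_fragment:
            frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
            if len(frags) > 1:
                mol = max(frags, key=lambda f: (f.GetNumHeavyAtoms(),
                                                Chem.MolToSmiles(f)))
        return Chem.MolToSmiles(mol)


def extract_molecules_from_reaction(rxn: str) -> list[str]:
    """All dot-separated components of a reaction string, in field order.

    Duplicates are preserved: downstream frequency analysis counts how often
    each molecule participates in reactions.
    """
    fields = rxn.strip().split(">")
    if len(fields) != 3:
        raise ValueError(
            f"malformed reaction (need exactly two '>'): {rxn!r}")
    out: list[str] = []
    for f in fields:
        out.extend(part for part in f.split(".") if part)
    return out


def frequency_analysis(records) -> dict[str, int]:
    """Duplicate counts keyed by canonical SMILES.

    Accepts :class:`SmilesRecord` items or plain canonical strings; counts
    sum to the number of input records.
    """
    counts: Counter = Counter()
    for rec in records:
        if isinstance(rec, SmilesRecord):
            counts[rec.canonical] += rec.count
        else:
            counts[rec] += 1
    return dict(counts)


def select_top_fraction(freq: dict[str, int], fraction: float) -> set[str]:
    """The top ``fraction`` of *duplicated* molecules by count.

    Only molecules with count > 1 participate; ``ceil(fraction * n_dup)``
    are selected, ordered by (count desc, canonical asc) so the boundary
    tie-break is deterministic.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    duplicated = [(c, k) for k, c in freq.items() if c > 1]
    if not duplicated:
        return set()
    duplicated.sort(key=lambda kv: (-kv[0], kv[1]))
    k = math.ceil(fraction * len(duplicated))
    return {k_ for _, k_ in duplicated[:k]}


def augment(canonical: str, n: int, seed: int) -> list[str]:
    """``n`` randomized SMILES of the molecule (graph-traversal permutations).

    Every returned string canonicalizes back to ``canonical``; molecules
    admitting no distinct traversal (e.g. single atoms) yield repeats.
    Reproducible under ``seed``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    with BlockLogs():
        mol = Chem.MolFromSmiles(canonical)
        if mol is None:
            raise SmilesRejection(canonical, RejectionReason.PARSE_ERROR)
        return list(Chem.MolToRandomSmilesVect(mol, n, randomSeed=int(seed) & 0x7FFFFFFF))


def chunked_shuffle(lines: list[str], seed: int, chunk_size: int) -> list[str]:
    """Seeded bounded-memory shuffle: shuffle fixed-size chunks, then merge
    by drawing from chunk queues with probability proportional to their
    remaining size.  Linear time; exact Fisher-Yates when everything fits in
    one chunk."""
    rng = np.random.default_rng(seed)
    chunks = []
    for lo in range(0, len(lines), chunk_size):
        chunk = list(lines[lo:lo + chunk_size])
        rng.shuffle(chunk)
        chunks.append(chunk)
    if len(chunks) <= 1:
        return chunks[0] if chunks else []
    out: list[str] = []
    remaining = np.array([len(c) for c in chunks], dtype=float)
    positions = [0] * len(chunks)
    while remaining.sum() > 0:
        probs = remaining / remaining.sum()
        i = int(rng.choice(len(chunks), p=probs))
        out.append(chunks[i][positions[i]])
        positions[i] += 1
        remaining[i] -= 1
    return out


def _mol_seed(base_seed: int, canonical: str) -> int:
    """Stable per-molecule augmentation seed below 2**31."""
    return (int(base_seed) ^ zlib.crc32(canonical.encode())) & 0x7FFFFFFF


def _token_length(smiles: str, tokenizer: UnigramTokenizer | None) -> int:
    if tokenizer is not None:
        return tokenizer.n_content_tokens(smiles)
    try:
        return len(regex_tokenize(smiles))
    except ValueError:
        # characters outside the atom-level pattern: fall back to characters
        return len(smiles)


def build_pretraining_corpus(sources: dict[str, list[str]],
                             config: CurationConfig,
                             out_path,
                             tokenizer: UnigramTokenizer | None = None,
                             manifest_path=None) -> dict:
    """Curate raw per-source SMILES streams into a shuffled corpus file.

    Every unique canonical molecule appears exactly once, except members of
    the top-``top_fraction`` duplicated set, which appear
    ``ceil(count * augment_ratio)`` times, split evenly between canonical
    and randomized forms.  Sequences longer than ``max_token_length``
    content tokens (measured with the trained unigram tokenizer when given,
    else with the regex baseline) are removed.  Returns the manifest, which
    is also written next to the corpus when ``manifest_path`` is given.
    """
    per_source: dict[str, dict] = {}
    records: list[SmilesRecord] = []
    first_source: dict[str, str] = {}
    for name, stream in sources.items():
        stats = {"input": 0, "rejected": 0, "retained": 0,
                 "rejection_reasons": Counter()}
        for raw in stream:
            raw = raw.rstrip("\n")
            stats["input"] += 1
            try:
                canonical = sanitize_and_canonicalize(raw)
            except SmilesRejection as rej:
                stats["rejected"] += 1
                stats["rejection_reasons"][rej.reason.value] += 1
                continue
            stats["retained"] += 1
            records.append(SmilesRecord(raw=raw, canonical=canonical, source=name))
            first_source.setdefault(canonical, name)
        stats["rejection_reasons"] = dict(stats["rejection_reasons"])
        per_source[name] = stats

    freq = frequency_analysis(records)
    if not freq:
        raise ValueError("zero retained records: nothing to write")
    top = select_top_fraction(freq, config.top_fraction)

    lines: list[str] = []
    n_augmented = 0
    n_length_filtered = 0
    for canonical in sorted(freq):
        if canonical in top:
            m = math.ceil(freq[canonical] * config.augment_ratio)
            m = max(m, 1)
            n_canon = math.ceil(m / 2)
            n_rand = m - n_canon
            emitted = [canonical] * n_canon
            if n_rand > 0:
                emitted += augment(canonical, n_rand,
                                   _mol_seed(config.shuffle_seed, canonical))
                n_augmented += n_rand
        else:
            emitted = [canonical]
        for s in emitted:
            if _token_length(s, tokenizer) > config.max_token_length:
                n_length_filtered += 1
            else:
                lines.append(s)

    if not lines:
        raise ValueError("zero retained records after length filtering")
    lines = chunked_shuffle(lines, config.shuffle_seed, config.chunk_size)

    with open(out_path, "w") as fh:
        for s in lines:
            fh.write(s + "\n")

    manifest = {
        "per_source": per_source,
        "n_unique": len(freq),
        "n_duplicated": sum(1 for c in freq.values() if c > 1),
        "top_set_size": len(top),
        "n_augmented_emitted": n_augmented,
        "n_length_filtered": n_length_filtered,
        "n_lines": len(lines),
        "config": {
            "top_fraction": config.top_fraction,
            "max_token_length": config.max_token_length,
            "augment_ratio": config.augment_ratio,
            "shuffle_seed": config.shuffle_seed,
            "chunk_size": config.chunk_size,
        },
    }
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)
    return manifest


# A compact catalog of named functional-group SMARTS patterns.  Kept small
# and version-independent on purpose; callers may pass their own catalog.
DEFAULT_GROUP_CATALOG: dict[str, str] = {
    "hydroxyl": "[OX2H]",
    "carboxylic_acid": "[CX3](=O)[OX2H1]",
    "ester": "[CX3](=O)[OX2H0][#6]",
    "amide": "[CX3](=O)[NX3]",
    "primary_amine": "[NX3;H2;!$(NC=O)]",
    "nitro": "[NX3+](=O)[O-]",
    "nitrile": "[CX2]#[NX1]",
    "ketone": "[#6][CX3](=O)[#6]",
    "aldehyde": "[CX3H1]=O",
    "ether": "[OD2]([#6])[#6]",
    "halogen": "[F,Cl,Br,I]",
    "thiol": "[SX2H]",
    "alkene": "[CX3]=[CX3]",
    "alkyne": "[CX2]#[CX2]",
    "aromatic_ring": "[a]",
}


@dataclass
class GroupProfile:
    """Per-group molecule counts plus the number of unparseable inputs."""

    counts: dict[str, int] = field(default_factory=dict)
    n_invalid: int = 0


def functional_group_profile(sample: list[str],
                             catalog: dict[str, str] | None = None) -> GroupProfile:
    """Count how many molecules in ``sample`` match each catalog pattern.

    A molecule may count toward several groups; invalid SMILES are skipped
    and tallied in ``n_invalid``.
    """
    if catalog is None:
        catalog = DEFAULT_GROUP_CATALOG
    patterns = {}
    for name, smarts in catalog.items():
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS for group {name!r}: {smarts!r}")
        patterns[name] = patt
    profile = GroupProfile(counts={name: 0 for name in catalog})
    with BlockLogs():
        for smi in sample:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                profile.n_invalid += 1
                continue
            for name, patt in patterns.items():
                if mol.HasSubstructMatch(patt):
                    profile.counts[name] += 1
    return profile
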