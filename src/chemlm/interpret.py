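"""Attention attribution: which tokens functional groups occupy, and how
much attention those tokens receive.

The pipeline: extract the full (layer, head, from, to) attention tensor
for a molecule; map each functional-group substructure match to the
character spans of its atoms (atom tokens in a SMILES string appear in
RDKit atom-index order) and thence to the subword tokens overlapping those
spans; and summarize the attention a token set *receives* as the mean over
layers and heads of its column-sum share.  A Mann–Whitney U test compares
attention-proportion samples between groups of molecules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.rdBase import BlockLogs
from scipy.stats import mannwhitneyu

from .corpus import DEFAULT_GROUP_CATALOG
from .model import TransformerEncoder
from .tokenizer import (DEFAULT_SMILES_REGEX, TokenSequence, UnigramTokenizer,
                        regex_tokenize)

__all__ = [
    "AttentionMap", "GroupAttribution", "extract_attention",
    "match_groups_to_tokens", "attention_proportion", "mann_whitney_u",
    "attribute_molecule", "attribution_report",
]

# regex alternatives that denote atoms (vs bonds/branches/ring closures)
_ATOM_TOKEN = re.compile(r"\[[^\]]+\]|Br|Cl|[BCNOSPFIbcnosp]")


@dataclass
class GroupAttribution:
    """One functional group's token footprint and attention share."""

    group: str
    token_idx: set[int] = field(default_factory=set)
    attention_proportion: float = 0.0


@dataclass
class AttentionMap:
    """(n_layers, n_heads, L, L) attention with token surfaces and offsets.

    Row ``[layer, head, i, :]`` is token i's attention distribution and
    sums to 1.  ``offsets`` are the content tokens' character spans;
    position 0 is [CLS] and position L-1 is [SEP].
    """

    tensor: np.ndarray
    tokens: list[str]
    offsets: list[tuple[int, int]]
    smiles: str
    truncated: bool = False

    @property
    def n_layers(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_heads(self) -> int:
        return self.tensor.shape[1]

    @property
    def length(self) -> int:
        return self.tensor.shape[2]


def extract_attention(encoder: TransformerEncoder, tokenizer: UnigramTokenizer,
                      smiles: str) -> AttentionMap:
    """Full attention tensor for one molecule (deterministic, eval mode)."""
    encoder.eval()
    seq: TokenSequence = tokenizer.encode(smiles)
    ids = np.asarray(seq.ids)[None, :]
    _, collected = encoder(ids, collect_attention=True)
    tensor = np.stack([layer[0] for layer in collected])  # (layers, heads, L, L)
    tokens = [tokenizer.id_to_token[i] for i in seq.ids]
    return AttentionMap(tensor=tensor, tokens=tokens, offsets=seq.offsets,
                        smiles=smiles, truncated=seq.truncated)


def match_groups_to_tokens(smiles: str, offsets: list[tuple[int, int]],
                           catalog: dict[str, str] | None = None
                           ) -> dict[str, set[int]]:
    """Map each matched catalog group to the token positions covering it.

    Atom indices from substructure matches are converted to character
    spans using the atom-level tokenization of the SMILES (the i-th atom
    token corresponds to RDKit atom i), then to the content tokens whose
    offsets overlap those spans.  Returned indices are sequence positions
    (content token j sits at position j + 1, after [CLS]).  Groups whose
    atoms fall outside the tokenized region (truncation) are skipped.
    """
    if catalog is None:
        catalog = DEFAULT_GROUP_CATALOG
    with BlockLogs():
        mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    # character span of each atom, in atom-index order
    atom_spans: list[tuple[int, int]] = []
    pos = 0
    for tok in regex_tokenize(smiles, DEFAULT_SMILES_REGEX):
        end = pos + len(tok)
        if _ATOM_TOKEN.fullmatch(tok):
            atom_spans.append((pos, end))
        pos = end
    if len(atom_spans) != mol.GetNumAtoms():
        raise ValueError(
            f"atom/token mismatch for {smiles!r}: {len(atom_spans)} atom "
            f"tokens vs {mol.GetNumAtoms()} atoms")
    out: dict[str, set[int]] = {}
    with BlockLogs():
        for name, smarts in catalog.items():
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"invalid SMARTS for group {name!r}")
            matches = mol.GetSubstructMatches(patt)
            if not matches:
                continue
            token_idx: set[int] = set()
            ok = True
            for match in matches:
                for atom in match:
                    lo, hi = atom_spans[atom]
                    covering = {j + 1 for j, (s, e) in enumerate(offsets)
                                if s < hi and e > lo}
                    if not covering:
                        ok = False  # atom beyond the truncated token range
                        break
                    token_idx |= covering
                if not ok:
                    break
            if ok and token_idx:
                out[name] = token_idx
    return out


def attention_proportion(amap: AttentionMap, token_idx, reduction: str = "mean",
                         direction: str = "received") -> float | np.ndarray:
    """Share of total attention the token set receives (or emits).

    Received attention of token t is its column sum; each (layer, head)
    map's rows are normalized, so total attention is L and the proportion
    of any index set lies in [0, 1].  ``reduction='mean'`` averages over
    all layers and heads; ``'none'`` returns the (layers, heads) matrix.
    """
    idx = sorted(set(int(i) for i in token_idx))
    if not idx:
        return 0.0 if reduction == "mean" else np.zeros(amap.tensor.shape[:2])
    L = amap.length
    if any(i < 0 or i >= L for i in idx):
        raise IndexError("token index out of range")
    axis = 2 if direction == "received" else 3
    sums = amap.tensor.sum(axis=axis)          # (layers, heads, L)
    per_lh = sums[:, :, idx].sum(axis=2) / L   # (layers, heads)
    if reduction == "mean":
        return float(per_lh.mean())
    if reduction == "none":
        return per_lh
    raise ValueError("reduction must be 'mean' or 'none'")


@dataclass
class MannWhitneyResult:
    U: float
    p: float
    method: str            # 'exact' or 'asymptotic'
    degenerate: bool = False


def mann_whitney_u(sample_a, sample_b) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test.

    Exact null distribution when both samples have at most 8 observations
    and no ties are present; normal approximation with tie correction
    otherwise.  Fully tied samples are degenerate: p = 1 with a flag.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(U=len(a) * len(b) / 2.0, p=1.0,
                                 method="degenerate", degenerate=True)
    has_ties = len(np.unique(pooled)) < len(pooled)
    if max(len(a), len(b)) <= 8 and not has_ties:
        res = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return MannWhitneyResult(U=float(res.statistic), p=float(res.pvalue),
                                 method="exact")
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                       use_continuity=True)
    return MannWhitneyResult(U=float(res.statistic), p=float(res.pvalue),
                             method="asymptotic")


def attribute_molecule(encoder: TransformerEncoder, tokenizer: UnigramTokenizer,
                       smiles: str, catalog: dict[str, str] | None = None
                       ) -> list[GroupAttribution]:
    """Per-group token sets and received-attention shares for one molecule."""
    amap = extract_attention(encoder, tokenizer, smiles)
    groups = match_groups_to_tokens(smiles, amap.offsets, catalog)
    return [GroupAttribution(group=name, token_idx=idx,
                             attention_proportion=attention_proportion(amap, idx))
            for name, idx in groups.items()]


def attribution_report(encoder: TransformerEncoder, tokenizer: UnigramTokenizer,
                       smiles_sample: list[str],
                       catalog: dict[str, str] | None = None) -> dict:
    """Per-group attention-proportion distributions over a molecule sample.

    For every molecule, each matched functional group contributes one
    attention-proportion observation; the report also carries the group
    frequency distribution and the U test between the proportions of each
    group and the pooled proportions of all other groups.
    """
    if catalog is None:
        catalog = DEFAULT_GROUP_CATALOG
    per_group: dict[str, list[float]] = {name: [] for name in catalog}
    skipped = 0
    for s in smiles_sample:
        try:
            attributions = attribute_molecule(encoder, tokenizer, s, catalog)
        except ValueError:
            skipped += 1
            continue
        for att in attributions:
            per_group[att.group].append(att.attention_proportion)
    report: dict = {"n_molecules": len(smiles_sample), "skipped": skipped,
                    "groups": {}}
    for name, props in per_group.items():
        if not props:
            continue
        others = [p for other, ps in per_group.items() if other != name
                  for p in ps]
        entry = {"n": len(props), "mean_proportion": float(np.mean(props)),
                 "proportions": [float(p) for p in props]}
        if others:
            res = mann_whitney_u(props, others)
            entry["U"] = res.U
            entry["p"] = res.p
        report["groups"][name] = entry
    return report
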