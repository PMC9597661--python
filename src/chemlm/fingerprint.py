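"""Fixed-length molecular fingerprints from encoder token embeddings.

Two pooling modes over the final hidden states: the mean of all token
embeddings (padding excluded; auxiliary [CLS]/[SEP] included by default,
excludable by flag) and the [CLS] row alone.  Fingerprints are stored
unnormalized; cosine similarity normalizes internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.rdBase import BlockLogs

from .model import TransformerEncoder, collate
from .tokenizer import UnigramTokenizer, CLS_ID, SEP_ID

__all__ = [
    "Fingerprint", "FingerprintBatch", "pool_mean", "pool_cls",
    "cosine_similarity", "fingerprint_batch", "save_fingerprints",
]

POOLINGS = ("mean", "cls")


@dataclass
class Fingerprint:
    vector: np.ndarray
    pooling: str = "mean"
    model_id: str = ""

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.ndim != 1:
            raise ValueError("fingerprint vector must be 1-D")
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("fingerprint has non-finite entries")

    def __len__(self) -> int:
        return self.vector.shape[0]


def pool_mean(embeddings: np.ndarray, mask: np.ndarray | None = None,
              pooling_label: str = "mean") -> Fingerprint:
    """Arithmetic mean of the unmasked embedding rows.

    ``embeddings``: (L, hidden); ``mask``: length-L booleans, True = include
    (pass padding as False).  All-masked input is an error.
    """
    embeddings = np.asarray(embeddings, dtype=float)
    if embeddings.ndim != 2:
        raise ValueError("embeddings must be (L, hidden)")
    if mask is None:
        mask = np.ones(embeddings.shape[0], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("all positions masked: nothing to pool")
    return Fingerprint(embeddings[mask].mean(axis=0), pooling=pooling_label)


def pool_cls(embeddings: np.ndarray) -> Fingerprint:
    """Row 0 (the [CLS] position) as the aggregate embedding."""
    embeddings = np.asarray(embeddings, dtype=float)
    if embeddings.ndim != 2 or embeddings.shape[0] == 0:
        raise ValueError("embeddings must be a non-empty (L, hidden) matrix")
    return Fingerprint(embeddings[0].copy(), pooling="cls")


def cosine_similarity(a, b) -> float:
    va = a.vector if isinstance(a, Fingerprint) else np.asarray(a, dtype=float)
    vb = b.vector if isinstance(b, Fingerprint) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError("fingerprint lengths differ")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero-norm fingerprint")
    return float(va @ vb / (na * nb))


@dataclass
class FingerprintBatch:
    """Row i is the fingerprint of smiles[i]; invalid rows are flagged."""

    matrix: np.ndarray
    smiles: list[str]
    pooling: str
    invalid: list[int] = field(default_factory=list)  # flagged, not dropped

    @property
    def valid_mask(self) -> np.ndarray:
        m = np.ones(len(self.smiles), dtype=bool)
        m[self.invalid] = False
        return m


def fingerprint_batch(encoder: TransformerEncoder, tokenizer: UnigramTokenizer,
                      smiles: list[str], pooling: str = "mean",
                      include_special: bool = True, batch_size: int = 64,
                      validate: bool = True) -> FingerprintBatch:
    """Fingerprints for a list of SMILES (deterministic: encoder in eval mode).

    Rows for RDKit-unparseable inputs are NaN and recorded in ``invalid``
    rather than silently dropped.  ``include_special=False`` restricts the
    mean to content tokens.
    """
    if pooling not in POOLINGS:
        raise ValueError(f"pooling must be one of {POOLINGS}")
    encoder.eval()
    H = encoder.config.hidden
    out = np.full((len(smiles), H), np.nan)
    invalid: list[int] = []
    if validate:
        with BlockLogs():
            for i, s in enumerate(smiles):
                if Chem.MolFromSmiles(s) is None:
                    invalid.append(i)
    todo = [i for i in range(len(smiles)) if i not in set(invalid)]
    for lo in range(0, len(todo), batch_size):
        idx = todo[lo:lo + batch_size]
        seqs = [tokenizer.encode(smiles[i]).ids for i in idx]
        ids, pad = collate(seqs)
        hidden, _ = encoder(ids, pad)
        emb = hidden.data
        for row, i in enumerate(idx):
            if pooling == "cls":
                out[i] = pool_cls(emb[row]).vector
            else:
                mask = pad[row].copy()
                if not include_special:
                    mask &= ~np.isin(ids[row], (CLS_ID, SEP_ID))
                out[i] = pool_mean(emb[row], mask).vector
    return FingerprintBatch(matrix=out, smiles=list(smiles), pooling=pooling,
                            invalid=invalid)


def save_fingerprints(batch: FingerprintBatch, csv_path, sidecar_path=None,
                      model_id: str = "") -> None:
    """CSV matrix plus a JSON sidecar recording provenance and row order."""
    np.savetxt(csv_path, batch.matrix, delimiter=",")
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump({"model_id": model_id, "pooling": batch.pooling,
                       "smiles": batch.smiles, "invalid_rows": batch.invalid},
                      fh, indent=2)
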