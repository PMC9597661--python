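"""Fine-tuning the encoder for labeled tasks.

Three strategies:

* **single** — dropout-regularized mean-pooled embedding through a
  one-layer feed-forward head (sigmoid + binary cross-entropy for
  classification, identity + MSE for regression);
* **Siamese classification** — each molecule is paired with a seeded
  random SMILES permutation of itself; both strings pass through the
  *same* encoder (shared weights by identity) and the head consumes
  ``[fp1 | fp2 | |fp2 - fp1|]``;
* **Siamese latent training** — unlabeled: pulls the cosine similarity of
  canonical/permuted fingerprint pairs toward 1 with an MSE objective.

Classical heads (SVM / random forest / feed-forward network from
scikit-learn) evaluate frozen fingerprint matrices for comparison.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds.MurckoScaffold import MurckoScaffoldSmiles
from rdkit.rdBase import BlockLogs

from . import nn
from .nn import Tensor
from .corpus import augment, SmilesRejection
from .fingerprint import cosine_similarity, fingerprint_batch
from .model import TransformerEncoder, collate
from .tokenizer import UnigramTokenizer

__all__ = [
    "FineTuneConfig", "FineTuned", "finetune_single", "strip_head",
    "siamese_features", "siamese_classify", "siamese_latent_loss",
    "siamese_latent_train", "classical_head_eval", "split_dataset",
]


@dataclass
class FineTuneConfig:
    dropout: float = 0.2
    epochs: int = 10
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)  # train/valid/test
    loss: str = "bce"                    # 'bce' (classification) or 'mse'
    seed: int = 0
    split_strategy: str = "random"       # 'random' or 'scaffold'
    lr: float = 1e-3
    batch_size: int = 32
    freeze_encoder: bool = False

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.loss not in ("bce", "mse"):
            raise ValueError("loss must be 'bce' or 'mse'")
        if self.split_strategy not in ("random", "scaffold"):
            raise ValueError("split_strategy must be 'random' or 'scaffold'")


def _as_frame(dataset) -> pd.DataFrame:
    frame = dataset.frame if hasattr(dataset, "frame") else dataset
    if not {"smiles", "label"}.issubset(frame.columns):
        raise ValueError("dataset needs 'smiles' and 'label' columns")
    return frame.reset_index(drop=True)


def split_dataset(frame: pd.DataFrame, cfg: FineTuneConfig):
    """Seeded train/valid/test split, random or Murcko-scaffold grouped.

    Scaffold splitting groups molecules by Bemis–Murcko scaffold and packs
    whole groups, largest first, into train then valid then test, so the
    test set holds unseen chemotypes.
    """
    n = len(frame)
    n_train = int(round(cfg.split[0] * n))
    n_valid = int(round(cfg.split[1] * n))
    if cfg.split_strategy == "random":
        order = np.random.default_rng(cfg.seed).permutation(n)
    else:
        groups: dict[str, list[int]] = {}
        with BlockLogs():
            for i, s in enumerate(frame["smiles"]):
                try:
                    scaf = MurckoScaffoldSmiles(smiles=s)
                except Exception:
                    scaf = s
                groups.setdefault(scaf, []).append(i)
        order = []
        for _, idx in sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0])):
            order.extend(idx)
        order = np.asarray(order)
    return (frame.iloc[order[:n_train]],
            frame.iloc[order[n_train:n_train + n_valid]],
            frame.iloc[order[n_train + n_valid:]])


def _pool_mean_tensor(hidden: Tensor, pad_mask: np.ndarray) -> Tensor:
    """Differentiable mean over unpadded positions: (B,L,H) -> (B,H)."""
    w = pad_mask.astype(float)
    counts = w.sum(axis=1, keepdims=True)
    return (hidden * Tensor(w[:, :, None])).sum(axis=1) / Tensor(counts)


def _bce_loss(logits: Tensor, y: np.ndarray) -> Tensor:
    p = nn.sigmoid(logits)
    yt = Tensor(y)
    eps = 1e-12
    return -((yt * (p + eps).log()) + (1.0 - yt) * (1.0 - p + eps).log()).mean()


def _mse_loss(pred: Tensor, y: np.ndarray) -> Tensor:
    return ((pred - Tensor(y)) ** 2).mean()


@dataclass
class FineTuned:
    """Fine-tuned bundle: encoder + head + per-epoch metric trace."""

    encoder: TransformerEncoder
    head: nn.Linear
    tokenizer: UnigramTokenizer
    cfg: FineTuneConfig
    mode: str                                   # 'single' or 'siamese'
    metrics: list[dict] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    def predict(self, smiles: list[str]) -> np.ndarray:
        """Scores (sigmoid probabilities for 'bce', raw values for 'mse')."""
        self.encoder.eval()
        out = []
        for lo in range(0, len(smiles), self.cfg.batch_size):
            chunk = smiles[lo:lo + self.cfg.batch_size]
            feats = self._features(chunk, training=False)
            z = self.head(feats)
            v = nn.sigmoid(z).data if self.cfg.loss == "bce" else z.data
            out.append(v[:, 0] if v.ndim == 2 and v.shape[1] == 1 else v)
        return np.concatenate(out)

    def _features(self, smiles: list[str], training: bool) -> Tensor:
        seqs = [self.tokenizer.encode(s).ids for s in smiles]
        ids, pad = collate(seqs)
        hidden, _ = self.encoder(ids, pad)
        pooled = _pool_mean_tensor(hidden, pad)
        if self.mode == "siamese":
            seqs2 = [self.tokenizer.encode(s).ids for s in
                     self._augmented(smiles)]
            ids2, pad2 = collate(seqs2)
            hidden2, _ = self.encoder(ids2, pad2)  # same weights: shared
            pooled2 = _pool_mean_tensor(hidden2, pad2)
            pooled = siamese_features_tensor(pooled, pooled2)
        return pooled

    def _augmented(self, smiles: list[str]) -> list[str]:
        out = []
        for s in smiles:
            try:
                out.append(augment(s, 1, seed=_pair_seed(self.cfg.seed, s))[0])
            except SmilesRejection:
                out.append(s)
        return out


def _pair_seed(seed: int, smiles: str) -> int:
    import zlib
    return (int(seed) ^ zlib.crc32(smiles.encode())) & 0x7FFFFFFF


def _eval_metric(bundle: FineTuned, frame: pd.DataFrame) -> float:
    """Held-out accuracy at 0.5 (bce) or RMSE (mse)."""
    if len(frame) == 0:
        return float("nan")
    pred = bundle.predict(list(frame["smiles"]))
    y = frame["label"].to_numpy(dtype=float)
    if bundle.cfg.loss == "bce":
        return float(((pred >= 0.5) == (y >= 0.5)).mean())
    return float(np.sqrt(np.mean((pred - y) ** 2)))


def _finetune(encoder: TransformerEncoder, tokenizer: UnigramTokenizer,
              dataset, cfg: FineTuneConfig, mode: str) -> FineTuned:
    frame = _as_frame(dataset)
    train, valid, test = split_dataset(frame, cfg)
    y_train = train["label"].to_numpy(dtype=float)
    if cfg.loss == "bce" and len(np.unique(y_train >= 0.5)) < 2:
        raise ValueError("single-class training set: cannot fit a classifier")

    # clone so the caller's (possibly shared) encoder is untouched
    tuned = TransformerEncoder(copy.deepcopy(encoder.config))
    tuned.load_state_dict(encoder.state_dict())
    tuned.reseed(cfg.seed + 17)

    n_labels = 1
    in_dim = tuned.config.hidden * (3 if mode == "siamese" else 1)
    head = nn.Linear(in_dim, n_labels, np.random.default_rng(cfg.seed + 3))
    bundle = FineTuned(encoder=tuned, head=head, tokenizer=tokenizer,
                       cfg=cfg, mode=mode)

    # drop unparseable SMILES (logged), keep everything else
    with BlockLogs():
        ok = [i for i, s in enumerate(train["smiles"])
              if Chem.MolFromSmiles(s) is not None]
    bundle.skipped = [s for i, s in enumerate(train["smiles"]) if i not in set(ok)]
    train = train.iloc[ok]
    y_train = train["label"].to_numpy(dtype=float)

    params = head.parameters() if cfg.freeze_encoder else (
        tuned.parameters() + head.parameters())
    opt = nn.AdamW(params, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 5)
    drop_rng = np.random.default_rng(cfg.seed + 7)
    smiles_train = list(train["smiles"])
    for epoch in range(cfg.epochs):
        tuned.train()
        order = rng.permutation(len(smiles_train))
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            batch = [smiles_train[i] for i in idx]
            feats = bundle._features(batch, training=True)
            if cfg.freeze_encoder:
                feats = feats.detach()
            feats = nn.dropout(feats, cfg.dropout, drop_rng, True)
            z = head(feats)
            y = y_train[idx][:, None]
            loss = _bce_loss(z, y) if cfg.loss == "bce" else _mse_loss(z, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        tuned.eval()
        bundle.metrics.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)) if losses else float("nan"),
            "valid_metric": _eval_metric(bundle, valid),
        })
    bundle.metrics.append({"epoch": "test", "test_metric": _eval_metric(bundle, test)})
    tuned.eval()
    return bundle


def finetune_single(encoder: TransformerEncoder, tokenizer: UnigramTokenizer,
                    dataset, cfg: FineTuneConfig | None = None) -> FineTuned:
    """Single-branch fine-tuning on a (smiles, label) dataset."""
    return _finetune(encoder, tokenizer, dataset, cfg or FineTuneConfig(), "single")


def siamese_classify(encoder: TransformerEncoder, tokenizer: UnigramTokenizer,
                     dataset, cfg: FineTuneConfig | None = None) -> FineTuned:
    """Siamese fine-tuning: the second branch sees a seeded random SMILES
    permutation of each molecule; branch weights are shared by identity."""
    return _finetune(encoder, tokenizer, dataset, cfg or FineTuneConfig(), "siamese")


def strip_head(finetuned) -> TransformerEncoder:
    """Discard the head, exposing the specialized-fingerprint encoder.

    Idempotent: accepts either a fine-tuned bundle or a bare encoder.
    """
    if isinstance(finetuned, TransformerEncoder):
        return finetuned
    return finetuned.encoder


def siamese_features(fp1, fp2) -> np.ndarray:
    """``[fp1 | fp2 | |fp2 - fp1|]`` feature vector for paired inputs."""
    v1 = fp1.vector if hasattr(fp1, "vector") else np.asarray(fp1, dtype=float)
    v2 = fp2.vector if hasattr(fp2, "vector") else np.asarray(fp2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("fingerprint lengths differ")
    return np.concatenate([v1, v2, np.abs(v2 - v1)])


def siamese_features_tensor(fp1: Tensor, fp2: Tensor) -> Tensor:
    return nn.concat([fp1, fp2, (fp2 - fp1).abs()], axis=-1)


def siamese_latent_loss(fp1, fp2) -> float:
    """``(cosine(fp1, fp2) - 1)^2`` — MSE to a target similarity of 1."""
    return float((cosine_similarity(fp1, fp2) - 1.0) ** 2)


def _cosine_rows(a: Tensor, b: Tensor) -> Tensor:
    dot = (a * b).sum(axis=-1)
    na = ((a * a).sum(axis=-1) + 1e-12).sqrt()
    nb = ((b * b).sum(axis=-1) + 1e-12).sqrt()
    return dot / (na * nb)


def siamese_latent_train(encoder: TransformerEncoder, tokenizer: UnigramTokenizer,
                         smiles: list[str], cfg: FineTuneConfig | None = None,
                         holdout_fraction: float = 0.2) -> tuple[TransformerEncoder, dict]:
    """Pull canonical/permuted fingerprint pairs toward cosine similarity 1.

    Returns the trained encoder (the input encoder is not modified) and a
    report with held-out mean pair cosine before and after training.
    """
    cfg = cfg or FineTuneConfig(epochs=2)
    rng = np.random.default_rng(cfg.seed)
    smiles = [s for s in smiles if s.strip()]
    pairs = []
    for s in smiles:
        try:
            pairs.append((s, augment(s, 1, seed=_pair_seed(cfg.seed, s))[0]))
        except SmilesRejection:
            continue
    if len(pairs) < 2:
        raise ValueError("not enough valid molecules for latent training")
    order = rng.permutation(len(pairs))
    n_hold = max(1, int(holdout_fraction * len(pairs)))
    hold = [pairs[i] for i in order[:n_hold]]
    train = [pairs[i] for i in order[n_hold:]]

    tuned = TransformerEncoder(copy.deepcopy(encoder.config))
    tuned.load_state_dict(encoder.state_dict())
    tuned.reseed(cfg.seed + 23)

    def mean_holdout_cos(enc: TransformerEncoder) -> float:
        a = fingerprint_batch(enc, tokenizer, [p[0] for p in hold], validate=False)
        b = fingerprint_batch(enc, tokenizer, [p[1] for p in hold], validate=False)
        return float(np.mean([cosine_similarity(a.matrix[i], b.matrix[i])
                              for i in range(len(hold))]))

    before = mean_holdout_cos(tuned)
    opt = nn.AdamW(tuned.parameters(), lr=cfg.lr)
    trace = []
    for epoch in range(cfg.epochs):
        tuned.train()
        rng.shuffle(train)
        losses = []
        for lo in range(0, len(train), cfg.batch_size):
            batch = train[lo:lo + cfg.batch_size]
            ids1, pad1 = collate([tokenizer.encode(a).ids for a, _ in batch])
            ids2, pad2 = collate([tokenizer.encode(b).ids for _, b in batch])
            h1, _ = tuned(ids1, pad1)
            h2, _ = tuned(ids2, pad2)
            cos = _cosine_rows(_pool_mean_tensor(h1, pad1),
                               _pool_mean_tensor(h2, pad2))
            loss = ((cos - 1.0) ** 2).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        if losses and not np.isfinite(np.mean(losses)):
            raise FloatingPointError(f"latent training diverged at epoch {epoch}")
        trace.append(float(np.mean(losses)) if losses else float("nan"))
    tuned.eval()
    after = mean_holdout_cos(tuned)
    return tuned, {"holdout_cosine_before": before, "holdout_cosine_after": after,
                   "epoch_losses": trace, "n_train_pairs": len(train),
                   "n_holdout_pairs": len(hold)}


def classical_head_eval(fingerprints: np.ndarray, labels, head: str = "svm",
                        task: str = "clf", seed: int = 0,
                        test_fraction: float = 0.2) -> dict:
    """Fit an off-the-shelf head on a train split of frozen fingerprints.

    Reports AUCROC (classification) or RMSE (regression) on the held-out
    split.  ``head``: 'svm', 'rf' or 'ffnn'.
    """
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
    from sklearn.neural_network import MLPClassifier, MLPRegressor
    from sklearn.svm import SVC, SVR
    from sklearn.metrics import roc_auc_score

    X = np.asarray(fingerprints, dtype=float)
    y = np.asarray(labels, dtype=float)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    n_test = max(1, int(test_fraction * len(y)))
    test_idx, train_idx = order[:n_test], order[n_test:]
    if task == "clf":
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            raise ValueError("degenerate labels in train or test split")
        models = {
            "svm": SVC(random_state=seed),
            "rf": RandomForestClassifier(n_estimators=100, random_state=seed),
            "ffnn": MLPClassifier(hidden_layer_sizes=(64,), max_iter=500,
                                  random_state=seed),
        }
        clf = models[head]
        clf.fit(X[train_idx], y[train_idx])
        scores = (clf.decision_function(X[test_idx]) if head == "svm"
                  else clf.predict_proba(X[test_idx])[:, 1])
        return {"metric": "aucroc",
                "value": float(roc_auc_score(y[test_idx], scores))}
    elif task == "reg":
        if np.allclose(y[train_idx], y[train_idx][0]):
            raise ValueError("degenerate (constant) regression target")
        models = {
            "svm": SVR(),
            "rf": RandomForestRegressor(n_estimators=100, random_state=seed),
            "ffnn": MLPRegressor(hidden_layer_sizes=(64,), max_iter=500,
                                 random_state=seed),
        }
        reg = models[head]
        reg.fit(X[train_idx], y[train_idx])
        pred = reg.predict(X[test_idx])
        return {"metric": "rmse",
                "value": float(np.sqrt(np.mean((pred - y[test_idx]) ** 2)))}
    raise ValueError("task must be 'clf' or 'reg'")
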