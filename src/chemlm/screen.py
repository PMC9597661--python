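"""Virtual-screening evaluation: retrieval metrics and a benchmark harness.

A screening experiment ranks a library of actives + decoys by fused cosine
similarity to a handful of query actives and scores the ranking with
AUCROC (probability a random active outranks a random decoy) and BEDROC
(Boltzmann-enhanced discrimination of ROC: exponentially weighted early
recognition, min–max normalized to [0, 1]).  ``cluster_eval`` measures how
well a fingerprint matrix separates two labeled classes after PCA-2D +
K-means, the usual unsupervised quality check for learned fingerprints.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score, silhouette_score

from .fixtures import ScreeningTarget  # the target type consumed here

__all__ = [
    "ScreeningTarget", "ScreenMetrics", "rank_library", "auc_roc", "bedroc",
    "run_benchmark", "cluster_eval",
]


def rank_library(query_fps: np.ndarray, library_fps: np.ndarray,
                 fusion: str = "max") -> tuple[np.ndarray, np.ndarray]:
    """Rank library compounds by fused cosine similarity to the queries.

    ``fusion='max'`` scores each compound by its best query match (the
    convention of similarity-benchmark platforms); ``'mean'`` averages over
    queries.  Returns ``(order, scores)``: descending score order with ties
    broken by input index, and the per-compound fused scores in input order.
    """
    if fusion not in ("max", "mean"):
        raise ValueError("fusion must be 'max' or 'mean'")
    q = np.atleast_2d(np.asarray(query_fps, dtype=float))
    lib = np.atleast_2d(np.asarray(library_fps, dtype=float))
    if lib.shape[0] == 0:
        raise ValueError("empty library")
    qn = np.linalg.norm(q, axis=1, keepdims=True)
    ln = np.linalg.norm(lib, axis=1, keepdims=True)
    if np.any(qn == 0) or np.any(ln == 0):
        raise ValueError("zero-norm fingerprint")
    sims = (q / qn) @ (lib / ln).T            # (n_query, n_lib)
    scores = sims.max(axis=0) if fusion == "max" else sims.mean(axis=0)
    order = np.lexsort((np.arange(len(scores)), -scores))
    return order, scores


def auc_roc(scores, labels) -> float:
    """Probability a random active outranks a random decoy (ties count 1/2)."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def bedroc(scores, labels, alpha: float = 20.0) -> float:
    """Boltzmann-enhanced discrimination of ROC.

    With N compounds, n actives at 1-based ranks r_i (descending score,
    ties broken by input index) and Ra = n/N:

        RIE    = sum_i exp(-alpha * r_i / N)
                 / ( Ra * (1 - e^{-alpha}) / (e^{alpha/N} - 1) )
        BEDROC = RIE * Ra * sinh(alpha/2)
                 / ( cosh(alpha/2) - cosh(alpha/2 - alpha*Ra) )
                 + 1 / (1 - e^{alpha * (1 - Ra)})

    i.e. the exponentially weighted active-rank sum, min–max normalized so
    a perfect ranking scores 1 and a worst ranking approaches 0.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    N = len(scores)
    order = np.lexsort((np.arange(N), -scores))
    ranks = np.nonzero(np.asarray(labels)[order] == 1)[0] + 1  # 1-based
    n = len(ranks)
    ra = n / N
    s = float(np.exp(-alpha * ranks / N).sum())
    rie = s / (ra * (1.0 - math.exp(-alpha)) / (math.exp(alpha / N) - 1.0))
    bed = (rie * ra * math.sinh(alpha / 2.0)
           / (math.cosh(alpha / 2.0) - math.cosh(alpha / 2.0 - alpha * ra))
           + 1.0 / (1.0 - math.exp(alpha * (1.0 - ra))))
    return float(bed)


@dataclass
class ScreenMetrics:
    """Mean +/- std of both retrieval metrics over query resamplings."""

    name: str
    alpha: float
    repetitions: int
    aucroc_mean: float
    aucroc_std: float
    bedroc_mean: float
    bedroc_std: float
    aucroc_values: list[float] = field(default_factory=list)
    bedroc_values: list[float] = field(default_factory=list)


def run_benchmark(fingerprinter, targets: list[ScreeningTarget],
                  repetitions: int = 50, seed: int = 0, alpha: float = 20.0,
                  fusion: str = "max") -> tuple[list[ScreenMetrics], dict]:
    """Query-resampled retrieval benchmark over a list of targets.

    ``fingerprinter`` maps a SMILES list to an (n, hidden) matrix (see
    ``fingerprint.fingerprint_batch``).  Per repetition, ``n_queries``
    actives are drawn (seeded), the remaining actives + all decoys are
    ranked, and both metrics recorded.  Targets with too few actives are
    skipped with a warning entry in the aggregate.
    """
    rng = np.random.default_rng(seed)
    per_target: list[ScreenMetrics] = []
    skipped: list[str] = []
    for target in targets:
        if len(target.actives) < target.n_queries + 1:
            skipped.append(target.name)
            continue
        fp_act = np.asarray(fingerprinter(target.actives), dtype=float)
        fp_dec = np.asarray(fingerprinter(target.decoys), dtype=float)
        aucs, beds = [], []
        for _ in range(repetitions):
            q_idx = rng.choice(len(target.actives), size=target.n_queries,
                               replace=False)
            rest = np.setdiff1d(np.arange(len(target.actives)), q_idx)
            lib = np.vstack([fp_act[rest], fp_dec])
            labels = np.concatenate([np.ones(len(rest), dtype=int),
                                     np.zeros(len(fp_dec), dtype=int)])
            _, scores = rank_library(fp_act[q_idx], lib, fusion=fusion)
            aucs.append(auc_roc(scores, labels))
            beds.append(bedroc(scores, labels, alpha))
        per_target.append(ScreenMetrics(
            name=target.name, alpha=alpha, repetitions=repetitions,
            aucroc_mean=float(np.mean(aucs)), aucroc_std=float(np.std(aucs)),
            bedroc_mean=float(np.mean(beds)), bedroc_std=float(np.std(beds)),
            aucroc_values=[float(a) for a in aucs],
            bedroc_values=[float(b) for b in beds]))
    aggregate = {
        "aucroc": float(np.mean([m.aucroc_mean for m in per_target]))
        if per_target else float("nan"),
        "bedroc": float(np.mean([m.bedroc_mean for m in per_target]))
        if per_target else float("nan"),
        "n_targets": len(per_target),
        "skipped": skipped,
    }
    return per_target, aggregate


def cluster_eval(fingerprints: np.ndarray, labels, seed: int = 0,
                 silhouette_space: str = "pca2") -> dict:
    """Unsupervised class-separation score of a fingerprint matrix.

    PCA to 2 components, K-means with k = number of classes, clusters
    mapped to classes by the label permutation maximizing agreement;
    AUCROC is computed from the mapped hard assignments and the silhouette
    coefficient from the cluster assignments (in the 2-D projection by
    default; ``silhouette_space='full'`` uses the original space).
    """
    X = np.asarray(fingerprints, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if any((y == c).sum() < 2 for c in classes):
        raise ValueError("need >= 2 samples per class")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate fingerprints: all rows identical")
    proj = PCA(n_components=2, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=len(classes), n_init=10, random_state=seed)
    clusters = km.fit_predict(proj)
    # map cluster ids to class labels by best agreement
    best_map, best_hits = None, -1
    for perm in itertools.permutations(range(len(classes))):
        mapped = np.asarray([classes[perm[c]] for c in clusters])
        hits = int((mapped == y).sum())
        if hits > best_hits:
            best_hits, best_map = hits, mapped
    space = proj if silhouette_space == "pca2" else X
    return {
        "aucroc": auc_roc((best_map == classes.max()).astype(float),
                          (y == classes.max()).astype(int)),
        "silhouette": float(silhouette_score(space, clusters)),
        "accuracy": best_hits / len(y),
    }
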