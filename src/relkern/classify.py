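"""Kernel-SVM classification over precomputed Gram matrices, document-level
aggregation, evaluation metrics, and McNemar's paired significance test.

Both graph kernels are explicit inner products, so Gram matrices are computed
by featurizing every instance into one sparse vector (ASM: one coordinate per
ordered label pair and feature key; APG: one per label pair) and taking
``X @ X.T``. This is algebraically identical to pairwise kernel calls and is
verified against them in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.stats import chi2
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .apg import ApgConfig, apg_featurize
from .asm import pair_feature_maps
from .model import RelationInstance

__all__ = [
    "GramMatrix",
    "EvalResult",
    "McNemarResult",
    "KERNELS",
    "featurize",
    "gram",
    "cross_gram",
    "train",
    "predict",
    "aggregate_document",
    "evaluate",
    "auc",
    "mcnemar",
]


@dataclass
class GramMatrix:
    """Symmetric kernel matrix over an ordered instance list."""

    values: np.ndarray
    kernel: str
    normalized: bool


@dataclass
class EvalResult:
    """Precision/recall/F1 over relation pairs, with optional AUC."""

    tp: int
    fp: int
    fn: int
    tn: int = 0
    auc: float | None = None
    undefined: bool = False

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class McNemarResult:
    """Discordant counts and the p-value for "equally accurate" classifiers.

    ``b`` counts examples classifier A got right and B wrong; ``c`` the
    reverse. Below 25 discordant pairs the exact two-sided binomial p-value
    is used, above it the chi-square statistic with continuity correction
    (|b-c| - 1)^2 / (b + c).
    """

    b: int
    c: int
    statistic: float
    p_value: float
    exact: bool


# ---------------------------------------------------------------------------
# Sparse featurization and Gram matrices
# ---------------------------------------------------------------------------


def _asm_features(inst: RelationInstance, _cfg: ApgConfig | None) -> dict:
    out = {}
    for (li, lj), fm in pair_feature_maps(inst.graph).items():
        for key, val in fm.items():
            out[(li, lj, key)] = val
    return out


def _apg_features(inst: RelationInstance, cfg: ApgConfig | None) -> dict:
    conn = apg_featurize(inst, cfg)
    labs = conn.label_order
    out = {}
    nz = np.argwhere(np.abs(conn.Gm) > 0.0)
    for i, j in nz:
        out[(labs[i], labs[j])] = conn.Gm[i, j]
    return out


KERNELS = {"asm": _asm_features, "apg": _apg_features}


def featurize(
    instances: list[RelationInstance],
    kernel: str,
    config: ApgConfig | None = None,
    index: dict | None = None,
    grow_index: bool = True,
) -> tuple[sp.csr_matrix, dict]:
    """Explicit sparse feature matrix (instances x feature coordinates).

    ``index`` maps feature coordinates to columns and can be shared between
    train and test featurization; coordinates absent from a frozen index are
    dropped (they cannot contribute to a train-test inner product).
    """
    if kernel not in KERNELS:
        raise KeyError(f"unknown kernel {kernel!r}; available: {sorted(KERNELS)}")
    fn = KERNELS[kernel]
    index = {} if index is None else index
    rows, cols, vals = [], [], []
    for i, inst in enumerate(instances):
        for key, val in fn(inst, config).items():
            j = index.get(key)
            if j is None:
                if not grow_index:
                    continue
                j = index[key] = len(index)
            rows.append(i)
            cols.append(j)
            vals.append(val)
    X = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(instances), max(len(index), 1))
    )
    return X, index


def _normalize_rows(K: np.ndarray, d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    denom = np.sqrt(np.outer(d1, d2))
    out = np.zeros_like(K)
    np.divide(K, denom, out=out, where=denom > 0)
    return out


def gram(
    instances: list[RelationInstance],
    kernel: str = "asm",
    normalized: bool = True,
    config: ApgConfig | None = None,
) -> GramMatrix:
    """Pairwise kernel matrix over ``instances`` (symmetric by construction)."""
    X, _ = featurize(instances, kernel, config)
    K = np.asarray((X @ X.T).todense(), dtype=float)
    K = (K + K.T) / 2.0
    if normalized:
        K = _normalize_rows(K, np.diag(K), np.diag(K))
    return GramMatrix(values=K, kernel=kernel, normalized=normalized)


def cross_gram(
    test_instances: list[RelationInstance],
    train_instances: list[RelationInstance],
    kernel: str = "asm",
    normalized: bool = True,
    config: ApgConfig | None = None,
) -> np.ndarray:
    """Kernel values of every test instance against every training instance."""
    Xtr, index = featurize(train_instances, kernel, config)
    Xte, _ = featurize(test_instances, kernel, config, index=index, grow_index=False)
    K = np.asarray((Xte @ Xtr.T).todense(), dtype=float)
    if normalized:
        # Self-kernels need the full feature set, not the train-restricted one.
        Xte_full, _ = featurize(test_instances, kernel, config)
        d_te = np.asarray(Xte_full.multiply(Xte_full).sum(axis=1)).ravel()
        d_tr = np.asarray(Xtr.multiply(Xtr).sum(axis=1)).ravel()
        K = _normalize_rows(K, d_te, d_tr)
    return K


# ---------------------------------------------------------------------------
# SVM training and prediction
# ---------------------------------------------------------------------------


def _binary_labels(labels: list[str] | np.ndarray) -> np.ndarray:
    y = np.asarray([1 if lab in (1, "positive", True) else 0 for lab in labels])
    if len(set(y.tolist())) < 2:
        raise ValueError("training labels contain a single class")
    return y


def train(gram_matrix: GramMatrix, labels, C: float = 1.0) -> SVC:
    """Soft-margin SVM on a precomputed kernel (default C = 1, untuned)."""
    y = _binary_labels(labels)
    model = SVC(kernel="precomputed", C=C)
    model.fit(gram_matrix.values, y)
    return model


def predict(model: SVC, cross_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted 0/1 labels and real-valued decision scores for test rows."""
    return model.predict(cross_values), model.decision_function(cross_values)


# ---------------------------------------------------------------------------
# Document-level aggregation and evaluation
# ---------------------------------------------------------------------------


def aggregate_document(
    instances: list[RelationInstance],
    predictions: np.ndarray,
    scores: np.ndarray | None = None,
) -> tuple[set[tuple[str, str, str]], dict[tuple[str, str, str], float]]:
    """Existential aggregation to (document, C, D) triples.

    A concept pair is predicted positive iff any of its instances is; the
    sentence-level and cross subsystems are disjoint by construction, so this
    is their union. The returned score per triple is the max instance score
    (used for document-level AUC).
    """
    positives: set[tuple[str, str, str]] = set()
    best: dict[tuple[str, str, str], float] = {}
    for i, inst in enumerate(instances):
        key = (inst.provenance.doc_id, *inst.provenance.pair)
        if predictions[i]:
            positives.add(key)
        if scores is not None:
            best[key] = max(best.get(key, -math.inf), float(scores[i]))
    return positives, best


def evaluate(gold: set, predicted: set, n_candidates: int | None = None) -> EvalResult:
    """Precision/recall/F1 of predicted relation pairs against gold pairs."""
    tp = len(gold & predicted)
    fp = len(predicted - gold)
    fn = len(gold - predicted)
    tn = (n_candidates - tp - fp - fn) if n_candidates is not None else 0
    return EvalResult(tp=tp, fp=fp, fn=fn, tn=max(tn, 0),
                      undefined=not gold and not predicted)


def auc(scores, labels) -> float:
    """Area under the ROC curve (rank statistic; ties count one half)."""
    y = np.asarray([1 if lab in (1, "positive", True) else 0 for lab in labels])
    s = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("AUC needs both classes present")
    if np.all(s == s[0]):
        return 0.5
    return float(roc_auc_score(y, s))


def mcnemar(correct_a, correct_b) -> McNemarResult:
    """McNemar's test for the null that two classifiers are equally accurate.

    ``correct_a`` / ``correct_b`` are aligned per-example correctness flags.
    """
    a = np.asarray(correct_a, dtype=bool)
    bflags = np.asarray(correct_b, dtype=bool)
    if a.shape != bflags.shape:
        raise ValueError("correctness vectors must be aligned and equal length")
    b = int(np.sum(a & ~bflags))
    c = int(np.sum(~a & bflags))
    n = b + c
    if n == 0:
        return McNemarResult(b=b, c=c, statistic=0.0, p_value=1.0, exact=True)
    if n < 25:
        k = min(b, c)
        tail = sum(math.comb(n, i) for i in range(k + 1)) * 0.5**n
        return McNemarResult(
            b=b, c=c, statistic=float(k), p_value=min(1.0, 2.0 * tail), exact=True
        )
    stat = (abs(b - c) - 1) ** 2 / n
    return McNemarResult(
        b=b, c=c, statistic=stat, p_value=float(chi2.sf(stat, df=1)), exact=False
    )
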