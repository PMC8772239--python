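"""Evaluation harnesses for functional-similarity methods.

Three standard protocols: ROC/AUC separation of positive from negative
protein–protein interaction (PPI) gene pairs by similarity score, Pearson
correlation of similarity against an expression-derived co-expression
value per gene pair, and within- versus between-class similarity for
functionally classified gene sets (e.g. by EC number or pathway).

Pairs whose similarity is undefined (unannotated genes) are dropped with a
count — they are never silently scored 0 — and every result reports how
many pairs were used and dropped.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .similarity import SimilarityResult

__all__ = [
    "LabeledPairSet",
    "ExpressionPairTable",
    "EvalResult",
    "ClassificationSummary",
    "roc_auc",
    "pearson_eval",
    "classification_matrix",
    "sample_negative_pairs",
]


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class LabeledPairSet:
    """Unordered gene pairs with binary interaction labels (1 = positive)."""

    pairs: list[tuple[str, str, int]]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for a, b, label in self.pairs:
            if label not in (0, 1):
                raise ValueError(f"label must be 0 or 1, got {label!r} for ({a}, {b})")
            k = _key(a, b)
            if k in seen:
                raise ValueError(f"duplicate unordered pair {k}")
            seen.add(k)

    @classmethod
    def from_tsv(cls, path: str) -> "LabeledPairSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["gene_a", "gene_b", "label"])
        labels = df["label"].map({"positive": 1, "negative": 0, 1: 1, 0: 0, "1": 1, "0": 0})
        if labels.isna().any():
            bad = df.loc[labels.isna(), "label"].iloc[0]
            raise ValueError(f"unrecognized label {bad!r} in {path}")
        return cls(list(zip(df["gene_a"], df["gene_b"], labels.astype(int))), provenance=path)


@dataclass
class ExpressionPairTable:
    """Gene pairs with a real-valued expression-similarity value."""

    pairs: list[tuple[str, str, float]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for a, b, v in self.pairs:
            if not math.isfinite(v):
                raise ValueError(f"non-finite expression value for ({a}, {b})")

    @classmethod
    def from_tsv(cls, path: str) -> "ExpressionPairTable":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["gene_a", "gene_b", "value"])
        return cls(list(zip(df["gene_a"], df["gene_b"], df["value"].astype(float))),
                   provenance=path)


@dataclass
class EvalResult:
    """A scalar evaluation metric plus usage accounting."""

    metric: str
    value: float
    n_used: int
    n_dropped: int
    extra: dict = field(default_factory=dict)


def _lookup(scores, a: str, b: str) -> float:
    if isinstance(scores, SimilarityResult):
        try:
            return scores.score(a, b)
        except ValueError:
            return math.nan
    return float(scores.get(_key(a, b), math.nan))


def roc_auc(scores: SimilarityResult | dict, labels: LabeledPairSet) -> EvalResult:
    """AUC for separating positive from negative pairs by score.

    ``scores`` is a :class:`SimilarityResult` or a dict keyed by sorted
    gene-pair tuples.  Equivalent to the normalized Mann-Whitney U
    statistic, so ties contribute half (midrank handling).
    """
    y, s, dropped = [], [], 0
    for a, b, label in labels.pairs:
        v = _lookup(scores, a, b)
        if math.isnan(v):
            dropped += 1
            continue
        y.append(label)
        s.append(v)
    if len(set(y)) < 2:
        raise ValueError("AUC needs both a positive and a negative class after drops")
    auc = float(roc_auc_score(y, s))
    return EvalResult(metric="auc", value=auc, n_used=len(y), n_dropped=dropped)


def pearson_eval(scores: SimilarityResult | dict, expr: ExpressionPairTable) -> EvalResult:
    """Pearson correlation of similarity scores against expression
    similarity over the overlapping pairs.

    Zero variance in either vector yields NaN with a ``degenerate`` flag.
    """
    xs, ys, dropped = [], [], 0
    for a, b, v in expr.pairs:
        s = _lookup(scores, a, b)
        if math.isnan(s):
            dropped += 1
            continue
        xs.append(s)
        ys.append(v)
    if len(xs) < 3:
        raise ValueError(f"need >= 3 overlapping scored pairs, have {len(xs)}")
    if np.std(xs) == 0 or np.std(ys) == 0:
        return EvalResult(metric="pearson_r", value=math.nan, n_used=len(xs),
                          n_dropped=dropped, extra={"degenerate": True})
    r, p = stats.pearsonr(xs, ys)
    return EvalResult(metric="pearson_r", value=float(r), n_used=len(xs),
                      n_dropped=dropped, extra={"p_value": float(p)})


@dataclass
class ClassificationSummary:
    """Pairwise matrix plus within/between-class mean similarity."""

    result: SimilarityResult
    class_of: dict[str, str]
    within_mean: float
    between_mean: float
    difference: float
    singleton_classes: set[str] = field(default_factory=set)


def classification_matrix(
    genes_with_classes: dict[str, str],
    scores: SimilarityResult,
) -> ClassificationSummary:
    """Within- vs between-class similarity for class-labeled genes.

    Genes of a shared functional class (same EC number, same pathway)
    should score higher among themselves than against other classes, so
    ``difference = within_mean - between_mean`` is the summary statistic.
    Classes with a single member contribute no within-class pair and are
    flagged.
    """
    classes = set(genes_with_classes.values())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    counts: dict[str, int] = {}
    for c in genes_with_classes.values():
        counts[c] = counts.get(c, 0) + 1
    singletons = {c for c, n in counts.items() if n == 1}

    within, between = [], []
    genes = sorted(genes_with_classes)
    for a, b in itertools.combinations(genes, 2):
        s = _lookup(scores, a, b)
        if math.isnan(s):
            continue
        (within if genes_with_classes[a] == genes_with_classes[b] else between).append(s)
    return ClassificationSummary(
        result=scores,
        class_of=dict(genes_with_classes),
        within_mean=float(np.mean(within)) if within else math.nan,
        between_mean=float(np.mean(between)) if between else math.nan,
        difference=(float(np.mean(within)) - float(np.mean(between))
                    if within and between else math.nan),
        singleton_classes=singletons,
    )


def sample_negative_pairs(
    genes: list[str],
    positives: list[tuple[str, str]],
    n: int | None = None,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Uniform random unordered gene pairs excluding the positives,
    matched 1:1 in count by default (the usual negative-PPI construction)."""
    rng = np.random.default_rng(seed)
    n = len(positives) if n is None else n
    pos = {_key(a, b) for a, b in positives}
    out: set[tuple[str, str]] = set()
    max_pairs = len(genes) * (len(genes) - 1) // 2
    if n > max_pairs - len(pos):
        raise ValueError("not enough non-positive pairs to sample from")
    while len(out) < n:
        i, j = rng.integers(len(genes), size=2)
        if i == j:
            continue
        k = _key(genes[i], genes[j])
        if k in pos or k in out:
            continue
        out.add(k)
    return sorted(out)
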