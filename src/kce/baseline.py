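"""Concept co-occurrence baseline.

Classifies a (PK, cancer) pair positive when the two concepts co-occur in at
least k abstracts, sweeping k = 1..25 and reporting precision/recall/F1 per
k.  Counting is at document level: one co-occurrence per abstract containing
at least one token for each concept, regardless of how often either is
mentioned inside it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = ["BaselineConfig", "SweepRow", "count_cooccurrence", "baseline_sweep"]

Pair = tuple[str, str]


@dataclass(frozen=True)
class BaselineConfig:
    k_min: int = 1
    k_max: int = 25
    counting_mode: str = "abstracts"

    def __post_init__(self) -> None:
        if not (1 <= self.k_min <= self.k_max):
            raise ValueError("need 1 <= k_min <= k_max")
        if self.counting_mode != "abstracts":
            raise ValueError("only document-level ('abstracts') counting is implemented")


@dataclass(frozen=True)
class SweepRow:
    k: int
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float


def count_cooccurrence(
    corpus: Iterable,
    pk_tokens: Mapping[str, Iterable[str]],
    cancer_tokens: Mapping[str, Iterable[str]],
) -> dict[Pair, int]:
    """Documents containing >=1 token of the PK and >=1 of the cancer.

    ``pk_tokens``/``cancer_tokens`` map each entity to its concept token(s).
    Pairs that never co-occur are absent from the result (implicit zero).
    """
    pk_by_token: dict[str, set[str]] = {}
    for pk, toks in pk_tokens.items():
        for t in [toks] if isinstance(toks, str) else toks:
            pk_by_token.setdefault(t, set()).add(pk)
    cancer_by_token: dict[str, set[str]] = {}
    for cancer, toks in cancer_tokens.items():
        for t in [toks] if isinstance(toks, str) else toks:
            cancer_by_token.setdefault(t, set()).add(cancer)
    counts: dict[Pair, int] = {}
    for doc in corpus:
        tokens = set(doc.tokens if hasattr(doc, "tokens") else doc)
        pks = {pk for t in tokens & set(pk_by_token) for pk in pk_by_token[t]}
        cancers = {c for t in tokens & set(cancer_by_token) for c in cancer_by_token[t]}
        for pk in pks:
            for cancer in cancers:
                counts[(pk, cancer)] = counts.get((pk, cancer), 0) + 1
    return counts


def baseline_sweep(
    counts: Mapping[Pair, int],
    positives: Iterable[Pair],
    negatives: Iterable[Pair],
    config: BaselineConfig = BaselineConfig(),
) -> tuple[list[SweepRow], int, float]:
    """Confusion matrix and F1 per threshold k; returns (rows, best_k, max_f1).

    Prediction at threshold k is count >= k.  F1 is 0 when undefined.  Among
    equal F1 values the smallest k is reported as best.
    """
    positives, negatives = set(positives), set(negatives)
    if positives & negatives:
        raise ValueError("positives and negatives must be disjoint")
    rows = []
    best_k, max_f1 = config.k_min, 0.0
    for k in range(config.k_min, config.k_max + 1):
        tp = sum(1 for p in positives if counts.get(p, 0) >= k)
        fn = len(positives) - tp
        fp = sum(1 for p in negatives if counts.get(p, 0) >= k)
        tn = len(negatives) - fp
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        rows.append(SweepRow(k, tp, fp, fn, tn, precision, recall, f1))
        if f1 > max_f1 + 1e-12:
            best_k, max_f1 = k, f1
    return rows, best_k, max_f1
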