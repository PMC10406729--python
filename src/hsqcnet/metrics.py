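"""Benchmark metrics for retrieval over queries with known structures.

A retrieved candidate counts as *identified* when its binary fingerprint
has cosine 1.0 with the query's true fingerprint, and as *annotated*
("similar") when the cosine is at least 0.8; both thresholds are inclusive,
and identity is tested as cosine >= 1 - 1e-9 to absorb floating error.
From the ranked hit lists the module computes identification/annotation
rate at k, and precision@k, recall@k and F1@k of structure annotation
(macro-averaged over queries).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .chem import MoleculeRecord
from .retrieval import RankedHit, ReferenceDB, cosine

__all__ = [
    "IDENTICAL_THRESHOLD",
    "SIMILAR_THRESHOLD",
    "HitStatus",
    "EvalCase",
    "MetricsReport",
    "hit_status",
    "rate_at_k",
    "precision_at_k",
    "recall_at_k",
    "f1_at_k",
    "count_similar_in_db",
    "compute_report",
]

IDENTICAL_THRESHOLD = 1.0 - 1e-9
SIMILAR_THRESHOLD = 0.8


class HitStatus(Enum):
    IDENTICAL = "identical"
    SIMILAR = "similar"
    NEITHER = "neither"


def hit_status(truth_fp: np.ndarray, hit_fp: np.ndarray) -> HitStatus:
    """Classify a retrieved fingerprint against the truth fingerprint."""
    c = cosine(truth_fp, hit_fp)
    if c >= IDENTICAL_THRESHOLD:
        return HitStatus.IDENTICAL
    if c >= SIMILAR_THRESHOLD - 1e-9:  # inclusive, robust to rounding
        return HitStatus.SIMILAR
    return HitStatus.NEITHER


@dataclass
class EvalCase:
    """One query: its true record and the ranked hits with their statuses."""

    query_id: str
    truth: MoleculeRecord
    hits: list[RankedHit]
    statuses: list[HitStatus]

    def __post_init__(self) -> None:
        if [h.rank for h in self.hits] != sorted(h.rank for h in self.hits):
            raise ValueError("hits must be sorted by rank")
        if len(self.hits) != len(self.statuses):
            raise ValueError("one status per hit required")

    @classmethod
    def from_hits(
        cls, query_id: str, truth: MoleculeRecord, hits: list[RankedHit], db: ReferenceDB
    ) -> "EvalCase":
        statuses = [
            hit_status(truth.fingerprint, db[h.record_id].fingerprint) for h in hits
        ]
        return cls(query_id=query_id, truth=truth, hits=hits, statuses=statuses)


def _status_ok(status: HitStatus, required: HitStatus) -> bool:
    if required is HitStatus.SIMILAR:
        return status in (HitStatus.SIMILAR, HitStatus.IDENTICAL)
    return status is required


def rate_at_k(cases: list[EvalCase], k: int, status_required: HitStatus) -> float:
    """Fraction of queries with a qualifying hit in the top k.

    With ``status_required=IDENTICAL`` this is the identification rate;
    with ``SIMILAR`` (which identical hits also satisfy) the annotation
    rate.
    """
    if not cases:
        raise ValueError("empty case set")
    if k < 1:
        raise ValueError("k must be >= 1")
    found = sum(
        any(_status_ok(s, status_required) for h, s in zip(c.hits, c.statuses) if h.rank <= k)
        for c in cases
    )
    return found / len(cases)


def precision_at_k(case: EvalCase, k: int) -> float:
    """Annotated (similar-or-identical) hits in the top k, divided by k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = sum(
        1
        for h, s in zip(case.hits, case.statuses)
        if h.rank <= k and _status_ok(s, HitStatus.SIMILAR)
    )
    return n / k


def recall_at_k(case: EvalCase, k: int, n_similar_in_db: int) -> float:
    """Annotated hits in the top k over all similar structures in the db.

    When the database holds no similar structure the recall is 1.0 by
    convention (nothing relevant to miss).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_similar_in_db < 0:
        raise ValueError("n_similar_in_db must be >= 0")
    n = sum(
        1
        for h, s in zip(case.hits, case.statuses)
        if h.rank <= k and _status_ok(s, HitStatus.SIMILAR)
    )
    if n_similar_in_db == 0:
        return 1.0
    if n > n_similar_in_db:
        raise ValueError(
            f"retrieved {n} similar hits but database holds only {n_similar_in_db}"
        )
    return n / n_similar_in_db


def f1_at_k(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def count_similar_in_db(
    truth: MoleculeRecord, db: ReferenceDB, exclude_self: bool = False
) -> int:
    """Exhaustively count db records similar (cosine >= 0.8) to the truth.

    ``exclude_self`` drops records whose fingerprint is identical to the
    truth fingerprint (used when the query compound is known to be in the
    db and should not count as its own relevant item).
    """
    tn = np.linalg.norm(truth.fingerprint.astype(np.float64))
    sims = (db.fingerprints @ truth.fingerprint.astype(np.float64)) / (db._norms * tn)
    n = int((sims >= SIMILAR_THRESHOLD - 1e-9).sum())
    if exclude_self:
        n -= int((sims >= IDENTICAL_THRESHOLD).sum())
    return n


@dataclass
class MetricsReport:
    """Macro-averaged benchmark metrics over a query set."""

    ks: tuple[int, ...]
    identification_rate: dict[int, float]
    annotation_rate: dict[int, float]
    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    n_queries: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "k": list(self.ks),
                "identification_rate": [self.identification_rate[k] for k in self.ks],
                "annotation_rate": [self.annotation_rate[k] for k in self.ks],
                "precision": [self.precision[k] for k in self.ks],
                "recall": [self.recall[k] for k in self.ks],
                "f1": [self.f1[k] for k in self.ks],
            }
        )


def compute_report(
    cases: list[EvalCase],
    db: ReferenceDB,
    ks: tuple[int, ...] = (1, 5, 10),
    exclude_self: bool = False,
) -> MetricsReport:
    """Compute all benchmark metrics for a set of evaluated queries."""
    if not cases:
        raise ValueError("empty case set")
    n_similar = {
        c.query_id: count_similar_in_db(c.truth, db, exclude_self=exclude_self)
        for c in cases
    }
    ident, annot, prec, rec, f1 = {}, {}, {}, {}, {}
    for k in ks:
        ident[k] = rate_at_k(cases, k, HitStatus.IDENTICAL)
        annot[k] = rate_at_k(cases, k, HitStatus.SIMILAR)
        ps = [precision_at_k(c, k) for c in cases]
        rs = [recall_at_k(c, k, n_similar[c.query_id]) for c in cases]
        prec[k] = float(np.mean(ps))
        rec[k] = float(np.mean(rs))
        f1[k] = float(np.mean([f1_at_k(p, r) for p, r in zip(ps, rs)]))
    return MetricsReport(
        ks=tuple(ks),
        identification_rate=ident,
        annotation_rate=annot,
        precision=prec,
        recall=rec,
        f1=f1,
        n_queries=len(cases),
    )
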