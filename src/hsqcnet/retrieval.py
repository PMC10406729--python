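"""Candidate-structure retrieval: fingerprint cosine ranking and the
chemical-shift baseline matcher.

The predicted fingerprint probability vector is compared directly against
the binary fingerprints of a reference database by cosine similarity;
optional molecular-weight and class pre-filters narrow the candidate pool
before ranking.  Ties are broken by MW difference, then id, so rankings are
total and reproducible.

The baseline matcher scores a query peak list against reference peak lists
by one-to-one peak pairing under fixed shift tolerances (0.5 ppm on 13C,
0.05 ppm on 1H) — the classic dereplication-by-shift-lookup approach the
network is benchmarked against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .chem import (
    FINGERPRINT_DIM,
    ClassVocabulary,
    MoleculeRecord,
    build_record,
)
from .model import Prediction
from .peaks import PeakList

__all__ = [
    "C_SHIFT_TOL",
    "H_SHIFT_TOL",
    "RankedHit",
    "ReferenceDB",
    "cosine",
    "search",
    "baseline_shift_match",
    "build_db",
]

#: Peak-matching tolerances of the shift-lookup baseline, in ppm.
C_SHIFT_TOL = 0.5
H_SHIFT_TOL = 0.05


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two nonnegative fingerprint vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


@dataclass(frozen=True)
class RankedHit:
    """One retrieval result; ``rank`` is 1-based."""

    record_id: str
    cosine: float
    mw_delta: float
    class_match: bool
    rank: int


class ReferenceDB:
    """A searchable library of precomputed molecule records.

    Fingerprints are cached as a dense matrix for batch cosine scoring.
    """

    def __init__(self, records: list[MoleculeRecord], vocabulary: ClassVocabulary):
        ids = [r.id for r in records]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(f"duplicate record ids: {dupes}")
        self.records = list(records)
        self.vocabulary = vocabulary
        self._by_id = {r.id: r for r in records}
        self.fingerprints = (
            np.stack([r.fingerprint for r in records]).astype(np.float64)
            if records
            else np.zeros((0, FINGERPRINT_DIM))
        )
        self._norms = np.linalg.norm(self.fingerprints, axis=1)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, record_id: str) -> MoleculeRecord:
        return self._by_id[record_id]

    # -- persistence -----------------------------------------------------
    def save(self, path: str) -> None:
        """Persist to a single .npz archive with a JSON manifest."""
        manifest = {
            "version": 1,
            "fingerprint_dim": FINGERPRINT_DIM,
            "vocabulary": list(self.vocabulary.names),
            "glycoside_name": self.vocabulary.glycoside_name,
            "ids": [r.id for r in self.records],
            "smiles": [r.smiles for r in self.records],
            "mw": [r.mw for r in self.records],
            "class_label": [r.class_label for r in self.records],
            "glycoside": [bool(r.glycoside) for r in self.records],
        }
        packed = np.packbits(
            np.stack([r.fingerprint for r in self.records])
            if self.records
            else np.zeros((0, FINGERPRINT_DIM), dtype=np.uint8),
            axis=1,
        )
        with open(path, "wb") as fh:  # write to the exact path, no .npz suffixing
            np.savez(fh, manifest=json.dumps(manifest), fingerprints=packed)

    @classmethod
    def load(cls, path: str) -> "ReferenceDB":
        with np.load(path, allow_pickle=False) as data:
            manifest = json.loads(str(data["manifest"]))
            bits = np.unpackbits(data["fingerprints"], axis=1)[:, :FINGERPRINT_DIM]
        vocab = ClassVocabulary(
            names=tuple(manifest["vocabulary"]), glycoside_name=manifest["glycoside_name"]
        )
        records = [
            MoleculeRecord(
                id=i, smiles=s, fingerprint=fp, mw=m, class_label=c, glycoside=g
            )
            for i, s, fp, m, c, g in zip(
                manifest["ids"],
                manifest["smiles"],
                bits,
                manifest["mw"],
                manifest["class_label"],
                manifest["glycoside"],
            )
        ]
        return cls(records, vocab)


def search(
    pred: Prediction,
    db: ReferenceDB,
    k: int = 10,
    mw_window: float | None = None,
    class_filter: bool = False,
    binarize: bool = False,
) -> list[RankedHit]:
    """Rank database records against a prediction by fingerprint cosine.

    ``mw_window`` (fractional, e.g. 0.2 for 20%) excludes records whose MW
    differs from the predicted MW by more than that fraction;
    ``class_filter`` keeps only records of the argmax predicted class.
    Survivors are sorted by cosine descending, ties by MW difference then
    id.  ``binarize`` thresholds the predicted probabilities at 0.5 before
    scoring (off by default: raw probabilities preserve ranking
    information).
    """
    if len(db) == 0:
        raise ValueError("cannot search an empty reference database")
    if k < 1:
        raise ValueError("k must be >= 1")
    q = np.asarray(pred.fingerprint, dtype=np.float64)
    if binarize:
        q = (q >= 0.5).astype(np.float64)
    qn = np.linalg.norm(q)
    if qn == 0:
        raise ValueError("query fingerprint is all-zero; cosine undefined")

    keep = np.ones(len(db), dtype=bool)
    mw_deltas = np.array([abs(r.mw - pred.mw) for r in db.records])
    if mw_window is not None:
        keep &= mw_deltas / pred.mw <= mw_window
    if class_filter:
        pred_class = int(np.argmax(pred.class_probs))
        keep &= np.array([r.class_label == pred_class for r in db.records])
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return []

    sims = (db.fingerprints[idx] @ q) / (db._norms[idx] * qn)
    pred_class = int(np.argmax(pred.class_probs))
    order = sorted(
        range(idx.size),
        key=lambda i: (-sims[i], mw_deltas[idx[i]], db.records[idx[i]].id),
    )
    hits = []
    for rank, i in enumerate(order[:k], start=1):
        r = db.records[idx[i]]
        hits.append(
            RankedHit(
                record_id=r.id,
                cosine=float(sims[i]),
                mw_delta=float(mw_deltas[idx[i]]),
                class_match=r.class_label == pred_class,
                rank=rank,
            )
        )
    return hits


def _match_count(query: PeakList, ref: PeakList) -> int:
    """Maximum number of one-to-one peak pairs within the shift tolerances.

    Eligible pairs satisfy |dC| <= 0.5 ppm and |dH| <= 0.05 ppm; among
    maximum-cardinality pairings the one minimizing total normalized
    distance (|dC|/0.5 + |dH|/0.05) is chosen, which makes the score
    deterministic and symmetric.
    """
    nq, nr = len(query), len(ref)
    if nq == 0 or nr == 0:
        return 0
    qc = np.array([p.c_shift for p in query])[:, None]
    qh = np.array([p.h_shift for p in query])[:, None]
    rc = np.array([p.c_shift for p in ref])[None, :]
    rh = np.array([p.h_shift for p in ref])[None, :]
    dc = np.abs(qc - rc)
    dh = np.abs(qh - rh)
    # inclusive thresholds, robust to binary-float representation of ppm
    eligible = (dc <= C_SHIFT_TOL + 1e-9) & (dh <= H_SHIFT_TOL + 1e-9)
    if not eligible.any():
        return 0
    cost = dc / C_SHIFT_TOL + dh / H_SHIFT_TOL
    # forbidden pairs get a penalty dwarfing any sum of eligible costs, so
    # the assignment maximizes the number of eligible pairs first
    penalty = 4.0 * max(nq, nr) + 4.0
    cost = np.where(eligible, cost, penalty)
    rows, cols = linear_sum_assignment(cost)
    return int(eligible[rows, cols].sum())


@dataclass(frozen=True)
class ShiftMatchHit:
    """Baseline-matcher result: Dice-style matched-peak fraction."""

    record_id: str
    score: float
    n_matched: int
    rank: int


def baseline_shift_match(
    query: PeakList,
    refs: list[tuple[str, PeakList]],
    k: int = 10,
) -> list[ShiftMatchHit]:
    """Rank reference peak lists by shift-tolerance peak matching.

    Score = 2 * matched / (n_query + n_ref), 1.0 for an identical list.
    Ranked descending; ties broken by reference id.
    """
    if len(query) == 0:
        raise ValueError("query peak list is empty")
    scored = []
    for ref_id, ref in refs:
        m = _match_count(query, ref)
        denom = len(query) + len(ref)
        scored.append((ref_id, 2.0 * m / denom if denom else 0.0, m))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [
        ShiftMatchHit(record_id=rid, score=s, n_matched=m, rank=rank)
        for rank, (rid, s, m) in enumerate(scored[:k], start=1)
    ]


def build_db(
    structures: list[tuple[str, str, str]] | list[tuple[str, str, str, bool]],
    vocabulary: ClassVocabulary,
) -> ReferenceDB:
    """Build a :class:`ReferenceDB` from (id, smiles, class_name[, glycoside]) rows."""
    records = []
    for row in structures:
        id_, smiles, class_name = row[0], row[1], row[2]
        glycoside = row[3] if len(row) > 3 else None
        records.append(
            build_record(
                id=id_,
                smiles=smiles,
                class_label=vocabulary.index(class_name),
                vocabulary=vocabulary,
                glycoside=glycoside,
            )
        )
    return ReferenceDB(records, vocabulary)
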