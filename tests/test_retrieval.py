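"""Cosine ranking, filters, persistence, and the shift-matching baseline."""

import itertools

import numpy as np
import pytest

from hsqcnet.chem import FINGERPRINT_DIM, ClassVocabulary, MoleculeRecord
from hsqcnet.model import Prediction
from hsqcnet.peaks import Peak, PeakList
from hsqcnet.retrieval import (
    C_SHIFT_TOL,
    H_SHIFT_TOL,
    ReferenceDB,
    baseline_shift_match,
    build_db,
    cosine,
    search,
)

VOCAB = ClassVocabulary(names=("a", "b", "c"))


def _fp(bits):
    v = np.zeros(FINGERPRINT_DIM, dtype=np.uint8)
    v[list(bits)] = 1
    return v


def _rec(id_, bits, mw=100.0, class_label=0):
    return MoleculeRecord(id=id_, smiles="C", fingerprint=_fp(bits), mw=mw,
                          class_label=class_label, glycoside=False)


def _pred(probs=None, bits=None, class_probs=(1.0, 0.0, 0.0), mw=100.0):
    if probs is None:
        probs = _fp(bits).astype(float)
    return Prediction(fingerprint=probs, class_probs=np.array(class_probs),
                      mw=mw, glycoside_prob=0.5)


def _random_db(rng, n_records):
    recs = []
    for i in range(n_records):
        bits = rng.choice(FINGERPRINT_DIM, size=rng.integers(3, 30), replace=False)
        recs.append(_rec(f"r{i:03d}", bits, mw=float(rng.uniform(50, 900)),
                         class_label=int(rng.integers(3))))
    return ReferenceDB(recs, VOCAB)


def _brute_force(pred, db, k, mw_window, class_filter, binarize):
    q = np.asarray(pred.fingerprint, dtype=float)
    if binarize:
        q = (q >= 0.5).astype(float)
    pred_class = int(np.argmax(pred.class_probs))
    scored = []
    for r in db.records:
        if mw_window is not None and abs(r.mw - pred.mw) / pred.mw > mw_window:
            continue
        if class_filter and r.class_label != pred_class:
            continue
        c = float(q @ r.fingerprint / (np.linalg.norm(q) * np.linalg.norm(r.fingerprint)))
        scored.append((-c, abs(r.mw - pred.mw), r.id))
    scored.sort()
    return [s[2] for s in scored[:k]]


class TestCosine:
    def test_self_similarity(self):
        v = _fp([1, 2, 3])
        assert cosine(v, v) == pytest.approx(1.0)

    def test_disjoint_support(self):
        assert cosine(_fp([0, 1]), _fp([2, 3])) == 0.0

    def test_half_overlap(self):
        # a = {0,1}, b = {0,2}: 1/(sqrt2*sqrt2) = 0.5
        assert cosine(_fp([0, 1]), _fp([0, 2])) == pytest.approx(0.5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine(_fp([]), _fp([1]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cosine(np.ones(4), np.ones(5))


class TestSearch:
    def test_self_retrieval_at_rank_one(self):
        db = ReferenceDB([_rec("x", [1, 2]), _rec("y", [3, 4]), _rec("z", [5])], VOCAB)
        hits = search(_pred(bits=[3, 4]), db, k=1)
        assert hits[0].record_id == "y"
        assert hits[0].cosine == pytest.approx(1.0)
        assert hits[0].rank == 1

    def test_k_larger_than_db(self):
        db = ReferenceDB([_rec("x", [1]), _rec("y", [2])], VOCAB)
        assert len(search(_pred(bits=[1]), db, k=10)) == 2

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            search(_pred(bits=[1]), ReferenceDB([], VOCAB), k=1)

    def test_all_filtered_returns_empty_list(self):
        db = ReferenceDB([_rec("x", [1], mw=500.0)], VOCAB)
        assert search(_pred(bits=[1], mw=100.0), db, k=5, mw_window=0.1) == []

    @pytest.mark.parametrize("mw_window", [None, 0.5])
    @pytest.mark.parametrize("class_filter", [False, True])
    @pytest.mark.parametrize("binarize", [False, True])
    def test_matches_brute_force_oracle(self, mw_window, class_filter, binarize):
        rng = np.random.default_rng(17)
        for _ in range(20):
            db = _random_db(rng, int(rng.integers(5, 50)))
            probs = rng.random(FINGERPRINT_DIM) * 0.4
            probs[rng.choice(FINGERPRINT_DIM, 10, replace=False)] = 0.9
            pred = _pred(probs=probs, mw=float(rng.uniform(50, 900)),
                         class_probs=np.array([0.2, 0.5, 0.3]))
            got = [h.record_id for h in search(pred, db, k=10, mw_window=mw_window,
                                               class_filter=class_filter,
                                               binarize=binarize)]
            want = _brute_force(pred, db, 10, mw_window, class_filter, binarize)
            assert got == want

    def test_widening_mw_window_never_drops_hits(self):
        rng = np.random.default_rng(5)
        db = _random_db(rng, 30)
        pred = _pred(probs=rng.random(FINGERPRINT_DIM), mw=300.0)
        previous: set[str] = set()
        for w in (0.1, 0.3, 0.8, 2.0):
            ids = {h.record_id for h in search(pred, db, k=30, mw_window=w)}
            assert previous <= ids
            previous = ids


class TestBaselineShiftMatch:
    def test_identical_lists_score_one(self):
        pl = PeakList(peaks=(Peak(6.30, 92.9), Peak(6.19, 97.8)))
        hits = baseline_shift_match(pl, [("self", pl), ("other", PeakList(peaks=(Peak(1.0, 20.0),)))])
        assert hits[0].record_id == "self"
        assert hits[0].score == pytest.approx(1.0)

    def test_proton_threshold_boundary_excludes(self):
        # |dH| = 0.06 > 0.05: no match even though carbon matches exactly
        q = PeakList(peaks=(Peak(6.30, 92.9),))
        r = PeakList(peaks=(Peak(6.36, 92.9),))
        hits = baseline_shift_match(q, [("r", r)])
        assert hits[0].score == 0.0

    def test_thresholds_inclusive_at_exact_boundary(self):
        q = PeakList(peaks=(Peak(1.00, 20.0),))
        r = PeakList(peaks=(Peak(1.05, 20.5),))
        hits = baseline_shift_match(q, [("r", r)])
        assert hits[0].score == pytest.approx(1.0)

    def test_partial_match_dice_score(self):
        # 3 vs 3 peaks, exactly 2 pairable: 2*2/6
        q = PeakList(peaks=(Peak(1.0, 20.0), Peak(2.0, 40.0), Peak(3.0, 60.0)))
        r = PeakList(peaks=(Peak(1.01, 20.1), Peak(2.02, 40.2), Peak(9.0, 160.0)))
        hits = baseline_shift_match(q, [("r", r)])
        assert hits[0].score == pytest.approx(2 * 2 / 6)

    def test_symmetric_for_equal_sizes(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            a = PeakList(peaks=tuple(Peak(float(h), float(c)) for h, c in
                                     zip(rng.uniform(0, 10, 4), rng.uniform(0, 200, 4))))
            b = PeakList(peaks=tuple(Peak(float(h) + float(dh), float(c) + float(dc))
                                     for (h, c, dh, dc) in
                                     zip(rng.uniform(0, 10, 4), rng.uniform(0, 200, 4),
                                         rng.normal(0, 0.05, 4), rng.normal(0, 0.5, 4))))
            sab = baseline_shift_match(a, [("b", b)])[0].score
            sba = baseline_shift_match(b, [("a", a)])[0].score
            assert sab == pytest.approx(sba)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            baseline_shift_match(PeakList(), [("r", PeakList(peaks=(Peak(1, 1),)))])

    def test_greedy_trap_instance_still_maximal(self):
        # q0 pairs with both refs, q1 only with r0; the nearest-first pairing
        # (q0, r0) would strand q1 — the matcher must still find 2 pairs
        q = PeakList(peaks=(Peak(0.0, 0.0), Peak(-0.03, -0.3)))
        r = PeakList(peaks=(Peak(0.01, 0.1), Peak(0.04, 0.4)))
        hits = baseline_shift_match(q, [("r", r)])
        assert hits[0].n_matched == 2

    def test_matches_exhaustive_maximum_matching(self):
        # brute force over all injective pairings on random small instances
        rng = np.random.default_rng(31)

        def max_matching(q, r):
            # pad to a square eligibility matrix and take the best over all
            # permutations — exhaustive for n <= 4
            n = max(len(q), len(r))
            elig = [[False] * n for _ in range(n)]
            for i, a in enumerate(q):
                for j, b in enumerate(r):
                    elig[i][j] = (
                        abs(a.c_shift - b.c_shift) <= C_SHIFT_TOL
                        and abs(a.h_shift - b.h_shift) <= H_SHIFT_TOL
                    )
            return max(
                sum(elig[i][p[i]] for i in range(n))
                for p in itertools.permutations(range(n))
            )

        for _ in range(100):
            nq, nr = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            # cluster shifts so eligible pairs are common
            q = PeakList(peaks=tuple(Peak(float(h), float(c)) for h, c in
                                     zip(rng.uniform(0, 0.2, nq), rng.uniform(0, 2, nq))))
            r = PeakList(peaks=tuple(Peak(float(h), float(c)) for h, c in
                                     zip(rng.uniform(0, 0.2, nr), rng.uniform(0, 2, nr))))
            got = baseline_shift_match(q, [("r", r)])[0].n_matched
            assert got == max_matching(q.peaks, r.peaks)


class TestBuildDb:
    def test_three_smiles(self):
        db = build_db([("a", "CCO", "a"), ("b", "c1ccccc1", "b"), ("c", "CC(=O)O", "a")],
                      VOCAB)
        assert len(db) == 3
        assert db["b"].class_label == 1

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="dup"):
            build_db([("dup", "C", "a"), ("dup", "CC", "b")], VOCAB)

    def test_save_load_roundtrip_bit_identical(self, tmp_path):
        db = build_db([("a", "CCO", "a"), ("b", "COC1OC(CO)C(O)C(O)C1O", "c")], VOCAB)
        path = str(tmp_path / "db.npz")
        db.save(path)
        loaded = ReferenceDB.load(path)
        assert [r.id for r in loaded.records] == ["a", "b"]
        for orig, back in zip(db.records, loaded.records):
            np.testing.assert_array_equal(orig.fingerprint, back.fingerprint)
            assert orig.mw == back.mw and orig.glycoside == back.glycoside
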