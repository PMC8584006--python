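"""Ranking, enrichment score, permutation NES and state classification."""

import numpy as np
import pandas as pd
import pytest

import phosflow as pf
from phosflow.activity import (
    STATE_ACTIVATED,
    STATE_INHIBITED,
    STATE_INDETERMINATE,
    _null_scores,
)
from phosflow.model import ComparisonResult, QuantTable


def ranked_series(values, ids=None):
    ids = ids or [f"s{i:04d}" for i in range(len(values))]
    cr = ComparisonResult(
        ("n", "d"), pd.DataFrame({"log2fc": values}, index=ids)
    )
    return pf.rank_metric(cr)


def brute_force_es(ranked, subset, weight):
    """Independent running-sum oracle: explicit python loop."""
    subset = set(subset)
    values = ranked.to_numpy()
    hits = [sid in subset for sid in ranked.index]
    m = sum(hits)
    total = sum(abs(v) ** weight for v, h in zip(values, hits) if h)
    running, best = 0.0, 0.0
    for v, h in zip(values, hits):
        if h:
            running += (abs(v) ** weight) / total if total > 0 else 1.0 / m
        else:
            running -= 1.0 / (len(values) - m)
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return best


class TestRankMetric:
    def test_ties_break_lexicographically(self):
        r = ranked_series([1.0, 1.0, 1.0], ids=["c", "a", "b"])
        assert list(r.index) == ["a", "b", "c"]

    def test_descending_order(self):
        r = ranked_series([2.0, 0.0, -1.0], ids=["x", "y", "z"])
        assert list(r.index) == ["x", "y", "z"]

    def test_sample_mode_is_zscore(self):
        rng = np.random.default_rng(0)
        vals = np.exp2(rng.normal(20, 1, size=50))
        q = QuantTable(
            pd.DataFrame({"a.r1": vals, "a.r2": vals}, index=[f"s{i}" for i in range(50)]),
            {"a.r1": "a", "a.r2": "a"},
        )
        r = pf.rank_metric(q, "a.r1")
        assert r.mean() == pytest.approx(0.0, abs=1e-12)
        assert r.to_numpy().std() == pytest.approx(1.0, rel=1e-6)  # population sd
        assert (np.diff(r.to_numpy()) <= 0).all()

    def test_unknown_sample(self):
        q = QuantTable(pd.DataFrame({"a.r1": [1.0]}, index=["s"]), {"a.r1": "a"})
        with pytest.raises(ValueError):
            pf.rank_metric(q, "nope")


class TestEnrichmentScore:
    def test_full_set_scores_one(self):
        r = ranked_series([3.0, 2.0, 1.0])
        es, running = pf.enrichment_score(r, set(r.index))
        assert es == pytest.approx(1.0)
        assert running[-1] == pytest.approx(1.0)

    def test_single_bottom_element_unweighted(self):
        # all misses then one hit: the running sum bottoms out at -1 just
        # before the final hit and returns to 0 at the end
        r = ranked_series(list(range(10, 0, -1)))
        es, running = pf.enrichment_score(r, {r.index[-1]}, weight_exponent=0)
        assert es == pytest.approx(-1.0)
        assert running[-1] == pytest.approx(0.0)

    def test_vs_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for trial in range(200):
            n = int(rng.integers(8, 30))
            r = ranked_series(rng.normal(size=n))
            m = int(rng.integers(1, max(2, n // 2)))
            subset = set(rng.choice(list(r.index), size=m, replace=False))
            for w in (0.0, 1.0):
                es, _ = pf.enrichment_score(r, subset, w)
                assert es == brute_force_es(r, subset, w)

    def test_monotone_invariance_unweighted(self):
        rng = np.random.default_rng(2)
        vals = np.sort(rng.normal(size=40))[::-1]
        r1 = ranked_series(vals)
        r2 = ranked_series(np.exp(vals) + 5)  # strictly monotone transform
        subset = set(rng.choice(list(r1.index), size=6, replace=False))
        es1, _ = pf.enrichment_score(r1, subset, weight_exponent=0)
        es2, _ = pf.enrichment_score(r2, subset, weight_exponent=0)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_reversal_negates(self):
        rng = np.random.default_rng(3)
        n = 30
        vals = np.sort(rng.normal(size=n))[::-1]
        ids = [f"s{i:02d}" for i in range(n)]
        subset = set(rng.choice(ids, size=5, replace=False))
        fwd = pd.Series(vals, index=ids)
        rev = pd.Series(vals[::-1], index=ids[::-1])
        es_f, _ = pf.enrichment_score(fwd, subset, weight_exponent=0)
        es_r, _ = pf.enrichment_score(rev, subset, weight_exponent=0)
        assert es_f == pytest.approx(-es_r, abs=1e-12)
        # weight 1 on a sign-symmetric vector: approximate antisymmetry
        sym = np.concatenate([np.arange(n // 2, 0, -1), -np.arange(1, n // 2 + 1)]) / 10
        fwd = pd.Series(sym, index=ids)
        rev = pd.Series(sym[::-1], index=ids[::-1])
        es_f, _ = pf.enrichment_score(fwd, subset, weight_exponent=1)
        es_r, _ = pf.enrichment_score(rev, subset, weight_exponent=1)
        assert es_f == pytest.approx(-es_r, abs=0.05)

    def test_no_overlap_raises(self):
        r = ranked_series([1.0, 2.0])
        with pytest.raises(ValueError, match="overlap"):
            pf.enrichment_score(r, {"nope"})


class TestNullScoresFastPath:
    def test_matches_cumsum_definition(self):
        """The closed-form permutation scorer agrees with the running-sum
        definition on the same drawn sets."""
        rng = np.random.default_rng(4)
        for trial in range(100):
            n = int(rng.integers(15, 80))
            m = int(rng.integers(2, 10))
            vals = np.sort(rng.normal(size=n))[::-1]
            ids = [f"s{i:03d}" for i in range(n)]
            ranked = pd.Series(vals, index=ids)
            keys = np.random.default_rng(trial).random((1, n))
            pos = np.sort(np.argpartition(keys, m - 1, axis=1)[:, :m], axis=1)[0]
            es_ref, _ = pf.enrichment_score(ranked, {ids[p] for p in pos})
            es_fast = _null_scores(vals, m, 1, np.random.default_rng(trial), 1.0)[0]
            assert es_fast == pytest.approx(es_ref, abs=1e-12)


class TestNormalizeAndTest:
    def test_nes_sign_matches_es(self):
        rng = np.random.default_rng(9)
        for trial in range(10):
            r = ranked_series(rng.normal(size=60))
            subset = set(rng.choice(list(r.index), size=6, replace=False))
            es, nes, p = pf.normalize_and_test(r, subset, n_permutations=100,
                                               seed=trial)
            assert np.sign(nes) == np.sign(es)
            assert 0 < p <= 1

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        r = ranked_series(rng.normal(size=100))
        subset = set(rng.choice(list(r.index), size=8, replace=False))
        out1 = pf.normalize_and_test(r, subset, n_permutations=200, seed=42)
        out2 = pf.normalize_and_test(r, subset, n_permutations=200, seed=42)
        assert out1 == out2

    def test_requires_enough_permutations(self):
        r = ranked_series([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="100"):
            pf.normalize_and_test(r, set(r.index), n_permutations=10)

    def test_planted_top_decile_kinase_is_significant(self):
        """Substrates packed into the top decile of a 1000-site list are
        called significant (p <= 0.01) across seeds."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals = np.sort(rng.normal(size=1000))[::-1]
            ids = [f"s{i:04d}" for i in range(1000)]
            r = pd.Series(vals, index=ids)
            subset = set(rng.choice(ids[:100], size=12, replace=False))
            es, nes, p = pf.normalize_and_test(
                r, subset, n_permutations=1000, seed=seed
            )
            assert es > 0 and nes >= 1
            assert p <= 0.01


class TestClassifyState:
    @pytest.mark.parametrize(
        "nes, state",
        [
            (1.8, STATE_ACTIVATED),
            (1.0, STATE_ACTIVATED),
            (0.4, STATE_INDETERMINATE),
            (-0.4, STATE_INDETERMINATE),
            (-1.0, STATE_INHIBITED),
            (-1.8, STATE_INHIBITED),
            (float("nan"), STATE_INDETERMINATE),
        ],
    )
    def test_boundaries(self, nes, state):
        assert pf.classify_state(nes) == state


class TestScoreKinases:
    def test_small_sets_reported_as_skipped(self):
        rng = np.random.default_rng(6)
        r = ranked_series(rng.normal(size=50))
        sets = {"K1": set(list(r.index)[:10]), "K2": {r.index[0]}}
        acts = pf.score_kinases(r, sets, "ctx", n_permutations=100, seed=0)
        by_id = {a.kinase_id: a for a in acts}
        assert by_id["K2"].note.startswith("skipped")
        assert by_id["K2"].state == STATE_INDETERMINATE
        assert by_id["K1"].note == ""

    def test_recovers_planted_direction(self, default_study):
        study = default_study
        result = pf.compare(study.quant, ("AC-B4", "AC-MG"))
        ranked = pf.rank_metric(result)
        sets = {k: set(v) for k, v in study.truth.substrates.items()}
        acts = pf.score_kinases(ranked, sets, "AC-B4/AC-MG",
                                n_permutations=500, seed=3)
        planted = study.truth.planted_kinases(("AC-B4", "AC-MG"))
        by_id = {a.kinase_id: a for a in acts}
        correct = sum(by_id[k].state == s for k, s in planted.items())
        assert correct >= 4  # >= 80% of the 5 planted kinases
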