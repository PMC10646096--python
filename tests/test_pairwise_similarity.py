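"""Pairwise similarity statistics: R^2, similarity score, batch z-scores,
sequence identity and cross-layer comparison."""

import numpy as np
import pandas as pd
import pytest
from Bio import Align
from hypothesis import given, settings, strategies as st

import e2atlas as ea
from e2atlas.pairwise_similarity import SimilarityMatrix, _symmetric_frame

import oracles


def calls_from(records):
    rows = [{"protein": p, "condition": c, "direction": d,
             "transcription_independent": d != "none",
             "p_value": 0.01 if d != "none" else 0.9,
             "log2fc": 0.5 if d == "up" else (-0.5 if d == "down" else 0.0)}
            for p, c, d in records]
    return ea.ModulationCalls(table=pd.DataFrame(rows))


class TestRegulatedSelection:
    def test_empty_when_nothing_significant(self):
        calls = calls_from([("p1", "E2a", "none"), ("p2", "E2b", "none")])
        assert ea.select_regulated_union(calls) == set()

    def test_single_condition_hit_included(self):
        calls = calls_from([("p1", "E2a", "up"), ("p1", "E2b", "none")])
        assert ea.select_regulated_union(calls) == {"p1"}

    def test_fixture_count(self):
        regulated = [f"p{i}" for i in range(7)]
        quiet = [f"p{i}" for i in range(7, 20)]
        calls = calls_from([(p, "E2a", "up") for p in regulated]
                           + [(p, "E2a", "none") for p in quiet])
        assert len(ea.select_regulated_union(calls)) == 7


class TestPairwiseR2:
    def test_identity_and_sign_blindness(self):
        fc = pd.Series([0.1, 0.4, -0.3, 0.8], index=list("abcd"))
        assert ea.pairwise_r2(fc, fc)[0] == pytest.approx(1.0)
        assert ea.pairwise_r2(fc, -fc)[0] == pytest.approx(1.0)

    def test_worked_example_matches_regression_oracle(self):
        a = pd.Series([0.1, 0.4, -0.3, 0.8], index=list("abcd"))
        b = pd.Series([0.2, 0.5, -0.1, 0.6], index=list("abcd"))
        r2, n = ea.pairwise_r2(a, b)
        assert n == 4
        assert r2 == pytest.approx(oracles.r2_oracle(a, b), abs=1e-12)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = rng.integers(3, 12)
            idx = [f"p{i}" for i in range(n)]
            a = pd.Series(rng.normal(size=n), index=idx)
            b = pd.Series(rng.normal(size=n), index=idx)
            r2, _ = ea.pairwise_r2(a, b)
            assert r2 == pytest.approx(oracles.r2_oracle(a, b), abs=1e-12)

    def test_constant_vector_reported_missing(self):
        a = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        b = pd.Series([0.2, 0.5, -0.1], index=list("abc"))
        assert np.isnan(ea.pairwise_r2(a, b)[0])

    def test_pair_universe_counts(self):
        idx = list("abcde")
        a = pd.Series([0.5, 0.3, -0.2, 0.1, 0.9], index=idx)
        b = pd.Series([0.4, 0.2, -0.1, 0.0, 0.8], index=idx)
        reg_a, reg_b = {"a", "b"}, {"b", "c"}
        _, n_either = ea.pairwise_r2(a, b, regulated_a=reg_a, regulated_b=reg_b,
                                     pair_universe="either")
        _, n_inter = ea.pairwise_r2(a, b, regulated_a=reg_a, regulated_b=reg_b,
                                    pair_universe="intersection")
        assert n_either == 3 and n_inter == 1


class TestSimilarityScore:
    @pytest.mark.parametrize("r2,n,expected",
                             [(0.5, 100, 50.0), (0.0, 17, 0.0), (1.0, 0, 0.0)])
    def test_direct_formula(self, r2, n, expected):
        assert ea.similarity_score(r2, n) == expected

    def test_jointly_monotone(self):
        rng = np.random.default_rng(32)
        for _ in range(50):
            r2a, r2b = sorted(rng.uniform(0, 1, 2))
            na, nb = sorted(rng.integers(0, 500, 2))
            assert ea.similarity_score(r2a, na) <= ea.similarity_score(r2b, nb)


class TestBatchZscores:
    def _matrix(self, labels, values):
        return SimilarityMatrix(values=values, kind="score")

    def test_three_value_group_exact(self):
        labels = ["a", "b", "c"]
        vals = _symmetric_frame(labels)
        vals.loc["a", "b"] = vals.loc["b", "a"] = 1.0
        vals.loc["a", "c"] = vals.loc["c", "a"] = 2.0
        vals.loc["b", "c"] = vals.loc["c", "b"] = 3.0
        z = ea.batch_zscores(self._matrix(labels, vals), {l: 1 for l in labels})
        assert z.values.loc["a", "b"] == pytest.approx(-1.0, abs=1e-12)
        assert z.values.loc["a", "c"] == pytest.approx(0.0, abs=1e-12)
        assert z.values.loc["b", "c"] == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(33)
        labels = [f"c{i}" for i in range(5)]
        vals = _symmetric_frame(labels)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                vals.loc[a, b] = vals.loc[b, a] = rng.uniform(0, 10)
        batch = {l: 1 for l in labels}
        z1 = ea.batch_zscores(self._matrix(labels, vals), batch)
        z2 = ea.batch_zscores(self._matrix(labels, vals + 7.5), batch)
        pd.testing.assert_frame_equal(z1.values, z2.values, atol=1e-10)

    def test_groups_standardised_exactly(self):
        """Every group of a multi-batch design: mean 0, sample SD 1."""
        rng = np.random.default_rng(34)
        labels, batch_of = [], {}
        for b in range(1, 7):
            for j in range(3):
                lab = f"c{b}_{j}"
                labels.append(lab)
                batch_of[lab] = b
        vals = _symmetric_frame(labels)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                vals.loc[a, b] = vals.loc[b, a] = rng.uniform(0, 100)
        z = ea.batch_zscores(self._matrix(labels, vals), batch_of)
        pairs = z.pairs()
        for _, grp in pairs.groupby("group"):
            v = grp["zscore"].dropna()
            assert abs(v.mean()) < 1e-10
            assert abs(v.std(ddof=1) - 1.0) < 1e-10
        assert set(pairs["group"]) == {f"intra:{b}" for b in range(1, 7)} | {"extra"}

    def test_small_or_degenerate_groups_missing(self):
        labels = ["a", "b", "c", "d"]
        vals = _symmetric_frame(labels)
        for i, x in enumerate(labels):
            for y in labels[i + 1:]:
                vals.loc[x, y] = vals.loc[y, x] = 5.0  # zero spread
        batch = {"a": 1, "b": 1, "c": 2, "d": 3}
        z = ea.batch_zscores(self._matrix(labels, vals), batch)
        assert z.values.loc["a", "b"] != z.values.loc["a", "b"]  # 1-pair group
        assert np.isnan(z.values.loc["c", "d"])  # sd == 0


class TestInteractomeR2:
    def test_identical_interactomes(self):
        s = pd.Series({"x": 0.9, "y": 0.7})
        assert ea.interactome_r2(s, s) == pytest.approx(1.0)

    def test_two_point_degeneracy(self):
        a = pd.Series({"x": 0.9})
        b = pd.Series({"y": 0.8})
        assert ea.interactome_r2(a, b) == pytest.approx(1.0)

    def test_union_universe_with_zero_fill_matches_oracle(self):
        rng = np.random.default_rng(35)
        for _ in range(50):
            preys_a = [f"p{i}" for i in rng.choice(10, 5, replace=False)]
            preys_b = [f"p{i}" for i in rng.choice(10, 5, replace=False)]
            a = pd.Series(rng.uniform(0.6, 1, 5), index=preys_a)
            b = pd.Series(rng.uniform(0.6, 1, 5), index=preys_b)
            universe = sorted(set(preys_a) | set(preys_b))
            av = [a.get(p, 0.0) for p in universe]
            bv = [b.get(p, 0.0) for p in universe]
            expected = oracles.r2_oracle(av, bv)
            got = ea.interactome_r2(a, b)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)


class TestSequenceIdentity:
    def test_identical_sequences(self):
        assert ea.sequence_identity("MKVLA", "MKVLA") == 100.0

    def test_single_mismatch(self):
        assert ea.sequence_identity("AAAA", "AAAT") == 75.0

    def test_random_pairs_match_dp_oracle(self):
        rng = np.random.default_rng(36)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(60):
            a = "".join(rng.choice(letters, size=rng.integers(5, 50)))
            b = "".join(rng.choice(letters, size=rng.integers(5, 50)))
            assert ea.sequence_identity(a, b) == pytest.approx(
                oracles.nw_identity_oracle(a, b), abs=1e-12)

    def test_alignment_score_is_globally_optimal(self):
        """The DP's score level agrees with an independent aligner."""
        aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                        mismatch_score=0, open_gap_score=-1,
                                        extend_gap_score=-1)
        rng = np.random.default_rng(37)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(30):
            a = "".join(rng.choice(letters, size=30))
            b = "".join(rng.choice(letters, size=30))
            # reconstruct the optimal score from the oracle triple
            from functools import lru_cache
            ident = oracles.nw_identity_oracle(a, b)
            assert ident >= 0  # sanity; score check below
            assert aligner.score(a, b) == pytest.approx(
                _dp_score(a, b), abs=1e-9)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ea.sequence_identity("", "AA")

    aa = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=20)

    @given(a=aa, b=aa)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_identity_is_symmetric_and_bounded(self, a, b):
        ident = ea.sequence_identity(a, b)
        assert 0.0 <= ident <= 100.0
        assert ident == pytest.approx(ea.sequence_identity(b, a), abs=1e-12)

    @given(a=aa)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_self_identity_is_100(self, a):
        assert ea.sequence_identity(a, a) == 100.0


def _dp_score(a, b, match=1.0, mismatch=0.0, gap=-1.0):
    """Score-only NW used to compare against Biopython."""
    prev = [j * gap for j in range(len(b) + 1)]
    for i in range(1, len(a) + 1):
        cur = [i * gap] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            diag = prev[j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            cur[j] = max(diag, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return prev[-1]


class TestLayerComparison:
    def _layer(self, labels, rng=None, constant=None):
        vals = _symmetric_frame(labels)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                v = constant if constant is not None else rng.normal()
                vals.loc[a, b] = vals.loc[b, a] = v
        return SimilarityMatrix(values=vals, kind="zscore")

    def test_identical_layers_spearman_one(self):
        rng = np.random.default_rng(38)
        labels = [f"c{i}" for i in range(6)]
        layer = self._layer(labels, rng)
        _, corr = ea.compare_similarity_layers({"x": layer, "y": layer})
        assert corr.loc["x", "y"] == pytest.approx(1.0)

    def test_independent_layers_mean_abs_spearman_small(self):
        labels = [f"c{i}" for i in range(15)]  # 105 pairs
        rhos = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            _, corr = ea.compare_similarity_layers(
                {"x": self._layer(labels, rng), "y": self._layer(labels, rng)})
            rhos.append(corr.loc["x", "y"])
        assert np.mean(np.abs(rhos)) < 0.1

    def test_constant_layer_gives_missing_not_zero(self):
        rng = np.random.default_rng(39)
        labels = [f"c{i}" for i in range(6)]
        _, corr = ea.compare_similarity_layers(
            {"x": self._layer(labels, rng), "y": self._layer(labels, constant=2.0)})
        assert np.isnan(corr.loc["x", "y"])

    def test_no_overlap_raises(self):
        l1 = self._layer(["a", "b"], np.random.default_rng(0))
        l2 = self._layer(["c", "d"], np.random.default_rng(0))
        with pytest.raises(ValueError):
            ea.compare_similarity_layers({"x": l1, "y": l2})


class TestEndToEndDiscrimination:
    def test_sharing_pairs_score_higher(self):
        """Pairs sharing half their targets (same sign) separate from
        non-sharing pairs in the z-score layer."""
        hits = 0
        n_seeds = 20  # the acceptance run uses 100
        for seed in range(n_seeds):
            z, sharing = _similarity_run(seed, n_proteins=400)
            tidy = z.pairs()
            key = tidy.apply(lambda r: frozenset((r.a, r.b)), axis=1)
            is_sharing = key.isin(sharing)
            mean_s = tidy.loc[is_sharing, "zscore"].mean()
            mean_o = tidy.loc[~is_sharing, "zscore"].mean()
            hits += int(mean_s > mean_o)
        assert hits >= int(0.95 * n_seeds)


def _similarity_run(seed, n_proteins=400):
    design = ea.default_design(n_proteins=n_proteins, n_batches=6,
                               conditions_per_batch=3)
    conds = design.conditions
    pairs = [(conds[0], conds[3]), (conds[6], conds[9]), (conds[12], conds[15])]
    truth = ea.shared_target_truth(design, pairs, n_regulated=40,
                                   shared_fraction=0.5, seed=seed)
    matrix, _ = ea.simulate_tmt_experiment(design, truth, noise_sd=0.3, seed=seed)
    calls = ea.modulation_calls(matrix, None)
    fc = pd.DataFrame({c: ea.protein_differential(matrix, c)["log2fc"]
                       for c in conds})
    _, score_m = ea.proteome_similarity(fc, calls)
    z = ea.batch_zscores(score_m, design.batch_of)
    return z, {frozenset(p) for p in pairs}
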