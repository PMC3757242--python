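"""Agreement statistics and permutation inference."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbcompare import (
    AgdexConfig,
    ExpressionStudy,
    OrthologPairSet,
    adaptive_permutation_pvalue,
    agreement_proportion,
    cosine_stat,
    diff_stat,
    dop_stat,
    geneset_agdex,
    match_pairs,
    permutation_pvalue,
)
from rbcompare.agdex import genomewide_agdex

from conftest import make_null_studies


class TestDiffStat:
    def test_mean_difference_arithmetic(self):
        mat = np.array([[5.0, 5.0, 2.0, 2.0], [1.0, 1.0, 1.0, 1.0]])
        s = ExpressionStudy(mat, ["g1", "g2"],
                            ["tumor", "tumor", "control", "control"])
        d = diff_stat(s)
        assert d["g1"] == pytest.approx(3.0)
        assert d["g2"] == pytest.approx(0.0)

    def test_group_size_validated(self):
        with pytest.raises(ValueError, match=">= 2 samples"):
            ExpressionStudy(np.zeros((1, 3)), ["g"],
                            ["tumor", "control", "control"])

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(3)
        delta, n_feat, n_t, n_c = 1.5, 400, 10, 10
        mat = rng.normal(0, 1, (n_feat, n_t + n_c))
        mat[:, :n_t] += delta
        s = ExpressionStudy(mat, [f"g{i}" for i in range(n_feat)],
                            ["tumor"] * n_t + ["control"] * n_c)
        d = diff_stat(s)
        se = np.sqrt((1 / n_t + 1 / n_c) / n_feat)
        assert abs(d.mean() - delta) <= 3 * se


class TestMatchPairs:
    def test_empty_and_order_contract(self):
        d1 = diff_stat(ExpressionStudy(np.arange(8.0).reshape(2, 4),
                                       ["a0", "a1"],
                                       ["tumor", "tumor", "control", "control"]))
        d2 = d1.rename({"a0": "b0", "a1": "b1"})
        x, y = match_pairs(d1, d2, OrthologPairSet([]))
        assert x.size == 0 and y.size == 0
        pairs = OrthologPairSet([("a1", "b0"), ("a0", "b1"), ("a1", "b1")])
        x, y = match_pairs(d1, d2, pairs)
        assert list(x) == [d1["a1"], d1["a0"], d1["a1"]]  # duplicates kept

    def test_unresolvable_ids_listed(self):
        d1 = diff_stat(ExpressionStudy(np.zeros((1, 4)), ["a0"],
                                       ["tumor", "tumor", "control", "control"]))
        with pytest.raises(KeyError, match="zz"):
            match_pairs(d1, d1, OrthologPairSet([("a0", "zz")]))


class TestStatistics:
    def test_cosine_hand_examples(self):
        x = np.array([1.0, 2.0])
        assert cosine_stat(x, x) == pytest.approx(1.0)
        assert cosine_stat(x, np.array([-2.0, 1.0])) == pytest.approx(0.0)
        assert cosine_stat(x, np.array([2.0, 1.0])) == pytest.approx(0.8)

    def test_cosine_zero_norm_errors(self):
        with pytest.raises(ZeroDivisionError):
            cosine_stat(np.array([0.0, 0.0]), np.array([1.0, 2.0]))

    def test_dop_enumeration_example(self):
        # sign pattern (+,+),(+,-),(-,-),(+,+): 3 concordant, 1 discordant
        x = np.array([1.0, 1.0, -1.0, 2.0])
        y = np.array([0.5, -1.0, -3.0, 1.0])
        assert dop_stat(x, y) == pytest.approx(0.5)
        assert agreement_proportion(x, y) == pytest.approx(0.75)

    def test_dop_identity_and_reflection(self):
        x = np.array([1.0, -2.0, 3.0])
        assert dop_stat(x, x) == pytest.approx(1.0)
        assert dop_stat(x, -x) == pytest.approx(-1.0)

    def test_dop_excludes_zero_pairs(self):
        x = np.array([1.0, 0.0, -1.0])
        y = np.array([1.0, 5.0, 1.0])
        # only pairs 0 and 2 count: one concordant, one discordant
        assert dop_stat(x, y) == pytest.approx(0.0)

    def test_dop_all_zero_pairs_errors(self):
        with pytest.raises(ZeroDivisionError):
            dop_stat(np.array([0.0, 1.0]), np.array([1.0, 0.0]))

    @given(
        st.lists(
            st.floats(min_value=-10, max_value=10).filter(lambda v: abs(v) > 1e-6),
            min_size=2, max_size=20,
        ),
        st.integers(0, 2**32 - 1),
        st.floats(min_value=0.1, max_value=50),
    )
    @settings(max_examples=60, derandomize=True)
    def test_agreement_identity_and_scale_invariance(self, xs, seed, scale):
        x = np.asarray(xs)
        rng = np.random.default_rng(seed)
        y = rng.normal(0, 1, x.size)
        y[y == 0] = 1.0
        assert agreement_proportion(x, y) == pytest.approx((dop_stat(x, y) + 1) / 2)
        assert dop_stat(scale * x, y) == pytest.approx(dop_stat(x, y))
        assert cosine_stat(scale * x, y) == pytest.approx(cosine_stat(x, y))


def _exact_permutation_p(study_perm, fixed_d, pairs, statistic, obs, side):
    """Full enumeration over label assignments of the permuted study."""
    from rbcompare.agdex import _STATS

    n = len(study_perm.sample_labels)
    n_t = sum(lab == "tumor" for lab in study_perm.sample_labels)
    idx_map = {f: i for i, f in enumerate(study_perm.feature_ids)}
    col = 0 if side == "A" else 1
    perm_idx = [idx_map[p[col]] for p in pairs.pairs]
    X = study_perm.matrix
    hits = total = 0
    for tumor_cols in itertools.combinations(range(n), n_t):
        mask = np.zeros(n, dtype=bool)
        mask[list(tumor_cols)] = True
        d = X[:, mask].mean(axis=1) - X[:, ~mask].mean(axis=1)
        dp = d[perm_idx]
        if side == "A":
            val = _STATS[statistic](dp, fixed_d)
        else:
            val = _STATS[statistic](fixed_d, dp)
        hits += abs(val) >= abs(obs) - 1e-12
        total += 1
    return hits / total


class TestPermutation:
    def test_pvalue_floor_and_determinism(self, tiny_pair_studies):
        sa, sb, pairs = tiny_pair_studies
        p1 = permutation_pvalue(sa, sb, pairs, "cosine", "A", B=500, rng=11)
        p2 = permutation_pvalue(sa, sb, pairs, "cosine", "A", B=500, rng=11)
        assert p1 == p2
        assert p1 >= 1 / 501

    @pytest.mark.parametrize("statistic", ["cosine", "dop"])
    @pytest.mark.parametrize("scheme", ["A", "B"])
    def test_matches_full_enumeration_oracle(self, tiny_pair_studies,
                                             statistic, scheme):
        """Monte-Carlo p within 3 SE of the exhaustive label-enumeration p."""
        sa, sb, pairs = tiny_pair_studies
        da, db = diff_stat(sa), diff_stat(sb)
        x, y = match_pairs(da, db, pairs)
        from rbcompare.agdex import _STATS

        obs = _STATS[statistic](x, y)
        perm_study = sa if scheme == "A" else sb
        fixed = (y if scheme == "A" else x)
        exact = _exact_permutation_p(perm_study, fixed, pairs, statistic, obs,
                                     scheme)
        B = 4000
        mc = permutation_pvalue(sa, sb, pairs, statistic, scheme, B=B, rng=2)
        se = np.sqrt(max(exact * (1 - exact), 1e-6) / B)
        assert abs(mc - exact) <= 3 * se + 2 / B

    def test_null_type_one_error_calibrated(self):
        """Permutation p is ~uniform under the null: alpha=0.05 holds.

        Groups of 5v5 keep the exact permutation distribution fine enough
        (C(10,5)=252 assignments) for p <= 0.05 to be attainable.
        """
        rng = np.random.default_rng(42)
        alpha, n_rep, B = 0.05, 200, 199
        hits = 0
        for rep in range(n_rep):
            sa, sb, pairs = make_null_studies(rng, n_features=8,
                                              n_a=(5, 5), n_b=(5, 5))
            p = permutation_pvalue(sa, sb, pairs, "cosine", "A", B=B,
                                   rng=int(rng.integers(2**31)))
            hits += p <= alpha
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(hits / n_rep - alpha) <= 3 * se


class TestAdaptivePermutation:
    def test_null_stops_at_bmin(self):
        rng = np.random.default_rng(0)
        sa, sb, pairs = make_null_studies(rng, n_features=10)
        cfg = AgdexConfig(B_min=100, B_max=5000)
        p, b_used = adaptive_permutation_pvalue(sa, sb, pairs, "cosine", "A",
                                                cfg, rng=1)
        assert b_used == 100
        assert p >= 1 / (5000 + 1)

    def test_strong_signal_runs_to_bmax(self):
        rng = np.random.default_rng(5)
        n = 40
        ids_a = [f"a{i}" for i in range(n)]
        ids_b = [f"b{i}" for i in range(n)]
        shift = rng.choice([-3.0, 3.0], n)
        ma = rng.normal(0, 0.3, (n, 12)) + np.outer(shift, [1] * 6 + [0] * 6)
        mb = rng.normal(0, 0.3, (n, 12)) + np.outer(shift, [1] * 6 + [0] * 6)
        sa = ExpressionStudy(ma, ids_a, ["tumor"] * 6 + ["control"] * 6)
        sb = ExpressionStudy(mb, ids_b, ["tumor"] * 6 + ["control"] * 6)
        pairs = OrthologPairSet(list(zip(ids_a, ids_b)))
        cfg = AgdexConfig(B_min=100, B_max=800)
        p, b_used = adaptive_permutation_pvalue(sa, sb, pairs, "cosine", "A",
                                                cfg, rng=2)
        assert b_used == 800
        assert p <= 0.05
        assert p >= 1 / 801


class TestGenesetAgdex:
    def test_duplicate_set_names_rejected(self, tiny_pair_studies):
        sa, sb, pairs = tiny_pair_studies
        sets = {"s1": ["b0"], "s2": ["b1"]}
        # dict keys are unique by construction; simulate duplicates via list
        with pytest.raises(ValueError, match="duplicate"):
            geneset_agdex(sa, sb, pairs, _DupMap([("s", ["b0", "b1"]),
                                                  ("s", ["b2"])]))

    def test_small_sets_skipped_not_failed(self, tiny_pair_studies):
        sa, sb, pairs = tiny_pair_studies
        out = geneset_agdex(sa, sb, pairs, {"tiny": ["b0"]},
                            AgdexConfig(B_min=20, B_max=50), rng=0)
        assert list(out["status"]) == ["skipped"]
        assert not out["robust_significant"].iloc[0]

    def test_concordant_planted_set_flagged_significant(self):
        """A fully concordant planted set clears all four tests at 0.01.

        Effects are moderate (2-fold) on purpose: when planted shifts dwarf
        the noise, label permutations that partially overlap the true
        grouping retain near-perfect sign concordance and put a floor under
        the dop permutation p-value.
        """
        from rbcompare.synthetic import SimConfig, gen_expression_pair

        cfg = SimConfig(seed=10, n_features_m=30, n_features_h=30,
                        de_fraction=1.0, concordance_rate=1.0,
                        effect_size=1.2, n_epi_genes=0)
        sa, sb, pairs, _ = gen_expression_pair(cfg)
        acfg = AgdexConfig(B_min=100, B_max=2000, alpha=0.01)
        out = geneset_agdex(sa, sb, pairs,
                            {"planted": [b for _, b in pairs.pairs]},
                            acfg, rng=3)
        assert bool(out["robust_significant"].iloc[0])

    def test_genomewide_summary_fields(self, tiny_pair_studies):
        sa, sb, pairs = tiny_pair_studies
        out = genomewide_agdex(sa, sb, pairs, B=99, rng=0)
        assert out["n_pairs"] == 6
        assert -1 <= out["cosine"] <= 1 and -1 <= out["dop"] <= 1
        for k in ("p_cosine_permA", "p_cosine_permB", "p_dop_permA",
                  "p_dop_permB"):
            assert 1 / 100 <= out[k] <= 1


class _DupMap:
    """Mapping with duplicate keys, to exercise the name-collision check."""

    def __init__(self, items):
        self._items = items

    def __iter__(self):
        return (k for k, _ in self._items)

    def __getitem__(self, key):
        for k, v in self._items:
            if k == key:
                return v
        raise KeyError(key)
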