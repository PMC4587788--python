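import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cagesurv as cs
from cagesurv.crossval import (
    CrossvalError,
    adjust_observed,
    make_folds,
    predict_phenotypes,
    rank_correlation,
    rank_with_censoring,
)


class TestFolds:
    def _cages(self, n, n_classes=2):
        return pd.DataFrame(
            {
                "cage": np.arange(1, n + 1),
                "class_id": [f"k{i % n_classes}" for i in range(n)],
                "member1": np.arange(1, n + 1) * 10,
            }
        )

    def test_balanced_counts(self):
        plan = make_folds(self._cages(10), k=5, seed=0)
        counts = plan.assignment["fold"].value_counts()
        assert (counts == 2).all()

    def test_deterministic(self):
        a = make_folds(self._cages(23), k=5, seed=9).assignment
        b = make_folds(self._cages(23), k=5, seed=9).assignment
        assert a.equals(b)

    def test_every_class_in_every_training_set(self):
        cages = self._cages(25, n_classes=5)
        plan = make_folds(cages, k=5, seed=3)
        merged = cages.merge(plan.assignment, on="cage")
        for f in range(1, 6):
            assert set(merged.loc[merged["fold"] != f, "class_id"]) == set(
                cages["class_id"]
            )

    def test_single_cage_class_rejected(self):
        cages = self._cages(9)
        cages.loc[0, "class_id"] = "lonely"
        with pytest.raises(CrossvalError, match="lonely"):
            make_folds(cages, k=3, seed=0)

    def test_fold_frequencies_uniform(self):
        """Over many seeds each cage visits each fold ~uniformly."""
        cages = self._cages(15, n_classes=3)
        n_seeds = 300
        hits = np.zeros((15, 5))
        for s in range(n_seeds):
            f = make_folds(cages, k=5, seed=s).assignment["fold"].to_numpy()
            hits[np.arange(15), f - 1] += 1
        p = 1 / 5
        se = np.sqrt(p * (1 - p) / n_seeds)
        assert np.abs(hits / n_seeds - p).max() < 4 * se


class TestAdjustObserved:
    def test_single_class_centered(self):
        days = pd.DataFrame(
            {
                "id": [1, 2, 3],
                "class_id": ["a"] * 3,
                "days": [100.0, 200.0, 300.0],
                "censored": [False] * 3,
            }
        )
        adj = adjust_observed(days)
        assert np.allclose(adj.to_numpy(), [-100.0, 0.0, 100.0])

    def test_residuals_sum_to_zero_per_class(self):
        rng = np.random.default_rng(0)
        days = pd.DataFrame(
            {
                "id": np.arange(40),
                "class_id": ["a", "b"] * 20,
                "days": 300 + 50 * rng.standard_normal(40),
                "censored": [False] * 40,
            }
        )
        adj = adjust_observed(days)
        frame = days.set_index("id").loc[adj.index]
        for c, grp in adj.groupby(frame["class_id"].to_numpy()):
            assert abs(grp.sum()) < 1e-9

    def test_two_class_hand_computation(self):
        """Six records, two classes: residuals match hand OLS."""
        days = pd.DataFrame(
            {
                "id": [1, 2, 3, 4, 5, 6],
                "class_id": ["a", "a", "a", "b", "b", "b"],
                "days": [100.0, 150.0, 200.0, 300.0, 310.0, 350.0],
                "censored": [False] * 6,
            }
        )
        adj = adjust_observed(days)
        # class means: a = 150, b = 320
        assert np.allclose(
            adj.to_numpy(), [-50.0, 0.0, 50.0, -20.0, -10.0, 30.0]
        )

    def test_censored_records_never_adjusted(self):
        days = pd.DataFrame(
            {
                "id": [1, 2],
                "class_id": ["a", "a"],
                "days": [100.0, 416.0],
                "censored": [False, True],
            }
        )
        adj = adjust_observed(days)
        assert list(adj.index) == [1]


class TestCensoredRanks:
    def test_printed_example_five_of_ten(self):
        """5 censored among 10 -> shared rank (6+7+8+9+10)/5 = 8."""
        adjusted = pd.Series([3.0, 1.0, 4.0, 2.0, 5.0], index=[1, 2, 3, 4, 5])
        ranks = rank_with_censoring(adjusted, censored_ids=[6, 7, 8, 9, 10])
        for c in (6, 7, 8, 9, 10):
            assert ranks.loc[c] == 8.0
        assert ranks.loc[2] == 1.0 and ranks.loc[5] == 5.0

    def test_no_censoring_ordinary_ranks(self):
        adjusted = pd.Series([10.0, 30.0, 20.0], index=[1, 2, 3])
        ranks = rank_with_censoring(adjusted, [])
        assert list(ranks.loc[[1, 2, 3]]) == [1.0, 3.0, 2.0]

    def test_all_censored(self):
        ranks = rank_with_censoring(pd.Series(dtype=float), [1, 2, 3])
        assert np.allclose(ranks.to_numpy(), 2.0)  # (k+1)/2

    @given(st.permutations(list(range(5))))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_censored_order(self, perm):
        adjusted = pd.Series([1.0, 2.0], index=[100, 101])
        base = rank_with_censoring(adjusted, censored_ids=[0, 1, 2, 3, 4])
        shuffled = rank_with_censoring(
            adjusted, censored_ids=[perm[i] for i in range(5)]
        )
        assert base.sort_index().equals(shuffled.sort_index())


class TestPredictedPhenotypes:
    def _fit(self, d, i_, levels, pedigree):
        return cs.FitResult(
            components=cs.VarianceComponents(),
            solutions={"genetic_d": d, "genetic_i": i_},
            loglik=0.0, converged=True, n_iter=0, gradient_norm=0.0,
            se_components=None, genetic_levels=np.asarray(levels),
            genetic_pedigree=pedigree, fixed_names=[],
            spec=cs.ModelSpec("STM"),
        )

    def test_toy_arithmetic(self, fullsib_pedigree):
        """own DGE 3 plus mate IGEs 1, -2, 0.5 -> predicted 2.5."""
        ped = cs.Pedigree.from_records(
            [(k, 0, 0, 0, "F") for k in (1, 2, 3, 4)]
        )
        fit = self._fit(
            np.array([3.0, 0.0, 0.0, 0.0]),
            np.array([0.0, 1.0, -2.0, 0.5]),
            [1, 2, 3, 4],
            ped,
        )
        pred = predict_phenotypes(fit, [1], {1: (2, 3, 4)}, ped)
        assert pred.loc[1] == pytest.approx(2.5)

    def test_zero_ige_ranks_by_dge(self):
        ped = cs.Pedigree.from_records(
            [(k, 0, 0, 0, "F") for k in (1, 2, 3, 4)]
        )
        d = np.array([0.4, -1.0, 2.0, 0.1])
        fit = self._fit(d, np.zeros(4), [1, 2, 3, 4], ped)
        mates = {k: tuple(j for j in (1, 2, 3, 4) if j != k) for k in (1, 2, 3, 4)}
        pred = predict_phenotypes(fit, [1, 2, 3, 4], mates, ped)
        assert list(pred.rank().loc[[1, 2, 3, 4]]) == list(
            pd.Series(d, index=[1, 2, 3, 4]).rank()
        )


class TestRankCorrelation:
    def _pairs(self, obs, pred):
        rows = []
        for f, (o, p) in enumerate(zip(obs, pred), start=1):
            for oo, pp in zip(o, p):
                rows.append(dict(id=0, fold=f, obs_rank=oo, pred_rank=pp,
                                 censored=False))
        return pd.DataFrame(rows)

    def test_perfect(self):
        pairs = self._pairs(
            [[1, 2, 3, 4], [1, 2, 3]], [[1, 2, 3, 4], [1, 2, 3]]
        )
        r, se, per = rank_correlation(pairs)
        assert r == pytest.approx(1.0)

    def test_reversed(self):
        pairs = self._pairs(
            [[1, 2, 3, 4], [1, 2, 3]], [[4, 3, 2, 1], [3, 2, 1]]
        )
        r, _, _ = rank_correlation(pairs)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_fold_centred(self):
        obs = [[1, 2, 3, 4, 5], [1, 2, 3, 4, 5]]
        pred = [[2, 1, 3, 5, 4], [1, 2, 3, 4, 5]]
        pairs = self._pairs(obs, pred)
        r, se, per = rank_correlation(pairs)
        xs = np.concatenate([np.array(o) - 3.0 for o in obs])
        ys = np.concatenate([np.array(p) - 3.0 for p in pred])
        hand = np.mean(xs * ys) / (xs.std() * ys.std())
        assert r == pytest.approx(hand)
        assert per[1] == pytest.approx(1.0)

    def test_needs_two_folds(self):
        pairs = self._pairs([[1, 2, 3]], [[1, 2, 3]])
        with pytest.raises(CrossvalError):
            rank_correlation(pairs)


class TestAccuracyAlgebra:
    def test_sqrt_r2_w1(self):
        """Table-1 W1 inputs give the printed upper bound 0.31."""
        assert cs.sqrt_r2(28.0**2, 10.0**2, 107.0**2, n=4) == pytest.approx(
            0.31, abs=0.005
        )

    def test_sqrt_r2_wb(self):
        assert cs.sqrt_r2(41.0**2, 16.0**2, 135.0**2, n=4) == pytest.approx(
            0.37, abs=0.005
        )

    def test_sqrt_r2_zero_genetics(self):
        assert cs.sqrt_r2(0.0, 0.0, 100.0) == 0.0

    def test_accuracy_printed_value(self):
        """0.135 divided by the un-rounded bound gives 0.44."""
        bound = cs.sqrt_r2(28.0**2, 10.0**2, 107.0**2, n=4)
        assert cs.approx_accuracy(0.135, bound) == pytest.approx(0.44, abs=0.005)

    def test_accuracy_at_bound_is_one(self):
        assert cs.approx_accuracy(0.31, 0.31) == 1.0

    def test_second_printed_accuracy(self):
        bound = cs.sqrt_r2(28.0**2, 10.0**2, 107.0**2, n=4)
        assert cs.approx_accuracy(0.162, bound) == pytest.approx(0.53, abs=0.005)

    def test_zero_bound_rejected(self):
        with pytest.raises(CrossvalError):
            cs.approx_accuracy(0.1, 0.0)


def test_accuracy_increases_with_training_data():
    """EBV prediction quality for held-out cages rises with the share of
    cages whose phenotypes are available (25 % -> 50 % -> 100 %).

    Predictions are scored against the true simulated breeding-value
    combination (own DGE + mates' IGE), which removes phenotype noise from
    the criterion; every cage serves as validation once per fraction (full
    5-fold rotation).  The means over replicates must be monotone and the
    25-vs-100 % contrast significant in a paired one-sided test."""
    import cagesurv as cs
    from scipy import stats
    from cagesurv.modelspec import ModelSpec, build_design
    from cagesurv.crossval import _remove_cages
    from cagesurv.mme import reml_fit
    from conftest import days_only_table

    fractions = (0.25, 0.5, 1.0)
    res = {f: [] for f in fractions}
    for rep in range(10):
        cfg = cs.SimConfig(
            n_sires=16, dams_per_sire=8, offspring_per_dam=5,
            n_generations=2, n_batches=1, layout=((2, 2),), seed=3000 + rep,
        )
        ped, cages = cs.generate_population(cfg)
        days, eff, _ = cs.simulate_gaussian_days(
            ped, cages, cs.GaussianConfig(), rng=3100 + rep
        )
        table = days_only_table(days)
        rng = np.random.default_rng(rep)
        cage_ids = [int(c) for c in cages["cage"]]
        member_cols = [c for c in cages.columns if c.startswith("member")]
        mates = {}
        for _, row in cages.iterrows():
            ms = [int(row[c]) for c in member_cols]
            for i in ms:
                mates[i] = tuple(j for j in ms if j != i)
        plan = make_folds(cages, k=5, seed=rep)
        all_ids = days["id"].to_numpy()
        idx = ped.index_of(all_ids)
        true_pred = pd.Series(
            eff[idx, 0]
            + [eff[ped.index_of(mates[int(i)]), 1].sum() for i in all_ids],
            index=all_ids,
        )
        for frac in fractions:
            if frac < 1:
                sub = set(
                    rng.choice(
                        cage_ids, size=int(len(cage_ids) * frac), replace=False
                    ).tolist()
                )
            else:
                sub = set(cage_ids)
            avail = _remove_cages(table, set(cage_ids) - sub)
            full = cs.fit_model(
                avail, ped, cs.ModelSpec("STM"), tol=1e-6, max_iter=40
            )
            preds = {}
            for f in range(1, 6):
                vc = set(int(c) for c in plan.validation_cages(f))
                training = _remove_cages(table, (set(cage_ids) - sub) | vc)
                bundle = build_design(ModelSpec("STM"), training, ped)
                ff = reml_fit(bundle, start=full.components, max_iter=0)
                vids = [
                    int(x)
                    for x in cages.loc[
                        cages.cage.isin(vc), member_cols
                    ].to_numpy().ravel()
                ]
                preds.update(predict_phenotypes(ff, vids, mates, ped).to_dict())
            pr = pd.Series(preds)
            r = stats.spearmanr(true_pred.loc[pr.index], pr).statistic
            res[frac].append(float(r))
    means = {f: float(np.mean(res[f])) for f in fractions}
    assert means[0.25] < means[0.5] < means[1.0], means
    for f in fractions:
        assert all(-0.2 < v <= 1.0 for v in res[f])
    diff = np.asarray(res[1.0]) - np.asarray(res[0.25])
    t = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
    p = 1.0 - stats.t.cdf(t, df=len(diff) - 1)
    assert p < 0.05, (means, p)


def test_run_crossval_end_to_end(small_sim):
    """CV pipeline produces finite fold-stratified correlations and ranks
    forming a permutation (with censored ties) within each fold."""
    res = cs.run_crossval(
        small_sim["table"],
        small_sim["pedigree"],
        cs.ModelSpec("STM"),
        small_sim["cages"],
        seed=2,
        reml_kw=dict(tol=1e-6, max_iter=40),
    )
    assert np.isfinite(res.correlation)
    assert len(res.per_fold) == 5
    for f, sub in res.pairs.groupby("fold"):
        k = len(sub)
        assert sub["obs_rank"].max() <= k
        assert sub["obs_rank"].min() >= 1
        cen = sub[sub["censored"]]
        if len(cen):
            assert cen["obs_rank"].nunique() == 1
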