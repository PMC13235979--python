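import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from puprev import (
    ClassifierConfig,
    SyntheticConfig,
    estimate_alpha_scar,
    estimate_densities,
    fit_pu_scores,
    generate_cohort,
    make_partition_plan,
    pulscar,
)
from puprev.pu_alpha import ScoreSet


class TestPartitionPlan:
    def test_exact_division(self):
        plan = make_partition_plan(100, np.arange(1000), seed=0)
        assert plan.k == 10
        assert all(len(p) == 100 for p in plan.partition_ids)

    def test_paper_scale_k(self):
        # floor(1,304,495 / 24,625) = 52
        plan = make_partition_plan(24_625, np.arange(1_304_495), seed=0)
        assert plan.k == 52

    def test_remainder_absorbed_by_last(self):
        plan = make_partition_plan(100, np.arange(150), seed=0)
        assert plan.k == 1
        assert len(plan.partition_ids[0]) == 150

    def test_disjoint_cover(self):
        ids = np.arange(757)
        plan = make_partition_plan(70, ids, seed=3)
        seen = np.concatenate(plan.partition_ids)
        assert len(seen) == len(ids)
        assert set(seen) == set(ids)

    def test_deterministic(self):
        a = make_partition_plan(50, np.arange(500), seed=5)
        b = make_partition_plan(50, np.arange(500), seed=5)
        for pa, pb in zip(a.partition_ids, b.partition_ids):
            assert np.array_equal(pa, pb)

    def test_too_few_unlabeled_errors(self):
        with pytest.raises(ValueError, match="k=0"):
            make_partition_plan(100, np.arange(99), seed=0)


def _balanced_from(ds, seed=0):
    pos = np.flatnonzero(ds.labels == 1)
    unl = np.flatnonzero(ds.labels == 0)
    plan = make_partition_plan(len(pos), unl, seed)
    return ds.take(np.concatenate([pos, plan.partition_ids[0]]))


class TestFitPUScores:
    def test_separable_scores_ordered(self, scar_cohort, fast_clf):
        bal = _balanced_from(scar_cohort)
        scores = fit_pu_scores(bal, fast_clf, seed=0)
        assert scores.scores_P.mean() > scores.scores_U.mean()

    def test_scores_clipped_and_finite(self, scar_cohort, fast_clf):
        bal = _balanced_from(scar_cohort)
        s = fit_pu_scores(bal, fast_clf, seed=0)
        alls = np.concatenate([s.scores_P, s.scores_U])
        assert np.all(alls >= 1e-6) and np.all(alls <= 1 - 1e-6)

    def test_shuffled_labels_auc_near_half(self, scar_cohort, fast_clf):
        bal = _balanced_from(scar_cohort)
        rng = np.random.default_rng(1)
        bal.labels = rng.permutation(bal.labels)
        bal.latent_status = None
        s = fit_pu_scores(bal, fast_clf, seed=1)
        y = np.concatenate([np.ones_like(s.scores_P), np.zeros_like(s.scores_U)])
        auc = roc_auc_score(y, np.concatenate([s.scores_P, s.scores_U]))
        n_p, n_u = len(s.scores_P), len(s.scores_U)
        null_sd = np.sqrt((n_p + n_u + 1) / (12 * n_p * n_u))
        assert abs(auc - 0.5) <= 4 * null_sd

    def test_identical_rows_give_base_rate(self, fast_clf):
        import scipy.sparse as sp

        from puprev import PUDataset

        n = 200
        feats = sp.csr_matrix(np.ones((n, 5), dtype=np.int8))
        labels = np.zeros(n, dtype=np.int8)
        labels[: n // 2] = 1
        ds = PUDataset(
            features=feats,
            labels=labels,
            record_ids=np.array([str(i) for i in range(n)]),
            covariate_ids=np.array([f"c{j}" for j in range(5)]),
        )
        s = fit_pu_scores(ds, fast_clf, seed=0)
        alls = np.concatenate([s.scores_P, s.scores_U])
        assert np.all(np.abs(alls - 0.5) < 0.05)

    def test_out_of_fold_contract(self, scar_cohort, fast_clf):
        bal = _balanced_from(scar_cohort)
        s = fit_pu_scores(bal, fast_clf, v_folds=3, seed=0)
        assert len(np.unique(s.fold_map)) == 3
        assert len(s.fold_map) == bal.n_records

    def test_v_folds_too_small(self, scar_cohort, fast_clf):
        bal = _balanced_from(scar_cohort)
        with pytest.raises(ValueError, match="v_folds"):
            fit_pu_scores(bal, fast_clf, v_folds=1, seed=0)


def _score_set(s_p, s_u):
    return ScoreSet(scores_P=np.asarray(s_p), scores_U=np.asarray(s_u),
                    fold_map=np.zeros(len(s_p) + len(s_u), dtype=int))


class TestEstimateDensities:
    def test_same_multiset_gives_equal_densities(self, rng):
        s = rng.random(500)
        d = estimate_densities(_score_set(s, s.copy()))
        assert np.array_equal(d.f_P, d.f_U)

    def test_uniform_scores_flat_density(self, rng):
        n = 5000
        d = estimate_densities(_score_set(rng.random(n), rng.random(n)), n_bins=10)
        se = np.sqrt(0.1 * 0.9 / n) / 0.1
        assert np.all(np.abs(d.f_P - 1.0) <= 3 * se)
        assert np.all(np.abs(d.f_U - 1.0) <= 3 * se)

    def test_single_bin_concentration(self, rng):
        s = np.full(100, 0.505)
        u = rng.random(100)
        d = estimate_densities(_score_set(s, u), n_bins=10)
        assert np.isclose(d.f_P.max(), 10.0)
        assert np.count_nonzero(d.f_P) == 1

    def test_density_integrates_to_one(self, rng):
        d = estimate_densities(_score_set(rng.random(400), rng.beta(2, 5, 400)))
        w = d.grid[1] - d.grid[0]
        assert np.isclose(d.f_P.sum() * w, 1.0, atol=1e-6)
        assert np.isclose(d.f_U.sum() * w, 1.0, atol=1e-6)

    def test_requires_30_scores(self, rng):
        with pytest.raises(ValueError, match="30"):
            estimate_densities(_score_set(rng.random(10), rng.random(100)))

    def test_too_few_nonempty_bins(self):
        s = np.full(100, 0.5)
        with pytest.raises(ValueError, match="nonempty"):
            estimate_densities(_score_set(s, s), n_bins=10)


class TestEstimateAlphaSCAR:
    def test_identical_arms_alpha_one(self, rng):
        s = rng.beta(5, 2, 2000)
        d = estimate_densities(_score_set(s, s.copy()))
        assert estimate_alpha_scar(d) == 1.0

    def test_disjoint_supports_alpha_near_zero(self, rng):
        s_p = 0.8 + 0.19 * rng.random(2000)
        s_u = 0.01 + 0.19 * rng.random(2000)
        d = estimate_densities(_score_set(s_p, s_u))
        assert estimate_alpha_scar(d) <= 0.05

    def test_beta_mixture_oracle(self):
        # closed-form density-ratio oracle: min_s f_U/f_P = 0.3 because
        # Beta(2,8)/Beta(8,2) -> 0 as s -> 1
        for seed in range(3):
            rng = np.random.default_rng(seed)
            s_p = rng.beta(8, 2, 10000)
            n1 = rng.binomial(10000, 0.3)
            s_u = np.concatenate([rng.beta(8, 2, n1), rng.beta(2, 8, 10000 - n1)])
            d = estimate_densities(_score_set(s_p, s_u))
            assert 0.25 <= estimate_alpha_scar(d) <= 0.35

    def test_alpha_clipped_to_unit_interval(self, rng):
        s_p = rng.beta(2, 8, 1000)
        s_u = rng.beta(8, 2, 1000)
        d = estimate_densities(_score_set(s_p, s_u))
        assert 0.0 <= estimate_alpha_scar(d) <= 1.0


class TestPulscar:
    def test_scar_recovery_small(self, scar_cohort, fast_clf):
        est, _ = pulscar(scar_cohort, fast_clf, seed=0)
        truth = (scar_cohort.latent_status[scar_cohort.labels == 0]).mean()
        assert abs(est.alpha - truth) <= 0.07

    def test_every_record_scored(self, scar_cohort, fast_clf):
        est, raw = pulscar(scar_cohort, fast_clf, seed=0, max_partitions=1)
        assert raw.shape == (scar_cohort.n_records,)
        assert np.all(np.isfinite(raw))
        assert np.all((raw > 0) & (raw < 1))

    def test_mean_of_partitions_identity(self, scar_cohort, fast_clf):
        est, _ = pulscar(scar_cohort, fast_clf, seed=0)
        assert abs(est.alpha - np.mean(est.per_partition)) < 1e-12
        assert 0.0 <= est.alpha <= 1.0

    def test_zero_positive_unlabeled_set(self, fast_clf):
        # coded_fraction=1: every latent positive is labeled, U is pure negative
        cfg = SyntheticConfig(
            n_records=3000, n_covariates=100, true_alpha=0.25,
            coded_fraction=1.0, n_informative=25, baseline_rate=0.02,
            lift=25, seed=2,
        )
        ds = generate_cohort(cfg)
        est, _ = pulscar(ds, fast_clf, seed=2, max_partitions=2)
        assert est.alpha <= 0.05

    def test_k_one_degenerate(self, fast_clf):
        cfg = SyntheticConfig(
            n_records=1200, n_covariates=60, true_alpha=0.5,
            coded_fraction=0.85, n_informative=20, baseline_rate=0.02,
            lift=25, seed=4,
        )
        ds = generate_cohort(cfg)
        assert (ds.labels == 0).sum() // (ds.labels == 1).sum() == 1
        est, _ = pulscar(ds, fast_clf, seed=0)
        assert len(est.per_partition) == 1
        assert est.per_partition[0] == est.alpha

    def test_seed_determinism(self, scar_cohort, fast_clf):
        e1, r1 = pulscar(scar_cohort, fast_clf, seed=3, max_partitions=1)
        e2, r2 = pulscar(scar_cohort, fast_clf, seed=3, max_partitions=1)
        assert e1.alpha == e2.alpha
        assert np.array_equal(r1, r2)
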