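import numpy as np
import pandas as pd
import pytest
from scipy.linalg import orthogonal_procrustes, subspace_angles

from jointomics import (
    FeatureTable,
    JointRPCA,
    RobustPCA,
    cross_correlations,
    joint_complete,
    joint_factorize,
    permanova,
    rpca,
    select_features_by_loading,
)
from jointomics import projection_holdout_error
from jointomics.joint import project_samples


def paired_masked_tables(n=120, p1=40, p2=50, r=2, dropout=0.3, seed=0, noise=0.05):
    """Two NaN-masked tables sharing the same n x r sample factors."""
    rng = np.random.default_rng(seed)
    F = rng.normal(size=(n, r))
    mats = []
    for p in (p1, p2):
        L = rng.normal(size=(p, r))
        M = F @ L.T + rng.normal(scale=noise, size=(n, p))
        mask = rng.random((n, p)) >= dropout
        mats.append(np.where(mask, M, np.nan))
    return mats, F


def tables_from_counts(counts_list, sample_ids=None):
    out = []
    for k, c in enumerate(counts_list):
        idx = sample_ids or [f"s{i}" for i in range(c.shape[0])]
        cols = [f"t{k}f{j}" for j in range(c.shape[1])]
        out.append(FeatureTable(pd.DataFrame(c, index=idx, columns=cols)))
    return out


class TestJointComplete:
    def test_recovers_shared_subspace(self):
        mats, F = paired_masked_tables(seed=1)
        U, sig, Vs, losses = joint_complete(mats, rank=2, tol=1e-10)
        angle = np.degrees(subspace_angles(U, F)).max()
        assert angle < 10.0

    def test_monotone_joint_objective(self):
        mats, _ = paired_masked_tables(seed=2, noise=0.3)
        _, _, _, losses = joint_complete(mats, rank=2, tol=1e-14, max_iter=80)
        assert (np.diff(losses) <= 1e-10).all()

    def test_structure_of_factors(self):
        mats, _ = paired_masked_tables(seed=3)
        U, sig, Vs, _ = joint_complete(mats, rank=2)
        assert np.allclose(U.T @ U, np.eye(2), atol=1e-8)
        W = np.vstack(Vs)
        assert np.allclose(W.T @ W, np.eye(2), atol=1e-8)
        assert (np.diff(sig) <= 1e-12).all() and (sig >= 0).all()

    def test_sample_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same number of samples"):
            joint_complete([np.ones((4, 3)), np.ones((5, 3))], rank=1)


class TestJointRPCA:
    def test_train_test_split_sizes(self, small_cohort):
        mic, met, _, _ = small_cohort
        est = JointRPCA(rank=2, n_splits=1, train_fraction=0.8, seed=0)
        n = mic.shape[0]
        # 45 samples -> exactly 36 train / 9 test
        rng = np.random.default_rng(0)
        n_train = int(round(0.8 * n))
        assert n_train == 36 and n - n_train == 9
        est.fit([mic, met])
        assert est.cv_test_error_.shape == (1,)

    def test_single_table_equals_rpca_up_to_rotation(self, small_cohort):
        mic = small_cohort[0]
        ordn, _ = rpca(mic, rank=2, seed=0)
        jf = joint_factorize([mic], rank=2, seed=0, n_splits=2)
        A = ordn.samples.to_numpy()
        B = (jf.shared_U * jf.singular_values).to_numpy()
        R, _ = orthogonal_procrustes(B, A)
        assert np.linalg.norm(B @ R - A) < 1e-6

    def test_mismatched_sample_ids_rejected(self, small_cohort):
        mic, met, _, _ = small_cohort
        shuffled = FeatureTable(met.data.iloc[::-1], kind="intensities")
        with pytest.raises(ValueError, match="identical sample ids"):
            joint_factorize([mic, shuffled], rank=2)

    def test_unrelated_tables_do_not_beat_mean_baseline(self):
        # shared structure is measured by cross-omic transfer: project test
        # samples from the microbe-like table's entries alone and score the
        # reconstruction of the metabolite-like table.  Permuting the second
        # table's samples destroys the sharing, so the transfer does no
        # better than the column-mean baseline (which predicts 0 after
        # centering); intact pairing transfers strongly.
        rng = np.random.default_rng(42)
        reps = 20
        near_baseline = 0

        def cross_table_sse(mats, rank):
            n = mats[0].shape[0]
            tr, te = slice(0, int(0.8 * n)), slice(int(0.8 * n), n)
            tr_mats = [M[tr] for M in mats]
            mu = [np.nanmean(M, axis=0, keepdims=True) for M in tr_mats]
            tr_c = [M - m for M, m in zip(tr_mats, mu)]
            _, sig, Vs, _ = joint_complete(tr_c, rank=rank, tol=1e-9)
            te_c = [M[te] - m for M, m in zip(mats, mu)]
            # project from table 0 only
            blank = np.full_like(te_c[1], np.nan)
            Ute = project_samples([te_c[0], blank], Vs, sig)
            mask = ~np.isnan(te_c[1])
            R = (Ute @ (Vs[1] * sig).T - np.where(mask, te_c[1], 0.0)) * mask
            return (R**2).sum(), np.nansum(te_c[1][mask] ** 2)

        for rep in range(reps):
            mats, _ = paired_masked_tables(
                n=40, p1=25, p2=25, seed=100 + rep, noise=0.1
            )
            permuted = [mats[0], mats[1][rng.permutation(40)]]
            sse_perm, base = cross_table_sse(permuted, rank=2)
            if sse_perm >= 0.8 * base:
                near_baseline += 1
            sse_true, base_true = cross_table_sse(mats, rank=2)
            assert sse_true < 0.5 * base_true
        assert near_baseline >= 0.9 * reps

    def test_rank_sweep_minimizes_cv_error_near_truth(self):
        # projection holdout error scores entries held out from the
        # projection, so over a rank sweep it has a real minimum at the
        # planted rank (the rclr / column-centering preprocessing of real
        # tables adds its own weak predictable components, so this is a
        # solver-level property on masked matrices)
        true_r = 2
        hits = 0
        reps = 20
        for rep in range(reps):
            mats, _ = paired_masked_tables(
                n=80, p1=30, p2=30, r=true_r, seed=200 + rep, noise=0.15
            )
            rng = np.random.default_rng(rep)
            errs = {r: 0.0 for r in range(1, 6)}
            for _ in range(3):
                perm = rng.permutation(80)
                tr, te = np.sort(perm[:64]), np.sort(perm[64:])
                trc = [M[tr] for M in mats]
                tec = [M[te] for M in mats]
                for r in errs:
                    _, sig, Vs, _ = joint_complete(trc, rank=r, tol=1e-8)
                    errs[r] += np.mean(
                        [
                            projection_holdout_error(tec, Vs, sig, seed=s)
                            for s in range(5)
                        ]
                    )
            best = min(errs, key=errs.get)
            hits += abs(best - true_r) <= 1
        assert hits >= 0.8 * reps


class TestRobustPCA:
    def test_duplicated_samples_at_zero_distance(self, toy_counts):
        dup = FeatureTable(
            pd.concat(
                [toy_counts.data,
                 toy_counts.data.set_axis([f"{s}_dup" for s in toy_counts.sample_ids])]
            ),
            kind="counts",
        )
        est = RobustPCA(rank=2, tol=1e-10).fit(dup)
        d = est.distance_matrix_
        for s in toy_counts.sample_ids:
            assert d[s, f"{s}_dup"] < 1e-6

    def test_distances_invariant_to_sample_scaling(self, toy_counts):
        scaled = FeatureTable(
            toy_counts.data.mul([3, 1, 7, 2], axis=0), kind="counts"
        )
        a = RobustPCA(rank=2, tol=1e-10).fit(toy_counts).distance_matrix_
        b = RobustPCA(rank=2, tol=1e-10).fit(scaled).distance_matrix_
        assert np.allclose(a.data, b.data, atol=1e-8)

    def test_two_planted_clusters_significant(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0.5, 2.0, size=40)
        logit = np.tile(np.log(base), (30, 1)) + rng.normal(0, 0.2, (30, 40))
        logit[15:, :8] += 2.0  # second cluster enriched in 8 features
        p = np.exp(logit)
        p /= p.sum(axis=1, keepdims=True)
        counts = np.vstack([rng.multinomial(3000, pi) for pi in p])
        t = tables_from_counts([counts])[0]
        _, dist = rpca(t, rank=2)
        groups = ["a"] * 15 + ["b"] * 15
        res = permanova(dist, groups, permutations=999, seed=1)
        assert res.p_value < 0.01

    def test_ordination_proportions(self, small_cohort):
        est = RobustPCA(rank=3).fit(small_cohort[0])
        pe = est.proportion_explained_
        assert pe.sum() <= 1 + 1e-9
        assert (pe >= 0).all() and (np.diff(pe) <= 1e-12).all()


class TestCrossCorrelations:
    def _fit(self, small_cohort, rank=2):
        mic, met, _, _ = small_cohort
        return joint_factorize([mic, met], rank=rank, n_splits=2, seed=0)

    def test_entries_bounded(self, small_cohort):
        C = cross_correlations(self._fit(small_cohort)).matrix.to_numpy()
        assert (np.abs(C) <= 1.0).all()

    def test_swapping_tables_transposes(self, small_cohort):
        jf = self._fit(small_cohort)
        a = cross_correlations(jf, 0, 1).matrix
        b = cross_correlations(jf, 1, 0).matrix
        assert np.array_equal(a.to_numpy(), b.to_numpy().T)

    def test_zero_loading_feature_gets_zero_row(self, small_cohort):
        jf = self._fit(small_cohort)
        jf.feature_loadings[0].iloc[3, :] = 0.0
        C = cross_correlations(jf).matrix
        assert (C.iloc[3, :] == 0).all()

    def test_single_table_rejected(self, small_cohort):
        jf = joint_factorize([small_cohort[0]], rank=2, n_splits=2)
        with pytest.raises(ValueError, match="2 tables"):
            cross_correlations(jf)

    def test_spearman_flag(self, small_cohort):
        C = cross_correlations(self._fit(small_cohort), method="spearman")
        assert C.method == "spearman"
        assert (np.abs(C.matrix.to_numpy()) <= 1.0).all()


def test_select_features_by_loading():
    s = pd.Series([0.9, -0.8, 0.1, 0.0, -0.2], index=list("abcde"))
    sel = select_features_by_loading(s, q=0.2)
    assert sel == ["a", "b"]
    with pytest.raises(ValueError):
        select_features_by_loading(s, q=0.7)
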