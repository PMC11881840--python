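import itertools

import numpy as np
import pandas as pd
import pytest

from jointomics import (
    LogRatioSeries,
    SampleMetadata,
    lme_trend,
    logratio_group_regression,
    pairwise_mannwhitney,
    permanova,
)


def random_distance(n, seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    np.fill_diagonal(d, 0.0)
    return d


def brute_force_permanova_p(D, groups):
    """Independent oracle: enumerate every ordering of the label vector and
    compute the pseudo-F from first principles."""
    groups = list(groups)
    n = len(groups)

    def F_direct(labels):
        labels = np.asarray(labels)
        uniq = sorted(set(labels.tolist()))
        k = len(uniq)
        sst = sum(D[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
        ssw = 0.0
        for g in uniq:
            idx = [i for i in range(n) if labels[i] == g]
            ssw += sum(
                D[i, j] ** 2 for i in idx for j in idx if i < j
            ) / len(idx)
        ssb = sst - ssw
        return (ssb / (k - 1)) / (ssw / (n - k))

    f_obs = F_direct(groups)
    seen = set()
    count = total = 0
    for perm in itertools.permutations(groups):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if F_direct(perm) >= f_obs - 1e-12:
            count += 1
    return f_obs, count / total


class TestPermanova:
    def test_exact_enumeration_matches_brute_force(self):
        D = random_distance(6, seed=1)
        groups = ["a", "a", "a", "b", "b", "b"]
        f_oracle, p_oracle = brute_force_permanova_p(D, groups)
        res = permanova(D, groups, exact=True)
        assert res.method == "exact-enumeration"
        assert res.permutations == 20  # C(6,3)
        assert res.pseudo_F == pytest.approx(f_oracle)
        assert res.p_value == pytest.approx(p_oracle)

    def test_scale_invariance_of_pseudo_f(self):
        D = random_distance(10, seed=2)
        groups = ["a"] * 5 + ["b"] * 5
        a = permanova(D, groups, permutations=99, seed=0)
        b = permanova(3.7 * D, groups, permutations=99, seed=0)
        assert a.pseudo_F == pytest.approx(b.pseudo_F)
        assert a.p_value == b.p_value

    def test_asymmetric_matrix_rejected(self):
        D = random_distance(6, seed=3)
        D[0, 1] += 1.0
        with pytest.raises(ValueError, match="symmetric"):
            permanova(D, ["a"] * 3 + ["b"] * 3)

    def test_degenerate_groups_rejected(self):
        D = random_distance(4, seed=4)
        with pytest.raises(ValueError, match=">=2 groups"):
            permanova(D, ["a", "a", "a", "b"])

    def test_p_value_floor(self):
        D = random_distance(12, seed=5)
        D[:6] += 5.0
        D[:, :6] += 5.0
        D[:6, :6] -= 10.0
        np.fill_diagonal(D, 0.0)
        D = np.abs((D + D.T) / 2)
        np.fill_diagonal(D, 0.0)
        res = permanova(D, ["a"] * 6 + ["b"] * 6, permutations=99, seed=1)
        assert res.p_value >= 1 / 100

    def test_matches_skbio_statistic(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        D = random_distance(12, seed=6)
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        ours = permanova(D, groups, permutations=999, seed=0)
        theirs = skbio_permanova(
            DistanceMatrix(D, ids=[str(i) for i in range(12)]),
            grouping=groups,
            permutations=999,
        )
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-10)
        assert abs(ours.p_value - theirs["p-value"]) < 0.05


def mw_enumeration_p(x, y):
    """Exact two-sided p by enumerating all label assignments (oracle)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    M = n1 * len(y)

    def u_stat(xs, ys):
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in xs for yi in ys)

    u_obs = u_stat(x, y)
    lo, hi = min(u_obs, M - u_obs), max(u_obs, M - u_obs)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = pooled[list(combo)]
        ys = np.delete(pooled, list(combo))
        u = u_stat(xs, ys)
        total += 1
        if u <= lo + 1e-12 or u >= hi - 1e-12:
            count += 1
    return count / total


class TestPairwiseMannWhitney:
    def test_textbook_example(self):
        vals = [1, 2, 3, 4, 5, 6]
        groups = ["x"] * 3 + ["y"] * 3
        out = pairwise_mannwhitney(vals, groups)
        row = out.iloc[0]
        assert row["U"] == 0.0
        assert row["p_raw"] == pytest.approx(0.1)
        assert row["method"] == "exact"

    def test_exact_path_matches_enumeration(self):
        rng = np.random.default_rng(8)
        for n1, n2 in [(3, 3), (4, 5), (2, 6)]:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2) + 0.5
            out = pairwise_mannwhitney(
                np.concatenate([x, y]), ["x"] * n1 + ["y"] * n2
            )
            assert out.iloc[0]["p_raw"] == pytest.approx(mw_enumeration_p(x, y))

    def test_bonferroni_arithmetic_and_monotonicity(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=30)
        vals[20:] += 2.0
        groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        out = pairwise_mannwhitney(vals, groups)
        assert len(out) == 3
        assert np.allclose(
            out["p_adj"], np.minimum(1.0, out["p_raw"] * 3)
        )
        assert (out["p_adj"] >= out["p_raw"]).all()

    def test_identical_groups_midrank_u(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        out = pairwise_mannwhitney(vals, ["a"] * 3 + ["b"] * 3)
        assert out.iloc[0]["U"] == pytest.approx(4.5)  # n1*n2/2
        assert out.iloc[0]["method"] == "asymptotic"  # ties force approximation

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            pairwise_mannwhitney([1.0, 2.0], ["a", "a"])


def series(vals, ids=None, num=("n1",), den=("d1",)):
    ids = ids or [f"s{i}" for i in range(len(vals))]
    return LogRatioSeries(
        values=pd.Series(vals, index=ids), numerator_ids=num, denominator_ids=den
    )


class TestLogratioRegression:
    def test_perfect_line(self):
        x = series([0.0, 1.0, 2.0, 3.0])
        y = series([1.0, 3.0, 5.0, 7.0])
        res = logratio_group_regression(x, y)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_mismatched_drop_ledgers_intersect(self):
        x = series([0.0, 1.0, 2.0, 3.0], ids=["a", "b", "c", "d"])
        y = series([5.0, 2.0, 1.0], ids=["b", "c", "d"])
        res = logratio_group_regression(x, y)
        assert res.n == 3

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            logratio_group_regression(
                series([1.0, 1.0, 1.0]), series([0.0, 1.0, 2.0])
            )

    def test_null_correlation_stays_small(self):
        rng = np.random.default_rng(12)
        small = 0
        seeds = 100
        for _ in range(seeds):
            x = series(rng.normal(size=200))
            y = series(rng.normal(size=200))
            if abs(logratio_group_regression(x, y).r) < 0.2:
                small += 1
        assert small >= 0.95 * seeds


def _lme_data(seed, n_subj=12, n_t=4, interaction=0.0):
    rng = np.random.default_rng(seed)
    rows, vals = [], []
    for s in range(n_subj):
        grp = "HFHC-IHC" if s % 2 else "RC-Air"
        diet, exp = ("HFHC", "IHC") if s % 2 else ("RC", "Air")
        b = rng.normal(0, 0.5)
        for t in range(n_t):
            age = 10.0 + 2.0 * t
            sid = f"m{s}t{t}"
            y = b + 0.05 * age + interaction * age * (s % 2) + rng.normal(0, 0.3)
            rows.append((sid, f"m{s}", age, diet, exp))
            vals.append((sid, y))
    meta = SampleMetadata(
        pd.DataFrame(
            [r[1:] for r in rows],
            columns=["host_subject_id", "host_age", "diet", "exposure"],
            index=[r[0] for r in rows],
        )
    )
    x = series([v for _, v in vals], ids=[s for s, _ in vals])
    return x, meta


class TestLmeTrend:
    def test_interaction_power(self):
        hits = 0
        seeds = 30
        for s in range(seeds):
            x, meta = _lme_data(s, interaction=0.2)
            res = lme_trend(x, meta)
            inter = [t for t in res.coefficients.index if "host_age:" in t]
            assert len(inter) == 1
            hits += res.coefficients.loc[inter[0], "p"] < 0.01
        assert hits >= 0.9 * seeds

    def test_null_group_term_p_roughly_uniform(self):
        # under no group effect the interaction p-value should not pile up
        # near zero; a KS test against uniform must not reject at 1%
        from scipy.stats import kstest

        ps = []
        for s in range(100):
            x, meta = _lme_data(1000 + s, interaction=0.0)
            res = lme_trend(x, meta)
            inter = [t for t in res.coefficients.index if "host_age:" in t][0]
            ps.append(res.coefficients.loc[inter, "p"])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_single_subject_rejected(self):
        x, meta = _lme_data(0)
        one = meta.data["host_subject_id"] == "m0"
        with pytest.raises(ValueError, match="subject"):
            lme_trend(
                series(
                    x.values.loc[meta.data.index[one]].to_numpy(),
                    ids=meta.data.index[one].tolist(),
                ),
                SampleMetadata(meta.data[one]),
            )
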