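"""Group inference on distance matrices and log-ratio series.

PERMANOVA uses the Anderson (2001) pseudo-F partition of squared
distances with seeded label permutations (or full enumeration of distinct
label assignments for small designs).  Pairwise group comparisons of a
log-ratio series use the Mann-Whitney U test with Bonferroni correction.
The longitudinal trend model (log_ratio ~ host_age * group with a random
intercept per mouse) is delegated to statsmodels' MixedLM.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import LogRatioSeries, SampleMetadata


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    permutations: int
    group_sizes: dict[str, int]
    method: str = "permutation"


@dataclass
class RegressionResult:
    r: float
    p: float
    slope: float
    intercept: float
    n: int


@dataclass
class LmeTrendResult:
    coefficients: pd.DataFrame  # estimate, stderr, p per term
    singular: bool
    converged: bool
    n_obs: int
    n_subjects: int
    formula: str


def _as_distance_array(d) -> np.ndarray:
    if hasattr(d, "data"):  # skbio DistanceMatrix
        return np.asarray(d.data, dtype=float)
    if isinstance(d, pd.DataFrame):
        return d.to_numpy(dtype=float)
    return np.asarray(d, dtype=float)


def _pseudo_f(D2: np.ndarray, gidx: np.ndarray, k: int, n: int) -> float:
    """Anderson pseudo-F from squared distances (Gower partition)."""
    sst = D2.sum() / (2.0 * n)
    ssw = 0.0
    for g in range(k):
        m = gidx == g
        ng = m.sum()
        ssw += D2[np.ix_(m, m)].sum() / (2.0 * ng)
    ssb = sst - ssw
    return (ssb / (k - 1)) / (ssw / (n - k))


def permanova(
    d,
    groups,
    permutations: int = 999,
    seed: int = 0,
    exact: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Parameters
    ----------
    d : square symmetric distance matrix (ndarray, DataFrame or skbio
        DistanceMatrix) with zero diagonal.
    groups : per-sample labels, at least 2 groups of at least 2.
    exact : bool
        Enumerate every distinct assignment of the label multiset instead
        of sampling; p is then the exact fraction of assignments with
        F >= observed (the identity assignment included).
    """
    D = _as_distance_array(d)
    n = D.shape[0]
    if D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    groups = np.asarray(list(groups))
    if len(groups) != n:
        raise ValueError("groups length must match distance matrix")
    labs, gidx = np.unique(groups, return_inverse=True)
    k = len(labs)
    sizes = {str(l): int((gidx == i).sum()) for i, l in enumerate(labs)}
    if k < 2 or min(sizes.values()) < 2:
        raise ValueError("need >=2 groups with >=2 members each")
    D2 = D**2
    F = _pseudo_f(D2, gidx, k, n)

    if exact:
        count = 0
        total = 0
        for perm in _distinct_assignments(gidx):
            total += 1
            if _pseudo_f(D2, perm, k, n) >= F - 1e-12:
                count += 1
        return PermanovaResult(
            pseudo_F=float(F), p_value=count / total, permutations=total,
            group_sizes=sizes, method="exact-enumeration",
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        if _pseudo_f(D2, rng.permutation(gidx), k, n) >= F - 1e-12:
            count += 1
    return PermanovaResult(
        pseudo_F=float(F),
        p_value=(count + 1) / (permutations + 1),
        permutations=permutations,
        group_sizes=sizes,
    )


def _distinct_assignments(gidx: np.ndarray):
    """Yield every distinct permutation of the label multiset."""
    n = len(gidx)
    counts = np.bincount(gidx)
    # positions for group 0, then group 1 among the rest, etc.
    def rec(remaining: tuple[int, ...], g: int, current: np.ndarray):
        if g == len(counts) - 1:
            out = current.copy()
            out[list(remaining)] = g
            yield out
            return
        for combo in itertools.combinations(remaining, counts[g]):
            out = current.copy()
            out[list(combo)] = g
            rest = tuple(i for i in remaining if i not in set(combo))
            yield from rec(rest, g + 1, out)

    yield from rec(tuple(range(n)), 0, np.empty(n, dtype=int))


def pairwise_mannwhitney(
    values, groups, alpha: float = 0.05
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U for every pair of groups, Bonferroni-adjusted.

    The exact null distribution is used when both groups have n <= 8 and
    there are no ties; otherwise the normal approximation with tie
    correction.  Returns a DataFrame with one row per pair: group_a,
    group_b, n_a, n_b, U, p_raw, p_adj, significant, method.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(list(groups))
    labs = sorted(set(groups.tolist()))
    if len(labs) < 2:
        raise ValueError("need at least 2 groups")
    for l in labs:
        if (groups == l).sum() == 0:
            raise ValueError(f"group {l!r} is empty")
    pairs = list(itertools.combinations(labs, 2))
    rows = []
    for a, b in pairs:
        xa = values[groups == a]
        xb = values[groups == b]
        no_ties = len(np.unique(np.concatenate([xa, xb]))) == len(xa) + len(xb)
        use_exact = len(xa) <= 8 and len(xb) <= 8 and no_ties
        method = "exact" if use_exact else "asymptotic"
        res = sps.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        rows.append(
            {
                "group_a": a, "group_b": b, "n_a": len(xa), "n_b": len(xb),
                "U": float(res.statistic), "p_raw": float(res.pvalue),
                "method": method,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = np.minimum(1.0, out["p_raw"] * len(pairs))
    out["significant"] = out["p_adj"] <= alpha
    return out


def logratio_group_regression(
    x: LogRatioSeries, y: LogRatioSeries
) -> RegressionResult:
    """Pearson correlation and least-squares line between two log-ratio
    series, matched on the samples both retained."""
    shared = x.values.index.intersection(y.values.index)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} samples retained by both series; need >=3"
        )
    xv = x.values.loc[shared].to_numpy(dtype=float)
    yv = y.values.loc[shared].to_numpy(dtype=float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero variance input")
    fit = sps.linregress(xv, yv)
    return RegressionResult(
        r=float(fit.rvalue), p=float(fit.pvalue), slope=float(fit.slope),
        intercept=float(fit.intercept), n=len(shared),
    )


def lme_trend(x: LogRatioSeries, meta: SampleMetadata) -> LmeTrendResult:
    """Random-intercept trend model: log_ratio ~ host_age * group + (1 | mouse).

    Fitting is delegated to statsmodels MixedLM; a singular/non-converged
    fit is reported through flags, not an exception.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    df = x.values.rename("log_ratio").to_frame()
    sub = meta.data.reindex(df.index)
    df["host_age"] = sub["host_age"].astype(float)
    df["group"] = sub["group"].astype(str)
    df["host_subject_id"] = sub["host_subject_id"].astype(str)
    df = df.dropna()
    per_subj = df.groupby("host_subject_id")["host_age"].nunique()
    if len(per_subj) < 2 or (per_subj >= 2).mean() < 0.5:
        raise ValueError(
            "need >=2 timepoints per subject for at least half the subjects"
        )
    formula = "log_ratio ~ host_age * C(group)"
    singular = False
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, df, groups=df["host_subject_id"])
        fit = model.fit(reml=True)
        for w in caught:
            if issubclass(w.category, ConvergenceWarning):
                singular = True
    converged = bool(getattr(fit, "converged", True))
    coef = pd.DataFrame(
        {"estimate": fit.params, "stderr": fit.bse, "p": fit.pvalues}
    )
    return LmeTrendResult(
        coefficients=coef,
        singular=singular,
        converged=converged,
        n_obs=len(df),
        n_subjects=df["host_subject_id"].nunique(),
        formula=formula + " + (1 | host_subject_id)",
    )
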