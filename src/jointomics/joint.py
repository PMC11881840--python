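"""Single-table RPCA ordination and multi-table joint factorization.

RPCA here is the compositional (Aitchison) flavor: rclr-transform the
table, treat zeros as missing, complete at low rank, and read sample
scores/feature loadings off the factors; inter-sample Euclidean distance
in score space approximates Aitchison distance.

The joint model shares one set of sample scores U across all omics
tables: X_m ~ U S V_m^T, with the per-table observed-entry mean squared
errors averaged (equal weights by default) into a joint objective.  Each
sweep solves the per-table loadings exactly given U (column-wise least
squares on observed entries), re-orthogonalizes through a joint SVD of
the concatenated loadings — recomputing the shared eigenvalue matrix — and
then solves the shared scores row-wise given the loadings.  Every block
solve is an exact minimizer, so the joint objective is monotone
nonincreasing.

Cross-validation assigns whole samples to train/test; a test sample is
projected onto the trained loadings by least squares on half of its
observed entries and the reconstruction is scored on the other half, so
the reported test error is a genuine generalization error (scoring the
same entries used for the projection would reward any extra rank).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from skbio import DistanceMatrix, OrdinationResults
from sklearn.base import BaseEstimator

from .compositional import RclrMatrix, rclr
from .containers import FeatureTable
from .optspace import OptSpace

_RIDGE = 1e-12


# ---------------------------------------------------------------------------
# array-level solvers


def _masked_col_center(M: np.ndarray, means: np.ndarray | None = None):
    """Center columns on their observed-entry means (NaN-masked)."""
    if means is None:
        with np.errstate(invalid="ignore"):
            means = np.nanmean(M, axis=0, keepdims=True)
        means = np.where(np.isnan(means), 0.0, means)
    return M - means, means


def _solve_feature_blocks(U, X0, mask, rank):
    A = np.einsum("ir,is,ij->jrs", U, U, mask.astype(float))
    A += _RIDGE * np.eye(rank)
    b = np.einsum("ir,ij->jr", U, X0)
    return np.linalg.solve(A, b[..., None])[..., 0]


def _solve_sample_rows(Hs, Xs, masks, wts, rank):
    A = sum(
        w * np.einsum("jr,js,ij->irs", H, H, mk.astype(float))
        for H, mk, w in zip(Hs, masks, wts)
    ) + _RIDGE * np.eye(rank)
    b = sum(w * np.einsum("jr,ij->ir", H, X) for H, X, w in zip(Hs, Xs, wts))
    return np.linalg.solve(A, b[..., None])[..., 0]


def joint_complete(
    mats: list[np.ndarray],
    rank: int = 3,
    max_iter: int = 200,
    tol: float = 1e-6,
    weights: list[float] | None = None,
    seed: int = 0,
):
    """Jointly factorize NaN-masked matrices over identical sample rows.

    Returns ``(U, sig, Vs, loss_curve)`` with orthonormal shared scores U
    (n x r), shared singular values ``sig`` (descending) and per-table
    loadings ``Vs`` whose vertical concatenation is orthonormal.

    A single matrix degrades to :class:`~jointomics.optspace.OptSpace`
    completion, so the one-table path is exactly RPCA.
    """
    n = mats[0].shape[0]
    if any(M.shape[0] != n for M in mats):
        raise ValueError("all tables must have the same number of samples")
    if len(mats) == 1:
        est = OptSpace(rank=rank, max_iter=max_iter, tol=tol, seed=seed).fit(mats[0])
        return est.U_, np.diag(est.S_).copy(), [est.V_], est.loss_curve_

    masks = [~np.isnan(M) for M in mats]
    for k, mk in enumerate(masks):
        if (mk.sum(axis=1) == 0).any() or (mk.sum(axis=0) == 0).any():
            raise ValueError(f"table {k} has a sample or feature with no observed entries")
    Xs = [np.where(mk, M, 0.0) for M, mk in zip(mats, masks)]
    if weights is None:
        weights = [1.0] * len(mats)
    wts = [w / mk.sum() for w, mk in zip(weights, masks)]

    Z = np.hstack([X / max(mk.mean(), 1e-12) for X, mk in zip(Xs, masks)])
    U = np.linalg.svd(Z, full_matrices=False)[0][:, :rank]

    def _loss(U, Hs):
        return sum(
            w * np.sum(((U @ H.T - X) * mk) ** 2)
            for H, X, mk, w in zip(Hs, Xs, masks, wts)
        ) / len(mats)

    losses = []
    prev = np.inf
    sig = np.ones(rank)
    Vs = [np.zeros((X.shape[1], rank)) for X in Xs]
    for _ in range(max_iter):
        Gs = [_solve_feature_blocks(U, X, mk, rank) for X, mk in zip(Xs, masks)]
        # joint SVD of concatenated loadings: re-orthogonalizes the shared
        # scores and recomputes the shared eigenvalue matrix each iteration
        G = np.vstack(Gs)
        W, sig, At = np.linalg.svd(G, full_matrices=False)
        U = U @ At.T
        offs = np.cumsum([0] + [g.shape[0] for g in Gs])
        Vs = [W[offs[k] : offs[k + 1]] for k in range(len(Gs))]
        Hs = [V * sig for V in Vs]
        Uraw = _solve_sample_rows(Hs, Xs, masks, wts, rank)
        U, Rq = np.linalg.qr(Uraw)
        cur = _loss(U, [H @ Rq.T for H in Hs])
        losses.append(cur)
        if prev - cur <= tol * max(prev, 1e-300):
            break
        prev = cur
    # final consistent (U, sig, Vs) triple
    Gs = [_solve_feature_blocks(U, X, mk, rank) for X, mk in zip(Xs, masks)]
    G = np.vstack(Gs)
    W, sig, At = np.linalg.svd(G, full_matrices=False)
    U = U @ At.T
    offs = np.cumsum([0] + [g.shape[0] for g in Gs])
    Vs = [W[offs[k] : offs[k + 1]] for k in range(len(Gs))]
    return U, sig, Vs, np.asarray(losses)


def project_samples(
    mats: list[np.ndarray],
    Vs: list[np.ndarray],
    sig: np.ndarray,
    weights: list[float] | None = None,
):
    """Project new samples onto trained loadings by least squares on their
    observed entries (test-set projection of the cross-validation)."""
    rank = len(sig)
    masks = [~np.isnan(M) for M in mats]
    Xs = [np.where(mk, M, 0.0) for M, mk in zip(mats, masks)]
    if weights is None:
        weights = [1.0] * len(mats)
    wts = [w / max(mk.sum(), 1) for w, mk in zip(weights, masks)]
    Hs = [V * sig for V in Vs]
    return _solve_sample_rows(Hs, Xs, masks, wts, rank)


def projection_holdout_error(
    mats: list[np.ndarray],
    Vs: list[np.ndarray],
    sig: np.ndarray,
    seed: int = 0,
    holdout_fraction: float = 0.5,
    weights: list[float] | None = None,
) -> float:
    """Generalization error of projecting new samples onto trained loadings.

    Each sample's observed entries are split at random: the projection is
    estimated from one part and the reconstruction is scored on the held
    out part, so extra rank is only rewarded when it generalizes.  Returns
    the pooled RMSE over scored entries.
    """
    rng = np.random.default_rng(seed)
    masks = [~np.isnan(M) for M in mats]
    score_masks = [mk & (rng.random(M.shape) < holdout_fraction)
                   for M, mk in zip(mats, masks)]
    src_mats = [np.where(mk & ~sm, M, np.nan)
                for M, mk, sm in zip(mats, masks, score_masks)]
    # samples with no source entries in a table are fine as long as they
    # keep at least one somewhere; guard the all-empty case
    if all(sm.sum() == 0 for sm in score_masks):
        raise ValueError("no entries to score; lower holdout_fraction")
    U = project_samples(src_mats, Vs, sig, weights)
    sse = 0.0
    cnt = 0
    for M, V, sm in zip(mats, Vs, score_masks):
        R = (U @ (V * sig).T - np.where(sm, M, 0.0)) * sm
        sse += np.sum(R**2)
        cnt += sm.sum()
    return float(np.sqrt(sse / max(cnt, 1)))


def _observed_rmse(mats, U, sig, Vs) -> float:
    num = 0.0
    cnt = 0
    for M, V in zip(mats, Vs):
        mk = ~np.isnan(M)
        R = (U @ (V * sig).T - np.where(mk, M, 0.0)) * mk
        num += np.sum(R**2)
        cnt += mk.sum()
    return float(np.sqrt(num / max(cnt, 1)))


# ---------------------------------------------------------------------------
# results containers


@dataclass
class JointFactorization:
    """Shared-score factorization of one or more omics tables."""

    shared_U: pd.DataFrame
    singular_values: np.ndarray
    feature_loadings: list[pd.DataFrame]
    proportion_explained: np.ndarray
    cv_train_error: np.ndarray
    cv_test_error: np.ndarray
    loss_curve: np.ndarray
    rclr_matrices: list[RclrMatrix] = field(repr=False, default_factory=list)

    @property
    def n_tables(self) -> int:
        return len(self.feature_loadings)

    @property
    def sample_scores(self) -> pd.DataFrame:
        return self.shared_U * self.singular_values


@dataclass
class CrossOmicCorrelations:
    matrix: pd.DataFrame
    method: str


# ---------------------------------------------------------------------------
# estimators


class JointRPCA(BaseEstimator):
    """Joint compositional factorization with shared sample scores.

    Parameters
    ----------
    rank : int, default 3
    max_iter, tol : solver stopping rule.
    n_splits : int, default 5
        Number of random train/test sample splits for the reconstruction
        cross-validation.
    train_fraction : float in (0.5, 0.95), default 0.8
    weights : per-table objective weights (equal by default).
    seed : int
        Seeds the CV splits; the solver itself is deterministic.

    Attributes (fitted)
    -------------------
    shared_U_ : DataFrame (samples x rank), orthonormal columns.
    singular_values_, proportion_explained_
    feature_loadings_ : list of DataFrames (features x rank).
    cv_train_error_, cv_test_error_ : per-split observed-entry RMSE.
    """

    def __init__(self, rank: int = 3, max_iter: int = 200, tol: float = 1e-6,
                 n_splits: int = 5, train_fraction: float = 0.8,
                 weights=None, seed: int = 0):
        self.rank = rank
        self.max_iter = max_iter
        self.tol = tol
        self.n_splits = n_splits
        self.train_fraction = train_fraction
        self.weights = weights
        self.seed = seed

    def fit(self, tables: list[FeatureTable], y=None):
        if not tables:
            raise ValueError("need at least one table")
        if not (0.5 < self.train_fraction < 0.95):
            raise ValueError("train_fraction must be in (0.5, 0.95)")
        sample_ids = tables[0].sample_ids
        for t in tables[1:]:
            if t.sample_ids != sample_ids:
                raise ValueError("tables must share identical sample ids in order")
        rms = [rclr(t) for t in tables]
        mats = [np.where(m.observed_mask, m.values, np.nan) for m in rms]
        n = len(sample_ids)

        # cross-validated reconstruction error on whole held-out samples
        rng = np.random.default_rng(self.seed)
        n_train = int(round(self.train_fraction * n))
        cv_train, cv_test = [], []
        for _ in range(self.n_splits):
            perm = rng.permutation(n)
            tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])
            tr_mats, means = [], []
            for M in mats:
                Mc, mu = _masked_col_center(M[tr])
                tr_mats.append(Mc)
                means.append(mu)
            Ut, sigt, Vst, _ = joint_complete(
                tr_mats, self.rank, self.max_iter, self.tol, self.weights
            )
            cv_train.append(_observed_rmse(tr_mats, Ut, sigt, Vst))
            te_mats = [M[te] - mu for M, mu in zip(mats, means)]
            cv_test.append(
                projection_holdout_error(
                    te_mats, Vst, sigt, seed=self.seed, weights=self.weights
                )
            )

        # final factors on all samples
        cmats, self._col_means_ = [], []
        for M in mats:
            Mc, mu = _masked_col_center(M)
            cmats.append(Mc)
            self._col_means_.append(mu)
        U, sig, Vs, losses = joint_complete(
            cmats, self.rank, self.max_iter, self.tol, self.weights
        )
        axes = [f"PC{k+1}" for k in range(self.rank)]
        self.shared_U_ = pd.DataFrame(U, index=sample_ids, columns=axes)
        self.singular_values_ = sig
        self.feature_loadings_ = [
            pd.DataFrame(V, index=t.feature_ids, columns=axes)
            for V, t in zip(Vs, tables)
        ]
        tot = np.sum(sig**2)
        self.proportion_explained_ = sig**2 / tot if tot > 0 else np.zeros_like(sig)
        self.cv_train_error_ = np.asarray(cv_train)
        self.cv_test_error_ = np.asarray(cv_test)
        self.loss_curve_ = losses
        self.rclr_matrices_ = rms
        return self

    @property
    def sample_scores_(self) -> pd.DataFrame:
        return self.shared_U_ * self.singular_values_

    def to_result(self) -> JointFactorization:
        return JointFactorization(
            shared_U=self.shared_U_,
            singular_values=self.singular_values_,
            feature_loadings=self.feature_loadings_,
            proportion_explained=self.proportion_explained_,
            cv_train_error=self.cv_train_error_,
            cv_test_error=self.cv_test_error_,
            loss_curve=self.loss_curve_,
            rclr_matrices=self.rclr_matrices_,
        )


class RobustPCA(BaseEstimator):
    """Compositional RPCA ordination of a single table.

    rclr -> masked column centering -> OptSpace completion.  Exposes the
    ordination, the Aitchison-type sample distance matrix, and the feature
    loadings usable as differential ranks.
    """

    def __init__(self, rank: int = 3, max_iter: int = 200, tol: float = 1e-6,
                 seed: int = 0):
        self.rank = rank
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def fit(self, table: FeatureTable, y=None):
        m = rclr(table)
        M = np.where(m.observed_mask, m.values, np.nan)
        Mc, self._col_means_ = _masked_col_center(M)
        est = OptSpace(rank=self.rank, max_iter=self.max_iter, tol=self.tol,
                       seed=self.seed).fit(Mc)
        axes = [f"PC{k+1}" for k in range(self.rank)]
        sig = np.diag(est.S_).copy()
        scores = est.U_ @ est.S_
        self.samples_ = pd.DataFrame(scores, index=table.sample_ids, columns=axes)
        self.features_ = pd.DataFrame(est.V_, index=table.feature_ids, columns=axes)
        self.singular_values_ = sig
        tot = np.sum(sig**2)
        self.proportion_explained_ = sig**2 / tot if tot > 0 else np.zeros_like(sig)
        d = np.sqrt(
            np.maximum(
                ((scores[:, None, :] - scores[None, :, :]) ** 2).sum(-1), 0.0
            )
        )
        np.fill_diagonal(d, 0.0)
        self.distance_matrix_ = DistanceMatrix((d + d.T) / 2, ids=table.sample_ids)
        self.ordination_ = OrdinationResults(
            short_method_name="RPCA",
            long_method_name="Robust Aitchison PCA (rclr + matrix completion)",
            eigvals=pd.Series(sig**2, index=axes),
            samples=self.samples_,
            features=self.features_,
            proportion_explained=pd.Series(self.proportion_explained_, index=axes),
        )
        return self


# ---------------------------------------------------------------------------
# functional wrappers


def rpca(
    t: FeatureTable, rank: int = 3, max_iter: int = 200, tol: float = 1e-6,
    seed: int = 0,
) -> tuple[OrdinationResults, DistanceMatrix]:
    """Single-table RPCA: ordination plus Aitchison-type distances."""
    est = RobustPCA(rank=rank, max_iter=max_iter, tol=tol, seed=seed).fit(t)
    return est.ordination_, est.distance_matrix_


def joint_factorize(
    tables: list[FeatureTable],
    rank: int = 3,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
    train_fraction: float = 0.8,
    n_splits: int = 5,
    weights=None,
) -> JointFactorization:
    """Joint factorization of tables over identical samples; see
    :class:`JointRPCA`."""
    est = JointRPCA(
        rank=rank, max_iter=max_iter, tol=tol, n_splits=n_splits,
        train_fraction=train_fraction, weights=weights, seed=seed,
    ).fit(tables)
    return est.to_result()


def cross_correlations(
    jf: JointFactorization, table_a: int = 0, table_b: int = 1,
    method: str = "pearson",
) -> CrossOmicCorrelations:
    """Feature-feature correlations between two tables' reconstructed
    shared-space profiles.

    Each feature's profile is its reconstructed column U S v_j over all
    samples.  Profiles are first re-centered across features within each
    table (removing the shared clr-reference component) and then correlated
    across tables.  Features with zero loading on every axis get a zero
    correlation row/column.
    """
    if jf.n_tables < 2:
        raise ValueError("cross-omic correlations require at least 2 tables")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    U = jf.shared_U.to_numpy()
    sig = jf.singular_values

    def _profiles(k: int) -> np.ndarray:
        R = U @ (jf.feature_loadings[k].to_numpy() * sig).T
        return R - R.mean(axis=1, keepdims=True)

    Ra, Rb = _profiles(table_a), _profiles(table_b)
    zero_a = np.all(jf.feature_loadings[table_a].to_numpy() == 0, axis=1)
    zero_b = np.all(jf.feature_loadings[table_b].to_numpy() == 0, axis=1)
    if method == "spearman":
        Ra = np.apply_along_axis(rankdata, 0, Ra)
        Rb = np.apply_along_axis(rankdata, 0, Rb)
    Za = Ra - Ra.mean(axis=0)
    Zb = Rb - Rb.mean(axis=0)
    na = np.linalg.norm(Za, axis=0)
    nb = np.linalg.norm(Zb, axis=0)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    C = (Za / na).T @ (Zb / nb)
    C[zero_a, :] = 0.0
    C[:, zero_b] = 0.0
    # clip numerical dust only
    excess = np.abs(C) - 1.0
    if (excess > 1e-12).any():
        raise FloatingPointError("correlation left [-1, 1] beyond numerical dust")
    C = np.clip(C, -1.0, 1.0)
    return CrossOmicCorrelations(
        matrix=pd.DataFrame(
            C,
            index=jf.feature_loadings[table_a].index,
            columns=jf.feature_loadings[table_b].index,
        ),
        method=method,
    )


def select_features_by_loading(loadings: pd.Series, q: float = 0.1) -> list[str]:
    """Top and bottom ``q`` fraction of features ranked by a loading axis —
    the loading-rank surrogate for differential abundance filtering."""
    if not (0 < q <= 0.5):
        raise ValueError("q must be in (0, 0.5]")
    k = max(1, int(round(q * len(loadings))))
    ordered = loadings.sort_values(ascending=False, kind="mergesort")
    return ordered.index[:k].tolist() + ordered.index[-k:].tolist()
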