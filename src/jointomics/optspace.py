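"""Low-rank matrix completion on masked (rclr) matrices.

The solver follows the OptSpace recipe: optional degree trimming, rank-r
spectral initialization of the zero-filled, fraction-rescaled matrix, then
descent over orthonormal factor pairs (U, V) minimizing squared error on
the observed entries only, with the r x r core S re-solved exactly at each
step.  Steps use backtracking (halve until the loss decreases); a small
SVD reparametrization after each accepted step keeps U and V orthonormal
and S diagonal with nonincreasing nonnegative entries, without changing
the reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .compositional import RclrMatrix

_MAX_HALVINGS = 20


@dataclass
class CompletionResult:
    """Factors of the completed matrix: X ~ U S V^T on observed entries."""

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray
    iterations: int
    observed_rmse: float
    converged: bool
    loss_curve: np.ndarray

    @property
    def reconstruction(self) -> np.ndarray:
        return self.U @ self.S @ self.V.T


def _solve_core(X0, mask, U, V) -> np.ndarray:
    """Exact least-squares r x r core given orthonormal U, V."""
    r = U.shape[1]
    ii, jj = np.nonzero(mask)
    design = (U[ii][:, :, None] * V[jj][:, None, :]).reshape(len(ii), r * r)
    s, *_ = np.linalg.lstsq(design, X0[ii, jj], rcond=None)
    return s.reshape(r, r)


def _canonicalize(U, S, V):
    """Reparametrize so U, V are orthonormal and S diagonal, descending."""
    Qu, Ru = np.linalg.qr(U)
    Qv, Rv = np.linalg.qr(V)
    A, sig, Bt = np.linalg.svd(Ru @ S @ Rv.T)
    return Qu @ A, np.diag(sig), Qv @ Bt.T


def _trim(X0, mask):
    """OptSpace degree trimming: blank rows/columns observed more than
    twice the average degree (helps under very uneven sampling)."""
    mask = mask.copy()
    row_deg = mask.sum(axis=1)
    col_deg = mask.sum(axis=0)
    mask[row_deg > 2 * row_deg.mean(), :] = False
    mask[:, col_deg > 2 * col_deg.mean()] = False
    return np.where(mask, X0, 0.0), mask


class OptSpace(BaseEstimator):
    """Matrix completion estimator for NaN-masked arrays.

    Parameters
    ----------
    rank : int
        Target rank r.  Default 3 (2-3 ordination axes are what the
        downstream biplots display).
    max_iter, tol : stopping rule — relative observed-entry loss change
        below ``tol`` or ``max_iter`` gradient steps.
    trim : bool
        Apply OptSpace degree trimming before the spectral init.
    seed : int
        Recorded for provenance; the solver itself is deterministic.

    Attributes
    ----------
    U_, S_, V_ : factors with orthonormal U_/V_ columns and diagonal S_.
    observed_rmse_ : RMSE of the residual over observed entries.
    n_iter_, converged_, loss_curve_
    """

    def __init__(self, rank: int = 3, max_iter: int = 200, tol: float = 1e-6,
                 trim: bool = False, seed: int = 0):
        self.rank = rank
        self.max_iter = max_iter
        self.tol = tol
        self.trim = trim
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if not (1 <= self.rank <= min(n, p)):
            raise ValueError(f"rank must be in [1, {min(n, p)}], got {self.rank}")
        mask = ~np.isnan(X)
        empty_rows = np.flatnonzero(mask.sum(axis=1) == 0)
        empty_cols = np.flatnonzero(mask.sum(axis=0) == 0)
        if len(empty_rows) or len(empty_cols):
            raise ValueError(
                f"mask has empty rows {empty_rows.tolist()[:5]} "
                f"and/or columns {empty_cols.tolist()[:5]}"
            )
        X0 = np.where(mask, X, 0.0)

        init_X, init_mask = (X0, mask) if not self.trim else _trim(X0, mask)
        frac = max(init_mask.mean(), 1e-12)
        Uf, _, Vft = np.linalg.svd(init_X / frac, full_matrices=False)
        U, V = Uf[:, : self.rank], Vft[: self.rank].T

        S = _solve_core(X0, mask, U, V)
        loss = 0.5 * np.sum(((U @ S @ V.T - X0) * mask) ** 2)
        losses = [loss]
        step = 1.0 / frac
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            R = (U @ S @ V.T - X0) * mask
            gU = R @ V @ S.T
            gV = R.T @ U @ S
            gnorm = np.sqrt(np.sum(gU**2) + np.sum(gV**2))
            if gnorm == 0.0:
                converged = True
                it -= 1
                break
            accepted = False
            for _ in range(_MAX_HALVINGS + 1):
                Un, _ = np.linalg.qr(U - step * gU)
                Vn, _ = np.linalg.qr(V - step * gV)
                Sn = _solve_core(X0, mask, Un, Vn)
                ln = 0.5 * np.sum(((Un @ Sn @ Vn.T - X0) * mask) ** 2)
                if ln <= loss:
                    accepted = True
                    break
                step /= 2.0
            if not accepted:
                converged = True
                it -= 1
                break
            prev, loss = loss, ln
            U, V, S = Un, Vn, Sn
            losses.append(loss)
            step *= 1.5
            if prev - loss <= self.tol * max(prev, 1e-300):
                converged = True
                break

        U, S, V = _canonicalize(U, S, V)
        resid = (U @ S @ V.T - X0) * mask
        self.U_, self.S_, self.V_ = U, S, V
        self.n_iter_ = it
        self.converged_ = converged
        self.observed_rmse_ = float(np.sqrt(np.sum(resid**2) / mask.sum()))
        self.loss_curve_ = np.asarray(losses)
        return self

    def transform(self, X=None) -> np.ndarray:
        """Sample scores U S of the fitted factorization."""
        return self.U_ @ self.S_


def complete(
    m: RclrMatrix | np.ndarray,
    rank: int = 3,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
    trim: bool = False,
) -> CompletionResult:
    """Complete a masked rclr matrix (or NaN-masked array) at the given rank."""
    X = m.to_frame().to_numpy() if isinstance(m, RclrMatrix) else np.asarray(m, float)
    if isinstance(m, RclrMatrix):
        X = np.where(m.observed_mask, m.values, np.nan)
    est = OptSpace(rank=rank, max_iter=max_iter, tol=tol, trim=trim, seed=seed).fit(X)
    return CompletionResult(
        U=est.U_,
        S=est.S_,
        V=est.V_,
        iterations=est.n_iter_,
        observed_rmse=est.observed_rmse_,
        converged=est.converged_,
        loss_curve=est.loss_curve_,
    )
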