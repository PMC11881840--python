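"""Two-class PLS-DA with VIP feature selection and cross-validated CER.

The PLS core is NIPALS (scikit-learn's ``PLSRegression``); what this
module adds is the discriminant wrapping used in metabolomics: a +/-1
class response, variable-importance-in-projection (VIP) scores whose
squares average to 1, nearest-class-centroid prediction in score space,
and a pooled classification error rate (CER) over stratified k-fold
held-out predictions.  Features with VIP above the threshold (1 by
convention) are "significant" and feed the panel log ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

from .compositional import RclrMatrix, feature_set_log_ratio
from .containers import FeatureTable, LogRatioSeries


def _vip(pls: PLSRegression) -> np.ndarray:
    """VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ).

    SSY_a is the class variance explained by component a
    (q_a^2 t_a^T t_a); the identity mean(VIP^2) = 1 follows directly.
    """
    W = pls.x_weights_
    T = pls.x_scores_
    Q = pls.y_loadings_
    p, a = W.shape
    ssy = (Q[0] ** 2) * np.einsum("ia,ia->a", T, T)
    wnorm2 = np.einsum("ja,ja->a", W, W)
    wnorm2[wnorm2 == 0] = 1.0
    num = p * (W**2 / wnorm2) @ ssy
    den = ssy.sum()
    if den == 0:
        return np.zeros(p)
    return np.sqrt(num / den)


def _centroid_predict(scores_train, y_train, scores_test, classes):
    cents = np.vstack([
        scores_train[y_train == c].mean(axis=0) for c in classes
    ])
    d = ((scores_test[:, None, :] - cents[None, :, :]) ** 2).sum(-1)
    return np.asarray(classes)[np.argmin(d, axis=1)]


class PLSDiscriminant(ClassifierMixin, BaseEstimator):
    """Two-class PLS-DA estimator.

    Parameters
    ----------
    n_components : int, default 2
        Number of latent components; with ``auto_ncomp`` the value in
        {1, 2, 3} with the smallest CV CER is used instead.
    n_folds : int, default 5
        Stratified folds for the classification error rate.
    vip_threshold : float, default 1.0
    random_state : int
        Seeds the CV fold shuffling only; the fit itself is deterministic
        given the data.

    Attributes
    ----------
    vip_ : per-feature VIP scores (mean of squares = 1).
    cv_cer_ : pooled misclassification rate over held-out folds.
    selected_ : boolean mask of features with VIP > threshold.
    x_weights_, x_loadings_, x_scores_ : NIPALS quantities of the
        full-data fit.
    """

    def __init__(self, n_components: int = 2, n_folds: int = 5,
                 vip_threshold: float = 1.0, auto_ncomp: bool = False,
                 random_state: int = 0):
        self.n_components = n_components
        self.n_folds = n_folds
        self.vip_threshold = vip_threshold
        self.auto_ncomp = auto_ncomp
        self.random_state = random_state

    def _cv_cer(self, X, y01, classes, ncomp) -> float:
        skf = StratifiedKFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.random_state
        )
        wrong = 0
        for tr, te in skf.split(X, y01):
            pls = PLSRegression(n_components=ncomp, scale=False)
            ytr = np.where(y01[tr] == 1, 1.0, -1.0)
            pls.fit(X[tr], ytr)
            str_, ste = pls.transform(X[tr]), pls.transform(X[te])
            pred = _centroid_predict(str_, classes[y01[tr]], ste, classes)
            wrong += int((pred != classes[y01[te]]).sum())
        return wrong / len(y01)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(
                f"PLS-DA here is two-class (pairwise comparisons); got "
                f"{len(classes)} classes"
            )
        y01 = (y == classes[1]).astype(int)
        counts = np.bincount(y01, minlength=2)
        if counts.min() < self.n_folds:
            raise ValueError(
                f"each class needs >= n_folds={self.n_folds} members; "
                f"sizes {dict(zip(classes, counts))}"
            )
        ncomp = self.n_components
        if self.auto_ncomp:
            cers = {a: self._cv_cer(X, y01, classes, a) for a in (1, 2, 3)}
            ncomp = min(cers, key=lambda a: (cers[a], a))
        self.n_components_ = ncomp
        self.classes_ = classes
        self.cv_cer_ = self._cv_cer(X, y01, classes, ncomp)
        pls = PLSRegression(n_components=ncomp, scale=False)
        pls.fit(X, np.where(y01 == 1, 1.0, -1.0))
        self._pls = pls
        self.x_weights_ = pls.x_weights_
        self.x_loadings_ = pls.x_loadings_
        self.x_scores_ = pls.x_scores_
        self.vip_ = _vip(pls)
        self.selected_ = self.vip_ > self.vip_threshold
        self._train_scores = pls.transform(X)
        self._train_y01 = y01
        return self

    def transform(self, X) -> np.ndarray:
        return self._pls.transform(np.asarray(X, dtype=float))

    def predict(self, X):
        scores = self.transform(X)
        return _centroid_predict(
            self._train_scores, self.classes_[self._train_y01], scores,
            self.classes_,
        )


def fit_plsda(
    m: RclrMatrix,
    labels,
    n_components: int = 2,
    folds: int = 5,
    seed: int = 0,
    vip_threshold: float = 1.0,
    auto_ncomp: bool = False,
) -> PLSDiscriminant:
    """Fit PLS-DA on an rclr matrix (unobserved entries as 0, the
    row-centered neutral value — supervised path only)."""
    est = PLSDiscriminant(
        n_components=n_components, n_folds=folds, vip_threshold=vip_threshold,
        auto_ncomp=auto_ncomp, random_state=seed,
    )
    return est.fit(m.zero_filled(), np.asarray(list(labels)))


def vip_table(model: PLSDiscriminant, m: RclrMatrix, labels) -> pd.DataFrame:
    """Per-feature VIP with the class association (class whose mean rclr
    value is higher)."""
    X = m.zero_filled()
    labels = np.asarray(list(labels))
    means = {
        c: X[labels == c].mean(axis=0) for c in model.classes_
    }
    assoc = np.where(
        means[model.classes_[0]] >= means[model.classes_[1]],
        model.classes_[0], model.classes_[1],
    )
    return pd.DataFrame(
        {
            "vip": model.vip_,
            "selected": model.selected_,
            "class_association": assoc,
        },
        index=list(m.feature_ids),
    )


def significant_feature_log_ratio(
    model: PLSDiscriminant,
    t: FeatureTable,
    m: RclrMatrix,
    labels,
    numerator_class=None,
) -> LogRatioSeries:
    """Log ratio of VIP-selected features associated with one class over
    those associated with the other.

    Each selected feature is assigned to the class with the higher mean
    rclr value; the numerator side is ``numerator_class`` (first class by
    default), so swapping class labels negates the series.
    """
    if not model.selected_.any():
        raise ValueError("no features exceed the VIP threshold")
    tab = vip_table(model, m, labels)
    sel = tab[tab["selected"]]
    if numerator_class is None:
        numerator_class = model.classes_[0]
    if numerator_class not in model.classes_:
        raise ValueError(f"{numerator_class!r} is not a class of the model")
    other = [c for c in model.classes_ if c != numerator_class][0]
    num = sel.index[sel["class_association"] == numerator_class].tolist()
    den = sel.index[sel["class_association"] == other].tolist()
    if not num or not den:
        raise ValueError(
            "selected features all associate with one class; log ratio undefined"
        )
    return feature_set_log_ratio(t, num, den)
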