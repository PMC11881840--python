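"""Robust centered log-ratio transform and feature-set log ratios.

The robust clr (rclr) takes each sample's positive entries to
``ln(x) - mean(ln(positive entries))``; zeros stay *missing* — they are
never imputed or pseudocounted.  The result is scale invariant per sample,
so library size cancels.  Feature-set log ratios (``ln(sum num / sum den)``)
are the total-independent biomarker statistic used for family-level and
panel-level trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import FeatureTable, LogRatioSeries


@dataclass
class RclrMatrix:
    """rclr-transformed matrix defined only on observed (positive) entries.

    ``values`` holds NaN wherever ``observed_mask`` is False.  Every row
    with at least one observed entry has observed-entry mean zero.
    """

    values: np.ndarray
    observed_mask: np.ndarray
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.values.shape != self.observed_mask.shape:
            raise ValueError("values and mask shapes differ")
        self.sample_ids = tuple(self.sample_ids)
        self.feature_ids = tuple(self.feature_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def zero_filled(self) -> np.ndarray:
        """Design copy with unobserved entries at 0, the row-centered
        neutral value (used by the supervised PLS-DA path only)."""
        return np.where(self.observed_mask, self.values, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_ids)
        )


def _rclr_array(x: np.ndarray) -> np.ndarray:
    out = np.full(x.shape, np.nan)
    np.log(x, where=x > 0, out=out)
    return out - np.nanmean(out, axis=1, keepdims=True)


def rclr(t: FeatureTable, pseudocount: float | None = None) -> RclrMatrix:
    """Robust centered log-ratio transform of a nonnegative table.

    Parameters
    ----------
    pseudocount : float, optional
        Off by default.  When given, it is added to every entry first and
        the result is a dense (fully observed) clr matrix.

    Raises
    ------
    ValueError
        If any sample has no positive entry (naming the sample).
    """
    x = t.values
    if pseudocount is not None:
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        x = x + pseudocount
    zero_rows = np.flatnonzero((x > 0).sum(axis=1) == 0)
    if len(zero_rows):
        names = [t.sample_ids[i] for i in zero_rows]
        raise ValueError(f"samples with no positive entries: {names}")
    vals = _rclr_array(x)
    return RclrMatrix(
        values=vals,
        observed_mask=~np.isnan(vals),
        sample_ids=tuple(t.sample_ids),
        feature_ids=tuple(t.feature_ids),
    )


class RclrTransformer(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer applying the rclr row-wise.

    ``transform`` returns an array with NaN at unobserved (zero) entries;
    use :func:`rclr` when the mask and ids must travel together.
    """

    def __init__(self, pseudocount: float | None = None):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if (X < 0).any():
            raise ValueError("rclr requires nonnegative input")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if (X < 0).any():
            raise ValueError("rclr requires nonnegative input")
        if self.pseudocount is not None:
            X = X + self.pseudocount
        if ((X > 0).sum(axis=1) == 0).any():
            raise ValueError("all-zero sample row")
        return _rclr_array(X)


def feature_set_log_ratio(
    t: FeatureTable, numerator, denominator
) -> LogRatioSeries:
    """Per-sample ``ln(sum(numerator) / sum(denominator))``.

    Samples with a zero sum on either side are excluded and reported in
    ``dropped_samples`` (drop-and-report; no pseudocounts).
    """
    num = list(dict.fromkeys(numerator))
    den = list(dict.fromkeys(denominator))
    if not num or not den:
        raise ValueError("numerator and denominator sets must be nonempty")
    overlap = set(num) & set(den)
    if overlap:
        raise ValueError(f"numerator and denominator overlap: {sorted(overlap)[:5]}")
    missing = (set(num) | set(den)) - set(t.feature_ids)
    if missing:
        raise KeyError(f"features not in table: {sorted(missing)[:5]}")
    num_sum = t.data[num].sum(axis=1)
    den_sum = t.data[den].sum(axis=1)
    ok = (num_sum > 0) & (den_sum > 0)
    values = np.log(num_sum[ok] / den_sum[ok])
    return LogRatioSeries(
        values=values.rename("log_ratio"),
        numerator_ids=tuple(num),
        denominator_ids=tuple(den),
        dropped_samples=tuple(t.data.index[~ok]),
    )


def loading_rank_log_ratio(
    loadings: pd.Series,
    t: FeatureTable,
    k: int,
    tie_break: bool = False,
) -> LogRatioSeries:
    """Log ratio of the top-k over the bottom-k features by loading.

    Feature ranks come from an ordination axis (e.g. the first RPCA
    loading); the resulting ratio is the standard differential-rank
    biomarker.  Exact ties at the selection boundary raise unless
    ``tie_break`` enables the deterministic feature-id tie-break.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    loadings = loadings.loc[[f for f in t.feature_ids if f in loadings.index]]
    if 2 * k > len(loadings):
        raise ValueError(
            f"k={k} too large for {len(loadings)} ranked features (need 2k)"
        )
    df = loadings.rename("loading").to_frame()
    df["fid"] = df.index
    ordered = df.sort_values(
        by=["loading", "fid"], ascending=[False, True]
    )  # id breaks exact ties deterministically
    if not tie_break:
        vals = ordered["loading"].to_numpy()
        boundary_ties = (
            (len(vals) > 2 * k and (vals[k - 1] == vals[k] or vals[-k] == vals[-k - 1]))
            or (len(vals) == 2 * k and vals[k - 1] == vals[k])
        )
        if boundary_ties:
            raise ValueError(
                "ties make top/bottom undefined; pass tie_break=True to break "
                "ties by feature id"
            )
    top = ordered.index[:k].tolist()
    bottom = ordered.index[-k:].tolist()
    return feature_set_log_ratio(t, top, bottom)


def write_log_ratio(
    series: LogRatioSeries, path, meta=None
) -> None:
    """Write a log-ratio series as TSV (sample_id, value, group, host_age);
    dropped samples go to a ``<path>.dropped.tsv`` sidecar."""
    df = series.values.rename("log_ratio").to_frame()
    if meta is not None:
        sub = meta.data.reindex(df.index)
        df["group"] = sub["group"]
        df["host_age"] = sub["host_age"]
    df.to_csv(path, sep="\t", index_label="sample_id")
    side = pd.DataFrame({"dropped_sample_id": list(series.dropped_samples)})
    side.to_csv(str(path) + ".dropped.tsv", sep="\t", index=False)
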