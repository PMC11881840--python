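"""Core in-memory containers shared across the package.

A :class:`FeatureTable` is a samples x features matrix of nonnegative
counts (16S ASV tables) or intensities (LC-MS/MS peak areas), carried as a
:class:`pandas.DataFrame` with sample ids on the index and feature ids on
the columns.  :class:`SampleMetadata` holds the per-sample study design:
host subject, host age in weeks, diet (RC / HFHC), exposure (Air / IHC)
and the derived diet-exposure group label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_KINDS = ("counts", "intensities")
VALID_DIETS = ("RC", "HFHC")
VALID_EXPOSURES = ("Air", "IHC")


@dataclass
class FeatureTable:
    """Nonnegative samples x features matrix with unique string ids.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are features.  All entries must be
        finite and nonnegative.
    kind : {"counts", "intensities"}
        Whether the values are sequencing counts or MS peak areas.
    """

    data: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame")
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicated sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicated feature ids: {dups}")
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("feature table contains non-finite values")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValueError(
                "negative value at sample "
                f"{self.data.index[i]!r}, feature {self.data.columns[j]!r}"
            )

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def feature_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def filter_samples(self, ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(ids)], kind=self.kind)

    def filter_features(self, ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[:, list(ids)], kind=self.kind)


@dataclass
class SampleMetadata:
    """Per-sample study design, one row per sample id.

    Columns: ``host_subject_id``, ``host_age`` (weeks), ``diet``,
    ``exposure``; ``group`` is derived as ``"{diet}-{exposure}"`` and
    checked for consistency if already present.
    """

    data: pd.DataFrame

    REQUIRED = ("host_subject_id", "host_age", "diet", "exposure")

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.index = df.index.astype(str)
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicated sample ids in metadata: {dups}")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        bad_diet = set(df["diet"].unique()) - set(VALID_DIETS)
        if bad_diet:
            raise ValueError(f"unknown diet values: {sorted(bad_diet)}")
        bad_exp = set(df["exposure"].unique()) - set(VALID_EXPOSURES)
        if bad_exp:
            raise ValueError(f"unknown exposure values: {sorted(bad_exp)}")
        df["host_age"] = df["host_age"].astype(float)
        if (df["host_age"] < 0).any():
            raise ValueError("host_age must be nonnegative")
        derived = df["diet"].astype(str) + "-" + df["exposure"].astype(str)
        if "group" in df.columns:
            mismatch = df.index[df["group"].astype(str) != derived]
            if len(mismatch):
                raise ValueError(
                    f"group label inconsistent with diet/exposure for {mismatch.tolist()[:5]}"
                )
        df["group"] = derived
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    def filter_samples(self, ids) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(ids)])


@dataclass
class LogRatioSeries:
    """Per-sample natural log ratio of two disjoint feature sets.

    ``values`` is indexed by the retained sample ids; samples where either
    the numerator or the denominator sums to zero are excluded and listed
    in ``dropped_samples``.
    """

    values: pd.Series
    numerator_ids: tuple[str, ...]
    denominator_ids: tuple[str, ...]
    dropped_samples: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        num = frozenset(self.numerator_ids)
        den = frozenset(self.denominator_ids)
        if not num or not den:
            raise ValueError("numerator and denominator sets must be nonempty")
        overlap = num & den
        if overlap:
            raise ValueError(
                f"numerator and denominator overlap: {sorted(overlap)[:5]}"
            )
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("log-ratio values must be finite for retained samples")
        self.numerator_ids = tuple(self.numerator_ids)
        self.denominator_ids = tuple(self.denominator_ids)
        self.dropped_samples = tuple(self.dropped_samples)
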