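"""Reading, writing, aligning, filtering and rarefying feature tables.

Feature tables travel as BIOM (HDF5 or JSON) or TSV; sample metadata is a
TSV whose first column holds the sample id (QIIME2 convention).  TSV
orientation (features-as-rows vs samples-as-rows) must be declared — no
guessing.
"""

from __future__ import annotations

import logging
from pathlib import Path

import biom
import numpy as np
import pandas as pd

from .containers import FeatureTable, SampleMetadata

logger = logging.getLogger(__name__)


def _read_tsv_matrix(path: Path) -> pd.DataFrame:
    # manual pre-scan so a ragged file fails with the offending line number
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        width = len(header)
        for lineno, line in enumerate(fh, start=2):
            if line.strip() == "":
                continue
            ncol = line.rstrip("\n").count("\t") + 1
            if ncol != width:
                raise ValueError(
                    f"ragged TSV {path}: line {lineno} has {ncol} fields, "
                    f"header has {width}"
                )
    return pd.read_csv(path, sep="\t", index_col=0)


def read_feature_table(
    path,
    format: str = "tsv",
    orientation: str = "features",
    kind: str = "counts",
) -> FeatureTable:
    """Read a feature table from BIOM or TSV.

    Parameters
    ----------
    format : {"tsv", "biom"}
    orientation : {"features", "samples"}
        For TSV only: whether rows of the file are features (QIIME-style
        export) or samples.
    kind : {"counts", "intensities"}
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "biom":
        table = biom.load_table(str(path))
        df = table.to_dataframe(dense=True).T  # biom stores features x samples
        return FeatureTable(df, kind=kind)
    if format == "tsv":
        if orientation not in ("features", "samples"):
            raise ValueError("orientation must be 'features' or 'samples'")
        df = _read_tsv_matrix(path)
        if orientation == "features":
            df = df.T
        return FeatureTable(df.astype(float), kind=kind)
    raise ValueError(f"unknown format {format!r}")


def write_feature_table(
    t: FeatureTable, path, format: str = "tsv", orientation: str = "features"
) -> None:
    """Write a feature table as TSV (declared orientation) or JSON BIOM."""
    path = Path(path)
    if format == "biom":
        table = biom.Table(
            t.values.T, observation_ids=t.feature_ids, sample_ids=t.sample_ids
        )
        with open(path, "w") as fh:
            fh.write(table.to_json("jointomics"))
        return
    if format == "tsv":
        df = t.data.T if orientation == "features" else t.data
        if t.kind == "counts" and float(np.abs(df.to_numpy() % 1).max()) == 0.0:
            df = df.astype(np.int64)
        df.to_csv(path, sep="\t")
        return
    raise ValueError(f"unknown format {format!r}")


def read_metadata(path) -> SampleMetadata:
    """Read sample metadata TSV; the first column is the sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id")


def align_tables(
    t1: FeatureTable, t2: FeatureTable, meta: SampleMetadata
) -> tuple[FeatureTable, FeatureTable, SampleMetadata]:
    """Restrict two omics tables and the metadata to their shared samples.

    The intersection is ordered as in ``t1``; at least 3 shared samples are
    required.
    """
    shared = [
        s
        for s in t1.sample_ids
        if s in set(t2.sample_ids) and s in set(meta.sample_ids)
    ]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} samples shared between tables and metadata; "
            "need at least 3"
        )
    return (
        t1.filter_samples(shared),
        t2.filter_samples(shared),
        meta.filter_samples(shared),
    )


def rarefy(
    t: FeatureTable, depth: int = 10_200, seed: int = 0
) -> tuple[FeatureTable, list[str]]:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped; their ids are
    returned (and logged) rather than padded.  Subsampling is multivariate
    hypergeometric, so each retained sample sums exactly to ``depth``.

    Returns
    -------
    (rarefied_table, dropped_sample_ids)
    """
    if t.kind != "counts":
        raise ValueError("rarefaction is defined for count tables only")
    if depth <= 0:
        raise ValueError("depth must be a positive integer")
    rng = np.random.default_rng(seed)
    counts = np.rint(t.values).astype(np.int64)
    totals = counts.sum(axis=1)
    keep = totals >= depth
    dropped = [sid for sid, k in zip(t.sample_ids, keep) if not k]
    if dropped:
        logger.info("rarefy: dropped %d samples below depth %d: %s",
                    len(dropped), depth, dropped)
    out = np.empty((int(keep.sum()), counts.shape[1]), dtype=np.int64)
    for row, i in enumerate(np.flatnonzero(keep)):
        if totals[i] == depth:
            out[row] = counts[i]
        else:
            out[row] = rng.multivariate_hypergeometric(counts[i], depth)
    kept_ids = [sid for sid, k in zip(t.sample_ids, keep) if k]
    df = pd.DataFrame(out, index=kept_ids, columns=t.feature_ids)
    return FeatureTable(df, kind="counts"), dropped
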