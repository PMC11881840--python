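"""Config-driven end-to-end workflow.

Chains the analysis the way the study runs it: rarefy the count table,
rclr-transform, ordinate each table (RPCA) and test group separation
(PERMANOVA), select features by loading rank / VIP, jointly factorize the
two omics tables, correlate features across omics, build the family and
metabolite-panel log ratios, and regress one log ratio on the other.
Every stochastic stage takes its seed from the config and all seeds and
parameters are echoed into ``provenance.json``; reruns with the same
config are bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compositional import feature_set_log_ratio, rclr, write_log_ratio

from .io import align_tables, rarefy, read_feature_table, read_metadata
from .joint import (
    JointRPCA,
    RobustPCA,
    cross_correlations,
    select_features_by_loading,
)
from .plsda import fit_plsda, significant_feature_log_ratio, vip_table
from .stats import (
    lme_trend,
    logratio_group_regression,
    pairwise_mannwhitney,
    permanova,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a stage fails; message carries the stage name."""


@dataclass
class RunConfig:
    """Validated inputs, parameters and seeds of one pipeline run."""

    microbiome_path: str
    metabolome_path: str
    metadata_path: str
    out_dir: str
    table_format: str = "tsv"
    tsv_orientation: str = "features"
    rarefaction_depth: int = 10_200
    rarefaction_seed: int = 0
    rank: int = 3
    max_iter: int = 200
    tol: float = 1e-6
    seed: int = 0
    train_fraction: float = 0.8
    n_splits: int = 5
    loading_quantile: float = 0.1
    vip_threshold: float = 1.0
    plsda_components: int = 2
    plsda_folds: int = 5
    plsda_groups: tuple[str, str] = ("RC-Air", "HFHC-IHC")
    family_numerator: tuple[str, ...] = ()
    family_denominator: tuple[str, ...] = ()
    permanova_permutations: int = 999
    mw_last_k_timepoints: int = 2

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        return cfg

    def validate(self) -> None:
        for name in ("microbiome_path", "metabolome_path", "metadata_path"):
            p = getattr(self, name)
            if not p:
                raise ValueError(f"config missing {name}")
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        if self.rarefaction_depth <= 0:
            raise ValueError("rarefaction_depth must be positive")
        if not (0.5 < self.train_fraction < 0.95):
            raise ValueError("train_fraction must be in (0.5, 0.95)")
        if len(self.plsda_groups) != 2:
            raise ValueError("plsda_groups must name exactly two groups")
        if not self.family_numerator or not self.family_denominator:
            raise ValueError(
                "family_numerator and family_denominator feature lists are required"
            )


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    @_stage("read")
    def _read():
        microbes = read_feature_table(
            config.microbiome_path, format=config.table_format,
            orientation=config.tsv_orientation, kind="counts",
        )
        metabolites = read_feature_table(
            config.metabolome_path, format=config.table_format,
            orientation=config.tsv_orientation, kind="intensities",
        )
        meta = read_metadata(config.metadata_path)
        return microbes, metabolites, meta

    microbes, metabolites, meta = _read()

    @_stage("rarefy")
    def _rarefy():
        rt, dropped = rarefy(
            microbes, depth=config.rarefaction_depth, seed=config.rarefaction_seed
        )
        return rt, dropped

    microbes_r, dropped = _rarefy()

    @_stage("align")
    def _align():
        return align_tables(microbes_r, metabolites, meta)

    microbes_a, metabolites_a, meta_a = _align()

    @_stage("rpca")
    def _rpca():
        results = {}
        for name, table in (("microbiome", microbes_a), ("metabolome", metabolites_a)):
            est = RobustPCA(
                rank=config.rank, max_iter=config.max_iter, tol=config.tol,
                seed=config.seed,
            ).fit(table)
            est.ordination_.write(str(out / f"{name}_ordination.txt"))
            est.distance_matrix_.write(str(out / f"{name}_distance.tsv"))
            results[name] = est
        return results

    rpca_results = _rpca()

    @_stage("permanova")
    def _permanova():
        res = permanova(
            rpca_results["microbiome"].distance_matrix_,
            meta_a.data["group"],
            permutations=config.permanova_permutations,
            seed=config.seed,
        )
        _write_json(
            {
                "pseudo_F": res.pseudo_F, "p_value": res.p_value,
                "permutations": res.permutations, "group_sizes": res.group_sizes,
                "seed": config.seed,
            },
            out / "permanova.json",
        )
        return res

    perm = _permanova()

    @_stage("plsda")
    def _plsda():
        ga, gb = config.plsda_groups
        in_pair = meta_a.data["group"].isin([ga, gb])
        sub = metabolites_a.filter_samples(meta_a.data.index[in_pair])
        m = rclr(sub)
        labels = meta_a.data.loc[in_pair, "group"].to_numpy()
        model = fit_plsda(
            m, labels, n_components=config.plsda_components,
            folds=config.plsda_folds, seed=config.seed,
            vip_threshold=config.vip_threshold,
        )
        tab = vip_table(model, m, labels)
        tab.to_csv(out / "plsda_vip.tsv", sep="\t", index_label="feature_id",
                   float_format="%.6g")
        _write_json(
            {
                "groups": list(config.plsda_groups),
                "n_components": model.n_components_,
                "cv_cer": model.cv_cer_,
                "n_selected": int(model.selected_.sum()),
                "vip_threshold": config.vip_threshold,
                "seed": config.seed,
            },
            out / "plsda_summary.json",
        )
        return model, m, sub, labels

    plsda_model, plsda_rclr, plsda_table, plsda_labels = _plsda()

    @_stage("feature_selection")
    def _select():
        mic_sel = select_features_by_loading(
            rpca_results["microbiome"].features_["PC1"], q=config.loading_quantile
        )
        mic_keep = list(dict.fromkeys(
            mic_sel + list(config.family_numerator) + list(config.family_denominator)
        ))
        met_sel = select_features_by_loading(
            rpca_results["metabolome"].features_["PC1"], q=config.loading_quantile
        )
        vip_ids = (
            np.asarray(metabolites_a.feature_ids)[plsda_model.selected_].tolist()
            if plsda_model.selected_.any() else []
        )
        met_keep = list(dict.fromkeys(met_sel + vip_ids))
        return (
            microbes_a.filter_features(mic_keep),
            metabolites_a.filter_features(met_keep),
        )

    mic_f, met_f = _select()

    @_stage("joint")
    def _joint():
        est = JointRPCA(
            rank=config.rank, max_iter=config.max_iter, tol=config.tol,
            n_splits=config.n_splits, train_fraction=config.train_fraction,
            seed=config.seed,
        ).fit([mic_f, met_f])
        scores = est.sample_scores_
        scores.to_csv(out / "joint_sample_scores.tsv", sep="\t",
                      index_label="sample_id", float_format="%.6g")
        for name, ld in zip(("microbiome", "metabolome"), est.feature_loadings_):
            ld.to_csv(out / f"joint_{name}_loadings.tsv", sep="\t",
                      index_label="feature_id", float_format="%.6g")
        _write_json(
            {
                "rank": config.rank,
                "singular_values": est.singular_values_.tolist(),
                "proportion_explained": est.proportion_explained_.tolist(),
                "cv_train_error": est.cv_train_error_.tolist(),
                "cv_test_error": est.cv_test_error_.tolist(),
                "n_splits": config.n_splits,
                "train_fraction": config.train_fraction,
                "seed": config.seed,
            },
            out / "joint_cv.json",
        )
        return est

    joint_est = _joint()

    @_stage("correlations")
    def _correlations():
        corr = cross_correlations(joint_est.to_result())
        corr.matrix.to_csv(out / "cross_omic_correlations.tsv", sep="\t",
                           index_label="feature_id", float_format="%.6g")
        return corr

    _correlations()

    @_stage("log_ratios")
    def _log_ratios():
        fam = feature_set_log_ratio(
            microbes_a, config.family_numerator, config.family_denominator
        )
        write_log_ratio(fam, out / "family_log_ratio.tsv", meta_a)
        panel = significant_feature_log_ratio(
            plsda_model, metabolites_a, plsda_rclr, plsda_labels,
            numerator_class=config.plsda_groups[0],
        )
        write_log_ratio(panel, out / "metabolite_panel_log_ratio.tsv", meta_a)
        return fam, panel

    fam_lr, panel_lr = _log_ratios()

    @_stage("group_tests")
    def _group_tests():
        ages = meta_a.data["host_age"]
        last_ages = sorted(ages.unique())[-config.mw_last_k_timepoints:]
        late = fam_lr.values.index[
            ages.reindex(fam_lr.values.index).isin(last_ages)
        ]
        mw = pairwise_mannwhitney(
            fam_lr.values.loc[late],
            meta_a.data.loc[late, "group"],
        )
        mw.to_csv(out / "family_log_ratio_pairwise_tests.tsv", sep="\t",
                  index=False, float_format="%.6g")
        reg = logratio_group_regression(fam_lr, panel_lr)
        _write_json(
            {"r": reg.r, "p": reg.p, "slope": reg.slope,
             "intercept": reg.intercept, "n": reg.n},
            out / "logratio_regression.json",
        )
        try:
            lme = lme_trend(fam_lr, meta_a)
            lme.coefficients.round(6).to_csv(
                out / "family_log_ratio_lme.tsv", sep="\t", index_label="term"
            )
        except ValueError as exc:
            logger.warning("lme_trend skipped: %s", exc)
        return mw, reg

    _group_tests()

    @_stage("provenance")
    def _provenance():
        import scipy
        import sklearn

        prov = {
            "jointomics": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "config": asdict(config),
            "rarefaction_dropped_samples": dropped,
            "n_samples_analyzed": len(meta_a.sample_ids),
        }
        _write_json(prov, out / "provenance.json")

    _provenance()
    return out
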