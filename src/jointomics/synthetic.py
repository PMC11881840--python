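"""Synthetic paired longitudinal microbiome + metabolome cohorts.

The generator emulates the statistical structure of a three-arm mouse
study (RC-Air, HFHC-Air, HFHC-IHC) sampled repeatedly over ten weeks:

* a low-rank log-scale model shared between the two omics layers —
  per-sample latent factors ``F`` (n x r) with per-feature loadings;
* axis 1 carries the diet/exposure signal: it grows linearly with time
  scaled by a per-group multiplier (RC-Air 0 < HFHC-Air < HFHC-IHC 1)
  and by ``effect_size``; axis 2 mixes a per-mouse level with sample
  noise; further axes (if any) are pure sample noise;
* microbe counts are multinomial draws from softmax(log-linear model)
  with a subject random intercept and Bernoulli dropout (zero inflation);
* metabolite intensities are log-normal on the same factors with additive
  noise and their own dropout;
* planted structure for recovery tests: opposing-enrichment families
  ("MuribaculaceaeLike" depleted, "AkkermansiaceaeLike" enriched under
  HFHC-IHC), RC- vs HFHC-IHC-associated metabolite panels, and
  microbe-metabolite pairs whose metabolite loading vector *equals* the
  microbe's (and whose log intensity carries no feature noise).

Loading matrices are centered to zero column mean (clr identifiability),
planted-pair features get a high baseline so their profiles are well
determined, and all randomness flows from one master seed split into
named streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureTable, SampleMetadata
from .io import write_feature_table, write_metadata

GROUP_MULTIPLIERS = {"RC-Air": 0.0, "HFHC-Air": 0.6, "HFHC-IHC": 1.0}

_STREAMS = {
    "factors": 0,
    "loadings": 1,
    "baselines": 2,
    "subject": 3,
    "depth": 4,
    "counts": 5,
    "dropout": 6,
    "noise": 7,
    "met_dropout": 8,
}


def _default_timepoints() -> tuple[float, ...]:
    # host age in weeks: enrolled at 10, sampled twice weekly for 10 weeks
    return tuple(10.0 + 0.5 * k for k in range(20))


@dataclass
class CohortDesign:
    """Study design and generative scales of the synthetic cohort."""

    groups: tuple[str, ...] = ("RC-Air", "HFHC-Air", "HFHC-IHC")
    mice_per_group: int = 8
    timepoints: tuple[float, ...] = field(default_factory=_default_timepoints)
    n_microbes: int = 150
    n_metabolites: int = 250
    depth_mean: float = 12_000.0
    dropout: float = 0.3
    met_dropout: float = 0.2
    rank: int = 2
    effect_size: float = 1.2
    n_akkermansiaceae: int = 8
    n_muribaculaceae: int = 12
    n_group_metabolites: int = 15  # per associated panel
    n_pairs: int = 5
    factor_noise: float = 0.35
    subject_sd: float = 0.5
    loading_sd: float = 0.4
    feature_noise: float = 0.3
    subject_intercept_sd: float = 0.2
    depth_log_sd: float = 0.2
    dirichlet_overdispersion: float | None = None  # DM mixing when set

    def __post_init__(self) -> None:
        if self.mice_per_group < 2:
            raise ValueError("mice_per_group must be >= 2")
        if len(self.timepoints) < 2:
            raise ValueError("need >= 2 timepoints")
        tp = np.asarray(self.timepoints, dtype=float)
        if not (np.diff(tp) > 0).all():
            raise ValueError("timepoints must be strictly increasing")
        for name in ("depth_mean", "n_microbes", "n_metabolites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.dropout < 1 and 0 <= self.met_dropout < 1):
            raise ValueError("dropout probabilities must be in [0, 1)")
        if self.rank < 2:
            raise ValueError("rank must be >= 2 (group axis + mouse axis)")
        if any(g not in GROUP_MULTIPLIERS for g in self.groups):
            raise ValueError(f"groups must be among {list(GROUP_MULTIPLIERS)}")
        planted = (self.n_akkermansiaceae + self.n_muribaculaceae + self.n_pairs)
        if planted >= self.n_microbes:
            raise ValueError("too many planted microbe features for n_microbes")
        if 2 * self.n_group_metabolites + self.n_pairs >= self.n_metabolites:
            raise ValueError("too many planted metabolite features")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort, for recovery tests."""

    latent_factors: pd.DataFrame
    microbe_loadings: pd.DataFrame
    metabolite_loadings: pd.DataFrame
    group_effects: dict[str, float]
    family_map: dict[str, str]
    rc_metabolites: tuple[str, ...]
    ihc_metabolites: tuple[str, ...]
    planted_pairs: tuple[tuple[str, str], ...]
    seeds: dict[str, int]

    @property
    def muribaculaceae_ids(self) -> list[str]:
        return [f for f, fam in self.family_map.items() if fam == "MuribaculaceaeLike"]

    @property
    def akkermansiaceae_ids(self) -> list[str]:
        return [f for f, fam in self.family_map.items() if fam == "AkkermansiaceaeLike"]

    def to_json_dict(self) -> dict:
        return {
            "group_effects": self.group_effects,
            "family_map": self.family_map,
            "rc_metabolites": list(self.rc_metabolites),
            "ihc_metabolites": list(self.ihc_metabolites),
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "seeds": self.seeds,
            "latent_factors": {
                "index": self.latent_factors.index.tolist(),
                "values": self.latent_factors.round(6).to_numpy().tolist(),
            },
        }


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed % (2**31), _STREAMS[stream]])


def simulate(
    design: CohortDesign | None = None, truth_seed: int = 0
) -> tuple[FeatureTable, FeatureTable, SampleMetadata, SyntheticTruth]:
    """Simulate a paired cohort; identical seed gives identical tables."""
    d = design if design is not None else CohortDesign()
    tps = np.asarray(d.timepoints, dtype=float)
    tau = (tps - tps[0]) / (tps[-1] - tps[0])

    rows = []
    for g in d.groups:
        for m in range(d.mice_per_group):
            subj = f"{g}.m{m:02d}"
            for k, age in enumerate(tps):
                rows.append((f"{subj}.t{k:02d}", subj, g, float(age), tau[k]))
    n = len(rows)
    sample_ids = [r[0] for r in rows]
    subjects = sorted({r[1] for r in rows})
    sidx = {s: i for i, s in enumerate(subjects)}
    si = np.array([sidx[r[1]] for r in rows])
    gmult = np.array([GROUP_MULTIPLIERS[r[2]] for r in rows])
    tfrac = np.array([r[4] for r in rows])

    # latent factors
    rf = _rng(truth_seed, "factors")
    F = np.empty((n, d.rank))
    F[:, 0] = d.effect_size * gmult * tfrac + rf.normal(0, d.factor_noise, n)
    F[:, 1] = (
        rf.normal(0, d.subject_sd, len(subjects))[si]
        + rf.normal(0, d.subject_sd, n)
    )
    for k in range(2, d.rank):
        F[:, k] = rf.normal(0, 0.7, n)

    # microbe loadings: opposing families on axis 1, spread on later axes
    rl = _rng(truth_seed, "loadings")
    n_akk, n_muri, n_pairs = d.n_akkermansiaceae, d.n_muribaculaceae, d.n_pairs
    akk = np.arange(0, n_akk)
    muri = np.arange(n_akk, n_akk + n_muri)
    pair_mic = np.arange(n_akk + n_muri, n_akk + n_muri + n_pairs)
    L = rl.normal(0, d.loading_sd, (d.n_microbes, d.rank))
    L[akk, 0] = rl.uniform(0.6, 1.4, n_akk)
    L[muri, 0] = -rl.uniform(0.6, 1.4, n_muri)
    L[np.r_[akk, muri], 1:] = rl.normal(0, 0.8, (n_akk + n_muri, d.rank - 1))
    dirs = rl.normal(size=(n_pairs, d.rank))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    L[pair_mic] = 1.5 * dirs
    L -= L.mean(axis=0, keepdims=True)

    # metabolite loadings: RC vs HFHC-IHC panels, planted pairs copy the
    # (centered) microbe loadings exactly
    npm = d.n_group_metabolites
    rc_set = np.arange(0, npm)
    ihc_set = np.arange(npm, 2 * npm)
    pair_met = np.arange(2 * npm, 2 * npm + n_pairs)
    Lm = rl.normal(0, d.loading_sd, (d.n_metabolites, d.rank))
    Lm[rc_set, 0] = -rl.uniform(0.6, 1.4, npm)
    Lm[ihc_set, 0] = rl.uniform(0.6, 1.4, npm)
    Lm[np.r_[rc_set, ihc_set], 1:] = rl.normal(0, 0.8, (2 * npm, d.rank - 1))
    Lm -= Lm.mean(axis=0, keepdims=True)
    Lm[pair_met] = L[pair_mic]
    nonpair = np.ones(d.n_metabolites, bool)
    nonpair[pair_met] = False
    Lm[nonpair] -= Lm.mean(axis=0, keepdims=True) * (
        d.n_metabolites / (d.n_metabolites - n_pairs)
    )

    rb = _rng(truth_seed, "baselines")
    base_mic = rb.normal(0, 1.0, d.n_microbes)
    base_mic[np.r_[akk, muri]] = rb.normal(1.5, 0.3, n_akk + n_muri)
    base_mic[pair_mic] = rb.normal(3.0, 0.2, n_pairs)
    base_met = rb.normal(10.0, 1.0, d.n_metabolites)

    rs = _rng(truth_seed, "subject")
    subj_int = rs.normal(0, d.subject_intercept_sd, (len(subjects), d.n_microbes))

    # microbe counts: multinomial on softmax(log-linear), then dropout
    logp = F @ L.T + base_mic + subj_int[si]
    P = np.exp(logp - logp.max(axis=1, keepdims=True))
    P /= P.sum(axis=1, keepdims=True)
    rd = _rng(truth_seed, "depth")
    # depth_mean is the expected *observed* library size; dropout removes a
    # (1 - dropout) fraction of counts after the draw, so compensate here
    target = rd.lognormal(np.log(d.depth_mean), d.depth_log_sd, n)
    depth = np.maximum(200, (target / max(1.0 - d.dropout, 1e-9)).astype(np.int64))
    rc_counts = _rng(truth_seed, "counts")
    counts = np.empty((n, d.n_microbes), dtype=np.int64)
    for i in range(n):
        p = P[i]
        if d.dirichlet_overdispersion is not None:
            p = rc_counts.dirichlet(d.dirichlet_overdispersion * p)
        counts[i] = rc_counts.multinomial(depth[i], p)
    rdrop = _rng(truth_seed, "dropout")
    counts = np.where(rdrop.random(counts.shape) < d.dropout, 0, counts)

    # metabolite intensities: log-normal on the same factors
    rn = _rng(truth_seed, "noise")
    eps = rn.normal(0, d.feature_noise, (n, d.n_metabolites))
    eps[:, pair_met] = 0.0  # planted pairs are noiseless functions of the factors
    inten = np.exp(F @ Lm.T + base_met + eps)
    rmd = _rng(truth_seed, "met_dropout")
    inten = np.where(rmd.random(inten.shape) < d.met_dropout, 0.0, inten)

    mic_ids = [f"ASV_{j:04d}" for j in range(d.n_microbes)]
    met_ids = [f"MET_{j:04d}" for j in range(d.n_metabolites)]
    family_map = {mic_ids[j]: "Other" for j in range(d.n_microbes)}
    for j in akk:
        family_map[mic_ids[j]] = "AkkermansiaceaeLike"
    for j in muri:
        family_map[mic_ids[j]] = "MuribaculaceaeLike"
    for j in pair_mic:
        family_map[mic_ids[j]] = "PairedMarker"

    microbes = FeatureTable(
        pd.DataFrame(counts, index=sample_ids, columns=mic_ids), kind="counts"
    )
    metabolites = FeatureTable(
        pd.DataFrame(inten, index=sample_ids, columns=met_ids), kind="intensities"
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "host_subject_id": [r[1] for r in rows],
                "host_age": [r[3] for r in rows],
                "diet": [r[2].split("-")[0] for r in rows],
                "exposure": [r[2].split("-")[1] for r in rows],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    axes = [f"F{k+1}" for k in range(d.rank)]
    truth = SyntheticTruth(
        latent_factors=pd.DataFrame(F, index=sample_ids, columns=axes),
        microbe_loadings=pd.DataFrame(L, index=mic_ids, columns=axes),
        metabolite_loadings=pd.DataFrame(Lm, index=met_ids, columns=axes),
        group_effects={
            g: d.effect_size * GROUP_MULTIPLIERS[g] for g in d.groups
        },
        family_map=family_map,
        rc_metabolites=tuple(met_ids[j] for j in rc_set),
        ihc_metabolites=tuple(met_ids[j] for j in ihc_set),
        planted_pairs=tuple(
            (mic_ids[i], met_ids[j]) for i, j in zip(pair_mic, pair_met)
        ),
        seeds={"truth_seed": int(truth_seed)},
    )
    return microbes, metabolites, meta, truth


def write_fixture(
    bundle: tuple[FeatureTable, FeatureTable, SampleMetadata, SyntheticTruth],
    path,
    table_format: str = "tsv",
) -> dict[str, str]:
    """Write a simulated cohort to one directory.

    Intensities are rounded to 6 significant digits so the files are
    compact and read/write round trips are bit-stable.  Returns the map
    of artifact name -> file path.
    """
    microbes, metabolites, meta, truth = bundle
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ext = "biom" if table_format == "biom" else "tsv"
    files = {
        "microbes": str(path / f"microbes.{ext}"),
        "metabolites": str(path / f"metabolites.{ext}"),
        "metadata": str(path / "metadata.tsv"),
        "truth": str(path / "truth.json"),
    }
    if table_format == "tsv":
        microbes.data.T.astype(np.int64).to_csv(files["microbes"], sep="\t")
        metabolites.data.T.to_csv(
            files["metabolites"], sep="\t", float_format="%.6g"
        )
    else:
        write_feature_table(microbes, files["microbes"], format=table_format)
        write_feature_table(metabolites, files["metabolites"], format=table_format)
    write_metadata(meta, files["metadata"])
    with open(files["truth"], "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
    return files
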