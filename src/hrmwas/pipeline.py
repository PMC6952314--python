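"""End-to-end pipeline: simulate or load two studies, filter, batch-correct,
run the per-study censored-regression MWAS, match features across studies,
meta-analyze, apply the replication/selection rule and medication
sensitivity check, annotate, and correlate selected features with CSF
biomarkers. Writes TSV result tables and a JSON run manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import annotate_table
from .censored_regression import (
    MEDICATION_TARGETS,
    ModelSpec,
    detect_medication_indicators,
    fit_censored_lognormal,
    fit_with_medication_adjustment,
)
from .chem import packaged_compounds
from .correlations import biomarker_correlations
from .feature_table import (
    FeatureTable,
    correct_batches,
    filter_presence,
    filter_rt,
    read_feature_table,
)
from .matching import match_features, matches_to_frame
from .meta_mwas import combine_studies, medication_sensitivity_check, select_features
from .synthetic_data import SimConfig, generate_two_studies, spike_medication_features

log = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_DATA = 3
EXIT_NONCONVERGENCE = 4


@dataclass
class RunConfig:
    """Thresholds and inputs for one pipeline run. ``simulate`` holds
    SimConfig overrides; alternatively give per-study table/metadata paths."""

    out_dir: str = "hrmwas_run"
    seed: int = 0
    rt_min: float = 30.0
    presence_min: float = 0.80
    ppm_tol: float = 5.0
    rt_tol: float = 30.0
    fdr: float = 0.20
    per_study_p: float = 0.10
    attenuation: float = 0.20
    corr_min: float = 0.7
    max_nonconverged_frac: float = 0.05
    simulate: dict | None = None
    study1_table: str | None = None
    study1_metadata: str | None = None
    study2_table: str | None = None
    study2_metadata: str | None = None
    spike_medications: bool = True

    def validate(self):
        if not (0 < self.presence_min <= 1 and 0 < self.fdr <= 1 and 0 < self.per_study_p <= 1):
            raise ValueError("fractional thresholds must lie in (0, 1]")
        if self.ppm_tol <= 0 or self.rt_tol <= 0 or self.rt_min < 0:
            raise ValueError("tolerances must be positive (rt_min >= 0)")
        if not 0 < self.attenuation < 1:
            raise ValueError("attenuation must be in (0, 1)")
        files = (self.study1_table, self.study2_table)
        if self.simulate is None and any(f is None for f in files):
            raise ValueError("either simulate: settings or both study table paths are required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _mwas_one_study(table: FeatureTable, info: pd.DataFrame, study: str,
                    med_indicators: pd.DataFrame | None) -> pd.DataFrame:
    rows = []
    samples = info[info["study_id"] == study]
    for fid in table.feature_ids:
        spec = ModelSpec(outcome=fid)
        try:
            fit = fit_censored_lognormal(table.intensities.loc[fid], samples, spec)
        except Exception as exc:  # rank deficiency etc. — recorded, not fatal
            log.warning("%s/%s: fit failed (%s)", study, fid, exc)
            continue
        rec = fit.to_dict()
        rec.update(study_id=study, feature_id=fid)
        if med_indicators is not None:
            try:
                adj = fit_with_medication_adjustment(
                    table.intensities.loc[fid], samples, spec, med_indicators
                )
                rec["est_med_adjusted"] = float(adj.params["diagnosis"]) if adj.converged else np.nan
            except Exception:
                rec["est_med_adjusted"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Run the full workflow; returns the artifact directory.

    Deterministic given the seed. Writes mwas_results.tsv, matches.tsv,
    annotations.tsv, correlations.tsv and manifest.json.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "thresholds": {k: getattr(config, k) for k in
                                     ("rt_min", "presence_min", "ppm_tol", "rt_tol",
                                      "fdr", "per_study_p", "attenuation", "corr_min")},
                      "fdr_method": "Benjamini-Hochberg step-up",
                      "matching": "greedy one-to-one by |rt_diff| then |ppm_diff|",
                      "counts": {}}

    # --- load or simulate ---
    if config.simulate is not None:
        sim = SimConfig(**{**config.simulate, "seed": config.seed})
        t1, t2, info, truth = generate_two_studies(sim)
        if config.spike_medications:
            cases1 = info.index[(info["study_id"] == "study1") & (info["diagnosis"] == "AD")]
            cases2 = info.index[(info["study_id"] == "study2") & (info["diagnosis"] == "AD")]
            t1 = spike_medication_features(t1, MEDICATION_TARGETS, 0.4, cases1, seed=config.seed + 1)
            t2 = spike_medication_features(t2, MEDICATION_TARGETS, 0.4, cases2, seed=config.seed + 2)
        (out / "ground_truth.json").write_text(json.dumps(truth.to_json_dict(), indent=1))
    else:
        t1, info1 = read_feature_table(config.study1_table, config.study1_metadata)
        t2, info2 = read_feature_table(config.study2_table, config.study2_metadata)
        info = pd.concat([info1, info2])
    studies = {"study1": t1, "study2": t2}
    manifest["counts"]["features_in"] = {s: int(len(t.features)) for s, t in studies.items()}

    # --- medication indicators from the *unfiltered* tables ---
    med = {s: detect_medication_indicators(t) for s, t in studies.items()}

    # --- filter and batch-correct per study ---
    filtered = {}
    for s, t in studies.items():
        t = filter_rt(t, config.rt_min)
        manifest["counts"].setdefault("after_rt_filter", {})[s] = int(len(t.features))
        t = filter_presence(t, config.presence_min)
        manifest["counts"].setdefault("after_presence_filter", {})[s] = int(len(t.features))
        t = correct_batches(t)
        filtered[s] = t

    # --- per-study MWAS ---
    results = []
    for s, t in filtered.items():
        res = _mwas_one_study(t, info, s, med[s])
        frac_bad = 1.0 - res["converged"].mean() if len(res) else 1.0
        if frac_bad > config.max_nonconverged_frac:
            raise RuntimeError(
                f"stage mwas[{s}]: {frac_bad:.1%} of fits non-convergent "
                f"(limit {config.max_nonconverged_frac:.1%})"
            )
        results.append(res)
    study_results = pd.concat(results, ignore_index=True)

    # --- cross-study matching; meta-analysis over the common set ---
    pairs = match_features(filtered["study1"], filtered["study2"],
                           ppm_tol=config.ppm_tol, rt_tol=config.rt_tol)
    matches_to_frame(pairs, filtered["study1"], filtered["study2"]).to_csv(
        out / "matches.tsv", sep="\t", index=False)
    manifest["counts"]["matched_features"] = len(pairs)

    # canonical id per matched pair = study-1 feature id
    id2_to_1 = {p.feature_id_2: p.feature_id_1 for p in pairs}
    long = study_results.copy()
    long.loc[long["study_id"] == "study2", "feature_id"] = (
        long.loc[long["study_id"] == "study2", "feature_id"].map(id2_to_1))
    long = long.dropna(subset=["feature_id"])
    records = combine_studies(long[["study_id", "feature_id", "est", "se", "p"]]
                              .rename(columns={"est": "estimate"}))
    records = select_features(records, fdr_thresh=config.fdr, per_study_p=config.per_study_p)

    # --- medication sensitivity check on the selected features ---
    adj_map = long.set_index(["feature_id", "study_id"])
    verdicts = {}
    if "est_med_adjusted" in long.columns:
        for fid in records.index[records["selected"]]:
            unadj = {s: float(adj_map.loc[(fid, s), "est"]) for s in ("study1", "study2")}
            adjd = {}
            for s in ("study1", "study2"):
                v = adj_map.loc[(fid, s), "est_med_adjusted"]
                adjd[s] = float(v) if np.isfinite(v) else None
            verdicts[fid] = medication_sensitivity_check(unadj, adjd, config.attenuation)
        records["medication_verdict"] = [
            verdicts.get(f, {}).get("verdict", "") for f in records.index]
        records["selected_final"] = records["selected"] & (
            records["medication_verdict"] != "exclude")
    else:
        records["selected_final"] = records["selected"]
    records.to_csv(out / "mwas_results.tsv", sep="\t")
    manifest["counts"]["meta_analyzed"] = int(len(records))
    manifest["counts"]["selected"] = int(records["selected"].sum())
    manifest["counts"]["selected_final"] = int(records["selected_final"].sum())

    # --- annotation of the study-1 filtered table ---
    _, annotations = annotate_table(
        filtered["study1"], packaged_compounds(),
        corr_min=config.corr_min, tol_ppm=config.ppm_tol)
    annotations.to_csv(out / "annotations.tsv", sep="\t")

    # --- biomarker correlations for the selected features ---
    final = records.index[records["selected_final"]]
    feature_map = {}
    id1_to_2 = {p.feature_id_1: p.feature_id_2 for p in pairs}
    for fid in final:
        feature_map[fid] = {"study1": fid, "study2": id1_to_2.get(fid, fid)}
    corr = biomarker_correlations(
        {s: t.intensities for s, t in filtered.items()},
        {s: info[info["study_id"] == s] for s in filtered},
        feature_map,
    )
    corr.to_csv(out / "correlations.tsv", sep="\t", index=False)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def boxplot_by_diagnosis(table: FeatureTable, info: pd.DataFrame, feature_id: str, path) -> None:
    """Basic log2 intensity boxplot by diagnosis with the feature's LOD
    (lowest detected intensity) drawn as a horizontal line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = table.intensities.loc[feature_id]
    groups, labels = [], []
    for dx in ("NC", "MCI", "AD"):
        samp = info.index[info["diagnosis"] == dx].intersection(vals.index)
        if len(samp) == 0:
            continue
        v = np.log2(vals.loc[samp].dropna().to_numpy(float))
        groups.append(v)
        labels.append(dx)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.boxplot(groups, tick_labels=labels)
    ax.axhline(np.log2(table.lod[feature_id]), color="grey", linestyle="--", linewidth=1)
    ax.set_ylabel("log2 intensity")
    ax.set_title(feature_id)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
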