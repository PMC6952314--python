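"""Data model, I/O, filtering, batch correction and CSF classification for
untargeted LC-MS feature tables.

A feature table is a features x samples matrix of positive ion abundances in
which a missing cell means *non-detect* (the value is known only to lie below
that feature's limit of detection). The limit of detection (LOD) is defined
per feature as the lowest detected intensity, and is always derived from the
current matrix so the invariant "every detected intensity >= LOD" holds on
any table downstream code sees.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SCHEMA_HEADER = "# hrmwas feature-table schema v1"
METADATA_HEADER = "# hrmwas sample-metadata schema v1"

DIAGNOSES = ("NC", "MCI", "AD")

#: Required sample-metadata columns (besides the sample_id index).
SAMPLE_INFO_REQUIRED = ("study_id", "diagnosis", "sex", "age", "batch")
SAMPLE_INFO_OPTIONAL = ("abeta42", "t_tau", "p_tau181", "apoe_e4_count")


class ValidationError(ValueError):
    """Raised when a table or metadata frame violates the data contract."""


@dataclass
class FeatureTable:
    """Features x samples intensity matrix with m/z and retention time.

    Parameters
    ----------
    features : DataFrame indexed by feature_id with columns ``mz`` (Th) and
        ``rt`` (seconds).
    intensities : DataFrame indexed by feature_id, one column per sample;
        NaN encodes a non-detect.
    batches : Series mapping sample_id -> analytical batch label.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    batches: pd.Series = field(default=None)

    def __post_init__(self):
        if self.batches is None:
            self.batches = pd.Series("batch0", index=self.intensities.columns)
        self.validate()

    # -- derived views -------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.features.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def detected(self) -> pd.DataFrame:
        """Boolean detection mask aligned with ``intensities``."""
        return self.intensities.notna()

    @property
    def lod(self) -> pd.Series:
        """Per-feature limit of detection: the lowest detected intensity."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            return self.intensities.min(axis=1, skipna=True)

    @property
    def detection_fraction(self) -> pd.Series:
        return self.detected.mean(axis=1)

    def validate(self) -> None:
        feats, inten = self.features, self.intensities
        if feats.index.has_duplicates:
            dup = feats.index[feats.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dup}")
        if not feats.index.equals(inten.index):
            raise ValidationError("features and intensities indexes differ")
        for col in ("mz", "rt"):
            if col not in feats.columns:
                raise ValidationError(f"features frame lacks column {col!r}")
        if (feats["mz"] <= 0).any():
            raise ValidationError("m/z values must be positive")
        if (feats["rt"] < 0).any():
            raise ValidationError("retention times must be non-negative")
        vals = inten.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) <= 0:
            raise ValidationError("detected intensities must be positive")
        if not self.batches.index.equals(inten.columns):
            self.batches = self.batches.reindex(inten.columns)
            if self.batches.isna().any():
                missing = self.batches.index[self.batches.isna()].tolist()
                raise ValidationError(f"samples without batch label: {missing}")

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self.intensities.copy(), self.batches.copy())

    def subset_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(
            self.features.loc[feature_ids], self.intensities.loc[feature_ids], self.batches.copy()
        )

    def subset_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(
            self.features.copy(), self.intensities[list(sample_ids)], self.batches.loc[list(sample_ids)]
        )


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def validate_sample_info(info: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-sample metadata frame (indexed by sample_id).

    Required columns: study_id, diagnosis (NC/MCI/AD), sex (0/1), age
    (years, positive), batch. Optional: abeta42, t_tau, p_tau181 (pg/mL,
    positive when present) and apoe_e4_count (0/1/2).
    """
    if info.index.has_duplicates:
        raise ValidationError("duplicate sample ids in metadata")
    missing = [c for c in SAMPLE_INFO_REQUIRED if c not in info.columns]
    if missing:
        raise ValidationError(f"metadata lacks required columns: {missing}")
    bad_dx = sorted(set(info["diagnosis"]) - set(DIAGNOSES))
    if bad_dx:
        raise ValidationError(f"unknown diagnosis labels: {bad_dx}")
    if not set(np.unique(info["sex"])) <= {0, 1}:
        raise ValidationError("sex must be coded 0/1")
    if (info["age"] <= 0).any():
        raise ValidationError("ages must be positive")
    for col in ("abeta42", "t_tau", "p_tau181"):
        if col in info.columns:
            vals = info[col].dropna()
            if (vals <= 0).any():
                raise ValidationError(f"{col} values must be positive when present")
    if "apoe_e4_count" in info.columns:
        vals = info["apoe_e4_count"].dropna()
        if not set(np.unique(vals)) <= {0, 1, 2}:
            raise ValidationError("apoe_e4_count must be 0, 1 or 2")
    return info


# ---------------------------------------------------------------------------
# I/O — CSV with a schema-version header comment; empty cell = non-detect
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path) -> None:
    df = pd.concat([table.features[["mz", "rt"]], table.intensities], axis=1)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(SCHEMA_HEADER + "\n")
        df.to_csv(fh, index_label="feature_id")


def write_sample_info(info: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(METADATA_HEADER + "\n")
        info.to_csv(fh, index_label="sample_id")


def read_sample_info(path) -> pd.DataFrame:
    info = pd.read_csv(path, comment="#", index_col="sample_id")
    return validate_sample_info(info)


def read_feature_table(path, metadata_path=None):
    """Read a feature-table CSV (and optionally its sample metadata).

    Returns ``FeatureTable`` or, when ``metadata_path`` is given,
    ``(FeatureTable, sample_info)``. Empty intensity cells become
    non-detects; the per-feature LOD is the minimum detected value. Samples
    present in the table but absent from the metadata are an error naming
    the offenders.
    """
    df = pd.read_csv(path, comment="#", index_col="feature_id")
    for col in ("mz", "rt"):
        if col not in df.columns:
            raise ValidationError(f"feature table {path} lacks column {col!r}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate feature ids in {path}: {dup}")
    sample_cols = [c for c in df.columns if c not in ("mz", "rt")]
    inten = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    # pd.to_numeric maps junk to NaN; distinguish junk from genuinely empty
    raw = df[sample_cols]
    bad = raw.notna() & inten.isna()
    if bad.to_numpy().any():
        offenders = [
            (f, s) for f in bad.index for s in bad.columns if bad.at[f, s]
        ]
        raise ValidationError(f"non-numeric intensities at (feature, sample): {offenders[:10]}")

    batches = None
    info = None
    if metadata_path is not None:
        info = read_sample_info(metadata_path)
        missing = [s for s in sample_cols if s not in info.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        batches = info.loc[sample_cols, "batch"]
        batches.index = pd.Index(sample_cols)
    table = FeatureTable(df[["mz", "rt"]].astype(float), inten.astype(float), batches)
    return table if info is None else (table, info)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_rt(table: FeatureTable, min_rt: float = 30.0) -> FeatureTable:
    """Drop early-eluting features: retains features with rt >= ``min_rt``
    (features with rt strictly below the threshold are removed)."""
    if min_rt < 0:
        raise ValueError("min_rt must be non-negative")
    keep = table.features.index[table.features["rt"] >= min_rt]
    if len(keep) == 0:
        log.warning("filter_rt(min_rt=%s) removed every feature", min_rt)
    return table.subset_features(keep)


def filter_presence(table: FeatureTable, min_frac: float = 0.80) -> FeatureTable:
    """Keep features detected in strictly more than ``min_frac`` of samples."""
    if not 0 <= min_frac <= 1:
        raise ValueError("min_frac must be in [0, 1]")
    keep = table.features.index[table.detection_fraction > min_frac]
    if len(keep) == 0:
        log.warning("filter_presence(min_frac=%s) removed every feature", min_frac)
    return table.subset_features(keep)


def summarize_replicates(table: FeatureTable, groups: pd.Series) -> FeatureTable:
    """Optional helper: collapse replicate injections to one column per
    sample by the median of detected values (all-non-detect replicates stay
    non-detect). ``groups`` maps replicate column -> sample id."""
    med = table.intensities.T.groupby(groups).median().T
    batches = table.batches.groupby(groups).first()
    return FeatureTable(table.features.copy(), med, batches.reindex(med.columns))


# ---------------------------------------------------------------------------
# empirical-Bayes batch correction (parametric location/scale adjustment)
# ---------------------------------------------------------------------------

def _eb_shrink(Z: np.ndarray, batch_mask: np.ndarray):
    """Per-batch EB-shrunken location (gamma*) and scale (delta*) estimates
    for standardized data Z (features x samples); NaN = non-detect."""
    obs = ~np.isnan(Z[:, batch_mask])
    n_b = obs.sum(axis=1).astype(float)  # detections per feature in batch
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        gamma_hat = np.nanmean(Z[:, batch_mask], axis=1)
        delta_hat = np.nanvar(Z[:, batch_mask], axis=1, ddof=1)
    usable = (n_b >= 2) & np.isfinite(gamma_hat) & np.isfinite(delta_hat) & (delta_hat > 0)
    gamma_star = np.where(np.isfinite(gamma_hat), gamma_hat, 0.0)
    delta_star = np.where(usable, delta_hat, 1.0)
    if usable.sum() < 2:
        return gamma_star, delta_star

    g, d, n = gamma_hat[usable], delta_hat[usable], n_b[usable]
    gamma_bar, tau2 = g.mean(), g.var(ddof=1)
    m, s2 = d.mean(), d.var(ddof=1)
    if s2 <= 1e-12 and tau2 <= 1e-12:
        # no between-feature spread to shrink against; use raw estimates
        return gamma_star, delta_star
    if s2 <= 1e-12:
        a_prior, b_prior = None, None
    else:
        a_prior = (2.0 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2

    Zb = Z[:, batch_mask][usable]
    g_star, d_star = g.copy(), d.copy()
    for _ in range(200):
        g_old, d_old = g_star.copy(), d_star.copy()
        if tau2 > 1e-12:
            g_star = (n * tau2 * g + d_star * gamma_bar) / (n * tau2 + d_star)
        else:
            g_star = np.full_like(g, gamma_bar)
        if a_prior is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                sse = np.nansum((Zb - g_star[:, None]) ** 2, axis=1)
            d_star = (b_prior + 0.5 * sse) / (n / 2.0 + a_prior - 1.0)
        if max(np.abs(g_star - g_old).max(), np.abs(d_star - d_old).max()) < 1e-6:
            break
    gamma_star[usable] = g_star
    delta_star[usable] = np.maximum(d_star, 1e-8)
    return gamma_star, delta_star


def correct_batches(table: FeatureTable) -> FeatureTable:
    """Remove analytical-batch location/scale effects by parametric
    empirical-Bayes adjustment of detected log2 intensities.

    Batch means and variances are estimated per feature on detected values
    only, shrunk across features toward their batch-wide priors, and the
    standardized data are adjusted and mapped back to the intensity scale.
    Non-detects are untouched (they carry no value to adjust); output
    intensities are positive by construction.
    """
    batches = table.batches
    labels = batches.unique()
    counts = batches.value_counts()
    if (counts < 2).any():
        small = counts.index[counts < 2].tolist()
        raise ValidationError(f"batches with <2 samples: {small}")
    X = np.log2(table.intensities.to_numpy(dtype=float))
    masks = {b: (batches == b).to_numpy() for b in labels}
    for b, mask in masks.items():
        if np.all(np.isnan(X[:, mask])):
            raise ValidationError(f"batch {b!r} has no detected values for any feature")
    if len(labels) == 1:
        return table.copy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        batch_means = np.column_stack(
            [np.nanmean(X[:, m], axis=1) for m in masks.values()]
        )  # features x batches
        n_obs = np.column_stack([(~np.isnan(X[:, m])).sum(axis=1) for m in masks.values()])
    batch_means = np.where(np.isfinite(batch_means), batch_means, 0.0)
    alpha = (batch_means * n_obs).sum(axis=1) / np.maximum(n_obs.sum(axis=1), 1)

    # pooled residual variance about batch means
    resid = X.copy()
    for j, m in enumerate(masks.values()):
        resid[:, m] = X[:, m] - batch_means[:, [j]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        var_pooled = np.nanvar(resid, axis=1, ddof=1)
    var_pooled = np.where(np.isfinite(var_pooled) & (var_pooled > 0), var_pooled, 1.0)
    sd = np.sqrt(var_pooled)

    Z = (X - alpha[:, None]) / sd[:, None]
    Z_adj = Z.copy()
    for b, m in masks.items():
        gamma_star, delta_star = _eb_shrink(Z, m)
        Z_adj[:, m] = (Z[:, m] - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]
    X_adj = Z_adj * sd[:, None] + alpha[:, None]
    out = pd.DataFrame(
        np.power(2.0, X_adj), index=table.intensities.index, columns=table.intensities.columns
    )
    out = out.where(table.detected)  # non-detects untouched
    return FeatureTable(table.features.copy(), out, table.batches.copy())


# ---------------------------------------------------------------------------
# CSF biomarker classification
# ---------------------------------------------------------------------------

UNCLASSIFIABLE = "unclassifiable"
BIOMARKER_POSITIVE = "AD-biomarker-positive"
BIOMARKER_NEGATIVE = "AD-biomarker-negative"


def classify_csf(t_tau, abeta42, threshold: float = 0.39) -> str:
    """Classify a sample by its CSF t-Tau/Abeta42 ratio.

    Ratio >= ``threshold`` (default 0.39, inclusive) is consistent with
    Alzheimer pathology; used to split MCI into MCI-AD vs MCI-SNAP. Missing
    or non-positive biomarkers yield the explicit ``"unclassifiable"``
    label rather than a silent default.
    """
    if t_tau is None or abeta42 is None:
        return UNCLASSIFIABLE
    t_tau, abeta42 = float(t_tau), float(abeta42)
    if not np.isfinite(t_tau) or not np.isfinite(abeta42) or t_tau <= 0 or abeta42 <= 0:
        return UNCLASSIFIABLE
    return BIOMARKER_POSITIVE if t_tau / abeta42 >= threshold else BIOMARKER_NEGATIVE


def classify_csf_samples(info: pd.DataFrame, threshold: float = 0.39) -> pd.Series:
    """Vectorized :func:`classify_csf` over a metadata frame."""
    if "t_tau" not in info.columns or "abeta42" not in info.columns:
        return pd.Series(UNCLASSIFIABLE, index=info.index)
    return pd.Series(
        [classify_csf(t, a, threshold) for t, a in zip(info["t_tau"], info["abeta42"])],
        index=info.index,
    )
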