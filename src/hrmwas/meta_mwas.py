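"""Two-study fixed-effects meta-analysis, FDR control and the
replication/selection rule for a metabolome-wide association study.

Per-study coefficients are combined with inverse-variance weights
(w_i = 1/SE_i^2); the combined estimate is sum(w_i e_i)/sum(w_i) with
standard error (sum w_i)^(-1/2). A feature is selected when its
meta-analysis FDR (Benjamini-Hochberg) is below the FDR threshold AND it is
associated at the per-study p threshold in every study with one common
direction of association. A medication-sensitivity check excludes features
whose diagnosis coefficient is attenuated once medication-detection
indicators are adjusted for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetaResult:
    estimate: float
    se: float
    z: float
    p: float


def fixed_effects_meta(estimates, ses) -> MetaResult:
    """Inverse-variance fixed-effects combination of study estimates.

    Studies with non-finite or non-positive SE are excluded with a warning;
    a single remaining study passes through (also warned).
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.shape != se.shape:
        raise ValueError("estimates and ses must have equal length")
    ok = np.isfinite(est) & np.isfinite(se) & (se > 0)
    if ok.sum() < est.size:
        log.warning("excluding %d studies with invalid SE from meta-analysis", est.size - ok.sum())
    est, se = est[ok], se[ok]
    if est.size == 0:
        raise ValueError("no valid studies to combine")
    if est.size == 1:
        log.warning("single-study meta-analysis: passthrough")
        e, s = float(est[0]), float(se[0])
    else:
        w = 1.0 / se**2
        e = float(np.sum(w * est) / np.sum(w))
        s = float(np.sum(w) ** -0.5)
    z = e / s
    return MetaResult(e, s, z, float(2.0 * stats.norm.sf(abs(z))))


def heterogeneity(estimates, ses) -> tuple[float, float]:
    """Cochran's Q and I^2 (%); reported alongside the fixed-effects
    combination but never used in selection."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    w = 1.0 / se**2
    pooled = np.sum(w * est) / np.sum(w)
    q = float(np.sum(w * (est - pooled) ** 2))
    df = est.size - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 and df > 0 else 0.0
    return q, i2


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order
    preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# record assembly and selection
# ---------------------------------------------------------------------------

def combine_studies(study_results: pd.DataFrame) -> pd.DataFrame:
    """Build per-feature meta-analysis records from long-format study results.

    ``study_results`` columns: study_id, feature_id, estimate, se, p
    (one row per study x feature). Only features present in *every* study
    are combined — the analysis set is the features common to both studies
    — and FDR is computed over exactly that set.
    """
    required = {"study_id", "feature_id", "estimate", "se", "p"}
    if not required <= set(study_results.columns):
        raise ValueError(f"study_results must have columns {sorted(required)}")
    studies = sorted(study_results["study_id"].unique())
    wide = study_results.pivot(index="feature_id", columns="study_id", values=["estimate", "se", "p"])
    common = wide.dropna().index
    records = []
    for fid in common:
        est = [wide.loc[fid, ("estimate", s)] for s in studies]
        se = [wide.loc[fid, ("se", s)] for s in studies]
        meta = fixed_effects_meta(est, se)
        q, i2 = heterogeneity(est, se)
        rec = {"feature_id": fid, "meta_estimate": meta.estimate, "meta_se": meta.se,
               "meta_z": meta.z, "meta_p": meta.p, "het_q": q, "het_i2": i2}
        for s in studies:
            rec[f"est_{s}"] = float(wide.loc[fid, ("estimate", s)])
            rec[f"se_{s}"] = float(wide.loc[fid, ("se", s)])
            rec[f"p_{s}"] = float(wide.loc[fid, ("p", s)])
        records.append(rec)
    out = pd.DataFrame(records).set_index("feature_id")
    out["fdr_q"] = bh_fdr(out["meta_p"].to_numpy())
    return out


def select_features(records: pd.DataFrame, fdr_thresh: float = 0.20,
                    per_study_p: float = 0.10) -> pd.DataFrame:
    """Apply the replication/selection rule to meta-analysis records.

    Selected iff fdr_q < ``fdr_thresh`` AND every study's p < ``per_study_p``
    AND all per-study estimates share one sign (a zero estimate fails sign
    concordance). Returns the records with boolean flag columns
    ``pass_fdr``, ``pass_per_study_p``, ``pass_sign`` and ``selected``.
    """
    out = records.copy()
    est_cols = [c for c in out.columns if c.startswith("est_")]
    p_cols = [c for c in out.columns if c.startswith("p_") and c != "pass_per_study_p"]
    est = out[est_cols].to_numpy(float)
    out["pass_fdr"] = out["fdr_q"] < fdr_thresh
    out["pass_per_study_p"] = (out[p_cols] < per_study_p).all(axis=1)
    out["pass_sign"] = np.all(est > 0, axis=1) | np.all(est < 0, axis=1)
    if ((est == 0).any(axis=1) & out["pass_per_study_p"]).any():
        log.warning("zero per-study estimate encountered; sign concordance fails for it")
    out["selected"] = out["pass_fdr"] & out["pass_per_study_p"] & out["pass_sign"]
    return out


def medication_sensitivity_check(
    unadjusted: dict[str, float],
    adjusted: dict[str, float | None],
    attenuation_frac: float = 0.20,
) -> dict:
    """Decide keep/exclude for one feature after medication adjustment.

    ``unadjusted``/``adjusted`` map study_id -> diagnosis coefficient (an
    ``adjusted`` value of None marks a non-convergent adjusted model).
    Exclude iff in >=1 study the adjusted |beta| shrinks by at least
    ``attenuation_frac`` of the unadjusted |beta|, or the sign flips. A
    non-convergent adjusted fit makes the verdict "indeterminate", never an
    automatic exclusion.
    """
    if not 0 < attenuation_frac < 1:
        raise ValueError("attenuation_frac must be in (0, 1)")
    deltas = {}
    any_exclude = any_indeterminate = False
    for study, b0 in unadjusted.items():
        b1 = adjusted.get(study)
        if b1 is None or not np.isfinite(b1):
            deltas[study] = None
            any_indeterminate = True
            continue
        deltas[study] = b1 - b0
        attenuated = abs(b1) < (1.0 - attenuation_frac) * abs(b0)
        sign_flip = (b0 != 0) and (np.sign(b1) != np.sign(b0))
        any_exclude = any_exclude or attenuated or sign_flip
    verdict = "exclude" if any_exclude else ("indeterminate" if any_indeterminate else "keep")
    return {"verdict": verdict, "per_study_delta": deltas,
            "attenuation_frac": attenuation_frac}
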