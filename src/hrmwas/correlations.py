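"""Covariate-adjusted rank correlations of metabolite features with CSF
biomarkers and APOE e4 burden, meta-analyzed across studies.

Partial Spearman correlation: rank-transform the two variables (and any
continuous covariates; binary covariates enter as 0/1), regress each rank
vector on the covariate design, and correlate the residuals. Study-level
coefficients are combined on the Fisher z scale with inverse-variance
weights n - k - 3 (k = number of covariates).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def partial_spearman(x, y, covariates=None, binary: set | None = None) -> float:
    """Partial Spearman correlation of x and y given covariates.

    ``covariates`` is a mapping name -> vector (or a DataFrame); names in
    ``binary`` enter the rank regression as 0/1 without ranking. With no
    covariates this equals the classical Spearman rho exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        covariates = {}
    elif isinstance(covariates, pd.DataFrame):
        covariates = {c: covariates[c].to_numpy(float) for c in covariates.columns}
    binary = binary or set()
    k = len(covariates)

    cols = [np.asarray(v, dtype=float) for v in covariates.values()]
    mask = np.isfinite(x) & np.isfinite(y)
    for v in cols:
        mask &= np.isfinite(v)
    n = int(mask.sum())
    if n < k + 4:
        raise ValueError(f"need at least {k + 4} complete cases, got {n}")
    xv, yv = x[mask], y[mask]
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        raise ValueError("constant input vector; Spearman correlation undefined")

    rx, ry = _rank(xv), _rank(yv)
    design = [np.ones(n)]
    for name, v in covariates.items():
        vv = v[mask]
        design.append(vv if name in binary else _rank(vv))
    Z = np.column_stack(design)
    rx_res = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
    ry_res = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
    denom = np.sqrt(np.sum(rx_res**2) * np.sum(ry_res**2))
    scale = np.sqrt(np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2))
    if denom <= 1e-10 * scale:
        # covariates explain x and/or y completely: no partial association left
        return 0.0
    return float(np.clip(np.sum(rx_res * ry_res) / denom, -1.0, 1.0))


def meta_correlation(rhos, ns, k_covariates: int = 2) -> tuple[float, float]:
    """Fixed-effects combination of per-study partial Spearman correlations.

    Fisher z-transform each rho, weight by n - k - 3, inverse-variance
    combine, and back-transform; the two-sided p uses the normal reference.
    """
    rhos = np.asarray(rhos, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if np.any(np.abs(rhos) >= 1):
        raise ValueError("|rho| = 1 has infinite Fisher z; cannot combine")
    w = ns - k_covariates - 3
    if np.any(w <= 0):
        raise ValueError("each study needs n > k + 3")
    z = np.arctanh(rhos)
    zbar = float(np.sum(w * z) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    stat = zbar / se
    return float(np.tanh(zbar)), float(2.0 * stats.norm.sf(abs(stat)))


def biomarker_correlations(
    tables: dict[str, "pd.DataFrame"],
    infos: dict[str, pd.DataFrame],
    feature_map: dict[str, dict[str, str]],
    variables=("abeta42", "t_tau", "p_tau181", "apoe_e4_count"),
    covariates=("sex", "age"),
) -> pd.DataFrame:
    """Per-study partial Spearman correlations of features with clinical
    variables, meta-analyzed across studies.

    ``tables`` maps study -> intensity frame (features x samples, NaN =
    non-detect); ``feature_map`` maps a canonical feature key -> per-study
    feature id. Non-detects are excluded pairwise; each estimate reports
    the n used. Rows with too few complete cases in a study fall back to
    the remaining studies.
    """
    rows = []
    for key, per_study_ids in feature_map.items():
        for var in variables:
            rhos, ns = [], []
            for study, fid in per_study_ids.items():
                info = infos[study]
                if var not in info.columns:
                    continue
                inten = tables[study].loc[fid].reindex(info.index)
                x = np.log(inten.to_numpy(float))
                y = info[var].to_numpy(float)
                covs = {c: info[c].to_numpy(float) for c in covariates}
                try:
                    rho = partial_spearman(x, y, covs, binary={"sex"})
                except ValueError:
                    continue
                mask = np.isfinite(x) & np.isfinite(y)
                for v in covs.values():
                    mask &= np.isfinite(v)
                rhos.append(rho)
                ns.append(int(mask.sum()))
            if not rhos:
                continue
            if len(rhos) == 1:
                n = ns[0]
                z = np.arctanh(rhos[0]) * np.sqrt(n - len(covariates) - 3)
                meta_rho, meta_p = rhos[0], float(2.0 * stats.norm.sf(abs(z)))
            else:
                meta_rho, meta_p = meta_correlation(rhos, ns, k_covariates=len(covariates))
            rows.append({
                "feature": key, "variable": var,
                "meta_rho": meta_rho, "meta_p": meta_p,
                "per_study_rho": list(np.round(rhos, 4)),
                "per_study_n": ns,
            })
    return pd.DataFrame(rows)


def plasma_csf_correlation(
    plasma: pd.DataFrame,
    csf: pd.DataFrame,
    matched_pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Unadjusted Spearman correlation of plasma vs CSF levels per matched
    feature pair, over the shared samples where the feature is detected in
    both fluids. Pairs with <4 such samples are flagged with no estimate."""
    shared = plasma.columns.intersection(csf.columns)
    if len(shared) == 0:
        raise ValueError("no shared sample ids between plasma and CSF tables")
    rows = []
    for pf, cf in matched_pairs:
        x = plasma.loc[pf, shared].to_numpy(float)
        y = csf.loc[cf, shared].to_numpy(float)
        mask = np.isfinite(x) & np.isfinite(y)
        n = int(mask.sum())
        if n < 4:
            rows.append({"plasma_feature": pf, "csf_feature": cf, "rho": np.nan,
                         "p": np.nan, "n": n, "flag": "insufficient shared detections"})
            continue
        rho, p = stats.spearmanr(x[mask], y[mask])
        rows.append({"plasma_feature": pf, "csf_feature": cf, "rho": float(rho),
                     "p": float(p), "n": n, "flag": ""})
    return pd.DataFrame(rows)
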