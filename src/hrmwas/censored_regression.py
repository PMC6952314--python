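"""Left-censored lognormal regression of feature intensity on diagnosis.

Each LC-MS feature's intensity T is modelled on the natural-log scale as

    log T = mu + beta1*diagnosis + beta2*sex + beta3*age + sigma*eps,

with eps standard normal. A non-detected sample contributes the probability
that its intensity lies below the feature's limit of detection (the lowest
detected value), i.e. Phi((log LOD - x'beta)/sigma) — an accelerated
failure time model with lognormal errors and left censoring. beta1 is the
change in log mean intensity for cases versus controls.

The likelihood is maximized over (beta, log sigma) by quasi-Newton ascent
from an OLS start; Wald standard errors come from the observed information
at the optimum, with two-sided p-values from the normal reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .feature_table import FeatureTable, ValidationError

log = logging.getLogger(__name__)

_LOG_2PI = np.log(2.0 * np.pi)

#: [M+H]+ m/z of memantine and rivastigmine, and the 13C [M+H]+ of
#: donepezil — the three medication ions screened in the unfiltered tables.
MEDICATION_TARGETS = {
    "memantine": 180.1748,
    "rivastigmine": 251.1753,
    "donepezil": 381.2254,
}


@dataclass(frozen=True)
class ModelSpec:
    """Regression specification for one feature.

    ``contrast`` is (reference level, comparison level) of diagnosis;
    ``covariates`` are metadata columns entered linearly (sex 0/1, age in
    years by convention).
    """

    outcome: str
    contrast: tuple[str, str] = ("NC", "AD")
    covariates: tuple[str, ...] = ("sex", "age")

    def __post_init__(self):
        if self.contrast[0] == self.contrast[1]:
            raise ValueError("contrast reference and comparison levels must differ")
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("duplicated covariates")


@dataclass
class CensoredFit:
    """Maximum-likelihood fit of the left-censored lognormal model."""

    params: pd.Series  # intercept, diagnosis, then covariates
    ses: pd.Series
    sigma: float
    loglik: float
    converged: bool
    n_obs: int
    n_censored: int
    notes: list[str] = field(default_factory=list)

    @property
    def mu(self) -> float:
        return float(self.params["intercept"])

    @property
    def zs(self) -> pd.Series:
        return self.params / self.ses

    @property
    def ps(self) -> pd.Series:
        return pd.Series(2.0 * stats.norm.sf(np.abs(self.zs)), index=self.params.index)

    def to_dict(self) -> dict:
        return {
            "est": float(self.params["diagnosis"]),
            "se": float(self.ses["diagnosis"]),
            "z": float(self.zs["diagnosis"]),
            "p": float(self.ps["diagnosis"]),
            "sigma": self.sigma,
            "n": self.n_obs,
            "n_censored": self.n_censored,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# core likelihood machinery (array level)
# ---------------------------------------------------------------------------

def _negloglik_and_grad(theta, X, y, det, c):
    """Negative log-likelihood and gradient in (beta, log sigma)."""
    beta, logsig = theta[:-1], theta[-1]
    sigma = np.exp(logsig)
    xb = X @ beta
    r = (y - xb)[det] / sigma
    nll = 0.5 * np.sum(r * r) + det.sum() * (logsig + 0.5 * _LOG_2PI)
    gbeta = -(X[det].T @ r) / sigma
    glogsig = det.sum() - np.sum(r * r)
    if (~det).any():
        u = (c - xb[~det]) / sigma
        log_cdf = special.log_ndtr(u)
        nll -= log_cdf.sum()
        ratio = np.exp(-0.5 * u * u - 0.5 * _LOG_2PI - log_cdf)  # phi/Phi
        gbeta += (X[~det].T @ ratio) / sigma
        glogsig += np.sum(u * ratio)
    return nll, np.append(gbeta, glogsig)


def _numeric_hessian(theta, X, y, det, c):
    k = theta.size
    H = np.empty((k, k))
    h = 1e-5 * (1.0 + np.abs(theta))
    for j in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        _, gp = _negloglik_and_grad(tp, X, y, det, c)
        _, gm = _negloglik_and_grad(tm, X, y, det, c)
        H[:, j] = (gp - gm) / (2.0 * h[j])
    return 0.5 * (H + H.T)


def censored_lognormal_mle(y: np.ndarray, detected: np.ndarray, X: np.ndarray, log_lod: float):
    """Fit the left-censored normal model on the log scale.

    Parameters
    ----------
    y : log intensities (entries with ``detected`` False are ignored).
    detected : boolean detection mask.
    X : design matrix (first column should be the intercept).
    log_lod : common log LOD at which censored samples contribute.

    Returns ``(beta, sigma, cov, loglik, converged, note)`` with ``cov`` the
    observed-information covariance of (beta, log sigma).
    """
    det = detected.astype(bool)
    n, k = X.shape
    if det.sum() < 1:
        raise ValidationError("no detected values to fit")
    if np.linalg.matrix_rank(X) < k:
        raise ValidationError("design matrix is rank-deficient")

    # center/scale non-intercept columns for conditioning; the optimum is
    # mapped back exactly below, so reported coefficients are unaffected
    has_intercept = np.all(X[:, 0] == 1.0)
    means = np.zeros(k)
    scales = np.ones(k)
    if has_intercept:
        means[1:] = X[:, 1:].mean(axis=0)
        sd = X[:, 1:].std(axis=0)
        scales[1:] = np.where(sd > 0, sd, 1.0)
    X_raw = X
    X = (X - means) / scales

    # OLS start: censored rows imputed at the LOD for initialization only
    y0 = np.where(det, y, log_lod)
    beta0, *_ = np.linalg.lstsq(X, y0, rcond=None)
    resid = y0 - X @ beta0
    sigma0 = max(float(np.sqrt(np.mean(resid**2))), 1e-2)
    theta0 = np.append(beta0, np.log(sigma0))

    res = optimize.minimize(
        _negloglik_and_grad,
        theta0,
        args=(X, y, det, log_lod),
        jac=True,
        method="BFGS",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    note = ""
    _, grad = _negloglik_and_grad(res.x, X, y, det, log_lod)
    if not res.success and np.max(np.abs(grad)) >= 1e-5:
        # genuine stall: polish with a derivative-free pass, then re-climb
        res2 = optimize.minimize(
            lambda t: _negloglik_and_grad(t, X, y, det, log_lod)[0],
            res.x,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        res3 = optimize.minimize(
            _negloglik_and_grad, res2.x, args=(X, y, det, log_lod),
            jac=True, method="BFGS", options={"gtol": 1e-8, "maxiter": 200},
        )
        for cand in (res2, res3):
            if cand.fun <= res.fun:
                res = cand
        _, grad = _negloglik_and_grad(res.x, X, y, det, log_lod)
    converged = bool(np.max(np.abs(grad)) < 1e-5)
    if not converged:
        note = f"gradient norm {np.max(np.abs(grad)):.2e} at optimum; optimizer: {res.message}"

    theta = res.x
    H = _numeric_hessian(theta, X, y, det, log_lod)
    # back-transform (beta_std, log sigma) to the raw design's scale
    A = np.eye(k + 1)
    if has_intercept:
        A[1:k, 1:k] = np.diag(1.0 / scales[1:])
        A[0, 1:k] = -means[1:] / scales[1:]
    beta = A[:k, :k] @ theta[:-1]
    sigma = float(np.exp(theta[-1]))
    X = X_raw
    try:
        cov = A @ np.linalg.inv(H) @ A.T
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.full((k + 1, k + 1), np.nan)
        converged = False
        note = (note + "; " if note else "") + "observed information not positive definite"
    return beta, sigma, cov, -float(res.fun), converged, note


# ---------------------------------------------------------------------------
# feature-level interface
# ---------------------------------------------------------------------------

def _build_design(intensities: pd.Series, samples: pd.DataFrame, spec: ModelSpec,
                  extra: pd.DataFrame | None = None):
    ref, comp = spec.contrast
    use = samples.index[samples["diagnosis"].isin([ref, comp])]
    use = use.intersection(intensities.index)
    if len(use) == 0:
        raise ValidationError("no samples in the requested contrast levels")
    sub = samples.loc[use]
    cols = ["intercept", "diagnosis", *spec.covariates]
    X = np.column_stack(
        [np.ones(len(use)), (sub["diagnosis"] == comp).to_numpy(float)]
        + [sub[c].to_numpy(float) for c in spec.covariates]
    )
    if extra is not None:
        for name in extra.index:
            X = np.column_stack([X, extra.loc[name, use].to_numpy(float)])
            cols.append(name)
    vals = intensities.loc[use].to_numpy(float)
    detected = np.isfinite(vals)
    y = np.where(detected, np.log(np.where(detected, vals, 1.0)), np.nan)
    return X, y, detected, cols, sub


def fit_censored_lognormal(
    intensities: pd.Series,
    samples: pd.DataFrame,
    spec: ModelSpec,
    med_indicators: pd.DataFrame | None = None,
) -> CensoredFit:
    """Fit one feature's censored lognormal regression.

    ``intensities`` is the feature's row of the table (NaN = non-detect),
    indexed by sample id; ``samples`` the metadata frame. Only samples at
    the contrast's two diagnosis levels enter. The censoring value is the
    feature's LOD: its lowest detected intensity among included samples.
    """
    notes: list[str] = []
    extra = None
    if med_indicators is not None:
        keep = []
        for name in med_indicators.index:
            vals = med_indicators.loc[name]
            if vals.nunique() <= 1:
                notes.append(f"medication indicator {name!r} constant; dropped")
                log.warning("medication indicator %r constant across samples; dropped", name)
            else:
                keep.append(name)
        extra = med_indicators.loc[keep] if keep else None

    X, y, detected, cols, sub = _build_design(intensities, samples, spec, extra)
    if detected.sum() == 0:
        raise ValidationError(f"feature {spec.outcome!r} has no detected values")
    lod = float(np.nanmin(np.where(detected, np.exp(y), np.nan)))
    log_lod = np.log(lod)

    # flag complete separation of censoring by diagnosis group
    dx = X[:, 1].astype(bool)
    for grp, mask in (("comparison", dx), ("reference", ~dx)):
        if mask.any() and not detected[mask].any():
            notes.append(f"all {grp}-group samples censored (complete separation of censoring)")

    beta, sigma, cov, ll, converged, note = censored_lognormal_mle(y, detected, X, log_lod)
    if note:
        notes.append(note)
    ses = np.sqrt(np.diag(cov))[: len(cols)]
    return CensoredFit(
        params=pd.Series(beta, index=cols),
        ses=pd.Series(ses, index=cols),
        sigma=sigma,
        loglik=ll,
        converged=converged,
        n_obs=int(len(y)),
        n_censored=int((~detected).sum()),
        notes=notes,
    )


def fit_with_medication_adjustment(
    intensities: pd.Series,
    samples: pd.DataFrame,
    spec: ModelSpec,
    med_indicators: pd.DataFrame,
) -> CensoredFit:
    """Same likelihood with medication detection indicators (0/1 rows of
    ``med_indicators``, one per medication) added as covariates.
    Indicators constant across samples are dropped with a warning."""
    return fit_censored_lognormal(intensities, samples, spec, med_indicators=med_indicators)


def detect_medication_indicators(
    table: FeatureTable,
    target_mzs: dict[str, float] | None = None,
    ppm_tol: float = 5.0,
) -> pd.DataFrame:
    """Per-sample detection flags for medication ions in an *unfiltered* table.

    For each target m/z the nearest feature within ``ppm_tol`` supplies its
    detection flags; ties go to the smaller ppm difference, then the smaller
    feature id (logged). A target with no feature in tolerance yields an
    all-zero row with a warning.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    targets = dict(target_mzs) if target_mzs is not None else dict(MEDICATION_TARGETS)
    if any(v <= 0 for v in targets.values()):
        raise ValueError("target m/z values must be positive")
    mz = table.features["mz"]
    rows = {}
    for name, target in targets.items():
        ppm = (mz - target).abs() / target * 1e6
        in_tol = ppm[ppm <= ppm_tol]
        if in_tol.empty:
            log.warning("no feature within %.1f ppm of %s (%.4f); all-zero indicator", ppm_tol, name, target)
            rows[name] = pd.Series(0, index=table.sample_ids)
            continue
        best = in_tol.min()
        candidates = sorted(in_tol.index[in_tol == best])
        if len(candidates) > 1:
            log.info("tie at %.3f ppm for %s; choosing feature %r", best, name, candidates[0])
        rows[name] = table.detected.loc[candidates[0]].astype(int)
    return pd.DataFrame(rows).T
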