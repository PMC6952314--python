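"""Two-study synthetic LC-MS datasets with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: two case-control studies with partially overlapping feature sets,
lognormal intensities, daily-batch location/scale effects, per-feature left
censoring at the limit of detection, a minority of features carrying a true
diagnosis effect of configurable size, co-eluting correlated adduct
clusters, and binary medication-derived features detected only in cases.

Shared features carry the same feature id in both studies (the emitted
tables still differ in m/z by a small ppm jitter and in retention time by a
few seconds, so cross-study matching has real work to do); study-specific
features are placed on a mass grid coarse enough that they differ by far
more than 5 ppm from every feature of the other study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chem import C13_SPACING, DEFAULT_ADDUCTS, mz_for_adduct
from .feature_table import FeatureTable, validate_sample_info

#: ion roles planted in each adduct cluster (log response factors, natural log)
CLUSTER_ROLES = {
    "[M+H]+": 0.0,
    "[M+Na]+": -1.2,
    "[M+H-H2O]+": -0.8,
    "[M+H]+ (13C)": -2.2,
}

_ADDUCT_BY_LABEL = {h.label: h for h in DEFAULT_ADDUCTS}

# Table-1-calibrated CSF biomarker distributions (mean, sd) per diagnosis
_BIOMARKERS = {
    "abeta42": {"NC": (340, 137), "AD": (203, 76), "MCI": (218, 90)},
    "t_tau": {"NC": (44, 24), "AD": (117, 70), "MCI": (76, 67)},
    "p_tau181": {"NC": (32, 15), "AD": (75, 32), "MCI": (51, 25)},
}
_APOE_PROBS = {"NC": (0.61, 0.39, 0.0), "AD": (0.08, 0.61, 0.31), "MCI": (0.48, 0.33, 0.19)}


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings; defaults mirror the two-study design being
    emulated (group sizes ~45, effect sizes of the magnitude seen for the
    replicated features, ~40% of features shared between studies, daily
    batches of ~20 samples)."""

    n_per_group: int = 45
    n_features: int = 500
    frac_shared: float = 0.42
    frac_affected: float = 0.02
    effect_size: float = 0.3
    censor_frac_target: float = 0.10
    n_batches: int = 4
    batch_shift_sd: float = 0.3
    batch_scale_sd: float = 0.1
    residual_sd: float = 0.5
    n_adduct_clusters: int = 5
    include_mci_in_study1: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_shared", "frac_affected", "censor_frac_target"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if self.n_features < 1 or self.n_batches < 1 or self.n_adduct_clusters < 0:
            raise ValueError("counts must be positive (n_adduct_clusters >= 0)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative (applied as +effect on cases)")


@dataclass
class GroundTruth:
    affected_feature_ids: list[str]
    true_betas: dict[str, float]
    cluster_membership: dict[str, tuple[int, str]]
    batch_params: dict[str, dict[str, tuple[float, float]]]
    shared_feature_ids: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "affected_feature_ids": self.affected_feature_ids,
            "true_betas": self.true_betas,
            "cluster_membership": {k: list(v) for k, v in self.cluster_membership.items()},
            "batch_params": {s: {b: list(v) for b, v in d.items()} for s, d in self.batch_params.items()},
            "shared_feature_ids": self.shared_feature_ids,
        }


def _make_samples(study: str, groups: dict[str, int], n_batches: int,
                  rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    i = 0
    for dx, n in groups.items():
        for _ in range(n):
            i += 1
            rows.append({"sample_id": f"{study}_s{i:03d}", "study_id": study, "diagnosis": dx})
    info = pd.DataFrame(rows).set_index("sample_id")
    n = len(info)
    info["sex"] = rng.integers(0, 2, size=n)
    info["age"] = np.round(rng.uniform(55, 85, size=n), 1)
    order = rng.permutation(n)
    batch_idx = np.empty(n, dtype=int)
    batch_idx[order] = (np.arange(n) * n_batches) // n
    info["batch"] = [f"{study}_b{b + 1}" for b in batch_idx]

    # CSF biomarkers respect the inclusion rule: AD has t-Tau/Abeta42 >= 0.39,
    # NC < 0.39; MCI unconstrained.
    for col in ("abeta42", "t_tau", "p_tau181"):
        vals = np.empty(n)
        for j, dx in enumerate(info["diagnosis"]):
            m, s = _BIOMARKERS[col][dx]
            vals[j] = max(rng.normal(m, s), 5.0)
        info[col] = np.round(vals, 1)
    for j, (idx, row) in enumerate(info.iterrows()):
        dx = row["diagnosis"]
        if dx == "MCI":
            continue
        want_pos = dx == "AD"
        for _ in range(200):
            ratio = row["t_tau"] / row["abeta42"]
            if (ratio >= 0.39) == want_pos:
                break
            row["abeta42"] = max(rng.normal(*_BIOMARKERS["abeta42"][dx]), 5.0)
            row["t_tau"] = max(rng.normal(*_BIOMARKERS["t_tau"][dx]), 5.0)
        info.loc[idx, ["abeta42", "t_tau"]] = round(row["abeta42"], 1), round(row["t_tau"], 1)
    info["apoe_e4_count"] = [
        rng.choice([0, 1, 2], p=np.array(_APOE_PROBS[dx]) / sum(_APOE_PROBS[dx]))
        for dx in info["diagnosis"]
    ]
    return validate_sample_info(info)


def _censor(logI: np.ndarray, thresholds: np.ndarray, feature_ids) -> np.ndarray:
    """Mask log intensities below the per-feature threshold; a feature left
    with zero detections is a degenerate configuration and fails loudly."""
    out = logI.copy()
    below = logI < thresholds[:, None]
    dead = below.all(axis=1)
    if dead.any():
        names = [str(feature_ids[i]) for i in np.nonzero(dead)[0][:5]]
        raise ValueError(
            f"censoring leaves no detected values for feature(s) {names}; "
            "lower censor_frac_target or the noise scales"
        )
    out[below] = np.nan
    return out


def generate_two_studies(config: SimConfig):
    """Generate the two-study dataset.

    Returns ``(table1, table2, sample_info, truth)`` where ``sample_info``
    holds both studies' samples (``study_id`` column distinguishes them).
    Deterministic given (config, seed); per-study randomness uses sub-seeds
    derived from the single global seed.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_shared, rng_s1, rng_s2, rng_cluster = [np.random.default_rng(c) for c in ss.spawn(4)]

    n_shared = int(round(config.frac_shared * config.n_features))
    n_unique = config.n_features - n_shared

    # --- adduct clusters (all shared between studies) ---
    cluster_rows = []  # (fid, cluster, role, mz, rt)
    neutral_masses = rng_cluster.uniform(150, 900, size=config.n_adduct_clusters)
    cluster_rts = rng_cluster.uniform(40, 560, size=config.n_adduct_clusters)
    for c in range(config.n_adduct_clusters):
        base_rt = cluster_rts[c]
        for role, _ in CLUSTER_ROLES.items():
            if role.endswith("(13C)"):
                mz = mz_for_adduct(neutral_masses[c], _ADDUCT_BY_LABEL["[M+H]+"]) + C13_SPACING
            else:
                mz = mz_for_adduct(neutral_masses[c], _ADDUCT_BY_LABEL[role])
            fid = f"CL{c + 1}_{role}"
            cluster_rows.append((fid, c + 1, role, mz, base_rt + rng_cluster.uniform(-2, 2)))
    cluster_mzs = np.array([r[3] for r in cluster_rows])

    # --- regular feature masses on a coarse grid (grid spacing 0.1 Da with
    # +-0.02 jitter keeps any two distinct base masses >= 0.06 Da apart,
    # far beyond 5 ppm at m/z <= 1250) ---
    grid = np.arange(85.0, 1250.0, 0.1)
    if cluster_mzs.size:
        keep = np.min(np.abs(grid[:, None] - cluster_mzs[None, :]), axis=1) > 0.05
        grid = grid[keep]
    base_mz = np.sort(rng_shared.choice(grid, size=n_shared + 2 * n_unique, replace=False))
    base_mz = base_mz + rng_shared.uniform(-0.02, 0.02, size=base_mz.size)
    base_rt = rng_shared.uniform(10, 590, size=base_mz.size)

    shared_ids = [f"SH{i + 1:04d}" for i in range(n_shared)]
    u1_ids = [f"S1U{i + 1:04d}" for i in range(n_unique)]
    u2_ids = [f"S2U{i + 1:04d}" for i in range(n_unique)]
    mz_shared, mz_u1, mz_u2 = np.split(base_mz, [n_shared, n_shared + n_unique])
    rt_shared, rt_u1, rt_u2 = np.split(base_rt, [n_shared, n_shared + n_unique])

    # per-feature model parameters (shared features identical across studies)
    def _feature_params(n, rng):
        return (rng.normal(14.0, 1.5, n), rng.normal(0.0, 0.10, n), rng.normal(0.0, 0.010, n))

    mu_sh, bsex_sh, bage_sh = _feature_params(n_shared, rng_shared)
    mu_u1, bsex_u1, bage_u1 = _feature_params(n_unique, rng_s1)
    mu_u2, bsex_u2, bage_u2 = _feature_params(n_unique, rng_s2)

    n_aff = int(round(config.frac_affected * n_shared))
    affected = sorted(str(f) for f in rng_shared.choice(shared_ids, size=n_aff, replace=False)) if n_aff else []
    true_betas = {fid: config.effect_size for fid in affected}
    mu_cluster = rng_cluster.normal(15.0, 1.0, size=config.n_adduct_clusters)

    truth = GroundTruth(
        affected_feature_ids=list(affected),
        true_betas=true_betas,
        cluster_membership={r[0]: (r[1], r[2]) for r in cluster_rows},
        batch_params={},
        shared_feature_ids=list(shared_ids) + [r[0] for r in cluster_rows],
    )

    infos, tables = [], {}
    study_defs = [("study1", rng_s1, (mz_u1, rt_u1, u1_ids, mu_u1, bsex_u1, bage_u1)),
                  ("study2", rng_s2, (mz_u2, rt_u2, u2_ids, mu_u2, bsex_u2, bage_u2))]
    for study, rng, (mz_u, rt_u, uids, mu_u, bsex_u, bage_u) in study_defs:
        groups = {"NC": config.n_per_group, "AD": config.n_per_group}
        if study == "study1" and config.include_mci_in_study1:
            groups["MCI"] = config.n_per_group
        info = _make_samples(study, groups, config.n_batches, rng)
        n_samp = len(info)
        dx_effect = np.select(
            [info["diagnosis"] == "AD", info["diagnosis"] == "MCI"], [1.0, 0.5], 0.0
        )
        sex = info["sex"].to_numpy(float)
        age_c = info["age"].to_numpy(float) - 70.0

        batch_labels = sorted(info["batch"].unique())
        shifts = rng.normal(0.0, config.batch_shift_sd, size=len(batch_labels))
        scales = np.exp(rng.normal(0.0, config.batch_scale_sd, size=len(batch_labels)))
        truth.batch_params[study] = {
            b: (float(sh), float(sc)) for b, sh, sc in zip(batch_labels, shifts, scales)
        }
        b_idx = pd.Categorical(info["batch"], categories=batch_labels).codes
        shift_s, scale_s = shifts[b_idx], scales[b_idx]

        # regular features: shared block then study-specific block
        fids = list(shared_ids) + list(uids)
        mzs = np.concatenate([mz_shared, mz_u])
        rts = np.concatenate([rt_shared, rt_u])
        mu = np.concatenate([mu_sh, mu_u])
        bsex = np.concatenate([bsex_sh, bsex_u])
        bage = np.concatenate([bage_sh, bage_u])
        beta1 = np.array([true_betas.get(f, 0.0) for f in fids])

        eps = rng.normal(0.0, config.residual_sd, size=(len(fids), n_samp))
        logI = (
            mu[:, None]
            + beta1[:, None] * dx_effect[None, :]
            + bsex[:, None] * sex[None, :]
            + bage[:, None] * age_c[None, :]
            + shift_s[None, :]
            + scale_s[None, :] * eps
        )

        # adduct clusters: one latent abundance per metabolite, per-ion
        # response factors, small independent noise -> high correlation
        if cluster_rows:
            latent = mu_cluster[:, None] + rng.normal(0.0, 0.6, size=(config.n_adduct_clusters, n_samp))
            clog = np.empty((len(cluster_rows), n_samp))
            for k, (fid, c, role, mz, rt) in enumerate(cluster_rows):
                clog[k] = (
                    latent[c - 1]
                    + CLUSTER_ROLES[role]
                    + shift_s
                    + scale_s * rng.normal(0.0, 0.15, size=n_samp)
                )
            fids = fids + [r[0] for r in cluster_rows]
            mzs = np.concatenate([mzs, cluster_mzs])
            rts = np.concatenate([rts, np.array([r[4] for r in cluster_rows])])
            logI = np.vstack([logI, clog])
            mu = np.concatenate([mu, np.array([mu_cluster[r[1] - 1] + CLUSTER_ROLES[r[2]] for r in cluster_rows])])

        # small cross-study measurement jitter on m/z (<=2 ppm) and RT
        # (<=10 s); cluster members shift as a unit so co-elution survives
        mzs = mzs * (1.0 + rng.uniform(-2e-6, 2e-6, size=mzs.size))
        rt_jit = rng.uniform(-10, 10, size=rts.size)
        if cluster_rows:
            n_reg = rts.size - len(cluster_rows)
            per_cluster = rng.uniform(-10, 10, size=config.n_adduct_clusters)
            rt_jit[n_reg:] = np.array([per_cluster[r[1] - 1] for r in cluster_rows])
        rts = np.maximum(rts + rt_jit, 0.0)

        if config.censor_frac_target > 0:
            z_q = stats.norm.ppf(config.censor_frac_target)
            marg_sd = np.sqrt(config.residual_sd**2 + config.batch_shift_sd**2)
            thresholds = mu + z_q * marg_sd
            logI = _censor(logI, thresholds, fids)

        features = pd.DataFrame({"mz": mzs, "rt": rts}, index=pd.Index(fids, name="feature_id"))
        inten = pd.DataFrame(np.exp(logI), index=features.index, columns=info.index)
        tables[study] = FeatureTable(features, inten, info["batch"].copy())
        infos.append(info)

    sample_info = pd.concat(infos)
    return tables["study1"], tables["study2"], sample_info, truth


# ---------------------------------------------------------------------------
# medication features
# ---------------------------------------------------------------------------

def spike_medication_features(
    table: FeatureTable,
    target_mzs: dict[str, float],
    prevalence: float,
    case_sample_ids,
    seed: int = 0,
) -> FeatureTable:
    """Add medication-derived features detected only in a random subset of
    case samples at the given prevalence.

    ``target_mzs`` maps feature name -> m/z. A target colliding with an
    existing feature within 5 ppm is an error.
    """
    if not 0 <= prevalence <= 1:
        raise ValueError("prevalence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cases = [s for s in table.sample_ids if s in set(case_sample_ids)]
    mz_existing = table.features["mz"].to_numpy(float)
    new_feats, new_rows = [], []
    for name, mz in target_mzs.items():
        ppm = np.abs(mz_existing - mz) / mz * 1e6
        if (ppm <= 5.0).any():
            clash = table.features.index[ppm <= 5.0][0]
            raise ValueError(f"target m/z {mz} collides with existing feature {clash!r} within 5 ppm")
        n_det = int(round(prevalence * len(cases)))
        detected = rng.choice(len(cases), size=n_det, replace=False) if n_det else []
        row = pd.Series(np.nan, index=table.sample_ids)
        if n_det:
            vals = np.exp(rng.normal(13.0, 0.4, size=n_det))
            row.loc[[cases[i] for i in detected]] = vals
        new_feats.append({"feature_id": name, "mz": mz, "rt": float(rng.uniform(60, 400))})
        new_rows.append(row)
    features = pd.concat([table.features, pd.DataFrame(new_feats).set_index("feature_id")])
    inten = pd.concat([table.intensities, pd.DataFrame(new_rows, index=[f["feature_id"] for f in new_feats])])
    return FeatureTable(features, inten, table.batches.copy())


def spike_dependent_feature(
    table: FeatureTable,
    indicator: pd.Series,
    mz: float,
    effect: float = 1.0,
    seed: int = 0,
) -> FeatureTable:
    """Add one feature whose log intensity is shifted by ``effect`` in
    samples where the 0/1 ``indicator`` is set — an iatrogenic (e.g.
    medication-driven) signal for sensitivity-analysis tests."""
    rng = np.random.default_rng(seed)
    ind = indicator.reindex(table.sample_ids).fillna(0).to_numpy(float)
    logI = 14.0 + effect * ind + rng.normal(0.0, 0.4, size=ind.size)
    fid = f"DEP_{mz:.4f}"
    features = pd.concat([
        table.features,
        pd.DataFrame({"mz": [mz], "rt": [float(rng.uniform(60, 400))]}, index=pd.Index([fid], name="feature_id")),
    ])
    inten = pd.concat([
        table.intensities,
        pd.DataFrame(np.exp(logI)[None, :], index=[fid], columns=table.sample_ids),
    ])
    return FeatureTable(features, inten, table.batches.copy())


def generate_paired_fluid(
    intensities: pd.DataFrame, rho: float, seed: int = 0
) -> pd.DataFrame:
    """A second-biofluid intensity matrix whose per-feature Spearman
    correlation with ``intensities`` is calibrated to ``rho``.

    Uses the Gaussian-copula relation r = 2 sin(pi * rho / 6) between the
    latent Pearson and the target Spearman correlation.
    """
    if not -1 < rho < 1:
        raise ValueError("rho must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    r = 2.0 * np.sin(np.pi * rho / 6.0)
    X = np.log(intensities.to_numpy(float))
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        x = X[i]
        mask = np.isfinite(x)
        z = np.full(x.size, np.nan)
        xs = x[mask]
        z[mask] = (xs - xs.mean()) / (xs.std() if xs.std() > 0 else 1.0)
        noise = rng.normal(0.0, 1.0, size=x.size)
        out[i] = 13.0 + 0.5 * (r * z + np.sqrt(1.0 - r**2) * noise)
    return pd.DataFrame(np.exp(out), index=intensities.index, columns=intensities.columns)
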