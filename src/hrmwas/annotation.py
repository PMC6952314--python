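"""Pseudospectrum clustering and adduct/isotope annotation.

Features deriving from one metabolite (its adducts, natural-abundance
isotopes and in-source fragments) co-elute and have strongly correlated
intensities across samples. This module groups such features into
*pseudospectra* (single-linkage components of the co-elution/correlation
graph), predicts each member's ion role from the pairwise observed mass
differences, and searches a compound table by accurate mass at a ppm
tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .chem import (
    C13_SPACING,
    DEFAULT_ADDUCTS,
    AdductHypothesis,
    CompoundRecord,
    invert_adduct,
    mz_for_adduct,
)
from .feature_table import FeatureTable

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class Pseudospectrum:
    """A cluster of co-eluting, intensity-correlated features."""

    cluster_id: int
    members: list[str]
    representative_rt: float
    correlations: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)
    neutral_mass: float | None = None

    @property
    def size(self) -> int:
        return len(self.members)


def build_pseudospectra(
    table: FeatureTable,
    corr_min: float = 0.7,
    rt_window: float = 5.0,
    min_shared: int = 10,
) -> list[Pseudospectrum]:
    """Cluster features into pseudospectra.

    An edge joins two features when |delta rt| <= ``rt_window`` seconds and
    the Pearson correlation of their log2 intensities over co-detected
    samples (at least ``min_shared`` of them) is >= ``corr_min``; clusters
    are the connected components (single linkage). Singletons are allowed.
    """
    if table.intensities.shape[1] < 2:
        raise ValueError("need at least 2 samples to correlate")
    ids = table.features.index.to_numpy()
    rt = table.features["rt"].to_numpy(float)
    X = np.log2(table.intensities.to_numpy(float))
    det = np.isfinite(X)
    n = ids.size

    order = np.argsort(rt, kind="stable")
    rows, cols = [], []
    corr_entries: dict[tuple[int, int], float] = {}
    for a in range(n):
        i = order[a]
        for b in range(a + 1, n):
            j = order[b]
            if rt[j] - rt[i] > rt_window:
                break
            shared = det[i] & det[j]
            if shared.sum() < min_shared:
                continue
            xi, xj = X[i, shared], X[j, shared]
            if xi.std() == 0 or xj.std() == 0:
                continue
            r = float(np.corrcoef(xi, xj)[0, 1])
            corr_entries[(min(i, j), max(i, j))] = r
            if r >= corr_min:
                rows.append(i)
                cols.append(j)

    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    spectra = []
    for cid in range(n_comp):
        idx = np.nonzero(labels == cid)[0]
        members = [str(ids[k]) for k in idx]
        sub = np.eye(len(idx))
        for a, ka in enumerate(idx):
            for b, kb in enumerate(idx):
                if a < b:
                    key = (min(ka, kb), max(ka, kb))
                    sub[a, b] = sub[b, a] = corr_entries.get(key, np.nan)
        spectra.append(
            Pseudospectrum(
                cluster_id=cid,
                members=members,
                representative_rt=float(np.median(rt[idx])),
                correlations=pd.DataFrame(sub, index=members, columns=members),
            )
        )
    return spectra


def _ion_hypotheses(adducts, max_c13: int = 1):
    """All (label, delta, rank, base_label) ion hypotheses: each adduct plus
    its 13C isotopes. ``rank`` orders adducts by simplicity (their position
    in the configured set) and is used to break score ties in favour of the
    plainer interpretation (e.g. protonated/sodiated over the
    acetonitrile-cluster pair implying the same mass difference)."""
    out = []
    for rank, h in enumerate(adducts):
        out.append((h.label, h.mass_delta, float(rank), h.label))
        for k in range(1, max_c13 + 1):
            suffix = " (13C)" if k == 1 else f" ({k}x13C)"
            out.append((h.label + suffix, h.mass_delta + k * C13_SPACING, rank + 0.5, h.label))
    return out


def assign_roles(
    cluster: Pseudospectrum,
    table: FeatureTable,
    adducts: tuple[AdductHypothesis, ...] = DEFAULT_ADDUCTS,
    mass_tol_ppm: float = 5.0,
    max_c13: int = 1,
) -> Pseudospectrum:
    """Predict ion roles for the members of one pseudospectrum.

    Every member x ion-hypothesis combination implies a candidate neutral
    mass; the candidate explaining the most members (ties -> lower mass)
    wins, members inconsistent with it are labeled ``"unassigned"``, and
    the winning mass is stored as the cluster's inferred neutral mass.
    Pairwise observed m/z differences therefore only get a role when they
    sit within tolerance of a difference implied by two ion hypotheses of
    one common neutral mass.
    """
    if cluster.size < 2:
        cluster.roles = {m: UNASSIGNED for m in cluster.members}
        return cluster
    mzs = table.features.loc[cluster.members, "mz"].to_numpy(float)
    hyps = _ion_hypotheses(adducts, max_c13=max_c13)

    best: tuple[tuple, dict, float] | None = None  # (key, roles, mass)
    for m_idx in range(mzs.size):
        for _, delta, _, _ in hyps:
            M = mzs[m_idx] - delta
            if M <= 0:
                continue
            roles: dict[str, str] = {}
            ranks: dict[str, float] = {}
            bases: dict[str, str] = {}
            for o_idx, member in enumerate(cluster.members):
                assigned = None
                err_best = np.inf
                for label, d, rank, base in hyps:
                    pred = M + d
                    err = abs(mzs[o_idx] - pred) / pred * 1e6
                    if err <= mass_tol_ppm and err < err_best:
                        assigned, err_best = (label, rank, base), err
                if assigned:
                    roles[member], ranks[member], bases[member] = assigned
                else:
                    roles[member] = UNASSIGNED
            # a 13C label is only credible when its monoisotopic partner is
            # also in the cluster; demote orphan isotopes to unassigned
            assigned_plain = {roles[m] for m in roles if roles[m] != UNASSIGNED and "13C" not in roles[m]}
            for m in list(roles):
                if roles[m] != UNASSIGNED and "13C" in roles[m] and bases[m] not in assigned_plain:
                    roles[m] = UNASSIGNED
            n_explained = sum(1 for r in roles.values() if r != UNASSIGNED)
            rank_sum = sum(ranks[m] for m in roles if roles[m] != UNASSIGNED)
            key = (-n_explained, rank_sum, M)
            if best is None or key < best[0]:
                best = (key, roles, M)

    assert best is not None
    if -best[0][0] >= 2:
        cluster.roles = best[1]
        cluster.neutral_mass = best[2]
    else:  # no pair shares a neutral mass: nothing to anchor roles on
        cluster.roles = {m: UNASSIGNED for m in cluster.members}
        cluster.neutral_mass = None
    return cluster


@dataclass(frozen=True)
class DbHit:
    compound: CompoundRecord
    adduct: AdductHypothesis
    ppm_error: float


def db_search(
    mz: float,
    compounds: list[CompoundRecord],
    adducts: tuple[AdductHypothesis, ...] = DEFAULT_ADDUCTS,
    tol_ppm: float = 5.0,
    predicted_role: str | None = None,
) -> list[DbHit]:
    """Accurate-mass compound lookup for one observed m/z.

    For each adduct hypothesis the observed m/z is inverted to a neutral
    mass and compounds within ``tol_ppm`` (relative to the compound's
    theoretical m/z under that adduct) are returned, sorted by |ppm error|.
    When a predicted role is supplied — e.g. from :func:`assign_roles` —
    only that adduct is searched.
    """
    if not compounds:
        log.warning("db_search on empty compound table")
        return []
    if predicted_role is not None:
        search = [h for h in adducts if h.label == predicted_role]
        if not search:
            log.warning("predicted role %r not in adduct set; searching all", predicted_role)
            search = list(adducts)
    else:
        search = list(adducts)
    hits = []
    for h in search:
        neutral = invert_adduct(mz, h)
        if neutral <= 0:
            continue
        for c in compounds:
            pred = mz_for_adduct(c.monoisotopic_mass, h)
            ppm = (mz - pred) / pred * 1e6
            if abs(ppm) <= tol_ppm:
                hits.append(DbHit(c, h, float(ppm)))
    hits.sort(key=lambda hit: (abs(hit.ppm_error), hit.compound.name, hit.adduct.label))
    return hits


def annotate_table(
    table: FeatureTable,
    compounds: list[CompoundRecord],
    adducts: tuple[AdductHypothesis, ...] = DEFAULT_ADDUCTS,
    corr_min: float = 0.7,
    rt_window: float = 5.0,
    tol_ppm: float = 5.0,
) -> tuple[list[Pseudospectrum], pd.DataFrame]:
    """End-to-end annotation: cluster, assign roles, then search compounds.

    Returns the pseudospectra and a per-feature frame with cluster id,
    role, top compound candidate and its ppm error.
    """
    spectra = build_pseudospectra(table, corr_min=corr_min, rt_window=rt_window)
    rows = []
    for spec in spectra:
        assign_roles(spec, table, adducts=adducts, mass_tol_ppm=tol_ppm)
        for member in spec.members:
            role = spec.roles.get(member, UNASSIGNED)
            mz = float(table.features.at[member, "mz"])
            # isotope roles ("[M+H]+ (13C)") are searched at the
            # monoisotopic m/z under their base adduct
            search_mz, search_role = mz, None
            if role != UNASSIGNED:
                base, n13 = role, 0
                if role.endswith(" (13C)"):
                    base, n13 = role[: -len(" (13C)")], 1
                if any(h.label == base for h in adducts):
                    search_mz, search_role = mz - n13 * C13_SPACING, base
            hits = db_search(
                search_mz, compounds, adducts=adducts, tol_ppm=tol_ppm,
                predicted_role=search_role,
            )
            rows.append({
                "feature_id": member,
                "mz": mz,
                "rt": float(table.features.at[member, "rt"]),
                "cluster": spec.cluster_id,
                "role": role,
                "neutral_mass": spec.neutral_mass,
                "top_compound": hits[0].compound.name if hits else "",
                "top_adduct": hits[0].adduct.label if hits else "",
                "ppm_error": hits[0].ppm_error if hits else np.nan,
                "n_candidates": len(hits),
            })
    return spectra, pd.DataFrame(rows).set_index("feature_id")
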