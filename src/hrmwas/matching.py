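"""Cross-study m/z feature matching with ppm and retention-time tolerances.

Two features match when their masses agree within a ppm tolerance
(ppm = |mz1-mz2| / mean(mz1, mz2) * 1e6 — symmetric in the two studies)
and their retention times within an absolute tolerance (seconds). When a
feature has several in-tolerance candidates, the closest retention time
wins; the global map is made one-to-one by greedy resolution ordered by
|rt difference| then |ppm difference|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_table import FeatureTable


@dataclass(frozen=True)
class MatchPair:
    feature_id_1: str
    feature_id_2: str
    ppm_diff: float  # signed, study2 - study1 relative to the mean m/z
    rt_diff: float  # signed seconds, study2 - study1


def _ppm(mz1: np.ndarray, mz2: np.ndarray) -> np.ndarray:
    return (mz2 - mz1) / ((mz1 + mz2) / 2.0) * 1e6


def _greedy_resolve(cands: list[tuple]) -> list[MatchPair]:
    """One-to-one resolution: candidates sorted by |rt_diff|, then
    |ppm_diff|, then the two ids (exact ties logged deterministic)."""
    cands.sort(key=lambda t: (abs(t[3]), abs(t[2]), t[0], t[1]))
    used1: set = set()
    used2: set = set()
    out = []
    for f1, f2, ppm, rt in cands:
        if f1 in used1 or f2 in used2:
            continue
        used1.add(f1)
        used2.add(f2)
        out.append(MatchPair(f1, f2, float(ppm), float(rt)))
    return out


def _candidate_pairs_sorted(table1: FeatureTable, table2: FeatureTable,
                            ppm_tol: float, rt_tol: float) -> list[tuple]:
    """All in-tolerance pairs via window search on m/z-sorted arrays."""
    mz1 = table1.features["mz"].to_numpy(float)
    rt1 = table1.features["rt"].to_numpy(float)
    ids1 = table1.features.index.to_numpy()
    order2 = np.argsort(table2.features["mz"].to_numpy(float), kind="stable")
    mz2 = table2.features["mz"].to_numpy(float)[order2]
    rt2 = table2.features["rt"].to_numpy(float)[order2]
    ids2 = table2.features.index.to_numpy()[order2]

    cands = []
    for i in range(mz1.size):
        # window: |mz2 - mz1| <= tol approx mz1 * ppm_tol * 1e-6 * 1.001
        half = mz1[i] * ppm_tol * 1e-6 * 1.01 + 1e-9
        lo = np.searchsorted(mz2, mz1[i] - half, side="left")
        hi = np.searchsorted(mz2, mz1[i] + half, side="right")
        if lo == hi:
            continue
        ppm = _ppm(np.full(hi - lo, mz1[i]), mz2[lo:hi])
        rtd = rt2[lo:hi] - rt1[i]
        ok = (np.abs(ppm) <= ppm_tol) & (np.abs(rtd) <= rt_tol)
        for j in np.nonzero(ok)[0]:
            cands.append((ids1[i], ids2[lo + j], ppm[j], rtd[j]))
    return cands


def match_features(table1: FeatureTable, table2: FeatureTable,
                   ppm_tol: float = 5.0, rt_tol: float = 30.0) -> list[MatchPair]:
    """One-to-one cross-study matching at the given tolerances."""
    if ppm_tol <= 0 or rt_tol <= 0:
        raise ValueError("tolerances must be positive")
    return _greedy_resolve(_candidate_pairs_sorted(table1, table2, ppm_tol, rt_tol))


def brute_force_match(table1: FeatureTable, table2: FeatureTable,
                      ppm_tol: float = 5.0, rt_tol: float = 30.0) -> list[MatchPair]:
    """Reference implementation: exhaustive pair enumeration with the same
    tolerance and tie-break rules. Intended for small tables (<=500
    features each) and equivalence testing."""
    if ppm_tol <= 0 or rt_tol <= 0:
        raise ValueError("tolerances must be positive")
    if len(table1.features) > 500 or len(table2.features) > 500:
        raise ValueError("brute_force_match is for small tables (<=500 features)")
    mz1 = table1.features["mz"].to_numpy(float)
    rt1 = table1.features["rt"].to_numpy(float)
    mz2 = table2.features["mz"].to_numpy(float)
    rt2 = table2.features["rt"].to_numpy(float)
    ids1 = table1.features.index.to_numpy()
    ids2 = table2.features.index.to_numpy()
    cands = []
    for i in range(mz1.size):
        for j in range(mz2.size):
            ppm = _ppm(mz1[i], mz2[j])
            rtd = rt2[j] - rt1[i]
            if abs(ppm) <= ppm_tol and abs(rtd) <= rt_tol:
                cands.append((ids1[i], ids2[j], ppm, rtd))
    return _greedy_resolve(cands)


def matches_to_frame(pairs: list[MatchPair], table1: FeatureTable,
                     table2: FeatureTable) -> pd.DataFrame:
    """TSV-ready frame with both ids, both m/z, both RT and the differences."""
    rows = []
    for p in pairs:
        rows.append({
            "feature_id_1": p.feature_id_1,
            "feature_id_2": p.feature_id_2,
            "mz_1": table1.features.at[p.feature_id_1, "mz"],
            "mz_2": table2.features.at[p.feature_id_2, "mz"],
            "rt_1": table1.features.at[p.feature_id_1, "rt"],
            "rt_2": table2.features.at[p.feature_id_2, "rt"],
            "ppm_diff": p.ppm_diff,
            "rt_diff": p.rt_diff,
        })
    return pd.DataFrame(rows, columns=["feature_id_1", "feature_id_2", "mz_1", "mz_2",
                                       "rt_1", "rt_2", "ppm_diff", "rt_diff"])
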