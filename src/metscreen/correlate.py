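"""Correlation clusters around a best panel's core features.

Each core feature collects, over the pooled (both groups) samples, the
candidate features whose Pearson correlation with it reaches significance
(two-sided t-based p <= 0.05, unadjusted).  Significant features that
correlate with no core are "orphans"; their pairwise correlation table
tests whether they form an additional group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from metscreen.cohort import CohortMatrix
from metscreen.screen import UnivariateResult

MEMBERSHIP_P = 0.05


class CorrelationError(ValueError):
    """Raised for invalid correlation inputs."""


@dataclass
class CorrelationCluster:
    core: str
    members: list[tuple[str, float, float]]  # (feature, r, p), r descending

    @property
    def member_names(self) -> list[str]:
        return [m[0] for m in self.members]


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def correlate_with_cores(
    m: CohortMatrix,
    cores: Sequence[str],
    candidates: Sequence[str],
    p_threshold: float = MEMBERSHIP_P,
) -> tuple[list[CorrelationCluster], pd.DataFrame]:
    """Star-shaped correlation clusters plus the core-core correlation table.

    Returns ``(clusters, core_table)`` where ``core_table`` holds the
    pairwise core correlations (same code path as the member computation).
    A feature may belong to several cores' member lists.
    """
    missing = [c for c in cores if c not in m.feature_names]
    if missing:
        raise CorrelationError(f"core feature(s) not in cohort: {missing}")
    data = {}
    for name in dict.fromkeys(list(cores) + list(candidates)):
        col = m.values[name].to_numpy(dtype=float)
        col = col[~np.isnan(col)]
        if np.ptp(col) == 0.0:
            warnings.warn(f"feature {name!r} is constant; correlation undefined, skipped")
            continue
        data[name] = m.values[name].to_numpy(dtype=float)
    clusters = []
    for core in cores:
        if core not in data:
            clusters.append(CorrelationCluster(core=core, members=[]))
            continue
        members = []
        for cand in candidates:
            if cand == core or cand not in data:
                continue
            a, b = data[core], data[cand]
            ok = ~np.isnan(a) & ~np.isnan(b)
            r, p = _pearson(a[ok], b[ok])
            if p <= p_threshold:
                members.append((cand, r, p))
        members.sort(key=lambda t: (-t[1], t[0]))
        clusters.append(CorrelationCluster(core=core, members=members))
    core_rows = []
    for i, a in enumerate(cores):
        for b in cores[i + 1 :]:
            if a in data and b in data:
                mask = ~np.isnan(data[a]) & ~np.isnan(data[b])
                r, p = _pearson(data[a][mask], data[b][mask])
                core_rows.append({"core_a": a, "core_b": b, "r": r, "p": p})
    return clusters, pd.DataFrame(core_rows, columns=["core_a", "core_b", "r", "p"])


def find_orphans(
    screen: Sequence[UnivariateResult],
    clusters: Sequence[CorrelationCluster],
    m: CohortMatrix,
) -> tuple[list[str], pd.DataFrame]:
    """Significant features unclaimed by any core, with their pairwise table.

    Returns ``(orphans, table)``; the table is the symmetric orphan-orphan
    Pearson correlation matrix (unit diagonal) with a parallel p-value
    block appended, for checking whether the orphans form their own group.
    """
    cores = {c.core for c in clusters}
    claimed = set().union(*[set(c.member_names) for c in clusters]) if clusters else set()
    significant = [r.feature for r in screen if r.significant]
    orphans = [f for f in significant if f not in claimed and f not in cores]
    k = len(orphans)
    rmat = np.eye(k)
    pmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a = m.values[orphans[i]].to_numpy(dtype=float)
            b = m.values[orphans[j]].to_numpy(dtype=float)
            ok = ~np.isnan(a) & ~np.isnan(b)
            r, p = _pearson(a[ok], b[ok])
            rmat[i, j] = rmat[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    table = pd.DataFrame(rmat, index=orphans, columns=orphans)
    ptable = pd.DataFrame(pmat, index=orphans, columns=[f"p:{o}" for o in orphans])
    return orphans, pd.concat([table, ptable], axis=1)


def clusters_table(clusters: Sequence[CorrelationCluster]) -> pd.DataFrame:
    rows = [
        {"core": c.core, "member": f, "r": r, "p": p}
        for c in clusters
        for (f, r, p) in c.members
    ]
    return pd.DataFrame(rows, columns=["core", "member", "r", "p"])
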