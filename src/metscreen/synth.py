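"""Synthetic case-control cohorts with known ground truth.

The generator emulates the structure the downstream analysis assumes:

- a small targeted panel of quantitative markers plus a large broad panel
  of log-normal semi-quantitative abundances;
- latent correlated clusters: each cluster is one Gaussian factor shared
  (on the log scale) by its member features, so members correlate with one
  another but not across clusters;
- multiplicative case/control mean-ratio effects on cluster members, a few
  affected-but-independent "orphan" features, and affected targeted
  markers;
- left-censoring at a per-feature detection limit set at a quantile of the
  control-scale distribution;
- two independent Bernoulli genotype columns.

Everything is driven by one integer seed; a fixed seed fixes every
generated byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special

from metscreen.cohort import CASE_LABEL, CONTROL_LABEL, CohortMatrix, FeatureMeta
from metscreen.screen import UnivariateResult


class SynthError(ValueError):
    """Raised for infeasible generator configurations."""


@dataclass
class GeneratorConfig:
    n_case: int = 30
    n_control: int = 29
    n_features: int = 600  # broad-panel size
    n_targeted: int = 20  # quantitative targeted-pathway markers
    n_nutritional: int = 5
    n_clusters: int = 5
    cluster_size_range: tuple[int, int] = (8, 15)
    effect_ratio_range: tuple[float, float] = (0.63, 0.87)
    within_cluster_r: tuple[float, float] = (0.4, 0.9)
    cv: float = 0.3
    censor_quantile: float = 0.0
    n_orphans: int = 5
    n_affected_targeted: int = 3
    genotype_freqs: tuple[float, float] = (0.35, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 4 or self.n_control < 4:
            raise SynthError("each group needs at least 4 participants")
        if not (0.0 <= self.censor_quantile < 0.5):
            raise SynthError("censor_quantile must lie in [0, 0.5)")
        if min(self.effect_ratio_range) <= 0.0:
            raise SynthError("effect ratios must be positive")
        if self.cluster_size_range[0] > self.cluster_size_range[1]:
            raise SynthError("invalid cluster_size_range")


@dataclass
class GroundTruth:
    cluster_membership: dict[str, int]  # feature -> cluster index
    true_ratio: dict[str, float]  # feature -> case/control mean ratio
    orphan_features: list[str]

    @property
    def affected_features(self) -> list[str]:
        return sorted(f for f, r in self.true_ratio.items() if r != 1.0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "cluster_membership": self.cluster_membership,
                "true_ratio": self.true_ratio,
                "orphan_features": self.orphan_features,
            }
        )


def _lognormal_sigma(cv: float) -> float:
    # on the log scale: cv^2 = exp(sigma^2) - 1
    return math.sqrt(math.log(1.0 + cv * cv))


def generate_cohort(cfg: GeneratorConfig) -> tuple[CohortMatrix, GroundTruth]:
    """Generate a cohort and its ground truth, deterministically per seed."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_case + cfg.n_control
    case_mask = np.zeros(n, dtype=bool)
    case_mask[: cfg.n_case] = True
    sigma = _lognormal_sigma(cfg.cv)

    lo, hi = cfg.cluster_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_clusters)
    if sizes.sum() + cfg.n_orphans > cfg.n_features:
        raise SynthError(
            f"cluster sizes ({int(sizes.sum())}) plus orphans exceed n_features={cfg.n_features}"
        )

    broad_names = [f"met_{i:04d}" for i in range(cfg.n_features)]
    membership: dict[str, int] = {}
    true_ratio: dict[str, float] = {f: 1.0 for f in broad_names}
    pos = 0
    cluster_features: list[list[str]] = []
    for k, size in enumerate(sizes):
        members = broad_names[pos : pos + int(size)]
        pos += int(size)
        ratio = float(rng.uniform(*cfg.effect_ratio_range))
        for f in members:
            membership[f] = k
            true_ratio[f] = ratio
        cluster_features.append(members)
    orphans = broad_names[pos : pos + cfg.n_orphans]
    pos += cfg.n_orphans
    for f in orphans:
        true_ratio[f] = float(rng.uniform(*cfg.effect_ratio_range))

    factors = rng.standard_normal((n, cfg.n_clusters))
    cluster_r = rng.uniform(*cfg.within_cluster_r, size=cfg.n_clusters)

    cols = {}
    for f in broad_names:
        mu = rng.uniform(math.log(1e4), math.log(1e8))
        eps = rng.standard_normal(n)
        if f in membership:
            k = membership[f]
            loading = math.sqrt(cluster_r[k])
            z = loading * factors[:, k] + math.sqrt(1.0 - cluster_r[k]) * eps
        else:
            z = eps
        logv = mu + sigma * z
        if true_ratio[f] != 1.0:
            logv = logv + np.where(case_mask, math.log(true_ratio[f]), 0.0)
        cols[f] = np.exp(logv)

    # targeted quantitative markers: independent normals on the raw scale
    targeted_names = [f"focm_{i:02d}" for i in range(cfg.n_targeted)]
    affected_targeted = targeted_names[: cfg.n_affected_targeted]
    for f in targeted_names:
        base = rng.uniform(1.0, 50.0)
        ratio = 1.0
        if f in affected_targeted:
            ratio = float(rng.uniform(*cfg.effect_ratio_range))
        means = np.where(case_mask, base * ratio, base)
        cols[f] = np.abs(means * (1.0 + cfg.cv * rng.standard_normal(n)))
        true_ratio[f] = ratio
    nutritional_names = [f"nut_{i:02d}" for i in range(cfg.n_nutritional)]
    for f in nutritional_names:
        base = rng.uniform(5.0, 500.0)
        cols[f] = np.abs(base * (1.0 + cfg.cv * rng.standard_normal(n)))
        true_ratio[f] = 1.0
    genotype_names = ["mthfr_var_1", "mthfr_var_2"]
    for f, freq in zip(genotype_names, cfg.genotype_freqs):
        cols[f] = rng.binomial(1, freq, size=n).astype(float)

    values = pd.DataFrame(cols)
    censored = pd.DataFrame(False, index=values.index, columns=values.columns)
    if cfg.censor_quantile > 0.0:
        zq = special.ndtri(cfg.censor_quantile)
        # detection limits sit at the control-group quantile of each feature's law
        for f in broad_names:
            logv = np.log(values[f].to_numpy())
            mu_hat = logv[~case_mask].mean()
            limit = math.exp(mu_hat + sigma * zq)
            below = values[f].to_numpy() < limit
            censored[f] = below
            values.loc[below, f] = np.nan

    participants = [f"case_{i:02d}" for i in range(cfg.n_case)] + [
        f"ctrl_{i:02d}" for i in range(cfg.n_control)
    ]
    values.index = pd.Index(participants, name="participant")
    censored.index = values.index
    groups = pd.Series(
        np.where(case_mask, CASE_LABEL, CONTROL_LABEL), index=values.index, name="group"
    )
    features = (
        [FeatureMeta(f, "focm_ts", "continuous") for f in targeted_names]
        + [FeatureMeta(f, "nutritional", "continuous") for f in nutritional_names]
        + [FeatureMeta(f, "mthfr_binary", "binary") for f in genotype_names]
        + [
            FeatureMeta(f, "metabolon", "continuous", confirmed_standard=bool(rng.random() < 0.8))
            for f in broad_names
        ]
    )
    order = [f.name for f in features]
    cohort = CohortMatrix(
        values=values[order], censored=censored[order], groups=groups, features=features
    )
    gt = GroundTruth(
        cluster_membership=membership,
        true_ratio=true_ratio,
        orphan_features=list(orphans),
    )
    return cohort, gt


@dataclass
class RecoveryReport:
    sensitivity: float  # affected features flagged significant
    specificity: float  # null features not flagged
    n_affected: int
    n_null: int
    cluster_recall: dict[int, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "n_affected": self.n_affected,
                "n_null": self.n_null,
                "cluster_recall": self.cluster_recall,
            }
        )


def parameter_recovery_report(
    m: CohortMatrix,
    gt: GroundTruth,
    results: Sequence[UnivariateResult],
    clusters=None,
) -> RecoveryReport:
    """Score the screen's joint significance rule against the ground truth.

    Only features present in both the ground truth and the screen results
    are compared; mismatched universes are an error.  If correlation
    ``clusters`` are supplied, per-generated-cluster recall (largest
    fraction of a cluster's members landing in a single core's member
    list) is reported too.
    """
    result_features = {r.feature for r in results}
    known = set(gt.true_ratio)
    if not result_features <= set(m.feature_names):
        raise SynthError("screen results cover features missing from the cohort")
    overlap = result_features & known
    if not overlap:
        raise SynthError("no overlap between screen results and ground truth")
    flagged = {r.feature for r in results if r.significant}
    affected = {f for f in overlap if gt.true_ratio[f] != 1.0}
    null = overlap - affected
    sens = len(flagged & affected) / len(affected) if affected else float("nan")
    spec = len(null - flagged) / len(null) if null else float("nan")
    recall: dict[int, float] = {}
    if clusters is not None:
        by_cluster: dict[int, set[str]] = {}
        for f, k in gt.cluster_membership.items():
            by_cluster.setdefault(k, set()).add(f)
        for k, members in by_cluster.items():
            best = 0.0
            for c in clusters:
                got = len((members & set(c.member_names)) | (members & {c.core})) / len(members)
                best = max(best, got)
            recall[k] = best
    return RecoveryReport(
        sensitivity=float(sens),
        specificity=float(spec),
        n_affected=len(affected),
        n_null=len(null),
        cluster_recall=recall,
    )
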