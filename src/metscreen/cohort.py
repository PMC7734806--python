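"""Participants x features data model, I/O, imputation and subset assembly."""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CASE_LABEL = "ASD-M"
CONTROL_LABEL = "TD-M"

#: tokens interpreted as "below detection limit" when reading raw tables
DEFAULT_CENSOR_TOKENS = ("BDL", "")

PANELS = ("focm_ts", "nutritional", "mthfr_binary", "metabolon", "diet", "symptom")
KINDS = ("continuous", "binary", "ordinal")

SUBSET_IDS = ("i", "ii", "iii", "iv")


class CohortError(ValueError):
    """Raised for malformed cohort inputs."""


@dataclass(frozen=True)
class FeatureMeta:
    """Metadata for one measured feature.

    ``panel`` drives membership in the analysis subsets i-iv, ``kind``
    selects the statistical treatment (two-sample test vs. chi-square) and
    ``confirmed_standard`` records whether the identity was confirmed with
    a chemical standard.
    """

    name: str
    panel: str
    kind: str = "continuous"
    confirmed_standard: bool = True

    def __post_init__(self) -> None:
        if self.panel not in PANELS:
            raise CohortError(f"unknown panel {self.panel!r} for feature {self.name!r}")
        if self.kind not in KINDS:
            raise CohortError(f"unknown kind {self.kind!r} for feature {self.name!r}")
        if self.panel == "mthfr_binary" and self.kind != "binary":
            raise CohortError(f"genotype feature {self.name!r} must be binary")


@dataclass
class CohortMatrix:
    """A validated participants x features abundance matrix.

    ``values`` holds non-negative abundances (``NaN`` for missing or
    not-yet-imputed censored cells); ``censored`` is a same-shaped boolean
    mask marking cells that were below the detection limit in the raw data.
    """

    values: pd.DataFrame
    censored: pd.DataFrame
    groups: pd.Series
    features: list[FeatureMeta]
    case_label: str = CASE_LABEL
    control_label: str = CONTROL_LABEL

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise CohortError(f"duplicate feature name(s): {dupes}")
        if list(self.values.columns) != names:
            raise CohortError("values columns do not match feature metadata order")
        if self.values.shape != self.censored.shape:
            raise CohortError("values and censored masks have different shapes")
        if len(self.groups) != len(self.values):
            raise CohortError("group labels do not cover every participant")
        bad = set(self.groups.unique()) - {self.case_label, self.control_label}
        if bad:
            raise CohortError(f"unknown group label(s): {sorted(bad)}")
        if (self.values < 0).any().any():
            raise CohortError("abundances must be non-negative")
        self._meta = {f.name: f for f in self.features}

    # -- convenience accessors -------------------------------------------------

    @property
    def participants(self) -> pd.Index:
        return self.values.index

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    def meta(self, name: str) -> FeatureMeta:
        return self._meta[name]

    @property
    def case_mask(self) -> np.ndarray:
        return (self.groups == self.case_label).to_numpy()

    @property
    def n_case(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_control(self) -> int:
        return int((~self.case_mask).sum())

    def feature_samples(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Pairwise-complete (case, control) sample arrays for one feature."""
        col = self.values[name].to_numpy(dtype=float)
        case = col[self.case_mask]
        control = col[~self.case_mask]
        return case[~np.isnan(case)], control[~np.isnan(control)]

    def copy(self) -> "CohortMatrix":
        return replace(
            self,
            values=self.values.copy(),
            censored=self.censored.copy(),
            groups=self.groups.copy(),
            features=list(self.features),
        )


# -- file I/O ------------------------------------------------------------------


def read_feature_metadata(path: str | Path) -> list[FeatureMeta]:
    df = pd.read_csv(path, dtype={"name": str})
    required = {"name", "panel", "kind", "confirmed_standard"}
    missing = required - set(df.columns)
    if missing:
        raise CohortError(f"metadata file missing column(s): {sorted(missing)}")
    metas = []
    for row in df.itertuples(index=False):
        confirmed = row.confirmed_standard
        if isinstance(confirmed, str):
            confirmed = confirmed.strip().lower() in ("true", "1", "yes")
        metas.append(FeatureMeta(str(row.name), str(row.panel), str(row.kind), bool(confirmed)))
    return metas


def read_cohort(
    path: str | Path,
    metadata_path: str | Path,
    censor_tokens: Sequence[str] = DEFAULT_CENSOR_TOKENS,
) -> CohortMatrix:
    """Read a wide cohort table (one ``group`` column) plus feature metadata.

    Cells equal to a censoring token are recorded in the censored mask and
    left ``NaN`` in ``values`` until :func:`impute_below_detection` runs.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, index_col=0, keep_default_na=False)
    return _cohort_from_raw(raw, metadata_path, censor_tokens)


def _cohort_from_raw(
    raw: pd.DataFrame,
    metadata_path: str | Path,
    censor_tokens: Sequence[str],
) -> CohortMatrix:
    raw = raw.fillna("")
    if "group" not in raw.columns:
        raise CohortError("cohort file has no 'group' column")
    groups = raw["group"].str.strip()
    if (groups == "").any():
        missing = raw.index[groups == ""].tolist()
        raise CohortError(f"participant(s) lacking a group label: {missing}")
    features = read_feature_metadata(metadata_path)
    names = [f.name for f in features]
    data_cols = [c for c in raw.columns if c != "group"]
    if sorted(data_cols) != sorted(names):
        extra = set(data_cols) - set(names)
        absent = set(names) - set(data_cols)
        raise CohortError(
            f"cohort/metadata feature mismatch (extra in data: {sorted(extra)}, "
            f"missing from data: {sorted(absent)})"
        )
    tokens = {t.strip() for t in censor_tokens}
    block = raw[names]
    stripped = block.apply(lambda s: s.str.strip())
    censored = stripped.isin(tokens)
    missing_token = "NA"
    is_missing = stripped == missing_token
    numeric = stripped.mask(censored | is_missing)
    values = numeric.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & ~censored & ~is_missing
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise CohortError(
            f"non-numeric cell {stripped.iloc[r, c]!r} at participant "
            f"{values.index[r]!r}, feature {values.columns[c]!r}"
        )
    return CohortMatrix(values=values, censored=censored, groups=groups, features=features)


def write_cohort(
    m: CohortMatrix,
    path: str | Path,
    metadata_path: str | Path,
    censor_token: str = "BDL",
) -> None:
    """Write a cohort back to the wide-CSV + metadata-CSV representation.

    Censored cells are written as ``censor_token`` (their pre-imputation
    value is not representable), missing cells as ``NA``; the round trip
    with :func:`read_cohort` is the identity on un-imputed cohorts.
    """
    out = m.values.astype(object).copy()
    out = out.where(~m.censored, censor_token)
    out = out.where(~(m.values.isna() & ~m.censored), "NA")
    out.insert(0, "group", m.groups)
    out.index.name = "participant"
    out.to_csv(path)
    meta = pd.DataFrame(
        {
            "name": [f.name for f in m.features],
            "panel": [f.panel for f in m.features],
            "kind": [f.kind for f in m.features],
            "confirmed_standard": [f.confirmed_standard for f in m.features],
        }
    )
    meta.to_csv(metadata_path, index=False)


def read_workbook(
    path: str | Path,
    metadata_path: str | Path,
    censor_tokens: Sequence[str] = DEFAULT_CENSOR_TOKENS,
) -> CohortMatrix:
    """Read a sheet-per-lab Excel workbook into a cohort.

    Each sheet carries participants as rows (IDs in the first column) and
    features as columns; a ``group`` column may appear on any sheet.  The
    sheets are joined on participant ID and validated against the feature
    metadata exactly like :func:`read_cohort`.
    """
    sheets = pd.read_excel(path, sheet_name=None, index_col=0, dtype=str)
    blocks = []
    group = None
    for name, df in sheets.items():
        df = df.copy()
        df.index = df.index.astype(str).str.strip()
        if "group" in df.columns:
            g = df["group"].astype(str).str.strip()
            if group is None:
                group = g
            df = df.drop(columns="group")
        blocks.append(df)
    if group is None:
        raise CohortError("no sheet in the workbook carries a 'group' column")
    wide = pd.concat(blocks, axis=1)
    dupes = wide.columns[wide.columns.duplicated()].tolist()
    if dupes:
        raise CohortError(f"duplicate feature name(s) across sheets: {sorted(set(dupes))}")
    wide.insert(0, "group", group.reindex(wide.index))
    return _cohort_from_raw(wide, metadata_path, censor_tokens)


# -- preprocessing -------------------------------------------------------------


def impute_below_detection(m: CohortMatrix) -> CohortMatrix:
    """Replace below-detection-limit cells with feature minimum / sqrt(2).

    The minimum is taken over the feature's uncensored, non-missing cells;
    the censored mask is preserved, so the operation is idempotent.
    """
    out = m.copy()
    values = out.values
    for name in out.feature_names:
        cens = out.censored[name].to_numpy()
        if not cens.any():
            continue
        col = values[name].to_numpy(dtype=float)
        uncensored = col[~cens]
        uncensored = uncensored[~np.isnan(uncensored)]
        if uncensored.size == 0:
            raise CohortError(f"feature {name!r} is entirely censored; cannot impute")
        values.loc[cens, name] = uncensored.min() / math.sqrt(2.0)
    return out


# -- subset assembly -----------------------------------------------------------


@dataclass(frozen=True)
class SubsetSpec:
    """An ordered, named feature subset for the multivariate stage."""

    id: str
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.id not in SUBSET_IDS:
            raise CohortError(f"unknown subset id {self.id!r}")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise CohortError("subset contains duplicate feature names")

    def to_json(self) -> str:
        return json.dumps({"id": self.id, "features": list(self.feature_names)})


def _complete_features(m: CohortMatrix, names: Iterable[str]) -> list[str]:
    """Drop features with any missing cell (classification needs complete data)."""
    keep = []
    for n in names:
        if m.values[n].isna().any():
            warnings.warn(f"feature {n!r} dropped from subset: incomplete measurements")
        else:
            keep.append(n)
    return keep


def build_subset(
    m: CohortMatrix,
    subset_id: str,
    auc_table: Mapping[str, float] | None = None,
    top_k: int = 50,
    expected_size: int | None = None,
) -> SubsetSpec:
    """Assemble one of the nested analysis subsets i-iv.

    i   : the targeted-pathway (focm_ts) continuous measurements;
    ii  : i plus the nutritional markers;
    iii : ii plus the binary genotype features;
    iv  : iii plus the ``top_k`` broad-panel features ranked by AUC
          descending (ties broken by name ascending), de-duplicated by name.

    Features with missing cells are excluded (they stay available to the
    univariate screen).  If ``expected_size`` is given, the final size is
    asserted against it, making any double-counting between panels explicit.
    """
    if subset_id not in SUBSET_IDS:
        raise CohortError(f"unknown subset id {subset_id!r}")
    by_panel: dict[str, list[str]] = {p: [] for p in PANELS}
    for f in m.features:
        by_panel[f.panel].append(f.name)
    names: list[str] = list(by_panel["focm_ts"])
    if subset_id in ("ii", "iii", "iv"):
        names += by_panel["nutritional"]
    if subset_id in ("iii", "iv"):
        names += by_panel["mthfr_binary"]
    if subset_id == "iv":
        if auc_table is None:
            raise CohortError("subset iv requires a per-feature AUC table")
        broad = [n for n in by_panel["metabolon"] if n in auc_table]
        if len(broad) < top_k:
            raise CohortError(
                f"need at least {top_k} broad-panel features with AUC values, got {len(broad)}"
            )
        ranked = sorted(broad, key=lambda n: (-auc_table[n], n))
        names += ranked[:top_k]
    names = list(dict.fromkeys(names))  # de-duplicate, order-preserving
    names = _complete_features(m, names)
    spec = SubsetSpec(id=subset_id, feature_names=tuple(names))
    if expected_size is not None and len(spec.feature_names) != expected_size:
        raise CohortError(
            f"subset {subset_id} has {len(spec.feature_names)} features, "
            f"expected {expected_size}"
        )
    return spec
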