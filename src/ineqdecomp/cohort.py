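"""Cohort construction: inclusion rules, expenditure trimming, quintiles.

The analytic cohort consists of person-wave records for middle-aged and
older adults (age >= 45) reporting at least one disability.  Socioeconomic
status is measured by annual per-capita household expenditure; a small
fraction of extreme expenditure values at both tails is trimmed before
ranking, and expenditure quintiles are cut within each survey wave so that
secular drift in the price level does not leak into the quintile labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)

#: canonical quintile labels, poorest to richest
QUINTILE_LEVELS = ["low", "low_middle", "average", "high_middle", "high"]

#: the five single-disability indicator columns recognised by
#: :func:`derive_disability_type`, mapped to their type label
DISABILITY_INDICATORS = {
    "physical_disability": "physical",
    "intellectual_disability": "intellectual",
    "vision_problem": "vision",
    "hearing_problem": "hearing",
    "speech_impediment": "speech",
}

DISABILITY_TYPES = ["physical", "intellectual", "vision", "hearing", "speech", "multiple"]


@dataclass(frozen=True)
class VariableSpec:
    """Declares a covariate's role and encoding for models and decomposition.

    Parameters
    ----------
    name : str
        Column name in the cohort frame.
    role : {"need", "non_need", "ranker", "outcome", "control"}
        Need variables capture legitimate drivers of service demand and are
        the ones subtracted from the concentration index to form the
        horizontal inequity index; non-need variables are socioeconomic
        factors that should not drive utilization under horizontal equity.
        The ranker is the living-standard variable (expenditure).  Controls
        (wave dummies, disability type) enter regressions but belong to
        neither block.
    kind : {"binary", "categorical", "ordered"}
    levels : list
        Ordered levels; for binary variables stored as 0/1 this is [0, 1].
    reference : level
        Omitted level for dummy encoding.
    """

    name: str
    role: str
    kind: str
    levels: list = field(default_factory=list)
    reference: object = None

    def __post_init__(self):
        if self.role not in {"need", "non_need", "ranker", "outcome", "control"}:
            raise ConfigurationError(f"unknown role {self.role!r} for {self.name}")
        if self.levels and self.reference is not None and self.reference not in self.levels:
            raise ConfigurationError(
                f"reference {self.reference!r} is not a level of {self.name}"
            )

    @property
    def dummy_levels(self) -> list:
        """Non-reference levels, each contributing one design column."""
        return [lv for lv in self.levels if lv != self.reference]


def _binary(name, role):
    return VariableSpec(name, role, "binary", [0, 1], 0)


def default_variable_specs() -> list[VariableSpec]:
    """The study's default variable roles.

    Need variables: gender, age band, self-rated health, chronic disease,
    ADL and IADL limitation.  Non-need variables: expenditure quintile,
    smoking, drinking, marital status, education, social activity, child
    financial support, region and basic medical insurance.
    """
    return [
        VariableSpec("wave", "control", "categorical",
                     ["2011", "2013", "2015", "2018"], "2011"),
        VariableSpec("gender", "need", "binary", ["male", "female"], "male"),
        VariableSpec("age_band", "need", "ordered", ["45-59", "60-74", "75+"], "45-59"),
        VariableSpec("self_rated_health", "need", "categorical",
                     ["good", "general", "poor"], "good"),
        _binary("chronic_disease", "need"),
        _binary("adl_limited", "need"),
        _binary("iadl_limited", "need"),
        VariableSpec("expenditure_quintile", "non_need", "ordered",
                     QUINTILE_LEVELS, "low"),
        _binary("smoking", "non_need"),
        _binary("drinking", "non_need"),
        _binary("married", "non_need"),
        VariableSpec("education", "non_need", "ordered",
                     ["illiterate", "below_primary", "primary", "junior_plus"],
                     "illiterate"),
        _binary("social_activity", "non_need"),
        _binary("child_support", "non_need"),
        VariableSpec("region", "non_need", "categorical",
                     ["western", "central", "eastern"], "western"),
        _binary("insured", "non_need"),
        VariableSpec("disability_type", "control", "categorical",
                     DISABILITY_TYPES, "physical"),
        VariableSpec("expenditure", "ranker", "ordered"),
        _binary("outpatient", "outcome"),
        _binary("inpatient", "outcome"),
        _binary("self_treatment", "outcome"),
    ]


def specs_by_role(specs: list[VariableSpec] | None = None) -> dict[str, list[VariableSpec]]:
    """Group variable specs by role; exactly one ranker is required."""
    specs = default_variable_specs() if specs is None else specs
    out: dict[str, list[VariableSpec]] = {}
    for s in specs:
        out.setdefault(s.role, []).append(s)
    if len(out.get("ranker", [])) != 1:
        raise ConfigurationError("exactly one variable must have role='ranker'")
    return out


def derive_disability_type(df: pd.DataFrame) -> pd.Series:
    """Collapse the five single-disability indicators to one categorical.

    Records reporting two or more disability problems are labelled
    ``"multiple"``; records reporting none get a missing type (and are
    dropped by :func:`apply_inclusion`).
    """
    cols = [c for c in DISABILITY_INDICATORS if c in df.columns]
    if not cols:
        raise DataError(
            "no disability information: need a 'disability_type' column or "
            f"indicator columns among {sorted(DISABILITY_INDICATORS)}"
        )
    ind = df[cols].fillna(0).astype(float)
    total = ind.sum(axis=1)
    out = pd.Series(pd.NA, index=df.index, dtype="object")
    for c in cols:
        single = (total == 1) & (ind[c] == 1)
        out[single] = DISABILITY_INDICATORS[c]
    out[total >= 2] = "multiple"
    return out


def apply_inclusion(df: pd.DataFrame, min_age: int = 45) -> pd.DataFrame:
    """Retain records aged ``min_age`` or older with a known disability type.

    If the frame lacks a ``disability_type`` column it is derived from the
    five indicator columns first.  Exclusion counts are logged.
    """
    df = df.copy()
    if "disability_type" not in df.columns:
        df["disability_type"] = derive_disability_type(df)
    n0 = len(df)
    age_ok = pd.to_numeric(df.get("age"), errors="coerce") >= min_age
    dis_ok = df["disability_type"].notna()
    kept = df[age_ok & dis_ok]
    logger.info(
        "inclusion: kept %d of %d records (%d under age %d or missing age, "
        "%d without a disability)",
        len(kept), n0, int((~age_ok).sum()), min_age, int((~dis_ok).sum()),
    )
    return kept


def trim_expenditure(
    df: pd.DataFrame,
    trim_total: float = 0.02,
    by_wave: bool = True,
) -> pd.DataFrame:
    """Drop expenditure outliers at both tails.

    ``trim_total`` is the total trimmed proportion, split evenly between the
    tails; cut points are the ``trim_total/2`` and ``1 - trim_total/2``
    empirical quantiles (inclusive linear interpolation), computed within
    wave by default.  Records strictly outside the open interval between the
    cuts are dropped, so a degenerate all-tied sample loses nothing.
    Records with missing expenditure are passed through untouched and
    flagged with ``expenditure_missing = True``.
    """
    if not 0 <= trim_total < 0.5:
        raise ConfigurationError(f"trim_total must be in [0, 0.5), got {trim_total}")
    df = df.copy()
    exp = pd.to_numeric(df["expenditure"], errors="coerce")
    df["expenditure_missing"] = exp.isna()
    if trim_total == 0:
        return df
    alpha = trim_total / 2.0
    keep = pd.Series(True, index=df.index)
    groups = df.groupby("wave").groups if by_wave and "wave" in df.columns else {
        "all": df.index
    }
    for wave, idx in groups.items():
        x = exp.loc[idx].dropna()
        if x.empty:
            continue
        lo, hi = np.quantile(x.to_numpy(), [alpha, 1 - alpha])
        bad = (exp.loc[idx] < lo) | (exp.loc[idx] > hi)
        keep.loc[idx[bad.fillna(False)]] = False
        logger.info("trim wave %s: removed %d of %d (cuts %.2f, %.2f)",
                    wave, int(bad.sum()), len(x), lo, hi)
    return df[keep]


def _quintile_bins(x: np.ndarray) -> np.ndarray:
    """Quintile bin indices 0..4; ties at a cut point go to the lower bin."""
    cuts = np.quantile(x, [0.2, 0.4, 0.6, 0.8])
    return np.searchsorted(cuts, x, side="left")


def assign_quintiles(df: pd.DataFrame, by_wave: bool = True) -> pd.DataFrame:
    """Attach within-wave expenditure quintile labels.

    Cut points are the 20/40/60/80th percentiles of non-missing expenditure
    in each wave.  A wave with fewer than five distinct values triggers a
    degenerate-quintile warning; labels are still assigned by rank order
    (an all-tied wave collapses into the lowest quintile).
    """
    df = df.copy()
    exp = pd.to_numeric(df["expenditure"], errors="coerce")
    labels = pd.Series(pd.NA, index=df.index, dtype="object")
    groups = df.groupby("wave").groups if by_wave and "wave" in df.columns else {
        "all": df.index
    }
    for wave, idx in groups.items():
        x = exp.loc[idx]
        valid = x.notna()
        if valid.sum() == 0:
            continue
        vals = x[valid].to_numpy(dtype=float)
        if len(np.unique(vals)) < 5:
            warnings.warn(
                f"wave {wave}: fewer than 5 distinct expenditure values; "
                "quintiles are degenerate",
                stacklevel=2,
            )
        bins = _quintile_bins(vals)
        labels.loc[idx[valid]] = np.array(QUINTILE_LEVELS, dtype=object)[bins]
    df["expenditure_quintile"] = labels
    return df


def prepare_cohort(
    df: pd.DataFrame,
    min_age: int = 45,
    trim_total: float = 0.02,
) -> pd.DataFrame:
    """Inclusion filter, expenditure trimming and quintile assignment in order."""
    return assign_quintiles(trim_expenditure(apply_inclusion(df, min_age), trim_total))
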