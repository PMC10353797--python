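"""BMI classification, eligibility filtering and descriptive statistics.

BMI categories use the WHO Asian cutoffs.  Interval boundaries follow a
left-closed/right-open convention — underweight [0, 18.5), normal
[18.5, 23), overweight [23, 27.5), obese [27.5, inf) — configurable via
``cutoffs`` where a different reading of the boundary values is wanted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

#: WHO Asian BMI cutpoints (kg/m^2) separating the four categories.
DEFAULT_CUTOFFS = (18.5, 23.0, 27.5)

FOUR_LEVELS = ("underweight", "normal", "overweight", "obese")
THREE_LEVELS = ("underweight", "normal", "overweight_obese")


def classify_bmi(bmi, cutoffs=DEFAULT_CUTOFFS):
    """Four-level WHO Asian BMI category for a scalar or array of BMI values.

    Each interval is closed on the left: a BMI exactly at a cutpoint falls
    in the higher category (18.5 is "normal", 27.5 is "obese").
    """
    arr = np.asarray(bmi, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("BMI values must be finite and positive")
    idx = np.searchsorted(np.asarray(cutoffs, dtype=float), arr, side="right")
    if arr.ndim == 0:
        return FOUR_LEVELS[int(idx)]
    return np.asarray(FOUR_LEVELS, dtype=object)[idx]


def collapse_to_three(category):
    """Merge overweight and obese into ``overweight_obese``; keep the rest."""
    mapping = {
        "underweight": "underweight",
        "normal": "normal",
        "overweight": "overweight_obese",
        "obese": "overweight_obese",
    }
    if isinstance(category, str):
        try:
            return mapping[category]
        except KeyError:
            raise ValueError(f"unknown BMI category {category!r}") from None
    arr = np.asarray(category, dtype=object)
    bad = set(np.unique(arr)) - set(mapping)
    if bad:
        raise ValueError(f"unknown BMI categories {sorted(bad)}")
    return np.vectorize(mapping.get, otypes=[object])(arr)


def classify_records(df: pd.DataFrame, bmi_col: str = "bmi") -> pd.DataFrame:
    """Attach three-level ``nutrition_category`` derived from BMI."""
    out = df.copy()
    out["nutrition_category"] = collapse_to_three(classify_bmi(df[bmi_col].to_numpy()))
    return out


#: Exclusion reasons in priority order: a record failing several criteria is
#: logged once, under the first matching reason.
ELIGIBILITY_FLAGS = ("pregnant", "recent_birth_within_2_months")


def apply_inclusion_filters(
    df: pd.DataFrame, required_covariates=None
) -> tuple[pd.DataFrame, dict]:
    """Drop ineligible records and records missing modelled covariates.

    Eligibility flags (boolean columns ``pregnant`` and
    ``recent_birth_within_2_months``, when present) are checked first, then
    listwise deletion over ``required_covariates`` (default: every modelled
    covariate present in the frame, in the canonical covariate order).
    Returns the surviving records untouched plus a per-reason drop count.
    """
    from . import surveys

    if required_covariates is None:
        required_covariates = [c for c in surveys.COVARIATES if c in df.columns]
    log: dict[str, int] = {}
    dropped = np.zeros(len(df), dtype=bool)
    for flag in ELIGIBILITY_FLAGS:
        if flag in df.columns:
            hit = df[flag].fillna(False).astype(bool).to_numpy() & ~dropped
            if hit.any():
                log[flag] = int(hit.sum())
            dropped |= hit
    for cov in required_covariates:
        hit = df[cov].isna().to_numpy() & ~dropped
        if hit.any():
            log[f"missing_{cov}"] = int(hit.sum())
        dropped |= hit
    kept = df.loc[~dropped]
    if kept.empty:
        warnings.warn("all records excluded", stacklevel=2)
    return kept, log


def two_proportion_test(x1: int, n1: int, x2: int, n2: int):
    """Pooled two-sample z-test for proportions; returns (z, two-sided p).

    This is the standard large-sample test of H0: p1 = p2 (with the two
    survey rounds' sample sizes it is numerically indistinguishable from a
    t reference).  Degenerate pooled proportions (0 or 1) carry no
    evidence against H0 and return p = 1 with a warning.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1 or not 0 <= x <= n:
            raise ValueError("need 0 <= x <= n and n >= 1 in both groups")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("degenerate pooled proportion; p-value set to 1", stacklevel=2)
        return 0.0, 1.0
    z, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
    return float(z), float(p)


@dataclass(frozen=True)
class DescriptiveRow:
    variable: str
    level: str
    count_year1: int
    pct_year1: float
    count_year2: int
    pct_year2: float
    p_value: float


def descriptive_table(
    records_year1: pd.DataFrame,
    records_year2: pd.DataFrame,
    variables=None,
    levels=None,
) -> pd.DataFrame:
    """Per-level counts, column percentages and between-round p-values.

    Mirrors the published descriptive layout: one row per covariate level
    (plus the three nutrition categories), counts and column percentages
    per survey round, and the pooled two-proportion p-value for the change
    in share between rounds.
    """
    from . import surveys

    if variables is None:
        variables = [c for c in surveys.COVARIATES if c in records_year1.columns]
        if "nutrition_category" in records_year1.columns:
            variables = variables + ["nutrition_category"]
    levels = levels or {}
    n1, n2 = len(records_year1), len(records_year2)
    rows = []
    for var in variables:
        lv = levels.get(var)
        if lv is None:
            if var == "nutrition_category":
                lv = list(THREE_LEVELS)
            else:
                lv = surveys.COVARIATE_LEVELS.get(var)
            if lv is None:
                lv = sorted(
                    set(records_year1[var].astype(str))
                    | set(records_year2[var].astype(str))
                )
        c1 = records_year1[var].astype(str).value_counts()
        c2 = records_year2[var].astype(str).value_counts()
        observed = set(c1.index) | set(c2.index)
        for level in lv:
            if level not in observed:
                continue
            x1 = int(c1.get(level, 0))
            x2 = int(c2.get(level, 0))
            if x1 == 0 or x2 == 0:
                warnings.warn(
                    f"level {level!r} of {var!r} absent in one round", stacklevel=2
                )
            if len(lv) == 1:
                p = 1.0
            else:
                _, p = two_proportion_test(x1, n1, x2, n2)
            rows.append(
                DescriptiveRow(
                    variable=var,
                    level=level,
                    count_year1=x1,
                    pct_year1=column_percentage(x1, n1),
                    count_year2=x2,
                    pct_year2=column_percentage(x2, n2),
                    p_value=p,
                )
            )
    return pd.DataFrame(rows)


def column_percentage(count: int, total: int, decimals: int | None = None) -> float:
    """Column percentage 100*count/total, optionally rounded half-up."""
    pct = 100.0 * count / total
    if decimals is None:
        return pct
    # round-half-up at the requested precision, matching the published style
    # (tiny epsilon so binary representation of exact halves rounds up)
    scale = 10.0**decimals
    return float(np.floor(pct * scale + 0.5 + 1e-9) / scale)
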