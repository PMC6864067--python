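"""Questionnaire-derived analysis phenotypes.

Weekly alcohol units combine self-reported beverage intakes with the standard
unit conversion (1 unit per spirit measure, 2 per glass of wine of any type,
2.5 per pint of beer or cider).  Respondents drinking less than weekly are
not asked the intake questions and are assigned zero weekly units.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DataError
from .simulate import BEVERAGE_COLUMNS, SUBWEEKLY_CATEGORIES

log = logging.getLogger(__name__)

UNIT_FACTORS = {
    "spirits_measures": 1.0,
    "red_wine_glasses": 2.0,
    "white_wine_glasses": 2.0,
    "champagne_glasses": 2.0,
    "fortified_wine_glasses": 2.0,
    "beer_pints": 2.5,
    "cider_pints": 2.5,
}


def derive_weekly_units(intakes: pd.DataFrame, frequency_category: pd.Series) -> pd.Series:
    """Weekly alcohol units from beverage intakes and intake frequency.

    Individuals whose reported frequency is below weekly get 0 regardless of
    (typically missing) intakes.  Weekly-or-more drinkers with missing
    intakes get NaN.  Negative intakes are rejected.
    """
    for col in BEVERAGE_COLUMNS:
        if col not in intakes.columns:
            raise DataError(f"intake table lacks column {col!r}")
    vals = intakes[list(BEVERAGE_COLUMNS)].astype(float)
    if (vals.to_numpy() < 0).any():
        bad = vals.lt(0).any(axis=1)
        raise DataError(
            f"negative beverage intake for individual(s) {list(vals.index[bad][:5])}")
    units = sum(vals[c] * f for c, f in UNIT_FACTORS.items())
    sub = frequency_category.reindex(vals.index).isin(SUBWEEKLY_CATEGORIES)
    units = units.where(~sub, 0.0)
    units.name = "weekly_units"
    return units


def exclude_outlier_pairs(pairs: pd.DataFrame, weekly_units: pd.Series,
                          k: float = 5.0, two_sided: bool = True) -> tuple:
    """Remove pairs with a member more than ``k`` SD from the mean weekly units.

    Mean and SD are computed over individuals with *non-zero* units among the
    pair members.  With ``two_sided`` (default) the absolute deviation is
    used; one-sided applies the upper bound only.  Returns
    (filtered pairs, n_pairs_removed).
    """
    member_ids = pd.unique(np.r_[pairs["id_a"], pairs["id_b"]])
    u = weekly_units.reindex(member_ids).dropna()
    nonzero = u[u > 0]
    if len(nonzero) == 0:
        log.warning("all weekly units are zero; no outlier exclusion applied")
        return pairs.reset_index(drop=True), 0
    mu, sd = nonzero.mean(), nonzero.std()
    if sd == 0:
        return pairs.reset_index(drop=True), 0
    ua = weekly_units.reindex(pairs["id_a"]).to_numpy(dtype=float)
    ub = weekly_units.reindex(pairs["id_b"]).to_numpy(dtype=float)
    if two_sided:
        out = (np.abs(ua - mu) > k * sd) | (np.abs(ub - mu) > k * sd)
    else:
        out = (ua - mu > k * sd) | (ub - mu > k * sd)
    out = np.where(np.isnan(out.astype(float)), False, out).astype(bool)
    kept = pairs[~out].reset_index(drop=True)
    return kept, int(out.sum())


def recode_education(age_completed: pd.Series, has_degree: pd.Series,
                     country_of_birth: pd.Series) -> pd.Series:
    """Years-in-education recode used as a confounder covariate.

    Degree holders are assigned a leaving age of 21; self-reported leaving
    ages below 15 are floored at 15; individuals born outside England,
    Scotland or Wales are excluded (NaN) because of schooling-system
    differences.
    """
    age = age_completed.astype(float).copy()
    age[has_degree.astype(bool)] = 21.0
    age = age.clip(lower=15.0)
    outside = ~country_of_birth.isin(["England", "Scotland", "Wales"])
    age[outside] = np.nan
    age.name = "education_leaving_age"
    return age


def drinking_binaries(drinker_status: pd.Series, frequency_category: pd.Series) -> pd.DataFrame:
    """Ever-drinker and frequent-drinker (3+ times/week) indicators."""
    ever = (drinker_status != "never").astype(int)
    frequent = frequency_category.isin(["daily", "3-4 per week"]).astype(int)
    return pd.DataFrame({"ever_drinker": ever, "frequent_drinker": frequent})
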