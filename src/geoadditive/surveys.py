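"""Published BDHS summary tables used to parameterize the synthetic generator.

The package does not redistribute DHS microdata (access is gated).  What it
ships are the published frequency distributions of the modelled covariates
for the 2014 and 2017–18 Bangladesh DHS rounds: enough to draw synthetic
populations whose categorical marginals look like the real surveys, and to
reproduce the descriptive-table arithmetic (column percentages, year totals,
between-round proportion tests).
"""

from __future__ import annotations

import numpy as np

#: Modelled covariates, in the fixed order used for dummy coding and for the
#: missing-value priority of the exclusion log.
COVARIATES = (
    "residence",
    "wealth",
    "education",
    "working",
    "water",
    "toilet",
    "electricity",
    "newspaper",
    "radio",
    "television",
)

#: Reference level per covariate (the omitted dummy column).
REFERENCE_LEVELS = {
    "residence": "Rural",
    "wealth": "Poorest",
    "education": "No education",
    "working": "No",
    "water": "Unprotected",
    "toilet": "Unimproved",
    "electricity": "No",
    "newspaper": "No",
    "radio": "No",
    "television": "No",
}

#: Level order per covariate, reference level first.
COVARIATE_LEVELS = {
    "residence": ("Rural", "City Corporation", "Other Urban"),
    "wealth": ("Poorest", "Poorer", "Middle", "Richer", "Richest"),
    "education": ("No education", "Primary", "Secondary", "Higher"),
    "working": ("No", "Yes"),
    "water": ("Unprotected", "Protected"),
    "toilet": ("Unimproved", "Improved"),
    "electricity": ("No", "Yes"),
    "newspaper": ("No", "Yes"),
    "radio": ("No", "Yes"),
    "television": ("No", "Yes"),
}

OUTCOME_LEVELS = ("underweight", "normal", "overweight_obese")
OUTCOME_REFERENCE = "normal"

# Published per-level respondent counts, by survey round.  Totals are
# 14,997 (2014) and 16,751 (2017-18) after the surveys' exclusions.
_COUNTS = {
    2014: {
        "residence": {"City Corporation": 1782, "Other Urban": 3383, "Rural": 9832},
        "wealth": {
            "Poorest": 2774,
            "Poorer": 2841,
            "Middle": 3027,
            "Richer": 3148,
            "Richest": 3207,
        },
        "education": {
            "No education": 3884,
            "Primary": 4521,
            "Secondary": 5356,
            "Higher": 1236,
        },
        "working": {"No": 9951, "Yes": 5046},
        "water": {"Protected": 13942, "Unprotected": 1055},
        "toilet": {"Improved": 10405, "Unimproved": 4592},
        "electricity": {"No": 5753, "Yes": 9244},
        "newspaper": {"No": 14078, "Yes": 919},
        "radio": {"No": 14663, "Yes": 334},
        "television": {"No": 7344, "Yes": 7653},
        "nutrition": {"underweight": 2730, "normal": 6155, "overweight_obese": 6112},
    },
    2018: {
        "residence": {"City Corporation": 1630, "Other Urban": 4428, "Rural": 10693},
        "wealth": {
            "Poorest": 3249,
            "Poorer": 3252,
            "Middle": 3273,
            "Richer": 3378,
            "Richest": 3599,
        },
        "education": {
            "No education": 2980,
            "Primary": 5579,
            "Secondary": 6258,
            "Higher": 1934,
        },
        "working": {"No": 8185, "Yes": 8566},
        "water": {"Protected": 15378, "Unprotected": 1373},
        "toilet": {"Improved": 10963, "Unimproved": 5788},
        "electricity": {"No": 3846, "Yes": 12905},
        "newspaper": {"No": 16152, "Yes": 599},
        "radio": {"No": 16465, "Yes": 286},
        "television": {"No": 7692, "Yes": 9059},
        "nutrition": {"underweight": 1962, "normal": 6294, "overweight_obese": 8495},
    },
}

SUPPORTED_YEARS = tuple(sorted(_COUNTS))


def published_counts(year: int) -> dict:
    """Published per-level counts for a survey round, including the outcome."""
    _check_year(year)
    return {var: dict(levels) for var, levels in _COUNTS[year].items()}


def year_total(year: int) -> int:
    """Analysis sample size of a round, as the sum of outcome-level counts."""
    _check_year(year)
    return int(sum(_COUNTS[year]["nutrition"].values()))


def default_table1_marginals(year: int, include_outcome: bool = False) -> dict:
    """Covariate marginal probabilities matching a round's published table.

    Returns a map ``covariate -> {level: probability}`` with each vector
    normalized to sum to one.  With ``include_outcome=True`` the observed
    three-level nutrition distribution is included under ``"nutrition"``
    (the generator itself draws outcomes from the model, not from this).
    """
    _check_year(year)
    out = {}
    for var, levels in _COUNTS[year].items():
        if var == "nutrition" and not include_outcome:
            continue
        counts = np.array(list(levels.values()), dtype=float)
        probs = counts / counts.sum()
        out[var] = dict(zip(levels.keys(), probs))
    return out


def _check_year(year: int) -> None:
    if year not in _COUNTS:
        raise ValueError(f"unsupported survey year {year!r}; known: {SUPPORTED_YEARS}")
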