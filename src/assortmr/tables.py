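"""Published UK Biobank summary inputs used by the worked analyses.

These are printed summary statistics from the UK Biobank spousal alcohol
study (47,549 derived spouse-pairs; rs1229984 in ADH1B as the instrument):
the per-recruitment-centre spousal genotypic-concordance estimates among
pairs born within 100 km of each other, and the two cross-spouse MR stage
estimates.  They serve as inputs to the meta-analysis and Wald-ratio
recomputations; nothing here is a fitted output of this package.
"""

from __future__ import annotations

import pandas as pd

from .mr import MRInput

#: Per-centre spousal concordance for rs1229984 (effect = major allele count)
#: among spouse-pairs born within 100 km of each other.  Centres whose
#: regressions did not converge have missing estimates.
_CENTRE_ROWS = [
    ("Stockport", 9, None, None, None),
    ("Manchester", 662, 0.024, -0.088, 0.0675),
    ("Oxford", 669, -0.010, -0.088, 0.067),
    ("Cardiff", 930, 0.022, -0.043, 0.088),
    ("Glasgow", 1046, 0.072, 0.019, 0.125),
    ("Edinburgh", 611, -0.047, -0.166, 0.070),
    ("Stoke", 1215, -0.012, -0.075, 0.051),
    ("Reading", 1352, 0.003, -0.055, 0.060),
    ("Bury", 2244, 0.012, -0.031, 0.055),
    ("Newcastle", 2976, -0.025, -0.064, 0.013),
    ("Leeds", 2563, 0.041, 0.001, 0.081),
    ("Bristol", 2117, 0.015, -0.030, 0.060),
    ("St Bartholomew's Hospital", 122, -0.073, -0.220, 0.074),
    ("Nottingham", 2342, 0.025, -0.017, 0.066),
    ("Sheffield", 2260, 0.037, -0.009, 0.082),
    ("Liverpool", 2632, 0.023, -0.020, 0.066),
    ("Middlesbrough", 1477, 0.002, -0.050, 0.053),
    ("Hounslow", 838, 0.073, -0.000, 0.147),
    ("Croydon", 1034, 0.044, -0.027, 0.115),
    ("Birmingham", 1440, -0.019, -0.068, 0.031),
    ("Swansea", 85, -0.068, -0.283, 0.146),
    ("Wrexham", 29, None, None, None),
]


def centre_concordance_table() -> pd.DataFrame:
    """Published within-centre concordance estimates as a stratum table."""
    return pd.DataFrame(_CENTRE_ROWS,
                        columns=["label", "n", "beta", "ci_lo", "ci_hi"])


def ci_to_se(ci_lo: float, ci_hi: float) -> float:
    """Symmetric-width convention: SE = (upper - lower) / (2 x 1.96)."""
    return (ci_hi - ci_lo) / (2 * 1.96)


#: Published cross-spouse MR stage estimates for rs1229984 and weekly units:
#: exposure stage 3.99 (95% CI 3.52, 4.45) units/week per major allele in the
#: same individual; outcome stage 1.06 (95% CI 0.59, 1.52) in the partner.
ALCOHOL_STAGE_ESTIMATES = {
    "beta_exposure": 3.99, "ci_exposure": (3.52, 4.45),
    "beta_outcome": 1.06, "ci_outcome": (0.59, 1.52),
    "n_pairs": 47_321,
}

#: Published phenotypic spousal concordance for weekly units: 0.37 (0.36, 0.38).
ALCOHOL_PHENOTYPIC = {"beta": 0.37, "ci": (0.36, 0.38), "n_pairs": 47_321}


def alcohol_mr_input() -> MRInput:
    """The published two-stage summary statistics as an MRInput."""
    s = ALCOHOL_STAGE_ESTIMATES
    return MRInput(
        variant="rs1229984",
        beta_exposure=s["beta_exposure"],
        se_exposure=ci_to_se(*s["ci_exposure"]),
        beta_outcome=s["beta_outcome"],
        se_outcome=ci_to_se(*s["ci_outcome"]),
        effect_allele="major",
    )
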