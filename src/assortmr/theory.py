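"""Closed-form expectations under single-round phenotypic assortment.

Model: within an individual the phenotype P and a genetic score G are jointly
normal with corr(G, P) = sqrt(h2), where h2 is the fraction of phenotypic
variance explained by the score.  Mates pair such that the spousal phenotypic
correlation is C.  Conditional on the two phenotypes, the scores of the two
partners are independent (assortment acts on the phenotype only), so by linear
projection:

    corr(G_I, P_partner) = C * sqrt(h2)
    corr(G_I, G_partner) = C * h2

These are the oracles used to validate the couple simulator and the
concordance estimators, and they quantify why genotype-based estimates of
assortment are attenuated relative to the phenotypic correlation unless
rescaled as in Mendelian randomization.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

from .errors import ConfigError


@dataclass(frozen=True)
class TheoryExpectation:
    """Expected cross-spouse correlations induced by phenotypic assortment."""

    C: float
    h2: float
    exp_corr_G_Ppartner: float
    exp_corr_G_Gpartner: float

    def as_dict(self) -> dict:
        return {
            "C": self.C,
            "h2": self.h2,
            "exp_corr_G_Ppartner": self.exp_corr_G_Ppartner,
            "exp_corr_G_Gpartner": self.exp_corr_G_Gpartner,
        }


def expected_correlations(C: float, h2: float) -> TheoryExpectation:
    """Expected corr(G_I, P_partner) and corr(G_I, G_partner) under assortment.

    Parameters
    ----------
    C : spousal phenotypic correlation in [-1, 1].
    h2 : fraction of phenotypic variance explained by the genetic score, in [0, 1].
    """
    if not -1.0 <= C <= 1.0:
        raise ConfigError(f"C must be in [-1, 1], got {C}")
    if not 0.0 <= h2 <= 1.0:
        raise ConfigError(f"h2 must be in [0, 1], got {h2}")
    return TheoryExpectation(
        C=C,
        h2=h2,
        exp_corr_G_Ppartner=C * math.sqrt(h2),
        exp_corr_G_Gpartner=C * h2,
    )


def mr_rescaling_check(C: float, h2: float, beta_focal: float, maf: float) -> dict:
    """Expected two-stage betas and Wald ratio for a single focal variant.

    Under pure phenotypic assortment with a linear pairing rule, the exposure
    stage recovers the per-allele effect beta_focal, the cross-spouse outcome
    stage recovers C * beta_focal, and their Wald ratio equals C.  The
    heritability cancels: rescaling restores the full phenotypic assortment
    strength regardless of how much variance the instrument explains.
    """
    if not -1.0 <= C <= 1.0:
        raise ConfigError(f"C must be in [-1, 1], got {C}")
    if not 0.0 <= h2 <= 1.0:
        raise ConfigError(f"h2 must be in [0, 1], got {h2}")
    if not 0.0 < maf <= 0.5:
        raise ConfigError(f"maf must be in (0, 0.5], got {maf}")
    beta_gx = beta_focal
    beta_gy = C * beta_focal
    ratio = float("nan") if beta_focal == 0 else beta_gy / beta_gx
    return {
        "beta_exposure": beta_gx,
        "beta_outcome": beta_gy,
        "wald_ratio": ratio,
        "instrument_r2": beta_focal**2 * 2 * maf * (1 - maf),
    }
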