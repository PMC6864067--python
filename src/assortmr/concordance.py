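"""Spousal concordance estimators: phenotypic, genotypic, polygenic-score,
and the relationship-length proxy.

Pairing conventions follow the study design: concordance analyses use one
row per couple with the reference member chosen at random (seeded), so each
individual appears once; the cross-spouse MR stages (in :mod:`assortmr.mr`)
use two rows per couple.  Standard errors are conventional (not
cluster-adjusted) by default, with an optional HC-robust switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DataError


@dataclass
class AssocResult:
    """A single regression association: beta, normal-approximation CI and p."""

    beta: float
    se: float
    ci95: tuple
    p: float
    n: int
    covariates: list = field(default_factory=list)
    method: str = ""

    @classmethod
    def from_beta_se(cls, beta, se, n, covariates=(), method=""):
        beta, se = float(beta), float(se)
        z = beta / se if se > 0 else np.nan
        return cls(
            beta=beta,
            se=se,
            ci95=(beta - 1.96 * se, beta + 1.96 * se),
            p=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
            n=int(n),
            covariates=list(covariates),
            method=method,
        )

    @property
    def z(self) -> float:
        return self.beta / self.se if self.se > 0 else np.nan


def make_pair_frame(pairs: pd.DataFrame, individuals: pd.DataFrame,
                    columns: Sequence[str], seed: int = 0) -> pd.DataFrame:
    """One row per couple with ``ref_``/``partner_`` columns, orientation
    randomised by seed so neither sex is systematically the reference."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, len(pairs), 463]))
    flip = rng.random(len(pairs)) < 0.5
    ref_ids = np.where(flip, pairs["id_b"], pairs["id_a"])
    par_ids = np.where(flip, pairs["id_a"], pairs["id_b"])
    out = {}
    for col in columns:
        if col not in individuals.columns:
            raise DataError(f"individuals table lacks column {col!r}")
        out[f"ref_{col}"] = individuals.loc[ref_ids, col].to_numpy()
        out[f"partner_{col}"] = individuals.loc[par_ids, col].to_numpy()
    frame = pd.DataFrame(out)
    frame.insert(0, "ref_id", ref_ids)
    frame.insert(1, "partner_id", par_ids)
    return frame


def _design(frame: pd.DataFrame, exposure: str, covariates: Iterable[str]):
    """Build (y-less) design matrix: exposure + covariates, categoricals dummied."""
    cols = [frame[exposure].astype(float).rename("exposure")]
    names = []
    for cov in covariates:
        s = frame[cov]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(s, prefix=cov, drop_first=True, dtype=float)
            cols.append(d)
            names.extend(d.columns)
        else:
            cols.append(s.astype(float))
            names.append(cov)
    X = pd.concat(cols, axis=1)
    X = sm.add_constant(X, has_constant="add")
    return X


def _regress(y, X, family: str, robust: bool, n, covariates, method):
    try:
        if family == "linear":
            model = sm.OLS(np.asarray(y, dtype=float), np.asarray(X, dtype=float),
                           missing="drop")
            res = (model.fit(cov_type="HC1") if robust else model.fit())
        elif family == "logistic":
            model = sm.Logit(np.asarray(y, dtype=float), np.asarray(X, dtype=float),
                             missing="drop")
            res = model.fit(disp=False, maxiter=200)
            if not res.mle_retvals.get("converged", True):
                raise DataError("logistic regression did not converge")
        else:
            raise DataError(f"unknown family {family!r}")
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise DataError(f"regression failed ({exc})") from exc
    idx = list(X.columns).index("exposure")
    beta, se = res.params[idx], res.bse[idx]
    if not np.isfinite(se) or se == 0:
        raise DataError("degenerate regression: zero/undefined standard error")
    return AssocResult.from_beta_se(beta, se, n=n, covariates=covariates, method=method)


def phenotypic_concordance(pairs: pd.DataFrame, individuals: pd.DataFrame,
                           column: str, family: str = "linear",
                           covariates: Sequence[str] = (), seed: int = 0,
                           robust: bool = False) -> AssocResult:
    """Regression of the partner's phenotype on the reference individual's.

    ``covariates`` are ``ref:``/``partner:``-prefixed individual columns,
    e.g. ``("ref:sex", "ref:age", "partner:age", "ref:centre")``; recruitment
    centre (or any string column) is expanded to indicator variables.
    """
    need = {column} | {c.split(":", 1)[1] for c in covariates}
    frame = make_pair_frame(pairs, individuals, sorted(need), seed=seed)
    cov_cols = []
    for c in covariates:
        side, name = c.split(":", 1)
        if side not in ("ref", "partner"):
            raise DataError(f"covariate {c!r} must be 'ref:...' or 'partner:...'")
        cov_cols.append(f"{side}_{name}")
    if frame[f"ref_{column}"].isna().all():
        raise DataError(f"column {column!r} is entirely missing")
    sub = frame.dropna(subset=[f"ref_{column}", f"partner_{column}"] + cov_cols)
    # constant phenotype: slope is exactly zero by convention
    if sub[f"ref_{column}"].nunique() <= 1:
        return AssocResult(beta=0.0, se=np.nan, ci95=(np.nan, np.nan), p=np.nan,
                           n=len(sub), covariates=list(covariates),
                           method=f"phenotypic_{family}")
    X = _design(sub, f"ref_{column}", cov_cols)
    y = sub[f"partner_{column}"]
    return _regress(y, X, family, robust, n=len(sub), covariates=list(covariates),
                    method=f"phenotypic_{family}")


def genotypic_concordance(pairs: pd.DataFrame, genotypes: pd.DataFrame,
                          variant: str, individuals: pd.DataFrame | None = None,
                          covariates: Sequence[str] = (), seed: int = 0) -> AssocResult:
    """Linear regression of partner's effect-allele count on the reference's."""
    g = genotypes[variant]
    if g.dropna().nunique() <= 1:
        raise DataError(f"variant {variant!r} is monomorphic in the analysis sample")
    tab = individuals.copy() if individuals is not None else pd.DataFrame(index=g.index)
    tab = tab.assign(_gcount=g)
    covs = list(covariates)
    return phenotypic_concordance(pairs, tab, "_gcount", family="linear",
                                  covariates=covs, seed=seed)


def polygenic_score(genotypes: pd.DataFrame, weights: pd.Series,
                    standardize: bool = True) -> pd.Series:
    """Weighted effect-allele dosage sum, optionally standardised in-sample."""
    w = weights.reindex(genotypes.columns).fillna(0.0)
    score = genotypes.fillna(genotypes.mean()) @ w
    if standardize:
        sd = score.std()
        if sd == 0 or not np.isfinite(sd):
            raise DataError("polygenic score has zero variance")
        score = (score - score.mean()) / sd
    score.name = "pgs"
    return score


def pgs_concordance(pairs: pd.DataFrame, genotypes: pd.DataFrame,
                    weights: pd.Series, seed: int = 0) -> AssocResult:
    """Regression of partner's standardised PGS on the reference's."""
    score = polygenic_score(genotypes, weights, standardize=True)
    tab = pd.DataFrame({"pgs": score})
    return phenotypic_concordance(pairs, tab, "pgs", seed=seed)


def relationship_length_proxy(pairs: pd.DataFrame, individuals: pd.DataFrame,
                              column: str, seed: int = 0) -> AssocResult:
    """Association of the absolute spousal difference with mean couple age.

    Mean couple age proxies relationship duration; the regression of
    |difference in ``column``| on mean age (adjusted for reference sex)
    returns the change in spousal difference per year.
    """
    frame = make_pair_frame(pairs, individuals, [column, "age", "sex"], seed=seed)
    diff = (frame[f"ref_{column}"] - frame[f"partner_{column}"]).abs()
    mean_age = 0.5 * (frame["ref_age"] + frame["partner_age"])
    sub = pd.DataFrame({
        "absdiff": diff, "exposure": mean_age,
        "male_ref": (frame["ref_sex"] == "M").astype(float),
    }).dropna()
    if sub["absdiff"].nunique() <= 1:
        return AssocResult(beta=0.0, se=np.nan, ci95=(np.nan, np.nan), p=np.nan,
                           n=len(sub), covariates=["ref:sex"],
                           method="relationship_length_proxy")
    X = sm.add_constant(sub[["exposure", "male_ref"]], has_constant="add")
    return _regress(sub["absdiff"], X, "linear", False, n=len(sub),
                    covariates=["ref:sex"], method="relationship_length_proxy")
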