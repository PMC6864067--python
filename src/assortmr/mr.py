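"""Cross-spouse Mendelian randomization.

The exposure stage regresses the reference individual's phenotype on their
genotype; the outcome stage regresses the *partner's* phenotype on the
reference genotype, each couple contributing two rows (both orientations).
Per-variant summary statistics feed the estimator suite:

* Wald ratio (single instrument), first-order delta-method SE;
* fixed-effects inverse-variance weighted (IVW) with Cochran's Q and I^2;
* MR-Egger regression (intercept = average directional pleiotropy);
* weighted median and weighted mode, SEs by seeded parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .concordance import AssocResult
from .errors import DataError


@dataclass
class MRInput:
    """Per-variant two-stage summary statistics (alleles harmonised)."""

    variant: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    effect_allele: str = ""

    def __post_init__(self):
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise DataError(f"standard errors must be positive for {self.variant}")


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    ci95: tuple
    p: float
    n_variants: int
    egger_intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_p: Optional[float] = None
    Q: Optional[float] = None
    Q_p: Optional[float] = None
    I2: Optional[float] = None

    @property
    def z(self) -> float:
        return self.beta / self.se if self.se and self.se > 0 else np.nan


def _as_arrays(inputs: Sequence[MRInput]):
    bx = np.array([i.beta_exposure for i in inputs], dtype=float)
    sx = np.array([i.se_exposure for i in inputs], dtype=float)
    by = np.array([i.beta_outcome for i in inputs], dtype=float)
    sy = np.array([i.se_outcome for i in inputs], dtype=float)
    return bx, sx, by, sy


def _normal_ci_p(beta, se):
    z = beta / se
    return ((beta - 1.96 * se, beta + 1.96 * se), float(2 * stats.norm.sf(abs(z))))


# ----------------------------------------------------------------------
# per-SNP association stages


def make_cross_spouse_frame(pairs: pd.DataFrame, individuals: pd.DataFrame,
                            columns: Sequence[str]) -> pd.DataFrame:
    """Two rows per couple: (A,B) and (B,A) as (reference, partner)."""
    frames = []
    for ref, par in (("id_a", "id_b"), ("id_b", "id_a")):
        d = {"ref_id": pairs[ref].to_numpy(), "partner_id": pairs[par].to_numpy()}
        for col in columns:
            d[f"ref_{col}"] = individuals.loc[pairs[ref], col].to_numpy()
            d[f"partner_{col}"] = individuals.loc[pairs[par], col].to_numpy()
        frames.append(pd.DataFrame(d))
    return pd.concat(frames, ignore_index=True)


def _residualize(y: np.ndarray, C: np.ndarray) -> tuple:
    """Residuals of y on covariate matrix C (with intercept) via lstsq."""
    coef, *_ = np.linalg.lstsq(C, y, rcond=None)
    return y - C @ coef


def snp_association(genotypes: pd.DataFrame, outcome: pd.Series,
                    covariates: pd.DataFrame | None = None,
                    model: str = "additive") -> pd.DataFrame:
    """Per-variant OLS of ``outcome`` on genotype with shared covariates.

    Uses Frisch-Waugh partialling: outcome and each dosage are residualised
    on the covariates once, then slope and SE come from the simple
    regression of residuals (df corrected for the covariate count).
    ``model='dominant'`` recodes dosages {0,1,2} -> {0,1,1}.
    """
    if model not in ("additive", "dominant"):
        raise DataError(f"model must be 'additive' or 'dominant', got {model!r}")
    y = outcome.to_numpy(dtype=float)
    G = genotypes.to_numpy(dtype=float)
    if model == "dominant":
        G = (G > 0).astype(float)
    keep = ~np.isnan(y)
    if covariates is not None and len(covariates):
        C = covariates.to_numpy(dtype=float)
        keep &= ~np.isnan(C).any(axis=1)
    rows = []
    for j, vid in enumerate(genotypes.columns):
        g = G[:, j]
        ok = keep & ~np.isnan(g)
        n = int(ok.sum())
        yj, gj = y[ok], g[ok]
        if covariates is not None and len(covariates):
            Cj = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)[ok]])
            if np.linalg.matrix_rank(Cj) < Cj.shape[1]:
                raise DataError("collinear covariates in snp_association")
            yr = _residualize(yj, Cj)
            gr = _residualize(gj, Cj)
            df = n - Cj.shape[1] - 1
        else:
            yr = yj - yj.mean()
            gr = gj - gj.mean()
            df = n - 2
        ssg = (gr**2).sum()
        if ssg == 0 or df <= 0:
            rows.append({"variant": vid, "beta": np.nan, "se": np.nan, "n": n})
            continue
        beta = (gr * yr).sum() / ssg
        resid = yr - beta * gr
        sigma2 = (resid**2).sum() / df
        rows.append({"variant": vid, "beta": beta,
                     "se": float(np.sqrt(sigma2 / ssg)), "n": n})
    return pd.DataFrame(rows).set_index("variant")


def compare_additive_dominant(genotype: pd.Series, outcome: pd.Series,
                              covariates: pd.DataFrame | None = None) -> dict:
    """Fit additive, dominant and saturated (2-df factor) genotype codings.

    Returns log-likelihoods/AICs, the F-test of any genotype effect, and a
    recommendation: the better-AIC coding, or ``"neither"`` when the
    saturated model finds no genotype-outcome association at the 5% level.
    """
    import statsmodels.api as sm

    y = outcome.to_numpy(dtype=float)
    g = genotype.to_numpy(dtype=float)
    ok = ~(np.isnan(y) | np.isnan(g))
    C = None
    if covariates is not None and len(covariates):
        C = covariates.to_numpy(dtype=float)
        ok &= ~np.isnan(C).any(axis=1)
        C = C[ok]
    y, g = y[ok], g[ok]

    def fit(Xg):
        parts = [np.ones((len(y), 1)), Xg]
        if C is not None:
            parts.append(C)
        X = np.column_stack(parts)
        return sm.OLS(y, X).fit()

    res_add = fit(g[:, None])
    res_dom = fit((g > 0).astype(float)[:, None])
    het = np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])
    res_sat = fit(het)
    res_null = fit(np.empty((len(y), 0)))

    lr_sat = 2 * (res_sat.llf - res_null.llf)
    p_any = float(stats.chi2.sf(lr_sat, 2))
    lr_add = 2 * (res_sat.llf - res_add.llf)
    lr_dom = 2 * (res_sat.llf - res_dom.llf)
    if p_any > 0.05:
        rec = "neither"
    else:
        rec = "additive" if res_add.aic <= res_dom.aic else "dominant"
    return {
        "aic_additive": float(res_add.aic),
        "aic_dominant": float(res_dom.aic),
        "aic_saturated": float(res_sat.aic),
        "p_any_association": p_any,
        "p_additive_vs_saturated": float(stats.chi2.sf(lr_add, 1)),
        "p_dominant_vs_saturated": float(stats.chi2.sf(lr_dom, 1)),
        "recommendation": rec,
    }


# ----------------------------------------------------------------------
# estimators


def wald_ratio(inp: MRInput, second_order: bool = False) -> MREstimate:
    """Single-instrument causal estimate: beta_outcome / beta_exposure.

    First-order delta SE ``se_outcome / |beta_exposure|`` by default; the
    second-order option adds the exposure-stage uncertainty term.
    """
    if inp.beta_exposure == 0:
        raise DataError("weak instrument: beta_exposure is zero, Wald ratio undefined")
    beta = inp.beta_outcome / inp.beta_exposure
    se = inp.se_outcome / abs(inp.beta_exposure)
    if second_order:
        se = np.sqrt(
            inp.se_outcome**2 / inp.beta_exposure**2
            + inp.beta_outcome**2 * inp.se_exposure**2 / inp.beta_exposure**4
        )
    ci, p = _normal_ci_p(beta, se)
    return MREstimate("wald", float(beta), float(se), ci, p, 1)


def _ratio_weights(inputs: Sequence[MRInput]):
    bx, sx, by, sy = _as_arrays(inputs)
    if (bx == 0).any():
        raise DataError("beta_exposure of zero: ratio undefined")
    ratios = by / bx
    se_ratio = sy / np.abs(bx)
    w = 1.0 / se_ratio**2  # == bx^2 / sy^2
    return ratios, se_ratio, w


def ivw_fixed(inputs: Sequence[MRInput]) -> MREstimate:
    """Fixed-effects inverse-variance-weighted estimate with heterogeneity.

    Equivalent to weighted regression of beta_outcome on beta_exposure
    through the origin with weights 1/se_outcome^2.  Cochran's Q uses k-1
    df; I^2 = max(0, (Q - (k-1)) / Q).
    """
    k = len(inputs)
    if k == 0:
        raise DataError("ivw_fixed requires at least one variant")
    ratios, _, w = _ratio_weights(inputs)
    beta = float((w * ratios).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    Q = float((w * (ratios - beta) ** 2).sum())
    Q_p = float(stats.chi2.sf(Q, k - 1)) if k > 1 else np.nan
    I2 = float(max(0.0, (Q - (k - 1)) / Q)) if Q > 0 else 0.0
    ci, p = _normal_ci_p(beta, se)
    return MREstimate("ivw", beta, se, ci, p, k, Q=Q, Q_p=Q_p, I2=I2)


def mr_egger(inputs: Sequence[MRInput]) -> MREstimate:
    """MR-Egger: weighted regression of beta_outcome on beta_exposure with
    an intercept (average directional pleiotropy).

    Exposure betas are first oriented positive.  SEs use the conventional
    multiplicative random-effects dispersion floored at 1, with t(k-2)
    p-values.
    """
    k = len(inputs)
    if k < 3:
        raise DataError(f"mr_egger requires at least 3 variants, got {k}")
    bx, sx, by, sy = _as_arrays(inputs)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    WX = X * w[:, None]
    XtWX = X.T @ WX
    coef = np.linalg.solve(XtWX, WX.T @ by)
    resid = by - X @ coef
    dispersion = float((w * resid**2).sum() / (k - 2))
    dispersion = max(dispersion, 1.0)
    cov = np.linalg.inv(XtWX) * dispersion
    inter, slope = coef
    se_inter, se_slope = np.sqrt(np.diag(cov))
    p_slope = float(2 * stats.t.sf(abs(slope / se_slope), k - 2))
    p_inter = float(2 * stats.t.sf(abs(inter / se_inter), k - 2))
    return MREstimate(
        "egger", float(slope), float(se_slope),
        (float(slope - 1.96 * se_slope), float(slope + 1.96 * se_slope)),
        p_slope, k,
        egger_intercept=float(inter), intercept_se=float(se_inter),
        intercept_p=p_inter,
    )


def _weighted_median(ratios: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    ww = w[order] / w.sum()
    cum = np.cumsum(ww) - ww / 2.0
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] < 0.5:
        return float(r[-1])
    j = int(np.searchsorted(cum, 0.5))
    lo, hi = cum[j - 1], cum[j]
    return float(r[j - 1] + (r[j] - r[j - 1]) * (0.5 - lo) / (hi - lo))


def weighted_median(inputs: Sequence[MRInput], n_boot: int = 5000,
                    seed: int = 0) -> MREstimate:
    """Weighted-median estimate; consistent when >=50% of weight is valid.

    Ratio estimates are ordered and the inverse-variance-weighted cumulative
    distribution interpolated at 0.5; the SE comes from a seeded parametric
    bootstrap resampling each ratio from N(ratio_i, se_i).
    """
    k = len(inputs)
    if k < 3:
        raise DataError(f"weighted_median requires at least 3 variants, got {k}")
    ratios, se_ratio, w = _ratio_weights(inputs)
    beta = _weighted_median(ratios, w)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 911]))
    draws = rng.normal(ratios, se_ratio, size=(n_boot, k))
    boot = np.array([_weighted_median(d, w) for d in draws])
    se = float(boot.std(ddof=1))
    ci, p = _normal_ci_p(beta, se)
    return MREstimate("wmedian", float(beta), se, ci, p, k)


def _silverman_bandwidth(x: np.ndarray, factor: float) -> float:
    """Modified Silverman rule-of-thumb on the ratio estimates."""
    k = len(x)
    s = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(s, iqr / 1.34) if iqr > 0 else s
    if spread == 0:
        return 0.0
    return float(factor * 0.9 * spread * k ** (-0.2))


def _kde_argmax(ratios: np.ndarray, w: np.ndarray, h: float,
                n_grid: int = 4001, refine: bool = True) -> float:
    """Global maximiser of the weighted normal-kernel density.

    Dense grid scan locates every local maximum; each is then polished to a
    root of the analytic density derivative (Brent bracketing), so near-tied
    modes resolve to the true global one at machine precision.
    """
    if h <= 0 or len(np.unique(ratios)) == 1:
        return float(ratios[np.argmax(w)])
    lo = ratios.min() - 3 * h
    hi = ratios.max() + 3 * h
    grid = np.linspace(lo, hi, n_grid)
    ww = w / w.sum()

    def density(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return np.exp(-0.5 * ((x[:, None] - ratios[None, :]) / h) ** 2) @ ww

    def ddensity(x):
        z = (x - ratios) / h
        return float((-z / h * np.exp(-0.5 * z**2) * ww).sum())

    dens = density(grid)
    interior = np.r_[False, (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:]), False]
    cand_idx = np.flatnonzero(interior)
    if len(cand_idx) == 0:
        cand_idx = np.array([int(np.argmax(dens))])
    best_x, best_d = float(grid[cand_idx[0]]), -np.inf
    for i in cand_idx:
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, n_grid - 1)]
        x_star = float(grid[i])
        if refine and ddensity(a) > 0 > ddensity(b):
            x_star = float(brentq(ddensity, a, b, xtol=1e-14))
        d = float(density(x_star)[0])
        if d > best_d:
            best_d, best_x = d, x_star
    return best_x


def weighted_mode(inputs: Sequence[MRInput], bandwidth_factor: float = 1.0,
                  n_boot: int = 5000, seed: int = 0) -> MREstimate:
    """Weighted-mode estimate: argmax of the inverse-variance-weighted
    normal-kernel density over the ratio estimates.

    Bandwidth is ``bandwidth_factor`` times the modified Silverman
    rule-of-thumb; the SE comes from a seeded parametric bootstrap.
    """
    k = len(inputs)
    if k < 3:
        raise DataError(f"weighted_mode requires at least 3 variants, got {k}")
    ratios, se_ratio, w = _ratio_weights(inputs)
    h = _silverman_bandwidth(ratios, bandwidth_factor)
    beta = _kde_argmax(ratios, w, h)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 913]))
    draws = rng.normal(ratios, se_ratio, size=(n_boot, k))
    boot = np.empty(n_boot)
    for b in range(n_boot):
        hb = _silverman_bandwidth(draws[b], bandwidth_factor)
        boot[b] = _kde_argmax(draws[b], w, hb, n_grid=801, refine=False)
    se = float(boot.std(ddof=1))
    ci, p = _normal_ci_p(beta, se)
    return MREstimate("wmode", float(beta), se, ci, p, k)


def z_difference(beta1: float, se1: float, beta2: float, se2: float) -> tuple:
    """Two-sided z-test for a difference between two independent estimates."""
    z = (beta1 - beta2) / np.sqrt(se1**2 + se2**2)
    return float(z), float(2 * stats.norm.sf(abs(z)))


# ----------------------------------------------------------------------
# cohort-level convenience


def cross_spouse_mr(pairs: pd.DataFrame, individuals: pd.DataFrame,
                    genotypes: pd.DataFrame, variant: str, outcome_col: str,
                    covariate_cols: Sequence[str] = ("sex", "age")) -> dict:
    """Two-stage cross-spouse MR for a single variant.

    Exposure stage: own ``outcome_col`` on own genotype; outcome stage:
    partner's ``outcome_col`` on own genotype; both on the two-row-per-couple
    layout with the given reference-side covariates.  Returns the stage
    summaries and the Wald estimate.
    """
    tab = individuals.assign(_g=genotypes[variant])
    cols = [outcome_col, "_g"] + [c for c in covariate_cols]
    frame = make_cross_spouse_frame(pairs, tab, cols)
    cov = pd.DataFrame(index=frame.index)
    for c in covariate_cols:
        s = frame[f"ref_{c}"]
        if s.dtype == object:
            cov = pd.concat([cov, pd.get_dummies(s, prefix=c, drop_first=True,
                                                 dtype=float)], axis=1)
        else:
            cov[c] = s.astype(float)
    g = frame[["ref__g"]].rename(columns={"ref__g": variant})
    exp_stage = snp_association(g, frame[f"ref_{outcome_col}"],
                                cov if len(cov.columns) else None)
    out_stage = snp_association(g, frame[f"partner_{outcome_col}"],
                                cov if len(cov.columns) else None)
    inp = MRInput(
        variant=variant,
        beta_exposure=float(exp_stage.loc[variant, "beta"]),
        se_exposure=float(exp_stage.loc[variant, "se"]),
        beta_outcome=float(out_stage.loc[variant, "beta"]),
        se_outcome=float(out_stage.loc[variant, "se"]),
    )
    return {
        "input": inp,
        "exposure_stage": AssocResult.from_beta_se(
            inp.beta_exposure, inp.se_exposure, n=int(exp_stage.loc[variant, "n"]),
            method="snp_exposure"),
        "outcome_stage": AssocResult.from_beta_se(
            inp.beta_outcome, inp.se_outcome, n=int(out_stage.loc[variant, "n"]),
            method="snp_outcome"),
        "wald": wald_ratio(inp),
    }
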