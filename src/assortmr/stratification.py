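"""Population-structure diagnostics and stratified sensitivity analyses.

Hardy-Weinberg testing, allele-frequency comparison between samples,
SNP-geography/PC associations, within-centre fixed-effects meta-analysis
with Cochran's Q, and the 100-km birth-distance stratification.  Pooling
subpopulations that differ in allele frequency produces the Wahlund
heterozygote deficit these diagnostics are designed to catch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import mr as mr_mod
from .concordance import AssocResult, genotypic_concordance
from .errors import DataError


@dataclass
class HWEResult:
    observed: tuple       # counts of effect-allele copies (0, 1, 2)
    expected: tuple
    chi2: float
    p: float
    maf: float
    monomorphic: bool = False

    @property
    def heterozygote_deficit(self) -> bool:
        return self.observed[1] < self.expected[1]


@dataclass
class MetaResult:
    strata: pd.DataFrame          # label, n, beta, se, ci_lo, ci_hi
    excluded: pd.DataFrame        # label, reason
    combined_beta: float
    combined_se: float
    combined_ci: tuple
    combined_p: float
    Q: float
    Q_p: float
    k_used: int
    n_total: int


def hwe_test(genotype_counts: Sequence[int]) -> HWEResult:
    """1-df chi-square HWE test from genotype counts (0, 1, 2 effect alleles).

    Expected counts come from the sample allele frequency.  A monomorphic
    sample returns chi2 = 0 by convention, flagged.
    """
    n0, n1, n2 = (int(c) for c in genotype_counts)
    if min(n0, n1, n2) < 0 or (n0 + n1 + n2) == 0:
        raise DataError("genotype counts must be non-negative with positive total")
    n = n0 + n1 + n2
    p = (2 * n2 + n1) / (2 * n)
    q = 1 - p
    expected = (q * q * n, 2 * p * q * n, p * p * n)
    maf = min(p, q)
    if p in (0.0, 1.0):
        return HWEResult((n0, n1, n2), expected, 0.0, 1.0, maf, monomorphic=True)
    chi2 = sum((o - e) ** 2 / e for o, e in zip((n0, n1, n2), expected))
    return HWEResult((n0, n1, n2), expected, float(chi2),
                     float(stats.chi2.sf(chi2, 1)), float(maf))


def genotype_counts(dosages) -> tuple:
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    return (int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))


def allele_freq_diff(counts_sample1: Sequence[int],
                     counts_sample2: Sequence[int]) -> tuple:
    """2x2 allele-count chi-square between two samples; returns (chi2, p)."""
    def alleles(c):
        n0, n1, n2 = c
        return (2 * n2 + n1, 2 * n0 + n1)  # (effect, other)
    t = np.array([alleles(counts_sample1), alleles(counts_sample2)], dtype=float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DataError("allele table has a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def compute_pcs(genotypes: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k genetic principal components of the centred, scaled dosage matrix.

    Stand-in for cohort-supplied PCs; truncated SVD, scores standardised.
    """
    G = genotypes.to_numpy(dtype=float)
    G = np.where(np.isnan(G), np.nanmean(G, axis=0), G)
    sd = G.std(axis=0)
    keep = sd > 0
    Z = (G[:, keep] - G[:, keep].mean(axis=0)) / sd[keep]
    k = min(k, Z.shape[1], Z.shape[0] - 1)
    if Z.shape[1] > 300:
        from scipy.sparse.linalg import svds
        U, S, _ = svds(Z, k=k)
        order = np.argsort(S)[::-1]
        U, S = U[:, order], S[order]
    else:
        U, S, _ = np.linalg.svd(Z, full_matrices=False)
        U, S = U[:, :k], S[:k]
    scores = U * S
    scores = (scores - scores.mean(axis=0)) / scores.std(axis=0)
    return pd.DataFrame(scores, index=genotypes.index,
                        columns=[f"PC{i + 1}" for i in range(k)])


def snp_geo_assoc(genotype: pd.Series, coords: pd.DataFrame,
                  pcs: pd.DataFrame | None = None) -> dict:
    """Association of birth coordinates (and PCs) with effect-allele count.

    Each axis is regressed on the allele count; the betas read as "km
    farther north/east per additional effect allele".
    """
    out = {}
    targets = [coords[c] for c in coords.columns]
    if pcs is not None:
        targets += [pcs[c] for c in pcs.columns]
    g = genotype.astype(float)
    for t in targets:
        sub = pd.DataFrame({"y": t, "g": g}).dropna()
        if sub["g"].nunique() <= 1 or sub["y"].nunique() <= 1:
            out[t.name] = AssocResult(0.0, np.nan, (np.nan, np.nan), np.nan,
                                      len(sub), method="snp_geo")
            continue
        gc = sub["g"] - sub["g"].mean()
        beta = float((gc * sub["y"]).sum() / (gc**2).sum())
        resid = sub["y"] - sub["y"].mean() - beta * gc
        se = float(np.sqrt((resid**2).sum() / (len(sub) - 2) / (gc**2).sum()))
        out[t.name] = AssocResult.from_beta_se(beta, se, n=len(sub), method="snp_geo")
    return out


# ----------------------------------------------------------------------
# fixed-effects meta-analysis


def meta_fixed(betas, ses) -> dict:
    """Inverse-variance fixed-effects combination with Cochran's Q."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if len(b) == 0:
        raise DataError("no strata to combine")
    w = 1.0 / s**2
    beta = float((w * b).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    Q = float((w * (b - beta) ** 2).sum())
    k = len(b)
    Q_p = float(stats.chi2.sf(Q, k - 1)) if k > 1 else np.nan
    z = beta / se
    return {
        "beta": beta, "se": se,
        "ci": (beta - 1.96 * se, beta + 1.96 * se),
        "p": float(2 * stats.norm.sf(abs(z))),
        "Q": Q, "Q_p": Q_p, "k": k,
    }


def meta_from_table(table: pd.DataFrame) -> MetaResult:
    """Meta-analysis from a pre-made stratum table (label, n, beta, ci_lo, ci_hi).

    Stratum SEs use the symmetric-width convention SE = (ci_hi - ci_lo) / (2 x 1.96).
    Strata with missing estimates are excluded with reason ``no_estimate``.
    """
    t = table.copy()
    required = {"label", "n", "beta", "ci_lo", "ci_hi"}
    if not required.issubset(t.columns):
        raise DataError(f"stratum table needs columns {sorted(required)}")
    bad = t["beta"].isna() | t["ci_lo"].isna() | t["ci_hi"].isna()
    excluded = pd.DataFrame({"label": t.loc[bad, "label"], "reason": "no_estimate"})
    t = t[~bad].copy()
    t["se"] = (t["ci_hi"] - t["ci_lo"]) / (2 * 1.96)
    res = meta_fixed(t["beta"], t["se"])
    return MetaResult(
        strata=t[["label", "n", "beta", "se", "ci_lo", "ci_hi"]].reset_index(drop=True),
        excluded=excluded.reset_index(drop=True),
        combined_beta=res["beta"], combined_se=res["se"], combined_ci=res["ci"],
        combined_p=res["p"], Q=res["Q"], Q_p=res["Q_p"], k_used=res["k"],
        n_total=int(t["n"].sum()),
    )


def within_centre_meta(pairs: pd.DataFrame, genotypes: pd.DataFrame,
                       variant: str, individuals: pd.DataFrame,
                       min_pairs: int = 50, seed: int = 0) -> MetaResult:
    """Per-recruitment-centre genotypic concordance, combined by fixed effects.

    Strata with fewer than ``min_pairs`` couples, or whose regression fails
    (e.g. a centre-monomorphic variant), are excluded with a reason —
    the operational analogue of small-centre convergence failure.
    """
    centre = individuals.loc[pairs["id_a"], "centre"].to_numpy()
    rows, dropped = [], []
    for label in pd.unique(centre):
        sub = pairs[centre == label]
        if len(sub) < min_pairs:
            dropped.append({"label": label, "reason": "too_few_pairs"})
            continue
        try:
            r = genotypic_concordance(sub.reset_index(drop=True), genotypes,
                                      variant, seed=seed)
        except DataError:
            dropped.append({"label": label, "reason": "regression_failed"})
            continue
        rows.append({"label": label, "n": len(sub), "beta": r.beta, "se": r.se,
                     "ci_lo": r.ci95[0], "ci_hi": r.ci95[1]})
    if not rows:
        raise DataError("all strata excluded from meta-analysis")
    strata = pd.DataFrame(rows)
    res = meta_fixed(strata["beta"], strata["se"])
    return MetaResult(
        strata=strata, excluded=pd.DataFrame(dropped, columns=["label", "reason"]),
        combined_beta=res["beta"], combined_se=res["se"], combined_ci=res["ci"],
        combined_p=res["p"], Q=res["Q"], Q_p=res["Q_p"], k_used=res["k"],
        n_total=int(strata["n"].sum()),
    )


# ----------------------------------------------------------------------
# birth-distance stratification


def birth_distance_km(pairs: pd.DataFrame, individuals: pd.DataFrame) -> pd.Series:
    """Euclidean km distance between the members' birth coordinates."""
    a = individuals.loc[pairs["id_a"], ["birth_north_km", "birth_east_km"]].to_numpy(float)
    b = individuals.loc[pairs["id_b"], ["birth_north_km", "birth_east_km"]].to_numpy(float)
    return pd.Series(np.sqrt(((a - b) ** 2).sum(axis=1)), index=pairs.index,
                     name="birth_distance_km")


def distance_stratify(pairs: pd.DataFrame, individuals: pd.DataFrame,
                      genotypes: pd.DataFrame, variant: str,
                      outcome_col: str = "weekly_units",
                      threshold_km: float = 100.0, seed: int = 0) -> dict:
    """Genotypic concordance and Wald MR within vs beyond a birth-distance cut.

    Pairs at exactly the threshold fall in the "within" stratum.  Pairs with
    missing birth coordinates are counted separately and analysed in neither
    stratum.
    """
    dist = birth_distance_km(pairs, individuals)
    missing = dist.isna()
    within = pairs[(dist <= threshold_km) & ~missing].reset_index(drop=True)
    beyond = pairs[(dist > threshold_km) & ~missing].reset_index(drop=True)
    out = {"n_missing_coords": int(missing.sum()),
           "n_within": len(within), "n_beyond": len(beyond)}
    for name, sub in (("within", within), ("beyond", beyond)):
        if len(sub) < 3:
            out[name] = None
            continue
        conc = genotypic_concordance(sub, genotypes, variant, seed=seed)
        mr_res = mr_mod.cross_spouse_mr(sub, individuals, genotypes, variant,
                                        outcome_col)
        out[name] = {"genotypic": conc, "mr_wald": mr_res["wald"],
                     "mr_input": mr_res["input"]}
    if out.get("within") and out.get("beyond"):
        for key in ("genotypic", "mr_wald"):
            a, b = out["within"][key], out["beyond"][key]
            z, p = mr_mod.z_difference(a.beta, a.se, b.beta, b.se)
            out[f"z_diff_{key}"] = {"z": z, "p": p}
    return out
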