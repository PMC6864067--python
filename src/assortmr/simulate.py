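"""Couple-cohort simulator for the four spousal-concordance mechanisms.

The generator produces a cohort of genotyped individuals with UK-Biobank-like
questionnaire fields and a truth table of couples formed under one of (or a
sequential mixture of) four mechanisms:

* **assortative** — mate choice on the phenotype itself: noisy-rank pairing on
  the standardised latent phenotype, with the noise variance calibrated by
  bisection so that the spousal correlation of the pairing basis hits
  ``assort_C``;
* **homogamy** — mate choice on a genotype-independent confounder (or, with
  ``homogamy_basis='geography'``, on birth location along the allele-frequency
  cline axis), never on the phenotype;
* **interaction** — random pairing followed by within-couple convergence of
  the observed phenotype, at rate ``kappa`` per year of relationship;
* **dissolution** — random pairing followed by logistic break-up with odds
  increasing in the absolute within-couple phenotype difference.

Genotypes are drawn in Hardy-Weinberg proportions at each individual's *local*
focal-allele frequency, which follows a logistic cline over a planar km grid;
pooling regions therefore produces a Wahlund heterozygote deficit while each
neighbourhood is in HWE.

Randomness: a single master seed spawns named child streams in a fixed,
documented order (see ``_STREAMS``); identical configs give identical cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import SimulationConfig
from .errors import ConfigError

log = logging.getLogger(__name__)

# Child-stream spawn order off the master SeedSequence.  Appending is allowed;
# reordering would silently change every cohort.
_STREAMS = (
    "geography",
    "focal_genotypes",
    "pgs_genotypes",
    "pgs_weights",
    "confounder",
    "residual",
    "pairing",
    "duration",
    "interaction",
    "dissolution",
    "household",
    "beverages",
    "covariates",
)

ACCOMMODATION_TYPES = ("house", "flat", "bungalow")
RENTAL_STATUS = ("own", "mortgage", "rent")
FREQUENCY_CATEGORIES = (
    "daily",
    "3-4 per week",
    "1-2 per week",
    "1-3 per month",
    "special occasions",
    "never",
)
#: Categories for which weekly intake questions are not asked; weekly units are 0.
SUBWEEKLY_CATEGORIES = ("1-3 per month", "special occasions", "never")

BEVERAGE_COLUMNS = (
    "spirits_measures",
    "red_wine_glasses",
    "white_wine_glasses",
    "champagne_glasses",
    "fortified_wine_glasses",
    "beer_pints",
    "cider_pints",
)

#: The household fields used for spouse-pair matching (plus the cohabiting
#: flag and genotype availability, which gate eligibility).
HOUSEHOLD_MATCH_FIELDS = (
    "years_at_address",
    "n_occupants",
    "n_vehicles",
    "accommodation",
    "rental",
    "home_north_km",
    "home_east_km",
    "centre",
)


@dataclass
class Cohort:
    """A simulated cohort: individuals, genotypes, variant metadata, truth.

    ``individuals`` is indexed by individual id.  ``genotypes`` holds
    effect-allele counts (float, NaN for missing) with the same index and one
    column per variant.  ``truth`` holds one row per true couple or decoy
    pair; trio decoys are flagged per-individual in
    ``individuals['decoy_class']``.
    """

    individuals: pd.DataFrame
    genotypes: pd.DataFrame
    variants: pd.DataFrame
    truth: pd.DataFrame
    config: Optional[SimulationConfig] = None
    log_messages: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.individuals)

    def couple_frame(self, retained_only: bool = True) -> pd.DataFrame:
        """True (non-decoy) couples, optionally only those not dissolved."""
        t = self.truth[self.truth["decoy_class"] == "none"]
        if retained_only:
            t = t[~t["dissolved"]]
        return t.reset_index(drop=True)


def _spawn_streams(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


# ----------------------------------------------------------------------
# pairing


def _noisy_rank_pair(basis_m, basis_f, noise_sd, rng_draws_m, rng_draws_f, sign=1):
    """Pair males and females by rank of basis + noise; returns index arrays."""
    order_m = np.argsort(basis_m + noise_sd * rng_draws_m, kind="stable")
    score_f = basis_f + noise_sd * rng_draws_f
    order_f = np.argsort(sign * score_f, kind="stable")
    return order_m, order_f


def calibrate_pairing(basis_m, basis_f, target_C, rng, max_iter=60, tol=1e-4):
    """Bisection on the matching-noise SD so the paired-basis correlation hits target_C.

    The same standard-normal noise draws are reused across bisection steps and
    for the final pairing, which makes the achieved correlation continuous and
    monotone in the noise SD and puts the final cohort essentially on target.
    Returns (order_m, order_f, achieved_corr, noise_sd).
    """
    n = len(basis_m)
    sign = 1 if target_C >= 0 else -1
    target = abs(target_C)
    draws_m = rng.standard_normal(n)
    draws_f = rng.standard_normal(n)

    def achieved(sd):
        om, of = _noisy_rank_pair(basis_m, basis_f, sd, draws_m, draws_f, sign)
        c = np.corrcoef(basis_m[om], basis_f[of])[0, 1]
        return sign * c, (om, of)

    c0, pair0 = achieved(0.0)
    if target >= abs(c0) - 1e-12:
        if target > abs(c0) + 0.01:
            log.warning(
                "assort_C=%.3f unreachable at n=%d (max achievable %.3f); using exact rank pairing",
                target_C, n, c0,
            )
        om, of = pair0
        return om, of, sign * c0, 0.0

    lo, hi = 0.0, 1.0
    c_hi, _ = achieved(hi)
    while abs(c_hi) > target and hi < 1e6:
        hi *= 4.0
        c_hi, _ = achieved(hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        c_mid, pair_mid = achieved(mid)
        if abs(abs(c_mid) - target) < tol:
            lo = hi = mid
            break
        if abs(c_mid) > target:
            lo = mid
        else:
            hi = mid
    sd = 0.5 * (lo + hi)
    c_final, (om, of) = achieved(sd)
    return om, of, c_final, sd


# ----------------------------------------------------------------------
# questionnaire plumbing


def _decompose_beverages(units, rng):
    """Split weekly units into integer beverage counts consistent with the
    unit conversion (1 per spirit measure, 2 per wine glass, 2.5 per pint).

    Rounding is absorbed into the spirits term so the recomposed total is
    within 0.5 units of the input.  Returns (DataFrame of counts, recomposed
    weekly units).
    """
    n = len(units)
    out = pd.DataFrame(0, index=np.arange(n), columns=list(BEVERAGE_COLUMNS), dtype=int)
    pos = units > 0
    npos = int(pos.sum())
    if npos:
        u = units[pos]
        shares = rng.dirichlet([2.0, 2.0, 1.0], size=npos)  # beer, wine, spirits
        beer_total = np.floor(u * shares[:, 0] / 2.5).astype(int)
        wine_total = np.floor(u * shares[:, 1] / 2.0).astype(int)
        spirits = np.rint(u - 2.5 * beer_total - 2.0 * wine_total).astype(int)
        spirits = np.maximum(spirits, 0)
        cider = rng.binomial(beer_total, 0.2)
        wine_split = rng.multinomial(1, [0.4, 0.4, 0.1, 0.1], size=npos)
        # distribute wine glasses across the four wine types by a single draw
        # of dominant type plus remainder to red; keeps counts integral
        red = np.zeros(npos, int); white = np.zeros(npos, int)
        champ = np.zeros(npos, int); fort = np.zeros(npos, int)
        dominant = wine_split.argmax(axis=1)
        half = wine_total // 2
        rest = wine_total - half
        for k, arr in enumerate((red, white, champ, fort)):
            sel = dominant == k
            arr[sel] += half[sel]
        red += rest  # remainder always to red wine
        idx = np.flatnonzero(pos)
        out.loc[idx, "beer_pints"] = beer_total - cider
        out.loc[idx, "cider_pints"] = cider
        out.loc[idx, "spirits_measures"] = spirits
        out.loc[idx, "red_wine_glasses"] = red
        out.loc[idx, "white_wine_glasses"] = white
        out.loc[idx, "champagne_glasses"] = champ
        out.loc[idx, "fortified_wine_glasses"] = fort
    recomposed = (
        out["spirits_measures"]
        + 2.0 * (out[["red_wine_glasses", "white_wine_glasses",
                      "champagne_glasses", "fortified_wine_glasses"]].sum(axis=1))
        + 2.5 * (out["beer_pints"] + out["cider_pints"])
    ).to_numpy()
    return out, recomposed


def _assign_frequency(units, rng):
    """Frequency category and drinker status consistent with weekly units."""
    n = len(units)
    freq = np.empty(n, dtype=object)
    status = np.empty(n, dtype=object)
    pos = units > 0
    freq[pos & (units >= 30)] = "daily"
    freq[pos & (units >= 14) & (units < 30)] = "3-4 per week"
    freq[pos & (units < 14)] = "1-2 per week"
    status[pos] = "current"
    nz = int((~pos).sum())
    if nz:
        zcat = rng.choice(SUBWEEKLY_CATEGORIES, size=nz, p=[0.25, 0.35, 0.40])
        freq[~pos] = zcat
        st = np.where(
            zcat == "never",
            rng.choice(["never", "previous"], size=nz, p=[0.7, 0.3]),
            "current",
        )
        status[~pos] = st
    return freq, status


def _correlated_block(base_alleles, r2, n, rng, p):
    """One SNP correlated with the base SNP at allele-level corr sqrt(r2)."""
    q = np.sqrt(r2)
    keep = rng.random((n, 2)) < q
    fresh = rng.random((n, 2)) < p
    alleles = np.where(keep, base_alleles, fresh)
    return alleles.sum(axis=1)


# ----------------------------------------------------------------------
# main entry point


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a cohort of individuals paired into couples per the config.

    See the module docstring for the generative model.  The phenotype scale
    is weekly alcohol units; the latent (pre-censoring) phenotype is
    ``mean + beta_focal*(G-EG) + PGS + U + e`` with variance components
    matching ``h2_pgs`` and ``var_confounder`` empirically in-sample, and the
    observed phenotype is left-censored at zero (unless disabled) and then
    decomposed into integer beverage counts whose recomposition defines the
    analysed ``weekly_units`` exactly.
    """
    cfg = config.validate()
    rngs = _spawn_streams(cfg.seed)
    messages: list = []

    n = cfg.n_individuals
    n_c = n // 2
    ids = np.array([f"ID{i:06d}" for i in range(n)])
    sex = np.array(["M"] * n_c + ["F"] * (n - n_c))
    males = np.arange(n_c)
    females = np.arange(n_c, 2 * n_c)  # any odd leftover individual stays single

    # --- geography -----------------------------------------------------
    g_geo = rngs["geography"]
    gn, ge = cfg.grid_km
    centre_names = np.array([f"C{i + 1:02d}" for i in range(cfg.n_centres)])
    centre_loc = np.column_stack([
        g_geo.uniform(0.1 * gn, 0.9 * gn, cfg.n_centres),
        g_geo.uniform(0.1 * ge, 0.9 * ge, cfg.n_centres),
    ])
    centre_idx = g_geo.integers(cfg.n_centres, size=n)
    birth = centre_loc[centre_idx] + g_geo.normal(0.0, cfg.migration_sd_km, (n, 2))
    birth[:, 0] = np.clip(birth[:, 0], 0, gn)
    birth[:, 1] = np.clip(birth[:, 1], 0, ge)

    # --- focal genotype on the cline ----------------------------------
    grad_n, grad_e = cfg.cline_gradients
    local_logit = (
        logit(cfg.maf_focal)
        + grad_n * (birth[:, 0] - gn / 2.0)
        + grad_e * (birth[:, 1] - ge / 2.0)
    )
    local_maf = np.clip(expit(local_logit), 1e-4, 0.5)
    minor_count = rngs["focal_genotypes"].binomial(2, local_maf)
    g_focal = 2 - minor_count  # effect allele = major allele

    # --- polygenic background -----------------------------------------
    g_pgs = rngs["pgs_genotypes"]
    m = cfg.n_pgs_snps
    pgs_freq = g_pgs.uniform(0.05, 0.5, m) if m else np.empty(0)
    pgs_geno = g_pgs.binomial(2, pgs_freq, size=(n, m)) if m else np.empty((n, 0))

    block_cols = []
    if cfg.n_ld_block_snps > 0:
        # correlated marker block within one pruning window, tagged to the
        # first background SNP
        if m == 0:
            raise ConfigError("n_ld_block_snps > 0 requires n_pgs_snps >= 1")
        base_alleles = np.column_stack([
            g_pgs.random(n) < pgs_freq[0], g_pgs.random(n) < pgs_freq[0],
        ])
        # regenerate SNP 0 from explicit alleles so the block shares haplotypes
        pgs_geno[:, 0] = base_alleles.sum(axis=1)
        for _ in range(cfg.n_ld_block_snps):
            block_cols.append(
                _correlated_block(base_alleles, cfg.ld_block_r2, n, g_pgs, pgs_freq[0])
            )
    block = np.column_stack(block_cols) if block_cols else np.empty((n, 0))

    sigma2 = cfg.sd_weekly_units**2
    if m:
        w_raw = rngs["pgs_weights"].normal(0.0, 1.0, m)
        pgs_raw = (pgs_geno - 2 * pgs_freq) @ w_raw
        sd_raw = pgs_raw.std()
        scale = np.sqrt(cfg.h2_pgs * sigma2) / sd_raw if sd_raw > 0 else 0.0
        weights = w_raw * scale
        pgs_component = pgs_raw * scale
    else:
        weights = np.empty(0)
        pgs_component = np.zeros(n)

    focal_component = cfg.beta_focal * (g_focal - g_focal.mean())
    var_focal = focal_component.var()
    var_resid = sigma2 * (1.0 - cfg.h2_pgs - cfg.var_confounder) - var_focal
    if var_resid <= 0:
        raise ConfigError(
            "impossible variance budget: focal variant explains "
            f"{var_focal / sigma2:.3f} of variance on top of h2_pgs + var_confounder = "
            f"{cfg.h2_pgs + cfg.var_confounder:.3f}"
        )
    confounder = rngs["confounder"].normal(0.0, np.sqrt(cfg.var_confounder * sigma2), n)
    resid = rngs["residual"].normal(0.0, np.sqrt(var_resid), n)
    latent = cfg.mean_weekly_units + focal_component + pgs_component + confounder + resid

    # --- couple formation ---------------------------------------------
    weights_mech = cfg.mechanism_weights()
    g_pair = rngs["pairing"]
    w_a = weights_mech.get("assortative", 0.0)
    w_h = weights_mech.get("homogamy", 0.0)
    achieved_C = 0.0
    if w_a > 0 or w_h > 0:
        def z(x):
            return (x - x.mean()) / x.std()

        if w_h > 0:
            if cfg.homogamy_basis == "geography":
                homog = grad_n * birth[:, 0] + grad_e * birth[:, 1]
            else:
                homog = confounder
            basis = w_a * z(latent) + w_h * z(homog)
        else:
            basis = z(latent)
        order_m, order_f, achieved_C, _ = calibrate_pairing(
            basis[males], basis[females], cfg.assort_C, g_pair
        )
        messages.append(f"pairing calibrated: achieved basis correlation {achieved_C:.4f}")
    else:
        order_m = g_pair.permutation(n_c)
        order_f = g_pair.permutation(n_c)
    id_a = males[order_m]
    id_b = females[order_f]

    # --- relationship duration and ages --------------------------------
    g_dur = rngs["duration"]
    duration = g_dur.uniform(0.0, cfg.max_duration_years, n_c)
    mean_age = 44.0 + 0.5 * duration + g_dur.normal(0.0, 3.0, n_c)
    age_gap = g_dur.normal(0.0, 3.0, n_c)
    age = np.empty(n)
    age[id_a] = mean_age + age_gap / 2.0
    age[id_b] = mean_age - age_gap / 2.0
    if n > 2 * n_c:
        age[2 * n_c:] = g_dur.uniform(40.0, 69.0, n - 2 * n_c)
    age = np.clip(age, 39.0, 72.0)

    # --- partner interaction -------------------------------------------
    latent_obs = latent.copy()
    w_i = weights_mech.get("interaction", 0.0)
    if w_i > 0 and cfg.interaction_rate_kappa > 0:
        w = np.minimum(1.0, w_i * cfg.interaction_rate_kappa * duration)
        mean_couple = 0.5 * (latent[id_a] + latent[id_b])
        latent_obs[id_a] = (1 - w) * latent[id_a] + w * mean_couple
        latent_obs[id_b] = (1 - w) * latent[id_b] + w * mean_couple

    def censor(x):
        return np.maximum(x, 0.0) if cfg.censor_at_zero else x

    pheno_formation = censor(latent)
    pheno_observed = censor(latent_obs)

    # --- relationship dissolution --------------------------------------
    w_d = weights_mech.get("dissolution", 0.0)
    dissolved = np.zeros(n_c, dtype=bool)
    if w_d > 0 and cfg.dissolution_lambda > 0:
        diff = np.abs(pheno_observed[id_a] - pheno_observed[id_b])
        p_diss = expit(cfg.dissolution_alpha + w_d * cfg.dissolution_lambda * diff)
        dissolved = rngs["dissolution"].random(n_c) < p_diss
        messages.append(f"dissolution removed {int(dissolved.sum())} of {n_c} couples")

    # --- household fields ----------------------------------------------
    g_hh = rngs["household"]
    home = 0.5 * (birth[id_a] + birth[id_b]) + g_hh.normal(0.0, 20.0, (n_c, 2))
    home[:, 0] = np.clip(home[:, 0], 0, gn)
    home[:, 1] = np.clip(home[:, 1], 0, ge)
    couple_centre = np.argmin(
        ((home[:, None, :] - centre_loc[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    years_at_address = np.maximum(0, np.rint(duration - g_hh.uniform(0, 5, n_c))).astype(int)
    n_occupants = 2 + g_hh.poisson(0.8, n_c)
    n_vehicles = g_hh.integers(0, 4, n_c)
    accommodation = g_hh.choice(ACCOMMODATION_TYPES, size=n_c, p=[0.7, 0.2, 0.1])
    rental = g_hh.choice(RENTAL_STATUS, size=n_c, p=[0.5, 0.3, 0.2])

    cols: dict = {}
    cols["sex"] = sex
    cols["age"] = age
    cols["birth_north_km"] = birth[:, 0]
    cols["birth_east_km"] = birth[:, 1]
    centre = centre_names[centre_idx].copy()
    spouse_cohab = np.zeros(n, dtype=int)
    hh = {f: np.empty(n, dtype=object) for f in
          ("accommodation", "rental")}
    hh_num = {f: np.full(n, -1, dtype=int) for f in
              ("years_at_address", "n_occupants", "n_vehicles", "home_north_km", "home_east_km")}
    for arr, vals in (
        (hh_num["years_at_address"], years_at_address),
        (hh_num["n_occupants"], n_occupants),
        (hh_num["n_vehicles"], n_vehicles),
        (hh_num["home_north_km"], np.rint(home[:, 0]).astype(int)),
        (hh_num["home_east_km"], np.rint(home[:, 1]).astype(int)),
    ):
        arr[id_a] = vals
        arr[id_b] = vals
    for arr, vals in ((hh["accommodation"], accommodation), (hh["rental"], rental)):
        arr[id_a] = vals
        arr[id_b] = vals
    centre[id_a] = centre_names[couple_centre]
    centre[id_b] = centre_names[couple_centre]
    spouse_cohab[id_a] = 1
    spouse_cohab[id_b] = 1
    # dissolved couples no longer cohabit; give them fresh single households
    if dissolved.any():
        for member in (id_a[dissolved], id_b[dissolved]):
            spouse_cohab[member] = 0
            k = len(member)
            hh_num["years_at_address"][member] = g_hh.integers(0, 10, k)
            hh_num["n_occupants"][member] = 1
            hh_num["home_north_km"][member] = np.rint(
                g_hh.uniform(0, gn, k)).astype(int)
            hh_num["home_east_km"][member] = np.rint(
                g_hh.uniform(0, ge, k)).astype(int)
    singles = np.setdiff1d(np.arange(n), np.concatenate([id_a, id_b]))
    if len(singles):
        hh_num["years_at_address"][singles] = g_hh.integers(0, 10, len(singles))
        hh_num["n_occupants"][singles] = 1
        hh_num["n_vehicles"][singles] = g_hh.integers(0, 3, len(singles))
        hh["accommodation"][singles] = g_hh.choice(ACCOMMODATION_TYPES, size=len(singles))
        hh["rental"][singles] = g_hh.choice(RENTAL_STATUS, size=len(singles))
        hh_num["home_north_km"][singles] = np.rint(birth[singles, 0]).astype(int)
        hh_num["home_east_km"][singles] = np.rint(birth[singles, 1]).astype(int)
    # any remaining unset object fields (dissolved couples keep accommodation etc.)
    for f in ("accommodation", "rental"):
        unset = pd.isna(hh[f])
        if unset.any():
            hh[f][unset] = g_hh.choice(ACCOMMODATION_TYPES if f == "accommodation"
                                       else RENTAL_STATUS, size=int(unset.sum()))

    cols["centre"] = centre
    cols["spouse_cohab"] = spouse_cohab
    cols.update(hh_num)
    cols.update(hh)

    # --- questionnaire phenotypes --------------------------------------
    bev, weekly_units = _decompose_beverages(pheno_observed, rngs["beverages"])
    freq_cat, drinker_status = _assign_frequency(weekly_units, rngs["beverages"])
    cols["latent_pheno"] = latent
    cols["pheno_formation"] = pheno_formation
    cols["weekly_units"] = weekly_units
    cols["frequency_category"] = freq_cat
    cols["drinker_status"] = drinker_status
    for c in BEVERAGE_COLUMNS:
        cols[c] = bev[c].to_numpy()

    # --- covariate fields ----------------------------------------------
    g_cov = rngs["covariates"]
    height = np.where(sex == "M", g_cov.normal(175.3, 6.8, n), g_cov.normal(162.0, 6.2, n))
    cols["height_cm"] = height
    cols["age_completed_education"] = g_cov.choice(
        [13, 14, 15, 16, 17, 18], size=n, p=[0.03, 0.07, 0.20, 0.35, 0.15, 0.20])
    cols["has_degree"] = g_cov.random(n) < 0.3
    cols["country_of_birth"] = g_cov.choice(
        ["England", "Scotland", "Wales", "Other"], size=n, p=[0.77, 0.10, 0.06, 0.07])
    father_missing = g_cov.random(n) < 0.3
    mother_missing = g_cov.random(n) < 0.3
    father_age = g_cov.integers(45, 96, n).astype(float)
    mother_age = g_cov.integers(45, 96, n).astype(float)
    father_age[father_missing] = np.nan
    mother_age[mother_missing] = np.nan
    cols["father_death_age"] = father_age
    cols["mother_death_age"] = mother_age
    cols["decoy_class"] = np.array(["none"] * n, dtype=object)

    individuals = pd.DataFrame(cols, index=pd.Index(ids, name="id"))

    # --- genotype table and variant metadata ---------------------------
    variant_ids = ["rs_focal"] + [f"snp{j:04d}" for j in range(m)] + [
        f"ld{j:02d}" for j in range(cfg.n_ld_block_snps)]
    geno = np.column_stack([g_focal[:, None], pgs_geno, block]).astype(float)
    genotypes = pd.DataFrame(geno, index=individuals.index, columns=variant_ids)
    # positions: focal on chr4; background SNPs spaced 1 Mb on chr2 (outside
    # any pruning window); LD-block SNPs packed within 50 kb of snp0000
    chrom = ["4"] + ["2"] * m + ["2"] * cfg.n_ld_block_snps
    pos = [100_239_319] + [1_000_000 * (j + 1) for j in range(m)] + [
        1_000_000 + 5_000 * (j + 1) for j in range(cfg.n_ld_block_snps)]
    freq = np.concatenate([[1 - cfg.maf_focal], pgs_freq,
                           np.repeat(pgs_freq[0] if m else 0.0, cfg.n_ld_block_snps)])
    wcol = np.concatenate([[cfg.beta_focal], weights, np.zeros(cfg.n_ld_block_snps)])
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "effect_allele": "G",
            "freq": freq,
            "weight": wcol,
        },
        index=pd.Index(variant_ids, name="variant"),
    )

    mech_label = cfg.mechanism if isinstance(cfg.mechanism, str) else "mixture"
    truth = pd.DataFrame(
        {
            "couple_id": [f"CP{k:06d}" for k in range(n_c)],
            "id_a": ids[id_a],
            "id_b": ids[id_b],
            "mechanism": mech_label,
            "duration": duration,
            "dissolved": dissolved,
            "decoy_class": "none",
        }
    )

    return Cohort(
        individuals=individuals,
        genotypes=genotypes,
        variants=variants,
        truth=truth,
        config=cfg,
        log_messages=messages,
    )


# ----------------------------------------------------------------------
# decoys


def _mendelian_sibs(freqs, rng):
    """Genotypes for a sib pair at independent loci (expected relatedness 0.5)."""
    m = len(freqs)
    father = rng.random((m, 2)) < freqs[:, None]
    mother = rng.random((m, 2)) < freqs[:, None]
    def child():
        pick_f = rng.integers(0, 2, m)
        pick_m = rng.integers(0, 2, m)
        return (father[np.arange(m), pick_f].astype(int)
                + mother[np.arange(m), pick_m].astype(int))
    return child(), child()


def inject_decoys(
    cohort: Cohort,
    n_same_sex: int = 0,
    n_sib_pairs: int = 0,
    n_key_trios: int = 0,
    seed: int = 1,
) -> Cohort:
    """Append non-spouse decoy records that household matching will pick up.

    Three classes: same-sex cohabiting pairs (caught by the same-sex filter),
    opposite-sex full-sibling cohabiting pairs with Mendelian genotypes
    (caught by the relatedness filter; their parental-death ages are left
    missing so they survive the earlier filters), and trios sharing one
    household key (caught by the more-than-two rule).  The truth table marks
    pair decoys; trio members are flagged in ``individuals['decoy_class']``.
    Returns a new Cohort; the input is not modified.
    """
    if n_same_sex == 0 and n_sib_pairs == 0 and n_key_trios == 0:
        return cohort
    cfg = cohort.config or SimulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, cfg.seed, 977]))
    gn, ge = cfg.grid_km
    centres = np.sort(cohort.individuals["centre"].unique())

    new_rows = []
    new_geno = []
    new_truth = []
    counter = 0
    freqs_bg = cohort.variants["freq"].to_numpy()

    def base_record(sex, decoy_class, household, centre_name):
        nonlocal counter
        rid = f"DC{counter:05d}"
        counter += 1
        rec = {
            "id": rid,
            "sex": sex,
            "age": float(rng.uniform(40, 69)),
            "birth_north_km": float(rng.uniform(0, gn)),
            "birth_east_km": float(rng.uniform(0, ge)),
            "centre": centre_name,
            "spouse_cohab": 1,
            "latent_pheno": float(rng.normal(cfg.mean_weekly_units, cfg.sd_weekly_units)),
            "decoy_class": decoy_class,
            "height_cm": float(rng.normal(168, 8)),
            "age_completed_education": 16,
            "has_degree": False,
            "country_of_birth": "England",
            "father_death_age": np.nan,
            "mother_death_age": np.nan,
            "frequency_category": "1-2 per week",
            "drinker_status": "current",
        }
        rec.update(household)
        u = max(rec["latent_pheno"], 0.0)
        rec["pheno_formation"] = u
        rec["weekly_units"] = round(u)
        rec["spirits_measures"] = int(round(u))
        for c in BEVERAGE_COLUMNS[1:]:
            rec[c] = 0
        return rec

    def fresh_household(centre_name):
        return {
            "years_at_address": int(rng.integers(0, 30)),
            "n_occupants": int(rng.integers(2, 6)),
            "n_vehicles": int(rng.integers(0, 4)),
            "accommodation": str(rng.choice(ACCOMMODATION_TYPES)),
            "rental": str(rng.choice(RENTAL_STATUS)),
            "home_north_km": int(rng.integers(0, int(gn))),
            "home_east_km": int(rng.integers(0, int(ge))),
            "centre": centre_name,
        }

    def population_genotypes():
        g = rng.binomial(2, np.clip(freqs_bg, 1e-4, 1 - 1e-4)).astype(float)
        return g

    for _ in range(n_same_sex):
        sexes = str(rng.choice(["M", "F"]))
        cname = str(rng.choice(centres))
        hh = fresh_household(cname)
        r1 = base_record(sexes, "same_sex", hh, cname)
        r2 = base_record(sexes, "same_sex", hh, cname)
        new_rows += [r1, r2]
        new_geno += [population_genotypes(), population_genotypes()]
        new_truth.append({"id_a": r1["id"], "id_b": r2["id"], "decoy_class": "same_sex"})

    for _ in range(n_sib_pairs):
        cname = str(rng.choice(centres))
        hh = fresh_household(cname)
        r1 = base_record("M", "sib", hh, cname)
        r2 = base_record("F", "sib", hh, cname)
        g1, g2 = _mendelian_sibs(np.clip(freqs_bg, 1e-4, 1 - 1e-4), rng)
        new_rows += [r1, r2]
        new_geno += [g1.astype(float), g2.astype(float)]
        new_truth.append({"id_a": r1["id"], "id_b": r2["id"], "decoy_class": "sib"})

    for _ in range(n_key_trios):
        cname = str(rng.choice(centres))
        hh = fresh_household(cname)
        for s in ("M", "F", "F"):
            r = base_record(s, "key_trio", hh, cname)
            new_rows.append(r)
            new_geno.append(population_genotypes())

    add_ind = pd.DataFrame(new_rows).set_index("id")
    individuals = pd.concat([cohort.individuals, add_ind])
    genotypes = pd.concat([
        cohort.genotypes,
        pd.DataFrame(np.vstack(new_geno), index=add_ind.index,
                     columns=cohort.genotypes.columns),
    ])
    truth_add = pd.DataFrame(new_truth) if new_truth else pd.DataFrame(
        columns=["id_a", "id_b", "decoy_class"])
    if len(truth_add):
        truth_add["couple_id"] = [f"DP{k:05d}" for k in range(len(truth_add))]
        truth_add["mechanism"] = "decoy"
        truth_add["duration"] = np.nan
        truth_add["dissolved"] = False
    truth = pd.concat([cohort.truth, truth_add], ignore_index=True)
    return Cohort(
        individuals=individuals,
        genotypes=genotypes,
        variants=cohort.variants.copy(),
        truth=truth,
        config=cfg,
        log_messages=list(cohort.log_messages),
    )
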