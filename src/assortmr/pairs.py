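"""Spouse-pair derivation from household records and genotypes.

The derivation mirrors the UK Biobank household-matching recipe: candidate
pairs are individuals who report cohabiting with a spouse, have genotype
data, and agree exactly on years at address, household occupancy, vehicles,
accommodation type, rental status, home coordinates rounded to the km, and
recruitment centre.  Keys shared by more than two people are discarded
outright.  Candidates then pass, in order, a same-sex filter, a
parental-death-age filter (both parents' ages of death identical across the
pair), and a genomic-relatedness filter computed from an LD-pruned marker
pool.  Every exclusion is logged with its step and reason in a ledger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .simulate import HOUSEHOLD_MATCH_FIELDS

log = logging.getLogger(__name__)

STEP_ORDER = ("household_match", "same_sex", "parental_death", "relatedness")


@dataclass
class ExclusionLedger:
    """Per-step candidate counts and per-individual exclusion reasons."""

    steps: list = field(default_factory=list)
    reasons: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "step", "reason"]))

    def record_step(self, step: str, n_in: int, n_excluded: int) -> None:
        self.steps.append({"step": step, "n_pairs_in": n_in,
                           "n_excluded": n_excluded, "n_pairs_out": n_in - n_excluded})

    def record_individuals(self, ids, step: str, reason: str) -> None:
        if len(ids) == 0:
            return
        add = pd.DataFrame({"id": list(ids), "step": step, "reason": reason})
        self.reasons = pd.concat([self.reasons, add], ignore_index=True)

    def step_index(self, step: str) -> int:
        return STEP_ORDER.index(step)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


@dataclass
class SpousePairSet:
    """Derived pairs plus the exclusion ledger."""

    pairs: pd.DataFrame  # columns id_a, id_b
    ledger: ExclusionLedger

    def __len__(self) -> int:
        return len(self.pairs)


# ----------------------------------------------------------------------
# stage 1: household matching


def match_households(records: pd.DataFrame, genotyped_ids=None,
                     ledger: ExclusionLedger | None = None) -> tuple:
    """Extract candidate pairs sharing an identical household key.

    ``records`` is indexed by id and must carry ``spouse_cohab`` plus the
    eight matching fields.  Individuals with a missing matching field are
    skipped and logged; keys shared by more than two individuals are excluded
    entirely.  Returns (pairs DataFrame, ledger).
    """
    ledger = ledger or ExclusionLedger()
    missing_fields = [f for f in HOUSEHOLD_MATCH_FIELDS if f not in records.columns]
    if missing_fields:
        raise DataError(f"records lack household matching field(s): {missing_fields}")

    eligible = records[records["spouse_cohab"] == 1]
    if genotyped_ids is not None:
        eligible = eligible.loc[eligible.index.intersection(genotyped_ids)]

    key_cols = list(HOUSEHOLD_MATCH_FIELDS)
    has_missing = eligible[key_cols].isna().any(axis=1)
    if has_missing.any():
        ledger.record_individuals(eligible.index[has_missing], "household_match",
                                  "missing_field")
        eligible = eligible[~has_missing]

    # coordinates matched after rounding to integer km
    key = eligible[key_cols].copy()
    key["home_north_km"] = np.rint(key["home_north_km"].astype(float)).astype(int)
    key["home_east_km"] = np.rint(key["home_east_km"].astype(float)).astype(int)

    grouped = key.groupby(key_cols, sort=False, observed=True)
    pairs = []
    trio_ids: list = []
    for _, idx in grouped.groups.items():
        members = list(idx)
        if len(members) == 2:
            pairs.append(tuple(sorted(members)))
        elif len(members) > 2:
            trio_ids.extend(members)
    ledger.record_individuals(trio_ids, "household_match", "key_trio")
    pair_df = pd.DataFrame(pairs, columns=["id_a", "id_b"])
    ledger.record_step("household_match", len(pair_df) + len(trio_ids) // 2,
                       len(trio_ids) // 2)
    return pair_df, ledger


# ----------------------------------------------------------------------
# stage 2 & 3: demographic filters


def filter_same_sex(pairs: pd.DataFrame, records: pd.DataFrame,
                    ledger: ExclusionLedger | None = None) -> tuple:
    """Remove pairs of the same (or missing) reported sex."""
    ledger = ledger or ExclusionLedger()
    if len(pairs) == 0:
        ledger.record_step("same_sex", 0, 0)
        return pairs.copy(), ledger
    sex_a = records.loc[pairs["id_a"], "sex"].to_numpy()
    sex_b = records.loc[pairs["id_b"], "sex"].to_numpy()
    bad_missing = pd.isna(sex_a) | pd.isna(sex_b)
    same = (sex_a == sex_b) & ~bad_missing
    drop = same | bad_missing
    dropped = pairs[drop]
    ledger.record_individuals(
        np.r_[dropped["id_a"], dropped["id_b"]], "same_sex",
        "same_sex")
    ledger.record_step("same_sex", len(pairs), int(drop.sum()))
    return pairs[~drop].reset_index(drop=True), ledger


def filter_parental_death(pairs: pd.DataFrame, records: pd.DataFrame,
                          ledger: ExclusionLedger | None = None) -> tuple:
    """Remove pairs whose members report identical father's *and* mother's
    ages at death (all four values non-missing).  Missing ages never match."""
    ledger = ledger or ExclusionLedger()
    if len(pairs) == 0:
        ledger.record_step("parental_death", 0, 0)
        return pairs.copy(), ledger
    fa = records.loc[pairs["id_a"], "father_death_age"].to_numpy(dtype=float)
    fb = records.loc[pairs["id_b"], "father_death_age"].to_numpy(dtype=float)
    ma = records.loc[pairs["id_a"], "mother_death_age"].to_numpy(dtype=float)
    mb = records.loc[pairs["id_b"], "mother_death_age"].to_numpy(dtype=float)
    match = (fa == fb) & (ma == mb)  # NaN compares False: missing never matches
    dropped = pairs[match]
    ledger.record_individuals(np.r_[dropped["id_a"], dropped["id_b"]],
                              "parental_death", "parental_death_match")
    ledger.record_step("parental_death", len(pairs), int(match.sum()))
    return pairs[~match].reset_index(drop=True), ledger


# ----------------------------------------------------------------------
# stage 4: relatedness on an LD-pruned marker pool


def ld_prune(genotypes: pd.DataFrame, positions: pd.Series,
             chrom: pd.Series | None = None,
             window_kb: float = 50.0, step_kb: float = 5.0,
             r2_max: float = 0.1) -> list:
    """Greedy windowed LD pruning; returns the retained variant ids.

    Windows of ``window_kb`` advance in steps of ``step_kb`` along each
    chromosome; within a window the earlier variant of any pair with
    r^2 >= ``r2_max`` is kept and the later one dropped.  Monomorphic
    variants are dropped first (r^2 undefined).
    """
    cols = list(genotypes.columns)
    pos = positions.reindex(cols).to_numpy(dtype=float)
    if np.isnan(pos).any():
        raise DataError("every variant needs a position for LD pruning")
    chrom_arr = (chrom.reindex(cols).astype(str).to_numpy()
                 if chrom is not None else np.repeat("1", len(cols)))

    G = genotypes.to_numpy(dtype=float)
    sd = np.nanstd(G, axis=0)
    poly = sd > 0
    keep = dict.fromkeys(np.array(cols)[poly].tolist())
    window = window_kb * 1000.0
    step = step_kb * 1000.0

    for ch in pd.unique(chrom_arr):
        sel = np.flatnonzero((chrom_arr == ch) & poly)
        if len(sel) < 2:
            continue
        order = sel[np.argsort(pos[sel], kind="stable")]
        p = pos[order]
        start = p.min()
        while start <= p.max():
            in_win = order[(p >= start) & (p < start + window)]
            in_win = [i for i in in_win if cols[i] in keep]
            for a_i in range(len(in_win)):
                for b_i in range(a_i + 1, len(in_win)):
                    va, vb = cols[in_win[a_i]], cols[in_win[b_i]]
                    if va not in keep or vb not in keep:
                        continue
                    x, y = G[:, in_win[a_i]], G[:, in_win[b_i]]
                    ok = ~(np.isnan(x) | np.isnan(y))
                    r = np.corrcoef(x[ok], y[ok])[0, 1]
                    if r * r >= r2_max:
                        keep.pop(vb, None)
            start += step
    return list(keep)


def estimate_relatedness(genotypes: pd.DataFrame, pairs: pd.DataFrame,
                         markers=None, min_markers_warn: int = 100) -> pd.Series:
    """GRM-style relatedness for each candidate pair.

    For pair (j, k): mean over markers of
    ``(g_ij - 2 p_i)(g_ik - 2 p_i) / (2 p_i (1 - p_i))`` with allele
    frequencies ``p_i`` computed from the candidate-pair sample itself.
    Markers fixed in the sample are excluded; missing genotypes are imputed
    to the marker mean (contributing zero to the numerator).
    """
    markers = list(markers) if markers is not None else list(genotypes.columns)
    sample_ids = pd.unique(np.r_[pairs["id_a"], pairs["id_b"]])
    G = genotypes.loc[sample_ids, markers].to_numpy(dtype=float)
    p = np.nanmean(G, axis=0) / 2.0
    informative = (p > 0.0) & (p < 1.0)
    G = G[:, informative]
    p = p[informative]
    if G.shape[1] < min_markers_warn:
        log.warning("relatedness estimated from only %d markers (recommend >= %d)",
                    G.shape[1], min_markers_warn)
    if G.shape[1] == 0:
        raise DataError("no informative markers for relatedness estimation")
    centred = np.where(np.isnan(G), 0.0, G - 2.0 * p)
    scaled = centred / np.sqrt(2.0 * p * (1.0 - p))
    row = {iid: i for i, iid in enumerate(sample_ids)}
    ia = np.array([row[i] for i in pairs["id_a"]])
    ib = np.array([row[i] for i in pairs["id_b"]])
    rel = (scaled[ia] * scaled[ib]).mean(axis=1)
    return pd.Series(rel, index=pairs.index, name="relatedness")


def filter_relatedness(pairs: pd.DataFrame, genotypes: pd.DataFrame, markers,
                       threshold: float = 0.1,
                       ledger: ExclusionLedger | None = None) -> tuple:
    """Drop pairs with estimated relatedness strictly greater than threshold."""
    ledger = ledger or ExclusionLedger()
    if len(pairs) == 0:
        ledger.record_step("relatedness", 0, 0)
        return pairs.copy(), ledger
    rel = estimate_relatedness(genotypes, pairs, markers)
    drop = rel > threshold
    dropped = pairs[drop.to_numpy()]
    ledger.record_individuals(np.r_[dropped["id_a"], dropped["id_b"]],
                              "relatedness", "relatedness")
    ledger.record_step("relatedness", len(pairs), int(drop.sum()))
    out = pairs[~drop.to_numpy()].reset_index(drop=True)
    return out, ledger


# ----------------------------------------------------------------------
# full derivation


def derive_spouse_pairs(records: pd.DataFrame, genotypes: pd.DataFrame,
                        positions: pd.Series | None = None,
                        chrom: pd.Series | None = None,
                        window_kb: float = 50.0, step_kb: float = 5.0,
                        r2_max: float = 0.1,
                        relatedness_threshold: float = 0.1) -> SpousePairSet:
    """Run the full derivation: match -> same-sex -> parental-death -> relatedness.

    ``positions``/``chrom`` feed the LD pruning that defines the relatedness
    marker pool; if positions are omitted every polymorphic marker is used.
    """
    ledger = ExclusionLedger()
    pairs, ledger = match_households(records, genotyped_ids=genotypes.index,
                                     ledger=ledger)
    pairs, ledger = filter_same_sex(pairs, records, ledger)
    pairs, ledger = filter_parental_death(pairs, records, ledger)
    if positions is not None:
        markers = ld_prune(genotypes, positions, chrom,
                           window_kb=window_kb, step_kb=step_kb, r2_max=r2_max)
    else:
        markers = [c for c in genotypes.columns
                   if np.nanstd(genotypes[c].to_numpy(dtype=float)) > 0]
    pairs, ledger = filter_relatedness(pairs, genotypes, markers,
                                       threshold=relatedness_threshold,
                                       ledger=ledger)
    ledger.record_individuals(np.r_[pairs["id_a"], pairs["id_b"]],
                              "retained", "retained")
    return SpousePairSet(pairs=pairs, ledger=ledger)


def evaluate_derivation(spouse_set: SpousePairSet, truth: pd.DataFrame,
                        individuals: pd.DataFrame | None = None) -> dict:
    """Recall of true couples and the fate of each decoy class, against truth.

    Trio decoys have no truth-table pair rows; pass ``individuals`` (with its
    ``decoy_class`` column) to account for them.
    """
    derived = {tuple(sorted(t)) for t in
               spouse_set.pairs[["id_a", "id_b"]].itertuples(index=False)}
    true_pairs = truth[(truth["decoy_class"] == "none") & (~truth["dissolved"])]
    true_set = {tuple(sorted(t)) for t in
                true_pairs[["id_a", "id_b"]].itertuples(index=False)}
    recall = (len(true_set & derived) / len(true_set)) if true_set else float("nan")
    reasons = spouse_set.ledger.reasons.set_index("id")["reason"].to_dict()
    decoy_outcomes = {}
    for cls in ("same_sex", "sib", "key_trio"):
        rows = truth[truth["decoy_class"] == cls]
        ids = set(rows["id_a"]) | set(rows["id_b"]) if len(rows) else set()
        if individuals is not None and "decoy_class" in individuals.columns:
            ids |= set(individuals.index[individuals["decoy_class"] == cls])
        decoy_outcomes[cls] = {
            "n_individuals": len(ids),
            "n_retained": sum(1 for t in derived for i in t if i in ids),
            "reasons": sorted({reasons.get(i, "absent") for i in ids}),
        }
    false_pairs = derived - true_set
    return {
        "recall": recall,
        "n_true": len(true_set),
        "n_derived": len(derived),
        "n_false_pairs": len(false_pairs),
        "decoy_outcomes": decoy_outcomes,
    }
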