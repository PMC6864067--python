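"""End-to-end pipeline: simulate -> derive pairs -> concordance -> MR -> stratification.

A pipeline config is a mapping with a ``simulate`` section (a
:class:`~assortmr.config.SimulationConfig`) or an ``input_dir`` pointing at a
written cohort, plus an optional ``stages`` list.  Results are written as
TSV tables (floats at 6 significant digits) plus a JSON run manifest with
config hash, seed and file checksums; identical config + seed gives
identical checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import concordance as conc
from . import io as cio
from . import mr as mr_mod
from . import pairs as pairs_mod
from . import stratification as strat
from .config import SimulationConfig
from .errors import ConfigError, DataError
from .simulate import inject_decoys, simulate_cohort

ALL_STAGES = ("simulate", "pairs", "concordance", "mr", "stratify")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    files: dict = field(default_factory=dict)
    row_counts: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _fmt(x):
    if isinstance(x, float):
        return float(f"{x:.6g}")
    return x


def _assoc_row(name, r):
    return {"analysis": name, "beta": _fmt(r.beta), "se": _fmt(r.se),
            "ci_lo": _fmt(r.ci95[0]), "ci_hi": _fmt(r.ci95[1]),
            "p": _fmt(r.p), "n": r.n}


def run_pipeline(config, outdir, seed: int | None = None) -> RunManifest:
    """Execute the configured stages; returns the run manifest.

    ``config`` is a dict (or YAML path) with keys ``simulate`` / ``input_dir``,
    optional ``stages``, ``decoys`` and ``derive`` sections.  Any stage
    failure aborts with the stage name in the error.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("pipeline config must be a mapping")
    stages = tuple(config.get("stages", ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    canonical = yaml.safe_dump(config, sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(canonical.encode()).hexdigest(),
        seed=int(seed if seed is not None
                 else config.get("simulate", {}).get("seed", 0)),
        version=__version__,
    )

    # --- obtain cohort -------------------------------------------------
    if "input_dir" in config:
        in_dir = Path(config["input_dir"])
        if ("mr" in stages or "stratify" in stages) and not (
                in_dir / cio.FILENAMES["vcf"]).exists():
            raise ConfigError("mr requires genotypes")
        cohort = cio.read_cohort(in_dir)
    elif "simulate" in config or "simulate" in stages:
        sim_cfg = dict(config.get("simulate", {}))
        if seed is not None:
            sim_cfg["seed"] = int(seed)
        cfg = SimulationConfig.from_dict(sim_cfg)
        try:
            cohort = simulate_cohort(cfg)
            dec = config.get("decoys", {})
            if dec:
                cohort = inject_decoys(cohort, **dec)
        except (ConfigError, DataError):
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise DataError(f"stage simulate failed: {exc}") from exc
        data_dir = outdir / "cohort"
        paths = cio.write_cohort(cohort, data_dir)
        for k, p in paths.items():
            manifest.files[str(Path(p).relative_to(outdir))] = _sha256(p)
    else:
        raise ConfigError("pipeline config needs a 'simulate' section or 'input_dir'")
    manifest.row_counts["individuals"] = int(len(cohort.individuals))

    # --- derive pairs --------------------------------------------------
    results = []
    pair_df = None
    if "pairs" in stages:
        try:
            spouse_set = pairs_mod.derive_spouse_pairs(
                cohort.individuals, cohort.genotypes,
                positions=cohort.variants["pos"], chrom=cohort.variants["chrom"],
                **config.get("derive", {}))
        except (ConfigError, DataError) as exc:
            raise type(exc)(f"stage pairs: {exc}") from exc
        pair_df = spouse_set.pairs
        spouse_set.ledger.summary().to_csv(outdir / "ledger_steps.tsv",
                                           sep="\t", index=False)
        spouse_set.ledger.reasons.to_csv(outdir / "ledger_reasons.tsv",
                                         sep="\t", index=False)
        pair_df.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        manifest.row_counts["pairs"] = int(len(pair_df))

    focal = "rs_focal" if "rs_focal" in cohort.genotypes.columns else None
    if pair_df is not None and len(pair_df) >= 10:
        ind = cohort.individuals
        if "concordance" in stages:
            r = conc.phenotypic_concordance(
                pair_df, ind, "weekly_units",
                covariates=("ref:sex", "ref:age", "partner:age"),
                seed=manifest.seed)
            results.append(_assoc_row("phenotypic_weekly_units", r))
            if focal:
                r = conc.genotypic_concordance(pair_df, cohort.genotypes, focal,
                                               seed=manifest.seed)
                results.append(_assoc_row("genotypic_focal", r))
            w = cohort.variants["weight"]
            if (w != 0).any():
                r = conc.pgs_concordance(pair_df, cohort.genotypes, w,
                                         seed=manifest.seed)
                results.append(_assoc_row("pgs_concordance", r))
            r = conc.relationship_length_proxy(pair_df, ind, "weekly_units",
                                               seed=manifest.seed)
            results.append(_assoc_row("length_proxy_weekly_units", r))
        if "mr" in stages and focal:
            mr_res = mr_mod.cross_spouse_mr(pair_df, ind, cohort.genotypes,
                                            focal, "weekly_units")
            results.append(_assoc_row("mr_exposure_stage", mr_res["exposure_stage"]))
            results.append(_assoc_row("mr_outcome_stage", mr_res["outcome_stage"]))
            w = mr_res["wald"]
            results.append({"analysis": "mr_wald_ratio", "beta": _fmt(w.beta),
                            "se": _fmt(w.se), "ci_lo": _fmt(w.ci95[0]),
                            "ci_hi": _fmt(w.ci95[1]), "p": _fmt(w.p),
                            "n": len(pair_df)})
        if "stratify" in stages and focal:
            counts = strat.genotype_counts(cohort.genotypes[focal])
            hwe = strat.hwe_test(counts)
            results.append({"analysis": "hwe_pooled", "beta": _fmt(hwe.chi2),
                            "se": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
                            "p": _fmt(hwe.p), "n": int(sum(counts))})
            try:
                meta = strat.within_centre_meta(pair_df, cohort.genotypes, focal,
                                                ind, seed=manifest.seed)
                results.append({"analysis": "within_centre_meta",
                                "beta": _fmt(meta.combined_beta),
                                "se": _fmt(meta.combined_se),
                                "ci_lo": _fmt(meta.combined_ci[0]),
                                "ci_hi": _fmt(meta.combined_ci[1]),
                                "p": _fmt(meta.combined_p), "n": meta.n_total})
            except DataError:
                pass

    if results:
        pd.DataFrame(results).to_csv(outdir / "estimates.tsv", sep="\t", index=False)
        manifest.files["estimates.tsv"] = _sha256(outdir / "estimates.tsv")
    manifest.to_json(outdir / "manifest.json")
    return manifest
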