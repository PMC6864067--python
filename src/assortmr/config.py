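"""Simulation configuration: the study conditions the couple simulator emulates.

Defaults mirror the UK Biobank alcohol setting: a low-frequency large-effect
ADH1B-like variant (minor allele frequency 2.8%, 3.99 weekly units per major
allele), a polygenic background explaining 10% of variance (common-variant
heritability of self-reported consumption is ~13%, part of which the focal
variant carries), a socio-economic confounder at 15%, a target spousal
phenotypic correlation of 0.37, and a south-to-north allele-frequency cline
sized to reproduce geographic association of the order of tens of km per
allele over a UK-sized planar grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Union

import yaml

from .errors import ConfigError

MECHANISMS = ("assortative", "homogamy", "interaction", "dissolution", "none")
HOMOGAMY_BASES = ("confounder", "geography")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic couple cohort.

    ``mechanism`` is either one of :data:`MECHANISMS` or a mapping of
    mechanism name to weight; mixtures act sequentially (assortment/homogamy
    at couple formation, interaction during the relationship, dissolution at
    sampling) with each weight scaling that mechanism's strength.
    """

    n_individuals: int = 20_000
    maf_focal: float = 0.028
    beta_focal: float = 3.99          # weekly units per effect (major) allele
    n_pgs_snps: int = 100
    h2_pgs: float = 0.10              # variance fraction from the polygenic score
    var_confounder: float = 0.15      # variance fraction from the shared-environment confounder
    assort_C: float = 0.37            # target spousal correlation of the pairing basis
    mechanism: Union[str, Mapping[str, float]] = "assortative"
    homogamy_basis: str = "confounder"
    interaction_rate_kappa: float = 0.03    # convergence fraction per year of relationship
    dissolution_lambda: float = 0.15        # log-odds of dissolution per unit |phenotype difference|
    dissolution_alpha: float = -3.0         # baseline log-odds of dissolution
    cline_gradients: tuple = (-3.0e-4, 1.6e-4)  # minor-allele logit change per km (north, east)
    n_centres: int = 22
    seed: int = 0
    mean_weekly_units: float = 11.0
    sd_weekly_units: float = 10.0
    censor_at_zero: bool = True
    migration_sd_km: float = 60.0     # birth-location scatter around the recruitment centre
    grid_km: tuple = (1000.0, 600.0)  # (northing, easting) extent of the planar grid
    max_duration_years: float = 40.0
    n_ld_block_snps: int = 0          # optional correlated marker block for pruning tests
    ld_block_r2: float = 0.5
    extra: dict = field(default_factory=dict)

    # ------------------------------------------------------------------

    def mechanism_weights(self) -> dict:
        """Normalised view of ``mechanism`` as a name -> weight mapping."""
        if isinstance(self.mechanism, str):
            if self.mechanism == "none":
                return {}
            return {self.mechanism: 1.0}
        return {k: float(v) for k, v in self.mechanism.items() if float(v) != 0.0}

    def validate(self) -> "SimulationConfig":
        if self.n_individuals < 2:
            raise ConfigError("n_individuals must be >= 2")
        if not 0.0 < self.maf_focal <= 0.5:
            raise ConfigError(f"maf_focal must be in (0, 0.5], got {self.maf_focal}")
        if not 0.0 <= self.h2_pgs <= 1.0:
            raise ConfigError(f"h2_pgs must be in [0, 1], got {self.h2_pgs}")
        if not 0.0 <= self.var_confounder <= 1.0:
            raise ConfigError("var_confounder must be in [0, 1]")
        if self.h2_pgs + self.var_confounder > 1.0:
            raise ConfigError(
                "impossible variance budget: h2_pgs + var_confounder = "
                f"{self.h2_pgs + self.var_confounder:.3f} > 1"
            )
        if not -1.0 <= self.assort_C <= 1.0:
            raise ConfigError(f"assort_C must be in [-1, 1], got {self.assort_C}")
        if isinstance(self.mechanism, str):
            if self.mechanism not in MECHANISMS:
                raise ConfigError(f"unknown mechanism {self.mechanism!r}; choose from {MECHANISMS}")
        else:
            bad = set(self.mechanism) - set(MECHANISMS[:-1])
            if bad:
                raise ConfigError(f"unknown mechanism(s) in mixture: {sorted(bad)}")
            if any(float(v) < 0 for v in self.mechanism.values()):
                raise ConfigError("mechanism weights must be non-negative")
        if self.homogamy_basis not in HOMOGAMY_BASES:
            raise ConfigError(f"homogamy_basis must be one of {HOMOGAMY_BASES}")
        if self.interaction_rate_kappa < 0:
            raise ConfigError("interaction_rate_kappa must be >= 0")
        if self.sd_weekly_units <= 0:
            raise ConfigError("sd_weekly_units must be > 0")
        if self.n_pgs_snps < 0 or self.n_ld_block_snps < 0:
            raise ConfigError("SNP counts must be >= 0")
        if not 0.0 <= self.ld_block_r2 < 1.0:
            raise ConfigError("ld_block_r2 must be in [0, 1)")
        return self

    # ------------------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["mechanism"], dict):
            d["mechanism"] = dict(d["mechanism"])
        d["cline_gradients"] = list(self.cline_gradients)
        d["grid_km"] = list(self.grid_km)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "cline_gradients" in d:
            d["cline_gradients"] = tuple(d["cline_gradients"])
        if "grid_km" in d:
            d["grid_km"] = tuple(d["grid_km"])
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} did not parse to a mapping")
        return cls.from_dict(d)
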