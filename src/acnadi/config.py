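"""Generator configuration for the synthetic multilevel screening cohort.

Defaults encode the study conditions the package targets: two race strata
(European-American, EA, n=1457; African-American, AA, n=936) nested in 598
census tracts, covariate distributions matching the published cohort
characteristics, log-odds effect sizes matching the published multivariable
odds ratios, race-specific neighbourhood-deprivation (ADI) distributions
(EA mean 28.1, SD 11.5; AA mean 53.1, SD 15.3 on the 0-100 scale), and a
modest tract-level random intercept on the logit scale.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigurationError

__all__ = [
    "RaceBlock",
    "GeneratorConfig",
    "default_config",
    "ea_like_config",
    "aa_like_config",
    "load_config",
    "save_config",
]


@dataclass
class RaceBlock:
    """Per-stratum sampling parameters.

    Continuous covariates are drawn from truncated normals (age clipped to
    the 50-80 eligibility window, BMI to a plausible 15-60 range, the
    remaining frequencies floored at 0); binary covariates are Bernoulli.
    ``target_prevalence`` is the outcome rate the intercept is calibrated
    to; ``adi_target_mean``/``adi_target_sd`` shape which tracts the
    stratum's subjects are drawn from.  ``adi_log_or_per_10`` optionally
    overrides the global deprivation effect for this stratum.
    """

    n_subjects: int
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    smoking_years_mean: float
    smoking_years_sd: float
    red_meat_mean: float
    red_meat_sd: float
    alcohol_mean: float
    alcohol_sd: float
    p_female: float
    p_family_history: float
    p_diabetes: float
    p_calcium: float
    target_prevalence: float
    adi_target_mean: float
    adi_target_sd: float
    adi_log_or_per_10: float | None = None

    def validate(self, name: str) -> None:
        if self.n_subjects <= 0:
            raise ConfigurationError(f"race block '{name}': n_subjects must be positive")
        for attr in ("age_sd", "bmi_sd", "smoking_years_sd", "red_meat_sd",
                     "alcohol_sd", "adi_target_sd"):
            if getattr(self, attr) <= 0:
                raise ConfigurationError(f"race block '{name}': {attr} must be > 0")
        for attr in ("p_female", "p_family_history", "p_diabetes", "p_calcium"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"race block '{name}': {attr} must be in [0, 1]")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ConfigurationError(f"race block '{name}': target_prevalence must be in (0, 1)")


def _pc1_share_to_loading(share: float, k: int = 17) -> float:
    """Factor loading lambda for an equicorrelated single-factor model whose
    leading-eigenvalue share of total indicator variance equals ``share``:
    share = (1 + (k-1) lambda^2) / k."""
    return math.sqrt((share * k - 1.0) / (k - 1))


#: Default share of indicator variance carried by the deprivation factor.
DEFAULT_PC1_SHARE = 0.602


@dataclass
class GeneratorConfig:
    """Full configuration of the synthetic tract + cohort generator.

    Randomness is controlled by one master ``seed``; per-stage child
    streams (tract indicators, tract random effects, subject-tract
    assignment, covariates, outcomes) are spawned deterministically from it
    with fixed spawn indices 0..4.
    """

    n_tracts: int = 598
    factor_loading: float = _pc1_share_to_loading(DEFAULT_PC1_SHARE)
    race_blocks: dict[str, RaceBlock] = field(default_factory=dict)
    coefficients: dict[str, float] = field(default_factory=dict)
    adi_log_or_per_10: float = math.log(1.24)
    tract_sigma: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_tracts <= 1:
            raise ConfigurationError("n_tracts must be > 1")
        if not 0.0 < self.factor_loading < 1.0:
            raise ConfigurationError("factor_loading must lie strictly in (0, 1)")
        if self.tract_sigma < 0:
            raise ConfigurationError("tract_sigma must be >= 0")
        if not self.race_blocks:
            raise ConfigurationError("at least one race block is required")
        for name, block in self.race_blocks.items():
            if not isinstance(block, RaceBlock):
                raise ConfigurationError(f"race block '{name}' is not a RaceBlock")
            block.validate(name)

    def adi_effect(self, race: str) -> float:
        block = self.race_blocks[race]
        return self.adi_log_or_per_10 if block.adi_log_or_per_10 is None else block.adi_log_or_per_10

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        blocks = {k: RaceBlock(**v) for k, v in d.pop("race_blocks", {}).items()}
        cfg = cls(race_blocks=blocks, **d)
        cfg.validate()
        return cfg


# Published cohort characteristics used as generator defaults -----------------

_EA_BLOCK = dict(
    n_subjects=1457,
    age_mean=57.8, age_sd=7.0,
    bmi_mean=28.3, bmi_sd=5.9,
    smoking_years_mean=9.3, smoking_years_sd=13.6,
    red_meat_mean=2.9, red_meat_sd=2.8,
    alcohol_mean=3.0, alcohol_sd=5.6,
    p_female=0.567, p_family_history=0.107, p_diabetes=0.091, p_calcium=0.258,
    target_prevalence=0.063,
    adi_target_mean=28.1, adi_target_sd=11.5,
    adi_log_or_per_10=math.log(1.24),
)

_AA_BLOCK = dict(
    n_subjects=936,
    age_mean=57.9, age_sd=7.4,
    bmi_mean=31.8, bmi_sd=7.9,
    smoking_years_mean=17.4, smoking_years_sd=16.8,
    red_meat_mean=3.3, red_meat_sd=3.8,
    alcohol_mean=3.0, alcohol_sd=12.9,
    p_female=0.676, p_family_history=0.112, p_diabetes=0.250, p_calcium=0.111,
    target_prevalence=0.084,
    adi_target_mean=53.1, adi_target_sd=15.3,
    adi_log_or_per_10=math.log(1.07),
)

#: Log-odds per stated unit for the outcome model (combined-population
#: multivariable odds ratios; red meat from the AA-specific model; alcohol is
#: a forced candidate with no true effect).
DEFAULT_COEFFICIENTS = {
    "male": math.log(1.41),
    "age": math.log(1.03),
    "bmi": math.log(1.03),
    "family_history_fdr": math.log(1.69),
    "smoking_years": math.log(1.01),
    "diabetes": math.log(1.49),
    "calcium_use": math.log(0.59),
    "red_meat_per_week": math.log(1.04),
    "alcohol_per_week": 0.0,
}


def default_config(seed: int = 0) -> GeneratorConfig:
    """Two-stratum configuration matching the full study cohort."""
    cfg = GeneratorConfig(
        race_blocks={"EA": RaceBlock(**_EA_BLOCK), "AA": RaceBlock(**_AA_BLOCK)},
        coefficients=dict(DEFAULT_COEFFICIENTS),
        seed=seed,
    )
    cfg.validate()
    return cfg


def ea_like_config(seed: int = 0) -> GeneratorConfig:
    """EA-only stratum (n=1457) with the EA deprivation effect."""
    cfg = GeneratorConfig(
        race_blocks={"EA": RaceBlock(**_EA_BLOCK)},
        coefficients=dict(DEFAULT_COEFFICIENTS),
        adi_log_or_per_10=math.log(1.24),
        seed=seed,
    )
    cfg.validate()
    return cfg


def aa_like_config(seed: int = 0) -> GeneratorConfig:
    """AA-only stratum (n=936) with the AA deprivation effect."""
    cfg = GeneratorConfig(
        race_blocks={"AA": RaceBlock(**_AA_BLOCK)},
        coefficients=dict(DEFAULT_COEFFICIENTS),
        adi_log_or_per_10=math.log(1.07),
        seed=seed,
    )
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> GeneratorConfig:
    """Read a generator config from a JSON or TOML file."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            d = tomllib.load(fh)
    else:
        with open(path) as fh:
            d = json.load(fh)
    return GeneratorConfig.from_dict(d)


def save_config(cfg: GeneratorConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=1) + "\n")
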