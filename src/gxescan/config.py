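"""Configuration objects for simulation and scanning."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

__all__ = ["SimulationConfig", "ScanConfig", "TRAITS"]

#: Analyzed traits: natural-log liver enzymes plus the raw AST/ALT ratio.
TRAITS = ("ast_alt_ratio", "log_ALT", "log_AST", "log_GGT")


def _default_beta_e() -> dict:
    return {"log_ALT": 0.0008, "log_AST": 0.0015, "log_GGT": 0.006}


def _default_beta_ge() -> dict:
    # ALT: heterozygote drinkers lose ~20% ALT at tier 3 once the sex mix is
    # accounted for. AST: the interaction cancels the alcohol main effect in
    # carriers, so heterozygote AST is flat in drinking while the major-
    # homozygote AST trend (driven by beta_E) remains.
    return {"log_ALT": -0.011, "log_AST": -0.0015, "log_GGT": 0.0}


def _default_noise_sd() -> dict:
    return {"log_ALT": 0.40, "log_AST": 0.30, "log_GGT": 0.55}


def _default_log_center() -> dict:
    return {"log_ALT": 3.13, "log_AST": 3.40, "log_GGT": 2.94}


def _default_age_effect() -> dict:
    return {"log_ALT": 0.001, "log_AST": 0.003, "log_GGT": 0.004}


def _default_sex_effect() -> dict:
    return {"log_ALT": -0.25, "log_AST": -0.10, "log_GGT": -0.45}


def _default_bmi_effect() -> dict:
    return {"log_ALT": 0.04, "log_AST": 0.02, "log_GGT": 0.04}


@dataclass
class SimulationConfig:
    """Synthetic two-cohort study design.

    Defaults emulate the statistical structure of a two-prefecture Japanese
    community cohort: per-cohort sample sizes, covariate marginals and
    drinking prevalence; one causal intolerance-type variant (MAF 0.18)
    with correlated LD partners; a negative genotype x daily-alcohol
    interaction on log ALT that is stronger in men; and an avoidance effect
    by which intolerance-allele carriers are less likely to drink.

    ``beta_ge`` is the interaction effect per g/day per alt allele in men;
    women get ``beta_ge * sex_effect_multiplier``. The avoidance effect
    multiplies the drinker probability by ``avoidance_per_allele`` per alt
    allele (the magnitude is a placeholder: avoidance is qualitative in the
    source cohort literature, with no published size).
    """

    n_subjects: Sequence[int] = (3878, 3978)
    cohort_labels: Sequence[str] = ("Iwate", "Miyagi")
    n_variants: int = 5000
    causal_maf: float = 0.18
    n_ld_partners: int = 3
    ld_r2_range: tuple[float, float] = (0.62, 0.95)
    background_maf_range: tuple[float, float] = (0.05, 0.5)
    # exposure model
    drinker_fraction: Sequence[float] = (0.442, 0.480)
    avoidance_per_allele: float = 0.7
    dac_median: float = 16.0  # g/day among drinkers (log-normal median)
    dac_sigma: float = 0.9  # log-normal sigma of drinker DAC
    # phenotype model (log scale; ratio trait derived from AST and ALT)
    beta_e: Mapping[str, float] = field(default_factory=_default_beta_e)
    beta_ge: Mapping[str, float] = field(default_factory=_default_beta_ge)
    sex_effect_multiplier: float = 0.5
    trait_noise_sd: Mapping[str, float] = field(default_factory=_default_noise_sd)
    ast_alt_noise_corr: float = 0.5
    trait_log_center: Mapping[str, float] = field(default_factory=_default_log_center)
    age_effect: Mapping[str, float] = field(default_factory=_default_age_effect)
    sex_effect: Mapping[str, float] = field(default_factory=_default_sex_effect)
    bmi_effect: Mapping[str, float] = field(default_factory=_default_bmi_effect)
    # covariate marginals per cohort
    age_mean_sd: Sequence[tuple[float, float]] = ((63.1, 9.9), (59.5, 11.9))
    female_fraction: Sequence[float] = (0.640, 0.683)
    bmi_mean_sd: Sequence[tuple[float, float]] = ((23.4, 3.4), (23.4, 3.5))
    # data blemishes
    missing_rate: float = 0.02
    liver_disease_rate: float = 0.03
    seed: int = 2013

    def validate(self) -> None:
        k = len(self.n_subjects)
        if k < 1:
            raise ValueError("need at least one cohort")
        for name in ("cohort_labels", "drinker_fraction", "age_mean_sd",
                     "female_fraction", "bmi_mean_sd"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} must have one entry per cohort")
        if not 0 < self.causal_maf < 1:
            raise ValueError("causal_maf must be in (0, 1)")
        if self.n_ld_partners < 0:
            raise ValueError("n_ld_partners must be >= 0")
        if self.n_variants < 1 + self.n_ld_partners:
            raise ValueError("n_variants must cover causal variant + LD partners")
        lo, hi = self.ld_r2_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("ld_r2_range must be within [0, 1]")
        if any(sd <= 0 for sd in self.trait_noise_sd.values()):
            raise ValueError("trait noise SDs must be > 0")
        if self.dac_sigma <= 0:
            raise ValueError("dac_sigma must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScanConfig:
    """One genome-wide interaction scan.

    ``sensitivity_mode``: ``main`` (age, sex, BMI, PCs), ``no_bmi`` (BMI
    dropped everywhere) or ``gxcov_excov`` (G x covariate and E x covariate
    product terms added to both nested models). The sex covariate is
    dropped automatically under a sex-restricted scan.
    """

    trait: str = "log_ALT"
    covariates: Sequence[str] = ("age", "female", "bmi")
    n_pcs: int = 5
    sensitivity_mode: str = "main"
    sex_restriction: str = "all"

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}; one of {TRAITS}")
        if self.sensitivity_mode not in ("main", "no_bmi", "gxcov_excov"):
            raise ValueError(f"unknown sensitivity_mode {self.sensitivity_mode!r}")
        if self.sex_restriction not in ("all", "male", "female"):
            raise ValueError(f"unknown sex_restriction {self.sex_restriction!r}")

    def effective_covariates(self) -> list[str]:
        cov = list(self.covariates)
        if self.sensitivity_mode == "no_bmi":
            cov = [c for c in cov if c != "bmi"]
        if self.sex_restriction != "all":
            cov = [c for c in cov if c != "female"]
        return cov
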