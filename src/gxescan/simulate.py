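"""Synthetic two-cohort study generator.

Produces genotypes (one planted causal variant with LD partners among
independent background variants), questionnaire answers whose drinking
propensity is allele-aware, covariates, and log-scale liver-test phenotypes
carrying a configurable genotype x daily-alcohol interaction. Ground truth
is returned alongside for parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .genotypes import GenotypeMatrix
from .questionnaire import ETHANOL_CONTENT, FREQUENCY_DAYS

__all__ = ["TruthRecord", "SimulatedStudy", "simulate_genotypes", "simulate_study"]

CAUSAL_ID = "sim_causal"
CAUSAL_CHROM, CAUSAL_POS = "12", 112_337_924

# drinker beverage mix (primary-beverage choice probabilities)
_BEVERAGES = ("sake", "beer", "shochu", "chu-hai", "whisky", "wine")
_BEV_PROBS = (0.25, 0.35, 0.20, 0.08, 0.05, 0.07)

# drinking-frequency answer probabilities among current drinkers; chosen to
# give an overall mean near 1.9 days/week at ~45% drinker prevalence
_FREQ_LABELS = tuple(FREQUENCY_DAYS)
_FREQ_PROBS_DRINKER = (0.0, 0.12, 0.20, 0.23, 0.15, 0.30)


@dataclass
class TruthRecord:
    """Ground truth of one simulated study."""

    causal_variant_id: str
    ld_partner_ids: list[str]
    ld_target_r2: np.ndarray
    beta_e: dict
    beta_ge: dict
    sex_effect_multiplier: float
    latent: pd.DataFrame  # subject_id, cohort, latent_dac (pre-rounding g/day)

    def to_frame(self) -> pd.DataFrame:
        """Flat per-subject TSV-ready view with the causal id attached."""
        out = self.latent.copy()
        out["causal_variant_id"] = self.causal_variant_id
        return out


@dataclass
class SimulatedStudy:
    """Per-cohort genotypes and raw subject tables, plus the truth."""

    genotypes: dict[str, GenotypeMatrix]
    tables: dict[str, pd.DataFrame]
    truth: TruthRecord
    config: SimulationConfig


def _variant_frame(config: SimulationConfig, rng: np.random.Generator):
    """Variant metadata: causal + LD partners on 12q24, background elsewhere."""
    n_bg = config.n_variants - 1 - config.n_ld_partners
    ids = [CAUSAL_ID] + [f"sim_ld_{i + 1}" for i in range(config.n_ld_partners)]
    chroms = [CAUSAL_CHROM] * (1 + config.n_ld_partners)
    pos = [CAUSAL_POS] + [
        CAUSAL_POS + int(d)
        for d in rng.integers(-400_000, 400_000, config.n_ld_partners)
    ]
    bg_chrom = [str(c) for c in (np.arange(n_bg) % 22 + 1)]
    bg_pos = (1_000_000 + 1_500 * (np.arange(n_bg) // 22 + 1)).tolist()
    refs = ["G"] + ["C"] * config.n_ld_partners + ["A"] * n_bg
    alts = ["A"] + ["T"] * config.n_ld_partners + ["G"] * n_bg
    frame = pd.DataFrame(
        {
            "variant_id": ids + [f"sim_bg_{i + 1}" for i in range(n_bg)],
            "chrom": chroms + bg_chrom,
            "pos": pos + bg_pos,
            "ref": refs,
            "alt": alts,
            "imputation_r2": 1.0,
        }
    )
    return frame


def simulate_genotypes(
    config: SimulationConfig,
    n_subjects: int,
    rng: np.random.Generator,
    variants: pd.DataFrame,
    subject_ids: np.ndarray,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Hard-call dosages under HWE with a causal variant and LD partners.

    The causal variant is drawn as two haplotype allele vectors at the
    configured MAF; each LD partner copies those haplotypes and resamples
    each allele with probability eps, giving allele (and hence dosage)
    correlation 1 - eps, so eps = 1 - sqrt(target R²). Background variants
    are independent binomials at MAFs drawn from ``background_maf_range``.

    Returns the matrix and the per-partner target R² values.
    """
    config.validate()
    p = config.causal_maf
    h1 = rng.random(n_subjects) < p
    h2 = rng.random(n_subjects) < p
    n_bg = config.n_variants - 1 - config.n_ld_partners
    target_r2 = rng.uniform(*config.ld_r2_range, config.n_ld_partners)

    dosages = np.empty((n_subjects, config.n_variants), dtype=np.float32)
    dosages[:, 0] = h1.astype(np.float32) + h2.astype(np.float32)
    for j in range(config.n_ld_partners):
        eps = 1.0 - np.sqrt(target_r2[j])
        part = np.empty(n_subjects, dtype=np.float32)
        cols = []
        for h in (h1, h2):
            flip = rng.random(n_subjects) < eps
            fresh = rng.random(n_subjects) < p
            cols.append(np.where(flip, fresh, h))
        part = cols[0].astype(np.float32) + cols[1].astype(np.float32)
        dosages[:, 1 + j] = part
    if n_bg:
        mafs = rng.uniform(*config.background_maf_range, n_bg)
        dosages[:, 1 + config.n_ld_partners :] = rng.binomial(
            2, mafs, size=(n_subjects, n_bg)
        ).astype(np.float32)
    return GenotypeMatrix(dosages, variants, subject_ids), target_r2


def _simulate_questionnaire(
    config: SimulationConfig,
    cohort_idx: int,
    g_causal: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Drinking status / frequency / weekly beverage volumes, allele-aware.

    Drinker probability is ``base * avoidance^G``, with the base solved so
    the cohort-level drinker fraction matches its configured target under
    Hardy-Weinberg at the causal MAF. Drinker daily intake is log-normal;
    weekly grams are split 80/20 across a primary and secondary beverage
    and converted to volumes, so the exposure recomputed downstream equals
    the latent intake up to float error.
    """
    n = g_causal.size
    p = config.causal_maf
    avoid = config.avoidance_per_allele
    mean_avoid = (1 - p) ** 2 + 2 * p * (1 - p) * avoid + p**2 * avoid**2
    base = min(config.drinker_fraction[cohort_idx] / mean_avoid, 1.0)
    p_drink = base * avoid**g_causal
    is_drinker = rng.random(n) < p_drink

    latent_dac = np.zeros(n)
    n_dr = int(is_drinker.sum())
    latent_dac[is_drinker] = np.exp(
        rng.normal(np.log(config.dac_median), config.dac_sigma, n_dr)
    )

    status = np.full(n, "never", dtype=object)
    status[is_drinker] = "current"
    nd = ~is_drinker
    carrier = g_causal >= 1
    u = rng.random(n)
    status[nd & (u < 0.2)] = "former"
    intol = nd & (u >= 0.2) & (
        rng.random(n) < np.where(carrier, 0.5, 0.05)
    )
    status[intol] = "never_intolerant"

    freq = np.full(n, _FREQ_LABELS[0], dtype=object)
    freq[is_drinker] = rng.choice(_FREQ_LABELS, size=n_dr, p=_FREQ_PROBS_DRINKER)

    vols = {f"ml_{b}".replace("-", "_"): np.zeros(n) for b in _BEVERAGES}
    primary = rng.choice(len(_BEVERAGES), size=n, p=_BEV_PROBS)
    secondary = (primary + 1 + rng.integers(0, len(_BEVERAGES) - 1, n)) % len(
        _BEVERAGES
    )
    weekly_g = latent_dac * 7.0
    for share, which in ((0.8, primary), (0.2, secondary)):
        for b_idx, bev in enumerate(_BEVERAGES):
            sel = is_drinker & (which == b_idx)
            ref_ml, ref_g = ETHANOL_CONTENT[bev]
            col = f"ml_{bev}".replace("-", "_")
            vols[col][sel] += weekly_g[sel] * share * ref_ml / ref_g
    return pd.DataFrame(
        {"drinking_status": status, "frequency_category": freq, **vols,
         "latent_dac": latent_dac}
    )


def _simulate_covariates(
    config: SimulationConfig, cohort_idx: int, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    a_m, a_s = config.age_mean_sd[cohort_idx]
    b_m, b_s = config.bmi_mean_sd[cohort_idx]
    age = np.clip(rng.normal(a_m, a_s, n), 20, 90)
    bmi = np.clip(rng.normal(b_m, b_s, n), 14, 45)
    female = (rng.random(n) < config.female_fraction[cohort_idx]).astype(int)
    return pd.DataFrame({"age": age, "female": female, "bmi": bmi})


def _simulate_phenotypes(
    config: SimulationConfig,
    g_causal: np.ndarray,
    latent_dac: np.ndarray,
    cov: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Raw AST/ALT/GGT from the log-linear model with correlated noise.

    log T = center + age/sex/BMI effects + beta_E * E
            + beta_GE * G * E * (sex multiplier for women) + noise.

    AST and ALT noise terms share correlation ``ast_alt_noise_corr``
    (both are hepatocellular enzymes); GGT noise is independent. The
    AST/ALT ratio is never simulated directly — it derives downstream from
    the two simulated traits.
    """
    n = g_causal.size
    female = cov["female"].to_numpy()
    ge_scale = np.where(female == 1, config.sex_effect_multiplier, 1.0)
    rho = config.ast_alt_noise_corr
    z1, z2, z3 = rng.standard_normal((3, n))
    noise = {
        "log_AST": config.trait_noise_sd["log_AST"] * z1,
        "log_ALT": config.trait_noise_sd["log_ALT"]
        * (rho * z1 + np.sqrt(1 - rho**2) * z2),
        "log_GGT": config.trait_noise_sd["log_GGT"] * z3,
    }
    out = {}
    for trait in ("log_AST", "log_ALT", "log_GGT"):
        log_t = (
            config.trait_log_center[trait]
            + config.age_effect[trait] * (cov["age"].to_numpy() - 60.0)
            + config.sex_effect[trait] * female
            + config.bmi_effect[trait] * (cov["bmi"].to_numpy() - 23.4)
            + config.beta_e[trait] * latent_dac
            + config.beta_ge[trait] * ge_scale * g_causal * latent_dac
            + noise[trait]
        )
        out[trait.removeprefix("log_")] = np.exp(log_t)
    return pd.DataFrame(out)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate the full multi-cohort synthetic study.

    Bit-reproducible for a fixed config (one seeded generator drives every
    draw in a fixed order).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    variants = _variant_frame(config, rng)
    genotypes: dict[str, GenotypeMatrix] = {}
    tables: dict[str, pd.DataFrame] = {}
    latents = []
    target_r2 = np.zeros(config.n_ld_partners)
    for c_idx, (label, n) in enumerate(zip(config.cohort_labels, config.n_subjects)):
        subject_ids = np.array([f"{label}_{i:05d}" for i in range(n)])
        gm, r2 = simulate_genotypes(config, n, rng, variants.copy(), subject_ids)
        if c_idx == 0:
            target_r2 = r2
        g_causal = gm.dosage(CAUSAL_ID).astype(float)
        quest = _simulate_questionnaire(config, c_idx, g_causal, rng)
        cov = _simulate_covariates(config, c_idx, n, rng)
        pheno = _simulate_phenotypes(
            config, g_causal, quest["latent_dac"].to_numpy(), cov, rng
        )
        table = pd.concat(
            [pd.DataFrame({"subject_id": subject_ids, "cohort": label}),
             cov, quest.drop(columns="latent_dac"), pheno],
            axis=1,
        )
        table["liver_disease"] = (
            rng.random(n) < config.liver_disease_rate
        ).astype(int)
        # plant missingness: each hit subject loses one random required field
        hit = np.flatnonzero(rng.random(n) < config.missing_rate)
        fields = rng.choice(["bmi", "age", "AST", "drinking_status"], hit.size)
        for i, f in zip(hit, fields):
            table.loc[i, f] = np.nan if f != "drinking_status" else None
        genotypes[label] = gm
        tables[label] = table
        latents.append(
            pd.DataFrame(
                {"subject_id": subject_ids, "cohort": label,
                 "latent_dac": quest["latent_dac"]}
            )
        )
    truth = TruthRecord(
        causal_variant_id=CAUSAL_ID,
        ld_partner_ids=[f"sim_ld_{i + 1}" for i in range(config.n_ld_partners)],
        ld_target_r2=target_r2,
        beta_e=dict(config.beta_e),
        beta_ge=dict(config.beta_ge),
        sex_effect_multiplier=config.sex_effect_multiplier,
        latent=pd.concat(latents, ignore_index=True),
    )
    return SimulatedStudy(genotypes, tables, truth, config)
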