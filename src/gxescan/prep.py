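"""Cohort preparation: exposure derivation, exclusion rules, trait transforms.

Input is a per-subject table with questionnaire answers, covariates and raw
liver tests; output is an analysis-ready cohort plus an exclusion ledger
recording the single primary rule that removed each dropped subject.

Expected raw columns
--------------------
subject_id, cohort, age, female (0/1), bmi, drinking_status,
frequency_category, ml_<beverage> (weekly ml; beverage in sake, shochu,
chu_hai, beer, whisky, wine), AST, ALT, GGT, liver_disease (0/1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .questionnaire import DrinkingProfile, compute_exposure

__all__ = [
    "BEVERAGE_COLUMNS",
    "TRAIT_COLUMNS",
    "PreparedCohort",
    "compute_exposure_table",
    "apply_exclusions",
    "log_transform_traits",
    "prepare_cohort",
]

#: TSV column name -> beverage vocabulary name.
BEVERAGE_COLUMNS = {
    "ml_sake": "sake",
    "ml_shochu": "shochu",
    "ml_chu_hai": "chu-hai",
    "ml_beer": "beer",
    "ml_whisky": "whisky",
    "ml_wine": "wine",
}

#: Raw liver-test columns screened by the outlier rule.
TRAIT_COLUMNS = ("AST", "ALT", "GGT")

#: Covariate / exposure columns that must be non-missing.
REQUIRED_COLUMNS = ("age", "female", "bmi", "dac", "AST", "ALT", "GGT")


@dataclass
class PreparedCohort:
    """Analysis-ready subjects plus the ledger of exclusions."""

    data: pd.DataFrame
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["subject_id", "rule", "detail"]
        )
    )
    #: (cohort, trait) -> (low, high) outlier bounds frozen at first pass
    outlier_bounds: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.data)

    @property
    def n_excluded(self) -> int:
        return len(self.exclusions)

    def exclusion_counts(self) -> pd.Series:
        """Number of subjects removed per rule."""
        return self.exclusions["rule"].value_counts()


def compute_exposure_table(raw: pd.DataFrame) -> pd.DataFrame:
    """Append WAC/DAC/drinks/tier/frequency-days columns to a raw table.

    Rows with a missing drinking status or frequency answer get missing
    exposure values (they are removed later by the missingness rule).
    """
    out = raw.copy()
    wac = np.full(len(raw), np.nan)
    dac = np.full(len(raw), np.nan)
    drinks = np.full(len(raw), np.nan)
    tier = np.full(len(raw), -1)
    freq_days = np.full(len(raw), np.nan)
    bev_cols = [c for c in BEVERAGE_COLUMNS if c in raw.columns]
    for i, row in enumerate(raw.itertuples(index=False)):
        status = getattr(row, "drinking_status", None)
        freq = getattr(row, "frequency_category", None)
        if not isinstance(status, str) or not isinstance(freq, str):
            continue
        vols = {}
        ok = True
        for col in bev_cols:
            v = getattr(row, col)
            if pd.isna(v):
                ok = False
                break
            vols[BEVERAGE_COLUMNS[col]] = float(v)
        if not ok:
            continue
        rec = compute_exposure(DrinkingProfile(status, freq, vols))
        wac[i], dac[i], drinks[i] = rec.wac, rec.dac, rec.dac_drinks
        tier[i], freq_days[i] = rec.tier, rec.frequency_days
    out["wac"] = wac
    out["dac"] = dac
    out["dac_drinks"] = drinks
    out["tier"] = tier
    out["frequency_days"] = freq_days
    return out


def apply_exclusions(
    table: pd.DataFrame,
    sd_fold: float = 4.0,
    per_cohort: bool = True,
    outlier_bounds: dict | None = None,
) -> PreparedCohort:
    """Apply the subject-level exclusion rules.

    Rules, in priority order (a dropped subject gets the first that fired):

    1. ``missing`` — any missing value among age, sex, BMI, alcohol
       exposure, or a liver test.
    2. ``outlier`` — any raw liver test strictly outside mean +/- ``sd_fold``
       SD, with mean and SD computed per trait (and per cohort) on the
       sample remaining after rule 1. Bounds are frozen from that first
       pass (and returned on the result, or injectable via
       ``outlier_bounds``), so the filter is deterministic and re-applying
       it with the frozen bounds removes nobody further.
    3. ``liver_illness`` — flagged liver disease.
    """
    if not all(c in table.columns for c in REQUIRED_COLUMNS):
        missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
        raise ValueError(f"missing required columns: {missing}")
    df = table.copy()
    records: list[tuple] = []

    miss_mask = df[list(REQUIRED_COLUMNS)].isna().any(axis=1)
    for sid in df.loc[miss_mask, "subject_id"]:
        records.append((sid, "missing", "missing required field"))
    kept = df.loc[~miss_mask].copy()

    # Outlier bounds on the post-missingness sample, raw scale.
    group_cols = ["cohort"] if (per_cohort and "cohort" in kept.columns) else []
    out_mask = pd.Series(False, index=kept.index)
    detail = pd.Series("", index=kept.index)
    groups = kept.groupby(group_cols) if group_cols else [(None, kept)]
    bounds = {} if outlier_bounds is None else dict(outlier_bounds)
    for label, sub in groups:
        label = label[0] if isinstance(label, tuple) else label
        for trait in TRAIT_COLUMNS:
            if (label, trait) in bounds:
                lo, hi = bounds[(label, trait)]
            else:
                m, s = sub[trait].mean(), sub[trait].std()
                lo, hi = m - sd_fold * s, m + sd_fold * s
                bounds[(label, trait)] = (lo, hi)
            bad = (sub[trait] < lo) | (sub[trait] > hi)
            newly = bad & ~out_mask.loc[sub.index]
            out_mask.loc[sub.index] |= bad
            detail.loc[sub.index[newly]] = f"{trait} outside mean +/- {sd_fold} SD"
    for idx in kept.index[out_mask]:
        records.append((kept.at[idx, "subject_id"], "outlier", detail.at[idx]))
    kept = kept.loc[~out_mask]

    if "liver_disease" in kept.columns:
        ill = kept["liver_disease"].fillna(0).astype(bool)
        for sid in kept.loc[ill, "subject_id"]:
            records.append((sid, "liver_illness", "reported liver illness"))
        kept = kept.loc[~ill]

    if kept.empty:
        raise ValueError("all subjects excluded; empty cohort")
    ledger = pd.DataFrame(records, columns=["subject_id", "rule", "detail"])
    return PreparedCohort(kept.reset_index(drop=True), ledger, bounds)


def log_transform_traits(cohort: PreparedCohort) -> PreparedCohort:
    """Add natural-log liver tests and the raw AST/ALT ratio.

    GGT, AST and ALT are analyzed on the natural-log scale; the AST/ALT
    ratio is computed from the raw values and left untransformed.
    """
    df = cohort.data.copy()
    for trait in TRAIT_COLUMNS:
        vals = df[trait].to_numpy(float)
        if np.any(vals <= 0):
            raise ValueError(f"nonpositive {trait} value; exclude upstream")
        df[f"log_{trait}"] = np.log(vals)
    df["ast_alt_ratio"] = df["AST"].to_numpy(float) / df["ALT"].to_numpy(float)
    return PreparedCohort(df, cohort.exclusions, cohort.outlier_bounds)


def prepare_cohort(raw: pd.DataFrame, sd_fold: float = 4.0) -> PreparedCohort:
    """Raw questionnaire + phenotype table -> analysis-ready cohort.

    Chains exposure derivation, the exclusion rules and the trait
    transforms.
    """
    table = compute_exposure_table(raw)
    cohort = apply_exclusions(table, sd_fold=sd_fold)
    return log_transform_traits(cohort)
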