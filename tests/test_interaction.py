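"""Interaction model, genome scan and genomic control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import single_cohort_config
from gxescan.config import ScanConfig
from gxescan.genotypes import GenotypeMatrix
from gxescan.interaction import (
    CollinearityError,
    InteractionModel,
    apply_genomic_control,
    fit_interaction,
    genomic_control_lambda,
    scan_genome,
)
from gxescan.prep import prepare_cohort
from gxescan.simulate import simulate_study


def _toy_data(rng, n=2000, beta_ge=0.0, noise=0.3):
    g = rng.binomial(2, 0.3, n).astype(float)
    e = np.where(rng.random(n) < 0.5, 0.0, rng.lognormal(np.log(15), 0.8, n))
    cov = pd.DataFrame(
        {"age": rng.normal(60, 10, n), "female": rng.integers(0, 2, n)}
    )
    y = (
        1.0 + 0.02 * g + 0.003 * e - 0.01 * cov["age"] + 0.1 * cov["female"]
        + beta_ge * g * e + noise * rng.standard_normal(n)
    )
    return y.to_numpy(), g, e, cov


def test_exact_null_data_gives_zero_lrt(rng):
    y, g, e, cov = _toy_data(rng, beta_ge=0.0, noise=0.0)
    # y generated exactly by H0 with zero noise -> LRT = 0, p = 1
    res = fit_interaction(y, g, e, cov)
    assert res.lrt_stat == 0.0
    assert res.p_interaction == 1.0


def test_known_interaction_recovered(rng):
    y, g, e, cov = _toy_data(rng, n=4000, beta_ge=0.004)
    res = fit_interaction(y, g, e, cov)
    assert res.beta_ge == pytest.approx(0.004, abs=3 * res.se_ge)
    assert res.p_interaction < 1e-4


def test_lrt_invariant_to_exposure_units(rng):
    """P unchanged converting E between g/day and drinks/day."""
    y, g, e, cov = _toy_data(rng, n=1500, beta_ge=0.002)
    res_g = fit_interaction(y, g, e, cov)
    res_d = fit_interaction(y, g, e / 14.0, cov)
    assert res_d.lrt_stat == pytest.approx(res_g.lrt_stat, rel=1e-9)
    assert res_d.beta_ge == pytest.approx(res_g.beta_ge * 14.0, rel=1e-9)


def test_wald_and_lrt_agree_asymptotically(rng):
    y, g, e, cov = _toy_data(rng, n=8000, beta_ge=0.003)
    res = fit_interaction(y, g, e, cov)
    lp_lrt = -np.log10(res.p_interaction)
    lp_wald = -np.log10(res.wald_p())
    assert abs(lp_lrt - lp_wald) / lp_lrt < 0.05


def test_constant_exposure_is_collinear(rng):
    y, g, _, cov = _toy_data(rng, n=500)
    with pytest.raises(CollinearityError, match="E"):
        InteractionModel(y, g, np.ones(500), cov).fit()


def test_too_few_rows_errors(rng):
    y, g, e, cov = _toy_data(rng, n=2000)
    with pytest.raises(ValueError, match="few"):
        InteractionModel(y[:6], g[:6], e[:6], cov.iloc[:6]).fit()


def test_summary_mentions_key_terms(rng):
    y, g, e, cov = _toy_data(rng, n=800)
    text = fit_interaction(y, g, e, cov).summary()
    assert "G:E" in text and "LRT" in text


def _study_scan(trait="log_ALT", **cfg_kwargs):
    cfg = single_cohort_config(1500, n_variants=60, seed=17, **cfg_kwargs)
    study = simulate_study(cfg)
    cohort = prepare_cohort(study.tables["A"])
    return study, cohort, scan_genome(
        cohort.data, study.genotypes["A"], ScanConfig(trait=trait)
    )


def test_scan_matches_single_variant_fits():
    study, cohort, table = _study_scan()
    gm = study.genotypes["A"]
    pos = {s: i for i, s in enumerate(gm.subject_ids)}
    rows = np.array([pos[s] for s in cohort.data["subject_id"]])
    for j in [0, 7, 31, 59]:
        res = fit_interaction(
            cohort.data["log_ALT"],
            gm.dosages[rows, j].astype(float),
            cohort.data["dac"],
            cohort.data[["age", "female", "bmi"]],
        )
        row = table.iloc[j]
        assert row["beta_GE"] == pytest.approx(res.beta_ge, rel=1e-6)
        assert row["se_GE"] == pytest.approx(res.se_ge, rel=1e-6)
        assert row["lrt"] == pytest.approx(res.lrt_stat, rel=1e-5, abs=1e-8)


def test_scan_deterministic_and_complete():
    study, cohort, table = _study_scan()
    table2 = scan_genome(
        cohort.data, study.genotypes["A"], ScanConfig(trait="log_ALT")
    )
    pd.testing.assert_frame_equal(table, table2)
    assert len(table) == study.genotypes["A"].n_variants  # no silent drops


def test_scan_handles_missing_dosages():
    study, cohort, _ = _study_scan()
    gm = study.genotypes["A"]
    dos = gm.dosages.copy()
    dos[:50, 5] = np.nan
    gm2 = GenotypeMatrix(dos, gm.variants, gm.subject_ids)
    table = scan_genome(cohort.data, gm2, ScanConfig(trait="log_ALT"))
    assert np.isfinite(table.iloc[5]["p"])
    # complete-case per variant: matches a direct fit on the subset
    pos = {s: i for i, s in enumerate(gm.subject_ids)}
    rows = np.array([pos[s] for s in cohort.data["subject_id"]])
    gj = dos[rows, 5]
    ok = ~np.isnan(gj)
    res = fit_interaction(
        cohort.data["log_ALT"][ok], gj[ok], cohort.data["dac"][ok],
        cohort.data.loc[ok, ["age", "female", "bmi"]],
    )
    assert table.iloc[5]["beta_GE"] == pytest.approx(res.beta_ge, rel=1e-6)


def test_sensitivity_mode_gxcov_excov_shifts_but_close():
    study, cohort, main_table = _study_scan()
    table = scan_genome(
        cohort.data, study.genotypes["A"],
        ScanConfig(trait="log_ALT", sensitivity_mode="gxcov_excov"),
    )
    assert np.isfinite(table["p"]).all()
    # augmented nulls shift estimates slightly, not wildly
    r = np.corrcoef(main_table["beta_GE"], table["beta_GE"])[0, 1]
    assert r > 0.8


def test_sex_restricted_scan_drops_sex_covariate():
    study, cohort, _ = _study_scan()
    cfg = ScanConfig(trait="log_ALT", sex_restriction="male")
    assert "female" not in cfg.effective_covariates()
    table = scan_genome(cohort.data, study.genotypes["A"], cfg)
    n_male = (cohort.data["female"] == 0).sum()
    assert (table["n"] == n_male).all()


def test_genomic_control_null_and_scaling(rng):
    stats_null = stats.chi2.rvs(1, size=10_000, random_state=42)
    lam, (lo, hi) = genomic_control_lambda(stats_null)
    assert 0.95 < lam < 1.05
    assert lo <= lam <= hi
    lam2, _ = genomic_control_lambda(2.0 * stats_null)
    assert lam2 == pytest.approx(2 * lam, rel=1e-9)
    with pytest.raises(ValueError):
        genomic_control_lambda(np.array([]))


def test_apply_genomic_control_contract():
    x = np.array([7.879, 1.0, 0.1])
    p0 = stats.chi2.sf(x, 1)
    # lambda = 1: identity
    x1, p1 = apply_genomic_control(x, 1.0)
    assert np.allclose(x1, x) and np.allclose(p1, p0)
    # lambda = 2: statistic halves, p recomputed from the chi-square tail
    x2, p2 = apply_genomic_control(x, 2.0)
    assert x2[0] == pytest.approx(3.9395)
    assert p2[0] == pytest.approx(stats.chi2.sf(3.9395, 1))
    assert (p2 >= p0).all()  # monotone deflation
    # lambda < 1: floored at 1, no change
    x3, p3 = apply_genomic_control(x, 0.8)
    assert np.allclose(x3, x) and np.allclose(p3, p0)
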