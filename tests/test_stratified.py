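"""Adjusted traits, Jonckheere-Terpstra trend test, tier contrasts."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gxescan.stratified import (
    compare_vs_reference,
    compute_adjusted_trait,
    jonckheere_terpstra,
    jt_statistic,
    significance_stars,
    stratified_report,
)


def _cohort(rng, n=600, covariate_effects=True):
    age = rng.normal(60, 10, n)
    female = rng.integers(0, 2, n)
    bmi = rng.normal(23, 3, n)
    g = rng.binomial(2, 0.2, n).astype(float)
    tier = rng.integers(0, 5, n)
    y = 25 + 0.3 * g + rng.normal(0, 2, n)
    if covariate_effects:
        y = y + 0.1 * (age - 60) - 1.5 * female + 0.4 * (bmi - 23)
    return (
        pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "age": age,
                "female": female,
                "bmi": bmi,
                "tier": tier,
                "ALT": y,
            }
        ),
        g,
    )


def test_adjusted_mean_equals_raw_mean(rng):
    cohort, g = _cohort(rng)
    adj = compute_adjusted_trait(cohort, g, "ALT")
    included = np.isin(np.round(g), (0, 1))
    raw_mean = cohort.loc[included, "ALT"].mean()
    assert adj["adjusted"].mean() == pytest.approx(raw_mean, abs=1e-10)
    # minor-allele homozygotes excluded
    assert set(adj["genotype_group"]) <= {"GG", "GA"}
    assert len(adj) == included.sum()


def test_adjustment_removes_covariate_signal(rng):
    cohort, g = _cohort(rng, covariate_effects=True)
    adj = compute_adjusted_trait(cohort, g, "ALT")
    sub = cohort.set_index("subject_id").loc[adj["subject_id"]]
    r = np.corrcoef(adj["adjusted"], sub["age"])[0, 1]
    assert abs(r) < 0.1


def test_adjusted_invariant_to_covariate_shift(rng):
    cohort, g = _cohort(rng)
    shifted = cohort.copy()
    shifted["age"] = shifted["age"] + 1000.0
    a = compute_adjusted_trait(cohort, g, "ALT")
    b = compute_adjusted_trait(shifted, g, "ALT")
    assert np.allclose(a["adjusted"], b["adjusted"], atol=1e-8)


def test_no_covariate_effect_adjusted_close_to_raw(rng):
    cohort, g = _cohort(rng, covariate_effects=False)
    adj = compute_adjusted_trait(cohort, g, "ALT")
    sub = cohort.set_index("subject_id").loc[adj["subject_id"]]
    r = np.corrcoef(adj["adjusted"], sub["ALT"])[0, 1]
    assert r > 0.98


def jt_permutation_oracle(groups):
    """One-sided (increasing) P by exhaustive permutation over assignments."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    j_obs = jt_statistic([np.asarray(g, float) for g in groups])
    count = total = 0

    def recurse(remaining, depth, chosen):
        nonlocal count, total
        if depth == len(sizes) - 1:
            stat = jt_statistic(chosen + [pooled[list(remaining)]])
            total += 1
            if stat >= j_obs - 1e-9:
                count += 1
            return
        for idx in combinations(remaining, sizes[depth]):
            rest = tuple(i for i in remaining if i not in set(idx))
            recurse(rest, depth + 1, chosen + [pooled[list(idx)]])

    recurse(tuple(range(pooled.size)), 0, [])
    return count / total


def test_jt_all_identical_values():
    groups = [np.ones(5), np.ones(4), np.ones(6)]
    assert jonckheere_terpstra(groups) == 1.0


def test_jt_exact_matches_permutation_oracle():
    groups = [np.array([1.0, 2.0]), np.array([3.0, 4.0]), np.array([5.0, 6.0])]
    p = jonckheere_terpstra(groups, alternative="increasing", method="exact")
    assert p == pytest.approx(jt_permutation_oracle(groups), abs=1e-12)
    # a tied configuration
    groups2 = [np.array([1.0, 2.0, 2.0]), np.array([2.0, 3.0]), np.array([3.0, 5.0])]
    p2 = jonckheere_terpstra(groups2, alternative="increasing", method="exact")
    assert p2 == pytest.approx(jt_permutation_oracle(groups2), abs=1e-12)


def test_jt_reversal_symmetry():
    rng = np.random.default_rng(2)
    groups = [rng.normal(i, 1, 8) for i in range(4)]
    p_inc = jonckheere_terpstra(groups, alternative="increasing")
    p_dec = jonckheere_terpstra(groups[::-1], alternative="decreasing")
    assert p_inc == pytest.approx(p_dec, rel=1e-9)


def test_jt_statistic_decomposes_into_mann_whitney(rng):
    groups = [rng.normal(i * 0.3, 1, 30) for i in range(4)]
    j = jt_statistic(groups)
    total = 0.0
    for a, b in combinations(groups, 2):
        total += stats.mannwhitneyu(b, a, alternative="two-sided").statistic
    assert j == pytest.approx(total)


def test_jt_asymptotic_close_to_exact_on_small_sample(rng):
    groups = [rng.normal(i, 1, 4) for i in range(3)]
    p_exact = jonckheere_terpstra(groups, method="exact")
    p_asym = jonckheere_terpstra(groups, method="asymptotic")
    assert p_asym == pytest.approx(p_exact, abs=0.08)


def test_jt_input_validation():
    with pytest.raises(ValueError):
        jonckheere_terpstra([np.array([1.0, 2.0])])
    with pytest.raises(ValueError):
        jonckheere_terpstra([np.array([1.0]), np.array([])])
    with pytest.raises(ValueError):
        jonckheere_terpstra([np.ones(3), np.ones(3)], alternative="sideways")


def test_rank_sum_identical_and_exact():
    assert compare_vs_reference(np.ones(5), np.ones(7)) == 1.0
    # exact two-sided: P({1,2,3} vs {4,5,6}) = 2/C(6,3) = 0.1
    p = compare_vs_reference(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
    assert p == pytest.approx(0.1, abs=1e-12)
    with pytest.raises(ValueError):
        compare_vs_reference(np.array([]), np.ones(3))


def test_significance_star_bands():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.004) == "**"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.2) == ""


def _adjusted_table(rng, ga_slope=0.0, gg_slope=0.0, n_per=40):
    rows = []
    for group, slope in (("GG", gg_slope), ("GA", ga_slope)):
        for tier in range(5):
            vals = 25 + slope * tier + rng.normal(0, 2, n_per)
            for v in vals:
                rows.append(
                    {"subject_id": f"{group}{tier}", "trait": "ALT",
                     "adjusted": v, "genotype_group": group, "tier": tier}
                )
    return pd.DataFrame(rows)


def test_stratified_report_detects_group_specific_trend(rng):
    adj = _adjusted_table(rng, ga_slope=-1.5, gg_slope=0.0)
    report = stratified_report(adj)
    assert len(report) == 10  # 2 genotype groups x 5 tiers
    trends = report.groupby("genotype_group")["p_trend"].first()
    assert trends["GA"] < 0.05
    assert trends["GG"] > 0.05
    ga4 = report.query("genotype_group == 'GA' and tier == 4").iloc[0]
    assert ga4["p_vs_tier0"] < 0.01
    assert ga4["stars"] in ("**", "***")


def test_stratified_report_flags_single_tier_group(rng):
    adj = _adjusted_table(rng)
    adj = adj[(adj["genotype_group"] == "GG") | (adj["tier"] == 0)]
    report = stratified_report(adj)
    ga_rows = report[report["genotype_group"] == "GA"]
    assert (ga_rows["flag"] == "trend_omitted").all()
    assert ga_rows["p_trend"].isna().all()
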