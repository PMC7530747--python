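"""Inverse-variance meta-analysis, heterogeneity, alignment, significance."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gxescan.genotypes import GenotypeMatrix
from gxescan.interaction import fit_interaction
from gxescan.meta import (
    align_summaries,
    call_significance,
    heterogeneity,
    inverse_variance_meta,
    meta_analyze,
    sex_heterogeneity,
)


def test_single_study_identity():
    rec = inverse_variance_meta([(0.005, 0.001)])
    assert rec.beta_meta == pytest.approx(0.005)
    assert rec.se_meta == pytest.approx(0.001)
    assert rec.k == 1 and rec.direction == "+"
    assert math.isnan(rec.q_het)


def test_equal_se_symmetric_average():
    rec = inverse_variance_meta([(0.004, 0.002), (0.006, 0.002)])
    assert rec.beta_meta == pytest.approx(0.005)


def test_hand_computed_weights():
    # w = 1e6 and 2.5e5: beta = (4000 + 1500)/1.25e6 = 0.0044
    rec = inverse_variance_meta([(0.004, 0.001), (0.006, 0.002)])
    assert rec.beta_meta == pytest.approx(0.0044)
    assert rec.se_meta == pytest.approx(8.944e-4, rel=1e-3)


def test_nonpositive_se_rejected():
    with pytest.raises(ValueError):
        inverse_variance_meta([(0.1, 0.0)])
    with pytest.raises(ValueError):
        inverse_variance_meta([])


def test_heterogeneity_identical_effects():
    effects = [(0.01, 0.002), (0.01, 0.003)]
    beta = inverse_variance_meta(effects).beta_meta
    q, i2, p_het = heterogeneity(effects, beta)
    assert q == pytest.approx(0.0, abs=1e-20)
    assert i2 == 0.0
    assert p_het == pytest.approx(1.0)


def test_i2_floor_when_q_below_df():
    # engineer Q ~ 0.5 < k-1 = 1 -> I2 floored at 0
    effects = [(0.0, 1.0), (1.0, 1.0)]
    beta = inverse_variance_meta(effects).beta_meta
    q, i2, _ = heterogeneity(effects, beta)
    assert q == pytest.approx(0.5)
    assert i2 == 0.0


def test_p_het_equals_independent_chi2_tail():
    # for k studies, P_het must equal the chi-square upper tail at k-1 df;
    # for df=1 that is erfc(sqrt(Q/2)) — an independent closed form
    effects = [(0.0, 0.01), (0.05, 0.01)]
    beta = inverse_variance_meta(effects).beta_meta
    q, _, p_het = heterogeneity(effects, beta)
    assert p_het == pytest.approx(math.erfc(math.sqrt(q / 2.0)), rel=1e-12)


@settings(max_examples=100, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.floats(-1, 1, allow_nan=False),
            st.floats(1e-4, 10, allow_nan=False),
        ),
        min_size=1,
        max_size=6,
    )
)
def test_beta_meta_within_study_range(effects):
    rec = inverse_variance_meta(effects)
    betas = [b for b, _ in effects]
    assert min(betas) - 1e-12 <= rec.beta_meta <= max(betas) + 1e-12
    if len(effects) > 1:
        assert rec.se_meta <= min(s for _, s in effects) + 1e-15


def test_infinite_variance_study_is_ignored():
    base = inverse_variance_meta([(0.004, 0.001), (0.006, 0.002)])
    plus = inverse_variance_meta(
        [(0.004, 0.001), (0.006, 0.002), (5.0, 0.001 * 1e6)]
    )
    assert abs(plus.beta_meta - base.beta_meta) / abs(base.beta_meta) < 1e-6


def test_meta_equals_pooled_fit_on_homogeneous_halves(rng):
    """GLS equivalence: meta of two halves ~ pooled single-sample fit."""
    n = 6000
    g = rng.binomial(2, 0.3, n).astype(float)
    e = np.where(rng.random(n) < 0.5, 0, rng.lognormal(np.log(15), 0.8, n))
    y = 0.01 * g + 0.004 * e + 0.002 * g * e + 0.4 * rng.standard_normal(n)
    halves = [slice(0, n // 2), slice(n // 2, n)]
    effects = []
    for h in halves:
        res = fit_interaction(y[h], g[h], e[h])
        effects.append((res.beta_ge, res.se_ge))
    pooled = fit_interaction(y, g, e)
    rec = inverse_variance_meta(effects)
    assert abs(rec.beta_meta - pooled.beta_ge) < pooled.se_ge


def test_sex_heterogeneity_symmetry_and_null():
    same = sex_heterogeneity((0.01, 0.002), (0.01, 0.004))
    assert same.p_het == pytest.approx(1.0)
    a = sex_heterogeneity((0.01, 0.002), (-0.01, 0.003))
    b = sex_heterogeneity((-0.01, 0.003), (0.01, 0.002))
    assert a.p_het == pytest.approx(b.p_het)
    assert a.k == 2
    assert a.p_het < 0.05


def _summary(betas, ses, lrts=None, flip=None):
    m = len(betas)
    refs = ["A"] * m
    alts = ["G"] * m
    if flip:
        for i in flip:
            refs[i], alts[i] = alts[i], refs[i]
    return pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(m) * 1000 + 500,
            "ref": refs,
            "alt": alts,
            "n": 100,
            "af": 0.3,
            "beta_GE": betas,
            "se_GE": ses,
            "lrt": lrts if lrts is not None else np.ones(m),
            "p": 0.5,
            "error": False,
        }
    )


def test_align_summaries_flips_swapped_alleles():
    s1 = _summary([0.1, 0.2], [0.01, 0.01])
    s2 = _summary([0.1, -0.2], [0.01, 0.01], flip=[1])
    a1, a2 = align_summaries(s1, s2)
    assert len(a1) == 2
    assert a2["beta_GE"].iloc[1] == pytest.approx(0.2)  # sign restored
    # palindromic pair flagged ambiguous
    s3 = _summary([0.1], [0.01])
    s3.loc[0, ["ref", "alt"]] = ["A", "T"]
    s4 = s3.copy()
    a3, a4 = align_summaries(s3, s4)
    assert bool(a3["ambiguous"].iloc[0])


def test_meta_analyze_two_cohorts_matches_record_math():
    rng = np.random.default_rng(0)
    m = 200
    lrts = rng.chisquare(1, m)
    s1 = _summary(rng.normal(0, 0.01, m), np.full(m, 0.004), lrts)
    s2 = _summary(rng.normal(0, 0.01, m), np.full(m, 0.005), lrts)
    out = meta_analyze([s1, s2], gc="none")
    j = 17
    rec = inverse_variance_meta(
        [(s1["beta_GE"][j], s1["se_GE"][j]), (s2["beta_GE"][j], s2["se_GE"][j])]
    )
    assert out["beta_meta"][j] == pytest.approx(rec.beta_meta)
    assert out["p_meta"][j] == pytest.approx(rec.p_meta)
    assert out["i2"][j] == pytest.approx(rec.i2)
    assert out["direction"][j] == rec.direction


def test_significance_thresholds_are_strict():
    s = _summary([0.1, 0.1, 0.0], [0.01, 0.01, 0.01])
    meta = meta_analyze([s], gc="none")
    meta["p_meta"] = [5e-8, 4.9e-8, 2e-6]
    annotated, loci = call_significance(meta)
    assert not annotated["genome_wide"].iloc[0]  # exactly 5e-8 is not called
    assert annotated["genome_wide"].iloc[1]
    assert annotated["suggestive"].iloc[2]


def test_empty_significant_set_gives_empty_locus_table():
    s = _summary([0.0001], [0.01])
    meta = meta_analyze([s], gc="none")
    meta["p_meta"] = [0.5]
    _, loci = call_significance(meta)
    assert len(loci) == 0


def test_ld_clumping_groups_partner_variants(rng):
    n = 800
    causal = rng.binomial(2, 0.2, n).astype(float)
    partners = []
    for _ in range(3):
        flip = rng.random(n) < 0.05
        partners.append(np.where(flip, rng.binomial(2, 0.2, n), causal))
    indep = rng.binomial(2, 0.3, (n, 1)).astype(float)
    dos = np.column_stack([causal, *partners, indep])
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(5)],
            "chrom": ["12"] * 4 + ["2"],
            "pos": [100, 200, 300, 400, 100],
            "ref": "A",
            "alt": "G",
        }
    )
    gm = GenotypeMatrix(dos, variants, np.array([f"s{i}" for i in range(n)]))
    s = _summary([0.1] * 5, [0.001] * 5)
    s["chrom"] = variants["chrom"]
    s["pos"] = variants["pos"]
    meta = meta_analyze([s], gc="none")
    meta["p_meta"] = [1e-20, 1e-12, 1e-11, 1e-10, 1e-9]
    annotated, loci = call_significance(meta, genotypes=gm)
    assert len(loci) == 2
    top = loci.sort_values("min_p").iloc[0]
    assert top["lead_variant"] == "v0"
    assert top["n_variants"] == 4  # causal + 3 LD partners, one locus
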