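"""Fixed-effect inverse-variance meta-analysis with heterogeneity statistics.

Pools per-cohort interaction effects METAL-style: weights 1/SE², Cochran's
Q, I², per-study direction string, and significance calling with greedy LD
clumping of suggestive variants into loci. The same machinery applied to
sex-stratified fits within one cohort yields the male/female heterogeneity
test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .interaction import apply_genomic_control, genomic_control_lambda

__all__ = [
    "MetaRecord",
    "inverse_variance_meta",
    "heterogeneity",
    "sex_heterogeneity",
    "align_summaries",
    "meta_analyze",
    "call_significance",
    "GENOME_WIDE_P",
    "SUGGESTIVE_P",
]

GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 1e-5

_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class MetaRecord:
    """Pooled effect for one variant (or one sex contrast)."""

    beta_meta: float
    se_meta: float
    z: float
    p_meta: float
    q_het: float
    i2: float
    p_het: float
    direction: str
    k: int


def inverse_variance_meta(effects: list[tuple[float, float]]) -> MetaRecord:
    """Fixed-effect pooling of (beta, SE) pairs.

    beta_meta = sum(w_i b_i)/sum(w_i) with w_i = 1/SE_i²;
    SE_meta = sum(w_i)^(-1/2); two-sided normal P from z = beta/SE.
    A single study is returned unchanged. Heterogeneity fields are NaN for
    k < 2 (undefined), otherwise from :func:`heterogeneity`.
    """
    if len(effects) < 1:
        raise ValueError("need at least one study")
    betas = np.array([b for b, _ in effects], float)
    ses = np.array([s for _, s in effects], float)
    if np.any(ses <= 0):
        raise ValueError("standard errors must be > 0")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    direction = "".join("+" if b > 0 else "-" if b < 0 else "0" for b in betas)
    if len(effects) >= 2:
        q, i2, p_het = heterogeneity(effects, beta)
    else:
        q = i2 = p_het = float("nan")
    return MetaRecord(beta, se, float(z), p, q, i2, p_het, direction, len(effects))


def heterogeneity(
    effects: list[tuple[float, float]], beta_meta: float
) -> tuple[float, float, float]:
    """Cochran's Q, I² (%) and the heterogeneity P-value.

    Q = sum w_i (b_i - beta_meta)²; I² = max(0, (Q - (k-1))/Q) x 100;
    P_het from chi-square with k-1 df.
    """
    if len(effects) < 2:
        raise ValueError("heterogeneity undefined for k < 2")
    betas = np.array([b for b, _ in effects], float)
    ses = np.array([s for _, s in effects], float)
    w = 1.0 / ses**2
    q = float(np.sum(w * (betas - beta_meta) ** 2))
    k = len(effects)
    i2 = float(max(0.0, (q - (k - 1)) / q) * 100.0) if q > 0 else 0.0
    p_het = float(stats.chi2.sf(q, df=k - 1))
    return q, i2, p_het


def sex_heterogeneity(male: tuple[float, float], female: tuple[float, float]) -> MetaRecord:
    """Meta-analyze male and female effects; P_het tests their difference."""
    return inverse_variance_meta([male, female])


def align_summaries(
    reference: pd.DataFrame, other: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align a second summary table onto the first by chr:pos:ref:alt.

    Variants present in both are kept. A ref/alt swap relative to the
    reference flips the sign of beta; strand-ambiguous A/T and C/G pairs
    are flagged (``ambiguous`` column) rather than guessed; a non-matching
    allele pair drops the variant.
    """
    ref = reference.copy()
    ref["ambiguous"] = [
        (a.upper(), b.upper()) in _AMBIGUOUS_PAIRS
        for a, b in zip(ref["ref"], ref["alt"])
    ]
    key_ref = ref["chrom"].astype(str) + ":" + ref["pos"].astype(str)
    oth = other.copy()
    key_oth = oth["chrom"].astype(str) + ":" + oth["pos"].astype(str)
    oth = oth.set_index(key_oth.values)
    keep, flipped_rows = [], []
    for i, key in enumerate(key_ref.values):
        if key not in oth.index:
            continue
        row = oth.loc[key]
        if isinstance(row, pd.DataFrame):
            row = row.iloc[0]
        r0, a0 = ref["ref"].iat[i], ref["alt"].iat[i]
        if (row["ref"], row["alt"]) == (r0, a0):
            keep.append(i)
            flipped_rows.append(row)
        elif (row["ref"], row["alt"]) == (a0, r0):
            row = row.copy()
            row["beta_GE"] = -row["beta_GE"]
            row["ref"], row["alt"] = r0, a0
            if "af" in row:
                row["af"] = 1.0 - row["af"]
            keep.append(i)
            flipped_rows.append(row)
    aligned_ref = ref.iloc[keep].reset_index(drop=True)
    aligned_oth = pd.DataFrame(flipped_rows).reset_index(drop=True)
    aligned_oth["ambiguous"] = aligned_ref["ambiguous"].to_numpy()
    return aligned_ref, aligned_oth


def meta_analyze(
    summaries: list[pd.DataFrame],
    gc: str = "meta",
    gc_seed: int = 0,
) -> pd.DataFrame:
    """Variant-wise fixed-effect meta-analysis of per-cohort scan tables.

    ``gc`` controls genomic control placement: ``none``, ``cohort``
    (deflate each cohort's statistics before pooling), ``meta`` (deflate
    the pooled z² statistics; the default) or ``both``. Returns a table
    with pooled effect, heterogeneity statistics and GC-corrected
    ``p_meta``.
    """
    if gc not in ("none", "cohort", "meta", "both"):
        raise ValueError(f"unknown gc placement {gc!r}")
    if len(summaries) < 1:
        raise ValueError("need at least one summary table")
    tables = [summaries[0]]
    for other in summaries[1:]:
        ref_al, oth_al = align_summaries(tables[0], other)
        ids = ref_al["variant_id"].to_numpy()
        # restrict previously aligned tables to the surviving variants
        tables = [
            t.set_index("variant_id").loc[ids].reset_index() for t in tables[1:]
        ]
        tables = [ref_al] + tables + [oth_al]

    if gc in ("cohort", "both"):
        adj = []
        for t in tables:
            t = t.copy()
            lam, _ = genomic_control_lambda(t["lrt"].to_numpy())
            lam = max(lam, 1.0)
            _, p_corr = apply_genomic_control(t["lrt"].to_numpy(), lam)
            # deflating the chi-square inflates the SE by sqrt(lambda)
            t["se_GE"] = t["se_GE"] * np.sqrt(lam)
            t["p"] = p_corr
            adj.append(t)
        tables = adj

    base = tables[0]
    n_var = len(base)
    betas = np.column_stack([t["beta_GE"].to_numpy(float) for t in tables])
    ses = np.column_stack([t["se_GE"].to_numpy(float) for t in tables])
    records = []
    for i in range(n_var):
        ok = np.isfinite(betas[i]) & np.isfinite(ses[i]) & (ses[i] > 0)
        if not ok.any():
            records.append(
                MetaRecord(*(float("nan"),) * 7, direction="?" * len(tables), k=0)
            )
            continue
        rec = inverse_variance_meta(list(zip(betas[i, ok], ses[i, ok])))
        if not ok.all():
            d = list("?" * len(tables))
            for j, pos in enumerate(np.flatnonzero(ok)):
                d[pos] = rec.direction[j]
            rec.direction = "".join(d)
        records.append(rec)

    out = base[["variant_id", "chrom", "pos", "ref", "alt"]].copy()
    if "ambiguous" in base.columns:
        out["ambiguous"] = base["ambiguous"].to_numpy()
    out["k"] = [r.k for r in records]
    out["beta_meta"] = [r.beta_meta for r in records]
    out["se_meta"] = [r.se_meta for r in records]
    out["z"] = [r.z for r in records]
    out["p_meta_raw"] = [r.p_meta for r in records]
    out["q_het"] = [r.q_het for r in records]
    out["i2"] = [r.i2 for r in records]
    out["p_het"] = [r.p_het for r in records]
    out["direction"] = [r.direction for r in records]

    chi2_meta = out["z"].to_numpy() ** 2
    if gc in ("meta", "both"):
        lam_meta, ci = genomic_control_lambda(chi2_meta, seed=gc_seed)
        corrected, p_corr = apply_genomic_control(chi2_meta, lam_meta)
        out["chi2_gc"] = corrected
        out["p_meta"] = p_corr
        out.attrs["lambda_meta"] = lam_meta
        out.attrs["lambda_meta_ci"] = ci
    else:
        out["chi2_gc"] = chi2_meta
        out["p_meta"] = out["p_meta_raw"]
        out.attrs["lambda_meta"] = float("nan")
    return out


def call_significance(
    meta_table: pd.DataFrame,
    genotypes: GenotypeMatrix | None = None,
    genome_wide_p: float = GENOME_WIDE_P,
    suggestive_p: float = SUGGESTIVE_P,
    clump_r2: float = 0.1,
    clump_window_bp: int = 1_000_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag significant variants and group them into loci.

    Thresholds are strict (<). Suggestive variants are greedily clumped by
    descending significance: the most significant remaining variant leads a
    locus and absorbs variants within ``clump_window_bp`` on the same
    chromosome whose dosage R² with it is >= ``clump_r2`` (position-only
    when no genotype matrix is supplied). Returns the annotated table and
    a locus table (lead variant, n_variants, min P).
    """
    out = meta_table.copy()
    p = out["p_meta"].to_numpy(float)
    out["genome_wide"] = p < genome_wide_p
    out["suggestive"] = p < suggestive_p

    sig = out[out["suggestive"]].sort_values("p_meta")
    loci = []
    remaining = sig.index.to_list()
    locus_id = np.full(len(out), -1)
    while remaining:
        lead = remaining[0]
        lead_chrom = out.at[lead, "chrom"]
        lead_pos = out.at[lead, "pos"]
        members = [lead]
        for idx in remaining[1:]:
            if out.at[idx, "chrom"] != lead_chrom:
                continue
            if abs(out.at[idx, "pos"] - lead_pos) > clump_window_bp:
                continue
            if genotypes is not None:
                a = genotypes.dosage(out.at[lead, "variant_id"])
                b = genotypes.dosage(out.at[idx, "variant_id"])
                ok = ~np.isnan(a) & ~np.isnan(b)
                if ok.sum() < 2 or np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
                    continue
                r = np.corrcoef(a[ok], b[ok])[0, 1]
                if r * r < clump_r2:
                    continue
            members.append(idx)
        lid = len(loci)
        for idx in members:
            locus_id[out.index.get_loc(idx)] = lid
        loci.append(
            {
                "locus": lid,
                "chrom": lead_chrom,
                "lead_variant": out.at[lead, "variant_id"],
                "lead_pos": lead_pos,
                "n_variants": len(members),
                "min_p": out.at[lead, "p_meta"],
                "genome_wide": bool(out.at[lead, "genome_wide"]),
            }
        )
        remaining = [i for i in remaining if i not in members]
    out["locus"] = locus_id
    locus_table = pd.DataFrame(
        loci,
        columns=[
            "locus", "chrom", "lead_variant", "lead_pos", "n_variants",
            "min_p", "genome_wide",
        ],
    )
    return out, locus_table
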