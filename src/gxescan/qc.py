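"""Variant-level quality control and population-structure covariates.

Implements the Hardy-Weinberg exact test on genotype counts, the standard
variant filters (call rate, HWE, MAF, imputation quality), principal
components of the standardized dosage matrix, and pairwise dosage LD R².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.utils.extmath import randomized_svd

from .genotypes import GenotypeMatrix

__all__ = [
    "QCThresholds",
    "hwe_het_distribution",
    "hwe_exact_test",
    "qc_filter",
    "PCAResult",
    "pca_top_components",
    "ld_r2",
]

# Default variant-level filter thresholds: variants are retained when
# call rate >= 0.95, HWE exact P >= 1e-6, MAF >= 0.01 and, when an
# imputation quality is recorded, R2 >= 0.8.
@dataclass(frozen=True)
class QCThresholds:
    min_call_rate: float = 0.95
    min_hwe_p: float = 1e-6
    min_maf: float = 0.01
    min_imputation_r2: float = 0.8


def hwe_het_distribution(n_genotypes: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of the heterozygote count under Hardy-Weinberg.

    Conditional on ``n_genotypes`` diploid individuals and ``n_minor``
    copies of the minor allele, returns the possible heterozygote counts
    (sharing the parity of ``n_minor``) and their exact probabilities,
    computed with the stable mid-out recurrence

        P(h - 2) / P(h) = h (h - 1) / (4 (r + 1) (c + 1))

    where r and c are the implied minor/major homozygote counts at h.
    """
    if n_genotypes <= 0:
        raise ValueError("need at least one genotype")
    n_alleles = 2 * n_genotypes
    if not 0 <= n_minor <= n_genotypes * 2:
        raise ValueError("minor allele count out of range")
    if n_minor > n_alleles - n_minor:
        n_minor = n_alleles - n_minor
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    if hets.size == 1:
        return hets, np.ones(1)
    # cumulative log ratios from the smallest heterozygote count upward
    h = hets[:-1].astype(float)
    r = (n_minor - h) / 2.0  # minor-homozygote count at h
    c = n_genotypes - h - r  # major-homozygote count at h
    inc = np.log(4.0 * r * c) - np.log((h + 2.0) * (h + 1.0))
    logp = np.concatenate([[0.0], np.cumsum(inc)])
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    return hets, probs


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided Hardy-Weinberg exact test P-value from genotype counts.

    Sums, over the conditional null distribution of the heterozygote count,
    the probabilities of all outcomes no more likely than the observed one.
    Monomorphic samples return 1.
    """
    counts = (int(n_hom_ref), int(n_het), int(n_hom_alt))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be >= 0")
    n = sum(counts)
    if n == 0:
        raise ValueError("no genotypes")
    n_minor = min(2 * counts[0] + counts[1], 2 * counts[2] + counts[1])
    hets, probs = hwe_het_distribution(n, n_minor)
    p_obs = probs[hets == counts[1]]
    if p_obs.size == 0:  # inconsistent het count for the allele parity
        raise ValueError("heterozygote count inconsistent with allele counts")
    p = probs[probs <= p_obs[0] * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def _hard_calls(dosages: np.ndarray) -> np.ndarray:
    """Round dosages to 0/1/2 hard genotypes (NaN preserved)."""
    return np.round(dosages)


def qc_filter(
    genotypes: GenotypeMatrix, thresholds: QCThresholds = QCThresholds()
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Apply variant-level QC.

    Returns the filtered matrix, a per-variant info table (call rate, MAF,
    HWE P, imputation R2, pass flag) and a drop ledger naming each removed
    variant's first failing rule (rule order: call_rate, hwe, maf,
    imputation_r2). The HWE test runs on hard calls obtained by rounding
    dosages; call rate and MAF are computed on the dosages themselves.
    """
    call_rate = genotypes.call_rate()
    maf = genotypes.maf()
    hard = _hard_calls(genotypes.dosages)
    hwe_p = np.ones(genotypes.n_variants)
    for j in range(genotypes.n_variants):
        col = hard[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            hwe_p[j] = np.nan
            continue
        n_hom_ref = int(np.sum(col == 0))
        n_het = int(np.sum(col == 1))
        n_hom_alt = int(np.sum(col == 2))
        hwe_p[j] = hwe_exact_test(n_hom_ref, n_het, n_hom_alt)

    if "imputation_r2" in genotypes.variants.columns:
        imp_r2 = genotypes.variants["imputation_r2"].to_numpy(float)
    else:
        imp_r2 = np.full(genotypes.n_variants, np.nan)

    t = thresholds
    rules = [
        ("call_rate", call_rate < t.min_call_rate),
        ("hwe", ~np.isnan(hwe_p) & (hwe_p < t.min_hwe_p)),
        ("maf", maf < t.min_maf),
        ("imputation_r2", ~np.isnan(imp_r2) & (imp_r2 < t.min_imputation_r2)),
    ]
    fail_rule = np.array([""] * genotypes.n_variants, dtype=object)
    for name, mask in reversed(rules):  # earlier rules overwrite -> priority
        fail_rule[mask] = name
    keep = fail_rule == ""

    info = genotypes.variants.copy()
    info["call_rate"] = call_rate
    info["maf"] = maf
    info["hwe_p"] = hwe_p
    info["imputation_r2"] = imp_r2
    info["qc_pass"] = keep

    ledger = pd.DataFrame(
        {
            "variant_id": genotypes.variants.loc[~keep, "variant_id"].to_numpy(),
            "rule": fail_rule[~keep],
        }
    )
    return genotypes.subset_variants(keep), info, ledger


@dataclass
class PCAResult:
    """Top principal components of the standardized dosage matrix."""

    scores: np.ndarray  # subjects x k
    loadings: np.ndarray  # variants x k
    explained_variance: np.ndarray  # length k
    degenerate: np.ndarray  # length-k bool: ~zero-variance component

    def score_frame(self, subject_ids) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.scores[:, i] for i in range(self.scores.shape[1])}
        return pd.DataFrame({"subject_id": subject_ids, **cols})


def pca_top_components(
    genotypes: GenotypeMatrix, k: int = 5, random_state: int = 0
) -> PCAResult:
    """Top-k principal component scores of the standardized dosages.

    Missing dosages are mean-imputed per variant; each variant column is
    centred and scaled to unit variance (constant variants contribute
    zeros). The sign of each component is fixed by making its
    largest-magnitude loading positive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(genotypes.n_subjects, genotypes.n_variants):
        raise ValueError("k exceeds min(n_subjects, n_variants)")
    X = genotypes.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    X -= col_mean
    sd = X.std(axis=0)
    nonconst = sd > 0
    X[:, nonconst] /= sd[nonconst]
    X[:, ~nonconst] = 0.0
    U, S, Vt = randomized_svd(X, n_components=k, random_state=random_state)
    scores = U * S
    loadings = Vt.T
    for i in range(k):
        j = np.argmax(np.abs(loadings[:, i]))
        if loadings[j, i] < 0:
            loadings[:, i] *= -1
            scores[:, i] *= -1
    n = genotypes.n_subjects
    explained = S**2 / max(n - 1, 1)
    degenerate = S**2 <= 1e-12 * max(S[0] ** 2, 1.0)
    return PCAResult(scores, loadings, explained, degenerate)


def ld_r2(genotypes: GenotypeMatrix, variant_a: str, variant_b: str) -> float:
    """Squared Pearson correlation between two variants' dosages.

    Computed on subjects non-missing at both variants; symmetric in its
    arguments; errors on a constant dosage vector.
    """
    a = genotypes.dosage(variant_a)
    b = genotypes.dosage(variant_b)
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("LD undefined for constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
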