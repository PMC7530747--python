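"""Per-variant genotype x exposure interaction testing.

The test contrasts two nested ordinary-least-squares models of a liver
test Y on genotype dosage G, daily alcohol consumption E (g/day) and
covariates C:

    H0:  Y = b0 + bG G + bE E + C g
    H1:  Y = b0 + bG G + bE E + bGE G.E + C g

and evaluates the interaction coefficient bGE with the 1-df likelihood
ratio test under the Gaussian likelihood with the variance profiled out,
so  LRT = n log(RSS0 / RSS1)  ~  chi2(1).

`InteractionModel` fits one variant and returns an `InteractionResults`
object; `scan_genome` runs the same contrast across all variants of a
cohort with a vectorized residualization path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import ScanConfig
from .genotypes import GenotypeMatrix

__all__ = [
    "InteractionModel",
    "InteractionResults",
    "fit_interaction",
    "scan_genome",
    "genomic_control_lambda",
    "apply_genomic_control",
]


class CollinearityError(ValueError):
    """Design matrix is rank deficient; names the offending column."""


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    # incremental QR rank check to identify the first collinear column
    R = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(R))
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    bad = np.flatnonzero(diag < 1e-9 * scale[: diag.size])
    if bad.size:
        raise CollinearityError(
            f"design is rank deficient at column {names[bad[0]]!r}"
        )


@dataclass
class InteractionResults:
    """Fitted interaction contrast for one variant.

    ``params``/``bse`` are indexed by term name; the headline quantities
    are ``beta_ge``, ``se_ge``, ``lrt_stat`` and ``p_interaction``.
    """

    params: pd.Series
    bse: pd.Series
    loglik_null: float
    loglik_alt: float
    lrt_stat: float
    p_interaction: float
    n_used: int
    df_resid: int

    @property
    def beta_ge(self) -> float:
        return float(self.params["G:E"])

    @property
    def se_ge(self) -> float:
        return float(self.bse["G:E"])

    def wald_p(self) -> float:
        """Two-sided normal Wald P for the interaction term."""
        return float(2.0 * stats.norm.sf(abs(self.beta_ge / self.se_ge)))

    def summary(self) -> str:
        lines = [
            "G x E interaction fit (OLS, 1-df LRT)",
            f"  n = {self.n_used}, df_resid = {self.df_resid}",
            f"  loglik H0 = {self.loglik_null:.3f}, H1 = {self.loglik_alt:.3f}",
            f"  LRT = {self.lrt_stat:.4f}, P(interaction) = {self.p_interaction:.3e}",
            "",
            f"  {'term':<12}{'coef':>12}{'se':>12}",
        ]
        for name in self.params.index:
            lines.append(
                f"  {name:<12}{self.params[name]:>12.5g}{self.bse[name]:>12.5g}"
            )
        return "\n".join(lines)


class InteractionModel:
    """Nested-OLS interaction model for a single variant.

    Parameters
    ----------
    y : trait vector.
    g : alt-allele dosage vector (0..2).
    e : exposure vector (daily alcohol, g/day).
    covariates : optional DataFrame / 2-D array of adjustment covariates.
    sensitivity_mode : "main", "no_bmi" handled upstream by covariate
        choice; "gxcov_excov" adds G x covariate and E x covariate product
        terms to both nested models.
    """

    def __init__(self, y, g, e, covariates=None, sensitivity_mode: str = "main"):
        y = np.asarray(y, float)
        g = np.asarray(g, float)
        e = np.asarray(e, float)
        if covariates is None:
            C = np.empty((y.size, 0))
            cov_names: list[str] = []
        elif isinstance(covariates, pd.DataFrame):
            C = covariates.to_numpy(float)
            cov_names = list(covariates.columns)
        else:
            C = np.atleast_2d(np.asarray(covariates, float))
            if C.shape[0] != y.size:
                C = C.T
            cov_names = [f"cov{i}" for i in range(C.shape[1])]
        if not (y.size == g.size == e.size == C.shape[0]):
            raise ValueError("y, g, e and covariates must share length")
        ok = ~(
            np.isnan(y) | np.isnan(g) | np.isnan(e) | np.isnan(C).any(axis=1)
        )
        self.y, self.g, self.e, self.C = y[ok], g[ok], e[ok], C[ok]
        self.cov_names = cov_names
        self.sensitivity_mode = sensitivity_mode

    def _designs(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        n = self.y.size
        cols = [np.ones(n), self.g, self.e]
        names = ["const", "G", "E"]
        for j, name in enumerate(self.cov_names):
            cols.append(self.C[:, j])
            names.append(name)
        if self.sensitivity_mode == "gxcov_excov":
            for j, name in enumerate(self.cov_names):
                cols.append(self.g * self.C[:, j])
                names.append(f"G:{name}")
            for j, name in enumerate(self.cov_names):
                cols.append(self.e * self.C[:, j])
                names.append(f"E:{name}")
        X0 = np.column_stack(cols)
        X1 = np.column_stack(cols + [self.g * self.e])
        return X0, X1, names + ["G:E"]

    def fit(self) -> InteractionResults:
        X0, X1, names = self._designs()
        n = self.y.size
        if n <= X1.shape[1] + 2:
            raise ValueError(f"too few complete rows (n={n}) for the design")
        _check_full_rank(X1, names)
        fit0 = sm.OLS(self.y, X0).fit()
        fit1 = sm.OLS(self.y, X1).fit()
        # null model fitting to machine precision: no information in the
        # likelihood ratio (profiled variance degenerates)
        if fit0.ssr <= 1e-12 * max(float(self.y @ self.y), 1e-300):
            lrt = 0.0
        else:
            lrt = max(2.0 * (fit1.llf - fit0.llf), 0.0)
        p = float(stats.chi2.sf(lrt, df=1))
        return InteractionResults(
            params=pd.Series(fit1.params, index=names),
            bse=pd.Series(fit1.bse, index=names),
            loglik_null=float(fit0.llf),
            loglik_alt=float(fit1.llf),
            lrt_stat=float(lrt),
            p_interaction=min(max(p, np.nextafter(0, 1)), 1.0),
            n_used=n,
            df_resid=int(fit1.df_resid),
        )


def fit_interaction(y, g, e, covariates=None, sensitivity_mode="main") -> InteractionResults:
    """Convenience wrapper: build the model and fit it."""
    return InteractionModel(y, g, e, covariates, sensitivity_mode).fit()


def _scan_fast(y, E, C, dosage_block):
    """Vectorized nested-OLS LRT over a block of variants.

    All variant-independent columns (intercept, covariates, E) are
    projected out once by QR; per variant only the 1- and 2-column
    regressions of the residualized trait on residualized G and G.E
    remain, solved in closed form.
    """
    n = y.size
    X = np.column_stack([np.ones(n), C, E])
    Q, _ = np.linalg.qr(X)
    yp = y - Q @ (Q.T @ y)
    G = dosage_block
    GE = G * E[:, None]
    Gp = G - Q @ (Q.T @ G)
    GEp = GE - Q @ (Q.T @ GE)
    Syy = yp @ yp
    Sgg = np.einsum("ij,ij->j", Gp, Gp)
    See = np.einsum("ij,ij->j", GEp, GEp)
    Sge = np.einsum("ij,ij->j", Gp, GEp)
    Sgy = Gp.T @ yp
    Sey = GEp.T @ yp
    with np.errstate(divide="ignore", invalid="ignore"):
        rss0 = Syy - Sgy**2 / Sgg
        det = Sgg * See - Sge**2
        beta_g = (See * Sgy - Sge * Sey) / det
        beta_ge = (Sgg * Sey - Sge * Sgy) / det
        rss1 = Syy - (beta_g * Sgy + beta_ge * Sey)
        p_full = X.shape[1] + 2
        sigma2 = rss1 / (n - p_full)
        se_ge = np.sqrt(sigma2 * Sgg / det)
        lrt = n * np.log(rss0 / rss1)
    scale = Sgg.max(initial=1.0)
    bad = (Sgg <= 1e-10 * max(scale, 1.0)) | (det <= 1e-12 * Sgg * See) | ~np.isfinite(lrt)
    perfect_null = rss0 <= 1e-12 * max(Syy, 1e-300)
    lrt = np.where(perfect_null, 0.0, lrt)
    lrt = np.clip(lrt, 0.0, None)
    return beta_ge, se_ge, lrt, bad


def scan_genome(
    cohort: pd.DataFrame,
    genotypes: GenotypeMatrix,
    config: ScanConfig,
    pc_scores: pd.DataFrame | None = None,
    block_size: int = 512,
) -> pd.DataFrame:
    """Genome-wide interaction scan for one cohort.

    ``cohort`` is a prepared subject table (complete cases) with the trait,
    ``dac`` and covariate columns; subjects are matched to the genotype
    matrix by ``subject_id``. Returns one row per variant with the
    interaction estimate, the 1-df LRT and its P-value; variants whose fit
    is degenerate (monomorphic or collinear in the analysis sample) are
    flagged in the ``error`` column, not dropped.
    """
    df = cohort
    if config.sex_restriction == "male":
        df = df[df["female"] == 0]
    elif config.sex_restriction == "female":
        df = df[df["female"] == 1]
    df = df.reset_index(drop=True)
    if pc_scores is not None:
        df = df.merge(pc_scores, on="subject_id", how="left")
    cov_cols = config.effective_covariates() + (
        [f"PC{i + 1}" for i in range(config.n_pcs)] if pc_scores is not None else []
    )
    pos_of = {s: i for i, s in enumerate(genotypes.subject_ids)}
    try:
        rows = np.array([pos_of[s] for s in df["subject_id"]])
    except KeyError as exc:
        raise ValueError(f"subject missing from genotype matrix: {exc}") from exc

    y = df[config.trait].to_numpy(float)
    E = df["dac"].to_numpy(float)
    C = df[cov_cols].to_numpy(float) if cov_cols else np.empty((len(df), 0))
    n = y.size

    m = genotypes.n_variants
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    lrt = np.full(m, np.nan)
    err = np.zeros(m, dtype=bool)

    if config.sensitivity_mode == "gxcov_excov":
        covdf = df[cov_cols]
        for j in range(m):
            gj = genotypes.dosages[rows, j].astype(float)
            try:
                res = InteractionModel(y, gj, E, covdf, "gxcov_excov").fit()
                beta[j], se[j], lrt[j] = res.beta_ge, res.se_ge, res.lrt_stat
            except (ValueError, np.linalg.LinAlgError):
                err[j] = True
    else:
        for start in range(0, m, block_size):
            stop = min(start + block_size, m)
            block = genotypes.dosages[np.ix_(rows, np.arange(start, stop))].astype(
                float
            )
            if np.isnan(block).any():
                # complete-case per variant for columns with missing dosages
                has_nan = np.isnan(block).any(axis=0)
                for k in np.flatnonzero(has_nan):
                    gk = block[:, k]
                    ok = ~np.isnan(gk)
                    b, s, l, bad = _scan_fast(y[ok], E[ok], C[ok], gk[ok, None])
                    beta[start + k], se[start + k], lrt[start + k] = b[0], s[0], l[0]
                    err[start + k] = bad[0]
                cols = np.flatnonzero(~has_nan)
                if cols.size:
                    b, s, l, bad = _scan_fast(y, E, C, block[:, cols])
                    beta[start + cols] = b
                    se[start + cols] = s
                    lrt[start + cols] = l
                    err[start + cols] = bad
            else:
                b, s, l, bad = _scan_fast(y, E, C, block)
                beta[start:stop], se[start:stop], lrt[start:stop] = b, s, l
                err[start:stop] = bad

    p = stats.chi2.sf(lrt, df=1)
    af = np.nanmean(genotypes.dosages[rows, :], axis=0) / 2.0
    out = genotypes.variants[["variant_id", "chrom", "pos", "ref", "alt"]].copy()
    out["n"] = n
    out["af"] = af
    out["beta_GE"] = beta
    out["se_GE"] = se
    out["lrt"] = lrt
    out["p"] = p
    out["error"] = err
    out.loc[err, ["beta_GE", "se_GE", "lrt", "p"]] = np.nan
    return out


_CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)  # 0.4549...


def genomic_control_lambda(
    lrt_stats: np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
    min_variants: int = 100,
) -> tuple[float, tuple[float, float]]:
    """Genomic-control inflation factor with a bootstrap 95% CI.

    lambda = median(observed chi2) / median(chi2_1df); the CI resamples
    variants with replacement.
    """
    x = np.asarray(lrt_stats, float)
    x = x[~np.isnan(x)]
    if x.size < min_variants:
        raise ValueError(f"need >= {min_variants} variants, got {x.size}")
    lam = float(np.median(x) / _CHI2_MEDIAN_1DF)
    rng = np.random.default_rng(seed)
    boots = np.median(
        x[rng.integers(0, x.size, size=(n_boot, x.size))], axis=1
    ) / _CHI2_MEDIAN_1DF
    lo, hi = np.percentile(boots, [2.5, 97.5])
    lo, hi = min(lo, lam), max(hi, lam)
    return lam, (float(lo), float(hi))


def apply_genomic_control(
    lrt_stats: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Deflate chi-square statistics by max(lambda, 1) and recompute P.

    lambda <= 1 leaves the statistics unchanged (deflation only).
    """
    x = np.asarray(lrt_stats, float)
    corrected = x / max(lam, 1.0)
    return corrected, stats.chi2.sf(corrected, df=1)
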