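"""End-to-end orchestration: simulate -> prepare -> qc -> scan -> meta ->
stratify (-> power) with a reproducibility manifest.

Every stage communicates through plain TSV/VCF files in the run directory;
no stage mutates an upstream output. The manifest records the full
configuration, the per-stage outputs with SHA-256 checksums and subject/
variant counts, and alone suffices to reproduce a run byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import ScanConfig, SimulationConfig, TRAITS
from .interaction import genomic_control_lambda, scan_genome
from .meta import call_significance, meta_analyze
from .power import power_grid
from .prep import prepare_cohort
from .qc import pca_top_components, qc_filter
from .simulate import simulate_study
from .stratified import compute_adjusted_trait, stratified_report
from .vcfio import write_vcf_dosages

__all__ = ["RunConfig", "run_pipeline", "run_from_manifest", "export_plot_data"]

#: scan trait -> raw-scale column used in the stratified bar-plot analysis
_STRAT_COLUMN = {
    "log_ALT": "ALT",
    "log_AST": "AST",
    "log_GGT": "GGT",
    "ast_alt_ratio": "ast_alt_ratio",
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "gxescan_run"
    traits: tuple[str, ...] = TRAITS
    seed: int = 2013
    n_variants: int = 5000
    n_subjects: tuple[int, ...] = (3878, 3978)
    covariates: tuple[str, ...] = ("age", "female", "bmi")
    n_pcs: int = 5
    sensitivity_mode: str = "main"
    sex_restriction: str = "all"
    sex_stratified_scans: bool = True
    gc: str = "meta"
    genome_wide_p: float = 5e-8
    suggestive_p: float = 1e-5
    clump_r2: float = 0.1
    clump_window_bp: int = 1_000_000
    run_power: bool = False
    power_iterations: int = 200
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    def validate(self) -> None:
        bad = [t for t in self.traits if t not in TRAITS]
        if bad:
            raise ValueError(f"unknown trait(s) {bad}; choose from {TRAITS}")
        for name in ("genome_wide_p", "suggestive_p", "clump_r2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        ScanConfig(trait=self.traits[0], covariates=self.covariates,
                   sensitivity_mode=self.sensitivity_mode,
                   sex_restriction=self.sex_restriction)

    def simulation_config(self) -> SimulationConfig:
        kwargs = dict(self.simulation)
        kwargs.setdefault("seed", self.seed)
        kwargs.setdefault("n_variants", self.n_variants)
        kwargs.setdefault("n_subjects", tuple(self.n_subjects))
        if len(kwargs["n_subjects"]) != 2:
            labels = tuple(
                f"cohort{i + 1}" for i in range(len(kwargs["n_subjects"]))
            )
            kwargs.setdefault("cohort_labels", labels)
            k = len(kwargs["n_subjects"])
            kwargs.setdefault("drinker_fraction", (0.45,) * k)
            kwargs.setdefault("age_mean_sd", ((61.0, 11.0),) * k)
            kwargs.setdefault("female_fraction", (0.66,) * k)
            kwargs.setdefault("bmi_mean_sd", ((23.4, 3.5),) * k)
        return SimulationConfig(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("traits", "covariates", "n_subjects"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def export_plot_data(meta_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Manhattan- and QQ-plot-ready tables from a meta-analysis table.

    Manhattan: {chrom, pos, neglog10_p, flag}; one row per input variant.
    QQ: ranked observed -log10 P against expected quantiles
    -log10((i - 0.5)/n), with the genomic-control lambda in ``attrs``.
    """
    p = meta_table["p_meta"].to_numpy(float)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(p)
    flag = np.where(
        meta_table.get("genome_wide", p < 5e-8), "genome_wide",
        np.where(meta_table.get("suggestive", p < 1e-5), "suggestive", ""),
    )
    manhattan = pd.DataFrame(
        {
            "chrom": meta_table["chrom"],
            "pos": meta_table["pos"],
            "neglog10_p": neglog,
            "flag": flag,
        }
    )
    ok = np.isfinite(neglog)
    obs = np.sort(neglog[ok])[::-1]
    n = obs.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    qq = pd.DataFrame({"expected_neglog10_p": expected, "observed_neglog10_p": obs})
    try:
        lam, _ = genomic_control_lambda(meta_table["chi2_gc"].to_numpy())
        qq.attrs["lambda"] = lam
    except (KeyError, ValueError):
        pass
    return manhattan, qq


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage into ``config.outdir``; return the manifest dict.

    A failing stage raises with the stage name; outputs of completed
    stages remain on disk.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    def record(stage: str, files: dict[str, Path], **counts) -> None:
        manifest["stages"][stage] = {
            "files": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in files.items()},
            **counts,
        }

    def stage_guard(stage):
        class _Guard:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

        return _Guard()

    # --- simulate -----------------------------------------------------
    with stage_guard("simulate"):
        study = simulate_study(config.simulation_config())
        files = {}
        for label, gm in study.genotypes.items():
            p = out / f"genotypes_{label}.vcf"
            write_vcf_dosages(gm, p)
            files[f"vcf_{label}"] = p
        for label, table in study.tables.items():
            p = out / f"subjects_{label}.tsv"
            _write_tsv(table, p)
            files[f"subjects_{label}"] = p
        p = out / "truth.tsv"
        _write_tsv(study.truth.to_frame(), p)
        files["truth"] = p
        record("simulate", files,
               n_variants=int(study.genotypes[list(study.genotypes)[0]].n_variants),
               n_subjects={k: len(v) for k, v in study.tables.items()})

    labels = list(study.tables)

    # --- prepare ------------------------------------------------------
    with stage_guard("prepare"):
        prepared = {}
        files = {}
        for label in labels:
            cohort = prepare_cohort(study.tables[label])
            prepared[label] = cohort
            p = out / f"prepared_{label}.tsv"
            _write_tsv(cohort.data, p)
            files[f"prepared_{label}"] = p
            p = out / f"exclusions_{label}.tsv"
            _write_tsv(cohort.exclusions, p)
            files[f"exclusions_{label}"] = p
        record("prepare", files,
               retained={k: v.n_retained for k, v in prepared.items()},
               excluded={k: v.n_excluded for k, v in prepared.items()})

    # --- qc -----------------------------------------------------------
    with stage_guard("qc"):
        qc_geno, pc_frames = {}, {}
        files = {}
        for label in labels:
            gm, info, ledger = qc_filter(study.genotypes[label])
            qc_geno[label] = gm
            pca = pca_top_components(gm, k=config.n_pcs)
            pcs = pca.score_frame(gm.subject_ids)
            pc_frames[label] = pcs
            for name, df in (("variant_info", info), ("qc_dropped", ledger),
                             ("pcs", pcs)):
                p = out / f"{name}_{label}.tsv"
                _write_tsv(df, p)
                files[f"{name}_{label}"] = p
        record("qc", files,
               variants_retained={k: v.n_variants for k, v in qc_geno.items()})

    # --- scan ---------------------------------------------------------
    with stage_guard("scan"):
        scans: dict[tuple[str, str, str], pd.DataFrame] = {}
        files = {}
        sexes = ["all"]
        if config.sex_stratified_scans and config.sex_restriction == "all":
            sexes += ["male", "female"]
        for trait in config.traits:
            for label in labels:
                for sex in sexes:
                    sc = ScanConfig(
                        trait=trait, covariates=config.covariates,
                        n_pcs=config.n_pcs,
                        sensitivity_mode=config.sensitivity_mode,
                        sex_restriction=sex if sex != "all" else config.sex_restriction,
                    )
                    table = scan_genome(
                        prepared[label].data, qc_geno[label], sc,
                        pc_scores=pc_frames[label],
                    )
                    scans[(trait, label, sex)] = table
                    p = out / f"scan_{trait}_{label}_{sex}.tsv"
                    _write_tsv(table, p)
                    files[f"scan_{trait}_{label}_{sex}"] = p
        record("scan", files, traits=list(config.traits))

    # --- meta + significance + plot data ------------------------------
    with stage_guard("meta"):
        files = {}
        metas, loci = {}, {}
        for trait in config.traits:
            summaries = [scans[(trait, label, "all")] for label in labels]
            meta = meta_analyze(summaries, gc=config.gc)
            annotated, locus_table = call_significance(
                meta, genotypes=qc_geno[labels[0]],
                genome_wide_p=config.genome_wide_p,
                suggestive_p=config.suggestive_p,
                clump_r2=config.clump_r2,
                clump_window_bp=config.clump_window_bp,
            )
            metas[trait], loci[trait] = annotated, locus_table
            manhattan, qq = export_plot_data(annotated)
            for name, df in (("meta", annotated), ("loci", locus_table),
                             ("manhattan", manhattan), ("qq", qq)):
                p = out / f"{name}_{trait}.tsv"
                _write_tsv(df, p)
                files[f"{name}_{trait}"] = p
        record(
            "meta", files,
            lambda_meta={t: metas[t].attrs.get("lambda_meta") for t in metas},
            n_loci={t: len(loci[t]) for t in loci},
        )

    # --- stratified ---------------------------------------------------
    with stage_guard("stratified"):
        files = {}
        lead = _pick_lead_variant(metas, loci, config.traits)
        for trait in config.traits:
            col = _STRAT_COLUMN[trait]
            for label in labels:
                data = prepared[label].data
                gm = qc_geno[label]
                try:
                    dos_full = gm.dosage(lead)
                except KeyError:
                    continue
                pos_of = {s: i for i, s in enumerate(gm.subject_ids)}
                rows = np.array([pos_of[s] for s in data["subject_id"]])
                adj = compute_adjusted_trait(data, dos_full[rows], col)
                report = stratified_report(adj)
                p = out / f"stratified_{trait}_{label}.tsv"
                _write_tsv(report, p)
                files[f"stratified_{trait}_{label}"] = p
        record("stratified", files, lead_variant=lead)

    # --- power (optional) ---------------------------------------------
    if config.run_power:
        with stage_guard("power"):
            grid = power_grid(n_iterations=config.power_iterations,
                              seed=config.seed)
            p = out / "power_grid.tsv"
            _write_tsv(grid, p)
            record("power", {"power_grid": p})

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _pick_lead_variant(metas, loci, traits) -> str:
    """Representative variant for stratification: lead of the most
    significant locus across traits, else the overall top-P variant."""
    best, best_p = None, np.inf
    for trait in traits:
        lt = loci.get(trait)
        if lt is not None and len(lt):
            row = lt.sort_values("min_p").iloc[0]
            if row["min_p"] < best_p:
                best, best_p = row["lead_variant"], row["min_p"]
    if best is None:
        for trait in traits:
            mt = metas[trait]
            idx = mt["p_meta"].idxmin()
            if mt.loc[idx, "p_meta"] < best_p:
                best, best_p = mt.loc[idx, "variant_id"], mt.loc[idx, "p_meta"]
    return best


def run_from_manifest(manifest_path: str) -> dict:
    """Re-run a pipeline from its manifest's recorded configuration."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    raw = manifest["config"]
    for key in ("traits", "covariates", "n_subjects"):
        if isinstance(raw.get(key), list):
            raw[key] = tuple(raw[key])
    return run_pipeline(RunConfig(**raw))
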