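"""Staged orchestration of the full analysis.

Stage 1 tests each exposure's marginal association with the outcome per
stratum (GEE, sandwich SEs), pools strata by inverse-variance meta-analysis
and applies Bonferroni gating.  Stage 2 runs the marginal set test per
region and stratum.  Stage 3 runs the interaction set test only for gated
exposures, applies per-exposure FDR across regions, and combines strata by
Fisher's method for exposures significant in the pooled meta.  Stage 4
follows up FDR-significant (exposure, region) pairs with a single-variant
scan and adjusted cell means.  Every gating decision is logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from longgxe import __version__
from longgxe.gee import fit_gee, robust_test
from longgxe.meta import bh_fdr, bonferroni_threshold, fisher_combine, ivw_meta
from longgxe.regions import GenotypeMatrix, read_dosage_tsv
from longgxe.scan import adjusted_means, snp_interaction_scan
from longgxe.settest import (
    fit_null_model,
    interaction_set_test,
    marginal_set_test,
    standardize_genotypes,
    weighted_pca_adjustment,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated pipeline settings (see ``longgxe.cli`` for the YAML layout)."""

    phenotype_path: str
    genotype_paths: dict[str, tuple[str, str]]  # region -> (dosage TSV, meta TSV)
    out_dir: str
    exposures: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=lambda: ["age", "age2", "sex"])
    strata: list[str] | None = None  # values of stratum_col; None = single stratum
    stratum_col: str = "stratum"
    outcome: str = "Y"
    subject_col: str = "subject"
    alpha: float = 0.05
    fdr_level: float = 0.05
    tau: float = 0.95
    p_max: int | None = None
    pvalue_method: str = "auto"
    working: str = "exchangeable"
    seed: int = 0
    gate_nominal: bool = False  # gate at alpha instead of alpha/m

    def __post_init__(self) -> None:
        for name in ("alpha", "fdr_level"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not self.exposures:
            raise ValueError("at least one exposure is required")


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _strata_frames(
    data: pd.DataFrame, config: PipelineConfig
) -> dict[str, pd.DataFrame]:
    if config.strata is None:
        return {"all": data}
    missing = set(config.strata) - set(data[config.stratum_col].unique())
    if missing:
        raise ValueError(f"strata absent from phenotype table: {sorted(missing)}")
    return {
        s: data[data[config.stratum_col] == s].reset_index(drop=True)
        for s in config.strata
    }


def _stage1(
    frames: dict[str, pd.DataFrame], config: PipelineConfig, log: logging.Logger
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Per-stratum exposure tests, IVW meta, Bonferroni gating."""
    m = len(config.exposures)
    threshold = (
        config.alpha if config.gate_nominal else bonferroni_threshold(m, config.alpha)
    )
    log.info(
        "stage1: %d exposures per stratum; gating threshold %.6g (%s)",
        m,
        threshold,
        "nominal" if config.gate_nominal else f"Bonferroni alpha/{m}",
    )
    rows = []
    for exposure in config.exposures:
        per_stratum = {}
        for label, frame in frames.items():
            fit = fit_gee(
                frame.dropna(subset=[exposure]),
                outcome=config.outcome,
                terms=config.covariates + [exposure],
                groups=config.subject_col,
                working=config.working,
            )
            est, se, p = robust_test(fit, exposure)
            per_stratum[label] = (est, se, p)
            rows.append(
                {
                    "exposure": exposure,
                    "stratum": label,
                    "beta": est,
                    "se": se,
                    "p": p,
                    "n_subjects": fit.n_subjects,
                    "n_obs": fit.n_obs,
                    "significant": p < threshold,
                }
            )
        if len(per_stratum) >= 2:
            meta = ivw_meta([(b, s) for b, s, _ in per_stratum.values()])
            rows.append(
                {
                    "exposure": exposure,
                    "stratum": "meta",
                    "beta": meta.estimate,
                    "se": meta.se,
                    "p": meta.pvalue,
                    "n_subjects": np.nan,
                    "n_obs": np.nan,
                    "significant": meta.pvalue < threshold,
                }
            )
    table = pd.DataFrame(rows)
    gated = sorted(
        table.loc[table["significant"], "exposure"].unique()
    )  # significant anywhere (any stratum or meta)
    meta_sig = sorted(
        table.loc[
            (table["stratum"] == "meta") & table["significant"], "exposure"
        ].unique()
    )
    for exposure in config.exposures:
        status = "gated" if exposure in gated else "not gated"
        log.info("stage1 gating: %s -> %s", exposure, status)
    return table, gated, meta_sig


def _prepare_blocks(
    config: PipelineConfig,
) -> dict[str, GenotypeMatrix]:
    blocks = {}
    for region, (dosage_path, meta_path) in config.genotype_paths.items():
        blocks[region] = read_dosage_tsv(dosage_path, meta_path)
    return blocks


def _stage2(
    frames: dict[str, pd.DataFrame],
    matrices: dict[str, GenotypeMatrix],
    config: PipelineConfig,
    log: logging.Logger,
) -> pd.DataFrame:
    rows = []
    for label, frame in frames.items():
        for region, gm in matrices.items():
            sub = _subset_matrix(gm, frame[config.subject_col].unique())
            block, kept, _ = standardize_genotypes(sub)
            if not kept:
                log.warning("stage2: region %s has no usable variants", region)
                continue
            res = marginal_set_test(
                frame,
                block,
                covariates=config.covariates,
                outcome=config.outcome,
                subject_col=config.subject_col,
                region=region,
                method=config.pvalue_method,
                block_subjects=sub.subjects,
            )
            rows.append(
                {
                    "stratum": label,
                    "region": region,
                    "hypothesis": "marginal",
                    "n_subjects": res.n_subjects,
                    "p_variants": res.p_variants,
                    "Q": res.Q,
                    "p": res.pvalue,
                    "method": res.method,
                }
            )
    return pd.DataFrame(rows)


def _subset_matrix(gm: GenotypeMatrix, subjects) -> GenotypeMatrix:
    wanted = [s for s in gm.subjects if s in set(subjects)]
    idx = [gm.subjects.index(s) for s in wanted]
    return GenotypeMatrix(wanted, gm.variants, gm.dosages[idx])


def _stage3(
    frames: dict[str, pd.DataFrame],
    matrices: dict[str, GenotypeMatrix],
    gated: list[str],
    meta_sig: list[str],
    config: PipelineConfig,
    log: logging.Logger,
) -> pd.DataFrame:
    rows = []
    for exposure in gated:
        for label, frame in frames.items():
            frame = frame.dropna(subset=[exposure]).reset_index(drop=True)
            for region, gm in matrices.items():
                sub = _subset_matrix(gm, frame[config.subject_col].unique())
                block, kept, _ = standardize_genotypes(sub)
                if not kept:
                    continue
                adjustment = weighted_pca_adjustment(
                    block, tau=config.tau, p_max=config.p_max
                )
                null = fit_null_model(
                    frame,
                    outcome=config.outcome,
                    covariates=config.covariates,
                    exposure=exposure,
                    genotype_adjustment=adjustment,
                    subject_col=config.subject_col,
                    adjustment_subjects=sub.subjects,
                )
                res = interaction_set_test(
                    null,
                    block,
                    frame[exposure].to_numpy(dtype=float),
                    region=region,
                    method=config.pvalue_method,
                    block_subjects=sub.subjects,
                )
                rows.append(
                    {
                        "exposure": exposure,
                        "stratum": label,
                        "region": region,
                        "hypothesis": "interaction",
                        "n_subjects": res.n_subjects,
                        "p_variants": res.p_variants,
                        "Q": res.Q,
                        "p": res.pvalue,
                        "method": res.method,
                    }
                )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    # per-exposure FDR within each stratum's family of regions
    table["q"] = np.nan
    for (exposure, label), idx in table.groupby(["exposure", "stratum"]).groups.items():
        table.loc[idx, "q"] = bh_fdr(table.loc[idx, "p"].to_numpy())
    # Fisher meta across strata, only for exposures significant in pooled meta
    if len(frames) >= 2:
        meta_rows = []
        for exposure in [e for e in gated if e in meta_sig]:
            sub = table[table["exposure"] == exposure]
            for region in sub["region"].unique():
                ps = sub.loc[sub["region"] == region, "p"].tolist()
                if len(ps) < 2:
                    continue
                meta = fisher_combine(ps)
                meta_rows.append(
                    {
                        "exposure": exposure,
                        "stratum": "meta",
                        "region": region,
                        "hypothesis": "interaction",
                        "n_subjects": np.nan,
                        "p_variants": np.nan,
                        "Q": meta.statistic,
                        "p": meta.pvalue,
                        "method": "fisher",
                    }
                )
        if meta_rows:
            meta_table = pd.DataFrame(meta_rows)
            meta_table["q"] = np.nan
            for exposure, idx in meta_table.groupby("exposure").groups.items():
                meta_table.loc[idx, "q"] = bh_fdr(meta_table.loc[idx, "p"].to_numpy())
            table = pd.concat([table, meta_table], ignore_index=True)
    return table


def _stage4(
    frames: dict[str, pd.DataFrame],
    matrices: dict[str, GenotypeMatrix],
    hits: pd.DataFrame,
    config: PipelineConfig,
    log: logging.Logger,
    out: Path,
) -> list[str]:
    written = []
    for _, hit in hits.iterrows():
        exposure, region = hit["exposure"], hit["region"]
        for label, frame in frames.items():
            frame = frame.dropna(subset=[exposure]).reset_index(drop=True)
            gm = _subset_matrix(matrices[region], frame[config.subject_col].unique())
            scan = snp_interaction_scan(
                frame,
                gm,
                exposure=exposure,
                covariates=config.covariates,
                outcome=config.outcome,
                subject_col=config.subject_col,
                working=config.working,
            )
            scan_path = out / f"stage4_scan_{exposure}_{region}_{label}.tsv"
            scan.to_csv(scan_path, sep="\t", index=False)
            written.append(scan_path.name)
            ok = scan[scan["status"] == "ok"]
            if not ok.empty:
                top = ok.loc[ok["p_interaction"].idxmin(), "variant_id"]
                means = adjusted_means(
                    frame,
                    gm,
                    top,
                    exposure=exposure,
                    covariates=config.covariates,
                    outcome=config.outcome,
                    subject_col=config.subject_col,
                )
                means_path = out / f"stage4_means_{exposure}_{region}_{label}.tsv"
                means.to_csv(means_path, sep="\t", index=False)
                written.append(means_path.name)
                log.info(
                    "stage4: %s x %s in %s: top variant %s",
                    exposure,
                    region,
                    label,
                    top,
                )
    return written


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute stages 1-4, writing TSVs, a log and a JSON manifest.

    Returns the manifest dictionary.  An empty gated exposure set skips
    stages 3-4 with a logged explanation and exits successfully.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("longgxe.pipeline")
    log.setLevel(logging.INFO)
    log.handlers = [logging.FileHandler(out / "pipeline.log", mode="w")]
    log.handlers[0].setFormatter(logging.Formatter("%(asctime)s %(message)s"))

    pheno_path = Path(config.phenotype_path)
    if not pheno_path.exists():
        raise FileNotFoundError(f"phenotype table not found: {pheno_path}")
    data = pd.read_csv(pheno_path)
    if "age2" not in data.columns and "age" in data.columns:
        data["age2"] = data["age"] ** 2
    frames = _strata_frames(data, config)
    matrices = _prepare_blocks(config)

    stage1, gated, meta_sig = _stage1(frames, config, log)
    stage1.to_csv(out / "stage1_exposures.tsv", sep="\t", index=False)

    stage2 = _stage2(frames, matrices, config, log)
    stage2.to_csv(out / "stage2_marginal.tsv", sep="\t", index=False)

    stage4_files: list[str] = []
    if not gated:
        log.info(
            "stage3 skipped: no exposure passed the stage-1 gating rule "
            "(significance in any stratum or in the pooled meta-analysis); "
            "interaction models are only fit for gated exposures"
        )
        stage3 = pd.DataFrame()
    else:
        stage3 = _stage3(frames, matrices, gated, meta_sig, config, log)
        stage3.to_csv(out / "stage3_interaction.tsv", sep="\t", index=False)
        hits = stage3[
            (stage3["q"] < config.fdr_level) & (stage3["stratum"] != "meta")
        ]
        if hits.empty:
            log.info("stage4 skipped: no (exposure, region) pair passed FDR")
        else:
            stage4_files = _stage4(frames, matrices, hits, config, log, out)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_exposures": len(config.exposures),
        "gated_exposures": gated,
        "meta_significant_exposures": meta_sig,
        "stage3_tests": int(len(stage3)),
        "stage4_outputs": stage4_files,
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    for h in log.handlers:
        h.close()
    return manifest
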