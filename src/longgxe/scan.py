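"""Single-variant follow-up within a significant region.

Per-SNP GEE models with robust SEs for the variant, exposure and interaction
terms (dosages used additively as-is), plus covariate-adjusted genotype x
exposure cell means for display (hard-call genotype classes, subject-averaged
adjusted outcome).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from longgxe.gee import fit_gee, robust_test
from longgxe.regions import GenotypeMatrix

__all__ = ["snp_interaction_scan", "adjusted_means"]

#: dosages farther than this from the nearest integer are dropped from the
#: hard-call genotype classification used for cell means
HARD_CALL_BAND = 0.1


def _expand_to_observations(
    data: pd.DataFrame, matrix: GenotypeMatrix, subject_col: str
) -> np.ndarray:
    subj_index = pd.Series(
        np.arange(matrix.n_subjects), index=pd.Index(matrix.subjects)
    )
    missing = set(data[subject_col]) - set(matrix.subjects)
    if missing:
        raise ValueError(f"subjects absent from genotype matrix: {sorted(missing)[:5]}")
    return subj_index[data[subject_col]].to_numpy()


def snp_interaction_scan(
    data: pd.DataFrame,
    matrix: GenotypeMatrix,
    exposure: str,
    covariates: list[str],
    outcome: str = "Y",
    subject_col: str = "subject",
    working: str = "exchangeable",
) -> pd.DataFrame:
    """Fit ``Y ~ covariates + SNP + E + SNP:E`` per variant with robust SEs.

    Returns one record per variant ordered by position with the estimate,
    sandwich SE and two-sided p-value of the SNP, exposure and interaction
    terms.  Monomorphic variants are skipped (``status="monomorphic"``) and
    non-converged fits flagged, never silently dropped.
    """
    rows = _expand_to_observations(data, matrix, subject_col)
    records = []
    order = np.argsort(matrix.variants["pos"].to_numpy(), kind="stable")
    for j in order:
        meta = matrix.variants.iloc[j]
        vid = meta["variant_id"]
        dosage = matrix.dosages[rows, j]
        rec = {
            "variant_id": vid,
            "pos": int(meta["pos"]),
            "coded_allele": meta["alt"],
            "status": "ok",
        }
        finite = dosage[~np.isnan(dosage)]
        if finite.size == 0 or np.nanstd(dosage) == 0:
            rec["status"] = "monomorphic"
            records.append(rec)
            continue
        frame = data.copy()
        frame["snp"] = dosage
        try:
            fit = fit_gee(
                frame,
                outcome=outcome,
                terms=covariates + ["snp", exposure, f"snp:{exposure}"],
                groups=subject_col,
                working=working,
            )
        except np.linalg.LinAlgError:
            rec["status"] = "singular"
            records.append(rec)
            continue
        if not fit.converged:
            rec["status"] = "non_converged"
            records.append(rec)
            continue
        for label, term in (
            ("snp", "snp"),
            ("exposure", exposure),
            ("interaction", f"snp:{exposure}"),
        ):
            est, se, p = robust_test(fit, term)
            rec[f"beta_{label}"] = est
            rec[f"se_{label}"] = se
            rec[f"p_{label}"] = p
        rec["n_subjects"] = fit.n_subjects
        rec["n_obs"] = fit.n_obs
        records.append(rec)
    return pd.DataFrame(records)


def adjusted_means(
    data: pd.DataFrame,
    matrix: GenotypeMatrix,
    variant_id: str,
    exposure: str,
    covariates: list[str],
    outcome: str = "Y",
    subject_col: str = "subject",
) -> pd.DataFrame:
    """Covariate-adjusted outcome means by genotype class x exposure class.

    The adjustment model contains covariates only (no SNP, no exposure);
    each subject's exam residuals plus the grand mean are averaged, subjects
    are classified to hard-call genotype 0/1/2 (ambiguous dosages dropped)
    and to their first-exam exposure class, and cell means/counts reported.
    Empty cells appear with ``n = 0`` and missing mean.
    """
    fit = fit_gee(
        data,
        outcome=outcome,
        terms=covariates,
        groups=subject_col,
        working="independence",
    )
    grand_mean = float(data[outcome].mean())
    adjusted = fit.residuals + grand_mean
    per_subject = (
        pd.DataFrame({subject_col: fit.groups, "adj": adjusted})
        .groupby(subject_col)["adj"]
        .mean()
    )

    j = matrix.variant_ids.index(variant_id)
    dosage = pd.Series(matrix.dosages[:, j], index=pd.Index(matrix.subjects))
    hard = dosage.round()
    ambiguous = (dosage - hard).abs() > HARD_CALL_BAND
    hard[ambiguous | dosage.isna()] = np.nan

    first_exam = data.sort_values("exam").groupby(subject_col)[exposure].first()

    cells = pd.DataFrame(
        {
            "adj": per_subject,
            "genotype": hard.reindex(per_subject.index),
            "exposure": first_exam.reindex(per_subject.index),
        }
    ).dropna()
    out = []
    for g in (0, 1, 2):
        for e in (0, 1):
            sel = cells[(cells["genotype"] == g) & (cells["exposure"] == e)]
            out.append(
                {
                    "genotype": g,
                    "exposure": e,
                    "mean": float(sel["adj"].mean()) if len(sel) else np.nan,
                    "n": len(sel),
                }
            )
    return pd.DataFrame(out)
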