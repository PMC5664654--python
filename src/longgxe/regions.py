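"""Genotype containers and variant-set ("gene/region") construction.

Regions are anchored on index SNPs: if the index position falls within a
gene's most-inclusive transcript span plus a 5 kb buffer on either side, the
region is that gene's (unbuffered) span; otherwise it is a +/-50 kb window
around the index position.  Variants are then restricted by position,
imputation quality (INFO) and minor allele frequency, with strict thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "GenotypeMatrix",
    "build_region",
    "compute_maf",
    "filter_variants",
    "read_dosage_tsv",
    "read_vcf_dosages",
]

GENE_BUFFER = 5_000
WINDOW_HALF_WIDTH = 50_000

#: columns required in the per-variant metadata table
VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "info"]


@dataclass
class Region:
    """A named variant set anchored on an index SNP.

    ``start``/``end`` are 1-based inclusive; ``source`` records whether the
    span came from a containing gene or a fixed window around the index SNP.
    """

    name: str
    chrom: str
    start: int
    end: int
    source: str  # "gene" | "window"
    index_snp: str | None = None
    variant_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.name}: start > end")
        if self.source not in ("gene", "window"):
            raise ValueError(f"region {self.name}: bad source {self.source!r}")

    def contains(self, chrom: str, pos: int) -> bool:
        return str(chrom) == self.chrom and self.start <= pos <= self.end


class GenotypeMatrix:
    """Subjects x variants dosage matrix with per-variant metadata.

    Dosages are expected alternate-allele counts in [0, 2]; ``nan`` marks
    missing.  ``variants`` is a DataFrame with at least ``variant_id``,
    ``chrom``, ``pos``; ``info`` defaults to 1.0 and allele columns to
    single-base placeholders when absent.
    """

    def __init__(
        self,
        subjects: list,
        variants: pd.DataFrame,
        dosages: np.ndarray,
    ) -> None:
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(subjects), len(variants)):
            raise ValueError(
                f"dosage shape {dosages.shape} != "
                f"({len(subjects)} subjects, {len(variants)} variants)"
            )
        finite = dosages[~np.isnan(dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        variants = variants.reset_index(drop=True).copy()
        if "info" not in variants.columns:
            variants["info"] = 1.0
        if "ref" not in variants.columns:
            variants["ref"] = "A"
        if "alt" not in variants.columns:
            variants["alt"] = "C"
        missing_cols = {"variant_id", "chrom", "pos"} - set(variants.columns)
        if missing_cols:
            raise ValueError(f"variant metadata missing columns: {sorted(missing_cols)}")
        variants["chrom"] = variants["chrom"].astype(str)
        self.subjects = list(subjects)
        self.variants = variants
        self.dosages = dosages

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["variant_id"].tolist()

    def allele_frequencies(self) -> pd.DataFrame:
        """Alternate-allele frequency and MAF per variant (missing ignored)."""
        rows = []
        for j, vid in enumerate(self.variant_ids):
            f, maf = compute_maf(self.dosages[:, j], variant=vid)
            rows.append((vid, f, maf))
        return pd.DataFrame(rows, columns=["variant_id", "alt_freq", "maf"])

    def subset(self, variant_ids: list[str]) -> "GenotypeMatrix":
        """Restrict to ``variant_ids`` (kept in current positional order)."""
        keep = self.variants["variant_id"].isin(set(variant_ids)).to_numpy()
        return GenotypeMatrix(
            self.subjects,
            self.variants.loc[keep],
            self.dosages[:, keep],
        )

    def to_tsv(self, dosage_path, meta_path) -> None:
        frame = pd.DataFrame(
            self.dosages, index=pd.Index(self.subjects, name="subject"),
            columns=self.variant_ids,
        )
        frame.to_csv(dosage_path, sep="\t")
        self.variants.to_csv(meta_path, sep="\t", index=False)


def read_dosage_tsv(dosage_path, meta_path) -> GenotypeMatrix:
    """Read a dosage matrix TSV (rows=subjects) plus variant-metadata TSV."""
    frame = pd.read_csv(dosage_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t")
    order = {v: k for k, v in enumerate(frame.columns)}
    meta = meta.sort_values("variant_id", key=lambda s: s.map(order)).reset_index(
        drop=True
    )
    if list(meta["variant_id"]) != list(frame.columns):
        raise ValueError("variant metadata does not match dosage columns")
    return GenotypeMatrix(list(frame.index), meta, frame.to_numpy(dtype=float))


def read_vcf_dosages(path, region: Region | None = None) -> GenotypeMatrix:
    """Read per-sample dosages (DS format field) and INFO scores from a VCF.

    Requires ``cyvcf2``.  When ``region`` is given only records inside its
    span are loaded.  Multi-allelic records and non-SNVs are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    rows, dosage_cols = [], []
    for rec in vcf:
        if region is not None and not region.contains(rec.CHROM, rec.POS):
            continue
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue
        ds = rec.format("DS")
        if ds is None:
            gts = np.asarray(rec.gt_types, dtype=float)  # 0,1,3=hom-alt, 2=unknown
            ds = np.where(gts == 2, np.nan, np.where(gts == 3, 2.0, gts))
        else:
            ds = np.asarray(ds, dtype=float).reshape(-1)
        info = rec.INFO.get("INFO", 1.0)
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        rows.append((vid, str(rec.CHROM), rec.POS, rec.REF, rec.ALT[0], float(info)))
        dosage_cols.append(ds)
    meta = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = (
        np.column_stack(dosage_cols) if dosage_cols else np.empty((len(subjects), 0))
    )
    return GenotypeMatrix(subjects, meta, dosages)


def _collapse_transcripts(genes: pd.DataFrame) -> pd.DataFrame:
    """Most-inclusive start/stop per gene across transcripts."""
    required = {"chrom", "start", "end", "gene_id"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
    collapsed = (
        genes.astype({"chrom": str})
        .groupby(["gene_id", "chrom"], as_index=False)
        .agg(start=("start", "min"), end=("end", "max"))
    )
    return collapsed.sort_values("gene_id").reset_index(drop=True)


def build_region(
    index_snp: str,
    chrom: str,
    pos: int,
    genes: pd.DataFrame,
    buffer: int = GENE_BUFFER,
    window: int = WINDOW_HALF_WIDTH,
) -> Region:
    """Anchor a region on ``index_snp``.

    A gene (most-inclusive transcript span) wins when the index position lies
    within its span extended by ``buffer`` on either side; the region is then
    the unbuffered gene span.  With several candidates, genes whose unbuffered
    span contains the position take priority, then the nearest span boundary,
    then alphabetical gene id.  With no candidate gene the region is
    ``pos +/- window`` clamped at 1.
    """
    chrom = str(chrom)
    collapsed = _collapse_transcripts(genes)
    if chrom not in set(collapsed["chrom"]):
        raise ValueError(
            f"index SNP {index_snp}: chromosome {chrom!r} absent from annotation"
        )
    on_chrom = collapsed[collapsed["chrom"] == chrom]
    cand = on_chrom[
        (on_chrom["start"] - buffer <= pos) & (pos <= on_chrom["end"] + buffer)
    ]
    if cand.empty:
        return Region(
            name=index_snp,
            chrom=chrom,
            start=max(1, pos - window),
            end=pos + window,
            source="window",
            index_snp=index_snp,
        )
    cand = cand.copy()
    cand["inside"] = (cand["start"] <= pos) & (pos <= cand["end"])
    cand["distance"] = np.where(
        cand["inside"],
        0,
        np.minimum(np.abs(cand["start"] - pos), np.abs(cand["end"] - pos)),
    )
    cand = cand.sort_values(
        ["inside", "distance", "gene_id"], ascending=[False, True, True]
    )
    top = cand.iloc[0]
    return Region(
        name=str(top["gene_id"]),
        chrom=chrom,
        start=int(top["start"]),
        end=int(top["end"]),
        source="gene",
        index_snp=index_snp,
    )


def compute_maf(dosages: np.ndarray, variant: str = "?") -> tuple[float, float]:
    """Alternate-allele frequency (mean dosage / 2) and MAF, ignoring missing."""
    dosages = np.asarray(dosages, dtype=float)
    finite = dosages[~np.isnan(dosages)]
    if finite.size == 0:
        raise ValueError(f"variant {variant}: all dosages missing")
    f = float(np.mean(finite) / 2.0)
    return f, min(f, 1.0 - f)


def _is_biallelic_snv(ref: str, alt: str) -> bool:
    bases = {"A", "C", "G", "T"}
    return (
        isinstance(ref, str)
        and isinstance(alt, str)
        and len(ref) == 1
        and len(alt) == 1
        and ref.upper() in bases
        and alt.upper() in bases
    )


def filter_variants(
    matrix: GenotypeMatrix,
    region: Region,
    info_min: float = 0.5,
    maf_min: float = 0.01,
    snv_only: bool = True,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Restrict to variants inside ``region`` passing strict INFO/MAF filters.

    Returns the filtered matrix (positional order preserved) and a per-variant
    exclusion table with columns ``variant_id``/``reason`` (reason empty for
    retained variants).  Thresholds are strict: INFO must exceed ``info_min``
    and MAF must exceed ``maf_min``.
    """
    reasons = []
    keep_ids = []
    freqs = matrix.allele_frequencies().set_index("variant_id")["maf"]
    for _, row in matrix.variants.iterrows():
        vid = row["variant_id"]
        if not region.contains(row["chrom"], row["pos"]):
            reasons.append((vid, "outside_region"))
            continue
        if snv_only and not _is_biallelic_snv(row["ref"], row["alt"]):
            reasons.append((vid, "not_biallelic_snv"))
            continue
        if not row["info"] > info_min:
            reasons.append((vid, "low_info"))
            continue
        if not freqs[vid] > maf_min:
            reasons.append((vid, "low_maf"))
            continue
        reasons.append((vid, ""))
        keep_ids.append(vid)
    report = pd.DataFrame(reasons, columns=["variant_id", "reason"])
    if not keep_ids:
        warnings.warn(
            f"region {region.name}: no variants pass position/INFO/MAF filters",
            stacklevel=2,
        )
    out = matrix.subset(keep_ids)
    region.variant_ids = keep_ids
    return out, report
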