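"""Readers and writers for the file formats the pipeline touches.

All tabular formats are plain TSV.  Readers validate strictly and log a
count for every row they drop; they never silently coerce.  Genomic
positions are 1-based and intervals are inclusive on both ends (the
PLINK/VCF convention).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("mprsnet.io")

VALID_ALLELES = {"A", "C", "G", "T"}
DIAGNOSIS_LEVELS = ["CN", "SMC", "EMCI", "LMCI", "AD"]

__all__ = [
    "GenotypeMatrix",
    "ExpressionMatrix",
    "ModuleRecord",
    "DIAGNOSIS_LEVELS",
    "read_edge_list",
    "read_gene_scores",
    "read_sumstats",
    "read_genotypes",
    "read_annotation",
    "read_expression",
    "read_phenotypes",
    "read_gmt",
    "read_modules",
    "write_modules",
    "write_report",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals x SNPs) with per-SNP allele coding.

    ``dosages`` holds the expected count of ``counted_allele`` in [0, 2];
    missing genotypes are NaN.  Missing-data policy is decided downstream
    (score computation), not here.
    """

    individual_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray  # float, shape (n_individuals, n_snps), NaN = missing
    counted_allele: np.ndarray  # str, per SNP
    other_allele: np.ndarray  # str, per SNP

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if len(self.individual_ids) != n or len(self.snp_ids) != m:
            raise FormatError("genotype matrix dimensions inconsistent with ids")
        if len(set(self.individual_ids)) != n:
            raise FormatError("duplicate individual_id in genotype matrix")
        if len(set(self.snp_ids)) != m:
            raise FormatError("duplicate snp_id in genotype matrix")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"dosage outside [0, 2] for individual {self.individual_ids[i]!r}, "
                f"SNP {self.snp_ids[j]!r}: {self.dosages[i, j]}"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self) -> dict[str, int]:
        return {s: k for k, s in enumerate(self.snp_ids)}


@dataclass
class ExpressionMatrix:
    """Genes x samples expression for one tissue."""

    tissue_label: str
    values: pd.DataFrame  # index = gene_id, columns = sample_id

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise FormatError(f"duplicate gene_id in expression matrix {self.tissue_label!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class ModuleRecord:
    """One candidate module with (optionally) its disease-association stats."""

    module_id: str
    side: str
    genes: list[str]
    perm_p: float
    p_meta1: float = float("nan")
    p_meta2: float = float("nan")
    cohens_d: float = float("nan")
    d_ci_low: float = float("nan")
    d_ci_high: float = float("nan")

    @property
    def size(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path, header: bool = False) -> list[tuple[str, str]]:
    """Read an undirected edge list from a two-column TSV.

    Self-loops are dropped and duplicate edges (in either orientation)
    collapsed; the returned pairs are unique and lexicographically ordered
    within each pair, in first-seen order.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise FormatError(f"{path}:{lineno}: malformed edge line: {line!r}")
            a, b = parts[0].strip(), parts[1].strip()
            if a == b:
                n_self += 1
                continue
            key = (a, b) if a < b else (b, a)
            if key in seen:
                continue
            seen.add(key)
            edges.append(key)
    if n_self:
        logger.info("read_edge_list: dropped %d self-loop(s) from %s", n_self, path)
    if not edges:
        logger.warning("read_edge_list: no edges found in %s", path)
    return edges


def read_gene_scores(path: str | Path) -> pd.DataFrame:
    """Read a gene-level score table (columns ``gene_id``, ``p_value``)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "p_value"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    if df["p_value"].isna().any():
        raise FormatError(f"{path}: missing p_value")
    p = df["p_value"].to_numpy(float)
    if np.any(p <= 0) or np.any(p > 1):
        raise FormatError(f"{path}: p_value outside (0, 1]")
    return df[["gene_id", "p_value"]].reset_index(drop=True)


_SUMSTATS_DEFAULT_MAP = {
    "snp_id": "snp_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "p_value": "p_value",
}


def read_sumstats(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read disease meta-GWAS summary statistics.

    ``column_map`` maps canonical field names (snp_id, chrom, pos,
    effect_allele, other_allele, beta, p_value) to the column names in the
    file.  Alleles are upper-cased; rows with a missing beta, an invalid
    allele, or effect_allele == other_allele are dropped with a logged
    count.  Duplicate snp_ids are an error.
    """
    cmap = dict(_SUMSTATS_DEFAULT_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype={cmap["snp_id"]: str, cmap["chrom"]: str})
    missing = [k for k, v in cmap.items() if v not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing} (after column_map)")
    out = pd.DataFrame(
        {canon: df[fcol] for canon, fcol in cmap.items()}
    )
    out["effect_allele"] = out["effect_allele"].astype(str).str.upper()
    out["other_allele"] = out["other_allele"].astype(str).str.upper()

    n0 = len(out)
    out = out[out["beta"].notna()]
    n_missing_beta = n0 - len(out)
    if n_missing_beta:
        logger.info("read_sumstats: dropped %d row(s) with missing beta", n_missing_beta)

    bad_allele = (
        ~out["effect_allele"].isin(VALID_ALLELES)
        | ~out["other_allele"].isin(VALID_ALLELES)
        | (out["effect_allele"] == out["other_allele"])
    )
    if bad_allele.any():
        logger.info("read_sumstats: rejected %d row(s) with invalid allele pair", int(bad_allele.sum()))
    out = out[~bad_allele]

    if out["snp_id"].duplicated().any():
        dup = out.loc[out["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise FormatError(f"{path}: duplicate snp_id {dup!r}")
    out["pos"] = out["pos"].astype(np.int64)
    if (out["pos"] < 1).any():
        raise FormatError(f"{path}: pos must be >= 1 (1-based coordinates)")
    return out.reset_index(drop=True)


def read_genotypes(
    path: str | Path,
    format: str = "dosage_tsv",
    sidecar: str | Path | None = None,
) -> GenotypeMatrix:
    """Read genotypes from a dosage TSV (+ allele sidecar) or a VCF.

    dosage_tsv: individuals in rows (first column ``individual_id``), SNPs
    in columns; sidecar TSV with columns snp_id, counted_allele,
    other_allele.  "NA"/"." denote missing.  VCF: the ALT allele is
    counted; multi-allelic records are rejected.
    """
    if format == "dosage_tsv":
        if sidecar is None:
            sidecar = Path(str(path) + ".alleles.tsv")
        df = pd.read_csv(path, sep="\t", dtype={"individual_id": str}, na_values=["NA", "."])
        if "individual_id" not in df.columns:
            raise FormatError(f"{path}: first column must be 'individual_id'")
        side = pd.read_csv(sidecar, sep="\t", dtype=str)
        for col in ("snp_id", "counted_allele", "other_allele"):
            if col not in side.columns:
                raise FormatError(f"{sidecar}: missing column {col!r}")
        snp_ids = [c for c in df.columns if c != "individual_id"]
        if set(snp_ids) != set(side["snp_id"]):
            raise FormatError(f"{path}: SNP columns do not match sidecar snp_ids")
        side = side.set_index("snp_id").loc[snp_ids]
        dosages = df[snp_ids].to_numpy(float)
        return GenotypeMatrix(
            individual_ids=df["individual_id"].tolist(),
            snp_ids=snp_ids,
            dosages=dosages,
            counted_allele=side["counted_allele"].str.upper().to_numpy(),
            other_allele=side["other_allele"].str.upper().to_numpy(),
        )
    elif format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    individual_ids = list(vcf.samples)
    snp_ids: list[str] = []
    counted: list[str] = []
    other: list[str] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(f"{path}: multi-allelic record at {rec.CHROM}:{rec.POS}")
        snp_ids.append(rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}")
        counted.append(rec.ALT[0].upper())
        other.append(rec.REF.upper())
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types.astype(float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        rows.append(dos)
    dosages = np.array(rows, dtype=float).T if rows else np.empty((len(individual_ids), 0))
    return GenotypeMatrix(
        individual_ids=individual_ids,
        snp_ids=snp_ids,
        dosages=dosages,
        counted_allele=np.array(counted, dtype=object),
        other_allele=np.array(other, dtype=object),
    )


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation table (gene_id, chrom, start, end; 1-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    for col in ("gene_id", "chrom", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if df["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene_id")
    if (df["start"] > df["end"]).any():
        raise FormatError(f"{path}: start > end")
    if (df["start"] < 1).any():
        raise FormatError(f"{path}: start must be >= 1 (1-based coordinates)")
    return df[["gene_id", "chrom", "start", "end"]].reset_index(drop=True)


def read_expression(path: str | Path, tissue_label: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples expression TSV (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    label = tissue_label if tissue_label is not None else Path(path).stem
    return ExpressionMatrix(tissue_label=label, values=df)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the phenotype table; validates diagnosis levels and conversion fields."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str}, na_values=["NA", "."])
    required = [
        "individual_id", "diagnosis", "age", "sex", "education",
        "amyg_left", "amyg_right", "conv_months", "conv_event",
    ]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    bad = ~df["diagnosis"].isin(DIAGNOSIS_LEVELS)
    if bad.any():
        raise FormatError(f"{path}: invalid diagnosis value {df.loc[bad, 'diagnosis'].iloc[0]!r}")
    ev1 = df["conv_event"] == 1
    if (ev1 & df["conv_months"].isna()).any():
        raise FormatError(f"{path}: conv_event=1 requires conv_months")
    if (df["conv_months"].dropna() < 0).any():
        raise FormatError(f"{path}: conv_months must be non-negative")
    return df


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT gene-set file: set_id -> (description, genes)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            set_id, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: empty gene set {set_id!r}")
            if set_id in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set_id {set_id!r}")
            sets[set_id] = (desc, genes)
    return sets


# ---------------------------------------------------------------------------
# module / report writers
# ---------------------------------------------------------------------------

_MODULE_COLUMNS = [
    "module_id", "side", "size", "genes", "perm_p",
    "p_meta1", "p_meta2", "cohens_d", "d_ci_low", "d_ci_high",
]


def write_modules(modules: list[ModuleRecord], path: str | Path, metadata: dict | None = None) -> None:
    """Write modules as TSV plus a JSON sidecar with full metadata."""
    path = Path(path)
    rows = [
        {
            "module_id": m.module_id,
            "side": m.side,
            "size": m.size,
            "genes": ",".join(m.genes),
            "perm_p": m.perm_p,
            "p_meta1": m.p_meta1,
            "p_meta2": m.p_meta2,
            "cohens_d": m.cohens_d,
            "d_ci_low": m.d_ci_low,
            "d_ci_high": m.d_ci_high,
        }
        for m in modules
    ]
    pd.DataFrame(rows, columns=_MODULE_COLUMNS).to_csv(path, sep="\t", index=False)
    meta = dict(metadata or {})
    meta["n_modules"] = len(modules)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def read_modules(path: str | Path) -> list[ModuleRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"module_id": str, "side": str, "genes": str})
    out = []
    for _, r in df.iterrows():
        rec = ModuleRecord(
            module_id=r["module_id"],
            side=r["side"],
            genes=str(r["genes"]).split(",") if pd.notna(r["genes"]) else [],
            perm_p=float(r["perm_p"]),
            p_meta1=float(r["p_meta1"]),
            p_meta2=float(r["p_meta2"]),
            cohens_d=float(r["cohens_d"]),
            d_ci_low=float(r["d_ci_low"]),
            d_ci_high=float(r["d_ci_high"]),
        )
        if rec.size != int(r["size"]):
            raise FormatError(f"{path}: size field disagrees with gene list for {rec.module_id}")
        out.append(rec)
    return out


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    """Write an analysis report table as TSV."""
    report.to_csv(path, sep="\t", index=False)
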