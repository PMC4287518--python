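"""Core data model: sample sheet, genotype/methylation/expression matrices.

Matrices are held samples x features in memory (pandas DataFrames indexed by
sample id) together with a per-feature annotation table indexed by feature id.
On disk every matrix is a TSV with features in rows: first column the feature
id, remaining columns sample ids; missing values are written as "NA" (and "."
is also accepted on read). All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUPS = ("fetal", "adult")
TISSUES = ("liver", "muscle", "SAT", "VAT")
CGI_RELATIONS = ("island", "shore", "shelf", "other")
BODY_REGIONS = ("TSS-proximal", "exon", "intron", "intergenic")

_NA_VALUES = ["NA", "."]


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet (columns sample_id, cohort, group, tissue).

    Extra columns (e.g. the donor individual behind multiple tissue samples)
    are preserved.
    """
    required = ["sample_id", "cohort", "group", "tissue"]
    missing = [c for c in required if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dups[:5]}")
    if sheet[required].isna().any().any():
        raise ValueError("sample sheet has partially annotated samples")
    bad_group = set(sheet["group"]) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown group labels: {sorted(bad_group)}")
    bad_tissue = set(sheet["tissue"]) - set(TISSUES)
    if bad_tissue:
        raise ValueError(f"unknown tissue labels: {sorted(bad_tissue)}")
    return sheet.reset_index(drop=True)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path, sep="\t", dtype=str))


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# matrix containers
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Samples x features values plus a feature annotation table."""

    values: pd.DataFrame           # index: sample_id, columns: feature ids
    annotation: pd.DataFrame       # index: feature id

    def __post_init__(self) -> None:
        if self.annotation.index.duplicated().any():
            raise ValueError("duplicate feature ids in annotation")
        if not self.values.columns.equals(self.annotation.index):
            extra = self.values.columns.difference(self.annotation.index)
            if len(extra):
                raise ValueError(f"features without annotation: {list(extra[:5])}")
            self.annotation = self.annotation.loc[self.values.columns]

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, sample_ids: Sequence[str]):
        return type(self)(self.values.loc[list(sample_ids)], self.annotation)

    def subset_features(self, feature_ids: Sequence[str]):
        ids = list(feature_ids)
        return type(self)(self.values[ids], self.annotation.loc[ids])


class GenotypeMatrix(FeatureMatrix):
    """Allele dosages in {0,1,2} (float to allow missing=NaN).

    Annotation columns: chrom, pos, effect_allele, other_allele, maf.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = self.values.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0/1/2 or missing")
        if "maf" in self.annotation.columns:
            maf = self.annotation["maf"].to_numpy(dtype=float)
            if np.nanmin(maf, initial=0.0) < 0 or np.nanmax(maf, initial=0.0) > 0.5:
                raise ValueError("maf must lie in [0, 0.5]")
        if (self.annotation["pos"].to_numpy(dtype=float) <= 0).any():
            raise ValueError("SNP positions must be positive")

    @property
    def dosages(self) -> pd.DataFrame:
        return self.values

    @property
    def snps(self) -> pd.DataFrame:
        return self.annotation


class MethylationMatrix(FeatureMatrix):
    """Beta values in [0,1]; annotation: chrom, pos, cgi_relation, gene,
    body_region, interval_start, interval_end (the 50 bp probe footprint)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = self.values.to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if np.nanmin(vals, initial=0.5) < 0 or np.nanmax(vals, initial=0.5) > 1:
                raise ValueError("beta values must lie in [0, 1]")
        if "cgi_relation" in self.annotation.columns:
            bad = set(self.annotation["cgi_relation"].dropna()) - set(CGI_RELATIONS)
            if bad:
                raise ValueError(f"unknown cgi_relation labels: {sorted(bad)}")

    @property
    def betas(self) -> pd.DataFrame:
        return self.values

    @property
    def cpgs(self) -> pd.DataFrame:
        return self.annotation


class ExpressionMatrix(FeatureMatrix):
    """log2 intensities; annotation: chrom, start, end, gene, tss."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("expression values must be finite")

    @property
    def probes(self) -> pd.DataFrame:
        return self.annotation


# ---------------------------------------------------------------------------
# TSV IO
# ---------------------------------------------------------------------------

def write_matrix(values: pd.DataFrame, path: str | Path, feature_col: str = "feature_id") -> None:
    """Write a samples x features frame as a features-in-rows TSV."""
    out = values.T
    out.index.name = feature_col
    out.to_csv(path, sep="\t", na_rep="NA")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a features-in-rows TSV back to a samples x features frame."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=_NA_VALUES)
    return df.T


def write_annotation(ann: pd.DataFrame, path: str | Path, feature_col: str = "feature_id") -> None:
    out = ann.copy()
    out.index.name = feature_col
    out.to_csv(path, sep="\t", na_rep="NA")


def read_annotation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=_NA_VALUES)


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Read genotypes from a VCF; dosage counts the ALT (effect) allele."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, rows, ann = [], [], []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        gts = np.asarray(var.gt_types, dtype=float)  # 0=homref,1=het,2=unknown,3=homalt
        dos = np.where(gts == 3, 2.0, gts)
        dos[gts == 2] = np.nan
        ids.append(vid)
        rows.append(dos)
        alt = var.ALT[0] if var.ALT else "."
        p = np.nanmean(dos) / 2 if np.isfinite(dos).any() else np.nan
        ann.append({"chrom": var.CHROM, "pos": var.POS, "effect_allele": alt,
                    "other_allele": var.REF, "maf": min(p, 1 - p) if p == p else np.nan})
    values = pd.DataFrame(np.array(rows).T if rows else np.empty((len(samples), 0)),
                          index=samples, columns=ids)
    annotation = pd.DataFrame(ann, index=ids)
    return GenotypeMatrix(values, annotation)
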