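"""Feature and SNP quality filters.

Defaults: variable-CpG filter keeps CpGs with beta SD >= 0.02 across samples;
SNP QC keeps MAF >= 0.05, HWE exact-test p >= 1e-6 and missingness <= 5%.
All filters are idempotent. The HWE exact test is the standard conditional
(on allele counts) two-sided test summing genotype configurations no more
probable than the observed one.
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, MethylationMatrix

log = logging.getLogger(__name__)

DEFAULT_MIN_BETA_SD = 0.02
DEFAULT_MAF_MIN = 0.05
DEFAULT_HWE_ALPHA = 1e-6
DEFAULT_MAX_MISSING = 0.05


def filter_variable_cpgs(methylation: MethylationMatrix,
                         min_sd: float = DEFAULT_MIN_BETA_SD) -> MethylationMatrix:
    """Keep CpGs whose cross-sample beta standard deviation is >= min_sd."""
    if min_sd < 0:
        raise ValueError("min_sd must be non-negative")
    sds = methylation.values.std(axis=0, ddof=1)
    keep = methylation.feature_ids[(sds >= min_sd).to_numpy()]
    if len(keep) == 0:
        warnings.warn("variable-CpG filter removed every CpG", stacklevel=2)
    return methylation.subset_features(keep)


def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg p-value from genotype counts.

    Conditional on the minor-allele count, sums the probabilities of all
    heterozygote counts whose probability does not exceed the observed one
    (Wigginton-style SNPHWE).
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    # probabilities over possible het counts with the same parity as `rare`
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs = {mid: 1.0}
    # downward recurrence: P(het-2) = P(het) * het*(het-1) / ((rare-het+2)*(2n-rare-het+2))
    het, p = mid, 1.0
    while het >= 2:
        p = p * het * (het - 1) / ((rare - het + 2) * (2 * n - rare - het + 2))
        het -= 2
        probs[het] = p
    het, p = mid, 1.0
    while het <= rare - 2:
        p = p * (rare - het) * (2 * n - rare - het) / ((het + 2) * (het + 1))
        het += 2
        probs[het] = p
    total = sum(probs.values())
    p_obs = probs.get(n_het, 0.0) / total
    return min(1.0, sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total)


def _snp_qc_stats(dosages: np.ndarray) -> Tuple[float, float, float]:
    """(maf, hwe_p, missing_fraction) for one dosage column."""
    miss = np.isnan(dosages)
    obs = dosages[~miss]
    missing = miss.mean() if dosages.size else 1.0
    if obs.size == 0:
        return 0.0, 1.0, missing
    p_alt = obs.mean() / 2
    maf = min(p_alt, 1 - p_alt)
    n_hom_ref = int((obs == 0).sum())
    n_het = int((obs == 1).sum())
    n_hom_alt = int((obs == 2).sum())
    return maf, hwe_exact_pvalue(n_het, n_hom_ref, n_hom_alt), missing


def filter_snps(genotypes: GenotypeMatrix,
                maf_min: float = DEFAULT_MAF_MIN,
                hwe_alpha: float = DEFAULT_HWE_ALPHA,
                max_missing: float = DEFAULT_MAX_MISSING
                ) -> Tuple[GenotypeMatrix, Dict[str, int]]:
    """Remove SNPs failing MAF, exact-test HWE, or missingness cuts.

    Returns the surviving subset and per-filter removal counts (a SNP failing
    several cuts is counted in each).
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must lie in [0, 0.5]")
    vals = genotypes.values.to_numpy(dtype=float)
    keep, counts = [], {"maf": 0, "hwe": 0, "missing": 0}
    for j, snp_id in enumerate(genotypes.feature_ids):
        maf, hwe_p, missing = _snp_qc_stats(vals[:, j])
        ok = True
        if maf < maf_min:
            counts["maf"] += 1
            ok = False
        if hwe_p < hwe_alpha:
            counts["hwe"] += 1
            ok = False
        if missing > max_missing:
            counts["missing"] += 1
            ok = False
        if ok:
            keep.append(snp_id)
    log.info("SNP QC: kept %d/%d (removed maf=%d hwe=%d missing=%d)",
             len(keep), genotypes.values.shape[1], counts["maf"], counts["hwe"],
             counts["missing"])
    return genotypes.subset_features(keep), counts


def mean_impute(dosages: np.ndarray) -> np.ndarray:
    """Per-SNP mean imputation of missing dosages (columns = SNPs).

    Used only inside association computations; never written back to disk.
    """
    out = np.array(dosages, dtype=float)
    means = np.nanmean(np.where(np.isnan(out), np.nan, out), axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    idx = np.where(np.isnan(out))
    out[idx] = means[idx[1]]
    return out
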