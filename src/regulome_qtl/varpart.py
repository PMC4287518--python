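"""Variance partitioning of expression into SNP and CpG contributions.

For a probe with both a cis-eQTL and an eQTM, four nested OLS models are fit:
expression ~ SNP; ~ CpG; ~ SNP + CpG; ~ SNP + all eQTM CpGs. Reported are the
raw R-squared of each, the unique (semi-partial) contributions
unique_snp = R2(SNP+CpG) - R2(CpG) and unique_cpg = R2(SNP+CpG) - R2(SNP),
the shared component (which suppression can make negative), and the nested
F-test comparing SNP+CpG against SNP+all-CpGs. Genotype enters as an additive
0/1/2 dosage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

R2_TOL = 1e-10


def _design(predictors: np.ndarray) -> Tuple[np.ndarray, int]:
    """Add an intercept and drop collinear columns (greedy, by rank)."""
    n = predictors.shape[0]
    X = np.column_stack([np.ones(n)])
    kept = 0
    for j in range(predictors.shape[1]):
        cand = np.column_stack([X, predictors[:, j]])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(X):
            X = cand
            kept += 1
    if kept < predictors.shape[1]:
        warnings.warn(f"dropped {predictors.shape[1] - kept} collinear predictor "
                      "column(s)", stacklevel=3)
    return X, kept


def _ols_rss(y: np.ndarray, predictors: np.ndarray) -> Tuple[float, int]:
    X, p = _design(predictors)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), p


def fit_r2(outcome: np.ndarray, predictors: np.ndarray) -> float:
    """Ordinary least squares coefficient of determination (with intercept).

    Collinear predictor columns are dropped with a warning; a constant
    outcome returns NaN (R2 undefined).
    """
    y = np.asarray(outcome, dtype=float)
    X = np.atleast_2d(np.asarray(predictors, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    if y.shape[0] <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return np.nan
    rss, _ = _ols_rss(y, X)
    return 1.0 - rss / tss


def nested_f_test(rss_small: float, p_small: int, rss_full: float, p_full: int,
                  n: int) -> Dict[str, float]:
    """F-test of a nested model pair.

    p_* count predictors excluding the intercept; the full model must nest the
    small one (more predictors, no larger RSS up to tolerance).
    """
    if p_full <= p_small:
        raise ValueError("full model must have more predictors than the small model")
    if rss_full > rss_small + R2_TOL * max(1.0, rss_small):
        raise ValueError("models are not nested: full-model RSS exceeds small-model RSS")
    if n <= p_full + 1:
        raise ValueError("need n > p_full + 1")
    df1 = p_full - p_small
    df2 = n - p_full - 1
    f = max(0.0, (rss_small - rss_full) / df1) / (rss_full / df2)
    return {"f_stat": float(f), "p": float(stats.f.sf(f, df1, df2))}


@dataclass
class VariancePartitionResult:
    probe_id: str
    snp_id: str
    cpg_id: str
    r2_snp: float
    r2_cpg: float
    r2_snp_cpg: float
    r2_snp_all_cpgs: float
    unique_snp: float
    unique_cpg: float
    shared: float
    suppression_flag: bool
    f_stat: float
    f_p: float
    n: int

    def as_dict(self) -> Dict:
        return self.__dict__.copy()


def partition(expression_probe: np.ndarray, snp_dosage: np.ndarray,
              top_cpg: np.ndarray, all_assoc_cpgs: np.ndarray, *,
              probe_id: str = "", snp_id: str = "", cpg_id: str = ""
              ) -> VariancePartitionResult:
    """Four nested fits for one probe; `all_assoc_cpgs` is samples x CpGs and
    must contain the top CpG's signal (a duplicated column is dropped as
    collinear, leaving the R2 chain intact)."""
    y = np.asarray(expression_probe, dtype=float)
    g = np.asarray(snp_dosage, dtype=float).reshape(-1, 1)
    m = np.asarray(top_cpg, dtype=float).reshape(-1, 1)
    M = np.atleast_2d(np.asarray(all_assoc_cpgs, dtype=float))
    if M.shape[0] != y.shape[0]:
        M = M.T
    if M.shape[1] == 0:
        raise ValueError("all_assoc_cpgs must contain at least one CpG")
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("constant expression outcome; R2 undefined")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rss_g, p_g = _ols_rss(y, g)
        rss_m, _ = _ols_rss(y, m)
        rss_gm, p_gm = _ols_rss(y, np.column_stack([g, m]))
        rss_gM, p_gM = _ols_rss(y, np.column_stack([g, m, M]))
    r2_g, r2_m = 1 - rss_g / tss, 1 - rss_m / tss
    r2_gm, r2_gM = 1 - rss_gm / tss, 1 - rss_gM / tss
    unique_snp = r2_gm - r2_m
    unique_cpg = r2_gm - r2_g
    shared = r2_gm - unique_snp - unique_cpg
    if p_gM > p_gm:
        f = nested_f_test(rss_gm, p_gm, rss_gM, p_gM, len(y))
    else:  # every extra CpG was collinear with SNP + top CpG
        f = {"f_stat": 0.0, "p": 1.0}
    return VariancePartitionResult(
        probe_id=probe_id, snp_id=snp_id, cpg_id=cpg_id,
        r2_snp=r2_g, r2_cpg=r2_m, r2_snp_cpg=r2_gm, r2_snp_all_cpgs=r2_gM,
        unique_snp=unique_snp, unique_cpg=unique_cpg, shared=shared,
        suppression_flag=bool(shared < -R2_TOL),
        f_stat=f["f_stat"], f_p=f["p"], n=len(y))


def partition_from_results(expression, genotypes, methylation,
                           eqtl_table: pd.DataFrame, eqtm_table: pd.DataFrame,
                           sample_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Table-style driver: for every probe with both a significant eQTL and a
    significant eQTM, partition using the strongest SNP (max |meta_z|) and the
    strongest CpG (max |rho|), with all significant eQTM CpGs in the full model.
    """
    if sample_ids is None:
        sample_ids = (expression.values.index
                      .intersection(genotypes.values.index)
                      .intersection(methylation.values.index))
    sample_ids = list(sample_ids)
    e_sig = eqtl_table[eqtl_table.get("pair_significant", True) == True]  # noqa: E712
    m_sig = eqtm_table[eqtm_table["significant"]]
    probes = sorted(set(e_sig["feature_id"]) & set(m_sig["probe_id"]))
    rows = []
    for pid in probes:
        e_rows = e_sig[e_sig["feature_id"] == pid]
        snp = e_rows.loc[e_rows["meta_z"].abs().idxmax(), "snp_id"]
        m_rows = m_sig[m_sig["probe_id"] == pid]
        top_cpg = m_rows.loc[m_rows["rho"].abs().idxmax(), "cpg_id"]
        all_cpgs = list(dict.fromkeys(m_rows["cpg_id"]))
        res = partition(
            expression.values.loc[sample_ids, pid].to_numpy(),
            genotypes.values.loc[sample_ids, snp].to_numpy(),
            methylation.values.loc[sample_ids, top_cpg].to_numpy(),
            methylation.values.loc[sample_ids, all_cpgs].to_numpy(),
            probe_id=pid, snp_id=snp, cpg_id=top_cpg)
        row = res.as_dict()
        row["gene"] = (expression.annotation.loc[pid, "gene"]
                       if "gene" in expression.annotation.columns else "")
        rows.append(row)
    return pd.DataFrame(rows)
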