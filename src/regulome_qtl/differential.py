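"""Fetal-vs-adult differential methylation and expression.

Both data types use the same machinery: a two-sided Welch (unequal-variance)
t-test per feature, Benjamini-Hochberg FDR over all tested features, and a
dual significance rule — FDR q < alpha AND an absolute effect above a
data-type threshold (|delta beta| > 0.2 for methylation, |log2FC| > 1.0 for
expression). Effects are fetal-relative: fetal mean minus adult mean.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import CGI_RELATIONS, ExpressionMatrix, FeatureMatrix, MethylationMatrix

DEFAULT_DELTA_BETA = 0.2
DEFAULT_LFC = 1.0
DEFAULT_ALPHA = 0.05

RESULT_COLUMNS = ["feature_id", "effect", "raw_p", "fdr_q", "significant", "direction"]


def _group_masks(sample_ids: pd.Index, groups: pd.Series):
    g = groups.reindex(sample_ids)
    fetal = (g == "fetal").to_numpy()
    adult = (g == "adult").to_numpy()
    if fetal.sum() < 2 or adult.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    return fetal, adult


def _two_group_test(values: pd.DataFrame, groups: pd.Series,
                    effect_threshold: float, alpha: float) -> pd.DataFrame:
    fetal, adult = _group_masks(values.index, groups)
    X = values.to_numpy(dtype=float)
    xf, xa = X[fetal], X[adult]
    effect = xf.mean(axis=0) - xa.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(xf, xa, axis=0, equal_var=False)
    degenerate = (xf.var(axis=0) == 0) & (xa.var(axis=0) == 0)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} features have zero variance in both "
                      "groups; their p-values are set to 1", stacklevel=3)
        p = np.where(degenerate, 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    significant = (q < alpha) & (np.abs(effect) > effect_threshold)
    return pd.DataFrame({
        "feature_id": values.columns,
        "effect": effect,
        "raw_p": p,
        "fdr_q": q,
        "significant": significant,
        "direction": np.where(effect >= 0, "up_in_fetal", "down_in_fetal"),
    }, columns=RESULT_COLUMNS)


def diff_methylation(methylation: MethylationMatrix | pd.DataFrame, groups: pd.Series,
                     delta_threshold: float = DEFAULT_DELTA_BETA,
                     alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Per-CpG fetal-minus-adult beta difference with Welch test + BH FDR.

    `groups` maps sample_id -> {"fetal", "adult"}.
    """
    values = methylation.values if isinstance(methylation, FeatureMatrix) else methylation
    return _two_group_test(values, groups, delta_threshold, alpha)


def diff_expression(expression: ExpressionMatrix | pd.DataFrame, groups: pd.Series,
                    lfc_threshold: float = DEFAULT_LFC,
                    alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Per-probe fetal-minus-adult log2 fold change with Welch test + BH FDR."""
    values = expression.values if isinstance(expression, FeatureMatrix) else expression
    return _two_group_test(values, groups, lfc_threshold, alpha)


def cgi_direction_contingency(dm_results: pd.DataFrame,
                              cpg_annotation: pd.DataFrame) -> Dict:
    """2 x 4 (hypo/hyper in fetal x island/shore/shelf/other) contingency over
    significant CpGs, Pearson chi-squared without continuity correction.

    Returns {"table", "chi_squared", "p", "hypo_fraction", "note"}; the
    statistic is None (undefined) when any row or column is all-zero.
    """
    sig = dm_results[dm_results["significant"]]
    if len(sig) == 0:
        raise ValueError("no significant CpGs to tabulate")
    relation = cpg_annotation.loc[sig["feature_id"], "cgi_relation"].to_numpy()
    hypo = (sig["effect"] < 0).to_numpy()  # hypomethylated in fetal
    table = pd.DataFrame(0, index=["hypo_in_fetal", "hyper_in_fetal"],
                         columns=list(CGI_RELATIONS))
    for rel, h in zip(relation, hypo):
        table.loc["hypo_in_fetal" if h else "hyper_in_fetal", rel] += 1
    hypo_fraction = (table.loc["hypo_in_fetal"] / table.sum(axis=0)).rename("hypo_fraction")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return {"table": table, "chi_squared": None, "p": None,
                "hypo_fraction": hypo_fraction,
                "note": "chi-squared undefined: contingency table has an "
                        "all-zero row or column"}
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return {"table": table, "chi_squared": float(chi2), "p": float(p),
            "hypo_fraction": hypo_fraction, "note": ""}


def intersect_de_dm(de_results: pd.DataFrame, dm_results: pd.DataFrame,
                    probe_annotation: pd.DataFrame,
                    cpg_annotation: pd.DataFrame) -> pd.DataFrame:
    """Genes with >= 1 significant DE probe and >= 1 significant DM CpG.

    Per gene: expression and methylation direction classes; a gene whose
    significant probes (or CpGs) disagree in direction is flagged discordant.
    Features lacking a gene annotation are skipped with a warning.
    """
    def _gene_directions(results: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
        sig = results[results["significant"]]
        known = sig["feature_id"].isin(ann.index)
        if (~known).any():
            warnings.warn(f"{int((~known).sum())} significant features lack gene "
                          "annotation and were skipped", stacklevel=3)
            sig = sig[known]
        genes = ann.loc[sig["feature_id"], "gene"].to_numpy()
        df = sig.assign(gene=genes)
        df = df[df["gene"].astype(str) != ""]
        return df.groupby("gene")["direction"].agg(
            lambda d: d.iloc[0] if d.nunique() == 1 else "discordant")

    expr_dir = _gene_directions(de_results, probe_annotation)
    meth_dir = _gene_directions(dm_results, cpg_annotation)
    genes = expr_dir.index.intersection(meth_dir.index)
    out = pd.DataFrame({
        "gene": genes,
        "expression_direction": expr_dir.loc[genes].to_numpy(),
        "methylation_direction": meth_dir.loc[genes].to_numpy(),
    })
    out["discordant"] = ((out["expression_direction"] == "discordant")
                         | (out["methylation_direction"] == "discordant"))
    return out.reset_index(drop=True)
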