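"""Cis-QTL mapping: Spearman association, weighted-Z cohort meta-analysis,
and permutation-based feature-level FDR.

The discovery unit is the trait feature (expression probe for eQTL, CpG for
meQTL): for every feature the top |meta z| across its cis SNPs is compared
with the permutation null of per-feature top statistics, where each
permutation shuffles the sample linkage between genotypes and traits within
each cohort (preserving trait-trait and LD structure). FDR at threshold t is
the mean permutation count of null tops >= t divided by the observed count of
tops >= t. Pair-level significance extends to all pairs whose |meta z|
reaches the smallest significant feature-top statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, FeatureMatrix
from .filters import mean_impute
from .pairs import DEFAULT_WINDOW_BP, enumerate_cis_pairs, exclude_probe_snp_conflicts

MIN_N = 10
_P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def _rho_to_p_z(rho: np.ndarray, n: int) -> Tuple[np.ndarray, np.ndarray]:
    """Two-sided p via the t approximation; z = signed normal quantile of p."""
    rho_c = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    t = rho_c * np.sqrt((n - 2) / (1 - rho_c ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    z = stats.norm.isf(np.maximum(p, _P_FLOOR) / 2) * np.sign(rho)
    return p, z


def spearman_assoc(dosage: np.ndarray, trait: np.ndarray) -> Dict:
    """Spearman association of one trait on one dosage vector.

    Missing dosages are mean-imputed; samples with missing trait are dropped.
    Returns {"rho", "p", "z", "n"} or {"skipped": reason}.
    """
    dosage = np.asarray(dosage, dtype=float)
    trait = np.asarray(trait, dtype=float)
    ok = ~np.isnan(trait)
    dosage, trait = dosage[ok], trait[ok]
    if len(trait) < MIN_N:
        return {"skipped": "too_few_samples"}
    if np.unique(dosage[~np.isnan(dosage)]).size < 2:
        return {"skipped": "single_genotype_class"}
    if np.all(trait == trait[0]):
        return {"skipped": "constant_trait"}
    dosage = mean_impute(dosage[:, None])[:, 0]
    rg = stats.rankdata(dosage)
    rt = stats.rankdata(trait)
    rho = np.corrcoef(rg, rt)[0, 1]
    p, z = _rho_to_p_z(np.array([rho]), len(trait))
    return {"rho": float(rho), "p": float(p[0]), "z": float(z[0]), "n": len(trait)}


def meta_weighted_z(cohort_zs: Sequence[float], cohort_ns: Sequence[float]
                    ) -> Dict[str, float]:
    """Sample-size-weighted Z: meta_z = sum(sqrt(n_i) z_i) / sqrt(sum n_i)."""
    zs = np.asarray(cohort_zs, dtype=float)
    ns = np.asarray(cohort_ns, dtype=float)
    if zs.shape != ns.shape:
        raise ValueError("cohort_zs and cohort_ns must have equal length")
    valid = ~np.isnan(zs)
    if not valid.any():
        raise ValueError("no cohort with a valid z")
    meta_z = (np.sqrt(ns[valid]) * zs[valid]).sum() / np.sqrt(ns[valid].sum())
    return {"meta_z": float(meta_z), "meta_p": float(2 * stats.norm.sf(abs(meta_z)))}


def permutation_fdr(observed_top_stats: np.ndarray, perm_top_stats: np.ndarray,
                    alpha: float = 0.05) -> Tuple[np.ndarray, float]:
    """Counting FDR from per-feature top statistics.

    perm_top_stats has shape (n_perm, n_features_in_null). For each observed
    top t: FDR(t) = (count of null tops >= t / n_perm) / (count of observed
    tops >= t), clipped to [0, 1]. Returns (fdr array aligned with
    observed_top_stats, significance threshold = smallest observed top with
    FDR < alpha, inf when none).
    """
    obs = np.asarray(observed_top_stats, dtype=float)
    perm = np.asarray(perm_top_stats, dtype=float)
    if perm.ndim != 2 or perm.shape[0] < 1:
        raise ValueError("perm_top_stats must be (n_perm, n_features) with n_perm >= 1")
    n_perm = perm.shape[0]
    null_sorted = np.sort(perm[~np.isnan(perm)])
    obs_sorted = np.sort(obs)
    n_obs = len(obs)
    den = n_obs - np.searchsorted(obs_sorted, obs, side="left")
    num = (len(null_sorted) - np.searchsorted(null_sorted, obs, side="left")) / n_perm
    fdr = np.clip(num / np.maximum(den, 1), 0.0, 1.0)
    sig = fdr < alpha
    threshold = float(obs[sig].min()) if sig.any() else np.inf
    return fdr, threshold


# ---------------------------------------------------------------------------
# vectorized scan machinery
# ---------------------------------------------------------------------------

def _normalized_ranks(X: np.ndarray) -> np.ndarray:
    """Column-wise average ranks, centered and scaled to unit norm; a constant
    column becomes all-NaN so its correlations propagate as invalid."""
    R = stats.rankdata(X, axis=0).astype(float)
    R -= R.mean(axis=0)
    norms = np.sqrt((R ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(norms > 0, R / np.where(norms > 0, norms, 1.0), np.nan)
    return R


@dataclass
class _CohortData:
    name: str
    n: int
    rank_g: np.ndarray        # normalized dosage ranks (n x n_snps_used)
    rank_t: np.ndarray        # normalized trait ranks (n x n_traits_used)
    valid_g: np.ndarray       # per used SNP: >= 2 genotype classes
    li: np.ndarray            # pair -> column in rank_g
    ti: np.ndarray            # pair -> column in rank_t


def _pair_meta(cohorts: Sequence[_CohortData], perm_idx: Optional[Dict[str, np.ndarray]]
               ) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
    """Per-pair meta z over cohorts (optionally with permuted trait rows).

    Returns (meta_z, per-cohort rho dict); pairs invalid in every cohort get NaN.
    """
    n_pairs = len(cohorts[0].li)
    num = np.zeros(n_pairs)
    den = np.zeros(n_pairs)
    rhos: Dict[str, np.ndarray] = {}
    for cd in cohorts:
        rt = cd.rank_t if perm_idx is None else cd.rank_t[perm_idx[cd.name]]
        rho = np.einsum("ij,ij->j", cd.rank_g[:, cd.li], rt[:, cd.ti])
        ok = cd.valid_g[cd.li] & ~np.isnan(rho)
        _, z = _rho_to_p_z(np.where(ok, rho, 0.0), cd.n)
        num += np.where(ok, np.sqrt(cd.n) * z, 0.0)
        den += np.where(ok, float(cd.n), 0.0)
        rhos[cd.name] = np.where(ok, rho, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        meta = np.where(den > 0, num / np.sqrt(np.where(den > 0, den, 1.0)), np.nan)
    return meta, rhos


def _feature_tops(meta_abs: np.ndarray, feat_codes: np.ndarray, n_feat: int) -> np.ndarray:
    tops = np.full(n_feat, -np.inf)
    ok = ~np.isnan(meta_abs)
    np.maximum.at(tops, feat_codes[ok], meta_abs[ok])
    return np.where(np.isfinite(tops), tops, np.nan)


@dataclass
class QtlMapping:
    """Result bundle of map_cis_qtl."""
    table: pd.DataFrame
    feature_fdr: pd.Series
    threshold: float
    removed_pairs: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["pair_significant"]].reset_index(drop=True)

    def significant_features(self) -> pd.Index:
        return self.feature_fdr.index[self.feature_fdr < self.params.get("alpha", 0.05)]


def map_cis_qtl(genotypes: GenotypeMatrix, traits: FeatureMatrix,
                sample_sheet: pd.DataFrame, *, window: int = DEFAULT_WINDOW_BP,
                n_perm: int = 10, alpha: float = 0.05, mode: str = "eqtl",
                seed: int = 0, tissue: str = "liver",
                group: str = "adult") -> QtlMapping:
    """Cis eQTL/meQTL scan with cohort meta-analysis and permutation FDR.

    Samples are restricted to the given group and tissue; cohorts are taken
    from the sample sheet. mode="meqtl" additionally removes SNPs that fall
    inside the target methylation probe's footprint.
    """
    if mode not in ("eqtl", "meqtl"):
        raise ValueError("mode must be 'eqtl' or 'meqtl'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    sheet = sample_sheet[(sample_sheet["group"] == group)
                         & (sample_sheet["tissue"] == tissue)]
    pairs = enumerate_cis_pairs(genotypes.annotation, traits.annotation, window)
    removed = pairs.iloc[0:0]
    if mode == "meqtl" and {"interval_start", "interval_end"}.issubset(traits.annotation.columns):
        pairs, removed = exclude_probe_snp_conflicts(pairs, genotypes.annotation,
                                                     traits.annotation)
    if len(pairs) == 0:
        raise ValueError("no cis pairs to test")

    li_ids = pairs["left_id"].to_numpy()
    ti_ids = pairs["right_id"].to_numpy()
    snp_pos = pd.Series(np.arange(genotypes.values.shape[1]), index=genotypes.feature_ids)
    trait_pos = pd.Series(np.arange(traits.values.shape[1]), index=traits.feature_ids)
    li = snp_pos.loc[li_ids].to_numpy()
    ti = trait_pos.loc[ti_ids].to_numpy()

    cohorts: list[_CohortData] = []
    for name in sorted(sheet["cohort"].unique()):
        sids = sheet.loc[sheet["cohort"] == name, "sample_id"]
        sids = [s for s in sids if s in genotypes.values.index and s in traits.values.index]
        if len(sids) < MIN_N:
            continue
        G = genotypes.values.loc[sids].to_numpy(dtype=float)
        valid_g = np.array([np.unique(col[~np.isnan(col)]).size >= 2 for col in G.T])
        G = mean_impute(G)
        T = traits.values.loc[sids].to_numpy(dtype=float)
        cohorts.append(_CohortData(name, len(sids), _normalized_ranks(G),
                                   _normalized_ranks(T), valid_g, li, ti))
    if not cohorts:
        raise ValueError("no cohort with overlapping genotype and trait samples")

    meta_z, rhos = _pair_meta(cohorts, None)
    keep = ~np.isnan(meta_z)
    feat_ids, feat_codes = np.unique(ti_ids[keep], return_inverse=True)
    obs_tops = _feature_tops(np.abs(meta_z[keep]), feat_codes, len(feat_ids))

    rng = np.random.default_rng(seed)
    perm_tops = np.empty((n_perm, len(feat_ids)))
    for b in range(n_perm):
        idx = {cd.name: rng.permutation(cd.n) for cd in cohorts}
        pz, _ = _pair_meta(cohorts, idx)
        perm_tops[b] = _feature_tops(np.abs(pz[keep]), feat_codes, len(feat_ids))

    fdr, threshold = permutation_fdr(obs_tops, perm_tops, alpha)
    feature_fdr = pd.Series(fdr, index=pd.Index(feat_ids, name="feature_id"))

    meta_p = 2 * stats.norm.sf(np.abs(meta_z[keep]))
    gene = (traits.annotation["gene"].reindex(ti_ids[keep]).to_numpy()
            if "gene" in traits.annotation.columns else np.full(keep.sum(), ""))
    table = pd.DataFrame({
        "snp_id": li_ids[keep], "feature_id": ti_ids[keep], "gene": gene,
        "distance_bp": pairs["distance_bp"].to_numpy()[keep],
        "meta_z": meta_z[keep], "meta_p": meta_p,
    })
    for cd in cohorts:
        table[f"rho_{cd.name}"] = rhos[cd.name][keep]
        table[f"n_{cd.name}"] = cd.n
    table["fdr"] = feature_fdr.loc[table["feature_id"]].to_numpy()
    table["direction"] = np.where(table["meta_z"] >= 0, "+", "-")
    tops_by_feat = pd.Series(obs_tops, index=feat_ids)
    table["top_flag"] = (np.abs(table["meta_z"])
                         >= tops_by_feat.loc[table["feature_id"]].to_numpy() - 1e-12)
    # exactly one top per feature: break ties by first occurrence
    dup = table.loc[table["top_flag"]].duplicated("feature_id")
    table.loc[table.index[table["top_flag"]][dup], "top_flag"] = False
    table["feature_significant"] = (table["fdr"] < alpha)
    table["pair_significant"] = table["feature_significant"] & (
        np.abs(table["meta_z"]) >= threshold)
    table = table.sort_values(["feature_id", "snp_id"], kind="stable").reset_index(drop=True)
    params = {"window": window, "n_perm": n_perm, "alpha": alpha, "mode": mode,
              "seed": seed, "tissue": tissue, "group": group,
              "cohorts": {cd.name: cd.n for cd in cohorts}}
    return QtlMapping(table, feature_fdr, threshold, removed, params)


# ---------------------------------------------------------------------------
# eQTL / meQTL direction overlap
# ---------------------------------------------------------------------------

def overlap_eqtl_meqtl(eqtl: pd.DataFrame, meqtl: pd.DataFrame,
                       cpg_annotation: pd.DataFrame) -> Dict:
    """SNPs associated with both expression and methylation of the same gene.

    Inputs are significant-only result tables from map_cis_qtl. Each
    (snp, gene) overlap is classified opposite (allele raises methylation but
    lowers expression, or vice versa) or same. Returns pair rows, a per-gene
    summary (strongest association per side), the gene-level opposite
    fraction, and the per-CGI-class opposite fractions.
    """
    e = eqtl.rename(columns={"feature_id": "probe_id", "meta_z": "meta_z_expr"})
    m = meqtl.rename(columns={"feature_id": "cpg_id", "meta_z": "meta_z_meth"})
    merged = e.merge(m, on=["snp_id", "gene"], suffixes=("_e", "_m"))
    if len(merged) == 0:
        empty = pd.DataFrame(columns=["snp_id", "gene", "probe_id", "cpg_id",
                                      "overlap_class"])
        return {"pairs": empty, "gene_summary": empty, "fraction_opposite": np.nan,
                "cgi_breakdown": pd.Series(dtype=float)}
    merged["cgi_relation"] = cpg_annotation.loc[merged["cpg_id"], "cgi_relation"].to_numpy()
    merged["overlap_class"] = np.where(
        np.sign(merged["meta_z_expr"]) * np.sign(merged["meta_z_meth"]) < 0,
        "opposite", "same")
    cols = ["snp_id", "gene", "probe_id", "cpg_id", "meta_z_expr", "meta_z_meth",
            "cgi_relation", "overlap_class"]
    pairs_tab = merged[cols].reset_index(drop=True)

    score = np.abs(merged["meta_z_expr"]) + np.abs(merged["meta_z_meth"])
    best = merged.assign(_score=score).sort_values("_score").groupby("gene").tail(1)
    gene_summary = best[cols].sort_values("gene").reset_index(drop=True)
    frac_opp = float((gene_summary["overlap_class"] == "opposite").mean())
    cgi = pairs_tab.groupby("cgi_relation")["overlap_class"].apply(
        lambda s: (s == "opposite").mean())
    return {"pairs": pairs_tab, "gene_summary": gene_summary,
            "fraction_opposite": frac_opp, "cgi_breakdown": cgi}
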