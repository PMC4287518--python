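"""CpG-expression association (eQTM) within the cis window.

Per CpG-probe pair: Spearman correlation across adult samples and an add-one
permutation p-value, perm_p = (1 + #{|rho_null| >= |rho_obs|}) / (1 + n_perm),
where each null shuffles the sample linkage between the methylation and
expression matrices (one shared permutation per round, preserving the
correlation structure within each matrix). When samples come from multiple
cohorts the shuffle is within cohort, so cohort-level batch shifts that move
both data types stay aligned under the null instead of masquerading as
signal. The discovery unit is the pair:
no feature-level collapsing. A BH q over perm_p is reported alongside so a
pair-level FDR convention can also be applied downstream.

Distance convention: CpG position minus expression probe midpoint (positive =
CpG downstream of the probe on the plus strand; probe strand is not modeled).
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, MethylationMatrix
from .qtl import _normalized_ranks

DEFAULT_N_PERM = 999

RHO_BINS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
DISTANCE_BINS = (0, 50_000, 100_000, 150_000, 200_000, 250_000)


def map_eqtm(methylation: MethylationMatrix, expression: ExpressionMatrix,
             pairs: pd.DataFrame, *, n_perm: int = DEFAULT_N_PERM,
             alpha: float = 0.05, seed: int = 0,
             sample_ids: Optional[Sequence[str]] = None,
             cohorts: Optional[pd.Series] = None) -> pd.DataFrame:
    """Spearman eQTM scan with permutation p-values.

    `pairs` comes from enumerate_cis_pairs(cpg_annotation, probe_annotation),
    so pair distance is probe minus CpG; the reported distance_bp is negated
    to the CpG-relative-to-probe convention. `sample_ids` restricts the scan
    (callers pass the adult samples); default is all shared samples.
    `cohorts` maps sample_id -> cohort label; when given, permutations shuffle
    within cohort only.
    """
    if n_perm < 19:
        warnings.warn(f"n_perm={n_perm} cannot resolve p < 0.05 "
                      "(minimum attainable perm_p is 1/(1+n_perm))", stacklevel=2)
    if sample_ids is None:
        sample_ids = methylation.values.index.intersection(expression.values.index)
    sample_ids = list(sample_ids)
    M = _normalized_ranks(methylation.values.loc[sample_ids].to_numpy(dtype=float))
    E = _normalized_ranks(expression.values.loc[sample_ids].to_numpy(dtype=float))
    mcol = pd.Series(np.arange(M.shape[1]), index=methylation.feature_ids)
    ecol = pd.Series(np.arange(E.shape[1]), index=expression.feature_ids)
    mi = mcol.loc[pairs["left_id"]].to_numpy()
    ei = ecol.loc[pairs["right_id"]].to_numpy()

    Mp = M[:, mi]
    Ep = E[:, ei]
    rho = np.einsum("ij,ij->j", Mp, Ep)
    abs_rho = np.abs(rho)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(pairs), dtype=np.int64)
    n = len(sample_ids)
    if cohorts is not None:
        labels = cohorts.reindex(sample_ids).to_numpy()
        blocks = [np.where(labels == c)[0] for c in pd.unique(labels)]
    else:
        blocks = [np.arange(n)]
    for _ in range(n_perm):
        perm = np.arange(n)
        for block in blocks:
            perm[block] = block[rng.permutation(len(block))]
        null_rho = np.einsum("ij,ij->j", Mp[perm], Ep)
        exceed += (np.abs(null_rho) >= abs_rho).astype(np.int64)
    perm_p = (1 + exceed) / (1 + n_perm)
    _, q, _, _ = multipletests(perm_p, method="fdr_bh")

    out = pd.DataFrame({
        "cpg_id": pairs["left_id"].to_numpy(),
        "probe_id": pairs["right_id"].to_numpy(),
        "rho": rho,
        "perm_p": perm_p,
        "perm_q": q,
        "distance_bp": -pairs["distance_bp"].to_numpy(),  # CpG minus probe midpoint
        "direction": np.where(rho < 0, "negative", "positive"),
        "significant": perm_p < alpha,
        "n": n,
    })
    return out


def direction_distance_summary(results: pd.DataFrame,
                               rho_bins: Sequence[float] = RHO_BINS,
                               distance_bins: Sequence[float] = DISTANCE_BINS
                               ) -> Dict[str, pd.DataFrame]:
    """Fraction of negative-direction eQTMs per |rho| bin and per |distance| bin.

    Only significant pairs are summarized; empty bins report NaN (undefined),
    never zero.
    """
    sig = results[results["significant"]]
    if len(sig) == 0:
        raise ValueError("no significant eQTMs to summarize")

    def _binned(values: np.ndarray, edges: Sequence[float]) -> pd.DataFrame:
        idx = np.digitize(values, edges[1:-1], right=True)
        rows = []
        for b in range(len(edges) - 1):
            mask = idx == b
            n_bin = int(mask.sum())
            frac = float((sig["direction"].to_numpy()[mask] == "negative").mean()) \
                if n_bin else np.nan
            rows.append({"bin_low": edges[b], "bin_high": edges[b + 1],
                         "n": n_bin, "fraction_negative": frac})
        return pd.DataFrame(rows)

    return {
        "by_abs_rho": _binned(np.abs(sig["rho"].to_numpy()), list(rho_bins)),
        "by_abs_distance": _binned(np.abs(sig["distance_bp"].to_numpy()),
                                   list(distance_bins)),
    }
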