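"""Cross-tissue overlap of QTL/eQTM sets, allelic-direction concordance, and
matched-probe enrichment.

Replication across tissues is strict by default: an effect replicates when
its key (SNP-feature or CpG-probe pair) is declared significant in both
tissues. Matching for the enrichment analysis is greedy nearest-neighbor
without replacement in z-scored (median, SD) expression-summary space.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class OverlapReport:
    region_counts: Dict[Tuple[str, ...], int]   # keyed by sorted tissue subset
    union_size: int
    pairwise_replication: pd.DataFrame          # fraction of tissue i's set found in j
    concordance: float                          # same sign across all sharing tissues
    opposite_effects: pd.DataFrame              # key, tissues, per-tissue signs


def _keyed(results: pd.DataFrame, key_cols: Sequence[str]) -> pd.DataFrame:
    key = results[list(key_cols)].astype(str).agg("|".join, axis=1)
    if key.duplicated().any():
        raise ValueError("duplicate keys within one tissue's result set")
    return pd.DataFrame({"key": key.to_numpy(),
                         "sign": np.sign(results["__signed"].to_numpy())})


def cross_tissue_overlap(result_sets: Mapping[str, pd.DataFrame],
                         key_cols: Sequence[str] = ("snp_id", "feature_id"),
                         sign_col: str = "meta_z") -> OverlapReport:
    """Exact set algebra over per-tissue significant-effect keys.

    `result_sets` maps tissue -> significant-only result table carrying the
    key columns and a signed statistic column. All 2^k - 1 Venn regions are
    counted (disjoint, summing to the union size).
    """
    if len(result_sets) < 2:
        raise ValueError("need at least 2 tissues")
    tissues = list(result_sets)
    keyed = {}
    for t in tissues:
        df = result_sets[t].copy()
        df["__signed"] = df[sign_col]
        keyed[t] = _keyed(df, key_cols).set_index("key")["sign"]

    membership: Dict[str, set] = {}
    for t in tissues:
        for k in keyed[t].index:
            membership.setdefault(k, set()).add(t)
    region_counts: Dict[Tuple[str, ...], int] = {}
    for r in range(1, len(tissues) + 1):
        for subset in combinations(tissues, r):
            region_counts[tuple(subset)] = 0
    for k, mem in membership.items():
        region_counts[tuple(t for t in tissues if t in mem)] += 1

    rep = pd.DataFrame(np.nan, index=tissues, columns=tissues)
    for a in tissues:
        for b in tissues:
            if a == b or len(keyed[a]) == 0:
                continue
            rep.loc[a, b] = float(np.mean([k in keyed[b].index for k in keyed[a].index]))

    shared_keys = [k for k, mem in membership.items() if len(mem) > 1]
    same, opposite_rows = 0, []
    for k in shared_keys:
        signs = {t: int(keyed[t].loc[k]) for t in membership[k]}
        if len(set(signs.values())) == 1:
            same += 1
        else:
            opposite_rows.append({"key": k,
                                  "tissues": ",".join(sorted(signs)),
                                  "signs": ",".join(f"{t}:{s:+d}" for t, s in
                                                    sorted(signs.items()))})
    concordance = same / len(shared_keys) if shared_keys else np.nan
    return OverlapReport(region_counts=region_counts, union_size=len(membership),
                         pairwise_replication=rep, concordance=concordance,
                         opposite_effects=pd.DataFrame(
                             opposite_rows, columns=["key", "tissues", "signs"]))


def direction_concordance(shared_signs: pd.DataFrame) -> Dict:
    """Fraction of shared effects with identical sign across their tissues.

    `shared_signs` is keyed rows x tissue columns of {-1, +1, NaN(absent)};
    rows must be present in >= 2 tissues.
    """
    vals = shared_signs.to_numpy(dtype=float)
    present = ~np.isnan(vals)
    if (present.sum(axis=1) < 2).any():
        raise ValueError("every row must be shared by at least 2 tissues")
    same = np.array([len(set(row[ok])) == 1 for row, ok in zip(vals, present)])
    opposite = shared_signs.loc[~same]
    return {"fraction_same": float(same.mean()) if len(same) else np.nan,
            "opposite_list": opposite}


def matched_probe_enrichment(target_ids: Sequence[str], pool_ids: Sequence[str],
                             expression_summary: pd.DataFrame,
                             flags: pd.Series, *, seed: int = 0) -> Dict:
    """Fold enrichment of a flag (e.g. "has an eQTL") in a target probe set
    against an expression-matched control set.

    `expression_summary` is indexed by probe id with columns median and sd;
    for each target (in seeded random order) the nearest unused pool probe in
    z-scored (median, sd) space is taken without replacement. Returns the
    fold enrichment (flagged fraction in targets / in matched), the 2x2
    chi-squared p, and the matched ids.
    """
    targets = list(target_ids)
    pool = [p for p in pool_ids if p not in set(targets)]
    if len(pool) < len(targets):
        raise ValueError("pool smaller than target set")
    feats = expression_summary[["median", "sd"]].astype(float)
    mu, sigma = feats.mean(), feats.std(ddof=0).replace(0, 1.0)
    Z = (feats - mu) / sigma
    zt = Z.loc[targets].to_numpy()
    zp = Z.loc[pool].to_numpy()

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(targets))
    used = np.zeros(len(pool), dtype=bool)
    matched = [None] * len(targets)
    for i in order:
        d = ((zp - zt[i]) ** 2).sum(axis=1)
        d[used] = np.inf
        j = int(np.argmin(d))  # ties: lowest pool index
        used[j] = True
        matched[i] = pool[j]

    t_flag = int(flags.loc[targets].sum())
    m_flag = int(flags.loc[matched].sum())
    n = len(targets)
    table = np.array([[t_flag, n - t_flag], [m_flag, n - m_flag]])
    if m_flag == 0:
        fold = np.inf if t_flag > 0 else np.nan
    else:
        fold = (t_flag / n) / (m_flag / n)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        chi2_p = np.nan
    else:
        _, chi2_p, _, _ = stats.chi2_contingency(table, correction=False)
    return {"fold_enrichment": float(fold), "chi_squared_p": float(chi2_p),
            "matched_set": matched, "counts": table,
            "target_flagged": t_flag, "matched_flagged": m_flag}


def body_region_breakdown(cpg_ids: Sequence[str], cpg_annotation: pd.DataFrame
                          ) -> pd.Series:
    """Descriptive counts of CpG body-region context (used for the
    opposite-direction meQTL positional breakdown)."""
    return cpg_annotation.loc[list(cpg_ids), "body_region"].value_counts()
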