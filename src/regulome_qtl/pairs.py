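"""Cis-window pair enumeration and the SNP-in-probe exclusion filter.

A "pair" links a left feature (SNP or CpG) to a right feature (CpG or
expression probe) on the same chromosome with an anchor distance within the
cis window (default 250 kb, inclusive at the bound). Anchors: a feature with
a `pos` column is anchored at that position; an interval feature (expression
probe, columns start/end) is anchored at its integer midpoint.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd

DEFAULT_WINDOW_BP = 250_000

PAIR_COLUMNS = ["left_id", "right_id", "distance_bp"]


def anchor_positions(ann: pd.DataFrame) -> pd.Series:
    """Anchor coordinate per feature: `pos` if present, else interval midpoint."""
    if "pos" in ann.columns and ann["pos"].notna().all():
        return ann["pos"].astype(np.int64)
    if {"start", "end"}.issubset(ann.columns):
        return ((ann["start"].astype(np.int64) + ann["end"].astype(np.int64)) // 2)
    raise ValueError("annotation needs either a 'pos' or 'start'/'end' columns")


def enumerate_cis_pairs(left_ann: pd.DataFrame, right_ann: pd.DataFrame,
                        window_bp: int = DEFAULT_WINDOW_BP) -> pd.DataFrame:
    """All same-chromosome (left, right) pairs with |anchor distance| <= window_bp.

    distance_bp is signed: right anchor minus left anchor. Output is sorted by
    (left_id, right_id). Empty inputs yield an empty frame; non-empty inputs
    whose chromosome label sets are disjoint raise (catches chr-naming
    mismatches such as "chr1" vs "1").
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if len(left_ann) == 0 or len(right_ann) == 0:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    left_chroms = set(left_ann["chrom"].astype(str))
    right_chroms = set(right_ann["chrom"].astype(str))
    if not (left_chroms & right_chroms):
        raise ValueError(
            "no shared chromosome labels between the two annotations; "
            f"left has {sorted(left_chroms)[:5]}, right has {sorted(right_chroms)[:5]}"
        )

    left_anchor = anchor_positions(left_ann)
    right_anchor = anchor_positions(right_ann)
    out_left, out_right, out_dist = [], [], []
    for chrom in sorted(left_chroms & right_chroms):
        li = left_ann.index[left_ann["chrom"].astype(str) == chrom]
        ri = right_ann.index[right_ann["chrom"].astype(str) == chrom]
        rpos = right_anchor.loc[ri].to_numpy()
        order = np.argsort(rpos, kind="stable")
        rpos_sorted = rpos[order]
        rid_sorted = np.asarray(ri)[order]
        for lid, lpos in zip(li, left_anchor.loc[li].to_numpy()):
            lo = np.searchsorted(rpos_sorted, lpos - window_bp, side="left")
            hi = np.searchsorted(rpos_sorted, lpos + window_bp, side="right")
            if hi > lo:
                out_left.extend([lid] * (hi - lo))
                out_right.extend(rid_sorted[lo:hi])
                out_dist.extend(rpos_sorted[lo:hi] - lpos)
    pairs = pd.DataFrame({"left_id": out_left, "right_id": out_right,
                          "distance_bp": np.asarray(out_dist, dtype=np.int64)})
    return pairs.sort_values(["left_id", "right_id"], kind="stable").reset_index(drop=True)


def exclude_probe_snp_conflicts(pairs: pd.DataFrame, snp_ann: pd.DataFrame,
                                probe_intervals: pd.DataFrame
                                ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Drop SNP->probe pairs where the SNP sits inside the target probe footprint.

    `probe_intervals` is indexed by the right-side feature id with 1-based
    inclusive columns interval_start / interval_end. Returns (kept, removed).
    """
    if len(pairs) == 0:
        return pairs.copy(), pairs.copy()
    unknown = set(pairs["right_id"]) - set(probe_intervals.index)
    if unknown:
        raise ValueError(f"pairs reference unknown probes: {sorted(unknown)[:5]}")
    pos = snp_ann.loc[pairs["left_id"], "pos"].to_numpy(dtype=np.int64)
    start = probe_intervals.loc[pairs["right_id"], "interval_start"].to_numpy(dtype=np.int64)
    end = probe_intervals.loc[pairs["right_id"], "interval_end"].to_numpy(dtype=np.int64)
    conflict = (pos >= start) & (pos <= end)
    kept = pairs.loc[~conflict].reset_index(drop=True)
    removed = pairs.loc[conflict].reset_index(drop=True)
    return kept, removed
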