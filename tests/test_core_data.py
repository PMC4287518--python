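"""Pair enumeration, probe-conflict exclusion, QC filters, and TSV round-trips."""

import math

import numpy as np
import pandas as pd
import pytest

from regulome_qtl.datatypes import (GenotypeMatrix, MethylationMatrix,
                                    read_annotation, read_matrix,
                                    write_annotation, write_matrix)
from regulome_qtl.filters import (filter_snps, filter_variable_cpgs,
                                  hwe_exact_pvalue)
from regulome_qtl.pairs import enumerate_cis_pairs, exclude_probe_snp_conflicts


def brute_force_pairs(left, right, window):
    out = set()
    for lid, lrow in left.iterrows():
        for rid, rrow in right.iterrows():
            if str(lrow["chrom"]) == str(rrow["chrom"]) and \
                    abs(int(rrow["pos"]) - int(lrow["pos"])) <= window:
                out.add((lid, rid, int(rrow["pos"]) - int(lrow["pos"])))
    return out


class TestEnumerateCisPairs:
    def test_matches_brute_force_double_loop(self, toy_annotations):
        snps, cpgs = toy_annotations
        for window in (1_000, 250_000, 900_000):
            got = enumerate_cis_pairs(snps, cpgs, window)
            expected = brute_force_pairs(snps, cpgs, window)
            assert set(map(tuple, got.to_numpy())) == expected

    def test_window_bound_inclusive_and_zero_distance(self):
        left = pd.DataFrame({"chrom": ["1"], "pos": [500_000]}, index=["snp"])
        right = pd.DataFrame({"chrom": ["1", "1", "1"],
                              "pos": [500_000, 750_000, 750_001]},
                             index=["a", "b", "c"])
        got = enumerate_cis_pairs(left, right, 250_000)
        assert list(got["right_id"]) == ["a", "b"]
        assert got.loc[got["right_id"] == "a", "distance_bp"].iloc[0] == 0
        assert got.loc[got["right_id"] == "b", "distance_bp"].iloc[0] == 250_000

    def test_probe_anchor_is_interval_midpoint(self):
        left = pd.DataFrame({"chrom": ["1"], "pos": [100]}, index=["cg"])
        right = pd.DataFrame({"chrom": ["1"], "start": [200], "end": [299]},
                             index=["probe"])
        got = enumerate_cis_pairs(left, right, 250_000)
        assert got["distance_bp"].iloc[0] == (200 + 299) // 2 - 100

    def test_disjoint_chromosome_labels_raise(self):
        left = pd.DataFrame({"chrom": ["chr1"], "pos": [1]}, index=["a"])
        right = pd.DataFrame({"chrom": ["1"], "pos": [1]}, index=["b"])
        with pytest.raises(ValueError, match="chr1"):
            enumerate_cis_pairs(left, right, 100)

    def test_empty_input_gives_empty_output(self):
        left = pd.DataFrame(columns=["chrom", "pos"])
        right = pd.DataFrame({"chrom": ["1"], "pos": [1]}, index=["b"])
        assert len(enumerate_cis_pairs(left, right, 100)) == 0

    def test_output_sorted_and_side_symmetric(self, toy_annotations):
        snps, cpgs = toy_annotations
        fwd = enumerate_cis_pairs(snps, cpgs, 300_000)
        rev = enumerate_cis_pairs(cpgs, snps, 300_000)
        assert list(fwd["left_id"]) == sorted(fwd["left_id"])
        assert (set(zip(fwd["left_id"], fwd["right_id"]))
                == set(zip(rev["right_id"], rev["left_id"])))


class TestConflictExclusion:
    def _setup(self):
        g = np.random.default_rng(3)
        n = 20
        snp_pos = g.integers(1_000, 9_000, n)
        snps = pd.DataFrame({"chrom": "1", "pos": snp_pos},
                            index=[f"snp{i}" for i in range(n)])
        starts, ends = [], []
        for i in range(n):
            if i < 6:  # constructed conflicts: SNP inside the probe footprint
                starts.append(snp_pos[i] - 10)
                ends.append(snp_pos[i] + 39)
            else:
                starts.append(snp_pos[i] + 100)
                ends.append(snp_pos[i] + 149)
        probes = pd.DataFrame({"interval_start": starts, "interval_end": ends},
                              index=[f"cg{i}" for i in range(n)])
        pairs = pd.DataFrame({"left_id": snps.index, "right_id": probes.index,
                              "distance_bp": 0})
        return pairs, snps, probes

    def test_exact_conflicts_removed_vs_interval_scan(self):
        pairs, snps, probes = self._setup()
        kept, removed = exclude_probe_snp_conflicts(pairs, snps, probes)
        assert len(removed) == 6 and len(kept) == 14
        # independent interval-membership scan
        for _, row in pairs.iterrows():
            pos = snps.loc[row["left_id"], "pos"]
            s, e = probes.loc[row["right_id"], ["interval_start", "interval_end"]]
            in_removed = (removed["left_id"] == row["left_id"]).any()
            assert in_removed == (s <= pos <= e)

    def test_boundary_one_bp_outside_retained(self):
        snps = pd.DataFrame({"chrom": "1", "pos": [99, 100, 150, 151]},
                            index=list("abcd"))
        probes = pd.DataFrame({"interval_start": [100] * 4, "interval_end": [150] * 4},
                              index=["p0", "p1", "p2", "p3"])
        pairs = pd.DataFrame({"left_id": list("abcd"),
                              "right_id": ["p0", "p1", "p2", "p3"],
                              "distance_bp": 0})
        kept, removed = exclude_probe_snp_conflicts(pairs, snps, probes)
        assert set(kept["left_id"]) == {"a", "d"}

    def test_unknown_probe_raises(self):
        pairs, snps, probes = self._setup()
        with pytest.raises(ValueError, match="unknown"):
            exclude_probe_snp_conflicts(pairs, snps, probes.iloc[:3])


def _meth(values, ids=None):
    ids = ids or [f"cg{i}" for i in range(values.shape[1])]
    ann = pd.DataFrame({"chrom": "1", "pos": np.arange(1, values.shape[1] + 1),
                        "cgi_relation": "other"}, index=ids)
    samples = pd.Index([f"s{i}" for i in range(values.shape[0])])
    return MethylationMatrix(pd.DataFrame(values, index=samples, columns=ids), ann)


class TestVariableCpgFilter:
    def test_zero_threshold_is_identity(self, rng):
        m = _meth(rng.uniform(0, 1, (10, 20)))
        assert list(filter_variable_cpgs(m, 0.0).feature_ids) == list(m.feature_ids)

    def test_constant_column_always_removed(self, rng):
        vals = rng.uniform(0, 1, (10, 5))
        vals[:, 2] = 0.4
        kept = filter_variable_cpgs(_meth(vals), 1e-9).feature_ids
        assert "cg2" not in kept

    def test_survivors_match_direct_sd_computation(self, rng):
        vals = rng.beta(2, 2, (30, 100))
        m = _meth(vals)
        got = filter_variable_cpgs(m, 0.1)
        expected = [f"cg{j}" for j in range(100)
                    if np.std(vals[:, j], ddof=1) >= 0.1]
        assert list(got.feature_ids) == expected

    def test_idempotent(self, rng):
        m = _meth(rng.beta(2, 5, (15, 50)))
        once = filter_variable_cpgs(m, 0.05)
        twice = filter_variable_cpgs(once, 0.05)
        assert list(once.feature_ids) == list(twice.feature_ids)


def _enum_hwe_p(n_het, n_hom1, n_hom2):
    """Independent HWE exact oracle: direct enumeration of the conditional
    multinomial P(het | n, rare allele count) with exact rational arithmetic."""
    from fractions import Fraction

    n = n_het + n_hom1 + n_hom2
    rare = 2 * min(n_hom1, n_hom2) + n_het
    common = 2 * n - rare
    f = math.factorial

    def prob(het):
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        return (Fraction(f(n), f(hom_r) * f(het) * f(hom_c)) * 2 ** het
                * Fraction(f(rare) * f(common), f(2 * n)))

    hets = [h for h in range(rare % 2, min(rare, n) + 1, 2)
            if (rare - h) // 2 + h <= n and n - h - (rare - h) // 2 >= 0]
    probs = {h: prob(h) for h in hets}
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    return float(sum(v for v in probs.values() if v / total <= p_obs) / total)


class TestSnpQc:
    def test_hwe_exact_matches_enumeration_oracle(self):
        for counts in [(50, 25, 25), (10, 80, 10), (0, 90, 10), (30, 60, 10),
                       (5, 5, 5), (1, 0, 99)]:
            het, h1, h2 = counts
            assert hwe_exact_pvalue(het, h1, h2) == pytest.approx(
                _enum_hwe_p(het, h1, h2), rel=1e-9)

    def test_perfect_hwe_proportions_pass(self):
        # genotype counts (25, 50, 25) at n=100: textbook HWE
        assert hwe_exact_pvalue(50, 25, 25) > 0.5

    def _geno(self, vals):
        ids = [f"snp{j}" for j in range(vals.shape[1])]
        ann = pd.DataFrame({"chrom": "1", "pos": np.arange(1, vals.shape[1] + 1)},
                           index=ids)
        samples = pd.Index([f"s{i}" for i in range(vals.shape[0])])
        return GenotypeMatrix(pd.DataFrame(vals, index=samples, columns=ids), ann)

    def test_monomorphic_snp_removed(self, rng):
        vals = rng.binomial(2, 0.3, (50, 3)).astype(float)
        vals[:, 1] = 0.0
        kept, counts = filter_snps(self._geno(vals), maf_min=0.01)
        assert "snp1" not in kept.feature_ids and counts["maf"] >= 1

    def test_survivors_match_brute_force_qc(self, rng):
        n, m = 120, 200
        vals = rng.binomial(2, rng.uniform(0.02, 0.5, m), (n, m)).astype(float)
        miss = rng.random((n, m)) < rng.choice([0.0, 0.02, 0.10], m)
        vals[miss] = np.nan
        geno = self._geno(vals)
        kept, _ = filter_snps(geno, maf_min=0.05, hwe_alpha=1e-3, max_missing=0.05)
        expected = []
        for j in range(m):
            col = vals[:, j]
            obs = col[~np.isnan(col)]
            p = obs.mean() / 2 if obs.size else 0.0
            maf = min(p, 1 - p)
            hwe = _enum_hwe_p(int((obs == 1).sum()), int((obs == 0).sum()),
                              int((obs == 2).sum())) if obs.size else 1.0
            if maf >= 0.05 and hwe >= 1e-3 and np.isnan(col).mean() <= 0.05:
                expected.append(f"snp{j}")
        assert list(kept.feature_ids) == expected

    def test_idempotent(self, rng):
        vals = rng.binomial(2, rng.uniform(0.05, 0.5, 50), (80, 50)).astype(float)
        once, _ = filter_snps(self._geno(vals))
        twice, _ = filter_snps(once)
        assert list(once.feature_ids) == list(twice.feature_ids)


class TestRoundTrip:
    def test_matrix_and_annotation_round_trip(self, tmp_path, small_study):
        vals = small_study.methylation.values.iloc[:10, :10]
        write_matrix(vals, tmp_path / "m.tsv")
        back = read_matrix(tmp_path / "m.tsv")
        assert list(back.index) == list(vals.index)
        assert list(back.columns) == list(vals.columns)
        np.testing.assert_allclose(back.to_numpy(), vals.to_numpy(), rtol=1e-12)

        ann = small_study.methylation.annotation.iloc[:10]
        write_annotation(ann, tmp_path / "a.tsv")
        back_ann = read_annotation(tmp_path / "a.tsv")
        assert list(back_ann.index) == list(ann.index)
        assert (back_ann["cgi_relation"] == ann["cgi_relation"]).all()

    def test_missing_values_round_trip_as_na(self, tmp_path):
        vals = pd.DataFrame([[1.0, np.nan], [0.0, 2.0]],
                            index=["s1", "s2"], columns=["a", "b"])
        write_matrix(vals, tmp_path / "g.tsv")
        text = (tmp_path / "g.tsv").read_text()
        assert "NA" in text
        back = read_matrix(tmp_path / "g.tsv")
        assert np.isnan(back.loc["s1", "b"])
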