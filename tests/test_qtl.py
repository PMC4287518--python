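"""Cis-QTL machinery: Spearman oracle, weighted-Z closed forms, the
permutation-FDR counting rule, planted-effect recovery, and direction overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regulome_qtl.experiments import (default_study_config, eqtl_fdr_config,
                                      null_study_config)
from regulome_qtl.qtl import (map_cis_qtl, meta_weighted_z, overlap_eqtl_meqtl,
                              permutation_fdr, spearman_assoc)
from regulome_qtl.simulate import simulate_study


def brute_force_spearman(x, y):
    """Independent rank correlation: average ranks built by sorting, then the
    Pearson product-moment formula on the ranks."""
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v), dtype=float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r
    rx, ry = ranks(np.asarray(x)), ranks(np.asarray(y))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


class TestSpearman:
    def test_perfect_monotone_in_dosage(self):
        # trait strictly increasing in genotype class (tied within class, so
        # the rank patterns coincide exactly)
        dos = np.repeat([0, 1, 2], 4)
        trait = np.repeat([1.0, 5.0, 9.0], 4)
        assert spearman_assoc(dos, trait)["rho"] == pytest.approx(1.0)

    def test_worked_example_matches_rank_formula(self):
        dos = np.array([0, 0, 1, 1, 2, 2] * 2, dtype=float)
        trait = np.array([1.2, 0.8, 2.1, 1.9, 3.3, 3.0] * 2)
        got = spearman_assoc(dos, trait)
        assert got["rho"] == pytest.approx(brute_force_spearman(dos, trait),
                                           abs=1e-12)

    def test_agrees_with_brute_force_on_random_vectors(self, rng):
        for _ in range(1000):
            n = int(rng.integers(10, 40))
            dos = rng.integers(0, 3, n).astype(float)
            if np.unique(dos).size < 2:
                continue
            trait = np.round(rng.normal(size=n), 2)  # ties likely
            got = spearman_assoc(dos, trait)
            assert got["rho"] == pytest.approx(brute_force_spearman(dos, trait),
                                               abs=1e-12)

    def test_negation_symmetry(self, rng):
        dos = rng.integers(0, 3, 30).astype(float)
        trait = rng.normal(size=30)
        a = spearman_assoc(dos, trait)
        b = spearman_assoc(2 - dos, trait)
        assert abs(a["rho"]) == pytest.approx(abs(b["rho"]), abs=1e-12)
        assert a["rho"] == pytest.approx(-b["rho"], abs=1e-12)

    def test_skip_reasons_are_coded_not_raised(self):
        assert spearman_assoc(np.zeros(20), np.arange(20.0))["skipped"] \
            == "single_genotype_class"
        assert spearman_assoc(np.tile([0., 1], 10), np.ones(20))["skipped"] \
            == "constant_trait"
        assert spearman_assoc(np.array([0., 1, 2]), np.arange(3.0))["skipped"] \
            == "too_few_samples"


class TestMetaWeightedZ:
    def test_single_cohort_identity(self):
        assert meta_weighted_z([2.0], [50])["meta_z"] == pytest.approx(2.0)

    def test_equal_n_unit_zs_give_sqrt_two(self):
        assert meta_weighted_z([1.0, 1.0], [80, 80])["meta_z"] \
            == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_opposite_zs_cancel(self):
        assert meta_weighted_z([2.0, -2.0], [80, 80])["meta_z"] \
            == pytest.approx(0.0, abs=1e-12)

    def test_invariant_under_cohort_reordering(self, rng):
        zs = rng.normal(size=4)
        ns = rng.integers(20, 200, 4)
        base = meta_weighted_z(zs, ns)["meta_z"]
        perm = rng.permutation(4)
        assert meta_weighted_z(zs[perm], ns[perm])["meta_z"] \
            == pytest.approx(base, abs=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            meta_weighted_z([1.0, 2.0], [10])


class TestPermutationFdr:
    def test_hand_counting_oracle(self):
        # 5 features, 2 permutations of per-feature top |meta z|
        obs = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        perm = np.array([[2.5, 1.0, 0.5, 4.5, 1.5],
                         [0.5, 3.5, 1.0, 2.0, 1.0]])
        fdr, thr = permutation_fdr(obs, perm, alpha=0.5)
        # by hand: pooled nulls >= t (over 2 perms, halved) / observed >= t
        # t=5: 0/2/1; t=4: {4.5} -> 0.5/2; t=3: {4.5,3.5} -> 1/3;
        # t=2: {4.5,3.5,2.5,2.0} -> 2/4; t=1: 8 nulls -> 4/5
        expected = [0.0, 0.25, 1 / 3, 0.5, 0.8]
        np.testing.assert_allclose(fdr, expected)
        assert thr == 3.0  # smallest observed top with FDR < 0.5

    def test_empty_null_tail_gives_zero_fdr(self):
        obs = np.array([4.0, 5.0, 6.0])
        perm = np.array([[1.0, 2.0, 3.0]])
        fdr, thr = permutation_fdr(obs, perm, alpha=0.05)
        np.testing.assert_allclose(fdr, 0.0)
        assert thr == 4.0

    def test_null_identical_to_observed_saturates(self):
        obs = np.array([3.0, 2.0, 1.0])
        fdr, _ = permutation_fdr(obs, obs[None, :], alpha=0.05)
        np.testing.assert_allclose(fdr, 1.0)

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_fdr(np.array([1.0]), np.empty((0, 1)))


class TestMapCisQtl:
    def test_planted_eqtls_recovered_with_correct_signs(self):
        """40 planted standardized-slope-0.6 eQTLs over 500 probes, n=150 in
        two cohorts, 10 permutations: >=80% recovered at FDR<0.05, no sign
        errors among recovered effects."""
        cfg = eqtl_fdr_config(101, planted_fraction=0.08)  # 40 planted
        s = simulate_study(cfg)
        mapping = map_cis_qtl(s.genotypes, s.expression, s.sample_sheet,
                              n_perm=10, alpha=0.05, mode="eqtl", seed=101)
        truth = s.truth.of_kind("eqtl").set_index(["left_id", "right_id"])
        assert len(truth) == 40
        sig = mapping.significant
        keys = set(zip(sig["snp_id"], sig["feature_id"]))
        recovered = [k for k in truth.index if k in keys]
        assert len(recovered) >= 0.8 * len(truth)
        sig_idx = sig.set_index(["snp_id", "feature_id"])
        for k in recovered:
            got = sig_idx.loc[k, "direction"]
            want = truth.loc[k, "direction"]
            assert got == want

    def test_same_seed_and_inputs_reproduce_tables(self, small_study):
        s = small_study
        a = map_cis_qtl(s.genotypes, s.expression, s.sample_sheet, n_perm=3, seed=5)
        b = map_cis_qtl(s.genotypes, s.expression, s.sample_sheet, n_perm=3, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_significant_set_monotone_in_alpha(self, small_study):
        s = small_study
        sets = []
        for alpha in (0.01, 0.05, 0.2):
            m = map_cis_qtl(s.genotypes, s.expression, s.sample_sheet,
                            n_perm=5, alpha=alpha, seed=3)
            sets.append(set(m.significant_features()))
        assert sets[0] <= sets[1] <= sets[2]

    def test_exactly_one_top_per_feature(self, small_study):
        s = small_study
        m = map_cis_qtl(s.genotypes, s.methylation, s.sample_sheet,
                        n_perm=2, mode="meqtl", seed=1)
        tops = m.table[m.table["top_flag"]]
        assert tops["feature_id"].is_unique
        assert set(tops["feature_id"]) == set(m.table["feature_id"])

    def test_meqtl_mode_excludes_probe_snp_conflicts(self, small_study):
        s = small_study
        m = map_cis_qtl(s.genotypes, s.methylation, s.sample_sheet,
                        n_perm=2, mode="meqtl", seed=1)
        pos = s.genotypes.annotation["pos"]
        ann = s.methylation.annotation
        for _, r in m.table.iterrows():
            p = pos[r["snp_id"]]
            lo, hi = ann.loc[r["feature_id"], ["interval_start", "interval_end"]]
            assert not (lo <= p <= hi)

    def test_no_overlapping_samples_rejected(self, small_study):
        s = small_study
        sheet = s.sample_sheet.copy()
        sheet["sample_id"] = "x_" + sheet["sample_id"]
        with pytest.raises(ValueError, match="no cohort"):
            map_cis_qtl(s.genotypes, s.expression, sheet, n_perm=2)


class TestOverlapEqtlMeqtl:
    def _row(self, snp, feat, gene, z):
        return {"snp_id": snp, "feature_id": feat, "gene": gene, "meta_z": z}

    def test_single_opposite_direction_overlap(self):
        eqtl = pd.DataFrame([self._row("rs1", "p1", "G1", -4.0)])
        meqtl = pd.DataFrame([self._row("rs1", "c1", "G1", 5.0)])
        cpg_ann = pd.DataFrame({"cgi_relation": ["island"]}, index=["c1"])
        out = overlap_eqtl_meqtl(eqtl, meqtl, cpg_ann)
        assert len(out["pairs"]) == 1
        assert out["pairs"]["overlap_class"].iloc[0] == "opposite"
        assert out["fraction_opposite"] == 1.0

    def test_empty_eqtl_set_gives_empty_overlap(self):
        eqtl = pd.DataFrame(columns=["snp_id", "feature_id", "gene", "meta_z"])
        meqtl = pd.DataFrame([self._row("rs1", "c1", "G1", 5.0)])
        out = overlap_eqtl_meqtl(eqtl, meqtl, pd.DataFrame({"cgi_relation": []}))
        assert len(out["pairs"]) == 0 and np.isnan(out["fraction_opposite"])

    def test_planted_opposite_fraction_recovered(self):
        """Shared SNP effects planted with 70% opposite allelic direction are
        recovered within binomial 95% bounds after full eQTL+meQTL mapping."""
        cfg = default_study_config(
            seed=77, n_snps=400, n_cpgs=400, n_probes=200,
            n_adult_a=96, n_fetal_a=0, n_adult_b=85, tissues_b=("liver",),
            fraction_shared_snp=0.30, fraction_opposite_direction=0.7,
            fraction_eqtl=0.0, fraction_meqtl=0.0, fraction_eqtm=0.0,
            fraction_eqtl_and_eqtm=0.0, fraction_diff_meth=0.0,
            fraction_diff_expr=0.0, tissue_sharing_eqtl=1.0,
            tissue_sharing_meqtl=1.0, fraction_sign_flip_shared=0.0)
        s = simulate_study(cfg)
        eqtl = map_cis_qtl(s.genotypes, s.expression, s.sample_sheet,
                           n_perm=10, seed=7, mode="eqtl")
        meqtl = map_cis_qtl(s.genotypes, s.methylation, s.sample_sheet,
                            n_perm=10, seed=7, mode="meqtl")
        out = overlap_eqtl_meqtl(eqtl.significant, meqtl.significant,
                                 s.methylation.annotation)
        n = len(out["gene_summary"])
        assert n >= 40
        half_width = 1.96 * np.sqrt(0.7 * 0.3 / n)
        assert abs(out["fraction_opposite"] - 0.7) <= half_width + 0.05


def test_null_scan_declares_nothing_and_uniform_p():
    cfg = null_study_config(5, n_adult_a=75, n_fetal_a=0, n_adult_b=75,
                            tissues_b=("liver",), n_probes=300, n_snps=600,
                            n_cpgs=20)
    s = simulate_study(cfg)
    m = map_cis_qtl(s.genotypes, s.expression, s.sample_sheet, n_perm=5, seed=5)
    assert stats.kstest(m.table["meta_p"], "uniform").pvalue > 0.01
    assert len(m.significant_features()) / len(m.feature_fdr) <= 0.05
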