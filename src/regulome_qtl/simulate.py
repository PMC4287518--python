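"""Synthetic multi-cohort, multi-tissue genotype/methylation/expression studies.

The generator emulates a two-cohort liver study design: cohort A contributes
adult and fetal liver samples, cohort B contributes adult samples across four
tissues (liver, muscle, SAT, VAT) from the same donors. Effects are planted
as standardized slopes — a slope s contributes s * z(predictor) * noise_sd to
the outcome, so s^2/(1+s^2) is the expected variance fraction explained —
with configurable tissue sharing and allelic-direction architecture, and every
planted effect is registered exactly once in a truth table that downstream
acceptance checks use as their oracle.

Methylation is simulated on a latent M-value-like scale and mapped to beta
values through beta = 2^m / (2^m + 1), so genetic and developmental effects
are additive on the latent scale while all association tests see [0,1] betas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import (CGI_RELATIONS, BODY_REGIONS, ExpressionMatrix,
                        GenotypeMatrix, MethylationMatrix,
                        validate_sample_sheet, write_annotation, write_matrix,
                        write_sample_sheet)

LOG2 = np.log(2.0)

TRUTH_COLUMNS = ["effect_kind", "left_id", "right_id", "true_slope", "direction",
                 "tissues_active", "cohorts_active", "flipped_tissues", "shared",
                 "distance_bp"]


@dataclass
class SimulationConfig:
    """Study-design and effect-architecture parameters (defaults = the emulated
    two-cohort liver design: 96+14 cohort-A adult/fetal livers, 85 cohort-B
    donors with four tissues)."""

    seed: int
    # cohort / tissue design
    n_adult_a: int = 96
    n_fetal_a: int = 14
    n_adult_b: int = 85
    tissues_b: Tuple[str, ...] = ("liver", "muscle", "SAT", "VAT")
    # feature panel and geometry (one synthetic chromosome, disjoint cis windows)
    n_snps: int = 600
    n_cpgs: int = 600
    n_probes: int = 300
    maf_range: Tuple[float, float] = (0.05, 0.5)
    probe_spacing_bp: int = 600_000
    max_offset_bp: int = 200_000
    cgi_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"island": 0.30, "shore": 0.25, "shelf": 0.15, "other": 0.30})
    body_region_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"TSS-proximal": 0.25, "exon": 0.20,
                                 "intron": 0.35, "intergenic": 0.20})
    # planted cis effects (standardized slopes)
    fraction_eqtl: float = 0.05
    fraction_meqtl: float = 0.10
    fraction_eqtm: float = 0.10
    fraction_eqtl_and_eqtm: float = 0.03
    fraction_shared_snp: float = 0.05
    fraction_opposite_direction: float = 0.7
    eqtl_slope: float = 0.6
    meqtl_slope: float = 0.8
    eqtm_slope: float = 0.6
    negative_eqtm_fraction_near: float = 0.70
    negative_eqtm_fraction_far: float = 0.50
    eqtm_near_bp: int = 50_000
    # fetal-vs-adult group effects
    fraction_diff_meth: float = 0.10
    fraction_diff_expr: float = 0.10
    group_latent_shift: float = 2.0
    group_log2fc: float = 3.0
    island_hypo_bias: float = 0.86
    # tissue sharing of cis effects (liver is always active)
    tissue_sharing_eqtl: float = 0.45
    tissue_sharing_meqtl: float = 0.70
    tissue_sharing_eqtm: float = 0.04
    fraction_sign_flip_shared: float = 0.02
    # nuisance structure
    cohort_offset_sd: float = 0.2
    noise_sd_meth: float = 0.5
    noise_sd_expr: float = 1.0
    mu_cpg_range: Tuple[float, float] = (-3.0, 3.0)
    mu_probe_range: Tuple[float, float] = (6.0, 12.0)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_adult_a + self.n_fetal_a + self.n_adult_b <= 0:
            raise ValueError("every sample cell is empty")
        for name in ("n_snps", "n_cpgs", "n_probes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within [0, 0.5]")
        for name in ("fraction_eqtl", "fraction_meqtl", "fraction_eqtm",
                     "fraction_eqtl_and_eqtm", "fraction_shared_snp",
                     "fraction_opposite_direction", "fraction_diff_meth",
                     "fraction_diff_expr", "island_hypo_bias",
                     "tissue_sharing_eqtl", "tissue_sharing_meqtl",
                     "tissue_sharing_eqtm", "fraction_sign_flip_shared",
                     "negative_eqtm_fraction_near", "negative_eqtm_fraction_far"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} not in [0, 1]")

    def with_overrides(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


class TruthTable:
    """Registry of planted effects; the acceptance oracle.

    Also carries auxiliary generation-time state (`aux`): per-CpG latent means
    and the latent M matrix, which the expression stage consumes for eQTM terms.
    """

    def __init__(self) -> None:
        self.records: list[dict] = []
        self.aux: dict = {}

    def add(self, **kw) -> None:
        rec = {c: kw.get(c) for c in TRUTH_COLUMNS}
        rec.setdefault("cohorts_active")
        if rec["cohorts_active"] is None:
            rec["cohorts_active"] = "A,B"
        if rec["flipped_tissues"] is None:
            rec["flipped_tissues"] = ""
        if rec["shared"] is None:
            rec["shared"] = False
        self.records.append(rec)

    def frame(self) -> pd.DataFrame:
        if not self.records:
            return pd.DataFrame(columns=TRUTH_COLUMNS)
        return pd.DataFrame(self.records, columns=TRUTH_COLUMNS)

    def of_kind(self, kind: str) -> pd.DataFrame:
        df = self.frame()
        return df[df["effect_kind"] == kind].reset_index(drop=True)


@dataclass
class Architecture:
    """Feature annotations plus the probe-neighborhood assignment of SNPs/CpGs."""
    snps: pd.DataFrame
    cpgs: pd.DataFrame
    probes: pd.DataFrame
    snp_probe: np.ndarray   # probe index per SNP
    cpg_probe: np.ndarray   # probe index per CpG


def build_sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for i in range(config.n_adult_a):
        ind = f"A{i + 1:03d}"
        rows.append((f"{ind}_liver", "A", "adult", "liver", ind))
    for i in range(config.n_fetal_a):
        ind = f"AF{i + 1:03d}"
        rows.append((f"{ind}_liver", "A", "fetal", "liver", ind))
    for i in range(config.n_adult_b):
        ind = f"B{i + 1:03d}"
        for t in config.tissues_b:
            rows.append((f"{ind}_{t}", "B", "adult", t, ind))
    sheet = pd.DataFrame(rows, columns=["sample_id", "cohort", "group", "tissue",
                                        "individual"])
    return validate_sample_sheet(sheet)


def build_architecture(config: SimulationConfig, rng: np.random.Generator) -> Architecture:
    """One synthetic chromosome; probes spaced so cis windows do not overlap;
    SNPs and CpGs assigned round-robin to probe neighborhoods."""
    n_p, n_s, n_c = config.n_probes, config.n_snps, config.n_cpgs
    tss = 500_000 + np.arange(n_p, dtype=np.int64) * config.probe_spacing_bp
    probes = pd.DataFrame({
        "chrom": "1", "start": tss, "end": tss + 49,
        "gene": [f"GENE{i + 1:04d}" for i in range(n_p)], "tss": tss,
    }, index=pd.Index([f"probe{i + 1:04d}" for i in range(n_p)], name="feature_id"))

    snp_probe = np.arange(n_s) % n_p
    snp_pos = tss[snp_probe] + rng.integers(-config.max_offset_bp,
                                            config.max_offset_bp + 1, n_s)
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, n_s) if hi > lo else np.full(n_s, lo)
    snps = pd.DataFrame({
        "chrom": "1", "pos": snp_pos, "effect_allele": "A", "other_allele": "G",
        "maf": mafs, "gene": probes["gene"].to_numpy()[snp_probe],
    }, index=pd.Index([f"snp{j + 1:05d}" for j in range(n_s)], name="feature_id"))

    cpg_probe = np.arange(n_c) % n_p
    cpg_pos = tss[cpg_probe] + rng.integers(-config.max_offset_bp,
                                            config.max_offset_bp + 1, n_c)
    cgi = rng.choice(list(config.cgi_proportions),
                     p=np.array(list(config.cgi_proportions.values()))
                     / sum(config.cgi_proportions.values()), size=n_c)
    body = rng.choice(list(config.body_region_proportions),
                      p=np.array(list(config.body_region_proportions.values()))
                      / sum(config.body_region_proportions.values()), size=n_c)
    cpgs = pd.DataFrame({
        "chrom": "1", "pos": cpg_pos, "cgi_relation": cgi, "body_region": body,
        "gene": probes["gene"].to_numpy()[cpg_probe],
        "interval_start": cpg_pos - 25, "interval_end": cpg_pos + 24,
    }, index=pd.Index([f"cg{k + 1:06d}" for k in range(n_c)], name="feature_id"))
    return Architecture(snps, cpgs, probes, snp_probe, cpg_probe)


# ---------------------------------------------------------------------------
# effect planting
# ---------------------------------------------------------------------------

def _draw_tissues(config: SimulationConfig, sharing: float,
                  rng: np.random.Generator) -> Tuple[str, str]:
    """(tissues_active, flipped_tissues) as comma-joined strings; liver always active."""
    active = ["liver"]
    for t in config.tissues_b:
        if t != "liver" and rng.random() < sharing:
            active.append(t)
    flipped = []
    non_liver = [t for t in active if t != "liver"]
    if non_liver and rng.random() < config.fraction_sign_flip_shared:
        flipped.append(str(rng.choice(non_liver)))
    return ",".join(active), ",".join(flipped)


def plant_effects(config: SimulationConfig, arch: Architecture,
                  rng: np.random.Generator, truth: TruthTable) -> None:
    n_p, n_c = config.n_probes, config.n_cpgs
    probe_ids = arch.probes.index.to_numpy()
    cpg_ids = arch.cpgs.index.to_numpy()
    snps_of = [np.where(arch.snp_probe == i)[0] for i in range(n_p)]
    cpgs_of = [np.where(arch.cpg_probe == i)[0] for i in range(n_p)]
    probe_mid = ((arch.probes["start"] + arch.probes["end"]) // 2).to_numpy()

    def pick(arr):
        return int(rng.choice(arr))

    # --- shared SNPs driving both methylation and expression of one gene ---
    shared_probes = np.array([], dtype=int)
    n_shared = int(round(config.fraction_shared_snp * n_p))
    eligible = [i for i in range(n_p) if len(snps_of[i]) and len(cpgs_of[i])]
    used_cpgs: set[int] = set()
    if n_shared and eligible:
        shared_probes = rng.choice(eligible, size=min(n_shared, len(eligible)),
                                   replace=False)
        for i in shared_probes:
            s, c = pick(snps_of[i]), pick(cpgs_of[i])
            used_cpgs.add(c)
            s_m = 1.0 if rng.random() < 0.5 else -1.0
            opposite = rng.random() < config.fraction_opposite_direction
            s_e = -s_m if opposite else s_m
            tis_m, flip_m = _draw_tissues(config, config.tissue_sharing_meqtl, rng)
            tis_e, flip_e = _draw_tissues(config, config.tissue_sharing_eqtl, rng)
            truth.add(effect_kind="meqtl", left_id=arch.snps.index[s],
                      right_id=cpg_ids[c], true_slope=s_m * config.meqtl_slope,
                      direction="+" if s_m > 0 else "-", tissues_active=tis_m,
                      flipped_tissues=flip_m, shared=True,
                      distance_bp=int(arch.cpgs["pos"].iloc[c] - arch.snps["pos"].iloc[s]))
            truth.add(effect_kind="eqtl", left_id=arch.snps.index[s],
                      right_id=probe_ids[i], true_slope=s_e * config.eqtl_slope,
                      direction="+" if s_e > 0 else "-", tissues_active=tis_e,
                      flipped_tissues=flip_e, shared=True,
                      distance_bp=int(probe_mid[i] - arch.snps["pos"].iloc[s]))

    # --- plain meQTL on CpGs not already used by shared effects ---
    n_meqtl = int(round(config.fraction_meqtl * n_c))
    free_cpgs = [c for c in range(n_c) if c not in used_cpgs
                 and len(snps_of[arch.cpg_probe[c]])]
    if n_meqtl and free_cpgs:
        for c in rng.choice(free_cpgs, size=min(n_meqtl, len(free_cpgs)), replace=False):
            s = pick(snps_of[arch.cpg_probe[c]])
            sign = 1.0 if rng.random() < 0.5 else -1.0
            tis, flip = _draw_tissues(config, config.tissue_sharing_meqtl, rng)
            truth.add(effect_kind="meqtl", left_id=arch.snps.index[s],
                      right_id=cpg_ids[c], true_slope=sign * config.meqtl_slope,
                      direction="+" if sign > 0 else "-", tissues_active=tis,
                      flipped_tissues=flip,
                      distance_bp=int(arch.cpgs["pos"].iloc[c] - arch.snps["pos"].iloc[s]))

    # --- eQTL / eQTM / both, on probes outside the shared set ---
    taken = set(shared_probes.tolist())
    n_eqtl_total = int(round(config.fraction_eqtl * n_p))
    n_eqtm_total = int(round(config.fraction_eqtm * n_p))
    n_both = min(int(round(config.fraction_eqtl_and_eqtm * n_p)),
                 n_eqtl_total, n_eqtm_total)

    def _draw(candidates, k):
        cand = np.array([i for i in candidates if i not in taken])
        got = rng.choice(cand, size=min(k, len(cand)), replace=False) if k and len(cand) \
            else np.array([], dtype=int)
        taken.update(got.tolist())
        return got

    both_set = _draw([i for i in range(n_p) if len(snps_of[i]) and len(cpgs_of[i])],
                     n_both)
    eqtl_only = _draw([i for i in range(n_p) if len(snps_of[i])],
                      n_eqtl_total - len(both_set))
    eqtm_only = _draw([i for i in range(n_p) if len(cpgs_of[i])],
                      n_eqtm_total - len(both_set))
    eqtl_set = np.concatenate([both_set, eqtl_only]).astype(int)
    eqtm_set = np.concatenate([both_set, eqtm_only]).astype(int)

    for i in eqtl_set:
        s = pick(snps_of[i])
        sign = 1.0 if rng.random() < 0.5 else -1.0
        tis, flip = _draw_tissues(config, config.tissue_sharing_eqtl, rng)
        truth.add(effect_kind="eqtl", left_id=arch.snps.index[s],
                  right_id=probe_ids[i], true_slope=sign * config.eqtl_slope,
                  direction="+" if sign > 0 else "-", tissues_active=tis,
                  flipped_tissues=flip,
                  distance_bp=int(probe_mid[i] - arch.snps["pos"].iloc[s]))
    for i in eqtm_set:
        c = pick(cpgs_of[i])
        dist = int(arch.cpgs["pos"].iloc[c] - probe_mid[i])
        p_neg = (config.negative_eqtm_fraction_near if abs(dist) <= config.eqtm_near_bp
                 else config.negative_eqtm_fraction_far)
        sign = -1.0 if rng.random() < p_neg else 1.0
        tis, flip = _draw_tissues(config, config.tissue_sharing_eqtm, rng)
        truth.add(effect_kind="eqtm", left_id=cpg_ids[c], right_id=probe_ids[i],
                  true_slope=sign * config.eqtm_slope,
                  direction="-" if sign < 0 else "+", tissues_active=tis,
                  flipped_tissues=flip, distance_bp=dist)

    # --- fetal-vs-adult group effects ---
    n_dm = int(round(config.fraction_diff_meth * n_c))
    dm_idx = rng.choice(n_c, size=n_dm, replace=False) if n_dm else np.array([], dtype=int)
    is_island = (arch.cpgs["cgi_relation"].to_numpy() == "island")
    for c in dm_idx:
        p_hypo = config.island_hypo_bias if is_island[c] else 0.5
        sign = -1.0 if rng.random() < p_hypo else 1.0  # hypo = lower in fetal
        truth.add(effect_kind="diff_meth", left_id=cpg_ids[c], right_id="",
                  true_slope=sign * config.group_latent_shift,
                  direction="up_in_fetal" if sign > 0 else "down_in_fetal",
                  tissues_active="liver")
    truth.aux["dm_idx"] = np.asarray(dm_idx, dtype=int)

    n_de = int(round(config.fraction_diff_expr * n_p))
    de_idx = rng.choice(n_p, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    for i in de_idx:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        truth.add(effect_kind="diff_expr", left_id=probe_ids[i], right_id="",
                  true_slope=sign * config.group_log2fc,
                  direction="up_in_fetal" if sign > 0 else "down_in_fetal",
                  tissues_active="liver")


# ---------------------------------------------------------------------------
# matrix generation
# ---------------------------------------------------------------------------

def _standardized_dosage(dosage: np.ndarray, maf: float) -> np.ndarray:
    """Theoretical HWE standardization; degenerate (monomorphic) MAF -> zeros."""
    var = 2 * maf * (1 - maf)
    if var <= 0:
        return np.zeros_like(dosage, dtype=float)
    return (dosage - 2 * maf) / np.sqrt(var)


def _effect_sample_signs(rec: Mapping, sheet: pd.DataFrame) -> np.ndarray:
    """Per-sample multiplier: 0 if the effect is inactive in the sample's tissue,
    +/-1 otherwise (flipped tissues reverse the sign)."""
    active = set(str(rec["tissues_active"]).split(","))
    flipped = set(t for t in str(rec["flipped_tissues"]).split(",") if t)
    tissue = sheet["tissue"].to_numpy()
    out = np.where(np.isin(tissue, list(active)), 1.0, 0.0)
    if flipped:
        out = np.where(np.isin(tissue, list(flipped)), -out, out)
    return out


def simulate_genotypes(config: SimulationConfig,
                       snp_ann: Optional[pd.DataFrame] = None,
                       sample_sheet: Optional[pd.DataFrame] = None,
                       rng: Optional[np.random.Generator] = None) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes per individual, replicated across that
    individual's tissue samples."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if snp_ann is None:
        snp_ann = build_architecture(config, rng).snps
    if sample_sheet is None:
        sample_sheet = build_sample_sheet(config)
    individuals = pd.unique(sample_sheet["individual"])
    mafs = snp_ann["maf"].to_numpy(dtype=float)
    dos_ind = rng.binomial(2, mafs[None, :], size=(len(individuals), len(mafs))).astype(float)
    ind_row = pd.Series(np.arange(len(individuals)), index=individuals)
    rows = dos_ind[ind_row.loc[sample_sheet["individual"]].to_numpy()]
    values = pd.DataFrame(rows, index=pd.Index(sample_sheet["sample_id"]),
                          columns=snp_ann.index)
    return GenotypeMatrix(values, snp_ann)


def simulate_methylation(genotypes: GenotypeMatrix, sample_sheet: pd.DataFrame,
                         config: SimulationConfig, truth: TruthTable,
                         cpg_ann: Optional[pd.DataFrame] = None,
                         rng: Optional[np.random.Generator] = None) -> MethylationMatrix:
    """Latent m = mu + cohort offset + planted meQTL + fetal shift + noise;
    beta = 2^m / (2^m + 1). Stores the latent matrix in truth.aux."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    if cpg_ann is None:
        cpg_ann = truth.aux.get("cpg_ann")
    if cpg_ann is None:
        raise ValueError("cpg annotation required (pass cpg_ann or run simulate_study)")
    n_s, n_c = len(sample_sheet), len(cpg_ann)
    if "mu_cpg" not in truth.aux:
        lo, hi = config.mu_cpg_range
        mu = rng.uniform(lo, hi, n_c)
        # keep group-affected CpGs near the sigmoid's steep region so the
        # planted latent shift translates into |delta beta| > 0.2
        for c in truth.aux.get("dm_idx", []):
            mu[c] = rng.uniform(-0.5, 0.5)
        truth.aux["mu_cpg"] = pd.Series(mu, index=cpg_ann.index)
    mu = truth.aux["mu_cpg"].to_numpy()

    cohorts = sorted(sample_sheet["cohort"].unique())
    offsets = rng.normal(0, config.cohort_offset_sd, (len(cohorts), n_c))
    cidx = pd.Series(np.arange(len(cohorts)), index=cohorts)
    M = mu[None, :] + offsets[cidx.loc[sample_sheet["cohort"]].to_numpy()]

    col = pd.Series(np.arange(n_c), index=cpg_ann.index)
    dos = genotypes.values
    for rec in truth.of_kind("meqtl").to_dict("records"):
        c = col[rec["right_id"]]
        maf = float(genotypes.annotation.loc[rec["left_id"], "maf"])
        z = _standardized_dosage(dos[rec["left_id"]].to_numpy(), maf)
        M[:, c] += (rec["true_slope"] * config.noise_sd_meth * z
                    * _effect_sample_signs(rec, sample_sheet))
    fetal = (sample_sheet["group"] == "fetal").to_numpy()
    for rec in truth.of_kind("diff_meth").to_dict("records"):
        M[fetal, col[rec["left_id"]]] += rec["true_slope"]
    if config.noise_sd_meth > 0:
        M = M + rng.normal(0, config.noise_sd_meth, (n_s, n_c))
    betas = 1.0 / (1.0 + np.exp(-LOG2 * M))  # = 2^m / (2^m + 1)
    truth.aux["latent_m"] = pd.DataFrame(M, index=pd.Index(sample_sheet["sample_id"]),
                                         columns=cpg_ann.index)
    values = pd.DataFrame(betas, index=pd.Index(sample_sheet["sample_id"]),
                          columns=cpg_ann.index)
    return MethylationMatrix(values, cpg_ann)


def simulate_expression(genotypes: GenotypeMatrix, methylation: MethylationMatrix,
                        sample_sheet: pd.DataFrame, config: SimulationConfig,
                        truth: TruthTable,
                        probe_ann: Optional[pd.DataFrame] = None,
                        rng: Optional[np.random.Generator] = None) -> ExpressionMatrix:
    """y = mu + cohort offset + eQTL + eQTM (on the latent methylation scale)
    + fetal log2FC + noise."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    if probe_ann is None:
        probe_ann = truth.aux.get("probe_ann")
    if probe_ann is None:
        raise ValueError("probe annotation required (pass probe_ann or run simulate_study)")
    n_s, n_p = len(sample_sheet), len(probe_ann)
    lo, hi = config.mu_probe_range
    mu = rng.uniform(lo, hi, n_p)
    cohorts = sorted(sample_sheet["cohort"].unique())
    offsets = rng.normal(0, config.cohort_offset_sd, (len(cohorts), n_p))
    cidx = pd.Series(np.arange(len(cohorts)), index=cohorts)
    Y = mu[None, :] + offsets[cidx.loc[sample_sheet["cohort"]].to_numpy()]

    col = pd.Series(np.arange(n_p), index=probe_ann.index)
    dos = genotypes.values
    for rec in truth.of_kind("eqtl").to_dict("records"):
        maf = float(genotypes.annotation.loc[rec["left_id"], "maf"])
        z = _standardized_dosage(dos[rec["left_id"]].to_numpy(), maf)
        Y[:, col[rec["right_id"]]] += (rec["true_slope"] * config.noise_sd_expr * z
                                       * _effect_sample_signs(rec, sample_sheet))
    latent = truth.aux.get("latent_m")
    mu_cpg = truth.aux.get("mu_cpg")
    for rec in truth.of_kind("eqtm").to_dict("records"):
        if latent is None:
            raise ValueError("eQTM effects need the methylation stage's latent matrix")
        zm = (latent[rec["left_id"]].to_numpy() - mu_cpg[rec["left_id"]])
        zm = zm / config.noise_sd_meth if config.noise_sd_meth > 0 else zm
        Y[:, col[rec["right_id"]]] += (rec["true_slope"] * config.noise_sd_expr * zm
                                       * _effect_sample_signs(rec, sample_sheet))
    fetal = (sample_sheet["group"] == "fetal").to_numpy()
    for rec in truth.of_kind("diff_expr").to_dict("records"):
        Y[fetal, col[rec["left_id"]]] += rec["true_slope"]
    if config.noise_sd_expr > 0:
        Y = Y + rng.normal(0, config.noise_sd_expr, (n_s, n_p))
    values = pd.DataFrame(Y, index=pd.Index(sample_sheet["sample_id"]),
                          columns=probe_ann.index)
    return ExpressionMatrix(values, probe_ann)


@dataclass
class SimulatedStudy:
    sample_sheet: pd.DataFrame
    genotypes: GenotypeMatrix
    methylation: MethylationMatrix
    expression: ExpressionMatrix
    truth: TruthTable
    config: SimulationConfig

    @property
    def truth_frame(self) -> pd.DataFrame:
        return self.truth.frame()

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_sample_sheet(self.sample_sheet, out / "samples.tsv")
        write_matrix(self.genotypes.values, out / "genotypes.tsv")
        write_annotation(self.genotypes.annotation, out / "snps.tsv")
        write_matrix(self.methylation.values, out / "methylation.tsv")
        write_annotation(self.methylation.annotation, out / "cpgs.tsv")
        write_matrix(self.expression.values, out / "expression.tsv")
        write_annotation(self.expression.annotation, out / "probes.tsv")
        self.truth.frame().to_csv(out / "truth_table.tsv", sep="\t", index=False)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Full bundle: sample sheet, genotypes, methylation, expression, truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sheet = build_sample_sheet(config)
    arch = build_architecture(config, rng)
    truth = TruthTable()
    truth.aux["cpg_ann"] = arch.cpgs
    truth.aux["probe_ann"] = arch.probes
    plant_effects(config, arch, rng, truth)
    geno = simulate_genotypes(config, arch.snps, sheet, rng)
    meth = simulate_methylation(geno, sheet, config, truth, arch.cpgs, rng)
    expr = simulate_expression(geno, meth, sheet, config, truth, arch.probes, rng)
    return SimulatedStudy(sheet, geno, meth, expr, truth, config)
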