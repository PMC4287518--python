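"""Pre-configured study conditions shared by the analysis drivers, the test
suite and the acceptance script.

Two configurations matter:

* `default_study_config` — the full emulated design (cohort A: 96 adult + 14
  fetal livers; cohort B: 85 donors with liver, muscle, SAT and VAT) at a
  desk-scale feature panel, with the default planted-effect architecture.
* `eqtl_fdr_config` — the FDR-calibration condition: two adult liver cohorts
  of 75 samples each, 500 expression probes of which 5% carry a planted
  cis-eQTL with standardized slope 0.6, mapped with 10 permutations at
  nominal FDR 0.05. `empirical_eqtl_fdr` measures the realized false
  discovery proportion of the declared probes against the truth table,
  averaged over seeds.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np

from .qtl import map_cis_qtl
from .simulate import SimulationConfig, simulate_study

SEED_MOD = 2 ** 31 - 1


def default_study_config(seed: int = 2014, **overrides) -> SimulationConfig:
    """The emulated two-cohort, four-tissue design at desk scale."""
    cfg = SimulationConfig(seed=seed)
    return cfg.with_overrides(**overrides) if overrides else cfg


def null_study_config(seed: int, **overrides) -> SimulationConfig:
    """Same design with every planted effect switched off."""
    cfg = SimulationConfig(
        seed=seed, fraction_eqtl=0.0, fraction_meqtl=0.0, fraction_eqtm=0.0,
        fraction_eqtl_and_eqtm=0.0, fraction_shared_snp=0.0,
        fraction_diff_meth=0.0, fraction_diff_expr=0.0)
    return cfg.with_overrides(**overrides) if overrides else cfg


def eqtl_fdr_config(seed: int, planted_fraction: float = 0.05) -> SimulationConfig:
    """FDR-calibration condition: 500 probes, 5% planted eQTL (slope 0.6),
    two adult liver cohorts of 75 samples each."""
    return SimulationConfig(
        seed=seed,
        n_adult_a=75, n_fetal_a=0, n_adult_b=75, tissues_b=("liver",),
        n_probes=500, n_snps=1000, n_cpgs=20,
        fraction_eqtl=planted_fraction, eqtl_slope=0.6,
        fraction_meqtl=0.0, fraction_eqtm=0.0, fraction_eqtl_and_eqtm=0.0,
        fraction_shared_snp=0.0, fraction_diff_meth=0.0, fraction_diff_expr=0.0)


def eqtl_fdp_one_seed(seed: int, *, planted_fraction: float = 0.05,
                      n_perm: int = 10, alpha: float = 0.05) -> Dict[str, float]:
    """One replicate of the calibration experiment.

    Returns the false discovery proportion among declared eQTL probes (0 when
    nothing is declared), plus discovery and truth counts.
    """
    study = simulate_study(eqtl_fdr_config(seed, planted_fraction))
    mapping = map_cis_qtl(study.genotypes, study.expression, study.sample_sheet,
                          n_perm=n_perm, alpha=alpha, mode="eqtl", seed=seed)
    declared = set(mapping.significant_features())
    true_probes = set(study.truth.of_kind("eqtl")["right_id"])
    n_false = len(declared - true_probes)
    fdp = n_false / len(declared) if declared else 0.0
    return {"fdp": fdp, "n_declared": len(declared), "n_false": n_false,
            "n_true_probes": len(true_probes),
            "n_true_recovered": len(declared & true_probes)}


def empirical_eqtl_fdr(base_seed: int, n_seeds: int = 20, **kwargs) -> Dict:
    """Mean false discovery proportion over `n_seeds` replicate studies."""
    per_seed = []
    for k in range(n_seeds):
        seed = (int(base_seed) + k) % SEED_MOD
        per_seed.append(eqtl_fdp_one_seed(seed, **kwargs))
    fdps = [r["fdp"] for r in per_seed]
    power = [r["n_true_recovered"] / max(1, r["n_true_probes"]) for r in per_seed]
    return {"mean_fdp": float(np.mean(fdps)), "per_seed": per_seed,
            "mean_power": float(np.mean(power)), "n_seeds": n_seeds}
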