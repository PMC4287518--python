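"""Tissue specificity in cohort B (liver, muscle, SAT, VAT): per-tissue
eQTL/meQTL/eQTM discovery, Venn-region counts, allelic-direction concordance,
and the matched-probe eQTL-enrichment analysis of adult-specific genes."""

import json
import runpy
from pathlib import Path

import pandas as pd

from regulome_qtl.differential import diff_expression
from regulome_qtl.eqtm import map_eqtm
from regulome_qtl.pairs import enumerate_cis_pairs
from regulome_qtl.qtl import map_cis_qtl
from regulome_qtl.tissue import cross_tissue_overlap, matched_probe_enrichment

common = runpy.run_path(str(Path(__file__).parent / "00_common.py"))
study = common["get_study"]()
out = common["outdir"]("tissue")
sheet = study.sample_sheet
seed = common["STUDY_SEED"]
tissues = ("liver", "muscle", "SAT", "VAT")

report = {}
for kind in ("eqtl", "meqtl", "eqtm"):
    sets = {}
    for t in tissues:
        if kind == "eqtm":
            sample_ids = sheet.loc[(sheet["cohort"] == "B") & (sheet["tissue"] == t),
                                   "sample_id"]
            pairs = enumerate_cis_pairs(study.methylation.annotation,
                                        study.expression.annotation)
            res = map_eqtm(study.methylation, study.expression, pairs,
                           n_perm=199, seed=seed, sample_ids=list(sample_ids))
            sig = res[res["significant"]].rename(
                columns={"cpg_id": "snp_id", "probe_id": "feature_id",
                         "rho": "meta_z"})
        else:
            trait = study.expression if kind == "eqtl" else study.methylation
            mapping = map_cis_qtl(study.genotypes, trait, sheet[sheet["cohort"] == "B"],
                                  n_perm=10, mode=kind, seed=seed, tissue=t)
            sig = mapping.significant
        sets[t] = sig[["snp_id", "feature_id", "meta_z"]]
    rep = cross_tissue_overlap(sets)
    pairwise = rep.pairwise_replication.mean().mean()
    report[kind] = {
        "region_counts": {"+".join(k): v for k, v in rep.region_counts.items()
                          if v > 0},
        "union_size": rep.union_size,
        "concordance": rep.concordance,
        "n_opposite": len(rep.opposite_effects),
    }
    shared = rep.union_size - sum(rep.region_counts.get((t,), 0) for t in tissues)
    print(f"{kind}: union {rep.union_size}, shared by >=2 tissues {shared} "
          f"({shared / rep.union_size:.0%}), direction concordance "
          f"{rep.concordance:.1%}" if rep.union_size else f"{kind}: empty")

(out / "overlap.json").write_text(json.dumps(report, indent=2))

# matched-probe enrichment: are adult-up probes more likely to carry an eQTL?
liver_sheet = sheet[sheet["tissue"] == "liver"]
groups = liver_sheet.set_index("sample_id")["group"]
de = diff_expression(study.expression.subset_samples(liver_sheet["sample_id"]),
                     groups)
adult_up = de.loc[de["significant"] & (de["effect"] < 0), "feature_id"]
not_de = de.loc[~de["significant"], "feature_id"]
adults = common["adult_liver_ids"](sheet)
expr_adult = study.expression.values.loc[adults]
summary = pd.DataFrame({"median": expr_adult.median(), "sd": expr_adult.std()})
liver_eqtl = map_cis_qtl(study.genotypes, study.expression, sheet,
                         n_perm=10, mode="eqtl", seed=seed)
flags = pd.Series(False, index=study.expression.feature_ids)
flags[liver_eqtl.significant["feature_id"].unique()] = True
if len(adult_up) and len(not_de) >= len(adult_up):
    enr = matched_probe_enrichment(list(adult_up), list(not_de), summary, flags,
                                   seed=seed)
    print(f"adult-up probes with an eQTL: {enr['target_flagged']}/{len(adult_up)}; "
          f"matched probes: {enr['matched_flagged']}/{len(adult_up)}; "
          f"fold enrichment {enr['fold_enrichment']:.2f} "
          f"(chi-squared p = {enr['chi_squared_p']:.2g})")
else:
    print("matched-probe enrichment skipped: pool smaller than target set")
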