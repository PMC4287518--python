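"""Adult-liver eQTM mapping (Spearman, 999 within-cohort permutations,
pair-level perm p < 0.05) with the direction-by-correlation-strength and
direction-by-distance summaries."""

import runpy
from pathlib import Path

from regulome_qtl.eqtm import direction_distance_summary, map_eqtm
from regulome_qtl.pairs import enumerate_cis_pairs

common = runpy.run_path(str(Path(__file__).parent / "00_common.py"))
study = common["get_study"]()
out = common["outdir"]("eqtm")

pairs = enumerate_cis_pairs(study.methylation.annotation,
                            study.expression.annotation)
res = map_eqtm(study.methylation, study.expression, pairs, n_perm=999,
               seed=common["STUDY_SEED"],
               sample_ids=common["adult_liver_ids"](study.sample_sheet),
               cohorts=study.sample_sheet.set_index("sample_id")["cohort"])
res.to_csv(out / "eqtm.tsv", sep="\t", index=False)

sig = res[res["significant"]]
print(f"eQTMs: {len(sig)} significant of {len(res)} tested pairs")
if len(sig):
    print(f"negative-direction fraction: {(sig['direction'] == 'negative').mean():.1%}")
    summary = direction_distance_summary(res)
    summary["by_abs_rho"].to_csv(out / "direction_by_rho.tsv", sep="\t", index=False)
    summary["by_abs_distance"].to_csv(out / "direction_by_distance.tsv", sep="\t",
                                      index=False)
    print("fraction negative by |distance| bin:")
    print(summary["by_abs_distance"].round(3).to_string(index=False))
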