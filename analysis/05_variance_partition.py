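"""SNP + CpG variance partitioning of expression for probes carrying both a
significant cis-eQTL and a significant eQTM: four nested linear models,
unique contributions, and the nested F-test for adding all eQTM CpGs."""

import runpy
from pathlib import Path

from regulome_qtl.eqtm import map_eqtm
from regulome_qtl.pairs import enumerate_cis_pairs
from regulome_qtl.qtl import map_cis_qtl
from regulome_qtl.varpart import partition_from_results

common = runpy.run_path(str(Path(__file__).parent / "00_common.py"))
study = common["get_study"]()
out = common["outdir"]("varpart")
adults = common["adult_liver_ids"](study.sample_sheet)

eqtl = map_cis_qtl(study.genotypes, study.expression, study.sample_sheet,
                   n_perm=10, mode="eqtl", seed=common["STUDY_SEED"])
pairs = enumerate_cis_pairs(study.methylation.annotation,
                            study.expression.annotation)
eqtm = map_eqtm(study.methylation, study.expression, pairs, n_perm=999,
                seed=common["STUDY_SEED"], sample_ids=adults,
                cohorts=study.sample_sheet.set_index("sample_id")["cohort"])

table = partition_from_results(study.expression.subset_samples(adults),
                               study.genotypes.subset_samples(adults),
                               study.methylation.subset_samples(adults),
                               eqtl.significant, eqtm)
table.to_csv(out / "variance_partition.tsv", sep="\t", index=False)

print(f"probes with both eQTL and eQTM: {len(table)}")
if len(table):
    snp_stronger = (table["r2_snp"] > table["r2_cpg"]).mean()
    print(f"SNP explains more than the CpG for {snp_stronger:.0%} of probes")
    print(f"median unique SNP contribution: {table['unique_snp'].median():.3f}; "
          f"median unique CpG contribution: {table['unique_cpg'].median():.3f}")
    print(f"extra CpGs significant (F p < 0.05) for "
          f"{(table['f_p'] < 0.05).sum()} probes")
    cols = ["gene", "r2_snp", "r2_cpg", "r2_snp_cpg", "r2_snp_all_cpgs", "f_p"]
    print(table.sort_values("r2_snp_cpg", ascending=False)[cols]
          .head(10).round(3).to_string(index=False))
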