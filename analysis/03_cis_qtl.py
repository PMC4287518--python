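"""Adult-liver cis-eQTL and cis-meQTL mapping (two-cohort weighted-Z
meta-analysis, 10 within-cohort permutations, feature-level FDR < 0.05) and
the direction analysis of SNPs hitting both expression and methylation of
one gene."""

import runpy
from pathlib import Path

from regulome_qtl.qtl import map_cis_qtl, overlap_eqtl_meqtl

common = runpy.run_path(str(Path(__file__).parent / "00_common.py"))
study = common["get_study"]()
out = common["outdir"]("qtl")

eqtl = map_cis_qtl(study.genotypes, study.expression, study.sample_sheet,
                   n_perm=10, alpha=0.05, mode="eqtl", seed=common["STUDY_SEED"])
meqtl = map_cis_qtl(study.genotypes, study.methylation, study.sample_sheet,
                    n_perm=10, alpha=0.05, mode="meqtl", seed=common["STUDY_SEED"])
eqtl.table.to_csv(out / "eqtl.tsv", sep="\t", index=False)
meqtl.table.to_csv(out / "meqtl.tsv", sep="\t", index=False)

for name, res in (("eQTL", eqtl), ("meQTL", meqtl)):
    print(f"{name}: {int(res.table['pair_significant'].sum())} significant pairs, "
          f"{len(res.significant_features())} significant features "
          f"(|meta z| threshold {res.threshold:.2f})")
print(f"meQTL pairs removed for SNP-in-probe conflicts: {len(meqtl.removed_pairs)}")

overlap = overlap_eqtl_meqtl(eqtl.significant, meqtl.significant,
                             study.methylation.annotation)
overlap["pairs"].to_csv(out / "eqtl_meqtl_overlap.tsv", sep="\t", index=False)
n_genes = len(overlap["gene_summary"])
if n_genes:
    print(f"genes with both eQTL and meQTL: {n_genes}; "
          f"opposite allelic direction in {overlap['fraction_opposite']:.1%}")
    print("opposite fraction by CGI context:")
    print(overlap["cgi_breakdown"].round(3).to_string())
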