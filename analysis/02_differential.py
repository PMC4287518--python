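"""Fetal-vs-adult differential methylation and expression in cohort A liver,
the CGI-context direction contingency, and the DE/DM gene intersection.

Significance uses the dual rule: BH FDR < 0.05 AND |delta beta| > 0.2
(methylation) or |log2FC| > 1.0 (expression).
"""

import runpy
from pathlib import Path

from regulome_qtl.differential import (cgi_direction_contingency,
                                       diff_expression, diff_methylation,
                                       intersect_de_dm)

common = runpy.run_path(str(Path(__file__).parent / "00_common.py"))
study = common["get_study"]()
out = common["outdir"]("differential")

sheet = study.sample_sheet
liver = sheet[sheet["tissue"] == "liver"]
groups = liver.set_index("sample_id")["group"]

dm = diff_methylation(study.methylation.subset_samples(liver["sample_id"]), groups)
de = diff_expression(study.expression.subset_samples(liver["sample_id"]), groups)
dm.to_csv(out / "diff_methylation.tsv", sep="\t", index=False)
de.to_csv(out / "diff_expression.tsv", sep="\t", index=False)
print(f"differentially methylated CpGs: {int(dm['significant'].sum())} "
      f"of {len(dm)} tested")
print(f"differentially expressed probes: {int(de['significant'].sum())} "
      f"of {len(de)} tested")

cgi = cgi_direction_contingency(dm, study.methylation.annotation)
cgi["table"].to_csv(out / "cgi_contingency.tsv", sep="\t")
print("fraction hypomethylated in fetal by CGI context:")
print(cgi["hypo_fraction"].round(3).to_string())
if cgi["chi_squared"] is not None:
    print(f"chi-squared = {cgi['chi_squared']:.1f}, p = {cgi['p']:.3g}")

genes = intersect_de_dm(de, dm, study.expression.annotation,
                        study.methylation.annotation)
genes.to_csv(out / "de_dm_genes.tsv", sep="\t", index=False)
print(f"genes both DE and DM: {len(genes)} "
      f"({int(genes['discordant'].sum())} with discordant probe directions)")
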