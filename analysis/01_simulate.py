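"""Generate the emulated study and write the dataset bundle.

Cohort A contributes 96 adult and 14 fetal liver samples; cohort B
contributes 85 donors sampled in liver, muscle, SAT and VAT. Planted effects
(eQTL, meQTL, eQTM, fetal/adult group shifts, shared SNPs with opposite
allelic directions) are registered in a truth table.
"""

import runpy

common = runpy.run_path(str(__import__("pathlib").Path(__file__).parent / "00_common.py"))

study = common["get_study"]()
out = common["outdir"]("dataset")
study.write(out)

truth = study.truth_frame
print(f"samples: {len(study.sample_sheet)} "
      f"({(study.sample_sheet['group'] == 'fetal').sum()} fetal)")
print(f"features: {study.genotypes.values.shape[1]} SNPs, "
      f"{study.methylation.values.shape[1]} CpGs, "
      f"{study.expression.values.shape[1]} probes")
print("planted effects by kind:")
print(truth["effect_kind"].value_counts().to_string())
print(f"wrote dataset + truth table to {out}")
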