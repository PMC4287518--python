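"""Shared setup for the analysis drivers: one emulated two-cohort,
four-tissue study, regenerated deterministically from a fixed seed."""

from pathlib import Path

from regulome_qtl.experiments import default_study_config
from regulome_qtl.simulate import simulate_study

STUDY_SEED = 2014
RESULTS = Path(__file__).resolve().parent.parent / "results"


def get_study():
    return simulate_study(default_study_config(seed=STUDY_SEED))


def adult_liver_ids(sheet):
    mask = (sheet["group"] == "adult") & (sheet["tissue"] == "liver")
    return list(sheet.loc[mask, "sample_id"])


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
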