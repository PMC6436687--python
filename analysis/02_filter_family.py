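#!/usr/bin/env python
"""Run the successive filtering strategy on the simulated family.

Reads the bundle written by 01_simulate_family.py back through the file
readers, applies quality → public-MAF(1%) → local-control subtraction →
segregation filtering, and contrasts the candidate counts with and without
the matched control cohort.  Also emits the phenocopy × control-carrier
relaxation matrix and the unknown-status variant of the analysis.
"""

import json
from pathlib import Path

from famsieve.filtering import FilterConfig, relaxation_matrix, run_pipeline
from famsieve.pedigree import parse_ped
from famsieve.variants import load_frequency_table, quality_filter, read_vcf
from famsieve.filtering import public_maf_filter

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "results" / "sim"
OUT = ROOT / "results"


def main() -> None:
    fam = read_vcf(SIM / "family.vcf")
    control = read_vcf(SIM / "controls.vcf")
    ped = parse_ped(SIM / "family.ped")
    truth = json.loads((SIM / "truth.json").read_text())
    resources = [
        load_frequency_table(p, p.stem) for p in sorted((SIM / "resources").glob("*.tsv"))
    ]
    affected = ped.by_affection("affected")
    unknown = ped.by_affection("unknown")
    print(f"{fam.n_variants} family variants; {len(affected)} affected, "
          f"{len(unknown)} phenotype-unknown; {len(resources)} public resources")

    cfg = FilterConfig(max_phenocopies=2, local_mode="max_carriers",
                       max_control_carriers=1)
    with_ctrl = run_pipeline(cfg, fam, resources, control, affected)
    without_ctrl = run_pipeline(cfg, fam, resources, None, affected)
    print("waterfall with control:   ", with_ctrl.steps)
    print("waterfall without control:", without_ctrl.steps)
    print(f"candidates: {len(with_ctrl.candidates)} with the matched control "
          f"cohort vs {len(without_ctrl.candidates)} without it")
    causal = truth["causal_variant"]
    print(f"planted causal variant retained: "
          f"{any(str(v) == causal for v in with_ctrl.candidates)}")

    # unknown-status relatives as a (weaker) stand-in for the control cohort
    cfg_u = FilterConfig(max_phenocopies=2, max_unknown_carriers=len(unknown) // 3)
    with_unknown = run_pipeline(cfg_u, fam, resources, None, affected, unknown)
    print(f"candidates using unknown-status members instead "
          f"(<= {len(unknown) // 3} carriers): {len(with_unknown.candidates)}")

    pre = quality_filter(fam)
    pre = pre.subset_variants(public_maf_filter(pre.variants, resources, 0.01))
    rm = relaxation_matrix(pre, affected, control, p_max=4, c_max=8)
    rm.to_tsv(OUT / "relaxation_matrix.tsv")
    print("relaxation matrix (rows: max phenocopies, cols: max control carriers):")
    print(rm.counts.to_string())

    with_ctrl.table.to_csv(OUT / "candidates.tsv", sep="\t", index=False)
    (OUT / "filter_steps.json").write_text(
        json.dumps({"with_control": with_ctrl.steps,
                    "without_control": without_ctrl.steps}, indent=1)
    )
    print(f"wrote {OUT / 'candidates.tsv'}, relaxation_matrix.tsv, filter_steps.json")


if __name__ == "__main__":
    main()
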