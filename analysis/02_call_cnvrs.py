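"""Read depth -> copy number -> CNVRs, scored against the planted truth.

Pools the two individuals per population, applies the GC-stratum
correction and two-stage diploid calibration, chains bins with CN >= 2.5
into multi-copy regions (>= 6 consecutive 1 kb bins), merges them across
populations and keeps regions with cross-population CN s.d. >= 0.7.
Reports recovery of the planted regions and the group-specific sets.

Run:  python analysis/02_call_cnvrs.py [seed]
"""

import sys
import warnings

import numpy as np

from suscape.pipeline import PipelineConfig, run_pipeline

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
cfg = PipelineConfig(out_dir="results/cohort", seed=seed)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    state = run_pipeline(cfg, stages=("simulate", "cn", "cnvr"))

land = state["sim"]["landscape"]
cnvrs = state["cnvr"]["cnvrs"]
bs = cfg.bin_size
exact = loose = 0
cn_ok = cn_total = 0
for i, r in land.loci.iterrows():
    hit = cnvrs[(cnvrs["chrom"] == r["chrom"]) & (cnvrs["start"] < r["end"]) & (cnvrs["end"] > r["start"])]
    if not len(hit):
        continue
    loose += 1
    b = hit.iloc[0]
    exact += abs(b["start"] - r["start"]) <= bs and abs(b["end"] - r["end"]) <= bs
    for j, pop in enumerate(land.populations):
        cn_total += 1
        cn_ok += abs(b[pop] - land.cn[i, j]) <= 0.5

false = sum(
    not ((land.loci["chrom"] == b["chrom"]) & (land.loci["start"] < b["end"]) & (land.loci["end"] > b["start"])).any()
    for _, b in cnvrs.iterrows()
)
print(f"retained bins: {len(state['cn']['grid'])}")
print(f"ascertained CNVRs: {len(cnvrs)}; total span {int((cnvrs['end']-cnvrs['start']).sum())/1e6:.2f} Mb")
print(f"planted regions recovered: {loose}/{len(land.loci)} "
      f"({exact} with boundary error <= 1 bin)")
print(f"scored CN entries within +-0.5 of truth: {cn_ok}/{cn_total} ({100*cn_ok/max(cn_total,1):.1f}%)")
print(f"CNVRs not overlapping any planted region: {false} (FDR {100*false/max(len(cnvrs),1):.1f}%)")
for gname, frame in state["cnvr"]["groups"].items():
    print(f"group '{gname}': {len(frame)} CNVRs ascertained within group")
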