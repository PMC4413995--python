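"""Simulate the default synthetic cohort.

Seven pig-like populations (two individuals each, coverages 7-18x), one
20 Mb chromosome with ~35% repeat masking and autocorrelated GC, 60 planted
copy-number-variable regions, assumed-diploid seed regions, gene models
(OR / non-OR) and genotypes at putatively diploid sites.  Everything is
written under results/cohort/ for the later steps.

Run:  python analysis/01_simulate_cohort.py [seed]
"""

import sys

from suscape.pipeline import PipelineConfig, run_pipeline

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
cfg = PipelineConfig(out_dir="results/cohort", seed=seed)
state = run_pipeline(cfg, stages=("simulate",))
sim = state["sim"]
land = sim["landscape"]
print(f"chromosome: {cfg.chrom_size/1e6:.0f} Mb, bin size {cfg.bin_size} bp")
print(f"planted variable regions: {len(land.loci)} "
      f"({(land.loci['cls'] == 'OR').sum()} OR, {(land.loci['cls'] == 'nonOR').sum()} nonOR)")
print(f"populations: {', '.join(land.populations)}")
print(f"genes written: {len(sim['genes'])}; SNP sites: {sim['genotypes'][1].shape[1]}")
print("artifacts in results/cohort/ (mask.bed, depth_*.tsv, truth_cn.tsv, genes.bed, ...)")
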