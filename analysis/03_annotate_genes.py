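"""Gene annotation of CNVRs and the OR / non-OR partition census.

Genes overlapping the CNVR union by >= 70% of their length inherit the CN
of their largest-overlap CNVR; CNVRs are then partitioned into CNVR-OR,
CNVR-nonOR and CNVR-ALL (mixed regions count as OR).

Run:  python analysis/03_annotate_genes.py [seed]
"""

import sys
import warnings

from suscape.pipeline import PipelineConfig, run_pipeline

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
cfg = PipelineConfig(out_dir="results/cohort", seed=seed)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    state = run_pipeline(cfg, stages=("simulate", "cn", "cnvr", "annotate"))

ann = state["annotate"]
table = ann["gene_table"]
parts = ann["partitions"]
n_or = (table["cls"] == "OR").sum()
print(f"genes with >= 70% CNVR overlap: {len(table)} ({n_or} OR, {len(table) - n_or} nonOR)")
print(f"CNVR partitions: OR {len(parts['OR'])}, nonOR {len(parts['nonOR'])}, ALL {len(parts['ALL'])}")
print("gene-CN table written to results/cohort/gene_cn.tsv")
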