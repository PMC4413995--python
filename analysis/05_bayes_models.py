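"""Bayesian model comparison of admixture scenarios on CN characters.

Per-locus CN vectors are rescaled to ten integer states and analysed under
the variable-characters Mk model.  Five topology constraints are compared
by stepping-stone marginal likelihood: a null (monophyly of the scrofa-like
and island clades) and four hybridisation/translocation pairings.
delta-lnL = best minus model; 0 marks the winner.

The cohort here is tree-structured (CN evolved on the default species
history, nonOR loci drift/admixture-perturbed), so the expected pattern is
the interesting one: the null should win for the OR partition while the
nonOR partition should prefer, or at least rescue, an admixture scenario.
The run is reduced (8 ladder steps, ~1k samples per step) to stay
minutes-scale; between-model gaps are typically tens of log units.

Run:  python analysis/05_bayes_models.py [seed]
"""

import sys

import pandas as pd

from suscape import bayes, mkv
from suscape import simulate as sim

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0

species = sim.default_sus_tree()
land = sim.evolve_cn_on_tree(species, n_loci=500, rate=1.0, seed=seed + 51)
models = bayes.predefined_models()

tables = []
for part in ("OR", "nonOR", "ALL"):
    mask = slice(None) if part == "ALL" else (land.loci["cls"] == part).to_numpy()
    matrix = mkv.discretize(land.cn[mask].astype(float), land.populations)
    ests = {}
    for i, (name, model) in enumerate(models.items()):
        ests[name] = bayes.stepping_stone(
            matrix, [model], steps=8, samples_per_step=1_000,
            seed=seed + 60 + i, model_name=f"{part}:{name}",
        )
    t = bayes.compare_models(ests)
    t.insert(0, "partition", part)
    tables.append(t)
    best = t.loc[t["delta_lnl"].idxmin(), "model"]
    print(f"partition {part:6s}: best model = {best}  "
          f"(delta-lnL of null = {float(t.loc[t['model'] == 'null', 'delta_lnl'].iloc[0]):.2f})")

table = pd.concat(tables, ignore_index=True)
table.to_csv("results/model_comparison_tree_cohort.tsv", sep="\t", index=False, float_format="%.3f")
print()
print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print("table written to results/model_comparison_tree_cohort.tsv")
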