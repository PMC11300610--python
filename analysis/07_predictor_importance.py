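"""Relative importance of biome, site, species and year for peak timing.

Random-forest regressions of per-site-year fitted peaks with out-of-bag
permutation importance (%IncMSE), an 80/20 train/test split and repeated
cross-validation.
"""

import sys

import pandas as pd

from phenosync.pipeline import run_pipeline

OUT = "results/pipeline"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

run_pipeline(out_dir=OUT, stages=["importance"], seed=SEED)
imp = pd.read_csv(f"{OUT}/importance.csv")
print("%IncMSE by process and predictor:")
print(imp.pivot(index="process", columns="predictor",
                values="inc_mse_pct").round(1).to_string())
met = pd.read_csv(f"{OUT}/importance_metrics.csv")
print("\nmodel quality:")
print(met.round(2).to_string(index=False))
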