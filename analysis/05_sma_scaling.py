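"""SMA scaling of wood-phase peak timing on GPP peak timing across sites.

Per-biome standardized-major-axis lines with slope CIs and R², plus the
cross-biome common-slope likelihood-ratio test and, where slopes are
homogeneous, the Wald test for intercept differences.
"""

import sys

import pandas as pd

from phenosync.pipeline import run_pipeline

OUT = "results/pipeline"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

run_pipeline(out_dir=OUT, stages=["sma"], seed=SEED)
sma = pd.read_csv(f"{OUT}/sma.csv")
print(sma.round(3).to_string(index=False))
tests = pd.read_csv(f"{OUT}/sma_tests.csv")
print("\ncross-biome tests:")
print(tests.round(4).to_string(index=False))
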