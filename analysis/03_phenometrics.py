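"""Derive phenometrics: peaks, percentile times, activity intervals, AUCs.

Also prints the within-biome event sequence and the growing-season span
(earliest to latest seasonal event) per biome.
"""

import sys

import pandas as pd

from phenosync.pipeline import run_pipeline

OUT = "results/pipeline"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

run_pipeline(out_dir=OUT, stages=["phenology"], seed=SEED)
gs = pd.read_csv(f"{OUT}/growing_season.csv")
print(gs.round(1).to_string(index=False))
seq = pd.read_csv(f"{OUT}/event_sequence.csv")
for biome, g in seq.groupby("biome"):
    order = " -> ".join(g.sort_values("order").event)
    print(f"{biome}: {order}")
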