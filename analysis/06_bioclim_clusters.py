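"""Bioclimatic site classification.

Collinearity filtering (|r| > 0.7), PAM clustering with WSS-elbow
selection of the cluster count, and PCA ordination of the retained
variables.
"""

import sys

import pandas as pd

from phenosync.pipeline import run_pipeline

OUT = "results/pipeline"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

run_pipeline(out_dir=OUT, stages=["cluster"], seed=SEED)
retained = pd.read_csv(f"{OUT}/bioclim_retained.csv")
print(f"retained variables after collinearity filter: {list(retained.variable)}")
wss = pd.read_csv(f"{OUT}/wss_curve.csv")
print(wss.round(1).to_string(index=False))
labels = pd.read_csv(f"{OUT}/cluster_labels.csv")
print("cluster sizes:", labels.cluster.value_counts().sort_index().to_dict())
load = pd.read_csv(f"{OUT}/pca_loadings.csv", index_col=0)
print("PC1/PC2 variance explained:",
      load.variance_explained.iloc[:2].round(3).to_list())
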