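"""Separate tissue from solvent/matrix background channels by correlation
clustering.

Background ions concentrate off tissue, so their spatial distribution
anti-correlates with tissue channels.  The feature-feature correlation
matrix is accumulated one sample at a time from streaming sufficient
statistics, its rows are split into two k-means clusters, and the tissue
cluster is identified from the on/off-mask intensity ratio.
"""

import os
import tempfile

import numpy as np

from msistream import peakfilter
from msistream.synthetic import SyntheticParams, generate

params = SyntheticParams(n_samples=3, shape=(20, 20), n_features=60,
                         n_background=15, n_delocalized=5, seed=13)
ws, truth = generate(params, path=os.path.join(tempfile.mkdtemp(), "f.h5"))

clusters = peakfilter.filter_workspace(ws, method="kmeans", seed=17)
pred_tissue = set(clusters.tissue_indices())
true_tissue = set(truth.tissue_feature_ids)
accuracy = (len(pred_tissue & true_tissue)
            + (params.n_features - len(pred_tissue | true_tissue))) / params.n_features

print(f"decision: {clusters.decision}")
print(f"kept {len(pred_tissue)} tissue features, removed {len(clusters.background_indices())}")
print(f"label accuracy vs planted truth: {accuracy:.0%}")
deloc = set(truth.delocalized_feature_ids)
print(f"delocalized tissue features (present across the whole image) kept: "
      f"{len(deloc & pred_tissue)}/{len(deloc)}")
ws.close()
# Delocalized tissue channels stay in the tissue cluster because their
# spatial correlation structure is still closer to tissue than to background.
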