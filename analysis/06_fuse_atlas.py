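#!/usr/bin/env python
"""Desk-scale demonstration of the multi-atlas labelling core.

Simulates a 32^3 atlas stack (10 candidates, 5 label sets each), selects
the 10 morphologically best-matched exemplars by Jacobian-map correlation,
fuses their 50 labelled images by similarity-weighted majority vote, and
extracts regional volumes.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from sca1vol.atlas import simulate_atlas_stack
from sca1vol.fusion import (extract_volumes, fuse_labels, jacobian_similarity,
                            select_exemplars)

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
SEED = 2026


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    stack = simulate_atlas_stack((32, 32, 32), n_candidates=10,
                                 n_label_sets=5, seed=SEED,
                                 disagreement_rate=0.05)
    scores = jacobian_similarity(stack.target_jacobian,
                                 stack.candidate_jacobians, stack.mask)
    selection = select_exemplars(scores, k=10)
    fused = fuse_labels(stack, selection)
    volumes = extract_volumes(fused, stack.voxel_dims)
    pd.DataFrame([volumes]).to_csv(OUT / "fused_volumes.csv", index=False)

    print(f"exemplar similarity scores: {np.round(scores, 3).tolist()}")
    print(f"chosen exemplars (best first): {selection.chosen}")
    truth = stack.candidate_labels[0][0].copy()
    truth[~stack.mask] = 0
    agree = (fused.labels == truth).mean()
    print(f"fused labels agree with candidate 0's first label set on "
          f"{agree:.1%} of voxels (5% disagreement was injected per map)")
    parts = sum(v for k, v in volumes.items() if k != "icv")
    print(f"region volumes sum to {parts:.0f} mm^3 = icv {volumes['icv']:.0f} "
          "mm^3 (conservation)")
    print(f"wrote {OUT / 'fused_volumes.csv'}")


if __name__ == "__main__":
    main()
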