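#!/usr/bin/env python
"""Farthest-distance subsampling of the simulated branch hierarchy.

Selects a balanced, pseudo-replication-free branch set (no selected branch
is an ancestor or descendant of another) and writes the selected ids plus
the standardized sampling coordinates.
"""

import pandas as pd
from common import RESULTS, SCRATCH

from qsmflora.branch_data import frame_to_trees, read_branch_csv
from qsmflora.subsampling import SamplingSpace, farthest_distance_sample, scale_coordinates


def main() -> None:
    records = read_branch_csv(SCRATCH / "branches.csv", SCRATCH / "measurements.csv")
    trees = frame_to_trees(pd.read_csv(SCRATCH / "trees.csv", dtype={"tree_id": str}))

    space = SamplingSpace()
    coords = scale_coordinates(records, trees, space)
    selected = farthest_distance_sample(records, trees, SamplingSpace())

    coords.to_csv(SCRATCH / "sampling_coordinates.csv")
    pd.Series(selected, name="branch_id").to_csv(RESULTS / "subsample.csv", index=False)

    print(f"selected {len(selected)} of {len(records)} branches "
          f"({len(selected)/len(records):.0%}); seed branch: {selected[0]}")


if __name__ == "__main__":
    main()
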