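#!/usr/bin/env python
"""Simulate the study inputs: branch measurements and QSM cylinder tables.

Draws one synthetic forest from the reference hurdle truth (with nested
random intercepts), writes the branch/measurement/tree tables and the
cylinder tables of every QSM replicate, and reports the basic sample
description.
"""

from common import FOREST, SCRATCH, SEED

import qsmflora as qf
from qsmflora.branch_data import trees_to_frame, write_branch_csv
from qsmflora.qsm import write_cylinder_csv


def main() -> None:
    records, trees, truth = qf.generate_branch_dataset(FOREST, seed=SEED)
    write_branch_csv(records, SCRATCH / "branches.csv", SCRATCH / "measurements.csv")
    trees_to_frame(trees).to_csv(SCRATCH / "trees.csv", index=False)

    tree_df, qsms = qf.generate_forest(FOREST, seed=SEED)
    tree_df.to_csv(SCRATCH / "qsm_trees.csv", index=False)
    all_qsms = [q for reps in qsms.values() for q in reps]
    write_cylinder_csv(all_qsms, SCRATCH / "cylinders.csv")

    n_flowering = sum(r.own_flower_count > 0 for r in records)
    print(f"simulated {len(trees)} trees, {len(records)} branches "
          f"({n_flowering} flowering, {len(records) - n_flowering} without flowers)")
    print(f"QSMs: {len(all_qsms)} replicates over {len(qsms)} trees, "
          f"{sum(len(q.df) for q in all_qsms)} cylinders total")
    print(f"hurdle truth: theta={truth.theta}, random SDs "
          f"({truth.sd_tree}, {truth.sd_branch})")


if __name__ == "__main__":
    main()
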