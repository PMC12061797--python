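"""Shared settings for the analysis scripts.

One synthetic forest is threaded through the whole chain: 12 trees spanning
the 9-28 cm dbh range, 6 cut-off branches each, 5 QSM replicates per tree
with 5% reconstruction noise.  Bulky intermediates (cylinder tables, branch
tables) live under scratch/; the small summary tables the scripts report
live under results/.
"""

from pathlib import Path

from qsmflora.synthetic import SyntheticForestSpec

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 1

FOREST = SyntheticForestSpec(
    n_trees=12,
    cutoffs_per_tree=6,
    n_replicates=5,
    noise_sd=0.05,
)

for d in (SCRATCH, RESULTS):
    d.mkdir(parents=True, exist_ok=True)
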