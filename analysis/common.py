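"""Shared configuration for the numbered analysis drivers.

The desk-scale run: the full three-group cohort (22/12/8, TR 2.08 s, 220
volumes) on a 14x16x14 voxel grid at 3 mm, 20 ICA components, lags up to
+/-12 TRs.  All drivers read/write under results/run1/.
"""

from pathlib import Path

from netlag.cohort import CohortConfig
from netlag.pipeline import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "run1"

CONFIG = RunConfig(
    seed=7,
    cohort=CohortConfig(grid_dims=(14, 16, 14), seed=7),
    n_components=20,
    k_subject=30,
    max_lag=12,
    n_permutations=500,
)
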