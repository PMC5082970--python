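#!/usr/bin/env python
"""Simulate the synthetic three-group cohort and write its artifacts.

Writes participants.tsv, the ground-truth JSON, the network template maps
and one 4D BOLD NIfTI per subject under results/run1/.
"""

import dataclasses
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, RESULTS

from netlag import io
from netlag.cohort import simulate_cohort
from netlag.pipeline import derive_seed


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.replace(CONFIG.cohort, seed=derive_seed(CONFIG.seed, "simulate"))
    cohort = simulate_cohort(cfg)

    io.write_participants(cohort.participants, RESULTS / "participants.tsv")
    (RESULTS / "ground_truth.json").write_text(
        json.dumps(cohort.truth.to_json_dict(), indent=2)
    )
    io.write_templates(cohort.truth.network_maps.maps, cohort.grid,
                       RESULTS / "templates.nii.gz")
    bold = RESULTS / "bold"
    bold.mkdir(exist_ok=True)
    rows = []
    for sid, run in zip(cohort.participants["participant_id"], cohort.runs):
        p = io.write_bold(run, bold / f"{sid}_bold.nii.gz")
        rows.append(f"{sid}\t{p}\t{cohort.participants.set_index('participant_id').loc[sid, 'group']}")
    (RESULTS / "manifest.tsv").write_text("subject_id\tpath\tgroup\n" + "\n".join(rows) + "\n")

    part = cohort.participants
    print(f"Simulated {len(part)} subjects "
          f"({dict(part['group'].value_counts())}) on grid {cfg.grid_dims}, "
          f"T={cfg.T}, TR={cfg.tr_s}s -> {RESULTS}")


if __name__ == "__main__":
    main()
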