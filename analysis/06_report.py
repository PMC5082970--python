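#!/usr/bin/env python
"""Render the Markdown summary report from the saved stage outputs."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS

from netlag.io import write_report


def main() -> None:
    clusters = {}
    cl_path = RESULTS / "intra_clusters.tsv"
    if cl_path.exists():
        tbl = pd.read_csv(cl_path, sep="\t")
        for (net, con), sub in tbl.groupby(["network", "contrast"]):
            clusters.setdefault(net, {})[con] = sub.to_dict("records")
    grouped = pd.read_csv(RESULTS / "inter_group_pairs.tsv", sep="\t")
    anova = pd.read_csv(RESULTS / "inter_anova.tsv", sep="\t")
    path = write_report(
        {"cluster_tables": clusters, "pair_table": grouped, "anova_table": anova},
        RESULTS / "report.md",
    )
    print(f"Report written to {path}")


if __name__ == "__main__":
    main()
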