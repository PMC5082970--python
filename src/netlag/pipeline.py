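"""End-to-end orchestration: simulate -> preprocess -> ICA -> intra -> inter -> report.

A single :class:`RunConfig` (serializable to YAML) drives every stage with
per-stage seeds derived from one master seed, so any stage can be rerun in
isolation reproducibly.  Each stage writes its artifacts under the run
directory; a sha256 checksum manifest of every written file supports
byte-level reproducibility claims.  Stage toggles allow skipping stages
whose outputs are already cached on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import inter, intra, io
from .cohort import CohortConfig, simulate_cohort
from .core import BoldRun
from .ica import match_components, run_group_ica
from .preprocess import PreprocessConfig, preprocess_run

__all__ = ["RunConfig", "run_all", "derive_seed"]


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed: first 4 bytes of sha256(master:stage), < 2^31."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") & 0x7FFFFFFF


@dataclass
class RunConfig:
    """All stage configs plus master seed, output knobs and stage toggles."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    n_components: int = 20
    k_subject: int = 30
    max_lag: int = 12
    cluster_forming_p: float = 0.001
    n_permutations: int = 500
    stages: tuple[str, ...] = ("simulate", "preprocess", "ica", "intra", "inter", "report")
    write_nifti: bool = False   # per-subject NIfTI output is optional (large)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        path.write_text(yaml.safe_dump(d, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["cohort"] = CohortConfig(**{
            **d.get("cohort", {}),
            "grid_dims": tuple(d.get("cohort", {}).get("grid_dims", (20, 24, 20))),
            "band_hz": tuple(d.get("cohort", {}).get("band_hz", (0.01, 0.08))),
        })
        d["preprocess"] = PreprocessConfig(**{
            **d.get("preprocess", {}),
            "band_hz": tuple(d.get("preprocess", {}).get("band_hz", (0.01, 0.08))),
        })
        d["stages"] = tuple(d.get("stages", ()))
        return cls(**d)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Run the configured stages, writing artifacts + checksum manifest.

    Returns a dict of in-memory results keyed by stage.  Any stage failure
    propagates with the stage name prefixed; artifacts written before the
    failure stay on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    written: list[Path] = [outdir / "config.yaml"]
    results: dict = {}
    stage = "init"
    try:
        # ----- simulate -------------------------------------------------
        stage = "simulate"
        cfg = dataclasses.replace(config.cohort, seed=derive_seed(config.seed, "simulate"))
        cohort = simulate_cohort(cfg)
        results["cohort"] = cohort
        io.write_participants(cohort.participants, outdir / "participants.tsv")
        written.append(outdir / "participants.tsv")
        truth_path = outdir / "ground_truth.json"
        truth_path.write_text(json.dumps(cohort.truth.to_json_dict(), indent=2))
        written.append(truth_path)
        tpl_path, sidecar = io.write_templates(
            cohort.truth.network_maps.maps, cohort.grid, outdir / "templates.nii.gz"
        )
        written += [tpl_path, sidecar]
        if config.write_nifti:
            nii_dir = outdir / "bold"
            nii_dir.mkdir(exist_ok=True)
            for sid, run in zip(cohort.participants["participant_id"], cohort.runs):
                written.append(io.write_bold(run, nii_dir / f"{sid}_bold.nii.gz"))

        # ----- preprocess ----------------------------------------------
        stage = "preprocess"
        sids = list(cohort.participants["participant_id"])
        if "preprocess" in config.stages:
            runs = {
                sid: preprocess_run(run, config.preprocess)
                for sid, run in zip(sids, cohort.runs)
            }
        else:
            runs = dict(zip(sids, cohort.runs))
        results["preprocessed"] = runs

        # ----- group ICA -------------------------------------------------
        stage = "ica"
        dec = run_group_ica(
            runs, n_components=config.n_components, k_subject=config.k_subject,
            seed=derive_seed(config.seed, "ica"),
        )
        assignment = match_components(dec, cohort.truth.network_maps.maps, mask=dec.mask)
        results["decomposition"] = dec
        results["assignment"] = assignment
        assign_path = outdir / "assignment.json"
        assign_path.write_text(json.dumps(
            {n: {"component": c, "match_r": r} for n, (c, r) in assignment.assignment.items()},
            indent=2,
        ))
        written.append(assign_path)

        # ----- intra-network --------------------------------------------
        stage = "intra"
        cluster_tables: dict[str, dict[str, list]] = {}
        if "intra" in config.stages:
            design = intra.build_group_design(cohort.participants)
            seed_i = derive_seed(config.seed, "intra")
            for name, (comp, _r) in assignment.assignment.items():
                maps = np.stack([dec.subject_maps[s][comp] for s in sids])
                tbl: dict[str, list] = {}
                for contrast in ("group", "HC_gt_HOM", "HC_gt_HET", "HET_gt_HOM"):
                    tbl[contrast] = intra.cluster_inference(
                        maps, dec.mask, design, contrast=contrast,
                        cluster_forming_p=config.cluster_forming_p,
                        n_permutations=config.n_permutations, seed=seed_i,
                    )
                cluster_tables[name] = tbl
            results["cluster_tables"] = cluster_tables
            rows = [
                {"network": n, "contrast": c, **vars(cl)}
                for n, t in cluster_tables.items() for c, cls_ in t.items() for cl in cls_
            ]
            pd.DataFrame(rows).to_csv(outdir / "intra_clusters.tsv", sep="\t", index=False)
            written.append(outdir / "intra_clusters.tsv")

        # ----- inter-network --------------------------------------------
        stage = "inter"
        names = list(assignment.assignment)
        comps = [assignment.assignment[n][0] for n in names]
        tcs = {sid: dec.subject_timecourses[sid][:, comps] for sid in sids}
        # unit-variance normalization of each subject course
        tcs = {
            sid: tc / np.where(tc.std(axis=0) > 0, tc.std(axis=0), 1.0)
            for sid, tc in tcs.items()
        }
        pair_table = inter.subject_pair_table(tcs, names, max_lag=config.max_lag)
        grouped = inter.group_pair_table(pair_table, cohort.participants)
        anova = inter.inter_network_anova_table(pair_table, cohort.participants)
        results["pair_table"] = pair_table
        results["group_pair_table"] = grouped
        results["anova_table"] = anova
        for fname, df in (
            ("inter_subject_pairs.tsv", pair_table),
            ("inter_group_pairs.tsv", grouped),
            ("inter_anova.tsv", anova),
        ):
            df.to_csv(outdir / fname, sep="\t", index=False)
            written.append(outdir / fname)

        # ----- report ----------------------------------------------------
        stage = "report"
        if "report" in config.stages:
            rpt = io.write_report(
                {
                    "cluster_tables": cluster_tables,
                    "pair_table": grouped,
                    "anova_table": anova,
                },
                outdir / "report.md",
            )
            written.append(rpt)
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {err}") from err

    manifest = {str(p.relative_to(outdir)): _checksum(p) for p in written if p.exists()}
    (outdir / "checksums.json").write_text(json.dumps(manifest, indent=2))
    results["checksums"] = manifest
    return results
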