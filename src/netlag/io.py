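"""Readers, writers and validation for on-disk pipeline artifacts.

Formats: NIfTI-1 (.nii / .nii.gz) for 4D BOLD and map stacks, TSV (UTF-8,
'.' decimal, empty cell = missing) for tables, JSON for ground truth and
network assignments.  Voxel coordinates printed anywhere are 0-based grid
indices; mm coordinates go through the grid affine.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import BoldRun, VoxelGrid

__all__ = [
    "read_bold",
    "write_bold",
    "read_participants",
    "write_participants",
    "write_templates",
    "read_templates",
    "read_manifest",
    "write_report",
]

PARTICIPANT_COLUMNS = [
    "participant_id", "group", "gene", "age", "sex", "education",
    "gm_volume", "corsi", "moca", "ledd",
]
VALID_GROUPS = {"HC", "HET", "HOM"}


def _grid_from_img(img) -> VoxelGrid:
    dims = tuple(int(d) for d in img.shape[:3])
    zooms = img.header.get_zooms()[:3]
    return VoxelGrid(dims=dims, voxel_size_mm=tuple(float(z) for z in zooms),
                     affine=np.asarray(img.affine, dtype=float))


def read_bold(
    path: str | Path,
    tr_s: float | None = None,
    mask: np.ndarray | None = None,
) -> BoldRun:
    """Load a 4D NIfTI-1 BOLD run.

    TR comes from the header (pixdim[4]) unless overridden; a zero header
    TR without override is an error.  If no mask is given, voxels with
    nonzero temporal variance form the mask.
    """
    path = Path(path)
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4D BOLD file, got {img.ndim}D")
    data = np.asarray(img.dataobj, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: data contains NaN/Inf values")
    if tr_s is None:
        tr_hdr = float(img.header.get_zooms()[3])
        if tr_hdr <= 0:
            raise ValueError(
                f"{path}: header TR is {tr_hdr}; pass tr_s= explicitly"
            )
        tr_s = tr_hdr
    grid = _grid_from_img(img)
    if mask is None:
        mask = data.var(axis=-1) > 0
    return BoldRun(data=data, tr_s=tr_s, grid=grid, mask=mask)


def write_bold(run: BoldRun, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(run.data, run.grid.affine)
    img.header.set_zooms(run.grid.voxel_size_mm + (run.tr_s,))
    nib.save(img, str(path))
    return path


def read_participants(path: str | Path) -> pd.DataFrame:
    """Read and validate a BIDS-style participants.tsv."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str})
    missing = [c for c in PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df[~df["group"].isin(VALID_GROUPS)]
    if len(bad):
        raise ValueError(
            f"{path}: unknown group labels in rows {bad.index.tolist()}: "
            f"{sorted(set(bad['group']))}"
        )
    dup = df["participant_id"][df["participant_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate participant_ids {sorted(set(dup))}")
    for c in ("age", "education", "gm_volume", "corsi", "moca", "ledd"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


def write_participants(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, na_rep="")
    return path


def write_templates(
    maps: dict[str, np.ndarray], grid: VoxelGrid, path: str | Path
) -> tuple[Path, Path]:
    """Write named 3D template maps as one 4D NIfTI + JSON name sidecar."""
    path = Path(path)
    stack = np.stack([maps[n] for n in maps], axis=-1)
    img = nib.Nifti1Image(stack, grid.affine)
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii(.gz)
    sidecar = Path(str(sidecar) + ".json")
    sidecar.write_text(json.dumps({"names": list(maps)}, indent=2))
    return path, sidecar


def read_templates(path: str | Path) -> tuple[dict[str, np.ndarray], VoxelGrid]:
    path = Path(path)
    img = nib.load(str(path))
    sidecar = Path(str(path).removesuffix(".gz").removesuffix(".nii") + ".json")
    names = json.loads(sidecar.read_text())["names"]
    data = np.asarray(img.dataobj, dtype=float)
    if data.shape[-1] != len(names):
        raise ValueError(f"{path}: {data.shape[-1]} volumes but {len(names)} names")
    return {n: data[..., i] for i, n in enumerate(names)}, _grid_from_img(img)


def read_manifest(path: str | Path, participants: pd.DataFrame) -> pd.DataFrame:
    """Read a (subject_id, path, group) manifest TSV and validate it."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for c in ("subject_id", "path"):
        if c not in df.columns:
            raise ValueError(f"{path}: manifest needs a '{c}' column")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate subject_ids {sorted(set(dup))}")
    known = set(participants["participant_id"])
    unknown = [s for s in df["subject_id"] if s not in known]
    if unknown:
        raise ValueError(f"{path}: subjects not in participants table: {unknown}")
    missing = [p for p in df["path"] if not Path(p).exists()]
    if missing:
        raise ValueError(f"{path}: run files not found: {missing}")
    return df


def write_report(results: dict, path: str | Path) -> Path:
    """Render a Markdown summary of cluster and pair tables.

    ``results`` may hold ``cluster_tables`` (network -> contrast -> list of
    cluster dicts / ClusterResult), ``pair_table`` (grouped DataFrame) and
    ``anova_table`` (DataFrame).  Empty sections render as explicit
    'no significant clusters' statements.
    """
    path = Path(path)
    lines = ["# Resting-state connectivity report", ""]

    lines.append("## Intra-network cluster results")
    cluster_tables = results.get("cluster_tables", {})
    any_cluster = False
    for network, contrasts in cluster_tables.items():
        for contrast, clusters in contrasts.items():
            if not clusters:
                continue
            any_cluster = True
            lines += [f"", f"### {network} — {contrast}", "",
                      "| cluster | size (voxels) | peak voxel | peak stat | corrected p |",
                      "|---|---|---|---|---|"]
            for c in clusters:
                d = c if isinstance(c, dict) else vars(c)
                lines.append(
                    f"| {d['cluster_id']} | {d['size_voxels']} | {d['peak_voxel']} "
                    f"| {d['peak_stat']:.2f} | {d['corrected_p']:.4f} |"
                )
    if not any_cluster:
        lines.append("\nNo significant clusters.")

    pair_table = results.get("pair_table")
    lines += ["", "## Inter-network lagged correlations (group means)"]
    if pair_table is None or len(pair_table) == 0:
        lines.append("\nNo pair results.")
    else:
        lines += ["", pair_table.to_markdown(index=False)]

    anova = results.get("anova_table")
    if anova is not None and len(anova):
        lines += ["", "## Inter-network group ANOVA", "", anova.to_markdown(index=False)]

    path.write_text("\n".join(lines) + "\n")
    return path
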