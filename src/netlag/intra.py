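"""Intra-network voxelwise group statistics with permutation cluster FWE.

Subject-specific network maps are compared voxel by voxel with an ordinary
least-squares GLM: a three-level group factor (HC / HET / HOM) with total
grey-matter volume and years of education as nuisance covariates, plus a
two-group design with the Corsi span as covariate of interest.  Cluster
inference replaces parametric random-field correction with a
label-permutation maximal-cluster-size test: clusters are formed at a
voxelwise threshold (default p < 0.001 two-sided, 26-connectivity) and the
familywise-corrected p of each observed cluster is the proportion of
permutations whose largest cluster is at least as big.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "DesignMatrix",
    "ClusterResult",
    "build_group_design",
    "fit_voxelwise_glm",
    "t_contrast",
    "f_group_contrast",
    "cluster_inference",
    "corsi_correlation_analysis",
]

CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class DesignMatrix:
    """Named design matrix with interest/nuisance column bookkeeping."""

    X: np.ndarray
    columns: list[str]
    interest: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("X shape does not match column names")
        r = np.linalg.matrix_rank(self.X)
        if r < self.X.shape[1]:
            # identify a collinear column for the error message
            bad = []
            for j in range(self.X.shape[1]):
                others = np.delete(self.X, j, axis=1)
                if np.linalg.matrix_rank(others) == r:
                    bad.append(self.columns[j])
            raise ValueError(f"design is rank-deficient; collinear columns: {bad}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def column(self, name: str) -> int:
        return self.columns.index(name)


def build_group_design(
    participants: pd.DataFrame,
    nuisance: tuple[str, ...] = ("gm_volume", "education"),
    groups: tuple[str, ...] = ("HC", "HET", "HOM"),
) -> DesignMatrix:
    """Cell-means group design (one indicator per group) + centred nuisance."""
    cols, names, interest = [], [], []
    for g in groups:
        ind = (participants["group"] == g).to_numpy(float)
        if ind.sum() == 0:
            raise ValueError(f"no subjects in group {g}")
        cols.append(ind)
        names.append(f"group_{g}")
        interest.append(f"group_{g}")
    for c in nuisance:
        v = participants[c].to_numpy(float)
        cols.append(v - v.mean())
        names.append(c)
    return DesignMatrix(np.column_stack(cols), names, interest)


@dataclass
class GLMFit:
    beta: np.ndarray       # (p, V)
    sigma2: np.ndarray     # (V,)
    dof: int
    xtx_inv: np.ndarray    # (p, p)
    design: DesignMatrix


def fit_voxelwise_glm(maps: np.ndarray, design: DesignMatrix) -> GLMFit:
    """OLS per voxel: maps (n_subjects, V) on the design matrix."""
    Y = np.asarray(maps, dtype=float)
    X = design.X
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError(f"maps have {Y.shape[0]} rows but design has {n}")
    if n <= p:
        raise ValueError(f"need more subjects ({n}) than design columns ({p})")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    return GLMFit(beta=beta, sigma2=sigma2, dof=dof, xtx_inv=xtx_inv, design=design)


def t_contrast(fit: GLMFit, c: np.ndarray) -> np.ndarray:
    """Voxelwise t statistic for the contrast vector c."""
    c = np.asarray(c, dtype=float)
    num = c @ fit.beta
    den = np.sqrt(np.maximum(fit.sigma2, 1e-300) * (c @ fit.xtx_inv @ c))
    return num / den


def f_group_contrast(maps: np.ndarray, design: DesignMatrix) -> tuple[np.ndarray, int, int]:
    """Voxelwise F for equality of all group cell means (ANCOVA main effect)."""
    full = fit_voxelwise_glm(maps, design)
    interest_idx = [design.column(c) for c in design.interest]
    keep = [j for j in range(design.X.shape[1]) if j not in interest_idx]
    # reduced model: intercept replaces the group indicators
    Xr = np.column_stack([np.ones(design.n)] + [design.X[:, j] for j in keep])
    q = len(interest_idx) - 1
    br = np.linalg.lstsq(Xr, maps, rcond=None)[0]
    rss_r = ((maps - Xr @ br) ** 2).sum(axis=0)
    rss_f = full.sigma2 * full.dof
    F = ((rss_r - rss_f) / q) / np.maximum(rss_f / full.dof, 1e-300)
    return F, q, full.dof


def _contrast_vector(design: DesignMatrix, contrast: str | np.ndarray) -> np.ndarray:
    if not isinstance(contrast, str):
        return np.asarray(contrast, dtype=float)
    # "HC_gt_HOM" style: group_HC minus group_HOM
    a, _, b = contrast.partition("_gt_")
    c = np.zeros(design.X.shape[1])
    c[design.column(f"group_{a}")] = 1.0
    c[design.column(f"group_{b}")] = -1.0
    return c


@dataclass
class ClusterResult:
    cluster_id: int
    size_voxels: int
    peak_voxel: tuple[int, int, int]
    peak_stat: float
    corrected_p: float


def _clusters_above(stat3d: np.ndarray, thresh: float, two_sided: bool):
    supra = (np.abs(stat3d) if two_sided else stat3d) > thresh
    labels, n = ndimage.label(supra, structure=CONN26)
    return labels, n, supra


def _max_cluster_size(stat3d: np.ndarray, thresh: float, two_sided: bool) -> int:
    labels, n, _ = _clusters_above(stat3d, thresh, two_sided)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def cluster_inference(
    maps: np.ndarray,
    mask: np.ndarray,
    design: DesignMatrix,
    contrast: str | np.ndarray = "group",
    cluster_forming_p: float = 0.001,
    n_permutations: int = 1000,
    seed: int = 0,
    two_sided: bool = True,
) -> list[ClusterResult]:
    """Permutation maximal-cluster-size FWE inference on a voxelwise GLM.

    ``contrast="group"`` tests the group main effect with an F statistic;
    any other contrast (string like ``"HC_gt_HOM"`` or an explicit vector)
    uses a t statistic.  Permutations shuffle the rows of the interest
    (group) columns against the data/nuisance, and the corrected p of each
    observed cluster is ``(1 + #{perm max size >= observed}) / (n_perm + 1)``.
    An empty list means no supra-threshold voxels (not an error).
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    maps = np.asarray(maps, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    rng = np.random.default_rng(seed)
    interest_idx = [design.column(c) for c in design.interest]

    def stat_map(X: np.ndarray) -> np.ndarray:
        d = DesignMatrix.__new__(DesignMatrix)
        d.X, d.columns, d.interest = X, design.columns, design.interest
        if isinstance(contrast, str) and contrast == "group":
            F, q, dof = f_group_contrast(maps, d)
            return F, q, dof
        fit = fit_voxelwise_glm(maps, d)
        return t_contrast(fit, _contrast_vector(design, contrast)), None, fit.dof

    obs_stat, q, dof = stat_map(design.X)
    if isinstance(contrast, str) and contrast == "group":
        thresh = stats.f.isf(cluster_forming_p, q, dof)
        sided = False  # F is one-sided by construction
    else:
        thresh = stats.t.isf(cluster_forming_p / 2 if two_sided else cluster_forming_p, dof)
        sided = two_sided

    obs3d = np.zeros(mask.shape)
    obs3d[mask] = obs_stat
    labels, n_clusters, _ = _clusters_above(np.where(mask, obs3d, 0.0), thresh, sided)
    if n_clusters == 0:
        return []
    sizes = np.bincount(labels.ravel())[1:]

    null_max = np.empty(n_permutations, dtype=int)
    X_perm = design.X.copy()
    for i in range(n_permutations):
        perm = rng.permutation(design.n)
        X_perm[:, interest_idx] = design.X[np.ix_(perm, interest_idx)]
        pstat, _, _ = stat_map(X_perm)
        p3d = np.zeros(mask.shape)
        p3d[mask] = pstat
        null_max[i] = _max_cluster_size(np.where(mask, p3d, 0.0), thresh, sided)

    results = []
    order = np.argsort(sizes)[::-1]
    for rank, ci in enumerate(order, start=1):
        size = int(sizes[ci])
        in_cluster = labels == (ci + 1)
        vals = np.where(in_cluster, np.abs(obs3d) if sided else obs3d, -np.inf)
        peak = np.unravel_index(int(np.argmax(vals)), mask.shape)
        corrected = (1 + int((null_max >= size).sum())) / (n_permutations + 1)
        results.append(
            ClusterResult(
                cluster_id=rank, size_voxels=size,
                peak_voxel=tuple(int(v) for v in peak),
                peak_stat=float(obs3d[peak]), corrected_p=float(corrected),
            )
        )
    return results


def corsi_correlation_analysis(
    maps: np.ndarray,
    participants: pd.DataFrame,
    mask: np.ndarray | None = None,
    cluster_forming_p: float = 0.001,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict[str, list[ClusterResult]]:
    """Corsi-span correlation with network FC in the mutation-carrier groups.

    GLM over HET+HOM subjects with group indicators, group-specific
    (centred) Corsi slopes, and total grey-matter volume plus mutated gene
    as nuisance.  Returns, per carrier group, the clusters where the
    positive Corsi slope survives permutation cluster FWE.  ``maps`` rows
    must align with ``participants`` rows; subjects with missing Corsi are
    excluded (logged), and a group with fewer than 4 scored subjects is
    skipped with a warning.
    """
    part = participants.reset_index(drop=True)
    carriers = part["group"].isin(["HET", "HOM"]).to_numpy()
    has_corsi = part["corsi"].notna().to_numpy()
    keep = carriers & has_corsi
    n_dropped = int((carriers & ~has_corsi).sum())
    if n_dropped:
        warnings.warn(f"excluding {n_dropped} carriers with missing Corsi", stacklevel=2)
    sub = part[keep].reset_index(drop=True)
    Y = np.asarray(maps, dtype=float)[keep]

    results: dict[str, list[ClusterResult]] = {}
    cols, names = [], []
    for g in ("HET", "HOM"):
        ind = (sub["group"] == g).to_numpy(float)
        cols.append(ind)
        names.append(f"group_{g}")
    corsi = sub["corsi"].to_numpy(float)
    for g in ("HET", "HOM"):
        ind = (sub["group"] == g).to_numpy(bool)
        slope = np.zeros(len(sub))
        slope[ind] = corsi[ind] - corsi[ind].mean()
        cols.append(slope)
        names.append(f"corsi_{g}")
    gm = sub["gm_volume"].to_numpy(float)
    cols.append(gm - gm.mean())
    names.append("gm_volume")
    gene = (sub["gene"] == "Park2").to_numpy(float)
    if np.ptp(gene) > 0:
        cols.append(gene - gene.mean())
        names.append("gene_Park2")
    else:
        warnings.warn("single mutated gene in sample; gene covariate dropped",
                      stacklevel=2)
    design = DesignMatrix(np.column_stack(cols), names, interest=["corsi_HET", "corsi_HOM"])

    for g in ("HET", "HOM"):
        n_g = int(((sub["group"] == g)).sum())
        if n_g < 4:
            warnings.warn(f"group {g}: only {n_g} subjects with Corsi; slope skipped",
                          stacklevel=2)
            continue
        c = np.zeros(design.X.shape[1])
        c[design.column(f"corsi_{g}")] = 1.0
        # positive-slope (one-sided) t clusters
        d = DesignMatrix.__new__(DesignMatrix)
        d.X, d.columns, d.interest = design.X, design.columns, [f"corsi_{g}"]
        # flat pseudo-grid when no spatial mask is supplied
        mask3 = mask if mask is not None else np.ones((Y.shape[1], 1, 1), dtype=bool)
        results[g] = cluster_inference(
            Y, mask3, d, contrast=c, cluster_forming_p=cluster_forming_p,
            n_permutations=n_permutations, seed=seed, two_sided=False,
        )
    return results
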