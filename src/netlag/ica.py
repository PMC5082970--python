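"""Temporal-concatenation group spatial ICA with back-reconstruction.

Two-stage reduction in the GIFT lineage: each subject's (T, V) data is
reduced to k_subject principal time-basis components; the reduced stacks
are concatenated over the reduced-time dimension and a second PCA brings
the group data to the model order (20 components in the study setting).
Fixed-point ICA (FastICA, logcosh contrast) then unmixes the *spatial*
dimension, giving group spatial maps; per-subject maps and time courses
are back-reconstructed through the stored reduction matrices.  Each map's
sign is fixed so its skewness is positive (networks are sparse positive
activations), maps are z-scored over the mask, and the named networks of
interest are selected by globally optimal template matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import skew
from sklearn.decomposition import FastICA
from sklearn.utils.extmath import randomized_svd

from .core import BoldRun

__all__ = [
    "SubjectReduction",
    "ComponentDecomposition",
    "NetworkAssignment",
    "subject_reduce",
    "group_decompose",
    "zscore_maps",
    "match_components",
    "run_group_ica",
]


@dataclass
class SubjectReduction:
    """PCA reduction of one subject's masked (T, V) matrix."""

    basis: np.ndarray         # (T, k) orthonormal time basis F
    reduced: np.ndarray       # (k, V) reduced data R with X ~= F @ R + mean
    voxel_mean: np.ndarray    # (V,) per-voxel temporal mean
    variance_explained: np.ndarray  # (k,) singular-value energy fractions

    @property
    def k(self) -> int:
        return self.basis.shape[1]


def subject_reduce(run: BoldRun, k_subject: int) -> SubjectReduction:
    """Principal-subspace reduction of a run's voxels-by-time matrix.

    Keeps the top ``k_subject`` temporal principal components; the stored
    basis allows lossless reconstruction when ``k_subject`` reaches the
    data rank.
    """
    X = run.masked_matrix()  # (T, V)
    T = X.shape[0]
    if not 1 <= k_subject <= T:
        raise ValueError(f"k_subject={k_subject} must be in [1, T={T}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] <= 0 or not np.isfinite(s[0]):
        raise ValueError("degenerate (zero-variance) data; cannot reduce")
    F = U[:, :k_subject]
    R = s[:k_subject, None] * Vt[:k_subject]
    total = float((s**2).sum())
    return SubjectReduction(
        basis=F, reduced=R, voxel_mean=mean,
        variance_explained=(s[:k_subject] ** 2) / total,
    )


@dataclass
class ComponentDecomposition:
    """Group ICA output: group maps plus per-subject back-reconstructions."""

    n_components: int
    group_maps: np.ndarray                  # (m, V), z-scored over mask
    subject_maps: dict[str, np.ndarray]     # subject -> (m, V)
    subject_timecourses: dict[str, np.ndarray]  # subject -> (T, m)
    mask: np.ndarray                        # 3D boolean grid mask
    mixing_info: dict = field(default_factory=dict, repr=False)

    def map_3d(self, idx: int) -> np.ndarray:
        out = np.zeros(self.mask.shape)
        out[self.mask] = self.group_maps[idx]
        return out


@dataclass
class NetworkAssignment:
    """Injective mapping from named networks to component indices."""

    assignment: dict[str, tuple[int, float]]  # name -> (component index, match r)
    unassigned: list[int]
    match_floor: float = 0.3

    @property
    def flagged(self) -> list[str]:
        return [n for n, (_, r) in self.assignment.items() if r < self.match_floor]


def _fix_signs(maps: np.ndarray, *linked: np.ndarray) -> tuple[np.ndarray, ...]:
    """Flip components so each spatial map has positive skewness."""
    flips = np.where(skew(maps, axis=1) < 0, -1.0, 1.0)
    out = [maps * flips[:, None]]
    for arr in linked:
        out.append(arr * flips[None, :])
    return tuple(out)


def group_decompose(
    reductions: dict[str, SubjectReduction],
    n_components: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    on_nonconvergence: str = "warn",
    back_reconstruction: str = "gica",
) -> ComponentDecomposition:
    """Concatenate subject reductions, run spatial FastICA, back-reconstruct.

    ``back_reconstruction`` is ``"gica"`` (projection through the stored
    reduction matrices, the GIFT-lineage default) or ``"dual_regression"``
    (spatial maps re-estimated by least squares of each subject's data on
    its time courses).
    """
    if on_nonconvergence not in ("warn", "raise"):
        raise ValueError("on_nonconvergence must be 'warn' or 'raise'")
    sids = list(reductions)
    ks = [reductions[s].k for s in sids]
    if sum(ks) < n_components:
        raise ValueError(
            f"total reduced dimension {sum(ks)} < n_components {n_components}"
        )
    stack = np.vstack([reductions[s].reduced for s in sids])  # (sum k, V)
    # second-stage PCA to the model order
    G, s2, Vt2 = randomized_svd(
        stack, n_components=n_components, random_state=seed, n_iter=7
    )
    Y = s2[:, None] * Vt2  # (m, V): stack ~= G @ Y

    ica = FastICA(
        n_components=n_components, fun="logcosh", max_iter=max_iter, tol=tol,
        whiten="unit-variance", random_state=np.random.RandomState(seed),
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        S_vox = ica.fit_transform(Y.T)  # (V, m) spatial sources
    if ica.n_iter_ >= max_iter:
        msg = (
            f"FastICA did not converge within {max_iter} iterations "
            f"(tol={tol:g}); treat components with caution"
        )
        if on_nonconvergence == "raise":
            raise RuntimeError(msg)
        warnings.warn(msg, stacklevel=2)
    else:
        for w in caught:
            if "converge" not in str(w.message):
                warnings.warn_explicit(
                    w.message, w.category, w.filename, w.lineno
                )

    S = S_vox.T                      # (m, V)
    A = ica.mixing_                  # (m, m): Y.T ~= S_vox @ A.T + mean
    S, A = _fix_signs(S, A)

    subject_maps: dict[str, np.ndarray] = {}
    subject_tcs: dict[str, np.ndarray] = {}
    offset = 0
    for sid, k in zip(sids, ks):
        red = reductions[sid]
        G_i = G[offset : offset + k]         # (k, m)
        offset += k
        T_i = red.basis @ (G_i @ A)          # (T, m) subject time courses
        subject_tcs[sid] = T_i
        if back_reconstruction == "gica":
            subject_maps[sid] = np.linalg.pinv(G_i @ A) @ red.reduced
        elif back_reconstruction == "dual_regression":
            X_i = red.basis @ red.reduced    # (T, V) centred subject data
            subject_maps[sid] = np.linalg.lstsq(T_i, X_i, rcond=None)[0]
        else:
            raise ValueError(f"unknown back_reconstruction {back_reconstruction!r}")

    dec = ComponentDecomposition(
        n_components=n_components,
        group_maps=S,
        subject_maps=subject_maps,
        subject_timecourses=subject_tcs,
        mask=np.ones(1, dtype=bool),  # replaced by run_group_ica / caller
        mixing_info={"group_pca_basis": G, "ica_mixing": A, "singular_values": s2},
    )
    return dec


def zscore_maps(dec: ComponentDecomposition) -> ComponentDecomposition:
    """Standardize every group map to mean 0, SD 1 over the mask voxels."""
    maps = dec.group_maps
    sd = maps.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.nonzero(sd == 0)[0][0])
        raise ValueError(f"component {bad} has a constant map; cannot z-score")
    dec.group_maps = (maps - maps.mean(axis=1, keepdims=True)) / sd[:, None]
    return dec


def match_components(
    dec: ComponentDecomposition,
    templates: dict[str, np.ndarray],
    mask: np.ndarray | None = None,
    match_floor: float = 0.3,
) -> NetworkAssignment:
    """Assign named template networks to components, injectively and optimally.

    Solves the bipartite assignment maximizing total spatial correlation
    between template maps and group maps.  Ties prefer the lower component
    index.  Assignments with match r below ``match_floor`` are flagged but
    kept (audit trail for the automated stand-in of visual review).
    """
    names = list(templates)
    if len(names) > dec.n_components:
        raise ValueError(
            f"{len(names)} templates but only {dec.n_components} components"
        )
    if mask is None:
        mask = dec.mask if dec.mask.ndim == 3 else None
    tvecs = []
    for n in names:
        t = np.asarray(templates[n], dtype=float)
        tvecs.append(t[mask] if (mask is not None and t.ndim == 3) else t.ravel())
    tmat = np.stack(tvecs)  # (n_templates, V)
    if tmat.shape[1] != dec.group_maps.shape[1]:
        raise ValueError("template voxel count does not match decomposition")

    R = np.corrcoef(tmat, dec.group_maps)[: len(names), len(names) :]
    # tiny index penalty implements the lower-index tie-break deterministically
    penalty = 1e-9 * np.arange(dec.n_components)[None, :]
    ri, ci = linear_sum_assignment(-(R - penalty))
    assignment = {names[i]: (int(c), float(R[i, c])) for i, c in zip(ri, ci)}
    used = {c for c, _ in assignment.values()}
    unassigned = [i for i in range(dec.n_components) if i not in used]
    out = NetworkAssignment(assignment=assignment, unassigned=unassigned,
                            match_floor=match_floor)
    for n in out.flagged:
        warnings.warn(
            f"network {n} matched at r={assignment[n][1]:.3f} < {match_floor}",
            stacklevel=2,
        )
    return out


def run_group_ica(
    runs: dict[str, BoldRun],
    n_components: int = 20,
    k_subject: int = 30,
    seed: int = 0,
    **kwargs,
) -> ComponentDecomposition:
    """Subject reduction + group decomposition for a dict of runs.

    ``k_subject`` is capped at each run's T.  All runs must share one grid
    and mask; the common mask is the intersection.
    """
    sids = list(runs)
    mask = None
    for r in runs.values():
        mask = r.mask if mask is None else (mask & r.mask)
    runs = {s: BoldRun(r.data, r.tr_s, r.grid, mask) for s, r in runs.items()}
    reductions = {
        s: subject_reduce(r, min(k_subject, r.n_timepoints)) for s, r in runs.items()
    }
    dec = group_decompose(reductions, n_components=n_components, seed=seed, **kwargs)
    dec.mask = mask
    return zscore_maps(dec)
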