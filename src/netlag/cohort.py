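"""Synthetic multi-subject resting-state BOLD cohort with known ground truth.

Emulates a three-group study of autosomal-recessive parkinsonism gene
carriers — healthy controls (HC, n=22), heterozygous (HET, n=12) and
homozygous (HOM, n=8) PINK1/Park2 mutation carriers — scanned at TR 2.08 s
for 220 volumes.  Five canonical resting-state networks (default-mode,
salience, executive, right/left fronto-parietal) are embedded as Gaussian
blob maps whose time courses carry group-specific inter-network couplings
at non-zero circular lags, plus group-specific intra-network amplitude
deficits.  Every injected effect is recorded in a :class:`GroundTruth` so
each downstream stage can be validated without any real data.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import BoldRun, VoxelGrid

__all__ = [
    "NETWORK_NAMES",
    "GROUPS",
    "NetworkMaps",
    "GroundTruth",
    "SubjectPhenotype",
    "CohortConfig",
    "make_network_maps",
    "simulate_network_timecourses",
    "simulate_subject",
    "simulate_cohort",
    "subject_seed",
    "default_coupling",
    "default_amplitudes",
]

NETWORK_NAMES = ("DMN", "SN", "ExN", "rFP", "lFP")
GROUPS = ("HC", "HET", "HOM")

# Group demographics: mean/SD of age and years of education, and sex ratio
# (M, F) per group, for the default three-group cohort of 22/12/8.
GROUP_DEMOGRAPHICS = {
    "HC": {"n": 22, "age": (47.0, 12.2), "education": (14.7, 3.2), "sex_mf": (10, 12)},
    "HET": {"n": 12, "age": (41.9, 14.8), "education": (12.3, 2.1), "sex_mf": (5, 7)},
    "HOM": {"n": 8, "age": (51.4, 8.1), "education": (11.4, 2.3), "sex_mf": (6, 2)},
}
# Corsi block-tapping span (visuo-spatial working memory) and MoCA are only
# administered to mutation carriers; LEDD only to the treated (HOM) group.
GROUP_COGNITION = {
    "HET": {"corsi": (4.6, 0.5), "moca": (23.8, 1.8)},
    "HOM": {"corsi": (3.9, 0.3), "moca": (23.0, 2.6)},
}
LEDD_HOM = (590.9, 358.1)
# Total grey-matter volume (arbitrary units ~ ml): mild atrophy gradient.
GROUP_GM = {"HC": (640.0, 55.0), "HET": (625.0, 55.0), "HOM": (600.0, 55.0)}
# Genes per group: HET 10 PINK1 / 2 Park2; HOM 5 PINK1 / 3 Park2.
GROUP_GENES = {"HC": [], "HET": ["PINK1"] * 10 + ["Park2"] * 2, "HOM": ["PINK1"] * 5 + ["Park2"] * 3}


def subject_seed(master_seed: int, subject_id: str) -> int:
    """Stable per-subject seed: first 4 bytes of sha256(master:subject), < 2^31."""
    h = hashlib.sha256(f"{master_seed}:{subject_id}".encode()).digest()
    return int.from_bytes(h[:4], "big") & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# Spatial maps


@dataclass
class NetworkMaps:
    """Named nonnegative 3D network maps plus their per-blob decomposition."""

    names: tuple[str, ...]
    maps: dict[str, np.ndarray]
    blob_maps: dict[str, list[np.ndarray]]  # each peak-normalised to 1
    centers_mm: dict[str, list[np.ndarray]]
    sigma_mm: float

    def stacked(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n_networks, V) matrix of the maps, optionally masked."""
        arrs = [self.maps[n] for n in self.names]
        if mask is None:
            return np.stack([a.ravel() for a in arrs])
        return np.stack([a[mask] for a in arrs])


def _gaussian_blob(grid: VoxelGrid, center_mm: np.ndarray, sigma_mm: float) -> np.ndarray:
    axes = [np.arange(d) for d in grid.dims]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    ijk = np.stack([ii, jj, kk], axis=-1).astype(float)
    mm = grid.voxel_to_mm(ijk)
    d2 = ((mm - center_mm) ** 2).sum(axis=-1)
    return np.exp(-d2 / (2.0 * sigma_mm**2))


def _spatial_r(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a.ravel(), b.ravel())[0, 1])


def make_network_maps(
    grid: VoxelGrid,
    n_networks: int = 5,
    blobs_per_network: int = 2,
    seed: int = 0,
    sigma_mm: float = 5.0,
    max_overlap_r: float = 0.3,
    names: tuple[str, ...] | None = None,
    max_tries: int = 5000,
) -> NetworkMaps:
    """Place ``n_networks`` sums of Gaussian blobs with low pairwise overlap.

    Each network map is a sum of ``blobs_per_network`` 3D Gaussians of width
    ``sigma_mm``, peak-normalised to 1.  Blob centres are rejection-sampled
    so that the pairwise spatial correlation between any two *different*
    networks stays below ``max_overlap_r``.  Deterministic given ``seed``.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    if names is None:
        names = NETWORK_NAMES[:n_networks] if n_networks <= 5 else tuple(
            f"NET{i}" for i in range(n_networks)
        )
    if len(names) != n_networks:
        raise ValueError("names length must equal n_networks")
    rng = np.random.default_rng(seed)

    extent = np.asarray(grid.dims) * np.asarray(grid.voxel_size_mm)
    margin = 1.5 * sigma_mm
    lo = grid.voxel_to_mm(np.zeros(3)) + margin
    hi = grid.voxel_to_mm(np.asarray(grid.dims, float) - 1) - margin
    if np.any(hi <= lo):
        raise ValueError(
            f"grid extent {tuple(extent)} mm too small to place blobs of "
            f"sigma {sigma_mm} mm with a {margin} mm margin"
        )
    # Centre separation that guarantees two equal-width Gaussians correlate
    # below the bound: corr ~ exp(-d^2 / (4 sigma^2)).
    min_sep = 2.0 * sigma_mm * np.sqrt(np.log(1.0 / max_overlap_r))

    centers: list[np.ndarray] = []   # across-network centres, for separation
    per_net_centers: dict[str, list[np.ndarray]] = {n: [] for n in names}
    tries = 0
    for name in names:
        for _ in range(blobs_per_network):
            while True:
                tries += 1
                if tries > max_tries:
                    raise ValueError(
                        f"could not place {n_networks}x{blobs_per_network} blobs with "
                        f">= {min_sep:.1f} mm separation inside a {tuple(extent)} mm grid "
                        f"(overlap bound r < {max_overlap_r}); enlarge the grid or sigma down"
                    )
                c = rng.uniform(lo, hi)
                others = [p for n2, pts in per_net_centers.items() if n2 != name for p in pts]
                if all(np.linalg.norm(c - p) >= min_sep for p in others):
                    # same-network blobs may sit closer, but not on top of each other
                    own = per_net_centers[name]
                    if all(np.linalg.norm(c - p) >= 1.5 * sigma_mm for p in own):
                        break
            per_net_centers[name].append(c)
            centers.append(c)

    maps: dict[str, np.ndarray] = {}
    blob_maps: dict[str, list[np.ndarray]] = {}
    for name in names:
        blobs = [_gaussian_blob(grid, c, sigma_mm) for c in per_net_centers[name]]
        blobs = [b / b.max() for b in blobs]  # peak value 1 at the centre voxel
        blob_maps[name] = blobs
        total = np.sum(blobs, axis=0)
        maps[name] = total / total.max()

    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            r = _spatial_r(maps[a], maps[b])
            if r >= max_overlap_r:
                raise ValueError(
                    f"networks {a} and {b} overlap at spatial r={r:.3f} >= {max_overlap_r}"
                )
    return NetworkMaps(
        names=tuple(names), maps=maps, blob_maps=blob_maps,
        centers_mm={n: per_net_centers[n] for n in names}, sigma_mm=sigma_mm,
    )


# ---------------------------------------------------------------------------
# Time courses


def _band_bins(T: int, tr_s: float, band_hz: tuple[float, float]) -> np.ndarray:
    f = np.fft.rfftfreq(T, d=tr_s)
    keep = (f >= band_hz[0]) & (f <= band_hz[1]) & (f > 0)
    bins = np.nonzero(keep)[0]
    if bins.size == 0:
        raise ValueError(f"band {band_hz} Hz contains no DFT bins for T={T}, TR={tr_s}")
    return bins


def _cross_spectral_matrix(
    coupling: np.ndarray, coupling_lags: np.ndarray, m: int, T: int
) -> np.ndarray:
    """Target coherence matrix at DFT bin m: |c_ab| with the lag as phase."""
    phase = np.exp(2j * np.pi * m * coupling_lags / T)
    P = coupling * phase
    np.fill_diagonal(P, 1.0)
    return P


def coupling_feasibility(
    coupling: np.ndarray,
    coupling_lags: np.ndarray,
    T: int,
    tr_s: float,
    band_hz: tuple[float, float] = (0.01, 0.08),
) -> float:
    """Smallest eigenvalue of the target cross-spectral matrix over the band.

    The requested coupling structure is realizable iff this is positive.
    """
    bins = _band_bins(T, tr_s, band_hz)
    return float(
        min(
            np.linalg.eigvalsh(_cross_spectral_matrix(coupling, coupling_lags, m, T)).min()
            for m in bins
        )
    )


def shrink_to_feasible(
    coupling: np.ndarray,
    coupling_lags: np.ndarray,
    T: int,
    tr_s: float,
    band_hz: tuple[float, float] = (0.01, 0.08),
    min_eig: float = 0.1,
) -> np.ndarray:
    """Scale off-diagonal couplings down until the structure is realizable.

    Group-mean lagged correlations (which are maxima over lags) need not
    form a jointly consistent correlation structure; this returns
    ``lam * coupling`` with the largest ``lam <= 1`` for which every
    in-band cross-spectral matrix has smallest eigenvalue >= ``min_eig``.
    """
    worst = coupling_feasibility(coupling, coupling_lags, T, tr_s, band_hz)
    # eigenvalues are 1 + lam * (eig of off-diagonal part)
    off_min = worst - 1.0
    if off_min >= -(1.0 - min_eig):
        return coupling.copy()
    lam = (1.0 - min_eig) / (-off_min)
    return lam * coupling


def simulate_network_timecourses(
    T: int,
    tr_s: float,
    coupling: np.ndarray,
    coupling_lags: np.ndarray,
    band_hz: tuple[float, float] = (0.01, 0.08),
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate coupled band-limited network time courses.

    Construction: at each in-band DFT bin the complex spectra of the n
    courses are drawn jointly Gaussian with coherence matrix
    ``coupling[a, b] * exp(2i pi m lags[a, b] / T)`` (unit diagonal), via a
    Cholesky factor; out-of-band bins are zero.  The circular
    cross-correlation of course a with course b is then maximal in absolute
    value at lag ``coupling_lags[a, b]`` with expected value
    ``coupling[a, b]``.

    Returns a (T, n) matrix of exactly unit-variance, zero-mean courses.
    """
    coupling = np.asarray(coupling, dtype=float)
    coupling_lags = np.asarray(coupling_lags, dtype=int)
    n = coupling.shape[0]
    if coupling.shape != (n, n) or coupling_lags.shape != (n, n):
        raise ValueError("coupling and coupling_lags must be square and same shape")
    if np.any(np.abs(coupling) >= 1):
        raise ValueError("|coupling| must be < 1")
    if not np.allclose(coupling, coupling.T):
        raise ValueError("coupling must be symmetric")
    if np.any(coupling_lags != -coupling_lags.T):
        raise ValueError("coupling_lags must be antisymmetric (lags[a,b] = -lags[b,a])")
    max_lag = int(np.max(np.abs(coupling_lags))) if n > 1 else 0
    if T <= 2 * max_lag:
        raise ValueError(f"T={T} must exceed twice the largest |lag|={max_lag}")
    low, high = band_hz
    nyq = 1.0 / (2.0 * tr_s)
    if not (0 < low < high < nyq):
        raise ValueError(f"band {band_hz} invalid for TR={tr_s} (Nyquist {nyq:.3f} Hz)")

    if rng is None:
        rng = np.random.default_rng(seed)
    bins = _band_bins(T, tr_s, band_hz)
    n_rfft = T // 2 + 1
    spectra = np.zeros((n_rfft, n), dtype=complex)
    for m in bins:
        P = _cross_spectral_matrix(coupling, coupling_lags, m, T)
        try:
            L = np.linalg.cholesky(P)
        except np.linalg.LinAlgError as err:
            eig = float(np.linalg.eigvalsh(P).min())
            raise ValueError(
                "requested coupling structure is not realizable (cross-spectral "
                f"matrix at bin {m} has smallest eigenvalue {eig:.3f} <= 0); "
                "use shrink_to_feasible() to scale the couplings down"
            ) from err
        z = (rng.standard_normal(n) + 1j * rng.standard_normal(n)) / np.sqrt(2.0)
        spectra[m] = L @ z
    courses = np.fft.irfft(spectra, n=T, axis=0)
    courses -= courses.mean(axis=0)
    sd = courses.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate (zero-variance) simulated course")
    courses /= sd
    return courses


# ---------------------------------------------------------------------------
# Ground truth and phenotypes


@dataclass
class GroundTruth:
    """Everything injected into the synthetic cohort, for later validation."""

    network_maps: NetworkMaps
    coupling: dict[str, np.ndarray]          # group -> (5, 5) target r
    coupling_lags: dict[str, np.ndarray]     # group -> (5, 5) integer TR lags
    group_amplitude: dict[str, dict[str, list[float]]]  # group -> network -> per-blob
    ar_coef: float = 0.3
    noise_sd: float = 1.0
    drift_amplitude: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for g, c in self.coupling.items():
            lags = self.coupling_lags[g]
            if not np.allclose(c, c.T):
                raise ValueError(f"coupling[{g}] not symmetric")
            if np.any(lags != -lags.T):
                raise ValueError(f"coupling_lags[{g}] not antisymmetric")
            if np.any(np.abs(c) >= 1):
                raise ValueError(f"|coupling[{g}]| must be < 1")

    def to_json_dict(self) -> dict:
        return {
            "networks": list(self.network_maps.names),
            "sigma_mm": self.network_maps.sigma_mm,
            "centers_mm": {
                n: [list(map(float, c)) for c in cs]
                for n, cs in self.network_maps.centers_mm.items()
            },
            "coupling": {g: m.tolist() for g, m in self.coupling.items()},
            "coupling_lags": {g: m.tolist() for g, m in self.coupling_lags.items()},
            "group_amplitude": self.group_amplitude,
            "ar_coef": self.ar_coef,
            "noise_sd": self.noise_sd,
            "drift_amplitude": self.drift_amplitude,
            "seed": self.seed,
        }


@dataclass
class SubjectPhenotype:
    subject_id: str
    group: str
    gene: str            # "PINK1", "Park2" or "none"
    age_years: float
    sex: str             # "M" / "F"
    education_years: float
    gm_volume: float
    corsi_span: float | None = None
    moca: float | None = None
    ledd: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if (self.gene == "none") != (self.group == "HC"):
            raise ValueError("gene must be 'none' iff group is HC")
        if self.ledd is not None and self.group != "HOM":
            raise ValueError("LEDD is only recorded for the treated (HOM) group")
        if self.gm_volume <= 0:
            raise ValueError("gm_volume must be positive")


def default_coupling() -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-group 5x5 inter-network coupling (target Pearson r) and lag matrices.

    Values follow the observed group pattern: moderate couplings everywhere,
    anticorrelated DMN-to-task-positive pairs in controls, sign-flipped
    (positive) DMN couplings in heterozygotes, and a homozygote-specific
    SN-rFP increase of about +0.2 over controls.  Lags are small integers
    within the +/-12 TR analysis bound.
    """
    idx = {n: i for i, n in enumerate(NETWORK_NAMES)}

    def build(pairs: dict[tuple[str, str], tuple[float, int]]):
        c = np.zeros((5, 5))
        k = np.zeros((5, 5), dtype=int)
        for (a, b), (r, lag) in pairs.items():
            ia, ib = idx[a], idx[b]
            c[ia, ib] = c[ib, ia] = r
            k[ia, ib] = lag
            k[ib, ia] = -lag
        return c, k

    hc = {
        ("DMN", "ExN"): (-0.45, 0), ("DMN", "lFP"): (-0.39, 0),
        ("DMN", "rFP"): (-0.31, -1), ("DMN", "SN"): (-0.37, -1),
        ("lFP", "ExN"): (0.36, 0), ("lFP", "rFP"): (0.39, 0),
        ("rFP", "ExN"): (0.31, 2), ("SN", "ExN"): (0.38, -1),
        ("SN", "lFP"): (0.39, 0), ("SN", "rFP"): (0.34, 0),
    }
    het = {
        ("DMN", "ExN"): (-0.43, 0), ("DMN", "lFP"): (0.32, -2),
        ("DMN", "rFP"): (0.33, -1), ("DMN", "SN"): (0.36, -1),
        ("lFP", "ExN"): (-0.33, 0), ("lFP", "rFP"): (0.46, -1),
        ("rFP", "ExN"): (-0.36, -1), ("SN", "ExN"): (0.40, 0),
        ("SN", "lFP"): (-0.27, -2), ("SN", "rFP"): (0.30, 0),
    }
    hom = {
        ("DMN", "ExN"): (-0.36, 0), ("DMN", "lFP"): (-0.35, 1),
        ("DMN", "rFP"): (-0.48, 0), ("DMN", "SN"): (-0.39, 1),
        ("lFP", "ExN"): (0.27, 1), ("lFP", "rFP"): (0.49, 0),
        ("rFP", "ExN"): (0.33, 2), ("SN", "ExN"): (0.40, 1),
        ("SN", "lFP"): (0.32, 0), ("SN", "rFP"): (0.53, 0),
    }
    coupling, lags = {}, {}
    for g, pairs in zip(GROUPS, (hc, het, hom)):
        coupling[g], lags[g] = build(pairs)
    return coupling, lags


def default_amplitudes(blobs_per_network: int = 1) -> dict[str, dict[str, list[float]]]:
    """Per-group, per-network, per-blob amplitude multipliers.

    Encodes the intra-network deficits the group comparison should find:
    reduced DMN (posterior blob) coupling in both carrier groups, bilateral
    executive-network frontal reduction and a right fronto-parietal
    reduction in homozygotes only.
    """
    ones = [1.0] * blobs_per_network

    def amp(**over):
        d = {n: list(ones) for n in NETWORK_NAMES}
        for key, vals in over.items():
            d[key] = list(vals)
        return d

    return {
        "HC": amp(),
        "HET": amp(DMN=[0.75] + ones[1:]),
        "HOM": amp(
            DMN=[0.70] + ones[1:],
            ExN=[0.65] * blobs_per_network,
            rFP=[0.65] + ones[1:],
        ),
    }


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort (defaults = the study's)."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HC": 22, "HET": 12, "HOM": 8}
    )
    grid_dims: tuple[int, int, int] = (20, 24, 20)
    voxel_mm: float = 3.0
    T: int = 220
    tr_s: float = 2.08
    band_hz: tuple[float, float] = (0.01, 0.08)
    n_networks: int = 5
    blobs_per_network: int = 1
    blob_sigma_mm: float = 5.0
    signal_amplitude: float = 1.0
    ar_coef: float = 0.3
    noise_sd: float = 1.0
    drift_amplitude: float = 0.5
    seed: int = 0


def simulate_subject(
    phen: SubjectPhenotype,
    truth: GroundTruth,
    grid: VoxelGrid,
    T: int,
    tr_s: float,
    seed: int,
    band_hz: tuple[float, float] = (0.01, 0.08),
    signal_amplitude: float = 1.0,
    courses: np.ndarray | None = None,
) -> tuple[BoldRun, np.ndarray]:
    """Simulate one subject's BOLD run from the ground truth.

    data = sum over networks of (group- and blob-scaled map x time course)
    + voxelwise AR(1) noise + per-voxel linear drift.  The subject's RNG is
    seeded from ``subject_seed(seed, phen.subject_id)`` so cohorts are
    reproducible yet subjects independent.  Returns the run and the (T, n)
    network time courses actually injected.
    """
    if phen.group not in truth.coupling:
        raise ValueError(f"ground truth has no coupling for group {phen.group!r}")
    rng = np.random.default_rng(subject_seed(seed, phen.subject_id))
    names = truth.network_maps.names
    if courses is None:
        courses = simulate_network_timecourses(
            T, tr_s, truth.coupling[phen.group], truth.coupling_lags[phen.group],
            band_hz=band_hz, rng=rng,
        )
    data = np.zeros(grid.dims + (T,))
    amps = truth.group_amplitude[phen.group]
    for j, name in enumerate(names):
        net_map = np.zeros(grid.dims)
        for blob, a in zip(truth.network_maps.blob_maps[name], amps[name]):
            net_map += a * blob
        data += signal_amplitude * net_map[..., None] * courses[:, j]

    if truth.noise_sd > 0:
        from scipy.signal import lfilter

        innov_sd = truth.noise_sd * np.sqrt(1.0 - truth.ar_coef**2)
        w = rng.standard_normal(data.shape) * innov_sd
        data += lfilter([1.0], [1.0, -truth.ar_coef], w, axis=-1)
    if truth.drift_amplitude > 0:
        ramp = np.linspace(-1.0, 1.0, T)
        slope = rng.uniform(-1.0, 1.0, grid.dims) * truth.drift_amplitude
        data += slope[..., None] * ramp

    run = BoldRun(data=data, tr_s=tr_s, grid=grid)
    return run, courses


@dataclass
class Cohort:
    runs: list[BoldRun]
    participants: pd.DataFrame
    truth: GroundTruth
    grid: VoxelGrid
    courses: dict[str, np.ndarray]  # subject_id -> injected (T, n) courses


def _draw_phenotypes(config: CohortConfig, rng: np.random.Generator) -> list[SubjectPhenotype]:
    phens: list[SubjectPhenotype] = []
    for group in GROUPS:
        n = config.group_sizes.get(group, 0)
        demo = GROUP_DEMOGRAPHICS[group]
        m, f = demo["sex_mf"]
        # scale the tabulated sex ratio to the requested group size
        n_m = int(round(n * m / (m + f)))
        sexes = ["M"] * n_m + ["F"] * (n - n_m)
        genes = GROUP_GENES[group]
        for i in range(n):
            sid = f"sub-{group}{i + 1:02d}"
            age = rng.normal(*demo["age"])
            edu = max(5.0, rng.normal(*demo["education"]))
            gm = max(1.0, rng.normal(*GROUP_GM[group]))
            corsi = moca = ledd = None
            if group in GROUP_COGNITION:
                cg = GROUP_COGNITION[group]
                corsi = float(np.round(rng.normal(*cg["corsi"]), 1))
                moca = float(np.round(rng.normal(*cg["moca"]), 1))
            if group == "HOM":
                ledd = float(max(0.0, rng.normal(*LEDD_HOM)))
            gene = genes[i % len(genes)] if genes else "none"
            phens.append(
                SubjectPhenotype(
                    subject_id=sid, group=group, gene=gene,
                    age_years=float(np.round(age, 1)), sex=sexes[i],
                    education_years=float(np.round(edu, 1)),
                    gm_volume=float(np.round(gm, 1)),
                    corsi_span=corsi, moca=moca, ledd=ledd,
                )
            )
    return phens


def participants_frame(phens: list[SubjectPhenotype]) -> pd.DataFrame:
    rows = []
    for p in phens:
        rows.append(
            {
                "participant_id": p.subject_id, "group": p.group, "gene": p.gene,
                "age": p.age_years, "sex": p.sex, "education": p.education_years,
                "gm_volume": p.gm_volume, "corsi": p.corsi_span, "moca": p.moca,
                "ledd": p.ledd,
            }
        )
    return pd.DataFrame(rows)


def simulate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Simulate the full cohort: BOLD runs, participants table, ground truth.

    The default configuration reproduces the study conditions: 22 HC, 12 HET
    and 8 HOM subjects, 220 volumes at TR 2.08 s, five networks with
    group-specific intra-network amplitude deficits and inter-network
    couplings at non-zero lags, demographics matched to the group tables.
    """
    if config is None:
        config = CohortConfig()
    for g, n in config.group_sizes.items():
        if n < 2:
            raise ValueError(f"group {g} needs >= 2 subjects for group statistics, got {n}")
    grid = VoxelGrid.isotropic(config.grid_dims, config.voxel_mm)
    rng = np.random.default_rng(config.seed)

    maps = make_network_maps(
        grid, n_networks=config.n_networks,
        blobs_per_network=config.blobs_per_network, seed=config.seed,
        sigma_mm=config.blob_sigma_mm,
    )
    coupling, lags = default_coupling()
    coupling = {
        g: shrink_to_feasible(c, lags[g], config.T, config.tr_s, config.band_hz)
        for g, c in coupling.items()
    }
    truth = GroundTruth(
        network_maps=maps, coupling=coupling, coupling_lags=lags,
        group_amplitude=default_amplitudes(config.blobs_per_network),
        ar_coef=config.ar_coef, noise_sd=config.noise_sd,
        drift_amplitude=config.drift_amplitude, seed=config.seed,
    )
    phens = _draw_phenotypes(config, rng)
    runs: list[BoldRun] = []
    courses: dict[str, np.ndarray] = {}
    for p in phens:
        run, tc = simulate_subject(
            p, truth, grid, config.T, config.tr_s, config.seed,
            band_hz=config.band_hz, signal_amplitude=config.signal_amplitude,
        )
        runs.append(run)
        courses[p.subject_id] = tc
    return Cohort(
        runs=runs, participants=participants_frame(phens), truth=truth,
        grid=grid, courses=courses,
    )
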