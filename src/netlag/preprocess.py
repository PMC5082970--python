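"""Deterministic BOLD time-series preprocessing.

The pipeline applies, in order: discard of initial volumes (T1
equilibration), zero-phase band-pass filtering (default 0.01-0.08 Hz) and
3D Gaussian spatial smoothing (default 8 mm FWHM).  Head-motion
realignment and slice-timing correction are assumed already done (the
synthetic data need neither); the corresponding flags are accepted but are
warning no-ops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter

from .core import BoldRun

__all__ = [
    "PreprocessConfig",
    "discard_initial_volumes",
    "bandpass",
    "smooth",
    "preprocess_run",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # sigma = FWHM / 2.3548


@dataclass
class PreprocessConfig:
    """Preprocessing parameters (defaults are the study's settings)."""

    n_discard: int = 4
    band_hz: tuple[float, float] = (0.01, 0.08)
    smooth_fwhm_mm: float = 8.0
    filter_method: str = "butter"  # "butter" (zero-phase IIR) or "fft"
    realign: bool = False
    slice_timing: bool = False

    def validate(self, tr_s: float, T: int) -> None:
        low, high = self.band_hz
        nyq = 1.0 / (2.0 * tr_s)
        if not (0 <= low < high < nyq):
            raise ValueError(f"band {self.band_hz} invalid for TR={tr_s} (Nyquist {nyq:.3f})")
        if not 0 <= self.n_discard < T:
            raise ValueError(f"n_discard={self.n_discard} must be in [0, T={T})")
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smooth_fwhm_mm must be >= 0")
        if self.filter_method not in ("butter", "fft"):
            raise ValueError(f"unknown filter method {self.filter_method!r}")


def discard_initial_volumes(run: BoldRun, n: int = 4) -> BoldRun:
    """Drop the first ``n`` frames (T1-equilibration discard).

    Frames n..T-1 are preserved bit-exactly.
    """
    T = run.n_timepoints
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= T:
        raise ValueError(f"cannot discard {n} of {T} volumes (empty run)")
    if n == 0:
        return run.with_data(run.data.copy())
    return run.with_data(run.data[..., n:].copy())


def _butter_sos(band_hz: tuple[float, float], tr_s: float, order: int = 4):
    return signal.butter(order, band_hz, btype="bandpass", fs=1.0 / tr_s, output="sos")


def bandpass(
    run: BoldRun,
    band_hz: tuple[float, float] = (0.01, 0.08),
    method: str = "butter",
    order: int = 4,
) -> BoldRun:
    """Phase-insensitive band-pass filter of every voxel time series.

    ``butter`` applies a forward-backward (zero-phase) Butterworth IIR of
    the given order; ``fft`` zeroes all DFT bins outside the band (also
    exactly zero-phase).  The per-voxel mean is removed in both cases.
    """
    low, high = band_hz
    nyq = 1.0 / (2.0 * run.tr_s)
    if not (0 < low < high < nyq):
        raise ValueError(f"band {band_hz} invalid for TR={run.tr_s} (Nyquist {nyq:.3f} Hz)")
    T = run.n_timepoints
    data = run.data - run.data.mean(axis=-1, keepdims=True)
    if method == "butter":
        sos = _butter_sos(band_hz, run.tr_s, order)
        padlen = 3 * (2 * sos.shape[0] + 1)
        if T <= padlen:
            raise ValueError(
                f"run too short for order-{order} zero-phase filtering: "
                f"T={T} must exceed {padlen} samples"
            )
        out = signal.sosfiltfilt(sos, data, axis=-1)
    elif method == "fft":
        f = np.fft.rfftfreq(T, d=run.tr_s)
        X = np.fft.rfft(data, axis=-1)
        X[..., (f < low) | (f > high)] = 0.0
        out = np.fft.irfft(X, n=T, axis=-1)
    else:
        raise ValueError(f"unknown filter method {method!r}")
    out -= out.mean(axis=-1, keepdims=True)
    return run.with_data(out)


def smooth(run: BoldRun, fwhm_mm: float = 8.0) -> BoldRun:
    """Per-frame 3D Gaussian smoothing with the given FWHM in mm.

    sigma per axis = FWHM / (2 sqrt(2 ln 2)) converted to voxels through the
    grid's voxel size.  Reflect padding at the grid boundary keeps the frame
    mean approximately preserved on small grids.  ``fwhm_mm=0`` is the
    identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return run.with_data(run.data.copy())
    sigma_vox = tuple(
        fwhm_mm * FWHM_TO_SIGMA / vs for vs in run.grid.voxel_size_mm
    )
    out = gaussian_filter(run.data, sigma=sigma_vox + (0.0,), mode="reflect")
    return run.with_data(out)


def preprocess_run(run: BoldRun, config: PreprocessConfig | None = None) -> BoldRun:
    """Apply the full preprocessing chain: discard -> band-pass -> smooth."""
    if config is None:
        config = PreprocessConfig()
    config.validate(run.tr_s, run.n_timepoints)
    if config.realign or config.slice_timing:
        warnings.warn(
            "realignment/slice-timing are accepted as already done; flags are no-ops",
            stacklevel=2,
        )
    out = discard_initial_volumes(run, config.n_discard)
    out = bandpass(out, config.band_hz, method=config.filter_method)
    out = smooth(out, config.smooth_fwhm_mm)
    return out
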