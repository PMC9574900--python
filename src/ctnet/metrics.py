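"""Outcome measures: alpha-band spectral power and phase-locking value.

Neuronal activity is summarized as the power spectral density integrated
over the alpha band (8-13 Hz) and averaged over regions; functional
connectivity as the phase-locking value (PLV) between all region pairs —
the magnitude of the time-averaged unit phasor of the phase difference of
the band-filtered analytic signals — averaged over the off-diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .errors import DegenerateSignalError
from .model import SimulationResult

__all__ = [
    "SpectrumEstimate",
    "ConnectivityMatrix",
    "ALPHA_BAND",
    "downsample",
    "welch_psd",
    "alpha_power",
    "plv_matrix",
    "mean_plv",
    "percent_change",
]

ALPHA_BAND = (8.0, 13.0)
METRICS_FS = 250.0  # analysis rate after anti-aliased decimation


@dataclass
class SpectrumEstimate:
    """Per-region power spectral density on a common frequency grid.

    ``psd`` has shape (n_regions, n_freqs) in units^2/Hz; ``window_s`` and
    ``overlap`` record the Welch settings (window_s=inf marks an analytic
    spectrum).
    """

    freqs: np.ndarray
    psd: np.ndarray
    window_s: float
    overlap: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.atleast_2d(np.asarray(self.psd, dtype=float))
        if self.freqs.ndim != 1 or self.psd.shape[1] != self.freqs.size:
            raise ValueError("psd must be (n_regions, n_freqs)")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.psd < 0) or not np.all(np.isfinite(self.psd)):
            raise ValueError("psd must be finite and nonnegative")

    @property
    def n_regions(self) -> int:
        return self.psd.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (region, freq, psd)."""
        n, f = self.psd.shape
        return pd.DataFrame(
            {
                "region": np.repeat(np.arange(n), f),
                "freq": np.tile(self.freqs, n),
                "psd": self.psd.ravel(),
            }
        )


@dataclass
class ConnectivityMatrix:
    """Pairwise phase-locking values within an analysis band."""

    plv: np.ndarray
    band: tuple[float, float] = field(default=ALPHA_BAND)

    def __post_init__(self) -> None:
        p = np.asarray(self.plv, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("plv must be square")
        if not np.allclose(p, p.T, atol=1e-12):
            raise ValueError("plv must be symmetric")
        if not np.allclose(np.diag(p), 1.0, atol=1e-12):
            raise ValueError("plv diagonal must be 1")
        if np.any(p < 0) or np.any(p > 1 + 1e-12):
            raise ValueError("plv entries must lie in [0, 1]")
        self.plv = np.clip(p, 0.0, 1.0)

    def save(self, path: str | Path, delimiter: str = "\t") -> None:
        np.savetxt(path, self.plv, delimiter=delimiter)


def downsample(result: SimulationResult, target_fs: float = METRICS_FS) -> SimulationResult:
    """Anti-aliased integer-factor decimation of a simulation result."""
    factor = int(round(result.fs / target_fs))
    if factor <= 1:
        return result
    if abs(result.fs / factor - target_fs) > 1e-9:
        raise ValueError(
            f"target_fs {target_fs} is not an integer divisor of fs {result.fs}"
        )
    ser = signal.decimate(result.series, factor, axis=1, zero_phase=True)
    return SimulationResult(
        series=ser, fs=result.fs / factor, seed=result.seed,
        params_hash=result.params_hash,
    )


def welch_psd(
    result: SimulationResult, window_s: float = 4.0, overlap: float = 0.5
) -> SpectrumEstimate:
    """Welch PSD per region (Hann window, mean-detrended segments)."""
    nper = int(round(window_s * result.fs))
    if result.n_samples < nper:
        raise ValueError(
            f"series of {result.n_samples} samples is shorter than one "
            f"{window_s} s window"
        )
    freqs, psd = signal.welch(
        result.series,
        fs=result.fs,
        window="hann",
        nperseg=nper,
        noverlap=int(round(overlap * nper)),
        detrend="constant",
        axis=1,
    )
    return SpectrumEstimate(freqs=freqs, psd=psd, window_s=window_s, overlap=overlap)


def band_power(spec: SpectrumEstimate, band=ALPHA_BAND) -> np.ndarray:
    """Trapezoidal band-integrated power per region (units^2)."""
    lo, hi = band
    if lo < spec.freqs[0] or hi > spec.freqs[-1]:
        raise ValueError(f"band {band} outside frequency range")
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if mask.sum() < 2:
        raise ValueError(f"band {band} contains fewer than 2 grid points")
    return np.trapezoid(spec.psd[:, mask], spec.freqs[mask], axis=1)


def alpha_power(spec: SpectrumEstimate, band=ALPHA_BAND) -> float:
    """Mean over regions of the band-integrated PSD (the activity outcome)."""
    return float(band_power(spec, band).mean())


def _band_phases(result: SimulationResult, band, edge_trim_s, filter_order):
    lo, hi = band
    nyq = result.fs / 2.0
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist {nyq} Hz")
    std = result.series.std(axis=1)
    scale = float(np.abs(result.series).max())
    if np.any(std <= 1e-12 * max(scale, 1.0)):
        bad = int(np.argmin(std))
        raise DegenerateSignalError(
            f"region {bad} series is (near-)constant; analytic phase undefined"
        )
    sos = signal.butter(filter_order, [lo, hi], btype="bandpass", fs=result.fs,
                        output="sos")
    filt = signal.sosfiltfilt(sos, result.series, axis=1)
    phases = np.angle(signal.hilbert(filt, axis=1))
    trim = int(round(edge_trim_s * result.fs))
    if phases.shape[1] - 2 * trim < 5 * result.fs / lo:
        raise ValueError(
            "series too short: need at least 5 cycles at the band low edge "
            "after edge trimming"
        )
    return phases[:, trim : phases.shape[1] - trim]


def plv_matrix(
    result: SimulationResult,
    band=ALPHA_BAND,
    edge_trim_s: float = 1.0,
    filter_order: int = 4,
) -> ConnectivityMatrix:
    """Pairwise PLV of the band-filtered analytic phases.

    The signals are zero-phase band-passed (forward-backward 4th-order
    Butterworth), phases extracted from the analytic signal, ``edge_trim_s``
    seconds discarded at both ends, and
    ``PLV(x, y) = |mean_t exp(i(phase_x - phase_y))|``.
    """
    if result.n_regions < 2:
        raise ValueError("PLV requires at least 2 regions")
    phases = _band_phases(result, band, edge_trim_s, filter_order)
    z = np.exp(1j * phases)
    plv = np.abs(z @ z.conj().T) / phases.shape[1]
    np.fill_diagonal(plv, 1.0)
    plv = np.clip(0.5 * (plv + plv.T), 0.0, 1.0)
    return ConnectivityMatrix(plv=plv, band=tuple(band))


def mean_plv(mat: ConnectivityMatrix) -> float:
    """Mean of the strictly off-diagonal upper triangle, in [0, 1]."""
    n = mat.plv.shape[0]
    if n < 2:
        raise ValueError("mean PLV requires at least a 2x2 matrix")
    iu = np.triu_indices(n, k=1)
    return float(mat.plv[iu].mean())


def percent_change(value: float, baseline: float) -> float:
    """Percent change of ``value`` relative to ``baseline``."""
    if baseline == 0:
        raise ZeroDivisionError("percent change undefined for zero baseline")
    return 100.0 * (value - baseline) / baseline
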