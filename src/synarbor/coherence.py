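"""Multitaper spectra and complex coherence of optical activity traces.

Each trial provides per-cell fluorescence time series and a designated
reference cell (the postsynaptic hub neuron).  The analysis frequency ``f*``
is the dominant peak of the reference cell's multitaper power spectrum within
a behavior-specific search band, and every cell's *complex* coherence with the
reference is evaluated at the frequency bin containing ``f*``:

    z = Σ_k conj(X_k) · Y_k / sqrt(Σ_k |X_k|² · Σ_k |Y_k|²)

where ``X_k`` and ``Y_k`` are the k-th tapered Fourier transforms of the cell
trace and the reference trace at that bin.  By this convention |z| ≤ 1 and a
*positive* phase means the cell's trace lags the reference.  The 95% interval
on |z| comes from a leave-one-taper-out jackknife.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal.windows import dpss

__all__ = [
    "SpectralOptions",
    "TrialRecording",
    "CoherenceRecord",
    "BEHAVIOR_BANDS",
    "default_options",
    "detrend",
    "multitaper_psd",
    "dominant_frequency",
    "coherence_at",
    "coherence_map",
]

#: Default dominant-frequency search bands in Hz per fictive behavior.  Swim
#: rhythms run near 2 Hz, crawling an order of magnitude slower, local bends
#: in between; the bands bracket those rhythms generously.
BEHAVIOR_BANDS: dict[str, tuple[float, float]] = {
    "swim": (0.5, 3.0),
    "crawl": (0.02, 0.5),
    "local_bend": (0.05, 2.0),
}


@dataclass(frozen=True)
class SpectralOptions:
    """Multitaper settings: time-bandwidth product, taper count, detrending, band."""

    time_bandwidth: float = 4.0
    n_tapers: int = 7
    detrend_order: int = 2
    search_band: tuple[float, float] = (0.5, 3.0)

    def __post_init__(self) -> None:
        if self.time_bandwidth <= 1:
            raise ValueError("time_bandwidth must exceed 1")
        if not (1 <= self.n_tapers <= 2 * self.time_bandwidth - 1):
            raise ValueError("need 1 <= n_tapers <= 2*time_bandwidth - 1")
        if self.detrend_order < 0:
            raise ValueError("detrend_order must be >= 0")
        lo, hi = self.search_band
        if not (0 <= lo < hi):
            raise ValueError("search band must satisfy 0 <= f_lo < f_hi")


@dataclass
class TrialRecording:
    """One behavioral trial: per-cell traces sampled at a common interval."""

    trial_id: str
    behavior: str
    dt: float  # seconds
    traces: pd.DataFrame  # rows = samples, columns = cell ids
    reference_cell: str

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.reference_cell not in self.traces.columns:
            raise ValueError(
                f"reference cell {self.reference_cell!r} not among traces"
            )

    @property
    def cells(self) -> list[str]:
        return list(self.traces.columns)

    @property
    def duration(self) -> float:
        return len(self.traces) * self.dt


@dataclass(frozen=True)
class CoherenceRecord:
    """Complex coherence of one cell with the reference at frequency ``f_star``."""

    cell_id: str
    trial_id: str
    z: complex
    ci_magnitude: float  # half-width of the 95% interval on |z|
    f_star: float  # Hz

    @property
    def magnitude(self) -> float:
        return abs(self.z)

    @property
    def phase(self) -> float:
        return cmath.phase(self.z)


def default_options(behavior: str, **overrides) -> SpectralOptions:
    """Spectral options with the default search band for a behavior."""
    if behavior not in BEHAVIOR_BANDS:
        raise ValueError(f"unknown behavior {behavior!r}")
    kwargs = {"search_band": BEHAVIOR_BANDS[behavior]}
    kwargs.update(overrides)
    return SpectralOptions(**kwargs)


def detrend(trace: np.ndarray, order: int = 2) -> np.ndarray:
    """Remove a least-squares polynomial trend of the given order.

    Used to strip photobleaching trends and slow drifts before spectral
    analysis; order 0 removes the mean.
    """
    trace = np.asarray(trace, dtype=float)
    if order < 0:
        raise ValueError("order must be >= 0")
    if trace.size <= order + 1:
        raise ValueError(
            f"series of length {trace.size} too short for order-{order} detrending"
        )
    x = np.linspace(-1.0, 1.0, trace.size)
    coeffs = np.polynomial.polynomial.polyfit(x, trace, order)
    return trace - np.polynomial.polynomial.polyval(x, coeffs)


def _tapered_ffts(trace: np.ndarray, opts: SpectralOptions) -> np.ndarray:
    """Eigen-FFTs, shape (n_tapers, n_freq), of the detrended trace."""
    clean = detrend(trace, opts.detrend_order)
    tapers = dpss(clean.size, opts.time_bandwidth, Kmax=opts.n_tapers)
    return np.fft.rfft(tapers * clean[None, :], axis=1)


def multitaper_psd(
    trace: np.ndarray, dt: float, opts: SpectralOptions | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper power spectral density estimate.

    Returns (frequencies in Hz, power).  Power is the average over DPSS
    eigenspectra, scaled to density units (signal² per Hz).
    """
    opts = opts or SpectralOptions()
    trace = np.asarray(trace, dtype=float)
    eigen = _tapered_ffts(trace, opts)
    freqs = np.fft.rfftfreq(trace.size, d=dt)
    power = np.mean(np.abs(eigen) ** 2, axis=0) * dt
    return freqs, power


def dominant_frequency(
    reference: np.ndarray, dt: float, opts: SpectralOptions | None = None
) -> float:
    """Frequency (Hz) of the largest multitaper power within the search band."""
    opts = opts or SpectralOptions()
    freqs, power = multitaper_psd(reference, dt, opts)
    nyquist = 0.5 / dt
    lo, hi = opts.search_band
    if hi >= nyquist:
        raise ValueError(
            f"search band upper edge {hi} Hz is at or above Nyquist ({nyquist} Hz)"
        )
    in_band = (freqs >= lo) & (freqs <= hi)
    if not in_band.any():
        raise ValueError("search band contains no frequency bins")
    band_power = np.where(in_band, power, -np.inf)
    return float(freqs[int(np.argmax(band_power))])


def coherence_at(
    trace: np.ndarray,
    reference: np.ndarray,
    dt: float,
    f_star: float,
    opts: SpectralOptions | None = None,
    cell_id: str = "",
    trial_id: str = "",
) -> CoherenceRecord:
    """Complex coherence of a trace with the reference at frequency ``f_star``.

    The cross- and auto-spectra are averaged over DPSS tapers at the frequency
    bin containing ``f_star``.  Positive phase means the trace lags the
    reference.
    """
    opts = opts or SpectralOptions()
    trace = np.asarray(trace, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if trace.shape != reference.shape:
        raise ValueError("trace and reference must have equal length")
    if not (0 <= f_star <= 0.5 / dt):
        raise ValueError(f"f_star {f_star} Hz outside [0, Nyquist]")
    x = _tapered_ffts(trace, opts)
    y = _tapered_ffts(reference, opts)
    freqs = np.fft.rfftfreq(trace.size, d=dt)
    bin_idx = int(np.argmin(np.abs(freqs - f_star)))
    xk = x[:, bin_idx]
    yk = y[:, bin_idx]
    sxx = np.sum(np.abs(xk) ** 2)
    syy = np.sum(np.abs(yk) ** 2)
    if sxx == 0 or syy == 0:
        raise ValueError(
            f"degenerate signal: zero power at f* = {freqs[bin_idx]:.4g} Hz"
        )
    z = complex(np.sum(np.conj(xk) * yk) / math.sqrt(sxx * syy))
    ci = _jackknife_ci_magnitude(xk, yk)
    return CoherenceRecord(
        cell_id=cell_id, trial_id=trial_id, z=z, ci_magnitude=ci, f_star=float(freqs[bin_idx])
    )


def _jackknife_ci_magnitude(xk: np.ndarray, yk: np.ndarray) -> float:
    """95% half-width on |z| from leave-one-taper-out jackknife."""
    k = xk.size
    if k < 2:
        return math.nan
    estimates = np.empty(k)
    for drop in range(k):
        keep = np.arange(k) != drop
        sxy = np.sum(np.conj(xk[keep]) * yk[keep])
        sxx = np.sum(np.abs(xk[keep]) ** 2)
        syy = np.sum(np.abs(yk[keep]) ** 2)
        estimates[drop] = abs(sxy) / math.sqrt(sxx * syy) if sxx * syy > 0 else 0.0
    se = math.sqrt((k - 1) / k * np.sum((estimates - estimates.mean()) ** 2))
    return 1.96 * se


def coherence_map(
    trial: TrialRecording, opts: SpectralOptions | None = None
) -> list[CoherenceRecord]:
    """Coherence of every cell with the reference at the reference's f*.

    The analysis frequency is the dominant multitaper peak of the reference
    cell within the options' search band (defaulting to the behavior's band);
    every cell, including the reference itself (|z| = 1), is evaluated there.
    """
    if opts is None:
        opts = default_options(trial.behavior)
    reference = trial.traces[trial.reference_cell].to_numpy(dtype=float)
    f_star = dominant_frequency(reference, trial.dt, opts)
    records = []
    for cell in trial.cells:
        records.append(
            coherence_at(
                trial.traces[cell].to_numpy(dtype=float),
                reference,
                trial.dt,
                f_star,
                opts,
                cell_id=cell,
                trial_id=trial.trial_id,
            )
        )
    return records


def coherence_frame(records: list[CoherenceRecord]) -> pd.DataFrame:
    """Tabulate coherence records (one row per cell and trial)."""
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "trial_id": [r.trial_id for r in records],
            "re_z": [r.z.real for r in records],
            "im_z": [r.z.imag for r in records],
            "magnitude": [r.magnitude for r in records],
            "phase": [r.phase for r in records],
            "ci": [r.ci_magnitude for r in records],
            "f_star": [r.f_star for r in records],
        }
    )
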