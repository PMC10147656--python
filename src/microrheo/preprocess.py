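"""Trajectory cleaning: drift removal and spectral line-noise filtering.

Raw bead videos carry slow stage/instrument drift and narrow single-frequency
noise lines (mains harmonics, fans, pumps). Both corrupt the long-lag MSD and
the confined-position variance, so they are removed before any statistics:
drift by subtracting a fitted trend, lines by notching isolated Fourier peaks
above an absolute amplitude threshold back to the local background level.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import InvalidArgumentError, Trajectory

__all__ = ["FilterReport", "detrend", "filter_noise_peaks"]

#: Default absolute amplitude threshold for line removal (metres).
DEFAULT_AMPLITUDE_THRESHOLD = 2e-10


@dataclass
class FilterReport:
    """What a cleaning step removed, for provenance."""

    detrend_model: str | None = None
    detrend_coefficients: dict[str, list[float]] = field(default_factory=dict)
    removed_peak_frequencies: dict[str, list[float]] = field(default_factory=dict)
    removed_peak_amplitudes: dict[str, list[float]] = field(default_factory=dict)


def detrend(traj: Trajectory, model: str = "linear", order: int = 2,
            window: int | None = None) -> tuple[Trajectory, FilterReport]:
    """Remove long-term drift; returns the residual trajectory (mean ≈ 0).

    ``model`` is ``"linear"`` (default — removes stage drift without biasing
    the plateau variance), ``"polynomial"`` of the given ``order``, or
    ``"moving_mean"`` with an odd ``window`` length in frames.
    """
    if traj.n_samples < 10:
        raise InvalidArgumentError("detrend needs at least 10 samples")
    report = FilterReport(detrend_model=model if model != "polynomial"
                          else f"polynomial({order})")
    out = np.empty_like(traj.positions)
    t = traj.t - traj.t[0]
    for j, name in enumerate(traj.axes):
        x = traj.positions[:, j]
        finite = np.isfinite(x)
        if model in ("linear", "polynomial"):
            deg = 1 if model == "linear" else order
            coeffs = np.polyfit(t[finite], x[finite], deg)
            out[:, j] = x - np.polyval(coeffs, t)
            report.detrend_coefficients[name] = coeffs.tolist()
        elif model == "moving_mean":
            if window is None or window < 2:
                raise InvalidArgumentError("moving_mean requires a window >= 2")
            if window >= traj.n_samples:
                raise InvalidArgumentError(
                    f"window {window} must be shorter than the series "
                    f"({traj.n_samples} samples)")
            kernel = np.ones(window) / window
            filled = np.where(finite, x, np.nanmean(x))
            pad = window // 2
            padded = np.pad(filled, pad, mode="edge")
            trend = np.convolve(padded, kernel, mode="same")[pad:pad + len(x)]
            out[:, j] = x - trend
            report.detrend_coefficients[name] = [float(window)]
        else:
            raise InvalidArgumentError(f"unknown detrend model {model!r}")
        out[finite, j] -= np.mean(out[finite, j])
    cleaned = traj.with_positions(out, detrend=report.detrend_model)
    return cleaned, report


def filter_noise_peaks(traj: Trajectory,
                       amplitude_threshold: float = DEFAULT_AMPLITUDE_THRESHOLD,
                       neighbourhood_bins: int = 50,
                       max_peak_width_bins: int = 3,
                       excess_factor: float = 5.0,
                       ) -> tuple[Trajectory, FilterReport]:
    """Notch isolated single-frequency noise lines out of each axis.

    A Fourier bin is a noise line when its single-sided amplitude
    ``2|X_k|/N`` is at least ``amplitude_threshold`` (metres) *and* it
    exceeds ``excess_factor`` times the median amplitude of its
    ``neighbourhood_bins``-bin surroundings; contiguous flagged bins wider
    than ``max_peak_width_bins`` are left untouched (they are broadband
    signal, not a line). Flagged bins are scaled down to the local median
    background magnitude — not zeroed, which would delete legitimate
    Brownian power — keeping their phase. The filter is idempotent and
    reports every removal.
    """
    if traj.dropped_frames is not None and len(traj.dropped_frames):
        raise InvalidArgumentError(
            "spectral filtering requires a gap-free trajectory")
    report = FilterReport()
    n = traj.n_samples
    freqs = np.fft.rfftfreq(n, d=traj.dt)
    out = traj.positions.copy()
    half = neighbourhood_bins // 2
    for j, name in enumerate(traj.axes):
        x = traj.positions[:, j]
        mean = x.mean()
        X = np.fft.rfft(x - mean)
        mag = np.abs(X)
        amp = 2.0 * mag / n
        # local median background magnitude around each bin (excluding DC)
        background = np.empty_like(mag)
        for k in range(len(mag)):
            lo = max(1, k - half)
            hi = min(len(mag), k + half + 1)
            background[k] = np.median(mag[lo:hi])
        candidate = (amp >= amplitude_threshold) & (mag >= excess_factor * background)
        candidate[0] = False  # DC is drift, handled by detrend
        removed_f: list[float] = []
        removed_a: list[float] = []
        # group contiguous candidate bins; only narrow groups are lines
        k = 1
        while k < len(mag):
            if not candidate[k]:
                k += 1
                continue
            k2 = k
            while k2 + 1 < len(mag) and candidate[k2 + 1]:
                k2 += 1
            width = k2 - k + 1
            if width <= max_peak_width_bins:
                for b in range(k, k2 + 1):
                    removed_f.append(float(freqs[b]))
                    removed_a.append(float(amp[b]))
                    X[b] *= background[b] / mag[b] if mag[b] > 0 else 0.0
            k = k2 + 1
        out[:, j] = np.fft.irfft(X, n=n) + mean
        report.removed_peak_frequencies[name] = removed_f
        report.removed_peak_amplitudes[name] = removed_a
    cleaned = traj.with_positions(out, spectral_filter={
        "amplitude_threshold": amplitude_threshold,
        "removed": report.removed_peak_frequencies})
    return cleaned, report
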