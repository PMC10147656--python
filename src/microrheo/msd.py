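"""Time-domain trajectory statistics: MSD, NPAF, variance, and MSD smoothing.

The mean squared displacement (MSD) is estimated as the time average over
all overlapping pairs at each lag. Directional MSDs resample a 3D
trajectory along an arbitrary unit vector before the same 1D estimate.
The normalised position autocorrelation function (NPAF) of a trapped bead,
⟨x(t)x(t+τ)⟩/⟨x²⟩, decays as exp(−τ/τ_c) in a Newtonian medium and is the
basis of the dimensionless-lag viscometry implemented in
:mod:`microrheo.rheology`.

Finite records estimate the MSD poorly at the shortest and longest lags; a
stretched bi-exponential,

    MSD(τ) = A1·exp(−(τ/τ1)^B1) + A2·exp(−(τ/τ2)^B2),

is fitted as a smoothing model (with unconstrained amplitude signs — a
negative amplitude yields a rising, saturating MSD) before conversion to
material functions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .core import InvalidArgumentError, MicrorheoError, ProbeContext, Trajectory

__all__ = [
    "MSDCurve", "BiExpFit", "NPAFCurve",
    "compute_msd", "directional_msd", "fit_stretched_biexponential",
    "compute_npaf", "plateau_variance", "direction_vector",
]


@dataclass
class MSDCurve:
    """Lag-domain MSD with pair counts and the dimensionality of the sum."""

    lags: np.ndarray          # seconds, strictly increasing, > 0
    values: np.ndarray        # m^2
    n_pairs: np.ndarray
    dimension: int
    context: ProbeContext
    frame_rate: float

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(np.diff(self.lags) <= 0) or np.any(self.lags <= 0):
            raise InvalidArgumentError("lags must be strictly increasing and > 0")
        if np.any(self.values < 0) or np.any(self.n_pairs <= 0):
            raise InvalidArgumentError("MSD values must be >= 0 with n_pairs > 0")


@dataclass
class NPAFCurve:
    """Normalised position autocorrelation vs lag (and optionally vs τ*)."""

    lags: np.ndarray
    values: np.ndarray
    tau_star: np.ndarray | None = None
    axis: str = "x"

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags[0] != 0.0 or self.values[0] != 1.0:
            raise InvalidArgumentError("NPAF must start at (0, 1)")


def _lag_grid(n_max: int, scheme: str, n_per_decade: int) -> np.ndarray:
    if scheme == "all":
        return np.arange(1, n_max + 1)
    if scheme == "log":
        n_points = max(2, int(np.ceil(np.log10(n_max) * n_per_decade)))
        grid = np.unique(np.round(np.geomspace(1, n_max, n_points)).astype(int))
        return grid
    raise InvalidArgumentError(f"unknown lag scheme {scheme!r}")


def compute_msd(traj: Trajectory, axes=None, lag_scheme: str = "log",
                n_per_decade: int = 16, max_lag_fraction: float = 0.1) -> MSDCurve:
    """Time-averaged MSD over all overlapping pairs at each lag.

    ``axes`` selects which axes are summed (default: all axes present), so
    the returned dimension d equals ``len(axes)``. The default lag grid is
    log-spaced at 16 points per decade from one frame up to 10% of the
    record, which covers the broadband while staying O(N·n_lags).
    NaN rows (dropped frames) reduce the pair count at affected lags.
    """
    if traj.n_samples < 100:
        raise InvalidArgumentError("compute_msd needs at least 100 samples")
    names = tuple(traj.axes) if axes is None else tuple(axes)
    cols = np.column_stack([traj.axis(a) for a in names])
    n = traj.n_samples
    lags = _lag_grid(max(1, int(max_lag_fraction * n)), lag_scheme, n_per_decade)
    values = np.empty(len(lags))
    counts = np.empty(len(lags), dtype=int)
    for i, ell in enumerate(lags):
        d = cols[ell:] - cols[:-ell]
        sq = np.sum(d * d, axis=1)
        valid = np.isfinite(sq)
        counts[i] = int(valid.sum())
        values[i] = np.mean(sq[valid]) if counts[i] else np.nan
    keep = counts > 0
    return MSDCurve(lags=lags[keep] * traj.dt, values=values[keep],
                    n_pairs=counts[keep], dimension=len(names),
                    context=traj.context, frame_rate=traj.frame_rate)


def direction_vector(theta: float, phi: float) -> np.ndarray:
    """Unit vector from polar angle θ (from +z) and azimuth φ (from +x)."""
    u = np.array([np.sin(theta) * np.cos(phi),
                  np.sin(theta) * np.sin(phi),
                  np.cos(theta)])
    u[np.abs(u) < 1e-12] = 0.0  # snap to coordinate axes: exact projections
    n = np.linalg.norm(u)
    if n == 0:
        raise InvalidArgumentError("direction vector has zero norm")
    return u / n


def directional_msd(traj: Trajectory, theta: float, phi: float,
                    max_lag_fraction: float = 0.1, lag_scheme: str = "log",
                    n_per_decade: int = 16) -> MSDCurve:
    """1D MSD of the trajectory projected on the unit vector u(θ, φ)."""
    if traj.n_axes != 3:
        raise InvalidArgumentError("directional MSD requires a 3-axis trajectory")
    u = direction_vector(theta, phi)
    proj = traj.positions @ u
    sub = Trajectory(t=traj.t, positions=proj[:, None], frame_rate=traj.frame_rate,
                     context=traj.context, axes=("x",),
                     provenance={**traj.provenance, "projection": (theta, phi)},
                     dropped_frames=traj.dropped_frames)
    curve = compute_msd(sub, lag_scheme=lag_scheme, n_per_decade=n_per_decade,
                        max_lag_fraction=max_lag_fraction)
    return curve


class FitError(MicrorheoError):
    """Nonlinear fit failed; carries the best iterate for diagnostics."""

    def __init__(self, message: str, best_params=None):
        super().__init__(message)
        self.best_params = best_params


@dataclass
class BiExpFit:
    """Stretched bi-exponential MSD smoothing fit; callable as a function of τ."""

    A1: float
    A2: float
    B1: float
    B2: float
    tau1: float
    tau2: float
    residual: float            # rms relative residual over fitted lags
    lags: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __call__(self, tau) -> np.ndarray:
        return _biexp(np.asarray(tau, dtype=float), self.A1, self.A2,
                      self.B1, self.B2, self.tau1, self.tau2)


def _biexp(t, A1, A2, B1, B2, tau1, tau2):
    with np.errstate(over="ignore"):
        return (A1 * np.exp(-((t / tau1) ** B1))
                + A2 * np.exp(-((t / tau2) ** B2)))


def fit_stretched_biexponential(msd: MSDCurve, init_strategy: str = "heuristic",
                                n_starts: int = 8, seed: int = 0) -> BiExpFit:
    """Fit the stretched bi-exponential smoothing model to an MSD curve.

    Nonlinear least squares on the (log-spaced) lag grid, weighted by the
    pair counts (σ_i ∝ value scale / sqrt(n_pairs_i)) so that the
    well-averaged short lags do not dominate purely by their number.
    Amplitude signs are unconstrained: a rising, saturating MSD is captured
    by a negative A1 against a large-τ2 plateau term. ``init_strategy`` is
    ``"heuristic"`` (data-driven start, then perturbed restarts) or
    ``"random"`` (log-uniform restarts only).
    """
    if len(msd.lags) < 10:
        raise InvalidArgumentError("need at least 10 lag points to fit")
    t, y, npairs = msd.lags, msd.values, msd.n_pairs
    scale = float(np.max(np.abs(y)))
    if scale == 0:
        raise InvalidArgumentError("MSD is identically zero; nothing to fit")
    sigma = scale / np.sqrt(npairs / npairs.max())
    rng = np.random.default_rng(seed)

    plateau = float(np.mean(y[-3:]))
    rise = plateau - float(y[0])
    i_half = int(np.argmin(np.abs(y - (y[0] + 0.5 * rise))))
    tau_half = float(t[i_half]) if t[i_half] > 0 else float(np.sqrt(t[0] * t[-1]))
    p0_heuristic = [-rise, plateau, 1.0, 1.0, tau_half, 1e3 * t[-1]]

    bounds = ([-np.inf, -np.inf, 0.05, 0.05, t[0] / 100, t[0] / 100],
              [np.inf, np.inf, 4.0, 4.0, 1e12 * t[-1], 1e12 * t[-1]])

    starts = []
    if init_strategy == "heuristic":
        starts.append(p0_heuristic)
    for _ in range(n_starts):
        f = rng.uniform(0.3, 3.0, size=6)
        starts.append([p0_heuristic[0] * f[0], p0_heuristic[1] * f[1],
                       min(4.0, max(0.1, f[2])), min(4.0, max(0.1, f[3])),
                       tau_half * f[4] ** 3, 1e3 * t[-1] * f[5] ** 3])

    best = None
    best_cost = np.inf
    for p0 in starts:
        try:
            popt, _ = curve_fit(_biexp, t, y, p0=p0, sigma=sigma,
                                bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        resid = (_biexp(t, *popt) - y) / sigma
        cost = float(np.sum(resid ** 2))
        if cost < best_cost:
            best_cost, best = cost, popt
    if best is None:
        raise FitError("stretched bi-exponential fit did not converge",
                       best_params=p0_heuristic)
    rel = float(np.sqrt(np.mean(((_biexp(t, *best) - y) / scale) ** 2)))
    return BiExpFit(A1=best[0], A2=best[1], B1=best[2], B2=best[3],
                    tau1=best[4], tau2=best[5], residual=rel, lags=t)


def compute_npaf(traj: Trajectory, axis: str = "x", max_lag: int | None = None,
                 method: str = "direct", lag_scheme: str = "all",
                 n_per_decade: int = 32) -> NPAFCurve:
    """Normalised position autocorrelation ⟨x(t)x(t+τ)⟩/⟨x²⟩; exactly 1 at τ=0.

    The input should be detrended (the mean is subtracted here, but slow
    drift must already be removed). ``method="direct"`` averages products in
    the time domain at each lag ("unbiased": divides by the pair count);
    ``method="fft"`` computes all lags via the Wiener–Khinchin route with
    the same per-lag normalisation, and is preferred for long records.
    """
    x = traj.axis(axis)
    if not np.all(np.isfinite(x)):
        if method == "fft":
            raise InvalidArgumentError("fft NPAF requires a gap-free trajectory")
        finite = np.isfinite(x)
    else:
        finite = None
    xm = x - (np.nanmean(x))
    c0 = float(np.nanmean(xm * xm))
    if c0 == 0:
        raise InvalidArgumentError("zero-variance axis: NPAF undefined")
    n = traj.n_samples
    if max_lag is None:
        max_lag = n // 4
    max_lag = min(max_lag, n - 1)
    if method == "fft":
        m = int(2 ** np.ceil(np.log2(2 * n)))
        X = np.fft.rfft(xm, m)
        acov_sum = np.fft.irfft(X * np.conj(X), m)[:max_lag + 1]
        counts = n - np.arange(max_lag + 1)
        acf = (acov_sum / counts) / c0
        lags_i = np.arange(max_lag + 1)
    elif method == "direct":
        lags_i = np.concatenate([[0], _lag_grid(max_lag, lag_scheme, n_per_decade)])
        acf = np.empty(len(lags_i))
        acf[0] = 1.0
        for i, ell in enumerate(lags_i[1:], start=1):
            prod = xm[ell:] * xm[:-ell]
            if finite is not None:
                acf[i] = np.nanmean(prod) / c0
            else:
                acf[i] = np.mean(prod) / c0
    else:
        raise InvalidArgumentError(f"unknown NPAF method {method!r}")
    acf[0] = 1.0
    return NPAFCurve(lags=lags_i * traj.dt, values=acf, axis=axis)


def plateau_variance(traj: Trajectory, axes=None) -> float:
    """Sum over the requested axes of the stationary position variance (m²).

    For an overdamped bead in a harmonic potential this is the equipartition
    variance k_B·T/κ per axis; for a bead in a gel with elastic plateau G0
    it is k_B·T/(6π·a·G0) per axis. Requires a detrended trajectory.
    """
    names = tuple(traj.axes) if axes is None else tuple(axes)
    if traj.n_samples < 100:
        warnings.warn("variance from fewer than 100 samples is noisy", stacklevel=2)
    total = 0.0
    for a in names:
        x = traj.axis(a)
        x = x[np.isfinite(x)]
        total += float(np.var(x))
    return total
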