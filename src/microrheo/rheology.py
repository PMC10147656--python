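"""Motion statistics → material properties.

The generalised Stokes–Einstein route converts an MSD into the creep
compliance J(t) and then, through the Fourier transform of its
piecewise-linear interpolant, into the complex shear modulus
G*(ω) = 1/(iω·Ĵ(ω)). A gel's low-frequency elastic plateau G₀′ follows
directly from the bead's confined-position variance, and in Newtonian
media the trap-normalised NPAF lag axis reads out relative viscosity at
the e⁻¹ intercept. Near-wall hydrodynamics (Faxén parallel, Brenner
perpendicular) provide the reference predictions for apparent-viscosity
anisotropy next to a surface.

Dimension conventions
---------------------
The literal compliance prefactor k_B·T/(π·a) corresponds to a 3D MSD.
Measured MSDs are often 1D or 2D, so each converter takes a ``convention``
argument: ``"paper"`` applies the literal prefactor to whatever MSD it is
given (faithful to common practice in the field), while
``"dimension_corrected"`` rescales by the actual dimensionality d
(J = 3πa/(d·k_BT)·MSD_d; G0 = d·k_BT/(6πa·⟨r²⟩_d)). The convention used is
recorded in every output.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .core import InvalidArgumentError, MicrorheoError, ProbeContext, Trajectory
from .msd import MSDCurve, NPAFCurve, compute_msd, compute_npaf, direction_vector

__all__ = [
    "ComplianceCurve", "ComplexModulusCurve", "PlateauModulus",
    "DirectionalViscosity", "msd_to_compliance", "compliance_to_modulus",
    "plateau_modulus", "delta_plateau", "trap_stiffness_equipartition",
    "relative_viscosity_npaf", "directional_viscosity", "faxen_prediction",
    "attach_tau_star",
]

_CONVENTIONS = ("paper", "dimension_corrected")


@dataclass
class ComplianceCurve:
    t: np.ndarray                 # s, strictly increasing
    J: np.ndarray                 # 1/Pa
    terminal_slope: float         # 1/(Pa s): dJ/dt beyond t_max (0 for gels)
    context: ProbeContext
    dimension: int
    convention: str = "paper"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise InvalidArgumentError("compliance times must be strictly increasing")
        if np.any(self.J < 0):
            raise InvalidArgumentError("compliance must be non-negative")


@dataclass
class ComplexModulusCurve:
    omega: np.ndarray             # rad/s, strictly increasing
    G_prime: np.ndarray           # Pa
    G_doubleprime: np.ndarray     # Pa
    convention: str = "paper"


@dataclass
class PlateauModulus:
    G0_prime: float
    variance_used: float
    dimension: int
    convention: str


@dataclass
class DirectionalViscosity:
    theta: float
    phi: float
    D: float                      # m^2/s
    eta: float                    # Pa s
    eta_relative: float
    fit_window: tuple[float, float]


def msd_to_compliance(msd: MSDCurve, convention: str = "paper",
                      terminal_slope: float | str = "auto") -> ComplianceCurve:
    """Convert an MSD to the creep compliance J(t).

    ``"paper"``: J(t) = (π·a / k_B·T) · MSD(t) (literal 3D prefactor);
    ``"dimension_corrected"``: J(t) = (3π·a / (d·k_B·T)) · MSD_d(t), which
    coincides with the literal form at d = 3.

    ``terminal_slope`` extrapolates J beyond the last lag: ``"auto"``
    estimates dJ/dt by a linear fit over the last decade of t (≈ 1/η for a
    fluid, ≈ 0 on a gel plateau); pass 0.0 to pin an elastic plateau.
    """
    if convention not in _CONVENTIONS:
        raise InvalidArgumentError(f"unknown convention {convention!r}")
    ctx = msd.context
    if ctx is None:
        raise InvalidArgumentError("MSDCurve has no probe context")
    if convention == "paper":
        factor = np.pi * ctx.radius_a / ctx.kBT
    else:
        factor = 3.0 * np.pi * ctx.radius_a / (msd.dimension * ctx.kBT)
    J = factor * msd.values
    if terminal_slope == "auto":
        t = msd.lags
        sel = t >= t[-1] / 10.0
        if sel.sum() >= 2:
            slope = float(np.polyfit(t[sel], J[sel], 1)[0])
        else:
            slope = 0.0
        terminal_slope = max(slope, 0.0)
    return ComplianceCurve(t=msd.lags, J=J, terminal_slope=float(terminal_slope),
                           context=ctx, dimension=msd.dimension,
                           convention=convention)


def compliance_to_modulus(J: ComplianceCurve, omega: np.ndarray | None = None,
                          n_per_decade: int = 10,
                          j0: float | str = "extrapolate",
                          oversample_per_decade: int | None = 1000,
                          ) -> ComplexModulusCurve:
    """G*(ω) from the Fourier transform of the piecewise-linear J(t).

    With samples (t_k, J_k), k = 1..N, intercept J(0) = J₀ below t₁ and a
    linear tail of gradient ``terminal_slope`` beyond t_N, the transform of
    the interpolant gives

        A(ω) = iω·J₀ + (1 − e^(−iωt₁))·(J₁ − J₀)/t₁
               + terminal_slope·e^(−iωt_N)
               + Σ_{k=2..N} (J_k − J_{k−1})/(t_k − t_{k−1})
                              ·(e^(−iωt_{k−1}) − e^(−iωt_k)),

    and G*(ω) = 1/(iω·Ĵ(ω)) = iω / A(ω). G′ = Re G*, G″ = Im G*.
    The default frequency grid is log-spaced, 10 points per decade over
    ω ∈ [2π/t_max, π/t_min]; requested frequencies outside that band are
    trimmed with a warning.

    The piecewise-linear transform develops phase artifacts once ω
    approaches the reciprocal local sample spacing, which corrupts the
    smaller of G′/G″ near the top of the band. ``oversample_per_decade``
    therefore resamples J with a shape-preserving (PCHIP) interpolant onto
    a log grid of that density first (set ``None`` to transform the raw
    samples as given).
    """
    t, Jv = J.t, J.J
    if len(t) < 10:
        raise InvalidArgumentError("need J sampled at >= 10 times")
    if oversample_per_decade is not None:
        n_dense = max(len(t), int(np.ceil(
            np.log10(t[-1] / t[0]) * oversample_per_decade)))
        t_dense = np.geomspace(t[0], t[-1], n_dense)
        Jv = PchipInterpolator(t, Jv)(t_dense)
        t = t_dense
    w_lo, w_hi = 2.0 * np.pi / t[-1], np.pi / t[0]
    if omega is None:
        n_pts = max(2, int(np.ceil(np.log10(w_hi / w_lo) * n_per_decade)))
        omega = np.geomspace(w_lo, w_hi, n_pts)
    else:
        omega = np.asarray(omega, dtype=float)
        keep = (omega >= w_lo) & (omega <= w_hi)
        if not keep.all():
            warnings.warn("trimming frequencies outside the supported band",
                          stacklevel=2)
        omega = omega[keep]
        if omega.size == 0:
            raise InvalidArgumentError("no requested frequency inside the band")
    if j0 == "extrapolate":
        slope01 = (Jv[1] - Jv[0]) / (t[1] - t[0])
        j0 = float(np.clip(Jv[0] - slope01 * t[0], 0.0, Jv[0]))
    iw = 1j * omega
    E = np.exp(-iw[:, None] * t[None, :])       # (n_omega, N)
    slopes = np.diff(Jv) / np.diff(t)           # (N-1,)
    A = (iw * j0
         + (1.0 - E[:, 0]) * (Jv[0] - j0) / t[0]
         + J.terminal_slope * E[:, -1]
         + (E[:, :-1] - E[:, 1:]) @ slopes)
    G = iw / A
    return ComplexModulusCurve(omega=omega, G_prime=G.real, G_doubleprime=G.imag,
                               convention=J.convention)


def plateau_modulus(variance: float, ctx: ProbeContext,
                    convention: str = "paper", dimension: int = 2) -> PlateauModulus:
    """Low-frequency elastic plateau G₀′ from the confined-position variance.

    ``"paper"``: G₀′ = k_B·T / (π·a·⟨r²⟩) literally — exact when ⟨r²⟩ is the
    long-lag 3D MSD plateau (i.e. 2× the 3-axis position variance).
    ``"dimension_corrected"``: G₀′ = d·k_B·T / (6π·a·⟨r²⟩_d) for a position
    variance summed over d axes, which inverts the per-axis confinement
    ⟨x²⟩ = k_B·T/(6π·a·G0) exactly.
    """
    if convention not in _CONVENTIONS:
        raise InvalidArgumentError(f"unknown convention {convention!r}")
    if not variance > 0:
        raise InvalidArgumentError("variance must be > 0")
    literal = ctx.kBT / (np.pi * ctx.radius_a * variance)
    if convention == "paper":
        g0 = literal
    else:
        g0 = literal * dimension / 6.0
    return PlateauModulus(G0_prime=float(g0), variance_used=float(variance),
                          dimension=dimension, convention=convention)


def delta_plateau(G0_day_t: float, G0_day_1: float) -> float:
    """Proportional plateau change (G0_t − G0_1)/G0_1; negative = more compliant."""
    if G0_day_t <= 0 or G0_day_1 <= 0:
        raise InvalidArgumentError("plateau moduli must be positive")
    return (G0_day_t - G0_day_1) / G0_day_1


def trap_stiffness_equipartition(traj: Trajectory, axis: str = "x") -> float:
    """Trap stiffness κ = k_B·T/⟨x²⟩ from the stationary position variance."""
    x = traj.axis(axis)
    x = x[np.isfinite(x)]
    var = float(np.var(x))
    if var == 0:
        raise InvalidArgumentError("zero variance: cannot calibrate stiffness")
    return traj.context.kBT / var


def attach_tau_star(npaf: NPAFCurve, kappa: float, ctx: ProbeContext) -> NPAFCurve:
    """Attach the dimensionless lag axis τ* = κ·τ/(6π·a·η_s) to an NPAF."""
    if kappa <= 0:
        raise InvalidArgumentError("kappa must be positive")
    npaf.tau_star = kappa * npaf.lags / (6.0 * np.pi * ctx.radius_a
                                         * ctx.solvent_viscosity_eta_s)
    return npaf


def relative_viscosity_npaf(npaf: NPAFCurve, kappa: float | None = None,
                            ctx: ProbeContext | None = None) -> float:
    """Relative viscosity from the e⁻¹ intercept of the NPAF on the τ* axis.

    In a Newtonian medium of viscosity η the trapped bead's NPAF is
    exp(−τ/τ_c) with τ_c = 6π·a·η/κ, so on the dimensionless axis
    τ* = κτ/(6π·a·η_s) the e⁻¹ crossing sits exactly at η/η_s. The first
    downward crossing is located and refined by log-linear interpolation
    (noise can cause spurious re-crossings at long lag).
    """
    if npaf.tau_star is None:
        if kappa is None or ctx is None:
            raise InvalidArgumentError(
                "provide kappa and ctx, or an NPAF with a tau_star axis")
        attach_tau_star(npaf, kappa, ctx)
    target = np.exp(-1.0)
    v = npaf.values
    below = np.nonzero(v < target)[0]
    if below.size == 0:
        raise MicrorheoError(
            "NPAF never decays below e^-1 in the observed lags; "
            "record a longer trajectory")
    i = int(below[0])
    if i == 0:
        raise MicrorheoError("NPAF below e^-1 at zero lag: not a valid NPAF")
    t0, t1 = npaf.tau_star[i - 1], npaf.tau_star[i]
    v0, v1 = v[i - 1], v[i]
    if v0 <= 0 or v1 <= 0:
        frac = (v0 - target) / (v0 - v1)
        return float(t0 + frac * (t1 - t0))
    # log-linear: interpolate tau* against ln(NPAF)
    frac = (np.log(v0) - np.log(target)) / (np.log(v0) - np.log(v1))
    return float(t0 + frac * (t1 - t0))


def directional_viscosity(traj: Trajectory, theta: float, phi: float,
                          window_fraction: float = 0.1) -> DirectionalViscosity:
    """Viscosity along an arbitrary direction from the early-time MSD slope.

    At lags well below the trap relaxation time the trapped bead diffuses as
    if free, so Fick's law MSD(τ) = 2·D·τ holds along any unit vector
    u(θ, φ) and the Stokes–Einstein relation gives
    η(θ, φ) = k_B·T/(6π·D·a). The trap relaxation time along u is estimated
    from the e⁻¹ decay of the directional NPAF, and the slope is fitted over
    lags ≤ ``window_fraction``·τ_c (trap bias ≲ 5% at the default 0.1).
    """
    if traj.n_axes != 3:
        raise InvalidArgumentError("directional viscosity requires a 3-axis trajectory")
    u = direction_vector(theta, phi)
    proj = traj.positions @ u
    sub = Trajectory(t=traj.t, positions=proj[:, None], frame_rate=traj.frame_rate,
                     context=traj.context, axes=("x",),
                     dropped_frames=traj.dropped_frames)
    # trap relaxation time along u from the NPAF e^-1 decay
    npaf = compute_npaf(sub, "x", method="fft" if traj.dropped_frames is None
                        or not len(traj.dropped_frames) else "direct")
    below = np.nonzero(npaf.values < np.exp(-1.0))[0]
    if below.size == 0:
        raise MicrorheoError("cannot estimate the trap relaxation time: "
                             "NPAF does not decay below e^-1")
    tau_c = float(npaf.lags[below[0]])
    t_max = window_fraction * tau_c
    max_lag_frames = int(np.floor(t_max * traj.frame_rate))
    if max_lag_frames < 5:
        raise InvalidArgumentError(
            f"early-time window {t_max:g} s holds only {max_lag_frames} lags "
            f"(< 5) at {traj.frame_rate:g} Hz; increase the frame rate or the "
            f"window fraction")
    curve = compute_msd(sub, lag_scheme="all",
                        max_lag_fraction=max_lag_frames / traj.n_samples)
    ctx = traj.context
    slope = float(np.linalg.lstsq(curve.lags[:, None], curve.values, rcond=None)[0][0])
    D = slope / 2.0
    eta = ctx.kBT / (6.0 * np.pi * D * ctx.radius_a)
    return DirectionalViscosity(theta=theta, phi=phi, D=D, eta=eta,
                                eta_relative=eta / ctx.solvent_viscosity_eta_s,
                                fit_window=(float(curve.lags[0]),
                                            float(curve.lags[-1])))


def faxen_prediction(ctx: ProbeContext, h: float, mode: str = "parallel") -> float:
    """Near-wall apparent-viscosity factor η_app/η for a sphere at distance h.

    ``parallel`` (Faxén):
        1 / [1 − (9/16)s + (1/8)s³ − (45/256)s⁴ − (1/16)s⁵],  s = a/h.
    ``perpendicular`` (truncated Brenner series, Padé form):
        1 / [1 − (9/8)s + (1/2)s³ − (57/100)s⁴ + (1/5)s⁵
             + (7/200)s¹¹ − (1/25)s¹²].
    Both factors → 1 as h → ∞ and increase monotonically as the bead
    approaches the wall, with the perpendicular factor always the larger.
    """
    a = ctx.radius_a
    if not h > a:
        raise InvalidArgumentError(f"wall distance h={h} must exceed radius a={a}")
    s = a / h
    if mode == "parallel":
        denom = (1.0 - 9.0 / 16.0 * s + s ** 3 / 8.0
                 - 45.0 / 256.0 * s ** 4 - s ** 5 / 16.0)
    elif mode == "perpendicular":
        denom = (1.0 - 9.0 / 8.0 * s + 0.5 * s ** 3 - 0.57 * s ** 4
                 + 0.2 * s ** 5 + 7.0 / 200.0 * s ** 11 - 0.04 * s ** 12)
    else:
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    return float(1.0 / denom)
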