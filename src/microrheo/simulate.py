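"""Brownian-dynamics simulators and synthetic video renderers.

Every downstream stage (tracking, preprocessing, MSD statistics, rheology)
is validated against trajectories generated here with known ground truth:

* free diffusion in a Newtonian solvent (Fick / Stokes–Einstein),
* an overdamped bead in a 3D anisotropic harmonic optical trap
  (exact Ornstein–Uhlenbeck discretisation, correct statistics at any dt),
* a bead in a viscoelastic gel with a low-frequency elastic plateau
  (Kelvin–Voigt default, optional Prony relaxation modes),
* near-wall anisotropic drag (Faxén parallel / Brenner perpendicular),
* defocus-blurred transmission images of the bead, full-frame or tiled
  into nine axially offset sub-images (3×3 multiplane layout).

Inertia is neglected everywhere (micron beads in aqueous media at frame
rates ≤ 5 kHz are deep in the overdamped regime). Seeds are explicit; there
is no global RNG state.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.special import erfc

from .core import InvalidArgumentError, ProbeContext, Trajectory

log = logging.getLogger(__name__)

__all__ = [
    "TrapParams", "GelModelParams", "WallModel",
    "simulate_free_diffusion", "simulate_trapped_bead", "simulate_gel_bead",
    "simulate_near_wall", "add_drift", "add_line_noise",
    "render_bead_video", "render_multiplane_video",
    "MULTIPLANE_LABELS",
]

#: Row-major plane labels of the 3×3 multiplane tiling: tile (row, col)
#: (1-based) carries plane label 3·(row−1) + (col−1) − 4, i.e. −4..+4.
MULTIPLANE_LABELS = np.arange(-4, 5).reshape(3, 3)


@dataclass(frozen=True)
class TrapParams:
    """Optical-trap stiffness per axis, N/m.

    A weak trap (κ ≲ 1e-6 N/m) merely holds the probe in the field of view;
    the residual Brownian motion still samples the medium. The axial
    stiffness of a single-beam trap is typically ~5× weaker than lateral.
    """

    kappa_x: float = 3.2e-7
    kappa_y: float = 3.2e-7
    kappa_z: float = 6.7e-8

    def __post_init__(self) -> None:
        for name in ("kappa_x", "kappa_y", "kappa_z"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")

    def kappa(self, axis: str) -> float:
        return getattr(self, f"kappa_{axis}")


@dataclass(frozen=True)
class GelModelParams:
    """Kelvin–Voigt gel with optional Prony (generalised-Maxwell) modes.

    ``plateau_G0`` is the low-frequency elastic plateau in Pa; ``solvent_eta``
    the high-frequency viscous drag medium in Pa·s. Each Prony mode is a
    (modulus Pa, relaxation time s) pair adding a Maxwell arm in parallel.
    """

    plateau_G0: float = 5.0
    solvent_eta: float = 0.89e-3
    prony_modes: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.plateau_G0 < 0:
            raise InvalidArgumentError("plateau_G0 must be >= 0")
        if self.solvent_eta <= 0:
            raise InvalidArgumentError("solvent_eta must be > 0")
        for g, tau in self.prony_modes:
            if g <= 0 or tau <= 0:
                raise InvalidArgumentError("Prony mode moduli and times must be > 0")


@dataclass(frozen=True)
class WallModel:
    """A plane wall at distance ``wall_distance_h`` from the bead centre.

    The wall normal is the z axis: x/y motion is wall-parallel, z motion
    wall-perpendicular. ``h`` must exceed the bead radius.
    """

    wall_distance_h: float

    def validate(self, ctx: ProbeContext) -> None:
        if not self.wall_distance_h > ctx.radius_a:
            raise InvalidArgumentError(
                f"wall distance h={self.wall_distance_h} must exceed bead radius "
                f"a={ctx.radius_a}")


def _check_steps(dt: float, n_steps: int) -> None:
    if not (np.isfinite(dt) and dt > 0):
        raise InvalidArgumentError(f"dt must be positive, got {dt}")
    if n_steps < 2:
        raise InvalidArgumentError(f"n_steps must be >= 2, got {n_steps}")


def _rng(seed) -> np.random.Generator:
    if seed is None:
        raise InvalidArgumentError("an explicit seed is required")
    return np.random.default_rng(seed)


def _ou_axis(rng: np.random.Generator, n: int, tau_c: float, stat_var: float,
             dt: float) -> np.ndarray:
    """Exact OU discretisation: stationary start, AR(1) recursion via lfilter."""
    rho = np.exp(-dt / tau_c)
    innov_sd = np.sqrt(stat_var * (1.0 - rho * rho))
    w = rng.standard_normal(n) * innov_sd
    w[0] = rng.standard_normal() * np.sqrt(stat_var)  # stationary initial draw
    # x[k] = rho*x[k-1] + w[k]; lfilter implements the AR(1) recursion exactly
    return lfilter([1.0], [1.0, -rho], w)


def _free_axis(rng: np.random.Generator, n: int, D: float, dt: float) -> np.ndarray:
    steps = rng.standard_normal(n - 1) * np.sqrt(2.0 * D * dt)
    return np.concatenate([[0.0], np.cumsum(steps)])


def simulate_free_diffusion(ctx: ProbeContext, dt: float, n_steps: int,
                            n_axes: int = 1, seed=None) -> Trajectory:
    """Unconstrained diffusion: i.i.d. Gaussian increments of variance 2·D·dt.

    D follows Stokes–Einstein, D = k_B·T / (6π·η_s·a).
    """
    _check_steps(dt, n_steps)
    if not 1 <= n_axes <= 3:
        raise InvalidArgumentError("n_axes must be 1..3")
    rng = _rng(seed)
    D = ctx.diffusion_coefficient
    pos = np.column_stack([_free_axis(rng, n_steps, D, dt) for _ in range(n_axes)])
    t = np.arange(n_steps) * dt
    return Trajectory(t=t, positions=pos, frame_rate=1.0 / dt, context=ctx,
                      axes=tuple("xyz"[:n_axes]),
                      provenance={"simulator": "free_diffusion", "D": D, "seed": seed})


def simulate_trapped_bead(ctx: ProbeContext, trap: TrapParams, dt: float,
                          n_steps: int, seed=None, n_axes: int = 3,
                          medium_viscosity: float | None = None) -> Trajectory:
    """Overdamped bead in a 3D harmonic trap (exact OU update per axis).

    Per axis with stiffness κ > 0 the update is
    ``x ← x·exp(−dt/τ_c) + N(0, (k_B·T/κ)(1 − exp(−2dt/τ_c)))`` with
    relaxation time τ_c = γ/κ, so the stationary variance is exactly
    k_B·T/κ at any dt. Axes with κ = 0 fall back to free diffusion.
    ``medium_viscosity`` overrides the solvent viscosity of the medium the
    bead actually moves in (the context keeps η_s as the reference solvent).
    """
    _check_steps(dt, n_steps)
    if not 1 <= n_axes <= 3:
        raise InvalidArgumentError("n_axes must be 1..3")
    axes = tuple("xyz"[:n_axes])
    if all(trap.kappa(a) == 0 for a in axes):
        raise InvalidArgumentError("at least one trap axis must have kappa > 0")
    eta = ctx.solvent_viscosity_eta_s if medium_viscosity is None else medium_viscosity
    gamma = 6.0 * np.pi * eta * ctx.radius_a
    rng = _rng(seed)
    cols = []
    for a in axes:
        kappa = trap.kappa(a)
        if kappa == 0:
            cols.append(_free_axis(rng, n_steps, ctx.kBT / gamma, dt))
            continue
        tau_c = gamma / kappa
        if dt >= tau_c:
            warnings.warn(f"dt={dt:g} s does not resolve the trap relaxation "
                          f"time tau_c={tau_c:g} s on axis {a}", stacklevel=2)
        cols.append(_ou_axis(rng, n_steps, tau_c, ctx.kBT / kappa, dt))
    t = np.arange(n_steps) * dt
    return Trajectory(t=t, positions=np.column_stack(cols), frame_rate=1.0 / dt,
                      context=ctx, axes=axes,
                      provenance={"simulator": "trapped_bead", "trap": trap,
                                  "medium_viscosity": eta, "seed": seed})


def simulate_gel_bead(ctx: ProbeContext, gel: GelModelParams, dt: float,
                      n_steps: int, seed=None, n_axes: int = 2) -> Trajectory:
    """Bead confined by a gel network (Kelvin–Voigt default, Prony optional).

    The Kelvin–Voigt element maps onto an OU process with effective spring
    6π·a·G0 and drag 6π·a·η per axis, so the per-axis stationary variance is
    k_B·T/(6π·a·G0) and the long-lag MSD plateaus at twice that. With Prony
    modes, each Maxwell arm contributes an auxiliary relaxing variable and
    the dynamics are integrated by Euler–Maruyama at the requested dt
    (choose dt well below the shortest mode time).
    """
    _check_steps(dt, n_steps)
    if not 1 <= n_axes <= 3:
        raise InvalidArgumentError("n_axes must be 1..3")
    rng = _rng(seed)
    six_pi_a = 6.0 * np.pi * ctx.radius_a
    gamma = six_pi_a * gel.solvent_eta
    if gel.plateau_G0 == 0 and not gel.prony_modes:
        log.info("gel with G0=0 and no modes: falling back to free diffusion")
        ctx_eff = ProbeContext(ctx.radius_a, ctx.temperature_T, gel.solvent_eta)
        traj = simulate_free_diffusion(ctx_eff, dt, n_steps, n_axes=n_axes, seed=seed)
        traj.provenance["simulator"] = "gel_bead(free-diffusion fallback)"
        return traj

    axes = tuple("xyz"[:n_axes])
    kBT = ctx.kBT
    if not gel.prony_modes:
        kappa_eff = six_pi_a * gel.plateau_G0
        tau_c = gamma / kappa_eff
        if dt >= tau_c:
            warnings.warn(f"dt={dt:g} s does not resolve the gel relaxation "
                          f"time {tau_c:g} s", stacklevel=2)
        cols = [_ou_axis(rng, n_steps, tau_c, kBT / kappa_eff, dt)
                for _ in axes]
    else:
        cols = [_prony_axis(rng, n_steps, dt, ctx, gel) for _ in axes]
    t = np.arange(n_steps) * dt
    return Trajectory(t=t, positions=np.column_stack(cols), frame_rate=1.0 / dt,
                      context=ctx, axes=axes,
                      provenance={"simulator": "gel_bead", "gel": gel, "seed": seed})


def _prony_axis(rng: np.random.Generator, n: int, dt: float,
                ctx: ProbeContext, gel: GelModelParams) -> np.ndarray:
    """Bead coupled to Maxwell arms, integrated by exact-conditional splitting.

    Per step the bead makes an exact OU move about the instantaneous
    constrained minimum (stiffness κ0 + Σκ_i), then each arm relaxes
    exactly toward the bead with rate κ_i/γ_i. Each half-update is the
    exact conditional propagator, so the scheme is unconditionally stable;
    the splitting error vanishes as dt drops below the shortest mode time.
    """
    six_pi_a = 6.0 * np.pi * ctx.radius_a
    gamma = six_pi_a * gel.solvent_eta
    kappa0 = six_pi_a * gel.plateau_G0
    kappas = np.array([six_pi_a * g for g, _ in gel.prony_modes])
    rates = np.array([1.0 / tau for _, tau in gel.prony_modes])  # κ_i/γ_i
    kappa_tot = kappa0 + kappas.sum()
    kBT = ctx.kBT
    rho_x = np.exp(-dt * kappa_tot / gamma)
    sd_x = np.sqrt(kBT / kappa_tot * (1.0 - rho_x * rho_x))
    rho_y = np.exp(-dt * rates)
    sd_y = np.sqrt(kBT / kappas * (1.0 - rho_y * rho_y))
    # stationary start: x from its Boltzmann marginal, arms about x
    x = rng.standard_normal() * np.sqrt(kBT / max(kappa0, kappa_tot * 1e-12))
    y = x + rng.standard_normal(len(kappas)) * np.sqrt(kBT / kappas)
    out = np.empty(n)
    noise_x = rng.standard_normal(n)
    noise_y = rng.standard_normal((n, len(kappas)))
    for i in range(n):
        out[i] = x
        mu = (kappas @ y) / kappa_tot
        x = mu + (x - mu) * rho_x + sd_x * noise_x[i]
        y = x + (y - x) * rho_y + sd_y * noise_y[i]
    return out


def simulate_near_wall(ctx: ProbeContext, trap: TrapParams, wall: WallModel,
                       dt: float, n_steps: int, seed=None) -> Trajectory:
    """Trapped bead near a plane wall with anisotropically increased drag.

    The x/y (wall-parallel) drag is multiplied by the Faxén correction and
    the z (wall-perpendicular) drag by the truncated Brenner series (see
    :func:`microrheo.rheology.faxen_prediction`); the stationary variance
    k_B·T/κ per axis is unchanged, only the relaxation slows.
    """
    from .rheology import faxen_prediction  # local import avoids a cycle

    _check_steps(dt, n_steps)
    wall.validate(ctx)
    h = wall.wall_distance_h
    factors = {"x": faxen_prediction(ctx, h, "parallel"),
               "y": faxen_prediction(ctx, h, "parallel"),
               "z": faxen_prediction(ctx, h, "perpendicular")}
    gamma0 = ctx.drag
    rng = _rng(seed)
    cols = []
    for a in ("x", "y", "z"):
        kappa = trap.kappa(a)
        gamma = gamma0 * factors[a]
        if kappa == 0:
            cols.append(_free_axis(rng, n_steps, ctx.kBT / gamma, dt))
        else:
            cols.append(_ou_axis(rng, n_steps, gamma / kappa, ctx.kBT / kappa, dt))
    t = np.arange(n_steps) * dt
    return Trajectory(t=t, positions=np.column_stack(cols), frame_rate=1.0 / dt,
                      context=ctx, axes=("x", "y", "z"),
                      provenance={"simulator": "near_wall", "trap": trap,
                                  "wall": wall, "drag_factors": factors,
                                  "seed": seed})


def add_drift(traj: Trajectory, rates) -> Trajectory:
    """Superimpose linear instrument drift, ``rates`` in m/s per axis (scalar ok)."""
    rates = np.broadcast_to(np.atleast_1d(np.asarray(rates, float)),
                            (traj.n_axes,))
    drift = traj.t[:, None] * rates[None, :]
    return traj.with_positions(traj.positions + drift,
                               drift_rates=tuple(rates))


def add_line_noise(traj: Trajectory, amplitude: float, frequency: float,
                   phase: float = 0.0, axes=None) -> Trajectory:
    """Superimpose single-frequency 'line' noise of given amplitude (m)."""
    pos = traj.positions.copy()
    idx = range(traj.n_axes) if axes is None else [traj.axes.index(a) for a in axes]
    line = amplitude * np.sin(2 * np.pi * frequency * traj.t + phase)
    for i in idx:
        pos[:, i] += line
    return traj.with_positions(pos, line_noise=(amplitude, frequency))


# --------------------------------------------------------------------------
# Transmission-contrast renderers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastModel:
    """Dark-disk transmission contrast with defocus edge blur.

    The bead appears as a dark disk of its physical diameter on a bright
    background: I(r) = background − amplitude·½·erfc((r−R)/(√2·σ(z))) with
    σ(z) = blur_sigma0 + blur_per_m·|z − focus|, all in pixels except z.
    This is a phenomenological defocus model, not a physical PSF.
    """

    background: float = 3000.0
    amplitude: float = 2000.0
    blur_sigma0_px: float = 1.0
    blur_per_m_px: float = 2.0e6   # extra blur (px) per metre of defocus
    focus_z: float = 0.0


def _render_frame(xc: float, yc: float, z: float, radius_px: float,
                  shape: tuple[int, int], cm: ContrastModel) -> np.ndarray:
    yy, xx = np.indices(shape)
    r = np.hypot(xx - xc, yy - yc)
    sigma = cm.blur_sigma0_px + cm.blur_per_m_px * abs(z - cm.focus_z)
    profile = 0.5 * erfc((r - radius_px) / (np.sqrt(2.0) * sigma))
    return cm.background - cm.amplitude * profile


def _positions_px(traj: Trajectory, pixel_size: float,
                  shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map trajectory displacements to pixel coordinates about the frame centre."""
    cx = (shape[1] - 1) / 2.0
    cy = (shape[0] - 1) / 2.0
    x = traj.axis("x") / pixel_size + cx
    y = (traj.axis("y") / pixel_size + cy if "y" in traj.axes
         else np.full(traj.n_samples, cy))
    z = traj.axis("z") if "z" in traj.axes else np.zeros(traj.n_samples)
    return x, y, z


def _check_in_frame(x: np.ndarray, y: np.ndarray, radius_px: float,
                    shape: tuple[int, int], margin: float | None) -> None:
    m = radius_px if margin is None else margin
    bad = ((x < m) | (x > shape[1] - 1 - m) | (y < m) | (y > shape[0] - 1 - m))
    if np.any(bad):
        first = int(np.argmax(bad))
        raise InvalidArgumentError(
            f"bead leaves the field of view at frame {first} "
            f"(x={x[first]:.1f}, y={y[first]:.1f} px, margin {m:.1f} px)")


def render_bead_video(traj: Trajectory, pixel_size: float,
                      image_shape: tuple[int, int] = (64, 64),
                      contrast_model: ContrastModel | None = None,
                      noise_sigma: float = 0.0, seed=None,
                      shot_noise: bool | None = None,
                      margin_px: float | None = None) -> np.ndarray:
    """Render a full-frame transmission video of the bead, uint16 stack.

    Poisson shot noise is applied whenever any noise is requested
    (``noise_sigma > 0`` or ``shot_noise=True``); Gaussian read noise has
    std ``noise_sigma`` counts. ``noise_sigma=0`` with ``shot_noise`` unset
    gives a deterministic noiseless stack.
    """
    cm = contrast_model or ContrastModel()
    radius_px = traj.context.radius_a / pixel_size
    x, y, z = _positions_px(traj, pixel_size, image_shape)
    _check_in_frame(x, y, radius_px, image_shape, margin_px)
    noisy = (noise_sigma > 0) if shot_noise is None else shot_noise
    rng = _rng(seed) if (noisy or noise_sigma > 0) else None
    frames = np.empty((traj.n_samples, *image_shape), dtype=np.uint16)
    for i in range(traj.n_samples):
        img = _render_frame(x[i], y[i], z[i], radius_px, image_shape, cm)
        if noisy:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, image_shape)
        frames[i] = np.clip(img, 0, 65535).astype(np.uint16)
    return frames


def render_multiplane_video(traj: Trajectory, pixel_size: float,
                            plane_spacing: float = 0.79e-6, n_planes: int = 9,
                            tile_shape: tuple[int, int] = (48, 48),
                            contrast_model: ContrastModel | None = None,
                            noise_sigma: float = 0.0, seed=None,
                            shot_noise: bool | None = None,
                            margin_px: float | None = None) -> np.ndarray:
    """Render a 3×3-tiled nine-plane video (plane labels −4..+4, row-major).

    Tile with plane label p images the bead at defocus z_bead − p·Δz, so the
    nine planes span ``9·Δz`` axially (the span convention counts one plane
    spacing per plane). Only a 3×3 tiling is supported.
    """
    if n_planes != 9:
        raise InvalidArgumentError("only the 9-plane (3x3) layout is supported")
    if plane_spacing <= 0:
        raise InvalidArgumentError("plane_spacing must be > 0")
    cm = contrast_model or ContrastModel()
    radius_px = traj.context.radius_a / pixel_size
    x, y, z = _positions_px(traj, pixel_size, tile_shape)
    _check_in_frame(x, y, radius_px, tile_shape, margin_px)
    noisy = (noise_sigma > 0) if shot_noise is None else shot_noise
    rng = _rng(seed) if (noisy or noise_sigma > 0) else None
    H, W = tile_shape
    frames = np.empty((traj.n_samples, 3 * H, 3 * W), dtype=np.uint16)
    for i in range(traj.n_samples):
        for row in range(3):
            for col in range(3):
                p = MULTIPLANE_LABELS[row, col]
                img = _render_frame(x[i], y[i], z[i] - p * plane_spacing,
                                    radius_px, tile_shape, cm)
                if noisy:
                    img = rng.poisson(np.clip(img, 0, None)).astype(float)
                if noise_sigma > 0:
                    img = img + rng.normal(0.0, noise_sigma, tile_shape)
                frames[i, row * H:(row + 1) * H, col * W:(col + 1) * W] = \
                    np.clip(img, 0, 65535).astype(np.uint16)
    return frames
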