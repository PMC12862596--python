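"""Emission-pattern metrics: lobes, F/B ratio, integrated intensity.

The angular intensity pattern is read as a radial plot r = I(theta, phi);
a "lobe" is a contiguous high-intensity region and its volume is the
Euclidean volume enclosed by that radial surface over the lobe's solid
angle, V = integral of I^3 sin(phi) / 3.  Lobes are separated the way the
emission patterns suggest: the intensity profile along the x-z great
circle (where the dominant lobes lie) is scanned for local minima, whose
inclination angles partition each hemisphere into bands.  Forward means
phi < pi/2 (the laser propagates along +z); cells at exactly pi/2 count as
forward.  The forward/backward ratio F_SHG/B_SHG divides the summed
forward lobe volumes by the backward ones, and the integrated intensity
(relative conversion efficiency) is their sum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .emission import AngularGrid, EmissionPattern, compute_emission
from .optics import DispersionModel, OpticalConfig
from .spectral import DFFTConfig
from .structure import FibrilModel, VoxelVolume, voxelize

__all__ = [
    "Lobe",
    "LobeSet",
    "CreationMetrics",
    "segment_lobes",
    "lobe_volume",
    "fb_ratio",
    "integrated_intensity",
    "peak_lobe_error",
    "wavelength_series",
    "metrics_from_pattern",
]


@dataclass
class Lobe:
    mask: np.ndarray  # (n_theta, n_phi) bool
    hemisphere: str  # "forward" | "backward"
    volume: float
    peak_intensity: float


@dataclass
class LobeSet:
    lobes: list[Lobe] = field(default_factory=list)
    volume_method: str = "solid_angle"

    def __len__(self) -> int:
        return len(self.lobes)

    def hemisphere_total(self, tag: str) -> float:
        return float(sum(l.volume for l in self.lobes if l.hemisphere == tag))


@dataclass
class CreationMetrics:
    """Per-wavelength creation attributes of one structure."""

    lambda_fund: float
    FB_ratio: float
    F_total: float
    B_total: float
    integrated_intensity: float
    peak_intensity: float
    n_lobes: int
    fb_infinite: bool = False
    volume_method: str = "solid_angle"


def _cell_solid_angle(grid: AngularGrid) -> tuple[float, float]:
    theta = grid.theta
    phi = grid.phi
    return float(theta[1] - theta[0]), float(phi[1] - phi[0])


def _xz_profile(pattern: EmissionPattern) -> tuple[np.ndarray, np.ndarray]:
    """Closed-loop intensity profile around the x-z great circle.

    Returns (phi_loop, I_loop): the theta ~ 0 meridian traversed phi 0->pi
    stitched with the theta ~ pi meridian traversed pi->0.
    """
    I = pattern.intensity
    theta = pattern.grid.theta
    i0 = int(np.argmin(np.abs(theta)))
    i_pi = int(np.argmin(np.abs(theta - math.pi)))
    phi = pattern.grid.phi
    loop_I = np.concatenate([I[i0, :], I[i_pi, ::-1]])
    loop_phi = np.concatenate([phi, phi[::-1]])
    return loop_phi, loop_I


def segment_lobes(
    pattern: EmissionPattern,
    *,
    prominence_frac: float = 0.01,
    floor_frac: float = 1e-6,
    volume_method: str = "solid_angle",
) -> LobeSet:
    """Partition the pattern into lobes by x-z-plane local minima.

    Local minima of the great-circle profile with prominence at least
    ``prominence_frac`` of the global peak define break inclinations; bands
    between breaks (always split at the hemisphere boundary pi/2) crossed
    with the hemispheres are the lobes.  Cells below ``floor_frac`` of the
    peak stay unassigned; an all-zero pattern yields an empty set.
    """
    I = pattern.intensity
    peak = float(I.max())
    out = LobeSet(volume_method=volume_method)
    if peak <= 0.0:
        return out
    loop_phi, loop_I = _xz_profile(pattern)
    n = loop_I.size
    # circular minimum detection: tile 3x and keep the middle copy
    tiled = np.tile(loop_I, 3)
    mins, _ = find_peaks(-tiled, prominence=prominence_frac * peak)
    mins = mins[(mins >= n) & (mins < 2 * n)] - n
    breaks = sorted(set(float(loop_phi[i]) for i in mins) | {math.pi / 2.0})
    edges = np.array([0.0] + breaks + [math.pi])
    phi = pattern.grid.phi
    floor = floor_frac * peak
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= lo:
            continue
        # half-open bands; the final band includes phi = pi
        in_band = (phi >= lo) & ((phi < hi) if hi < math.pi else (phi <= hi))
        if not np.any(in_band):
            continue
        mask = np.zeros_like(I, dtype=bool)
        mask[:, in_band] = I[:, in_band] >= floor
        if not np.any(mask):
            continue
        peak_idx = np.unravel_index(int(np.argmax(np.where(mask, I, -1.0))), I.shape)
        phi_peak = phi[peak_idx[1]]
        tag = "forward" if phi_peak <= math.pi / 2.0 else "backward"
        lobe = Lobe(
            mask=mask,
            hemisphere=tag,
            volume=0.0,
            peak_intensity=float(I[peak_idx]),
        )
        lobe.volume = lobe_volume(lobe, pattern, method=volume_method)
        out.lobes.append(lobe)
    return out


def lobe_volume(
    lobe: Lobe, pattern: EmissionPattern, method: str = "solid_angle"
) -> float:
    """Volume enclosed by the radial plot r = I over the lobe's cells.

    ``solid_angle`` (default) integrates I^3 sin(phi)/3 over the lobe's
    grid cells — exact for the radial surface on the grid.
    ``boundary_triangulation`` mirrors a triangulated-boundary procedure:
    the convex hull volume of the lobe's Cartesian point cloud (plus the
    origin); degenerate clouds fall back to the solid-angle integral.
    """
    if not np.any(lobe.mask):
        raise ValueError("empty lobe")
    I = pattern.intensity
    if method == "solid_angle":
        d_theta, d_phi = _cell_solid_angle(pattern.grid)
        sin_phi = np.sin(pattern.grid.phi)[None, :]
        return float(
            np.sum((I[lobe.mask] ** 3) * np.broadcast_to(sin_phi, I.shape)[lobe.mask])
            / 3.0
            * d_theta
            * d_phi
        )
    if method == "boundary_triangulation":
        from scipy.spatial import ConvexHull, QhullError

        it, ip = np.nonzero(lobe.mask)
        theta = pattern.grid.theta[it]
        phi = pattern.grid.phi[ip]
        r = I[lobe.mask]
        pts = np.column_stack(
            [
                r * np.sin(phi) * np.cos(theta),
                r * np.sin(phi) * np.sin(theta),
                r * np.cos(phi),
            ]
        )
        pts = np.vstack([pts, [0.0, 0.0, 0.0]])
        if pts.shape[0] <= 4:
            warnings.warn("degenerate lobe; falling back to solid-angle volume")
            return lobe_volume(lobe, pattern, method="solid_angle")
        try:
            return float(ConvexHull(pts).volume)
        except QhullError:
            warnings.warn("hull failure; falling back to solid-angle volume")
            return lobe_volume(lobe, pattern, method="solid_angle")
    raise ValueError(f"unknown volume method {method!r}")


def fb_ratio(lobes: LobeSet) -> tuple[float, float, float, bool]:
    """(F_total, B_total, FB_ratio, infinite_flag) from a lobe set."""
    F = lobes.hemisphere_total("forward")
    B = lobes.hemisphere_total("backward")
    if B > 0.0:
        return F, B, F / B, False
    return F, B, math.inf, True


def integrated_intensity(lobes: LobeSet) -> float:
    """Total emitted volume: forward plus backward lobe volumes."""
    return lobes.hemisphere_total("forward") + lobes.hemisphere_total("backward")


def peak_lobe_error(pattern_a, pattern_b) -> float:
    """Percent error of a's peak intensity against reference b.

    Accepts EmissionPattern objects or raw intensity arrays.
    """
    Ia = pattern_a.intensity if hasattr(pattern_a, "intensity") else np.asarray(pattern_a)
    Ib = pattern_b.intensity if hasattr(pattern_b, "intensity") else np.asarray(pattern_b)
    ref = float(np.max(Ib))
    if ref <= 0.0:
        raise ValueError("reference pattern has zero peak intensity")
    return 100.0 * abs(float(np.max(Ia)) - ref) / ref


def metrics_from_pattern(
    pattern: EmissionPattern,
    *,
    volume_method: str = "solid_angle",
    prominence_frac: float = 0.01,
    floor_frac: float = 1e-6,
) -> CreationMetrics:
    """Segment a pattern and assemble its creation metrics."""
    lobes = segment_lobes(
        pattern,
        prominence_frac=prominence_frac,
        floor_frac=floor_frac,
        volume_method=volume_method,
    )
    F, B, ratio, flag = fb_ratio(lobes)
    return CreationMetrics(
        lambda_fund=pattern.lambda_fund,
        FB_ratio=ratio,
        F_total=F,
        B_total=B,
        integrated_intensity=F + B,
        peak_intensity=pattern.peak_intensity,
        n_lobes=len(lobes),
        fb_infinite=flag,
        volume_method=volume_method,
    )


def wavelength_series(
    model: FibrilModel,
    lambdas,
    *,
    NA: float = 0.8,
    xi: float = 1.0,
    dispersion: DispersionModel = DispersionModel(),
    grid_dims: tuple[int, int, int] = (100, 100, 300),
    dfft_cfg: DFFTConfig = DFFTConfig(),
    angular_grid: AngularGrid = AngularGrid(),
    window_mode: str = "windowed",
    volume_method: str = "solid_angle",
    vol: VoxelVolume | None = None,
    excitation: str = "constant_power",
) -> list[CreationMetrics]:
    """Creation metrics of one fixed structure across wavelengths.

    The geometry and its voxelization are fixed; per wavelength the focal
    window, beam geometry, Fourier components and emission pattern are
    rebuilt.  ``lambdas`` must be sorted ascending.

    ``excitation`` sets how the fundamental field scales across the sweep:
    ``"constant_power"`` (default) keeps the focused laser power fixed, so
    the field amplitude scales as 1/w_rho(lambda) (normalized to the first
    wavelength) — the condition under which relative conversion
    efficiencies at different wavelengths are comparable;
    ``"constant_field"`` keeps E_amp fixed instead.
    """
    lambdas = list(lambdas)
    if lambdas != sorted(lambdas):
        raise ValueError("lambdas must be sorted ascending")
    if excitation not in ("constant_power", "constant_field"):
        raise ValueError(f"unknown excitation mode {excitation!r}")
    if vol is None:
        vol = voxelize(model, grid_dims)
    from .optics import beam_geometry

    w_ref = beam_geometry(
        OpticalConfig(lambda_fund=float(lambdas[0]), NA=NA, xi=xi), dispersion
    ).w_rho
    out = []
    for lam in lambdas:
        if excitation == "constant_power":
            w_lam = beam_geometry(
                OpticalConfig(lambda_fund=float(lam), NA=NA, xi=xi), dispersion
            ).w_rho
            e_amp = w_ref / w_lam
        else:
            e_amp = 1.0
        cfg = OpticalConfig(lambda_fund=float(lam), NA=NA, xi=xi, E_amp=e_amp)
        pattern = compute_emission(
            model,
            vol,
            cfg,
            dispersion,
            dfft_cfg,
            angular_grid,
            window_mode=window_mode,
        )
        out.append(metrics_from_pattern(pattern, volume_method=volume_method))
    return out
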