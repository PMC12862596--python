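"""Wavelength-dependent optical quantities for focused-beam SHG.

This module collects the physics that depends only on the laser and the
medium, not on the fibril structure: the empirical refractive-index
dispersion of collagen (rat-tail tendon), the lateral and axial waists of a
focused Gaussian beam, the fundamental and second-harmonic wavenumbers, and
the direction-dependent phase mismatch

    dk_z = 2 xi k_w - k_2w cos(phi) + k_z
    dk_x = -k_2w cos(theta) sin(phi) + k_x
    dk_y = -k_2w sin(theta) sin(phi) + k_y

where ``xi`` is an empirical Gouy-phase factor multiplying the axial phase
of the fundamental, ``(theta, phi)`` are the azimuth and the inclination of
the emitted second-harmonic wavevector measured from the propagation axis
+z, and ``(k_x, k_y, k_z)`` is a momentum contribution of the medium.

All lengths are in nanometres and wavenumbers in rad/nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalConfig",
    "DispersionModel",
    "BeamGeometry",
    "refractive_index",
    "beam_geometry",
    "mismatch_vector",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Laser/medium configuration for a single fundamental wavelength.

    Parameters
    ----------
    lambda_fund : float
        Fundamental wavelength in nm (400-2000).
    NA : float
        Numerical aperture of the focusing objective (0 < NA < 1.33).
    xi : float
        Empirical Gouy correction factor multiplying ``k_w`` in the axial
        phase of the focused fundamental; 0 < xi <= 1.  The Gouy anomaly
        reduces the effective axial phase velocity, so xi < 1 in practice;
        xi = 1 recovers a plane-wave-like axial phase.
    E_amp : float
        Relative fundamental field amplitude (arbitrary units).
    d_eff_scale : float
        Relative scale of the effective second-order susceptibility.
    """

    lambda_fund: float
    NA: float = 0.8
    xi: float = 1.0
    E_amp: float = 1.0
    d_eff_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 400.0 <= self.lambda_fund <= 2000.0:
            raise ValueError(
                f"lambda_fund={self.lambda_fund} nm outside [400, 2000] nm"
            )
        if not 0.0 < self.NA < 1.33:
            raise ValueError(f"NA={self.NA} outside (0, 1.33)")
        if not 0.0 < self.xi <= 1.0:
            raise ValueError(f"xi={self.xi} outside (0, 1]")
        if self.E_amp <= 0.0:
            raise ValueError("E_amp must be positive")


@dataclass(frozen=True)
class DispersionModel:
    """Empirical collagen dispersion n(lambda) = A0 + A2/l^2 - A4/l^4 + A6/l^e.

    Default coefficients are the rat-tail-tendon values.  The last term is
    evaluated with exponent ``last_term_exponent``; the physically sensible
    reading is e = 6 (e = 4 yields n > 100 at 800 nm and is retained only
    for auditing the alternative dialect).
    """

    A0: float = 1.4389
    A2: float = 1.588e4
    A4: float = 1.4806e9
    A6: float = 4.3917e13
    last_term_exponent: int = 6

    def __post_init__(self) -> None:
        if self.last_term_exponent not in (4, 6):
            raise ValueError("last_term_exponent must be 4 or 6")


@dataclass(frozen=True)
class BeamGeometry:
    """Derived beam/medium quantities at one fundamental wavelength.

    Attributes
    ----------
    w_rho, w_z : float
        Lateral and axial 1/e field waists of the focused fundamental, nm.
    n_omega, n_2omega : float
        Refractive index at the fundamental and second-harmonic wavelengths.
    k_omega, k_2omega : float
        Wavenumbers 2*pi*n/lambda at the fundamental and second harmonic,
        rad/nm.
    lambda_fund : float
        Fundamental wavelength, nm (carried for provenance checks).
    """

    w_rho: float
    w_z: float
    n_omega: float
    n_2omega: float
    k_omega: float
    k_2omega: float
    lambda_fund: float = field(default=float("nan"))


def refractive_index(lambda_nm, model: DispersionModel = DispersionModel()):
    """Collagen refractive index at wavelength ``lambda_nm`` (nm).

    Accepts scalars or arrays.  Raises ``ValueError`` for non-positive
    wavelengths.
    """
    lam = np.asarray(lambda_nm, dtype=float)
    if np.any(lam <= 0.0):
        raise ValueError("wavelength must be positive")
    n = (
        model.A0
        + model.A2 / lam**2
        - model.A4 / lam**4
        + model.A6 / lam**model.last_term_exponent
    )
    return n if n.ndim else float(n)


def _lateral_waist(lambda_nm: float, NA: float) -> float:
    # Piecewise fit for a focused Gaussian; branches meet near NA = 0.7
    # with < 2% discontinuity.
    if NA <= 0.7:
        return 0.320 * lambda_nm / (math.sqrt(2.0) * NA)
    return 0.325 * lambda_nm / (math.sqrt(2.0) * NA**0.91)


def beam_geometry(
    cfg: OpticalConfig, model: DispersionModel = DispersionModel()
) -> BeamGeometry:
    """Beam waists and wavenumbers for the configuration ``cfg``.

    The axial waist uses the refractive index at the fundamental; the
    second-harmonic wavenumber uses the same dispersion formula evaluated at
    lambda/2 (normal dispersion makes ``k_2omega > 2 k_omega``).
    """
    lam = cfg.lambda_fund
    n_w = refractive_index(lam, model)
    n_2w = refractive_index(lam / 2.0, model)
    if cfg.NA >= n_w:
        raise ValueError(
            f"NA={cfg.NA} >= n_omega={n_w:.4f}: axial waist undefined"
        )
    w_rho = _lateral_waist(lam, cfg.NA)
    w_z = (0.532 * lam / math.sqrt(2.0)) / (n_w - math.sqrt(n_w**2 - cfg.NA**2))
    return BeamGeometry(
        w_rho=w_rho,
        w_z=w_z,
        n_omega=n_w,
        n_2omega=n_2w,
        k_omega=2.0 * math.pi * n_w / lam,
        k_2omega=2.0 * math.pi * n_2w / (lam / 2.0),
        lambda_fund=lam,
    )


def mismatch_vector(theta, phi, geom: BeamGeometry, xi: float, k_mnl=(0.0, 0.0, 0.0)):
    """Directional phase mismatch (dk_x, dk_y, dk_z) in rad/nm.

    ``theta`` (azimuth, [-pi, pi]) and ``phi`` (inclination from +z,
    [0, pi]) may be scalars or broadcastable arrays; ``k_mnl`` is the medium
    momentum 3-vector.  Returns a tuple of arrays broadcast over the angular
    inputs.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < -1e-12) or np.any(phi > math.pi + 1e-12):
        raise ValueError("phi must lie in [0, pi]")
    kx, ky, kz = (float(v) for v in k_mnl)
    sin_phi = np.sin(phi)
    dk_x = -geom.k_2omega * np.cos(theta) * sin_phi + kx
    dk_y = -geom.k_2omega * np.sin(theta) * sin_phi + ky
    dk_z = 2.0 * xi * geom.k_omega - geom.k_2omega * np.cos(phi) + kz
    return dk_x, dk_y, dk_z
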