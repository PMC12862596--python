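"""Biomimetic collagen fibril architectures and their voxelized volumes.

Fibrils are modelled as polar cylinders (normalized susceptibility +-1)
running the full length of a rectangular simulation box along x, with the
laser propagating along z.  Cross-sections are hard disks in the (y, z)
plane: random ensembles are packed by rejection sampling, lattices are laid
out on a near-square grid, and shifted lattices perturb each site
uniformly.  Voxelization assigns each voxel the polarity of the fibril
containing its centre, and a separable Gaussian focal window matched to the
beam waists confines the structure to the focal volume.

Coordinates are centred: x in [-L/2, L/2], y in [-W/2, W/2],
z in [-H/2, H/2], all in nm.  Voxel sample points are cell centres.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .optics import BeamGeometry, OpticalConfig, DispersionModel, beam_geometry

__all__ = [
    "FibrilEnsembleSpec",
    "FibrilModel",
    "VoxelVolume",
    "PrismLattice",
    "SquareWave1D",
    "box_dimensions",
    "generate_random",
    "generate_lattice",
    "shift_lattice",
    "assign_polarity",
    "voxelize",
    "apply_focal_window",
    "prism_lattice_volume",
    "square_wave_volume",
    "DEFAULT_BOX",
    "PackingError",
]

DEFAULT_BOX = (1400.0, 1400.0, 6000.0)  # printed L, W, H in nm

PolarityMode = Literal["aligned", "random", "alternating"]
PlacementMode = Literal["random", "lattice", "shifted_lattice"]


@dataclass(frozen=True)
class FibrilEnsembleSpec:
    """Parameters of a fibril ensemble.

    ``fill_fraction`` is the cross-sectional area fraction of the box
    occupied by fibril disks (equal to the volume fraction, as fibrils span
    the box along x).
    """

    mean_diameter: float
    diameter_sd_frac: float = 0.0
    fill_fraction: float = 0.25
    polarity_mode: PolarityMode = "random"
    placement_mode: PlacementMode = "random"
    shift_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_diameter <= 0:
            raise ValueError("mean_diameter must be positive")
        if not 0.0 <= self.diameter_sd_frac <= 0.5:
            raise ValueError("diameter_sd_frac must lie in [0, 0.5]")
        if not 0.0 < self.fill_fraction < math.pi / 4.0:
            raise ValueError(
                "fill_fraction must lie in (0, pi/4), the hard-disk bound"
            )
        if self.polarity_mode not in ("aligned", "random", "alternating"):
            raise ValueError(f"unknown polarity_mode {self.polarity_mode!r}")
        if self.placement_mode not in ("random", "lattice", "shifted_lattice"):
            raise ValueError(f"unknown placement_mode {self.placement_mode!r}")


@dataclass(frozen=True)
class FibrilModel:
    """A concrete list of polar cylinders in a box.

    ``fibrils`` has columns (center_y, center_z, radius, polarity);
    ``lattice_index`` holds (iy, iz) integer site indices for lattice-based
    models (required by alternating polarity), or None for random packing.
    """

    fibrils: np.ndarray  # (n, 4) float: cy, cz, r, polarity
    box: tuple[float, float, float]  # (L, W, H) nm
    spec: FibrilEnsembleSpec | None = None
    seed: int | None = None
    lattice_index: np.ndarray | None = None  # (n, 2) int

    @property
    def n_fibrils(self) -> int:
        return int(self.fibrils.shape[0])

    @property
    def fill_fraction(self) -> float:
        _, W, H = self.box
        return float(np.sum(math.pi * self.fibrils[:, 2] ** 2) / (W * H))

    def with_polarity(self, polarity: np.ndarray) -> "FibrilModel":
        fib = self.fibrils.copy()
        fib[:, 3] = polarity
        return replace(self, fibrils=fib)


@dataclass
class VoxelVolume:
    """Scalar susceptibility field sampled at voxel centres.

    ``values`` is (Nx, Ny, Nz); before windowing entries are in {-1, 0, +1}.
    ``window_a`` records the Gaussian envelope exponent scale (1 = field
    envelope, 2 = squared-field envelope) and ``lambda_window`` the
    wavelength whose waists defined the window.
    """

    values: np.ndarray
    box: tuple[float, float, float]
    windowed: bool = False
    window_a: float | None = None
    lambda_window: float | None = None

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]

    @property
    def pitch(self) -> tuple[float, float, float]:
        return tuple(b / n for b, n in zip(self.box, self.values.shape))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Cell-centre coordinates along ``axis`` (0=x, 1=y, 2=z)."""
        n = self.values.shape[axis]
        b = self.box[axis]
        return (np.arange(n) + 0.5) * (b / n) - b / 2.0


def box_dimensions(
    lambda_max: float,
    cfg: OpticalConfig | None = None,
    dispersion: DispersionModel = DispersionModel(),
    *,
    override: bool = False,
) -> tuple[float, float, float]:
    """Simulation box (L, W, H) in nm.

    By default L = W = 4 * w_rho(lambda_max) and H = 4 * w_z(lambda_max) so
    the focal window decays strongly before the box faces.  With
    ``override=True`` the fixed (1400, 1400, 6000) nm box is returned.
    """
    if override:
        return DEFAULT_BOX
    base = OpticalConfig(lambda_fund=lambda_max) if cfg is None else cfg
    geom = beam_geometry(
        OpticalConfig(
            lambda_fund=lambda_max,
            NA=base.NA,
            xi=base.xi,
            E_amp=base.E_amp,
            d_eff_scale=base.d_eff_scale,
        ),
        dispersion,
    )
    return (4.0 * geom.w_rho, 4.0 * geom.w_rho, 4.0 * geom.w_z)


class PackingError(RuntimeError):
    """Raised when rejection sampling cannot reach the target fill."""


def _draw_radius(rng: np.random.Generator, mean_r: float, sd_r: float) -> float:
    """Normal radius truncated at +-3 SD and at r > 0."""
    if sd_r == 0.0:
        return mean_r
    for _ in range(1000):
        r = rng.normal(mean_r, sd_r)
        if abs(r - mean_r) <= 3.0 * sd_r and r > 0.0:
            return r
    raise PackingError("could not draw a positive truncated-normal radius")


class _CellList:
    """Uniform-grid neighbour lookup for hard-disk overlap checks."""

    def __init__(self, W: float, H: float, cell: float):
        self.cell = cell
        self.ny = max(1, int(math.ceil(W / cell)))
        self.nz = max(1, int(math.ceil(H / cell)))
        self.W, self.H = W, H
        self.cells: dict[tuple[int, int], list[int]] = {}
        self.disks: list[tuple[float, float, float]] = []

    def _key(self, y: float, z: float) -> tuple[int, int]:
        iy = min(self.ny - 1, max(0, int((y + self.W / 2) / self.cell)))
        iz = min(self.nz - 1, max(0, int((z + self.H / 2) / self.cell)))
        return iy, iz

    def overlaps(self, y: float, z: float, r: float) -> bool:
        iy, iz = self._key(y, z)
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                for idx in self.cells.get((iy + dy, iz + dz), ()):
                    cy, cz, cr = self.disks[idx]
                    if (cy - y) ** 2 + (cz - z) ** 2 < (cr + r) ** 2:
                        return True
        return False

    def add(self, y: float, z: float, r: float) -> None:
        self.disks.append((y, z, r))
        self.cells.setdefault(self._key(y, z), []).append(len(self.disks) - 1)


def generate_random(
    spec: FibrilEnsembleSpec,
    box: tuple[float, float, float],
    *,
    max_attempts_per_fibril: int = 100_000,
) -> FibrilModel:
    """Pack non-overlapping fibril disks into the (W, H) cross-section.

    Centres are uniform over the admissible region (disks fully inside the
    cross-section), radii are truncated-normal, and disks are added by
    rejection until the achieved fill fraction reaches the target (the
    overshoot of the final disk is far below the +-2% acceptance band).
    Deterministic for a fixed spec/seed.
    """
    if spec.fill_fraction > 0.5:
        raise PackingError(
            f"fill_fraction={spec.fill_fraction} > 0.5 not reachable by "
            "rejection sampling"
        )
    _, W, H = box
    rng = np.random.default_rng(spec.seed)
    mean_r = spec.mean_diameter / 2.0
    sd_r = spec.diameter_sd_frac * mean_r
    r_max = mean_r * (1.0 + 3.0 * spec.diameter_sd_frac)
    cells = _CellList(W, H, cell=2.0 * r_max)
    area = W * H
    target_area = spec.fill_fraction * area
    filled = 0.0
    out: list[tuple[float, float, float]] = []
    while filled < target_area:
        placed = False
        for _ in range(max_attempts_per_fibril):
            r = _draw_radius(rng, mean_r, sd_r)
            y = rng.uniform(-W / 2 + r, W / 2 - r)
            z = rng.uniform(-H / 2 + r, H / 2 - r)
            if not cells.overlaps(y, z, r):
                cells.add(y, z, r)
                out.append((y, z, r))
                filled += math.pi * r**2
                placed = True
                break
        if not placed:
            raise PackingError(
                f"packing stalled at fill {filled / area:.4f} "
                f"(target {spec.fill_fraction}) after "
                f"{max_attempts_per_fibril} attempts for one fibril"
            )
    fib = np.array([(y, z, r, 1.0) for (y, z, r) in out], dtype=float)
    model = FibrilModel(fibrils=fib, box=tuple(box), spec=spec, seed=spec.seed)
    return assign_polarity(model, spec.polarity_mode, spec.seed)


def generate_lattice(
    diameter: float,
    target_fill: float,
    box: tuple[float, float, float],
) -> FibrilModel:
    """Near-square lattice of identical fibrils in the (y, z) cross-section.

    The ideal period a = d * sqrt(pi / (4 f)) is rounded per axis to an
    integer number of cells spanning the box, so the achieved fill (see
    ``FibrilModel.fill_fraction``) differs slightly from the target.
    """
    if target_fill <= 0 or target_fill >= math.pi / 4.0:
        raise ValueError("target_fill must lie in (0, pi/4)")
    _, W, H = box
    a = diameter * math.sqrt(math.pi / (4.0 * target_fill))
    if diameter > a:
        raise ValueError("diameter exceeds the feasible lattice period")
    ny = max(1, round(W / a))
    nz = max(1, round(H / a))
    ay, az = W / ny, H / nz
    if diameter > min(ay, az):
        raise ValueError("rounded lattice period smaller than the diameter")
    r = diameter / 2.0
    fib = []
    idx = []
    for iy in range(ny):
        for iz in range(nz):
            y = (iy + 0.5) * ay - W / 2.0
            z = (iz + 0.5) * az - H / 2.0
            fib.append((y, z, r, 1.0))
            idx.append((iy, iz))
    return FibrilModel(
        fibrils=np.array(fib, dtype=float),
        box=tuple(box),
        lattice_index=np.array(idx, dtype=int),
    )


def shift_lattice(
    model: FibrilModel,
    amplitude: float,
    seed: int,
    *,
    max_retries: int = 1000,
) -> FibrilModel:
    """Perturb each fibril centre by a uniform offset in [-A, +A]^2.

    Offsets that create an overlap, or push a disk outside the
    cross-section, are redrawn for that fibril (bounded retries).  Lattice
    indices are preserved so alternating polarity remains well defined.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    _, W, H = model.box
    fib = model.fibrils.copy()
    n = fib.shape[0]
    for i in range(n):
        y0, z0, r = fib[i, 0], fib[i, 1], fib[i, 2]
        for attempt in range(max_retries + 1):
            dy = rng.uniform(-amplitude, amplitude)
            dz = rng.uniform(-amplitude, amplitude)
            y, z = y0 + dy, z0 + dz
            if not (-W / 2 + r <= y <= W / 2 - r and -H / 2 + r <= z <= H / 2 - r):
                continue
            d2 = (fib[:, 0] - y) ** 2 + (fib[:, 1] - z) ** 2
            rr = (fib[:, 2] + r) ** 2
            d2[i] = np.inf
            if np.all(d2 >= rr):
                fib[i, 0], fib[i, 1] = y, z
                break
        else:
            raise PackingError(
                f"could not resolve overlap for fibril {i} after "
                f"{max_retries} retries"
            )
    return replace(model, fibrils=fib)


def assign_polarity(model: FibrilModel, mode: PolarityMode, seed: int) -> FibrilModel:
    """Assign +-1 polarities: all +1, i.i.d. random, or lattice checkerboard."""
    n = model.n_fibrils
    if mode == "aligned":
        pol = np.ones(n)
    elif mode == "random":
        rng = np.random.default_rng(seed)
        pol = rng.choice([-1.0, 1.0], size=n)
    elif mode == "alternating":
        if model.lattice_index is None:
            raise ValueError("alternating polarity requires a lattice model")
        pol = np.where((model.lattice_index.sum(axis=1) % 2) == 0, 1.0, -1.0)
    else:
        raise ValueError(f"unknown polarity mode {mode!r}")
    return model.with_polarity(pol)


def voxelize(
    model: FibrilModel, grid_dims: tuple[int, int, int] = (100, 100, 300)
) -> VoxelVolume:
    """Rasterize a fibril model by centre-inclusion.

    Each voxel takes the polarity of the fibril whose cross-section disk
    contains the voxel centre (0 in the background).  Since fibrils span the
    box along x the field is constant along that axis.
    """
    if any(n <= 0 for n in grid_dims):
        raise ValueError("grid_dims must be positive")
    L, W, H = model.box
    Nx, Ny, Nz = grid_dims
    py, pz = W / Ny, H / Nz
    if model.n_fibrils and max(py, pz) > float(np.min(model.fibrils[:, 2])):
        warnings.warn(
            "voxel pitch exceeds the smallest fibril radius; the rasterized "
            "fill will be inaccurate (the spectral path uses exact geometry)",
            stacklevel=2,
        )
    yc = (np.arange(Ny) + 0.5) * py - W / 2.0
    zc = (np.arange(Nz) + 0.5) * pz - H / 2.0
    cross = np.zeros((Ny, Nz))
    for cy, cz, r, pol in model.fibrils:
        iy0 = max(0, int((cy - r + W / 2) / py) - 1)
        iy1 = min(Ny, int((cy + r + W / 2) / py) + 2)
        iz0 = max(0, int((cz - r + H / 2) / pz) - 1)
        iz1 = min(Nz, int((cz + r + H / 2) / pz) + 2)
        yy = yc[iy0:iy1, None] - cy
        zz = zc[None, iz0:iz1] - cz
        mask = yy**2 + zz**2 <= r**2
        sub = cross[iy0:iy1, iz0:iz1]
        sub[mask] = pol
    values = np.broadcast_to(cross[None, :, :], (Nx, Ny, Nz)).copy()
    return VoxelVolume(values=values, box=model.box)


def focal_window_1d(coords: np.ndarray, waist: float, a: float) -> np.ndarray:
    """One axis of the separable focal window exp(-a u^2 / w^2)."""
    return np.exp(-a * coords**2 / waist**2)


def apply_focal_window(
    vol: VoxelVolume, geom: BeamGeometry, mode: Literal["field", "squared"] = "field"
) -> VoxelVolume:
    """Multiply by the Gaussian focal envelope centred on the box.

    ``mode="field"`` uses the fundamental field envelope (a = 1, matching
    E_w); ``mode="squared"`` uses the squared-field envelope (a = 2,
    matching E_w^2).  Windowing twice is a state error.
    """
    if vol.windowed:
        raise ValueError("volume is already windowed")
    a = {"field": 1.0, "squared": 2.0}[mode]
    wx = focal_window_1d(vol.axis_coords(0), geom.w_rho, a)
    wy = focal_window_1d(vol.axis_coords(1), geom.w_rho, a)
    wz = focal_window_1d(vol.axis_coords(2), geom.w_z, a)
    values = vol.values * wx[:, None, None] * wy[None, :, None] * wz[None, None, :]
    return VoxelVolume(
        values=values,
        box=vol.box,
        windowed=True,
        window_a=a,
        lambda_window=geom.lambda_fund,
    )


# ---------------------------------------------------------------------------
# Periodic validation fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrismLattice:
    """Rectangular-prism motif on a rectangular lattice (validation fixture).

    ``periods`` and ``motif`` are (x, y, z) in nm; sites are centred in the
    box with ``counts`` sites per axis.  The structure value is +1 inside a
    prism, 0 outside.
    """

    box: tuple[float, float, float]
    motif: tuple[float, float, float] = (100.0, 100.0, 100.0)
    periods: tuple[float, float, float] = (350.0, 350.0, 350.0)

    def centers(self, axis: int) -> np.ndarray:
        b, a = self.box[axis], self.periods[axis]
        n = max(1, int(math.floor(b / a)))
        return (np.arange(n) - (n - 1) / 2.0) * a

    def edges(self, axis: int) -> np.ndarray:
        """Sorted prism face coordinates along ``axis`` (jump locations)."""
        c = self.centers(axis)
        m = self.motif[axis] / 2.0
        return np.sort(np.concatenate([c - m, c + m]))


def prism_lattice_volume(
    lattice: PrismLattice, grid_dims: tuple[int, int, int]
) -> VoxelVolume:
    """Voxelize a prism lattice by centre-inclusion (value 1 inside prisms)."""
    masks = []
    for axis, n in enumerate(grid_dims):
        b = lattice.box[axis]
        u = (np.arange(n) + 0.5) * (b / n) - b / 2.0
        c = lattice.centers(axis)
        m = lattice.motif[axis] / 2.0
        masks.append(np.any(np.abs(u[:, None] - c[None, :]) <= m, axis=1))
    values = (
        masks[0][:, None, None] & masks[1][None, :, None] & masks[2][None, None, :]
    ).astype(float)
    return VoxelVolume(values=values, box=lattice.box)


@dataclass(frozen=True)
class SquareWave1D:
    """1D square wave centred on z = 0: +1 pulses of ``width`` on ``period``.

    The profile is +1 for |z - j*period| <= width/2 (any integer j) and -1
    elsewhere, truncated to [-length/2, length/2].
    """

    width: float = 200.0
    period: float = 400.0
    length: float = 7566.6  # 6 x the 800 nm axial waist by default

    def sample(self, z: np.ndarray) -> np.ndarray:
        frac = np.abs(((np.asarray(z) + self.period / 2) % self.period) - self.period / 2)
        return np.where(frac <= self.width / 2.0, 1.0, -1.0)

    def boundaries(self) -> np.ndarray:
        """Interior discontinuity coordinates, sorted."""
        half = self.length / 2.0
        jmax = int(math.ceil(half / self.period)) + 1
        j = np.arange(-jmax, jmax + 1)
        edges = np.concatenate([j * self.period - self.width / 2,
                                j * self.period + self.width / 2])
        edges = np.sort(edges)
        return edges[(edges > -half) & (edges < half)]

    def pieces(self) -> list[tuple[float, float, float]]:
        """(a, b, value) intervals covering [-length/2, length/2]."""
        half = self.length / 2.0
        pts = np.concatenate([[-half], self.boundaries(), [half]])
        out = []
        for a, b in zip(pts[:-1], pts[1:]):
            mid = 0.5 * (a + b)
            out.append((float(a), float(b), float(self.sample(np.array(mid)))))
        return out


def square_wave_volume(wave: SquareWave1D, n_samples: int = 300) -> VoxelVolume:
    """Sample a 1D square wave as a (1, 1, Nz) voxel volume."""
    vol = VoxelVolume(
        values=np.zeros((1, 1, n_samples)),
        box=(1.0, 1.0, wave.length),
    )
    vol.values[0, 0, :] = wave.sample(vol.axis_coords(2))
    return vol
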