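"""Density maps: simulation from models, cross-correlation, rigid-body fitting.

Maps are regular isotropic grids with a world-space origin (the centre of
voxel ``[0,0,0]``); the array is indexed ``grid[ix, iy, iz]``.  MRC/CCP4 file
handling goes through :mod:`gemmi`, with axis order normalised to X,Y,Z on
read.

Simulated density is a sum of per-atom isotropic Gaussians with
σ = resolution × sigma_factor.  The default ``sigma_factor = 1/(π·√2)``
matches the convention of the common interactive visualisation tools, so
cross-correlations are comparable with values computed there.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import RigidTransform, angle_axis_of, rotation_matrix
from .structio import Structure

__all__ = [
    "SIGMA_FACTOR",
    "DensityMap",
    "FitResult",
    "read_map",
    "write_map",
    "simulate_map",
    "cross_correlation",
    "rigid_fit",
    "coverage",
]

SIGMA_FACTOR = 1.0 / (np.pi * np.sqrt(2.0))  # ≈ 0.2251
_TRUNC_SIGMA = 4.5  # Gaussians truncated here; <0.1% of mass lost


@dataclasses.dataclass
class DensityMap:
    """Regular 3D grid of density values on an isotropic lattice."""

    grid: np.ndarray  # (nx, ny, nz)
    voxel_size: float  # Å
    origin: np.ndarray  # world coordinate of voxel (0,0,0) centre, Å
    contour: float | None = None

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=np.float64)
        if grid.ndim != 3 or min(grid.shape) < 2:
            raise ValueError("grid must be 3D with at least 2 voxels per axis")
        if not np.all(np.isfinite(grid)):
            raise ValueError("grid contains non-finite values")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        self.grid = grid
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def world_max(self) -> np.ndarray:
        """World coordinate of the last voxel centre."""
        return self.origin + (np.array(self.shape) - 1) * self.voxel_size

    def interpolate(self, points: np.ndarray, order: int = 1) -> np.ndarray:
        """Trilinear interpolation at world-space points; 0 outside the grid."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        frac = (points - self.origin) / self.voxel_size
        return map_coordinates(self.grid, frac.T, order=order, mode="constant", cval=0.0)

    def center_of_mass(self) -> np.ndarray:
        """Intensity-weighted centroid (negative values clipped to zero)."""
        w = np.clip(self.grid, 0.0, None)
        total = w.sum()
        if total == 0:
            raise ValueError("map has no positive density")
        idx = np.indices(self.shape).reshape(3, -1)
        com_idx = (idx * w.reshape(1, -1)).sum(axis=1) / total
        return self.origin + com_idx * self.voxel_size


@dataclasses.dataclass
class FitResult:
    """Best rigid placement of a model in a map and its cross-correlation."""

    transform: RigidTransform
    cc: float
    n_evaluations: int
    trace: list[tuple[int, float]]  # (evaluation count, best-so-far cc)


def read_map(path: str | Path, voxel_size_override: float | None = None) -> DensityMap:
    """Read an MRC/CCP4 map, normalising axis order to X,Y,Z.

    ``voxel_size_override`` replaces the header voxel size, e.g. to honour a
    recalibrated pixel size on deposited reconstructions.
    """
    path = Path(path)
    try:
        m = gemmi.read_ccp4_map(str(path), setup=True)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as MRC/CCP4: {exc}") from exc
    grid = np.array(m.grid, copy=True, dtype=np.float64)
    spacing = np.array(m.grid.spacing)
    if spacing.min() <= 0:
        raise ValueError(f"{path}: non-positive voxel size")
    if (spacing.max() - spacing.min()) / spacing.mean() > 1e-3:
        raise ValueError(f"{path}: anisotropic voxel size {spacing} not supported")
    voxel = float(spacing.mean())
    origin = np.array([m.header_float(w) for w in (50, 51, 52)], dtype=float)
    if np.allclose(origin, 0.0):
        # CCP4-style start offsets (in grid units) as fallback origin
        start = np.array([m.header_i32(w) for w in (5, 6, 7)], dtype=float)
        origin = start * voxel
    if voxel_size_override is not None:
        origin = origin * (voxel_size_override / voxel)
        voxel = float(voxel_size_override)
    return DensityMap(grid, voxel, origin)


def write_map(m: DensityMap, path: str | Path) -> None:
    """Write a map as MRC/CCP4 (mode 2, P1, origin in the MRC origin fields)."""
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(m.grid, dtype=np.float32))
    nx, ny, nz = m.shape
    v = m.voxel_size
    ccp4.grid.unit_cell = gemmi.UnitCell(nx * v, ny * v, nz * v, 90, 90, 90)
    ccp4.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    ccp4.update_ccp4_header()
    for w, val in zip((50, 51, 52), m.origin):
        ccp4.set_header_float(w, float(val))
    ccp4.write_ccp4_map(str(path))


def _atom_amplitudes(s: Structure, model: int = 0) -> np.ndarray:
    """Per-atom Gaussian amplitude ∝ atomic number (carbon fallback)."""
    amps = []
    for a in s.atoms(model):
        z = gemmi.Element(a.element).atomic_number if a.element else 0
        amps.append(float(z) if z > 0 else 6.0)
    return np.array(amps)


def _splat(
    grid: np.ndarray,
    origin: np.ndarray,
    voxel: float,
    coords: np.ndarray,
    amps: np.ndarray,
    sigma: float,
) -> None:
    """Accumulate truncated atom Gaussians onto a grid in place."""
    r = _TRUNC_SIGMA * sigma
    nvox = int(np.ceil(r / voxel))
    shape = grid.shape
    for pos, amp in zip(coords, amps):
        center = (pos - origin) / voxel
        lo = np.maximum(np.ceil(center - nvox).astype(int), 0)
        hi = np.minimum(np.floor(center + nvox).astype(int), np.array(shape) - 1)
        if np.any(lo > hi):
            continue
        ax = [np.arange(lo[d], hi[d] + 1) * voxel + origin[d] - pos[d] for d in range(3)]
        d2 = (
            ax[0][:, None, None] ** 2
            + ax[1][None, :, None] ** 2
            + ax[2][None, None, :] ** 2
        )
        grid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] += amp * np.exp(
            -d2 / (2.0 * sigma * sigma)
        )


def simulate_map(
    s: Structure,
    resolution: float,
    voxel_size: float | None = None,
    pad: float | None = None,
    sigma_factor: float = SIGMA_FACTOR,
    model: int = 0,
) -> DensityMap:
    """Simulate density from a model as a sum of per-atom Gaussians.

    σ = resolution × sigma_factor; amplitude ∝ atomic number (uniform carbon
    for Cα-only models).  Grid bounds are the model bounding box plus ``pad``
    (default 2 × resolution); voxel size defaults to resolution / 3.
    """
    if voxel_size is None:
        voxel_size = resolution / 3.0
    if pad is None:
        pad = 2.0 * resolution
    if resolution <= 2.0 * voxel_size:
        raise ValueError(
            f"resolution {resolution} Å undersampled at voxel size {voxel_size} Å"
        )
    coords = s.coords(model)
    amps = _atom_amplitudes(s, model)
    sigma = resolution * sigma_factor
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = np.maximum(np.ceil((hi - lo) / voxel_size).astype(int) + 1, 2)
    grid = np.zeros(tuple(shape), dtype=np.float64)
    _splat(grid, lo, voxel_size, coords, amps, sigma)
    return DensityMap(grid, float(voxel_size), lo)


def _world_grid(m: DensityMap) -> np.ndarray:
    idx = np.indices(m.shape).reshape(3, -1).T
    return m.origin + idx * m.voxel_size


def cross_correlation(
    a: DensityMap,
    b: DensityMap,
    mask: str = "overlap",
    contour: float | None = None,
) -> float:
    """Pearson correlation of two maps on ``a``'s grid.

    ``b`` is resampled trilinearly onto ``a``'s grid.  ``mask='overlap'``
    correlates voxels of ``a`` lying inside ``b``'s box; ``'above_contour'``
    restricts to voxels where resampled ``b`` ≥ contour (default 1% of the
    resampled maximum), which avoids diluting the score with empty box.
    """
    pts = _world_grid(a)
    b_vals = b.interpolate(pts)
    a_vals = a.grid.reshape(-1)
    if mask == "overlap":
        sel = np.all((pts >= b.origin) & (pts <= b.world_max()), axis=1)
    elif mask == "above_contour":
        level = 0.01 * b_vals.max() if contour is None else contour
        sel = b_vals >= level
    else:
        raise ValueError(f"unknown mask {mask!r}")
    av = a_vals[sel]
    bv = b_vals[sel]
    if av.size < 2 or av.std() == 0 or bv.std() == 0:
        raise ValueError("zero-variance masked region; cannot correlate")
    cc = float(np.corrcoef(av, bv)[0, 1])
    return float(np.clip(cc, -1.0, 1.0))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def _rotation_grid(step_deg: float, max_angle_deg: float = 180.0) -> list[np.ndarray]:
    """Deterministic uniform axis-angle grid including the identity."""
    if step_deg <= 0:
        raise ValueError("rotation step must be positive")
    step_rad = np.deg2rad(step_deg)
    n_axes = max(6, int(np.ceil(4 * np.pi / (step_rad * step_rad))))
    axes = _fibonacci_sphere(n_axes)
    rotations = [np.eye(3)]
    angle = step_deg
    while angle <= max_angle_deg + 1e-9:
        for ax in axes:
            rotations.append(rotation_matrix(ax, angle))
        angle += step_deg
    return rotations


def _model_cc(
    coords: np.ndarray,
    amps: np.ndarray,
    target: DensityMap,
    sigma: float,
) -> float:
    """CC between the target map and a model splatted onto the target grid,
    over voxels where the model density exceeds 1% of its maximum."""
    grid = np.zeros(target.shape, dtype=np.float64)
    _splat(grid, target.origin, target.voxel_size, coords, amps, sigma)
    peak = grid.max()
    if peak <= 0:
        return -1.0  # model entirely outside the box
    sel = grid >= 0.01 * peak
    av = target.grid[sel]
    bv = grid[sel]
    if av.size < 2 or av.std() == 0 or bv.std() == 0:
        return -1.0
    return float(np.corrcoef(av, bv)[0, 1])


def rigid_fit(
    s: Structure,
    m: DensityMap,
    resolution: float,
    search: Mapping | None = None,
    sigma_factor: float = SIGMA_FACTOR,
    model: int = 0,
) -> FitResult:
    """Rigid-body fit of a model into a density map by cross-correlation.

    ``search=None`` refines locally from the identity placement.  Otherwise
    ``search`` holds ``rot_step_deg`` (axis-angle grid step), optionally
    ``max_angle_deg`` (restricting the rotation magnitude), and optionally
    ``trans_range``/``trans_step`` in Å for a translation grid around the
    density-weighted centroid alignment.  The coarse stage is exhaustive and
    deterministic; the best placement is then refined by greedy coordinate
    descent on the true cross-correlation.  The identity placement is always a
    candidate, so the reported CC can never fall below it.
    """
    coords0 = s.coords(model)
    amps = _atom_amplitudes(s, model)
    sigma = resolution * sigma_factor
    center = coords0.mean(axis=0)
    evaluations = 0
    trace: list[tuple[int, float]] = []

    def cc_of(transform: RigidTransform) -> float:
        nonlocal evaluations
        evaluations += 1
        return _model_cc(transform.apply(coords0), amps, m, sigma)

    candidates: list[RigidTransform] = [RigidTransform.identity()]
    if search is not None:
        rot_step = float(search.get("rot_step_deg", 15.0))
        max_angle = float(search.get("max_angle_deg", 180.0))
        trans_range = float(search.get("trans_range", 0.0))
        trans_step = float(search.get("trans_step", m.voxel_size))
        com = m.center_of_mass()
        offsets = [np.zeros(3)]
        if trans_range > 0:
            steps = np.arange(-trans_range, trans_range + 1e-9, trans_step)
            offsets = [
                np.array([dx, dy, dz]) for dx in steps for dy in steps for dz in steps
            ]
        for R in _rotation_grid(rot_step, max_angle):
            # rotate about the model centroid, then align it to the map centroid
            base_t = center - R @ center + (com - center)
            for off in offsets:
                candidates.append(RigidTransform(R, base_t + off))
        if len(candidates) == 1:
            raise ValueError("empty search space")

    best_t = candidates[0]
    best_cc = cc_of(best_t)
    trace.append((evaluations, best_cc))
    for t in candidates[1:]:
        cc = cc_of(t)
        if cc > best_cc + 1e-12:
            best_cc, best_t = cc, t
            trace.append((evaluations, best_cc))

    # greedy local refinement: coordinate descent over rotation/translation
    rot_step = 4.0  # degrees
    trans_step = m.voxel_size
    axes = np.eye(3)
    while rot_step > 0.2 or trans_step > 0.05 * m.voxel_size:
        improved = False
        for ax in axes:
            for sign in (1.0, -1.0):
                R = rotation_matrix(ax, sign * rot_step)
                pivot = best_t.apply(coords0).mean(axis=0)
                delta = RigidTransform(R, pivot - R @ pivot)
                cand = delta.compose(best_t)
                cc = cc_of(cand)
                if cc > best_cc + 1e-12:
                    best_cc, best_t = cc, cand
                    trace.append((evaluations, best_cc))
                    improved = True
        for ax in axes:
            for sign in (1.0, -1.0):
                cand = RigidTransform(
                    best_t.rotation, best_t.translation + sign * trans_step * ax
                )
                cc = cc_of(cand)
                if cc > best_cc + 1e-12:
                    best_cc, best_t = cc, cand
                    trace.append((evaluations, best_cc))
                    improved = True
        if not improved:
            rot_step /= 2.0
            trans_step /= 2.0
    return FitResult(transform=best_t, cc=best_cc, n_evaluations=evaluations, trace=trace)


def coverage(
    s: Structure,
    m: DensityMap,
    contour: float,
    model: int = 0,
) -> tuple[float, dict[tuple[str, int, str], bool]]:
    """Fraction of Cα atoms inside density ≥ contour, with per-residue flags."""
    ca = s.ca_index(model)
    if not ca:
        raise ValueError("structure has no Cα atoms")
    coords = s.coords(model)
    keys = sorted(ca)
    values = m.interpolate(coords[[ca[k] for k in keys]])
    flags = {k: bool(v >= contour) for k, v in zip(keys, values)}
    frac = float(np.mean([flags[k] for k in keys]))
    return frac, flags
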