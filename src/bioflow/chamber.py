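"""Soil-mimicking chamber geometry and channel shear estimates.

Obstacle layouts for microfluidic chambers are derived from a 3D model of
close-packed spheres: an FCC bed of unit spheres, radii perturbed uniformly
to mimic grain-size heterogeneity, cut by an oblique plane, and linearly
scaled so the resulting circular columns span the size range of fine- to
medium-grain sand (80-200 um radius).  Wall shear stress in the rectangular
flow channel is estimated from plane-Poiseuille flow, with a rectangular-duct
series solution available for narrow channels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PackedBed",
    "ChamberLayout",
    "ChannelFlow",
    "DegenerateLayoutError",
    "ObliquePlaneError",
    "pack_spheres",
    "perturb_radii",
    "cross_section",
    "scale_to_physical",
    "wall_shear_stress",
    "generate_soil_layout",
    "DEFAULT_PLANE_NORMAL",
]

#: Default oblique section plane normal (unit-normalized at use); chosen to
#: clear every FCC symmetry-plane family by a wide angular margin.
DEFAULT_PLANE_NORMAL = (1.0, 0.37, 0.22)


class DegenerateLayoutError(ValueError):
    """Raised when fewer than three columns survive scaling/filtering."""


class ObliquePlaneError(ValueError):
    """Raised when a section plane is too close to a lattice symmetry plane."""


@dataclass(frozen=True)
class PackedBed:
    """A bed of spheres on an FCC lattice, in arbitrary units.

    Before perturbation all radii are 1 and nearest-neighbour centre
    distances are exactly 2 (touching spheres).
    """

    centers: np.ndarray  # (n, 3)
    radii: np.ndarray  # (n,)
    arrangement: str = "fcc"

    def __post_init__(self) -> None:
        if self.centers.ndim != 2 or self.centers.shape[1] != 3:
            raise ValueError("centers must be an (n, 3) array")
        if self.radii.shape != (self.centers.shape[0],):
            raise ValueError("radii must be an (n,) array matching centers")
        if np.any(self.radii <= 0):
            raise ValueError("sphere radii must be positive")

    @property
    def n_spheres(self) -> int:
        return self.centers.shape[0]


@dataclass(frozen=True)
class ChamberLayout:
    """Physical chamber with circular columns; all lengths in micrometres."""

    width: float
    height: float
    depth: float
    columns: np.ndarray  # (n, 3) rows of (cx_um, cy_um, r_um)

    def __post_init__(self) -> None:
        cols = np.asarray(self.columns, dtype=float)
        object.__setattr__(self, "columns", cols)
        if cols.ndim != 2 or cols.shape[1] != 3:
            raise ValueError("columns must be an (n, 3) array of (cx, cy, r)")

    @property
    def n_columns(self) -> int:
        return self.columns.shape[0]

    @property
    def radii(self) -> np.ndarray:
        return self.columns[:, 2]


@dataclass
class ChannelFlow:
    """Rectangular-channel flow conditions; derived Δp/L and wall shear.

    Parameters are in the units microfluidics people actually use: speeds in
    um/s, channel dimensions in um, viscosity in Pa*s.  Derived quantities
    are SI (Pa, Pa/m).
    """

    mean_speed: float  # um/s
    viscosity: float = 1.0e-3  # Pa*s (water at ~20 C)
    height: float = 75.0  # um
    width: float = 3000.0  # um
    length: float = 10000.0  # um
    model: str = "plane_poiseuille"  # or "rectangular_duct"
    pressure_gradient: float = field(init=False)  # Pa/m, derived
    wall_shear: float = field(init=False)  # Pa, derived

    def __post_init__(self) -> None:
        if self.height <= 0 or self.viscosity <= 0:
            raise ValueError("channel height and viscosity must be positive")
        if self.width <= 0 or self.length <= 0:
            raise ValueError("channel width and length must be positive")
        if self.mean_speed < 0:
            raise ValueError("mean speed must be non-negative")
        if self.model not in ("plane_poiseuille", "rectangular_duct"):
            raise ValueError(f"unknown shear model: {self.model!r}")
        self.pressure_gradient = self._pressure_gradient()
        self.wall_shear = self.pressure_gradient * (self.height * 1e-6) / 2.0

    def _pressure_gradient(self) -> float:
        """Δp/L in Pa/m for the configured model."""
        u = self.mean_speed * 1e-6  # m/s
        h = self.height * 1e-6  # m
        dpdl_plane = 12.0 * self.viscosity * u / h**2
        if self.model == "plane_poiseuille":
            return dpdl_plane
        # Rectangular-duct series (first 20 odd terms): the flow rate through
        # a duct of height H << width W at a given Δp/L exceeds the naive
        # parallel-plate value by the bracketed side-wall correction.
        w = self.width * 1e-6
        correction = 1.0 - sum(
            (192.0 * h) / (math.pi**5 * n**5 * w) * math.tanh(n * math.pi * w / (2.0 * h))
            for n in range(1, 40, 2)
        )
        return dpdl_plane / correction


def pack_spheres(n_per_axis: int, seed: int | None = None) -> PackedBed:
    """Build an FCC bed of touching unit spheres.

    The bed spans ``n_per_axis`` conventional FCC cells along each axis; the
    lattice constant is 2*sqrt(2) so that nearest-neighbour centre distances
    equal 2 (unit spheres in contact).  ``seed`` is accepted for interface
    symmetry with the stochastic steps but the lattice itself is
    deterministic.
    """
    if n_per_axis < 2:
        raise ValueError("n_per_axis must be at least 2")
    m = 2 * n_per_axis
    # FCC = points (u, v, w) on the half-lattice with even coordinate sum.
    u, v, w = np.meshgrid(np.arange(m + 1), np.arange(m + 1), np.arange(m + 1), indexing="ij")
    sites = np.stack([u, v, w], axis=-1).reshape(-1, 3)
    sites = sites[sites.sum(axis=1) % 2 == 0]
    centers = sites.astype(float) * math.sqrt(2.0)  # half-lattice step = a/2 = sqrt(2)
    radii = np.ones(centers.shape[0])
    return PackedBed(centers=centers, radii=radii, arrangement="fcc")


def perturb_radii(
    bed: PackedBed,
    r_min: float = 0.4,
    r_max: float = 1.0,
    seed: int | None = None,
) -> PackedBed:
    """Redraw every sphere radius i.i.d. uniform on [r_min, r_max].

    Emulates grain-size heterogeneity of natural sand/soil; centres are left
    on the lattice, so shrunken spheres simply lose contact.
    """
    if not (0.0 < r_min <= r_max <= 1.0):
        raise ValueError("require 0 < r_min <= r_max <= 1")
    rng = np.random.default_rng(seed)
    radii = rng.uniform(r_min, r_max, size=bed.n_spheres)
    return PackedBed(centers=bed.centers.copy(), radii=radii, arrangement=bed.arrangement)


# Normals of the FCC symmetry-plane families, one representative per
# direction (signs and permutations covered by |cos| below).
_SYMMETRY_NORMALS = np.array(
    [
        [1, 0, 0], [0, 1, 0], [0, 0, 1],
        [1, 1, 0], [1, -1, 0], [1, 0, 1], [1, 0, -1], [0, 1, 1], [0, 1, -1],
        [1, 1, 1], [1, 1, -1], [1, -1, 1], [-1, 1, 1],
    ],
    dtype=float,
)
_SYMMETRY_NORMALS /= np.linalg.norm(_SYMMETRY_NORMALS, axis=1, keepdims=True)


def cross_section(
    bed: PackedBed,
    plane_normal,
    plane_offset: float,
    min_angle_deg: float = 5.0,
) -> np.ndarray:
    """Intersect the bed with an oblique plane; return circles (cx, cy, r).

    The plane is {x : n.x = offset} with unit normal n.  Each sphere whose
    centre lies closer than its radius contributes a circle of radius
    sqrt(r^2 - d^2) at the in-plane projection of its centre.  Planes within
    ``min_angle_deg`` of a {100}/{110}/{111} symmetry plane are rejected:
    symmetric cuts produce regular, non-soil-like column arrays.
    """
    n = np.asarray(plane_normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0.0 or not np.all(np.isfinite(n)):
        raise ValueError("plane_normal must be a finite nonzero 3-vector")
    n = n / norm
    cosines = np.abs(_SYMMETRY_NORMALS @ n)
    angle = math.degrees(math.acos(min(1.0, cosines.max())))
    if angle < min_angle_deg:
        raise ObliquePlaneError(
            f"plane normal {tuple(np.round(n, 4))} lies {angle:.2f} deg from a lattice "
            f"symmetry plane (< {min_angle_deg} deg); choose an oblique plane"
        )
    # In-plane orthonormal basis (e1, e2): deterministic given n.
    helper = np.array([0.0, 0.0, 1.0]) if abs(n[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)

    signed = bed.centers @ n - plane_offset
    cut = np.abs(signed) < bed.radii
    if not np.any(cut):
        return np.empty((0, 3))
    centers = bed.centers[cut]
    proj = centers - np.outer(signed[cut], n)
    r_circ = np.sqrt(bed.radii[cut] ** 2 - signed[cut] ** 2)
    return np.column_stack([proj @ e1, proj @ e2, r_circ])


def scale_to_physical(
    circles: np.ndarray,
    chamber_width: float,
    chamber_height: float,
    r_phys_min: float = 80.0,
    r_phys_max: float = 200.0,
    depth: float = 75.0,
    gap: float = 5.0,
    margin: float = 25.0,
) -> ChamberLayout:
    """Map arbitrary-unit section circles onto a physical chamber (um).

    A single linear scale anchors the largest circle to ``r_phys_max``;
    circles scaling below ``r_phys_min`` or protruding beyond the chamber
    are discarded.  Radius perturbation can leave section circles
    overlapping; any remaining overlap is resolved by shrinking the smaller
    member of the pair until the two are tangent with a ``gap`` um
    clearance (fused columns would not be manufacturable).
    """
    circles = np.asarray(circles, dtype=float)
    if circles.ndim != 2 or circles.shape[1] != 3 or circles.shape[0] < 3:
        raise DegenerateLayoutError("need at least 3 section circles to build a layout")
    s = r_phys_max / circles[:, 2].max()
    scaled = circles * s
    # Shift so the inflated bounding box of the circles sits `margin` um off
    # the chamber walls (columns are free-standing, not wall-embedded).
    scaled[:, 0] -= (scaled[:, 0] - scaled[:, 2]).min() - margin
    scaled[:, 1] -= (scaled[:, 1] - scaled[:, 2]).min() - margin

    inside = (
        (scaled[:, 0] - scaled[:, 2] >= 0.0)
        & (scaled[:, 0] + scaled[:, 2] <= chamber_width)
        & (scaled[:, 1] - scaled[:, 2] >= 0.0)
        & (scaled[:, 1] + scaled[:, 2] <= chamber_height)
    )
    cols = scaled[inside & (scaled[:, 2] >= r_phys_min)]

    # Resolve overlaps by shrinking the smaller circle of each offending
    # pair; circles shrunk below r_phys_min are dropped.
    keep = np.ones(len(cols), dtype=bool)
    changed = True
    while changed:
        changed = False
        idx = np.flatnonzero(keep)
        for a_pos in range(len(idx)):
            for b_pos in range(a_pos + 1, len(idx)):
                a, b = idx[a_pos], idx[b_pos]
                d = math.hypot(cols[a, 0] - cols[b, 0], cols[a, 1] - cols[b, 1])
                if d >= cols[a, 2] + cols[b, 2] + gap:
                    continue
                small = a if cols[a, 2] <= cols[b, 2] else b
                big = b if small == a else a
                new_r = d - cols[big, 2] - gap
                if new_r < r_phys_min:
                    keep[small] = False
                else:
                    cols[small, 2] = new_r
                changed = True
    cols = cols[keep]
    if len(cols) < 3:
        raise DegenerateLayoutError(
            f"only {len(cols)} columns survive scaling/filtering; "
            "enlarge the chamber or the source bed"
        )
    return ChamberLayout(width=chamber_width, height=chamber_height, depth=depth, columns=cols)


def wall_shear_stress(flow: ChannelFlow) -> float:
    """Wall shear stress tau = (Δp/L)(H/2) in Pa, evaluated at the channel floor.

    In the plane-Poiseuille (parallel-plate) limit this reduces to
    tau = 6*alpha*U/H, linear in the mean speed U.
    """
    return flow.wall_shear


def generate_soil_layout(
    n_per_axis: int = 6,
    seed: int | None = None,
    chamber_width: float = 4000.0,
    chamber_height: float = 2000.0,
    r_phys_min: float = 80.0,
    r_phys_max: float = 200.0,
    depth: float = 75.0,
    r_min: float = 0.4,
    r_max: float = 1.0,
    plane_normal=DEFAULT_PLANE_NORMAL,
    plane_offset: float | None = None,
) -> ChamberLayout:
    """End-to-end layout generation: pack, perturb, section, scale.

    One integer ``seed`` governs all randomness (the radius perturbation);
    the default plane cuts through the middle of the bed.
    """
    bed = pack_spheres(n_per_axis, seed=seed)
    bed = perturb_radii(bed, r_min=r_min, r_max=r_max, seed=seed)
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    if plane_offset is None:
        plane_offset = float(bed.centers.mean(axis=0) @ n)
    circles = cross_section(bed, n, plane_offset)
    return scale_to_physical(
        circles,
        chamber_width=chamber_width,
        chamber_height=chamber_height,
        r_phys_min=r_phys_min,
        r_phys_max=r_phys_max,
        depth=depth,
    )
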