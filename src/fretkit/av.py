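"""Accessible-volume (AV) dye model and the R_<E> -> R_MP lookup table.

A dye tethered to a biomolecule by a flexible linker samples a cloud of
sterically allowed positions.  This module computes such clouds with a
single-radius dye sphere on a regular grid (linker length L limits the
reach, obstacle spheres model the biomolecule surface, and a flood fill
from the attachment point removes unreachable pockets), gives the
mean-position distance R_MP between two clouds, and builds the lookup table
that converts the measured apparent distance R_<E> -- an efficiency-averaged
quantity -- into the physical mean-position distance R_MP for defined AVs
and R0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.interpolate import PchipInterpolator
from scipy.spatial.distance import cdist

from .forster import distance_from_efficiency, mean_efficiency_positions


class BuriedAttachmentError(RuntimeError):
    """No sterically allowed dye position is reachable from the attachment."""


class LookupRangeError(ValueError):
    """Requested R_<E> lies outside the tabulated range (extrapolation refused)."""


@dataclass
class ObstacleSet:
    """Spheres (centers Å, radii Å) standing in for the biomolecule surface."""

    centers: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if self.centers.shape[0] != self.radii.shape[0]:
            raise ValueError("one radius per center required")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be > 0")


@dataclass
class AccessibleVolume:
    """Weighted 3-D point cloud of allowed dye positions (Å)."""

    points: np.ndarray
    weights: np.ndarray = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.weights is None:
            self.weights = np.full(len(self.points), 1.0 / len(self.points))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights < 0) or self.weights.sum() <= 0:
                raise ValueError("weights must be nonnegative with positive sum")
            self.weights = self.weights / self.weights.sum()

    @property
    def mean_position(self) -> np.ndarray:
        return self.weights @ self.points

    def translated(self, shift: np.ndarray) -> "AccessibleVolume":
        return AccessibleVolume(
            self.points + np.asarray(shift, float), self.weights.copy(), dict(self.params)
        )

    def subsample(self, max_points: int = 400) -> "AccessibleVolume":
        """Deterministic strided thinning for pairwise-average computations."""
        n = len(self.points)
        if n <= max_points:
            return self
        idx = np.linspace(0, n - 1, max_points).astype(int)
        return AccessibleVolume(self.points[idx], self.weights[idx], dict(self.params))


def compute_av(
    attachment: np.ndarray,
    linker_length: float,
    linker_width: float = 4.5,
    dye_radius: float = 3.5,
    grid: float = 1.0,
    obstacles: Optional[ObstacleSet] = None,
) -> AccessibleVolume:
    """Single-radius accessible volume on a regular grid.

    Grid nodes within ``linker_length`` of the attachment point that do not
    clash with any obstacle sphere (inflated by ``dye_radius``) and that are
    reachable through a clash-free 6-connected path from the attachment
    (minimum clearance ``linker_width/2`` along the path) form the cloud;
    weights are uniform.  ``grid`` must be <= L/5 for an adequately resolved
    volume.
    """
    attachment = np.asarray(attachment, dtype=float)
    if linker_length <= 0:
        raise ValueError("linker_length must be > 0")
    if grid > linker_length / 5:
        raise ValueError("grid must be <= linker_length/5")
    n_half = int(np.ceil(linker_length / grid))
    axis = np.arange(-n_half, n_half + 1) * grid
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + attachment
    shape = gx.shape
    within = (np.linalg.norm(pts - attachment, axis=1) <= linker_length).reshape(shape)

    if obstacles is not None and len(obstacles.centers):
        dist = cdist(pts, obstacles.centers) - obstacles.radii  # surface clearance
        clearance = dist.min(axis=1).reshape(shape)
    else:
        clearance = np.full(shape, np.inf)

    dye_ok = within & (clearance > dye_radius)
    path_ok = within & (clearance > min(linker_width / 2.0, dye_radius))

    # flood fill from the attachment node through the passable region
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, _ = ndimage.label(path_ok, structure=structure)
    center = (n_half, n_half, n_half)
    seed_label = labels[center]
    if seed_label == 0:
        # attachment node itself blocked (on the biomolecule surface): seed
        # from the nearest passable node the linker base could still reach
        idx = np.argwhere(path_ok)
        if idx.size == 0:
            raise BuriedAttachmentError("no passable grid node near the attachment")
        d = np.linalg.norm(idx - np.array(center), axis=1) * grid
        reach = max(2.0 * grid, dye_radius + linker_width)
        if d.min() > reach:
            raise BuriedAttachmentError("attachment point is buried")
        seed_label = labels[tuple(idx[np.argmin(d)])]
    reached = labels == seed_label
    allowed = reached & dye_ok
    if not allowed.any():
        raise BuriedAttachmentError("accessible volume is empty")
    cloud = pts[allowed.ravel()]
    return AccessibleVolume(
        cloud,
        params={
            "attachment": attachment.tolist(),
            "linker_length": linker_length,
            "linker_width": linker_width,
            "dye_radius": dye_radius,
            "grid": grid,
        },
    )


def sphere_av(center: np.ndarray, radius: float, grid: float = 1.0) -> AccessibleVolume:
    """Analytic spherical AV -- the useful assumption for unknown structures."""
    center = np.asarray(center, dtype=float)
    if radius <= 0:
        raise ValueError("radius must be > 0")
    n_half = int(np.ceil(radius / grid))
    axis = np.arange(-n_half, n_half + 1) * grid
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= radius]
    return AccessibleVolume(pts + center, params={"sphere_radius": radius, "grid": grid})


def mp_distance(av_D: AccessibleVolume, av_A: AccessibleVolume) -> float:
    """R_MP = |<R_D> - <R_A>|: distance between the cloud centroids (Å)."""
    return float(np.linalg.norm(av_D.mean_position - av_A.mean_position))


@dataclass
class LookupTable:
    """Monotone R_<E> -> R_MP conversion for a fixed AV pair and R0."""

    r_mp: np.ndarray
    r_e: np.ndarray
    r0: float
    _interp: PchipInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        order = np.argsort(self.r_e)
        self.r_e = self.r_e[order]
        self.r_mp = self.r_mp[order]
        if np.any(np.diff(self.r_e) <= 0):
            keep = np.r_[True, np.diff(self.r_e) > 0]
            self.r_e, self.r_mp = self.r_e[keep], self.r_mp[keep]
        self._interp = PchipInterpolator(self.r_e, self.r_mp, extrapolate=False)

    def rmp(self, r_e: float) -> float:
        if not (self.r_e[0] <= r_e <= self.r_e[-1]):
            raise LookupRangeError(
                f"R_<E> = {r_e:.2f} Å outside table range "
                f"[{self.r_e[0]:.2f}, {self.r_e[-1]:.2f}] Å"
            )
        return float(self._interp(r_e))


def build_lookup_table(
    av_D: AccessibleVolume,
    av_A: AccessibleVolume,
    r0: float,
    separations: Optional[np.ndarray] = None,
    max_points: int = 400,
) -> LookupTable:
    """Sweep rigid-body separations of the AV pair and tabulate R_<E>(R_MP).

    Both clouds are centered on their mean positions and the acceptor cloud
    is translated along one axis to each separation s (0.5 Å default
    resolution over 0.3..1.9 R0); at each s the pairwise efficiency average
    gives R_<E> while R_MP = s by construction.  Monotone cubic (PCHIP)
    interpolation inverts the sweep.
    """
    if separations is None:
        separations = np.arange(0.3 * r0, 1.9 * r0, 0.5)
    d0 = av_D.subsample(max_points)
    a0 = av_A.subsample(max_points)
    d_pts = d0.points - d0.mean_position
    a_pts = a0.points - a0.mean_position
    r_e = np.empty_like(separations, dtype=float)
    for i, s in enumerate(separations):
        shift = np.array([s, 0.0, 0.0])
        e_mean = mean_efficiency_positions(
            d_pts, a_pts + shift, r0, d0.weights, a0.weights
        )
        r_e[i] = distance_from_efficiency(e_mean, r0)
    return LookupTable(r_mp=np.asarray(separations, float), r_e=r_e, r0=r0)


def rmp_from_re(
    r_e: float,
    av_D: AccessibleVolume,
    av_A: AccessibleVolume,
    r0: float,
    table: Optional[LookupTable] = None,
) -> float:
    """Convert a measured apparent distance R_<E> to the physical R_MP.

    Point-like AVs give R_MP = R_<E> identically; extended clouds make
    R_<E> a biased (efficiency-averaged) estimate, and the lookup table
    built from the AV pair removes that bias.  A prebuilt ``table`` can be
    reused across calls.
    """
    if table is None:
        table = build_lookup_table(av_D, av_A, r0)
    return table.rmp(r_e)
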