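"""Grid-based accessible volume (AV) of a dye tethered to the DNA.

The dye is modeled as a single sphere on a flexible linker attached at
the labeled base.  A grid point belongs to the AV if a geodesic path of
adjacent unblocked grid nodes, no longer than the linker length, connects
it to the attachment point, where traversal requires linker-width
clearance from every obstacle pseudo-atom and the end point additionally
requires dye-radius clearance.  The pseudo-atoms of the labeled
nucleotide and its two sequence neighbors anchor the linker and are not
treated as obstacles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .dna_models import ROLE_B, ROLE_P, ROLE_S, StructureModel

# coarse-grain obstacle envelope per pseudo-atom role (Å)
OBSTACLE_RADIUS = {ROLE_P: 3.0, ROLE_S: 3.0, ROLE_B: 3.5}

# offset of the attachment point from the labeled base centroid,
# toward the major groove (Å)
ATTACHMENT_OFFSET = 2.0


class AccessibleVolumeError(RuntimeError):
    pass


@dataclass(frozen=True)
class DyeParameters:
    """Single-sphere dye on a flexible linker.

    Defaults are a calibrated stand-in for the short C2-linked dyes used
    on the dumbbell ligand (the attachment chemistry fixes only the order
    of magnitude); they are plain constructor arguments and can be
    overridden per dye.
    """

    linker_length: float = 14.0  # Å, maximum geodesic path length
    linker_width: float = 4.5    # Å, linker diameter (path clearance)
    dye_radius: float = 3.5      # Å (end-point clearance)
    name: str = "dye"

    def __post_init__(self):
        if min(self.linker_length, self.linker_width, self.dye_radius) <= 0:
            raise ValueError("all dye dimensions must be > 0")
        if self.linker_width > 2 * self.linker_length:
            raise ValueError("linker_width must be <= 2 * linker_length")


@dataclass
class AccessibleVolume:
    """Point cloud of positions the dye center can reach."""

    grid_spacing: float
    points: np.ndarray            # (N, 3) Å
    attachment_point: np.ndarray  # (3,)
    mean_position: np.ndarray     # (3,)
    principal_axis: np.ndarray    # (3,) unit, points away from the structure
    occupancy: np.ndarray         # 3D bool grid for fast membership tests
    origin: np.ndarray            # (3,) coordinate of grid node [0,0,0]

    @property
    def volume(self) -> float:
        """Volume in Å^3 (node count x spacing^3)."""
        return len(self.points) * self.grid_spacing ** 3

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        """Vectorized membership test (nearest-node rounding)."""
        idx = np.rint((np.atleast_2d(xyz) - self.origin)
                      / self.grid_spacing).astype(np.int64)
        shape = np.array(self.occupancy.shape)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        out = np.zeros(len(idx), dtype=bool)
        if ok.any():
            sel = idx[ok]
            out[ok] = self.occupancy[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out


# neighbor offsets up to Chebyshev radius 3 with coprime components;
# the extended shell keeps the grid-geodesic metric within ~1% of
# Euclidean (26-neighbor chamfer alone overestimates by up to ~8%,
# biasing the AV volume several percent low)
def _neighbor_offsets(radius: int = 3) -> tuple[np.ndarray, np.ndarray]:
    offs, costs = [], []
    for dx in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            for dz in range(-radius, radius + 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                if math.gcd(math.gcd(abs(dx), abs(dy)), abs(dz)) != 1:
                    continue
                offs.append((dx, dy, dz))
                costs.append(math.sqrt(dx * dx + dy * dy + dz * dz))
    return np.array(offs, dtype=np.int64), np.array(costs)


_OFFSETS, _COSTS = _neighbor_offsets()


@njit(cache=True)
def _grid_dijkstra(traversable, start, offsets, costs, max_len):
    """Geodesic distances from ``start`` over traversable nodes.

    Plain binary-heap Dijkstra on the 3D grid; distances beyond
    ``max_len`` are left at +inf.
    """
    nx, ny, nz = traversable.shape
    n = nx * ny * nz
    dist = np.full(n, np.inf)
    s = (start[0] * ny + start[1]) * nz + start[2]
    dist[s] = 0.0
    # binary heap of (distance, node)
    heap_d = np.empty(n * 4, dtype=np.float64)
    heap_i = np.empty(n * 4, dtype=np.int64)
    heap_d[0] = 0.0
    heap_i[0] = s
    hn = 1
    while hn > 0:
        d0 = heap_d[0]
        u = heap_i[0]
        hn -= 1
        heap_d[0] = heap_d[hn]
        heap_i[0] = heap_i[hn]
        # sift down
        i = 0
        while True:
            l = 2 * i + 1
            r = l + 1
            m = i
            if l < hn and heap_d[l] < heap_d[m]:
                m = l
            if r < hn and heap_d[r] < heap_d[m]:
                m = r
            if m == i:
                break
            heap_d[i], heap_d[m] = heap_d[m], heap_d[i]
            heap_i[i], heap_i[m] = heap_i[m], heap_i[i]
            i = m
        if d0 > dist[u]:
            continue
        ux = u // (ny * nz)
        uy = (u // nz) % ny
        uz = u % nz
        for k in range(offsets.shape[0]):
            vx = ux + offsets[k, 0]
            vy = uy + offsets[k, 1]
            vz = uz + offsets[k, 2]
            if vx < 0 or vx >= nx or vy < 0 or vy >= ny or vz < 0 or vz >= nz:
                continue
            if not traversable[vx, vy, vz]:
                continue
            nd = d0 + costs[k]
            if nd > max_len:
                continue
            v = (vx * ny + vy) * nz + vz
            if nd < dist[v]:
                dist[v] = nd
                # sift up
                heap_d[hn] = nd
                heap_i[hn] = v
                j = hn
                hn += 1
                while j > 0:
                    p = (j - 1) // 2
                    if heap_d[p] <= heap_d[j]:
                        break
                    heap_d[p], heap_d[j] = heap_d[j], heap_d[p]
                    heap_i[p], heap_i[j] = heap_i[j], heap_i[p]
                    j = p
    return dist.reshape((nx, ny, nz))


def attachment_point(model: StructureModel, site: int) -> np.ndarray:
    """Dye attachment: labeled base centroid offset toward the major groove.

    The major-groove direction is taken as the in-plane unit vector from
    the midpoint of the two backbone phosphates of the labeled base pair
    through the base-pair center (rotation-invariant, so it is valid for
    every ensemble member).
    """
    partner = None
    for i, j in model.design.pairings:
        if site == i:
            partner = j
        elif site == j:
            partner = i
    if partner is None:
        raise ValueError(f"label site {site} is not base-paired")
    b1 = model.atom_coord(site, ROLE_B)
    b2 = model.atom_coord(partner, ROLE_B)
    p1 = model.atom_coord(site, ROLE_P)
    p2 = model.atom_coord(partner, ROLE_P)
    center = 0.5 * (b1 + b2)
    u = center - 0.5 * (p1 + p2)
    u /= np.linalg.norm(u)
    return b1 + ATTACHMENT_OFFSET * u


def _obstacles(model: StructureModel, site: int
               ) -> tuple[np.ndarray, np.ndarray]:
    """Obstacle coordinates and radii, excluding the anchor nucleotides."""
    excluded = {site - 1, site, site + 1}
    keep = ~np.isin(model.nuc_index, sorted(excluded))
    radii = np.array([OBSTACLE_RADIUS[r] for r in model.role[keep]])
    return model.coords[keep], radii


def compute_av(model: StructureModel, site: int,
               dye: DyeParameters = DyeParameters(),
               grid_spacing: float = 1.0) -> AccessibleVolume:
    """Accessible volume of a dye attached at the given nucleotide."""
    attach = attachment_point(model, site)
    coords, radii = _obstacles(model, site)
    return av_from_obstacles(attach, coords, radii, dye, grid_spacing,
                             orientation_reference=model.coords.mean(axis=0),
                             label=f"site {site}")


def av_from_obstacles(attach: np.ndarray, coords: np.ndarray,
                      radii: np.ndarray,
                      dye: DyeParameters = DyeParameters(),
                      grid_spacing: float = 1.0,
                      orientation_reference: np.ndarray | None = None,
                      label: str = "attachment") -> AccessibleVolume:
    """Accessible volume from an explicit obstacle list (the geometric
    core of :func:`compute_av`, also usable for synthetic geometries)."""
    if grid_spacing > dye.linker_width:
        raise ValueError("grid_spacing must be <= linker_width")
    attach = np.asarray(attach, dtype=float)
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float).reshape(-1)

    half = dye.linker_length + grid_spacing
    nside = int(math.ceil(2 * half / grid_spacing)) + 1
    origin = attach - (nside - 1) / 2 * grid_spacing
    ax = origin[0] + grid_spacing * np.arange(nside)
    ay = origin[1] + grid_spacing * np.arange(nside)
    az = origin[2] + grid_spacing * np.arange(nside)
    gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    # distance from each node to the nearest obstacle *surface*, per
    # radius class
    clearance = np.full(len(nodes), np.inf)
    if len(coords):
        for r in np.unique(radii):
            tree = cKDTree(coords[radii == r])
            d, _ = tree.query(nodes, k=1)
            clearance = np.minimum(clearance, d - r)
    clearance = clearance.reshape((nside, nside, nside))

    traversable = clearance >= dye.linker_width / 2.0
    endpoint_ok = clearance >= dye.dye_radius

    start = np.rint((attach - origin) / grid_spacing).astype(np.int64)
    traversable[start[0], start[1], start[2]] = True  # linker anchor
    dist = _grid_dijkstra(traversable, start, _OFFSETS,
                          _COSTS * grid_spacing, dye.linker_length)
    reachable = np.isfinite(dist)
    occupancy = reachable & endpoint_ok

    if not occupancy.any():
        d_near, i_near = cKDTree(coords).query(attach, k=min(3, len(coords)))
        raise AccessibleVolumeError(
            f"empty AV at {label}: attachment buried; nearest obstacle "
            f"atoms at {np.round(d_near, 2)} Å (rows {np.atleast_1d(i_near).tolist()})"
        )

    idx = np.argwhere(occupancy)
    points = origin + idx * grid_spacing
    mean_position = points.mean(axis=0)
    reference = (attach - np.array([0.0, 0.0, 1.0])
                 if orientation_reference is None else orientation_reference)
    axis = _principal_axis(points, reference=reference, mean=mean_position)
    return AccessibleVolume(
        grid_spacing=grid_spacing,
        points=points,
        attachment_point=attach,
        mean_position=mean_position,
        principal_axis=axis,
        occupancy=occupancy,
        origin=origin,
    )


def _principal_axis(points: np.ndarray, reference: np.ndarray,
                    mean: np.ndarray) -> np.ndarray:
    if len(points) < 2:
        raise AccessibleVolumeError("principal axis undefined for < 2 nodes")
    cov = np.cov((points - mean).T)
    w, v = np.linalg.eigh(cov)
    axis = v[:, -1]
    if np.dot(axis, mean - reference) < 0:
        axis = -axis
    return axis


def av_summary(av: AccessibleVolume
               ) -> tuple[np.ndarray, np.ndarray, float]:
    """(mean_position, principal_axis, volume) of a computed AV."""
    if len(av.points) < 2:
        raise AccessibleVolumeError("principal axis undefined for < 2 nodes")
    return av.mean_position, av.principal_axis, av.volume


def export_xyz(av: AccessibleVolume, path: str, label: str = "AV") -> None:
    """Write the AV point cloud as a plain XYZ file (one pseudo-atom per
    grid node) for visualization."""
    with open(path, "w") as fh:
        fh.write(f"{len(av.points)}\n{label} spacing={av.grid_spacing}\n")
        for p in av.points:
            fh.write(f"D {p[0]:.3f} {p[1]:.3f} {p[2]:.3f}\n")
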