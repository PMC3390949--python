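"""Boolean set operations (difference, intersection, union) on mesh solids.

Two backends are provided behind one interface:

* **rectilinear** — exact constructive solid geometry for solids whose faces
  are all axis-aligned (box unions, nested boxes, lattice cubes).  Space is
  cut into cells by the union of both operands' face planes; every cell is
  entirely inside or outside each operand, so the Boolean is evaluated per
  cell and the boundary re-emitted as an exact axis-aligned mesh.  Volumes
  are exact to floating-point roundoff, including interior voids.

* **voxel** — for curved solids (spheres, isosurfaced cavities): operands are
  scan-line voxelized onto a common grid (default 0.25 Å), the Boolean is
  applied to the occupancy masks, and the result is isosurfaced back to a
  watertight mesh with marching cubes.

The backend is chosen automatically per call: exact whenever every operand is
axis-aligned, grid-based otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .config import Config, DEFAULT_CONFIG
from .mesh_core import MeshSolid, MeshError, signed_volume

log = logging.getLogger(__name__)

__all__ = [
    "BooleanResult",
    "difference",
    "intersection",
    "union_all",
    "is_rectilinear",
    "voxelize_mesh",
    "voxel_count_volume",
]

# irrational fractions used to offset sample points/grids off any
# rational-coordinate structure in the operands
_IRR = (0.6180339887498949, 0.7861513777574233, 0.5436890126920764)


@dataclass(frozen=True)
class BooleanResult:
    """Result of a Boolean set operation; ``solid`` may be empty."""

    solid: MeshSolid
    op: str                  # "difference" | "intersection" | "union"
    operands: tuple[str, ...]
    backend: str             # "rectilinear" | "voxel"

    @property
    def volume(self) -> float:
        return signed_volume(self.solid)

    @property
    def is_empty(self) -> bool:
        return self.solid.is_empty

    def provenance(self) -> dict:
        return {"op": self.op, "operands": list(self.operands), "backend": self.backend}


# ---------------------------------------------------------------------------
# rectilinear (exact) backend
# ---------------------------------------------------------------------------

def is_rectilinear(mesh: MeshSolid, tol: float = 1e-9) -> bool:
    """True if every face normal is parallel to a coordinate axis."""
    if mesh.is_empty:
        return True
    v0 = mesh.vertices[mesh.faces[:, 0]]
    n = np.cross(
        mesh.vertices[mesh.faces[:, 1]] - v0,
        mesh.vertices[mesh.faces[:, 2]] - v0,
    )
    a = np.abs(n)
    nn = np.linalg.norm(n, axis=1)
    if np.any(nn == 0):
        return False
    a = a / nn[:, None]
    # exactly one dominant component, other two ~ zero
    s = np.sort(a, axis=1)
    return bool(np.all(s[:, 1] < tol))


def _dedupe(values: np.ndarray, tol: float) -> np.ndarray:
    values = np.sort(values)
    if len(values) == 0:
        return values
    keep = [values[0]]
    for x in values[1:]:
        if x - keep[-1] > tol:
            keep.append(x)
    return np.array(keep)


def _planes(meshes, tol=1e-9):
    """Union of face-plane coordinates per axis over all operands."""
    axes = []
    for ax in range(3):
        coords = np.concatenate([m.vertices[:, ax] for m in meshes if not m.is_empty])
        axes.append(_dedupe(coords, tol))
    return axes


def _classify_cells(mesh: MeshSolid, xs, ys, zs) -> np.ndarray:
    """Boolean (nx-1, ny-1, nz-1) array: is each cell's interior inside the
    (axis-aligned) mesh?  Classification casts a +x ray from each cell
    center, counting crossings with x-perpendicular faces."""
    nx, ny, nz = len(xs) - 1, len(ys) - 1, len(zs) - 1
    inside = np.zeros((nx, ny, nz), dtype=bool)
    if mesh.is_empty or nx <= 0 or ny <= 0 or nz <= 0:
        return inside
    # sample points: cell centers nudged by an irrational sub-cell offset so
    # they cannot fall on any triangle edge of either operand
    gy = np.min(np.diff(ys)) if ny else 1.0
    gz = np.min(np.diff(zs)) if nz else 1.0
    cy = (ys[:-1] + ys[1:]) / 2 + 1e-3 * gy * (_IRR[0] - 0.5)
    cz = (zs[:-1] + zs[1:]) / 2 + 1e-3 * gz * (_IRR[1] - 0.5)

    v = mesh.vertices
    f = mesh.faces
    tri = v[f]  # (m, 3, 3)
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    nn = np.linalg.norm(n, axis=1)
    perp_x = np.abs(n[:, 0]) > (1 - 1e-9) * nn  # normal parallel to x
    cnt = np.zeros((len(xs), ny, nz), dtype=np.int32)
    for t in np.nonzero(perp_x)[0]:
        px = tri[t, :, 0].mean()
        p = int(np.searchsorted(xs, px))
        if p >= len(xs) or abs(xs[min(p, len(xs) - 1)] - px) > 1e-9:
            p = int(np.argmin(np.abs(xs - px)))
        y0, y1, y2 = tri[t, :, 1]
        z0, z1, z2 = tri[t, :, 2]
        jlo = int(np.searchsorted(cy, min(y0, y1, y2)))
        jhi = int(np.searchsorted(cy, max(y0, y1, y2)))
        klo = int(np.searchsorted(cz, min(z0, z1, z2)))
        khi = int(np.searchsorted(cz, max(z0, z1, z2)))
        if jlo >= jhi or klo >= khi:
            continue
        py = cy[jlo:jhi][:, None]
        pz = cz[klo:khi][None, :]
        d0 = (y1 - y0) * (pz - z0) - (z1 - z0) * (py - y0)
        d1 = (y2 - y1) * (pz - z1) - (z2 - z1) * (py - y1)
        d2 = (y0 - y2) * (pz - z2) - (z0 - z2) * (py - y2)
        hit = ((d0 > 0) & (d1 > 0) & (d2 > 0)) | ((d0 < 0) & (d1 < 0) & (d2 < 0))
        cnt[p, jlo:jhi, klo:khi] += hit
    # cell i (center between planes i and i+1) sees crossings at planes > i
    suffix = np.cumsum(cnt[::-1], axis=0)[::-1]
    inside = (suffix[1:] % 2).astype(bool)
    return inside


def _mesh_from_cells(xs, ys, zs, inside: np.ndarray) -> MeshSolid:
    """Emit the boundary of a set of rectilinear cells as an exact,
    consistently outward-oriented triangle mesh."""
    if not inside.any():
        return MeshSolid.empty()
    nx, ny, nz = inside.shape
    pad = np.zeros((nx + 2, ny + 2, nz + 2), dtype=bool)
    pad[1:-1, 1:-1, 1:-1] = inside
    planes = (np.asarray(xs), np.asarray(ys), np.asarray(zs))
    vid: dict[tuple[int, int, int], int] = {}
    verts: list[tuple[float, float, float]] = []
    tris: list[tuple[int, int, int]] = []

    def vertex(i, j, k) -> int:
        key = (i, j, k)
        idx = vid.get(key)
        if idx is None:
            idx = len(verts)
            vid[key] = idx
            verts.append((planes[0][i], planes[1][j], planes[2][k]))
        return idx

    # cyclic corner pattern giving a +axis normal: (0,0),(1,0),(1,1),(0,1)
    # in the (axis+1, axis+2) plane
    corner_uv = [(0, 0), (1, 0), (1, 1), (0, 1)]
    for axis in range(3):
        moved = np.moveaxis(pad, axis, 0)
        lo, hi = moved[:-1], moved[1:]
        diff = lo != hi
        # after moveaxis the transverse axes keep their original order
        rem = [a for a in range(3) if a != axis]
        u_ax, w_ax = (axis + 1) % 3, (axis + 2) % 3
        for a, b, c in zip(*np.nonzero(diff)):
            positive = lo[a, b, c]  # inside on the low side -> normal +axis
            base = {rem[0]: b - 1, rem[1]: c - 1}
            idx3 = [0, 0, 0]
            idx3[axis] = a  # plane index along axis (face between cells a-1, a)
            quad = []
            for du, dw in corner_uv:
                idx3[u_ax] = base[u_ax] + du
                idx3[w_ax] = base[w_ax] + dw
                quad.append(vertex(*idx3))
            if not positive:
                quad = quad[::-1]
            tris.append((quad[0], quad[1], quad[2]))
            tris.append((quad[0], quad[2], quad[3]))
    return MeshSolid(np.array(verts, dtype=np.float64), np.array(tris, dtype=np.int64))


def _rectilinear_boolean(op: str, meshes: list[MeshSolid]) -> MeshSolid:
    xs, ys, zs = _planes(meshes)
    if min(len(xs), len(ys), len(zs)) < 2:
        return MeshSolid.empty()
    masks = [_classify_cells(m, xs, ys, zs) for m in meshes]
    if op == "difference":
        out = masks[0] & ~masks[1]
    elif op == "intersection":
        out = masks[0] & masks[1]
    elif op == "union":
        out = np.logical_or.reduce(masks)
    else:  # pragma: no cover
        raise ValueError(op)
    return _mesh_from_cells(xs, ys, zs, out)


# ---------------------------------------------------------------------------
# voxel backend
# ---------------------------------------------------------------------------

def voxelize_mesh(
    mesh: MeshSolid,
    origin: np.ndarray,
    spacing: float,
    shape: tuple[int, int, int],
) -> np.ndarray:
    """Scan-line voxelization: occupancy of voxel centers by crossing parity
    of +x columns with the mesh triangles."""
    nx, ny, nz = shape
    occ = np.zeros(shape, dtype=bool)
    if mesh.is_empty:
        return occ
    h = spacing
    # marching-cubes output has vertices exactly on lattice edges, i.e. at
    # column-center (y, z) positions; a tiny fixed offset keeps the sample
    # columns strictly off such vertices (same side of every flat face)
    cy = origin[1] + (np.arange(ny) + 0.5 + 1e-5 * _IRR[0]) * h
    cz = origin[2] + (np.arange(nz) + 0.5 + 1e-5 * _IRR[1]) * h
    cnt = np.zeros((nx + 1, ny, nz), dtype=np.int32)
    tri = mesh.vertices[mesh.faces]
    for t in range(len(tri)):
        (x0, y0, z0), (x1, y1, z1), (x2, y2, z2) = tri[t]
        denom = (y1 - y0) * (z2 - z0) - (z1 - z0) * (y2 - y0)
        scale = max(abs(y1 - y0) + abs(y2 - y0), 1e-30) * max(
            abs(z1 - z0) + abs(z2 - z0), 1e-30
        )
        if abs(denom) < 1e-14 * max(scale, 1e-30):
            continue  # parallel to x: no transversal column crossing
        jlo = int(np.searchsorted(cy, min(y0, y1, y2)))
        jhi = int(np.searchsorted(cy, max(y0, y1, y2)))
        klo = int(np.searchsorted(cz, min(z0, z1, z2)))
        khi = int(np.searchsorted(cz, max(z0, z1, z2)))
        if jlo >= jhi or klo >= khi:
            continue
        py = cy[jlo:jhi][:, None]
        pz = cz[klo:khi][None, :]
        l1 = ((py - y0) * (z2 - z0) - (pz - z0) * (y2 - y0)) / denom
        l2 = ((y1 - y0) * (pz - z0) - (z1 - z0) * (py - y0)) / denom
        l0 = 1.0 - l1 - l2
        ins = (l0 > 0) & (l1 > 0) & (l2 > 0)
        if not ins.any():
            continue
        xhit = l0 * x0 + l1 * x1 + l2 * x2
        ih = np.floor((xhit - origin[0]) / h - 0.5).astype(np.int64) + 1
        ih = np.clip(ih, 0, nx)
        jj, kk = np.nonzero(ins)
        np.add.at(cnt, (ih[ins], jj + jlo, kk + klo), 1)
    occ = (np.cumsum(cnt, axis=0)[:nx] % 2).astype(bool)
    return occ


def _grid_for(meshes, spacing: float):
    bounds = np.array(
        [
            [m.bounds[0] for m in meshes if not m.is_empty],
            [m.bounds[1] for m in meshes if not m.is_empty],
        ]
    )
    lo = bounds[0].min(axis=0) - 2 * spacing
    hi = bounds[1].max(axis=0) + 2 * spacing
    # anchor every grid to the absolute frame so independent voxelizations
    # of solids sharing flat surfaces quantize them identically (otherwise
    # re-voxelized marching-cubes output grows phantom half-voxel slivers);
    # the fixed sub-voxel irrational shift keeps rational-coordinate mesh
    # features (box faces at integers) off the sample lattice
    origin = (np.floor(lo / spacing) - 1 + 1e-4 * np.array(_IRR)) * spacing
    shape = tuple(int(np.ceil((h - o) / spacing)) + 1 for o, h in zip(origin, hi))
    return origin, shape


def _mesh_from_mask(mask: np.ndarray, origin: np.ndarray, spacing: float) -> MeshSolid:
    if not mask.any():
        return MeshSolid.empty()
    pad = np.pad(mask.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(pad, level=0.5, spacing=(spacing,) * 3)
    verts = verts + (origin - spacing) + 0.5 * spacing
    solid = MeshSolid(verts, faces.astype(np.int64))
    if signed_volume(solid) < 0:
        solid = solid.flipped()
    return solid


def _voxel_boolean(op: str, meshes: list[MeshSolid], spacing: float) -> MeshSolid:
    live = [m for m in meshes if not m.is_empty]
    if not live:
        return MeshSolid.empty()
    origin, shape = _grid_for(live, spacing)
    masks = []
    for m in meshes:
        masks.append(
            voxelize_mesh(m, origin, spacing, shape)
            if not m.is_empty
            else np.zeros(shape, dtype=bool)
        )
    if op == "difference":
        out = masks[0] & ~masks[1]
    elif op == "intersection":
        out = masks[0] & masks[1]
    elif op == "union":
        out = np.logical_or.reduce(masks)
    else:  # pragma: no cover
        raise ValueError(op)
    return _mesh_from_mask(out, origin, spacing)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _run(op: str, meshes: list[MeshSolid], names, config: Config) -> BooleanResult:
    names = tuple(names)
    try:
        if all(is_rectilinear(m) for m in meshes):
            solid = _rectilinear_boolean(op, meshes)
            backend = "rectilinear"
        else:
            solid = _voxel_boolean(op, meshes, config.csg_spacing)
            backend = "voxel"
    except MeshError:
        raise
    except Exception as exc:  # noqa: BLE001 - keep operand context
        dump = "; ".join(
            f"{n}: {len(m.vertices)}v/{len(m.faces)}f bounds={m.bounds.tolist()}"
            for n, m in zip(names, meshes)
        )
        raise MeshError(f"CSG {op} failed ({exc}); operands: {dump}") from exc
    return BooleanResult(solid=solid, op=op, operands=names, backend=backend)


def difference(
    A: MeshSolid, B: MeshSolid, config: Config = DEFAULT_CONFIG, names=("A", "B")
) -> BooleanResult:
    """A \\ B: the region inside ``A`` and not inside ``B``."""
    if A.is_empty:
        return BooleanResult(MeshSolid.empty(), "difference", tuple(names), "rectilinear")
    if B.is_empty:
        return BooleanResult(A, "difference", tuple(names), "rectilinear")
    return _run("difference", [A, B], names, config)


def intersection(
    A: MeshSolid, B: MeshSolid, config: Config = DEFAULT_CONFIG, names=("A", "B")
) -> BooleanResult:
    """A ∩ B."""
    if A.is_empty or B.is_empty:
        return BooleanResult(MeshSolid.empty(), "intersection", tuple(names), "rectilinear")
    return _run("intersection", [A, B], names, config)


def union_all(
    solids, config: Config = DEFAULT_CONFIG, names=None
) -> BooleanResult:
    """n-ary Boolean union."""
    solids = list(solids)
    if not solids:
        raise ValueError("union_all requires at least one solid")
    if names is None:
        names = tuple(f"S{i}" for i in range(len(solids)))
    live = [s for s in solids if not s.is_empty]
    if not live:
        return BooleanResult(MeshSolid.empty(), "union", tuple(names), "rectilinear")
    if len(live) == 1:
        return BooleanResult(live[0], "union", tuple(names), "rectilinear")
    return _run("union", live, names, config)


# ---------------------------------------------------------------------------
# voxel oracle helper (used by tests and diagnostics)
# ---------------------------------------------------------------------------

def voxel_count_volume(mesh: MeshSolid, spacing: float) -> float:
    """Brute-force volume estimate: count of occupied voxel centers × h^3."""
    if mesh.is_empty:
        return 0.0
    origin, shape = _grid_for([mesh], spacing)
    occ = voxelize_mesh(mesh, origin, spacing, shape)
    return float(occ.sum()) * spacing**3
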