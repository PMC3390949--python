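"""Watertight triangular-mesh solids and the geometric primitives on them.

A :class:`MeshSolid` is an oriented, closed triangular mesh in Å whose
triangle normals point out of the enclosed solid.  A solid may consist of
several disjoint closed shells; shells bounding interior voids are wound the
opposite way, so the signed-tetrahedron volume sum automatically subtracts
their enclosed space.

The primitives here — enclosed volume by the divergence-theorem (surveyor's)
sum, edge-connected shell decomposition, and ray-crossing parity for point
containment — are the substrate for cavity-difference fragment isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .config import Config, DEFAULT_CONFIG

log = logging.getLogger(__name__)

__all__ = [
    "MeshSolid",
    "ComponentRef",
    "MeshError",
    "NotWatertightError",
    "DegenerateRayError",
    "compute_volume",
    "signed_volume",
    "centroid",
    "repair_mesh",
    "validate_closed",
    "ensure_oriented",
    "random_direction",
    "connected_components",
    "ray_crossings",
    "point_in_component",
    "read_mesh",
    "write_mesh",
]


class MeshError(ValueError):
    """Invalid mesh input."""


class NotWatertightError(MeshError):
    """The mesh is not closed (some edges are not shared by two triangles)."""

    def __init__(self, open_edges):
        self.open_edges = list(map(tuple, open_edges))
        shown = ", ".join(map(str, self.open_edges[:8]))
        more = "" if len(self.open_edges) <= 8 else f" (+{len(self.open_edges) - 8} more)"
        super().__init__(f"mesh is not watertight; open edges: {shown}{more}")


class DegenerateRayError(RuntimeError):
    """A ray hit an edge/vertex or lies in a triangle plane; re-draw it."""


@dataclass(frozen=True)
class MeshSolid:
    """Closed oriented triangular mesh (possibly several disjoint shells)."""

    vertices: np.ndarray  # (n, 3) float64, Å
    faces: np.ndarray     # (m, 3) int64 vertex indices, outward winding

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        f = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    # -- constructors ------------------------------------------------------
    @classmethod
    def empty(cls) -> "MeshSolid":
        return cls(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))

    @classmethod
    def box(cls, lo, hi) -> "MeshSolid":
        """Axis-aligned box [lo, hi] as a 12-triangle mesh, outward normals."""
        lo = np.asarray(lo, float)
        hi = np.asarray(hi, float)
        if np.any(hi <= lo):
            raise MeshError(f"degenerate box {lo}..{hi}")
        tm = trimesh.creation.box(bounds=np.array([lo, hi]))
        return cls(np.array(tm.vertices), np.array(tm.faces))

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "MeshSolid":
        return cls(np.array(tm.vertices, dtype=np.float64), np.array(tm.faces, dtype=np.int64))

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices.copy(), faces=self.faces.copy(), process=False)

    # -- basics ------------------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return len(self.faces) == 0

    @property
    def bounds(self) -> np.ndarray:
        if self.is_empty:
            return np.zeros((2, 3))
        return np.array([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def translated(self, offset) -> "MeshSolid":
        return MeshSolid(self.vertices + np.asarray(offset, float), self.faces)

    def flipped(self) -> "MeshSolid":
        """Reverse the winding of every triangle (negates signed volume)."""
        return MeshSolid(self.vertices, self.faces[:, ::-1])

    @staticmethod
    def concatenate(solids) -> "MeshSolid":
        """Stack several solids into one mesh (shells stay disjoint)."""
        solids = [s for s in solids if not s.is_empty]
        if not solids:
            return MeshSolid.empty()
        verts, faces, off = [], [], 0
        for s in solids:
            verts.append(s.vertices)
            faces.append(s.faces + off)
            off += len(s.vertices)
        return MeshSolid(np.vstack(verts), np.vstack(faces))


@dataclass(frozen=True)
class ComponentRef:
    """One edge-connected closed shell of a decomposed solid.

    ``seed_point`` is a vertex on the shell, used as the origin for the
    containment ray tests; ``signed_volume`` is negative for shells wound as
    interior voids.
    """

    component_id: int
    mesh: MeshSolid
    seed_point: np.ndarray
    signed_volume: float = field(default=0.0)


# ---------------------------------------------------------------------------
# repair / validation
# ---------------------------------------------------------------------------

def repair_mesh(solid: MeshSolid, weld_tol: float = 1e-6) -> MeshSolid:
    """Weld duplicate vertices (within ``weld_tol`` Å) and drop degenerate
    (zero-area or repeated-index) triangles."""
    if solid.is_empty:
        return solid
    v = solid.vertices
    # quantized welding: group vertices by rounded coordinates
    key = np.round(v / weld_tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    new_v = v[first]
    new_f = inverse[solid.faces]
    ok = (
        (new_f[:, 0] != new_f[:, 1])
        & (new_f[:, 1] != new_f[:, 2])
        & (new_f[:, 0] != new_f[:, 2])
    )
    new_f = new_f[ok]
    if not ok.all():
        log.debug("repair_mesh: dropped %d degenerate triangles", (~ok).sum())
    # drop zero-area triangles
    a = new_v[new_f[:, 1]] - new_v[new_f[:, 0]]
    b = new_v[new_f[:, 2]] - new_v[new_f[:, 0]]
    area2 = np.linalg.norm(np.cross(a, b), axis=1)
    new_f = new_f[area2 > 1e-14]
    # drop unreferenced vertices
    used = np.unique(new_f)
    remap = -np.ones(len(new_v), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return MeshSolid(new_v[used], remap[new_f])


def _directed_edges(faces: np.ndarray) -> np.ndarray:
    return np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])


def validate_closed(solid: MeshSolid, check_orientation: bool = True) -> None:
    """Raise unless every edge is shared by exactly two triangles, once in
    each direction (closed manifold, consistent winding)."""
    if solid.is_empty:
        return
    de = _directed_edges(solid.faces)
    und = np.sort(de, axis=1)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    bad = uniq[counts != 2]
    if len(bad):
        raise NotWatertightError(bad)
    if check_orientation:
        # each undirected edge must appear once per direction
        d_uniq, d_counts = np.unique(de, axis=0, return_counts=True)
        if np.any(d_counts != 1):
            raise MeshError(
                "inconsistent winding: some directed edges repeat "
                "(run repair/orientation fix or pass check_orientation=False)"
            )


def ensure_oriented(solid: MeshSolid, config: Config = DEFAULT_CONFIG) -> MeshSolid:
    """Validate closedness; on inconsistent winding either auto-repair
    (``config.repair``) via trimesh's normal fixing, or raise."""
    try:
        validate_closed(solid)
        return solid
    except NotWatertightError:
        raise
    except MeshError:
        if not config.repair:
            raise
        tm = solid.to_trimesh()
        trimesh.repair.fix_normals(tm, multibody=True)
        fixed = MeshSolid.from_trimesh(tm)
        validate_closed(fixed)
        return fixed


# ---------------------------------------------------------------------------
# volume & centroid (surveyor's formula)
# ---------------------------------------------------------------------------

def signed_volume(solid: MeshSolid) -> float:
    """Signed-tetrahedron (divergence theorem) volume sum; no validity check."""
    if solid.is_empty:
        return 0.0
    v0 = solid.vertices[solid.faces[:, 0]]
    v1 = solid.vertices[solid.faces[:, 1]]
    v2 = solid.vertices[solid.faces[:, 2]]
    return float(np.einsum("ij,ij->", v0, np.cross(v1, v2)) / 6.0)


def compute_volume(solid: MeshSolid, validate: bool = True) -> float:
    """Enclosed volume (Å^3) of a closed, consistently oriented solid.

    Interior-void shells subtract their enclosed volume automatically via
    their opposite winding.  Raises :class:`NotWatertightError` with the open
    edges if the mesh is not closed.
    """
    if solid.is_empty:
        return 0.0
    if validate:
        validate_closed(solid, check_orientation=False)
    return signed_volume(solid)


def centroid(solid: MeshSolid) -> np.ndarray:
    """Volume-weighted centroid of the enclosed solid."""
    if solid.is_empty:
        return np.zeros(3)
    v0 = solid.vertices[solid.faces[:, 0]]
    v1 = solid.vertices[solid.faces[:, 1]]
    v2 = solid.vertices[solid.faces[:, 2]]
    w = np.einsum("ij,ij->i", v0, np.cross(v1, v2)) / 6.0
    c = (v0 + v1 + v2) / 4.0  # tetra centroid with 4th vertex at origin
    vol = w.sum()
    if abs(vol) < 1e-300:
        return np.asarray(solid.vertices.mean(axis=0))
    return np.asarray((w[:, None] * c).sum(axis=0) / vol)


# ---------------------------------------------------------------------------
# connected components (edge connectivity)
# ---------------------------------------------------------------------------

def connected_components(solid: MeshSolid) -> list[ComponentRef]:
    """Split a solid into maximal edge-connected shells.

    Connectivity is over shared *edges* (not merely shared vertices), so
    shells touching at a pinch vertex stay separate.  Components are ordered
    by their lowest original vertex index, which makes the decomposition
    deterministic.
    """
    if solid.is_empty:
        return []
    faces = solid.faces
    m = len(faces)
    und = np.sort(_directed_edges(faces), axis=1)
    face_idx = np.tile(np.arange(m), 3)
    order = np.lexsort((und[:, 1], und[:, 0]))
    und_s, face_s = und[order], face_idx[order]
    same = np.all(und_s[1:] == und_s[:-1], axis=1)
    i = np.nonzero(same)[0]
    rows, cols = face_s[i], face_s[i + 1]
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
    n_comp, labels = _cc(adj, directed=False)
    raw: list[tuple[int, MeshSolid]] = []
    for cid in range(n_comp):
        fsel = faces[labels == cid]
        used = np.unique(fsel)
        remap = np.full(len(solid.vertices), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        sub = MeshSolid(solid.vertices[used], remap[fsel])
        raw.append((int(used[0]), sub))
    # deterministic order: by lowest original vertex index of each shell
    raw.sort(key=lambda t: t[0])
    return [
        ComponentRef(
            component_id=i,
            mesh=sub,
            seed_point=np.array(sub.vertices[0]),
            signed_volume=signed_volume(sub),
        )
        for i, (_, sub) in enumerate(raw)
    ]


# ---------------------------------------------------------------------------
# ray casting
# ---------------------------------------------------------------------------

def ray_crossings(
    origin,
    direction,
    component: ComponentRef | MeshSolid,
    tol: float = 1e-9,
) -> int:
    """Count transversal crossings of a ray with a shell.

    Parity decides containment: an odd count means the origin lies inside the
    shell.  A hit within ``tol`` of a triangle edge/vertex, a hit at the ray
    origin, or a ray lying in a triangle's plane raises
    :class:`DegenerateRayError`; the caller re-draws a random direction.
    """
    mesh = component.mesh if isinstance(component, ComponentRef) else component
    if mesh.is_empty:
        return 0
    o = np.asarray(origin, dtype=np.float64)
    d = np.asarray(direction, dtype=np.float64)
    nd = np.linalg.norm(d)
    if nd == 0:
        raise ValueError("zero ray direction")
    d = d / nd
    v0 = mesh.vertices[mesh.faces[:, 0]]
    e1 = mesh.vertices[mesh.faces[:, 1]] - v0
    e2 = mesh.vertices[mesh.faces[:, 2]] - v0
    p = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, p)
    tvec = o - v0
    scale = np.maximum(np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1), 1e-300)
    parallel = np.abs(det) < 1e-12 * scale
    if np.any(parallel):
        # a parallel triangle is only a problem if the ray origin lies in its plane
        n = np.cross(e1[parallel], e2[parallel])
        nn = np.linalg.norm(n, axis=1)
        dist = np.abs(np.einsum("ij,ij->i", tvec[parallel], n)) / np.maximum(nn, 1e-300)
        if np.any(dist < 1e-9 * np.sqrt(np.maximum(scale[parallel], 1e-300))):
            raise DegenerateRayError("ray coplanar with a triangle")
    keep = ~parallel
    inv = np.zeros_like(det)
    inv[keep] = 1.0 / det[keep]
    u = np.einsum("ij,ij->i", tvec, p) * inv
    q = np.cross(tvec, e1)
    v = (q @ d) * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    w = 1.0 - u - v
    near = keep & (t > -tol) & (u > -tol) & (v > -tol) & (w > -tol)
    boundary = near & (
        (np.minimum(np.minimum(u, v), w) < tol) | (np.abs(t) < tol)
    )
    if np.any(boundary):
        raise DegenerateRayError("ray grazes a triangle edge/vertex")
    hits = keep & (t > tol) & (u > tol) & (v > tol) & (w > tol)
    return int(hits.sum())


def random_direction(rng: np.random.Generator) -> np.ndarray:
    d = rng.normal(size=3)
    return d / np.linalg.norm(d)


def point_in_component(
    point,
    component: ComponentRef | MeshSolid,
    rng: np.random.Generator,
    config: Config = DEFAULT_CONFIG,
) -> bool:
    """Parity containment test with degenerate-ray retries (seeded RNG)."""
    for _ in range(config.max_ray_retries):
        try:
            return ray_crossings(point, random_direction(rng), component, tol=config.ray_tol) % 2 == 1
        except DegenerateRayError:
            continue
    raise DegenerateRayError(
        f"no non-degenerate ray found after {config.max_ray_retries} retries"
    )


# ---------------------------------------------------------------------------
# mesh I/O (OFF / PLY / OBJ via trimesh)
# ---------------------------------------------------------------------------

_FORMATS = {"off", "ply", "obj"}


def _format_of(path, fmt: str | None) -> str:
    f = (fmt or Path(path).suffix.lstrip(".")).lower()
    if f not in _FORMATS:
        raise MeshError(f"unknown mesh format {f!r} (supported: {sorted(_FORMATS)})")
    return f


def read_mesh(path, fmt: str | None = None, config: Config = DEFAULT_CONFIG) -> MeshSolid:
    """Read a mesh file (OFF, PLY ascii/binary, OBJ).  Non-triangular faces
    are fan-triangulated by the loader; repair (welding, degenerate-face
    removal) runs unless disabled in the config."""
    f = _format_of(path, fmt)
    try:
        tm = trimesh.load_mesh(str(path), file_type=f, process=False)
    except Exception as exc:  # noqa: BLE001 - normalize loader errors
        raise MeshError(f"cannot parse mesh file {path}: {exc}") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise MeshError(f"no mesh data in {path}")
        tm = trimesh.util.concatenate(geoms)
    if tm.vertices is None or len(tm.vertices) == 0 or len(tm.faces) == 0:
        raise MeshError(f"no mesh data in {path}")
    solid = MeshSolid.from_trimesh(tm)
    if config.repair:
        solid = repair_mesh(solid, config.weld_tol)
    return solid


def write_mesh(solid: MeshSolid, path, fmt: str | None = None, ascii_ply: bool = True) -> None:
    f = _format_of(path, fmt)
    tm = solid.to_trimesh()
    kw = {}
    if f == "ply":
        kw["encoding"] = "ascii" if ascii_ply else "binary"
    data = trimesh.exchange.export.export_mesh(tm, None, file_type=f, **kw)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)
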