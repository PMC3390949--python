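"""Shared fixtures and independent geometric oracles.

The oracles here deliberately avoid the package's CSG/mesh code paths:

* box unions are measured by coordinate-slab decomposition over the *box
  parameter lists* (never the meshes);
* nested-box solids are described analytically (strict nesting, parity
  membership) and their fragment structure is known by construction;
* voxel oracles rasterize membership from the primitive parameters and use
  scipy's 6-connected labeling for flood fill.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pytest
from scipy import ndimage

from pocketfrag.config import Config
from pocketfrag.mesh_core import MeshSolid


@pytest.fixture()
def config() -> Config:
    return Config(seed=1234)


@pytest.fixture()
def unit_cube() -> MeshSolid:
    return MeshSolid.box([0, 0, 0], [1, 1, 1])


# ---------------------------------------------------------------------------
# analytic box machinery (test-side oracle; works on box parameters only)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Box:
    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def contains(self, p) -> bool:
        return all(self.lo[a] < p[a] < self.hi[a] for a in range(3))

    def contains_box(self, other: "Box") -> bool:
        return all(
            self.lo[a] <= other.lo[a] and other.hi[a] <= self.hi[a] for a in range(3)
        )

    @property
    def volume(self) -> float:
        return float(np.prod([self.hi[a] - self.lo[a] for a in range(3)]))

    def mesh(self) -> MeshSolid:
        return MeshSolid.box(self.lo, self.hi)


def box_region_volume(membership, boxes: list[Box]) -> float:
    """Exact volume of a region defined by ``membership(point) -> bool`` that
    is constant on the slab decomposition induced by the boxes' face planes."""
    axes = []
    for a in range(3):
        coords = sorted({b.lo[a] for b in boxes} | {b.hi[a] for b in boxes})
        axes.append(np.array(coords))
    vol = 0.0
    for i, j, k in itertools.product(*(range(len(ax) - 1) for ax in axes)):
        center = (
            (axes[0][i] + axes[0][i + 1]) / 2,
            (axes[1][j] + axes[1][j + 1]) / 2,
            (axes[2][k] + axes[2][k + 1]) / 2,
        )
        if membership(center):
            vol += (
                (axes[0][i + 1] - axes[0][i])
                * (axes[1][j + 1] - axes[1][j])
                * (axes[2][k + 1] - axes[2][k])
            )
    return vol


def union_volume(boxes: list[Box]) -> float:
    return box_region_volume(lambda p: any(b.contains(p) for b in boxes), boxes)


def random_box(rng, lo=0.0, hi=10.0, min_side=0.8, max_side=5.0) -> Box:
    size = rng.uniform(min_side, max_side, size=3)
    a = rng.uniform(lo, hi - size.max(), size=3)
    return Box(tuple(a), tuple(a + size))


def random_box_union(rng, n_min=1, n_max=4) -> list[Box]:
    return [random_box(rng) for _ in range(rng.integers(n_min, n_max + 1))]


# ---------------------------------------------------------------------------
# nested-box solids: mesh + analytic fragment structure
# ---------------------------------------------------------------------------

@dataclass
class NestedSolid:
    """Strictly nested / disjoint boxes with parity membership.

    A point is in the solid iff it lies inside an odd number of boxes; with
    strict nesting this equals the classic box-minus-void-plus-island
    construction.  The boundary mesh is exactly the union of all box
    boundaries, each box wound outward at even nesting level and inward at
    odd level — no CSG involved.
    """

    boxes: list[Box]
    levels: list[int]

    def membership(self, p) -> bool:
        return sum(b.contains(p) for b in self.boxes) % 2 == 1

    def mesh(self) -> MeshSolid:
        parts = [
            b.mesh() if lvl % 2 == 0 else b.mesh().flipped()
            for b, lvl in zip(self.boxes, self.levels)
        ]
        return MeshSolid.concatenate(parts)

    @property
    def volume(self) -> float:
        return sum(b.volume * (1 if l % 2 == 0 else -1) for b, l in zip(self.boxes, self.levels))

    def expected_fragments(self) -> list[dict]:
        """One entry per even-level box: its fragment volume (box minus
        immediate children) and number of interior voids."""
        out = []
        for i, (b, lvl) in enumerate(zip(self.boxes, self.levels)):
            if lvl % 2 != 0:
                continue
            children = [
                j
                for j, (c, lc) in enumerate(zip(self.boxes, self.levels))
                if lc == lvl + 1 and b.contains_box(c)
            ]
            vol = b.volume - sum(self.boxes[j].volume for j in children)
            out.append({"volume": vol, "n_voids": len(children), "depth": lvl})
        return out


def _shrink(box: Box, rng, frac_lo=0.25, frac_hi=0.6, margin=0.5) -> Box | None:
    size = np.array(box.hi) - np.array(box.lo)
    new = size * rng.uniform(frac_lo, frac_hi, size=3)
    if np.any(size - new < 2 * margin):
        return None
    lo = np.array(box.lo) + margin + rng.uniform(0, 1, 3) * (size - new - 2 * margin)
    return Box(tuple(lo), tuple(lo + new))


def random_nested_solid(rng, max_depth=5) -> NestedSolid:
    """Seeded random solid: 1-3 disjoint roots, each a chain/tree of strictly
    nested boxes alternating solid/void down to ``max_depth`` levels."""
    n_roots = int(rng.integers(1, 4))
    boxes, levels = [], []
    # lay roots on disjoint x-slots so they can never touch
    for r in range(n_roots):
        side = rng.uniform(3.0, 5.5)
        x0 = r * 6.5 + rng.uniform(0, 0.5)
        lo = (x0, rng.uniform(0, 0.5), rng.uniform(0, 0.5))
        root = Box(lo, (lo[0] + side, lo[1] + side, lo[2] + side))
        stack = [(root, 0)]
        while stack:
            box, lvl = stack.pop()
            boxes.append(box)
            levels.append(lvl)
            if lvl + 1 >= max_depth:
                continue
            n_children = int(rng.integers(0, 3)) if lvl % 2 == 0 else int(rng.integers(0, 2))
            kids = []
            for _ in range(n_children):
                child = _shrink(box, rng)
                if child is None:
                    continue
                # keep siblings separated by > 2 voxel layers of the oracle
                if any(_boxes_overlap(_inflate(child, 0.5), k) for k in kids):
                    continue
                kids.append(child)
                stack.append((child, lvl + 1))
    return NestedSolid(boxes=boxes, levels=levels)


def _boxes_overlap(a: Box, b: Box) -> bool:
    return all(a.lo[x] < b.hi[x] and b.lo[x] < a.hi[x] for x in range(3))


def _inflate(b: Box, eps: float) -> Box:
    return Box(tuple(np.array(b.lo) - eps), tuple(np.array(b.hi) + eps))


# ---------------------------------------------------------------------------
# voxel flood-fill oracle (from primitive parameters)
# ---------------------------------------------------------------------------

def voxel_fragments(solid: NestedSolid, spacing: float = 0.2) -> list[dict]:
    """6-connected flood fill of the parity mask on a uniform grid; per
    component: voxel volume and number of enclosed voids (filled holes)."""
    lo = np.min([b.lo for b in solid.boxes], axis=0) - 2 * spacing
    hi = np.max([b.hi for b in solid.boxes], axis=0) + 2 * spacing
    shape = tuple(int(np.ceil((hi[a] - lo[a]) / spacing)) for a in range(3))
    axes = [lo[a] + (np.arange(shape[a]) + 0.5) * spacing for a in range(3)]
    count = np.zeros(shape, dtype=np.int16)
    for b in solid.boxes:
        sl = tuple(
            slice(
                int(np.searchsorted(axes[a], b.lo[a])),
                int(np.searchsorted(axes[a], b.hi[a])),
            )
            for a in range(3)
        )
        count[sl] += 1
    mask = (count % 2).astype(bool)
    labels, n = ndimage.label(mask)  # default structure = 6-connectivity
    out = []
    for lab in range(1, n + 1):
        comp = labels == lab
        filled = ndimage.binary_fill_holes(comp)
        hole_mask = filled & ~comp
        _, n_holes = ndimage.label(hole_mask)
        boundary = (comp ^ ndimage.binary_erosion(comp)) | (
            ndimage.binary_dilation(comp) ^ comp
        )
        out.append(
            {
                "volume": float(comp.sum()) * spacing**3,
                "filled_volume": float(filled.sum()) * spacing**3,
                "n_voids": int(n_holes),
                "layer": float(boundary.sum()) * spacing**3,
            }
        )
    out.sort(key=lambda d: -d["volume"])
    return out


def voxel_union_count(boxes: list[Box], spacing: float) -> tuple[float, float]:
    """(voxel volume, one-surface-layer volume bound) for a box union."""
    lo = np.min([b.lo for b in boxes], axis=0) - 2 * spacing
    hi = np.max([b.hi for b in boxes], axis=0) + 2 * spacing
    shape = tuple(int(np.ceil((hi[a] - lo[a]) / spacing)) for a in range(3))
    axes = [lo[a] + (np.arange(shape[a]) + 0.5) * spacing for a in range(3)]
    mask = np.zeros(shape, dtype=bool)
    for b in boxes:
        sl = tuple(
            slice(
                int(np.searchsorted(axes[a], b.lo[a])),
                int(np.searchsorted(axes[a], b.hi[a])),
            )
            for a in range(3)
        )
        mask[sl] = True
    boundary = mask ^ ndimage.binary_erosion(mask)
    boundary |= ndimage.binary_dilation(mask) ^ mask
    return float(mask.sum()) * spacing**3, float(boundary.sum()) * spacing**3
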