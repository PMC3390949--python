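"""Build binding-cavity solids from pre-aligned protein structures.

The cavity of a structure is assembled from three probe-derived solids:

* the *molecular surface* — the solvent-excluded surface (SES) with a
  water-sized probe of radius 1.4 Å;
* the *envelope surface* — the SES with a larger probe of radius 5.0 Å,
  bounding how far a cavity may reach from the protein;
* the *seed-sphere union* — 5 Å-radius spheres centered at atoms of a
  bound ligand (and ordered waters) in the reference structure, filling the
  superposed binding sites.

    cavity = ((∪ seed spheres) \\ molecular surface) ∩ envelope surface

Surfaces are computed on a grid: the union-of-balls distance field is
dilated by the probe radius and eroded back (morphological closing via a
Euclidean distance transform), then isosurfaced to a watertight mesh.  The
three set operations are evaluated on one shared grid, avoiding repeated
re-discretization.  Structures must arrive mutually superposed; this module
validates frames only, it does not align.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import gemmi
import numpy as np
from scipy import ndimage
from skimage import measure

from .config import Config, DEFAULT_CONFIG
from .mesh_core import MeshSolid, signed_volume

log = logging.getLogger(__name__)

__all__ = [
    "StructureAtoms",
    "SeedSelection",
    "VDW_RADII",
    "load_structure",
    "probe_surface",
    "build_cavity",
]

# van der Waals radii (Å), Bondi (1964) with common extensions; unknown
# elements fall back to the carbon radius with a warning
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "B": 1.92, "ZN": 1.39, "CA": 2.31, "MG": 1.73, "NA": 2.27, "K": 2.75,
    "FE": 2.00, "MN": 2.00, "CU": 1.40,
}
DEFAULT_RADIUS = 1.70


@dataclass
class StructureAtoms:
    """Cleaned heavy-atom set of one structure (protein atoms only)."""

    elements: list[str]
    residues: list[str]        # "chain/resnum resname"
    centers: np.ndarray        # (n, 3) Å
    radii: np.ndarray          # (n,) Å
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.radii)


@dataclass
class SeedSelection:
    """Coordinates of bound ligand/water atoms seeding the cavity spheres."""

    centers: np.ndarray        # (k, 3) Å
    source: str = ""

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        if len(self.centers) == 0:
            raise ValueError("seed selection is empty")


def _radius_for(element: str) -> float:
    r = VDW_RADII.get(element.upper())
    if r is None:
        warnings.warn(
            f"unknown element {element!r}: using default vdW radius {DEFAULT_RADIUS} Å",
            stacklevel=3,
        )
        r = DEFAULT_RADIUS
    return r


def load_structure(path, keep_het: tuple[str, ...] = ()) -> StructureAtoms:
    """Protein heavy atoms of the first model of a PDB file.

    Waters, ions and other non-protein residues are removed (unless their
    residue name is listed in ``keep_het``, for seed-ligand extraction);
    hydrogens (and deuteriums) are stripped; of alternate locations only the
    first is kept.  Atypical amino acids such as selenomethionine are
    retained — they are part of the protein.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    elements, residues, centers, radii = [], [], [], []
    for chain in model:
        for res in chain:
            is_water = res.is_water()
            info = gemmi.find_tabulated_residue(res.name)
            is_amino = bool(info and info.is_amino_acid())
            keep = (is_amino or res.name in keep_het) and not is_water
            if not keep:
                continue
            seen_names = set()
            for atom in res:
                el = atom.element.name.upper()
                if el in ("H", "D"):
                    continue
                if atom.name in seen_names:   # later altlocs
                    continue
                seen_names.add(atom.name)
                elements.append(el)
                residues.append(f"{chain.name}/{res.seqid.num} {res.name}")
                centers.append([atom.pos.x, atom.pos.y, atom.pos.z])
                radii.append(_radius_for(el))
    if not centers:
        raise ValueError(f"no protein atoms in {path}")
    return StructureAtoms(
        elements=elements,
        residues=residues,
        centers=np.array(centers, dtype=float),
        radii=np.array(radii, dtype=float),
        provenance=str(path),
    )


def seed_from_structure(path, residue_names: tuple[str, ...]) -> SeedSelection:
    """Seed coordinates: heavy atoms of the named bound residues (HOH
    included only if listed explicitly)."""
    st = gemmi.read_structure(str(path))
    model = st[0]
    centers = []
    for chain in model:
        for res in chain:
            if res.name not in residue_names:
                continue
            for atom in res:
                if atom.element.name.upper() in ("H", "D"):
                    continue
                centers.append([atom.pos.x, atom.pos.y, atom.pos.z])
    return SeedSelection(centers=np.array(centers), source=f"{path}:{','.join(residue_names)}")


# ---------------------------------------------------------------------------
# grid machinery
# ---------------------------------------------------------------------------

def _ball_union_field(centers, radii, origin, spacing, shape, reach_extra) -> np.ndarray:
    """Grid of min_i(|x - c_i| - r_i): negative inside the union of balls.

    The field is only guaranteed accurate within ``reach_extra`` of each
    ball surface (callers pass the probe radius plus an interpolation
    margin); farther out it saturates high, which Boolean minima ignore.
    """
    fld = np.full(shape, np.inf, dtype=np.float64)
    axes = [origin[a] + np.arange(shape[a]) * spacing for a in range(3)]
    for c, r in zip(centers, radii):
        # only a local neighborhood of each ball can lower the field
        reach = r + reach_extra
        sl, loc = [], []
        for a in range(3):
            i0 = int(np.searchsorted(axes[a], c[a] - reach))
            i1 = int(np.searchsorted(axes[a], c[a] + reach))
            sl.append(slice(i0, i1))
            loc.append(axes[a][i0:i1] - c[a])
        if any(s.start >= s.stop for s in sl):
            continue
        d = np.sqrt(
            loc[0][:, None, None] ** 2 + loc[1][None, :, None] ** 2 + loc[2][None, None, :] ** 2
        ) - r
        region = fld[sl[0], sl[1], sl[2]]
        np.minimum(region, d, out=region)
    return fld


def _ses_field(atoms: StructureAtoms, probe: float, origin, spacing, shape) -> np.ndarray:
    """Signed field positive inside the solvent-excluded surface.

    Closing: dilate the atom balls by the probe (d <= probe), then erode by
    the probe via the Euclidean distance transform of the dilated mask.
    Sub-voxel accuracy comes from interpolating edt - probe at isosurfacing.
    """
    d = _ball_union_field(
        atoms.centers, atoms.radii, origin, spacing, shape, reach_extra=probe + 4 * spacing
    )
    sas = d <= probe  # atom balls dilated by the probe radius
    if not sas.any():
        return np.full(shape, -probe)
    g = probe - d  # signed sub-voxel distance to the SAS boundary (|∇|≈1 nearby)
    inner, idx = ndimage.distance_transform_edt(
        sas, sampling=(spacing,) * 3, return_indices=True
    )
    # center-to-center EDT quantizes at the voxel scale; adding the (negative)
    # signed field at the nearest background voxel recovers the sub-voxel
    # boundary position (exact for a single ball, where g is the true distance)
    sub = g[idx[0], idx[1], idx[2]]
    dist = np.where(sas, np.maximum(inner + sub, 0.0), np.minimum(sub, 0.0))
    # distance to SAS complement minus probe: >= 0 inside the closed surface
    return dist - probe


def _mesh_from_field(fld: np.ndarray, origin, spacing, level: float = 0.0) -> MeshSolid:
    """Isosurface a positive-inside field to an outward-oriented mesh."""
    if not (fld > level).any():
        return MeshSolid.empty()
    # values exactly at the level make marching cubes emit degenerate,
    # occasionally non-watertight sheets; nudge them off the level
    fld = np.where(fld == level, level + 1e-9, fld)
    pad = np.pad(fld, 1, constant_values=fld.min() - 1.0)
    verts, faces, _, _ = measure.marching_cubes(pad, level=level, spacing=(spacing,) * 3)
    verts = verts + (np.asarray(origin) - spacing)
    solid = MeshSolid(verts, faces.astype(np.int64))
    if signed_volume(solid) < 0:
        solid = solid.flipped()
    return solid


def _grid_over(points: np.ndarray, pad: float, spacing: float):
    lo = points.min(axis=0) - pad
    hi = points.max(axis=0) + pad
    origin = lo
    shape = tuple(int(np.ceil((hi[a] - lo[a]) / spacing)) + 2 for a in range(3))
    return origin, shape


def probe_surface(
    atoms: StructureAtoms, probe_radius: float, config: Config = DEFAULT_CONFIG
) -> MeshSolid:
    """Solvent-excluded surface of the atom set at the given probe radius,
    as a watertight mesh (grid spacing ``config.ses_spacing``)."""
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    if len(atoms) == 0:
        raise ValueError("empty atom set")
    h = config.ses_spacing
    pad = atoms.radii.max() + probe_radius + 3 * h
    origin, shape = _grid_over(atoms.centers, pad, h)
    fld = _ses_field(atoms, probe_radius, origin, h, shape)
    return _mesh_from_field(fld, origin, h)


def build_cavity(
    atoms: StructureAtoms,
    seeds: SeedSelection,
    seed_radius: float = 5.0,
    probe_small: float = 1.4,
    probe_large: float = 5.0,
    config: Config = DEFAULT_CONFIG,
) -> MeshSolid:
    """Cavity solid: ((∪ seed spheres) \\ SES(1.4 Å)) ∩ SES(5.0 Å).

    All three fields are evaluated on one grid; the Boolean combination is
    the pointwise min of positive-inside fields, isosurfaced once.  An empty
    cavity (seeds outside the envelope, or swallowed by the protein body)
    is a valid, flagged result.

    The cavity is a subset of the seed-sphere union, so the grid covers the
    seed neighborhood only (seed radius plus twice the envelope probe, so
    grid-boundary erosion artifacts stay clear of the seed spheres); atoms
    outside the grid's reach cannot affect the result and cost nothing.
    """
    h = config.ses_spacing
    pad = seed_radius + 2 * probe_large + 4 * h
    origin, shape = _grid_over(seeds.centers, pad, h)

    seed_field = -(
        _ball_union_field(
            seeds.centers, np.full(len(seeds.centers), seed_radius),
            origin, h, shape, reach_extra=4 * h,
        )
    )  # positive inside the seed-sphere union
    ms_field = _ses_field(atoms, probe_small, origin, h, shape)
    env_field = _ses_field(atoms, probe_large, origin, h, shape)
    cavity_field = np.minimum(np.minimum(seed_field, -ms_field), env_field)
    solid = _mesh_from_field(cavity_field, origin, h)
    if solid.is_empty:
        log.warning("cavity is empty (seeds do not reach open space in the envelope)")
    return solid
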