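"""Separate a Boolean-difference solid into individual cavity fragments.

A *fragment* is one contiguous region lying inside one cavity and not inside
another.  A difference solid may contain several fragments, and a fragment
may enclose interior voids, so its boundary decomposes into several closed
shells.  Shells are regrouped by the containment-DAG algorithm:

1. split the difference mesh into edge-connected shells;
2. for every ordered shell pair, decide containment by ray-crossing parity
   from a seed point (random direction, re-drawn on degenerate hits);
3. build the directed acyclic containment graph and assign each shell the
   length of the longest containment path reaching it (its *depth*);
4. every even-depth shell is a fragment exterior; each odd-depth shell is an
   interior void attached to its unique immediate container at depth d-1.

This regrouping is correct for arbitrary nesting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Config, DEFAULT_CONFIG
from .mesh_core import (
    ComponentRef,
    MeshSolid,
    centroid,
    compute_volume,
    connected_components,
    point_in_component,
)
from . import csg_ops

log = logging.getLogger(__name__)

__all__ = [
    "ContainmentGraph",
    "Fragment",
    "build_containment_graph",
    "assign_depths",
    "group_fragments",
    "fragments_of",
    "fragments_between",
    "fragment_table",
]


@dataclass
class ContainmentGraph:
    """DAG over mesh shells: edge (i -> j) means shell j lies inside shell i."""

    nodes: list[ComponentRef]
    edges: set[tuple[int, int]]
    depths: dict[int, int] = field(default_factory=dict)

    def children(self, i: int) -> list[int]:
        return sorted(j for (a, j) in self.edges if a == i)

    def in_degree(self, j: int) -> int:
        return sum(1 for (_, b) in self.edges if b == j)


@dataclass
class Fragment:
    """One contiguous difference region: an exterior shell plus the interior
    voids immediately inside it.

    ``volume`` is exterior volume minus void volumes, computed by the
    divergence-theorem sum over the assembled oriented mesh (void shells keep
    their inward winding, so they subtract automatically).
    """

    exterior: ComponentRef
    voids: list[ComponentRef]
    volume: float
    centroid: np.ndarray
    pair_id: str = ""
    direction: str = ""   # "AB" | "BA" | "" for a bare difference solid

    @property
    def mesh(self) -> MeshSolid:
        return MeshSolid.concatenate([self.exterior.mesh] + [v.mesh for v in self.voids])

    @property
    def depth(self) -> int:
        return getattr(self, "_depth", 0)


class ContainmentError(RuntimeError):
    """Geometrically inconsistent containment structure."""


# ---------------------------------------------------------------------------

def build_containment_graph(
    components: list[ComponentRef], config: Config = DEFAULT_CONFIG
) -> ContainmentGraph:
    """All-pairs containment via ray parity from each shell's seed point.

    The seed point of shell j lies *on* the mesh of j, so the test against a
    different shell i is unambiguous; degenerate rays are re-drawn from a
    seeded RNG (at most ``config.max_ray_retries`` times).
    """
    rng = config.rng(salt=101)
    edges: set[tuple[int, int]] = set()
    for j, cj in enumerate(components):
        for i, ci in enumerate(components):
            if i == j:
                continue
            if point_in_component(cj.seed_point, ci, rng, config):
                edges.add((i, j))
    graph = ContainmentGraph(nodes=list(components), edges=edges)
    _check_acyclic(graph)
    return graph


def _check_acyclic(graph: ContainmentGraph) -> None:
    # Kahn's algorithm; leftovers mean a cycle (upstream parity fault)
    n = len(graph.nodes)
    indeg = {i: 0 for i in range(n)}
    for _, j in graph.edges:
        indeg[j] += 1
    queue = [i for i in range(n) if indeg[i] == 0]
    seen = 0
    while queue:
        i = queue.pop()
        seen += 1
        for j in graph.children(i):
            indeg[j] -= 1
            if indeg[j] == 0:
                queue.append(j)
    if seen != n:
        raise ContainmentError("containment graph has a cycle (parity fault upstream)")


def assign_depths(graph: ContainmentGraph) -> dict[int, int]:
    """Depth-first search from every zero-in-degree root, re-assigning a
    node's depth whenever a longer containment path reaches it.

    The result equals the longest path from any root (the number of shells a
    shell is nested within) and is independent of the DFS visiting order.
    """
    n = len(graph.nodes)
    depths = {i: 0 for i in range(n)}
    roots = [i for i in range(n) if graph.in_degree(i) == 0]
    if n and not roots:
        raise ContainmentError("no root component (cycle?)")

    def dfs(i: int, d: int) -> None:
        for j in graph.children(i):
            # re-assign (and re-descend) only on strict increase, which
            # bounds the work at O(nodes * edges)
            if d + 1 > depths[j]:
                depths[j] = d + 1
                dfs(j, d + 1)

    for r in roots:
        dfs(r, 0)
    graph.depths = depths
    return depths


def group_fragments(
    graph: ContainmentGraph, config: Config = DEFAULT_CONFIG
) -> list[Fragment]:
    """Assemble fragments from a depth-annotated containment graph.

    Every even-depth shell is a fragment exterior; every odd-depth shell is
    attached to its unique immediate container — the shell at depth d-1 with
    a containment edge to it.
    """
    if not graph.depths and graph.nodes:
        assign_depths(graph)
    depths = graph.depths
    frags: dict[int, Fragment] = {}
    for i, comp in enumerate(graph.nodes):
        if depths[i] % 2 == 0:
            frag = Fragment(
                exterior=comp,
                voids=[],
                volume=0.0,
                centroid=np.zeros(3),
            )
            frag._depth = depths[i]
            frags[i] = frag
    for j, comp in enumerate(graph.nodes):
        d = depths[j]
        if d % 2 == 0:
            continue
        containers = [
            i for (i, jj) in graph.edges if jj == j and depths[i] == d - 1
        ]
        if len(containers) != 1:
            raise ContainmentError(
                f"void shell {j} (depth {d}) has {len(containers)} immediate "
                f"containers at depth {d - 1}; geometry inconsistent"
            )
        frags[containers[0]].voids.append(comp)
    out = []
    for frag in frags.values():
        mesh = frag.mesh
        frag.volume = compute_volume(mesh, validate=False)
        frag.centroid = centroid(mesh)
        out.append(frag)
    out.sort(key=lambda fr: (-fr.volume, tuple(np.round(fr.centroid, 9))))
    return out


def fragments_of(
    solid: MeshSolid,
    config: Config = DEFAULT_CONFIG,
    pair_id: str = "",
    direction: str = "",
) -> list[Fragment]:
    """Fragments of one difference solid, ordered by descending volume
    (centroid lexicographic order breaks ties).  Fragments below the
    minimum-volume floor are dropped and counted in the log."""
    comps = connected_components(solid)
    if not comps:
        return []
    graph = build_containment_graph(comps, config)
    assign_depths(graph)
    frags = group_fragments(graph, config)
    kept, dropped_vol, dropped_n = [], 0.0, 0
    for fr in frags:
        if fr.volume < config.volume_floor:
            dropped_n += 1
            dropped_vol += fr.volume
            continue
        fr.pair_id = pair_id
        fr.direction = direction
        kept.append(fr)
    if dropped_n:
        log.info(
            "fragments_of(%s %s): dropped %d sliver fragment(s), %.4g A^3 total",
            pair_id, direction, dropped_n, dropped_vol,
        )
    return kept


def fragments_between(
    A: MeshSolid,
    B: MeshSolid,
    config: Config = DEFAULT_CONFIG,
    pair_id: str = "",
) -> list[Fragment]:
    """The full fragment set relating cavities A and B: fragments of A\\B
    (tagged AB) together with fragments of B\\A (tagged BA)."""
    ab = csg_ops.difference(A, B, config, names=(f"{pair_id}:A", f"{pair_id}:B"))
    ba = csg_ops.difference(B, A, config, names=(f"{pair_id}:B", f"{pair_id}:A"))
    frags = fragments_of(ab.solid, config, pair_id=pair_id, direction="AB")
    frags += fragments_of(ba.solid, config, pair_id=pair_id, direction="BA")
    frags.sort(key=lambda fr: (-fr.volume, tuple(np.round(fr.centroid, 9))))
    return frags


def fragment_table(fragments: list[Fragment]) -> pd.DataFrame:
    """Flat per-fragment table (CSV-exportable): provenance, volume,
    centroid, shell counts."""
    rows = [
        {
            "pair_id": fr.pair_id,
            "direction": fr.direction,
            "volume": fr.volume,
            "centroid_x": fr.centroid[0],
            "centroid_y": fr.centroid[1],
            "centroid_z": fr.centroid[2],
            "n_voids": len(fr.voids),
            "depth": fr.depth,
        }
        for fr in fragments
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id", "direction", "volume",
            "centroid_x", "centroid_y", "centroid_z", "n_voids", "depth",
        ],
    )
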