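"""Synthetic cavity families and the leave-one-out / leave-two-out drivers.

Real binding-cavity sets (serine proteases, enolases) require external
structure data and alignment; the synthetic generator stands in for them
with controllable geometry.  A *family* of same-specificity cavities is a
shared base solid (a box-shaped pocket) perturbed per member by small
surface bumps — carved dents or added protrusions — whose volumes follow a
log-normal law, mimicking the incidental shape variation seen between
cavities that bind the same ligand.  A *different-specificity* member
carries an additional variant bump far larger than the family's natural
variation.

Bumps are placed on a deterministic slot grid on one face, so bumps of
different members never overlap: each dent carved into a member then
reappears verbatim as one fragment of any pairwise difference, and the
fragment-volume distribution equals the bump-volume law by construction.
This makes the experiments' nominal significance levels interpretable.

For the nominal-level (null calibration) experiment the outgroup cavity is
the pristine base — a zero-perturbation member of the same family — so each
held-out-vs-outgroup comparison yields exactly one fragment, an i.i.d. draw
from the training law.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import trimesh

from .config import Config, DEFAULT_CONFIG
from .mesh_core import MeshSolid
from .fragmenter import Fragment, fragments_between
from .volumetric_stats import (
    RegionCube,
    SignificanceCall,
    build_lattice,
    evaluate_fragment,
    train_regional_model,
    train_standard_model,
    training_fragments,
)
from . import csg_ops

log = logging.getLogger(__name__)

__all__ = [
    "Bump",
    "SyntheticFamilySpec",
    "ExperimentReport",
    "make_base_box",
    "apply_bumps",
    "generate_family",
    "leave_one_out",
    "leave_two_out",
    "regional_scan",
]


# ---------------------------------------------------------------------------
# geometry construction
# ---------------------------------------------------------------------------

def make_base_box(dims=(12.0, 12.0, 6.0)) -> MeshSolid:
    """Box-shaped base cavity [0, L] x [0, W] x [0, H] (Å)."""
    return MeshSolid.box([0.0, 0.0, 0.0], list(dims))


@dataclass(frozen=True)
class Bump:
    """One surface perturbation on the +z face of a base box.

    ``center`` is the (x, y) footprint center on the face; ``volume`` is the
    material added (mode "add") or removed (mode "carve").  A box bump is a
    cube of side volume^(1/3) flush with the face; a sphere bump is a
    half-ball centered on the face (radius (3V/2π)^(1/3))."""

    center: tuple[float, float]
    volume: float
    mode: str = "carve"    # "carve" | "add"
    shape: str = "box"     # "box" | "sphere"

    def solid(self, face_z: float) -> MeshSolid:
        x, y = self.center
        if self.shape == "box":
            s = self.volume ** (1.0 / 3.0)
            if self.mode == "carve":
                lo, hi = face_z - s, face_z
            else:
                lo, hi = face_z, face_z + s
            return MeshSolid.box([x - s / 2, y - s / 2, lo], [x + s / 2, y + s / 2, hi])
        if self.shape == "sphere":
            r = (3.0 * self.volume / (2.0 * np.pi)) ** (1.0 / 3.0)
            tm = trimesh.creation.icosphere(subdivisions=3, radius=r)
            return MeshSolid.from_trimesh(tm).translated([x, y, face_z])
        raise ValueError(f"unknown bump shape {self.shape!r}")


def apply_bumps(base: MeshSolid, bumps: list[Bump], config: Config = DEFAULT_CONFIG) -> MeshSolid:
    """Base solid with bumps carved out of / added onto its top face."""
    face_z = float(base.bounds[1][2])
    solid = base
    add = [b.solid(face_z) for b in bumps if b.mode == "add"]
    carve = [b.solid(face_z) for b in bumps if b.mode == "carve"]
    if add:
        solid = csg_ops.union_all([solid] + add, config).solid
    for c in carve:
        solid = csg_ops.difference(solid, c, config).solid
    return solid


@dataclass
class SyntheticFamilySpec:
    """Conditions for one same-specificity cavity family.

    Defaults model a pocket-scale solid (12 x 12 x 6 Å, 864 Å^3) whose
    members differ by one small carved dent each: median dent volume 8 Å^3
    (under 1% of the pocket) with log-sd 0.5, i.e. the incidental variation
    the standard model is meant to absorb.  ``variant_volume`` adds one
    extra bump of exactly that volume to every member (used to build
    different-specificity outgroups).  Draws whose bump would overflow its
    placement slot are re-drawn (a <1% truncation of the upper tail).
    """

    base_dims: tuple[float, float, float] = (12.0, 12.0, 6.0)
    n_members: int = 6
    n_bumps: int = 1
    bump_log_mean: float = float(np.log(8.0))
    bump_log_sd: float = 0.5
    bump_mode: str = "carve"
    bump_shape: str = "box"
    variant_volume: float | None = None
    seed: int = 0

    def slot_grid(self) -> tuple[int, float, float]:
        """(slots per row, pitch x, pitch y) on the +z face; slot count
        covers every member bump plus one spare for variant placement."""
        needed = self.n_members * self.n_bumps + 1
        per_row = int(np.ceil(np.sqrt(needed)))
        return per_row, self.base_dims[0] / per_row, self.base_dims[1] / per_row


def _slot_center(spec: SyntheticFamilySpec, slot: int) -> tuple[float, float]:
    per_row, px, py = spec.slot_grid()
    i, j = slot % per_row, slot // per_row
    return ((i + 0.5) * px, (j + 0.5) * py)


def _draw_bump_volume(spec: SyntheticFamilySpec, rng: np.random.Generator) -> float:
    per_row, px, py = spec.slot_grid()
    max_side = min(px, py, spec.base_dims[2]) * 0.95
    vmax = max_side**3
    for _ in range(64):
        v = float(np.exp(rng.normal(spec.bump_log_mean, spec.bump_log_sd)))
        if v <= vmax:
            return v
    raise ValueError(
        f"bump volume distribution exp(N({spec.bump_log_mean}, {spec.bump_log_sd}))"
        f" incompatible with slot capacity {vmax:.3g} Å^3"
    )


def generate_family(
    spec: SyntheticFamilySpec, config: Config = DEFAULT_CONFIG
) -> list[MeshSolid]:
    """Deterministic (seeded) list of ``n_members`` cavity solids."""
    rng = np.random.default_rng(spec.seed)
    base = make_base_box(spec.base_dims)
    members = []
    for m in range(spec.n_members):
        bumps = []
        for b in range(spec.n_bumps):
            slot = m * spec.n_bumps + b
            bumps.append(
                Bump(
                    center=_slot_center(spec, slot),
                    volume=_draw_bump_volume(spec, rng),
                    mode=spec.bump_mode,
                    shape=spec.bump_shape,
                )
            )
        if spec.variant_volume is not None:
            spare = spec.n_members * spec.n_bumps
            bumps.append(
                Bump(
                    center=_slot_center(spec, spare),
                    volume=spec.variant_volume,
                    mode=spec.bump_mode,
                    shape=spec.bump_shape,
                )
            )
        members.append(apply_bumps(base, bumps, config) if bumps else base)
    return members


# ---------------------------------------------------------------------------
# experiment reports
# ---------------------------------------------------------------------------

@dataclass
class ExperimentReport:
    """Per-test significance calls plus the p-value histogram."""

    calls: list[SignificanceCall]
    histogram: np.ndarray          # counts in 10 bins of width 0.1
    n_tests: int
    n_empty_rounds: int
    seed: int
    config: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    @property
    def significant_fraction(self) -> float:
        if not self.calls:
            return float("nan")
        return sum(c.significant for c in self.calls) / len(self.calls)

    @property
    def p_values(self) -> np.ndarray:
        return np.array([c.p_value for c in self.calls])

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_tests": self.n_tests,
                "n_empty_rounds": self.n_empty_rounds,
                "significant_fraction": self.significant_fraction,
                "histogram": self.histogram.tolist(),
                "seed": self.seed,
                "config": self.config,
                "extras": self.extras,
                "calls": [
                    {
                        "p_value": c.p_value,
                        "significant": c.significant,
                        "categorical": c.categorical,
                        "pair_id": c.pair_id,
                        "direction": c.direction,
                        "volume": c.volume,
                        "cube_id": c.cube_id,
                    }
                    for c in self.calls
                ],
            },
            sort_keys=True,
        )


def _histogram(calls: list[SignificanceCall]) -> np.ndarray:
    p = np.array([c.p_value for c in calls]) if calls else np.zeros(0)
    # right-closed final bin so p = 1.0 lands in the last bin
    counts, _ = np.histogram(p, bins=np.linspace(0, 1, 11))
    return counts


def _report(calls, n_empty, seed, config: Config, **extras) -> ExperimentReport:
    return ExperimentReport(
        calls=calls,
        histogram=_histogram(calls),
        n_tests=len(calls),
        n_empty_rounds=n_empty,
        seed=seed,
        config={"alpha": config.alpha, "volume_floor": config.volume_floor},
        extras=extras,
    )


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def _pair_fragments(family, config) -> dict[tuple[int, int], list]:
    """Fragments for every unordered family pair, computed once; the
    hold-out drivers re-pool subsets of this cache instead of re-running
    the Boolean differences per training round."""
    return {
        (a, b): fragments_between(family[a], family[b], config, pair_id=f"{a}-{b}")
        for a, b in combinations(range(len(family)), 2)
    }


def leave_one_out(
    family: list[MeshSolid],
    outgroup: list[MeshSolid],
    config: Config = DEFAULT_CONFIG,
) -> ExperimentReport:
    """Hold out each family member; train on the rest; score the largest
    fragment between the held-out cavity and each outgroup cavity."""
    if len(family) < 3:
        raise ValueError("family must have >= 3 members")
    if not outgroup:
        raise ValueError("need at least one outgroup cavity")
    cache = _pair_fragments(family, config)
    calls, n_empty = [], 0
    for h in range(len(family)):
        rest = [c for i, c in enumerate(family) if i != h]
        pool = [
            fr for (a, b), frs in cache.items() if h not in (a, b) for fr in frs
        ]
        model = train_standard_model(rest, config, fragments=pool)
        for o, out_cav in enumerate(outgroup):
            frags = fragments_between(family[h], out_cav, config, pair_id=f"held{h}-out{o}")
            if not frags:
                n_empty += 1
                continue
            calls.append(evaluate_fragment(model, frags[0], config))
    return _report(calls, n_empty, config.seed, config)


def leave_two_out(
    family: list[MeshSolid],
    config: Config = DEFAULT_CONFIG,
) -> ExperimentReport:
    """For every unordered member pair: train on the remainder and score
    every fragment between the pair (same-specificity calibration)."""
    if len(family) < 4:
        raise ValueError("family must have >= 4 members")
    cache = _pair_fragments(family, config)
    calls, n_empty = [], 0
    for a, b in combinations(range(len(family)), 2):
        rest = [c for i, c in enumerate(family) if i not in (a, b)]
        pool = [
            fr
            for (i, j), frs in cache.items()
            if i not in (a, b) and j not in (a, b)
            for fr in frs
        ]
        model = train_standard_model(rest, config, fragments=pool)
        frags = cache[(a, b)]
        if not frags:
            n_empty += 1
            continue
        for fr in frags:
            calls.append(evaluate_fragment(model, fr, config))
    return _report(calls, n_empty, config.seed, config)


def regional_scan(
    train_family: list[MeshSolid],
    test_pair: tuple[MeshSolid, MeshSolid],
    config: Config = DEFAULT_CONFIG,
    side: float = 5.0,
    margin: float = 5.0,
    cubes: list[RegionCube] | None = None,
) -> ExperimentReport:
    """Train a regional model per lattice cube and evaluate every test
    fragment in every cube (categorical calls included)."""
    if cubes is None:
        cubes = build_lattice(train_family, side=side, margin=margin)
    pool = training_fragments(train_family, config)
    models = [
        train_regional_model(train_family, cube, config, fragments=pool)
        for cube in cubes
    ]
    test_frags = fragments_between(test_pair[0], test_pair[1], config, pair_id="test")
    calls = []
    n_empty_cubes = sum(m.is_empty for m in models)
    for rm in models:
        for fr in test_frags:
            call = evaluate_fragment(rm, fr, config)
            if call is not None:
                calls.append(call)
    return _report(
        calls, 0, config.seed, config,
        n_cubes=len(cubes),
        n_empty_cubes=n_empty_cubes,
        n_test_fragments=len(test_frags),
        n_training_fragments=len(pool),
    )
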