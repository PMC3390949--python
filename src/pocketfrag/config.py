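"""Package-wide configuration: tolerances, grid spacings and RNG seeding.

A single :class:`Config` object travels through the pipeline so that every
numeric knob (weld tolerance, degenerate-ray tolerance, CSG grid spacing,
minimum fragment volume, significance level) has one authoritative value,
surfaced as CLI flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Config:
    """Tolerances and defaults shared by the geometry and statistics layers.

    Attributes
    ----------
    weld_tol : float
        Duplicate-vertex welding distance on mesh ingest, in Å.
    ray_tol : float
        Barycentric / parametric distance below which a ray-triangle hit is
        declared degenerate and the ray is re-drawn.
    max_ray_retries : int
        Number of fresh random directions tried before a hard error.
    csg_spacing : float
        Grid spacing (Å) of the voxel CSG backend used for curved solids.
    ses_spacing : float
        Grid spacing (Å) for solvent-excluded-surface construction.
    volume_floor : float
        Minimum fragment volume (Å^3) retained for statistics.
    alpha : float
        Significance threshold for fragment calls.
    repair : bool
        Whether to weld duplicate vertices / drop degenerate triangles on
        ingest (the ``--no-repair`` CLI flag clears it).
    seed : int
        Seed for every internal RNG (ray directions, jitter).
    """

    weld_tol: float = 1e-6
    ray_tol: float = 1e-9
    max_ray_retries: int = 32
    csg_spacing: float = 0.25
    ses_spacing: float = 0.5
    volume_floor: float = 0.1
    alpha: float = 0.05
    repair: bool = True
    seed: int = 0

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))

    def with_(self, **kw) -> "Config":
        return replace(self, **kw)


DEFAULT_CONFIG = Config()
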