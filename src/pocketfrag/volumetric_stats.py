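"""Log-normal models of cavity-fragment volume: standard and regionalized.

The standard model is trained on the pooled fragment volumes generated
between all pairs of cavities sharing a binding specificity.  Fragment
volumes are strongly right-skewed and closely log-normal, so the model fits
``ln v`` with sample mean x̄ and standard deviation s, and scores a query
fragment of volume v by the upper-tail probability

    p = 1 - Φ((ln v - x̄) / s)

where Φ is the standard normal CDF.  A small p (below ``alpha``, default
0.05) marks a fragment too large to be consistent with same-specificity
variation.

The regionalized model restricts attention to a user-defined axis-aligned
cube g: every training fragment is clipped (Boolean intersection) to g,
clipped-away fragments are discarded, and the surviving volumes are fitted
as above.  A cube that no training fragment reaches carries no evidence of
natural variation there, so any test fragment that does reach it is called
significant *categorically* rather than numerically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .config import Config, DEFAULT_CONFIG
from .mesh_core import MeshSolid
from .fragmenter import Fragment, fragments_between
from . import csg_ops

log = logging.getLogger(__name__)

__all__ = [
    "VolumeModel",
    "RegionCube",
    "RegionalModel",
    "SignificanceCall",
    "fit_lognormal",
    "p_value",
    "train_standard_model",
    "build_lattice",
    "train_regional_model",
    "evaluate_fragment",
    "compare_distributions",
    "training_fragments",
]


class FitError(ValueError):
    """Too few / degenerate training volumes for a log-normal fit."""


@dataclass
class VolumeModel:
    """Fitted log-normal volume model.

    ``log_mean``/``log_sd`` are the mean and standard deviation of the
    natural-log volumes (unbiased, n-1 denominator by default); ``volumes``
    retains the training values for diagnostics (histograms, q-q plots).
    """

    log_mean: float
    log_sd: float
    n: int
    volumes: np.ndarray
    alpha: float = 0.05

    def to_json(self) -> str:
        return json.dumps(
            {
                "log_mean": self.log_mean,
                "log_sd": self.log_sd,
                "n": self.n,
                "alpha": self.alpha,
                "volumes": list(map(float, self.volumes)),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "VolumeModel":
        d = json.loads(text)
        return cls(
            log_mean=d["log_mean"],
            log_sd=d["log_sd"],
            n=d["n"],
            volumes=np.asarray(d["volumes"], dtype=float),
            alpha=d.get("alpha", 0.05),
        )


@dataclass(frozen=True)
class RegionCube:
    """Axis-aligned cube region g."""

    center: tuple[float, float, float]
    side: float = 5.0
    id: int = 0

    def __post_init__(self):
        if self.side <= 0:
            raise ValueError("cube side must be positive")

    @property
    def bounds(self) -> np.ndarray:
        c = np.asarray(self.center, float)
        return np.array([c - self.side / 2, c + self.side / 2])

    def mesh(self) -> MeshSolid:
        lo, hi = self.bounds
        return MeshSolid.box(lo, hi)


@dataclass
class RegionalModel:
    """A cube region plus either a fitted model or the EMPTY marker.

    EMPTY (``model is None``) means no training fragment intersected the
    cube with volume above the floor; significance there is categorical.
    """

    cube: RegionCube
    model: VolumeModel | None
    n_training_hits: int = 0

    @property
    def is_empty(self) -> bool:
        return self.model is None


@dataclass
class SignificanceCall:
    """p-value (or categorical flag) for one evaluated fragment."""

    p_value: float            # serialized 0.0 for categorical calls
    significant: bool
    categorical: bool = False
    pair_id: str = ""
    direction: str = ""
    volume: float = 0.0
    cube_id: int | None = None


# ---------------------------------------------------------------------------
# fitting and p-values
# ---------------------------------------------------------------------------

def fit_lognormal(
    volumes, alpha: float = 0.05, unbiased: bool = True
) -> VolumeModel:
    """Fit a log-normal by the sample mean and standard deviation of the
    log-transformed volumes.

    ``unbiased`` selects the n-1 denominator for the spread (default); the
    MLE (n) variant is available for sensitivity checks.
    """
    v = np.asarray(list(volumes), dtype=float)
    if len(v) < 2:
        raise FitError(
            f"need >= 2 volumes to fit (got {len(v)}); "
            "treat the region as EMPTY / categorical instead"
        )
    if np.any(v <= 0):
        raise FitError("all volumes must be positive")
    logs = np.log(v)
    sd = float(np.std(logs, ddof=1 if unbiased else 0))
    if sd == 0.0:
        raise FitError("zero spread in log-volumes; model undefined")
    return VolumeModel(
        log_mean=float(np.mean(logs)), log_sd=sd, n=len(v), volumes=v, alpha=alpha
    )


def p_value(model: VolumeModel, v: float) -> float:
    """Upper-tail probability of observing a fragment at least as large as v.

    p = 1 - Φ((ln v - x̄)/s).  The log-normal is supported on x > 0, so the
    normalization over x >= 0 is identically one and no truncation
    correction is needed.
    """
    if v <= 0:
        raise ValueError("fragment volume must be positive")
    z = (np.log(v) - model.log_mean) / model.log_sd
    return float(stats.norm.sf(z))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def training_fragments(
    cavities: list[MeshSolid], config: Config = DEFAULT_CONFIG
) -> list[Fragment]:
    """Fragments pooled over all unordered cavity pairs, both directions."""
    frags: list[Fragment] = []
    for a, b in combinations(range(len(cavities)), 2):
        frags.extend(
            fragments_between(cavities[a], cavities[b], config, pair_id=f"{a}-{b}")
        )
    return frags


def train_standard_model(
    cavities: list[MeshSolid],
    config: Config = DEFAULT_CONFIG,
    fragments: list[Fragment] | None = None,
) -> VolumeModel:
    """Standard model: pool fragment volumes over all cavity pairs and fit.

    ``fragments`` may carry a precomputed pool (e.g. shared with regional
    training); otherwise fragments are generated here.
    """
    if len(cavities) < 2:
        raise ValueError("need at least two cavities to train")
    if fragments is None:
        fragments = training_fragments(cavities, config)
    vols = [fr.volume for fr in fragments]
    if not vols:
        raise FitError("no fragments between any cavity pair (all identical?)")
    return fit_lognormal(vols, alpha=config.alpha)


def build_lattice(
    cavities: list[MeshSolid],
    side: float = 5.0,
    margin: float = 5.0,
) -> list[RegionCube]:
    """Space-filling lattice of non-overlapping cubes covering the joint
    bounding box of the cavities expanded by ``margin`` (Å).

    The lattice origin is the lower corner of the expanded box; the count
    per axis is the ceiling of extent/side, so the lattice always covers the
    box completely.
    """
    live = [c for c in cavities if not c.is_empty]
    if not live:
        raise ValueError("no non-empty cavities")
    lo = np.min([c.bounds[0] for c in live], axis=0) - margin
    hi = np.max([c.bounds[1] for c in live], axis=0) + margin
    counts = np.maximum(np.ceil((hi - lo) / side - 1e-12).astype(int), 1)
    cubes = []
    cid = 0
    for i in range(counts[0]):
        for j in range(counts[1]):
            for k in range(counts[2]):
                center = lo + side * (np.array([i, j, k]) + 0.5)
                cubes.append(RegionCube(center=tuple(center), side=side, id=cid))
                cid += 1
    return cubes


def clip_fragment_volume(
    fragment: Fragment | MeshSolid, cube: RegionCube, config: Config = DEFAULT_CONFIG
) -> float:
    """Volume of (fragment ∩ cube)."""
    mesh = fragment.mesh if isinstance(fragment, Fragment) else fragment
    res = csg_ops.intersection(mesh, cube.mesh(), config, names=("fragment", f"cube{cube.id}"))
    return res.volume


def train_regional_model(
    cavities: list[MeshSolid],
    cube: RegionCube,
    config: Config = DEFAULT_CONFIG,
    fragments: list[Fragment] | None = None,
) -> RegionalModel:
    """Regional model for cube g: clip every training fragment to g, drop
    fragments that miss g (or survive below the volume floor), fit the rest.

    A cube with no surviving training volume — or too few (< 2) to define a
    log-normal spread — is EMPTY and triggers categorical significance.
    """
    if fragments is None:
        fragments = training_fragments(cavities, config)
    vols = []
    for fr in fragments:
        cv = clip_fragment_volume(fr, cube, config)
        if cv >= config.volume_floor:
            vols.append(cv)
    if len(vols) < 2:
        return RegionalModel(cube=cube, model=None, n_training_hits=len(vols))
    try:
        model = fit_lognormal(vols, alpha=config.alpha)
    except FitError:
        return RegionalModel(cube=cube, model=None, n_training_hits=len(vols))
    return RegionalModel(cube=cube, model=model, n_training_hits=len(vols))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_fragment(
    model: VolumeModel | RegionalModel,
    fragment: Fragment | float,
    config: Config = DEFAULT_CONFIG,
) -> SignificanceCall | None:
    """Significance call for one fragment.

    Against a :class:`VolumeModel` the fragment volume is scored directly.
    Against a :class:`RegionalModel` the fragment is first clipped to the
    cube; a clipped-empty fragment yields no call (returns ``None``); a
    nonempty clipped fragment in an EMPTY region is categorically
    significant (serialized with p = 0 and the categorical flag set).
    """
    pair_id = direction = ""
    if isinstance(fragment, Fragment):
        pair_id, direction = fragment.pair_id, fragment.direction
    if isinstance(model, RegionalModel):
        v = (
            clip_fragment_volume(fragment, model.cube, config)
            if isinstance(fragment, Fragment)
            else float(fragment)
        )
        if v < config.volume_floor:
            return None
        if model.is_empty:
            return SignificanceCall(
                p_value=0.0, significant=True, categorical=True,
                pair_id=pair_id, direction=direction, volume=v,
                cube_id=model.cube.id,
            )
        p = p_value(model.model, v)
        return SignificanceCall(
            p_value=p, significant=p < model.model.alpha,
            pair_id=pair_id, direction=direction, volume=v,
            cube_id=model.cube.id,
        )
    v = fragment.volume if isinstance(fragment, Fragment) else float(fragment)
    p = p_value(model, v)
    return SignificanceCall(
        p_value=p, significant=p < model.alpha,
        pair_id=pair_id, direction=direction, volume=v,
    )


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

_FAMILIES = {
    # name -> (frozen-dist factory, #free parameters)
    "lognormal": (lambda x: stats.lognorm.fit(x, floc=0), stats.lognorm, 2),
    "gamma": (lambda x: stats.gamma.fit(x, floc=0), stats.gamma, 2),
    "weibull": (lambda x: stats.weibull_min.fit(x, floc=0), stats.weibull_min, 2),
    "pareto": (lambda x: stats.pareto.fit(x, floc=0), stats.pareto, 2),
    "gev": (lambda x: stats.genextreme.fit(x), stats.genextreme, 3),
}


@dataclass
class FitReport:
    family: str
    params: tuple
    loglik: float
    aic: float
    qq: np.ndarray | None  # (n, 2) theoretical vs sample quantiles
    failed: bool = False


def compare_distributions(volumes, min_n: int = 20) -> list[FitReport]:
    """Maximum-likelihood fits of the five candidate families (gamma,
    Weibull, Pareto, generalized extreme value, log-normal), ranked by AIC,
    with q-q pairs for plotting.  Families whose fit fails (non-convergence,
    degenerate sample) are flagged and ranked last."""
    v = np.asarray(list(volumes), dtype=float)
    if len(v) < min_n:
        raise ValueError(f"need >= {min_n} values (got {len(v)})")
    reports = []
    probs = (np.arange(1, len(v) + 1) - 0.5) / len(v)
    sample_q = np.sort(v)
    degenerate = np.ptp(v) == 0
    for name, (fitter, dist, k) in _FAMILIES.items():
        if degenerate:
            reports.append(FitReport(name, (), -np.inf, np.inf, None, failed=True))
            continue
        try:
            params = fitter(v)
            ll = float(np.sum(dist.logpdf(v, *params)))
            if not np.isfinite(ll):
                raise FloatingPointError("non-finite log-likelihood")
            qq = np.column_stack([dist.ppf(probs, *params), sample_q])
            reports.append(FitReport(name, tuple(params), ll, 2 * k - 2 * ll, qq))
        except Exception as exc:  # noqa: BLE001 - mark family failed
            log.info("fit of %s failed: %s", name, exc)
            reports.append(FitReport(name, (), -np.inf, np.inf, None, failed=True))
    reports.sort(key=lambda r: (r.failed, r.aic))
    return reports
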