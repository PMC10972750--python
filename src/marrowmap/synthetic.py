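"""Synthetic bone-marrow scene generator.

Generates labelled 3D marrow volumes with the statistical structure the
downstream analyses assume, together with ground truth for every stage:

* an axis-aligned slab (x–y extent × 35 µm optical-slice depth) whose
  y-extreme planes stand in for the endosteal bone surfaces;
* sinusoid and arteriole networks as tortuous capsule polylines;
* megakaryocytes placed perivascularly along sinusoids;
* a type-agnostic background pool of haematopoietic cells (complete spatial
  randomness over the slab — these positions, not uniform points, are what
  the empirical random-placement null resamples);
* multipotent/oligopotent HSPCs dispersed by a soft-core (repulsive)
  sequential process biased toward megakaryocytes and away from arterioles;
* planted production sites for the four blood lineages: sinusoid-attached
  CFU-E strings with budding erythroblast clusters, arteriole-anchored CLPs
  with graded B-cell stages within 150 µm, and focal neutrophil and
  monocyte/dendritic-cell sites on distinct sinusoids;
* pre CFU-E placed with a configurable sinusoid-contact probability;
* stochastic four-colour Confetti labels applied per clone.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .catalog import CONFETTI_COLOURS, mean_radius
from .errors import ConfigError, PlacementError
from .geometry import (
    TissueVolume,
    VesselNetwork,
    VesselSegment,
    CELL_COLUMNS,
    _min_dist_to_capsules,
)

__all__ = [
    "SizeDistribution",
    "VesselParams",
    "HspcParams",
    "ErythroidSiteParams",
    "BSiteParams",
    "MyeloidSiteParams",
    "PreCfuEParams",
    "ConfettiParams",
    "GeneratorConfig",
    "SyntheticMarrow",
    "build_volume",
    "place_vessel_network",
    "place_megakaryocytes",
    "place_pool",
    "place_hspc",
    "place_production_sites",
    "place_pre_cfu_e",
    "assign_confetti",
    "PRESETS",
]


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

@dataclass
class SizeDistribution:
    """Discretised gamma clipped to [min, max], calibrated to hit the mean.

    The raw gamma mean is adjusted (once, by root finding) so that the
    *clipped, rounded* distribution has expectation `mean`; only a range and
    mean/s.d. are known for the in-vivo size distributions.
    """

    min: int
    max: int
    mean: float
    sd: float

    def __post_init__(self):
        if not (self.min <= self.mean <= self.max):
            raise ConfigError("size distribution mean outside [min, max]")
        if self.sd < 0:
            raise ConfigError("size distribution sd must be >= 0")
        self._raw_mean = None

    def _clipped_mean(self, raw_mean: float) -> float:
        k = (raw_mean / self.sd) ** 2
        theta = self.sd**2 / raw_mean
        dist = stats.gamma(a=k, scale=theta)
        values = np.arange(self.min, self.max + 1)
        probs = dist.cdf(values + 0.5) - dist.cdf(values - 0.5)
        probs[0] = dist.cdf(self.min + 0.5)
        probs[-1] = dist.sf(self.max - 0.5)
        return float(np.dot(values, probs))

    def _calibrate(self) -> float:
        if self._raw_mean is None:
            if self.sd == 0:
                self._raw_mean = float(self.mean)
            else:
                lo = max(0.5 * self.sd, self.mean - 2 * self.sd)
                hi = self.mean + 2 * self.sd
                try:
                    self._raw_mean = float(
                        optimize.brentq(
                            lambda m: self._clipped_mean(m) - self.mean, lo, hi
                        )
                    )
                except ValueError:
                    self._raw_mean = float(self.mean)
        return self._raw_mean

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, int(round(self.mean)))
        m = self._calibrate()
        k = (m / self.sd) ** 2
        theta = self.sd**2 / m
        raw = rng.gamma(shape=k, scale=theta, size=n)
        return np.clip(np.rint(raw).astype(int), self.min, self.max)


@dataclass
class VesselParams:
    n_sinusoids: int = 40
    n_arterioles: int = 8
    sinusoid_radius_um: float = 9.0
    sinusoid_radius_sd_um: float = 2.0
    arteriole_radius_um: float = 5.0
    arteriole_radius_sd_um: float = 1.0
    n_steps: int = 22
    step_um: float = 60.0
    tortuosity: float = 0.25     # s.d. of per-step heading change, radians
    z_range_um: tuple[float, float] = (10.0, 25.0)


@dataclass
class HspcParams:
    """Soft-core dispersion of multipotent/oligopotent progenitors.

    Counts default to the observed per-segment sternal densities.  The
    repulsion (scale 120 µm, weight 4, hard floor at half the scale) was
    calibrated once so placement reproduces the observed dispersion of
    single HSPCs (median nearest-progenitor gap above 100 µm).
    """

    counts: dict[str, int] = field(
        default_factory=lambda: {
            "CD41- LT-HSC": 6,
            "CD41+ LT-HSC": 1,
            "ST-HSC": 10,
            "MPP2": 4,
            "MPP3": 8,
            "MkP": 12,
            "pre Meg-E": 12,
        }
    )
    repulsion_scale_um: float = 120.0
    repulsion_weight: float = 4.0
    mk_weight: float = 1.0              # enrichment toward megakaryocytes
    arteriole_avoidance: float = 1.0    # depletion near arterioles
    bias_range_um: float = 40.0         # decay length of both bias kernels
    max_tries_per_cell: int = 20000


@dataclass
class ErythroidSiteParams:
    n_sites: int = 10
    string_size: SizeDistribution = field(
        default_factory=lambda: SizeDistribution(3, 23, 8.0, 4.0)
    )
    late_cluster_size: SizeDistribution = field(
        default_factory=lambda: SizeDistribution(19, 96, 40.0, 15.0)
    )
    n_late_clusters: int = 1
    early_clusters_per_site: tuple[int, int] = (1, 3)   # inclusive range
    early_cluster_size: tuple[float, float] = (5.0, 2.0)  # mean, sd
    n_reticulocytes_mean: float = 15.0
    n_rbc_mean: float = 10.0
    bud_offset_um: float = 20.0
    member_spacing_um: float = 12.7     # ~ one CFU-E diameter along the string
    site_spacing_um: float = 150.0      # min distance between site footprints


@dataclass
class BSiteParams:
    n_sites: int = 10
    pre_pro_b: tuple[float, float] = (2.0, 1.0)   # mean, sd per CLP
    pro_b: tuple[float, float] = (3.0, 2.0)
    pre_b: tuple[float, float] = (16.0, 8.0)
    # radial bands (µm, centre distance from the CLP) encode the stage
    # gradient: more mature cells sit farther out, all within 150 µm
    stage_bands_um: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "pre-pro B": (20.0, 60.0),
            "pro B": (40.0, 90.0),
            "pre B": (50.0, 140.0),
        }
    )
    clp_spacing_um: float = 320.0


@dataclass
class MyeloidSiteParams:
    n_neutrophil_sites: int = 10
    pn_per_site: tuple[float, float] = (8.0, 3.0)
    n_monodc_sites: int = 6
    progeny_per_site: tuple[float, float] = (6.0, 2.0)
    cdc_fraction: float = 0.3
    progeny_radius_um: float = 40.0
    site_spacing_um: float = 120.0


@dataclass
class PreCfuEParams:
    count: int = 30
    contact_fraction: float = 0.6       # observed sinusoid-contact fraction
    clearance_um: float = 5.0           # min vessel gap for non-contact cells


@dataclass
class ConfettiParams:
    fraction: float = 0.073             # Cre recombination fraction
    colour_weights: dict[str, float] = field(
        default_factory=lambda: {c: 0.25 for c in CONFETTI_COLOURS}
    )
    string_clone_count: int = 3         # clones recruited per CFU-E string
    b_share_prob: float = 0.3           # progeny sharing the CLP clone
    myeloid_share_prob: float = 0.5


@dataclass
class GeneratorConfig:
    volume_extent_um: tuple[float, float, float] = (2000.0, 1250.0, 35.0)
    pool_count: int = 50_000
    per_type_frequency: dict[str, int] = field(default_factory=dict)
    vessel_params: VesselParams = field(default_factory=VesselParams)
    n_megakaryocytes: int = 40
    hspc: HspcParams = field(default_factory=HspcParams)
    erythroid: ErythroidSiteParams = field(default_factory=ErythroidSiteParams)
    b_site: BSiteParams = field(default_factory=BSiteParams)
    myeloid: MyeloidSiteParams = field(default_factory=MyeloidSiteParams)
    pre_cfu_e: PreCfuEParams = field(default_factory=PreCfuEParams)
    confetti: ConfettiParams = field(default_factory=ConfettiParams)
    seed: int = 0

    def validate(self) -> None:
        if any(e <= 0 for e in self.volume_extent_um):
            raise ConfigError("volume extents must be positive")
        if not (0.0 <= self.confetti.fraction <= 1.0):
            raise ConfigError("confetti fraction must be in [0, 1]")
        if not (0.0 <= self.pre_cfu_e.contact_fraction <= 1.0):
            raise ConfigError("contact fraction must be in [0, 1]")
        if self.erythroid.string_size.min < 3:
            raise ConfigError("string-size minimum must be >= 3")
        if self.pool_count < 0:
            raise ConfigError("pool_count must be >= 0")
        if sum(self.per_type_frequency.values()) > self.pool_count:
            raise ConfigError("per_type_frequency totals exceed pool_count")

    @property
    def volume(self) -> TissueVolume:
        return TissueVolume(tuple(self.volume_extent_um))


@dataclass
class SyntheticMarrow:
    """A generated scene: cells, vessels, volume and ground truth."""

    cells: pd.DataFrame
    vessels: VesselNetwork
    volume: TissueVolume
    truth: dict
    config: GeneratorConfig

    @property
    def megakaryocytes(self) -> pd.DataFrame:
        return self.cells[self.cells["cell_type"] == "MK"]


# ---------------------------------------------------------------------------
# internal helpers
# ---------------------------------------------------------------------------

def _seed_streams(seed: int) -> dict[str, np.random.Generator]:
    names = [
        "vessels", "mk", "pool", "scatter", "hspc",
        "erythroid", "B", "neutrophil", "monoDC", "pre_cfu_e", "confetti",
    ]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _perp_basis(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = _unit(tangent)
    a = np.array([0.0, 0.0, 1.0]) if abs(t[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = _unit(np.cross(t, a))
    return u, np.cross(t, u)


class _PolylineWalk:
    """Arc-length parameterisation of a segment polyline."""

    def __init__(self, seg: VesselSegment):
        self.seg = seg
        d = np.linalg.norm(np.diff(seg.points, axis=0), axis=1)
        self.cum = np.concatenate([[0.0], np.cumsum(d)])
        self.length = float(self.cum[-1])

    def at(self, s: float) -> tuple[np.ndarray, np.ndarray]:
        """Axis point and local tangent at arc position s."""
        s = float(np.clip(s, 0.0, self.length))
        i = int(np.searchsorted(self.cum, s, side="right") - 1)
        i = min(i, len(self.cum) - 2)
        span = self.cum[i + 1] - self.cum[i]
        w = 0.0 if span == 0 else (s - self.cum[i]) / span
        p = (1 - w) * self.seg.points[i] + w * self.seg.points[i + 1]
        return p, _unit(self.seg.points[i + 1] - self.seg.points[i])


def _surface_point(
    walk: _PolylineWalk,
    s: float,
    azimuth: float,
    cell_radius: float,
    gap: float,
) -> np.ndarray:
    """Cell centre touching the capsule surface at arc position s."""
    axis_pt, tangent = walk.at(s)
    u, v = _perp_basis(tangent)
    n = math.cos(azimuth) * u + math.sin(azimuth) * v
    return axis_pt + (walk.seg.radius_um + cell_radius + gap) * n


def _min_dist_to_points(p: np.ndarray, cloud: list[np.ndarray]) -> float:
    if not cloud:
        return np.inf
    arr = np.vstack(cloud)
    return float(np.min(np.linalg.norm(arr - p, axis=1)))


# ---------------------------------------------------------------------------
# placement stages
# ---------------------------------------------------------------------------

def place_vessel_network(
    config: GeneratorConfig, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> VesselNetwork:
    """Random tortuous sinusoid/arteriole capsules inside the volume.

    Each vessel is a persistent random walk in the x–y plane (with mild z
    wander inside the slab) reflected off the volume margins, so every
    polyline vertex lies inside the volume.
    """
    vp = config.vessel_params
    rng = rng if rng is not None else np.random.default_rng(seed)
    ext = np.asarray(config.volume_extent_um)
    margin = 5.0
    segments = []

    def _walk(radius: float, vclass: str, sid: str) -> VesselSegment:
        z_lo, z_hi = vp.z_range_um
        z_hi = min(z_hi, ext[2] - margin)
        start = np.array(
            [
                rng.uniform(margin, ext[0] - margin),
                rng.uniform(margin, ext[1] - margin),
                rng.uniform(z_lo, z_hi),
            ]
        )
        heading = rng.uniform(0.0, 2.0 * math.pi)
        pts = [start]
        p = start.copy()
        for _ in range(vp.n_steps):
            heading += rng.normal(0.0, vp.tortuosity)
            step = np.array(
                [
                    math.cos(heading) * vp.step_um,
                    math.sin(heading) * vp.step_um,
                    rng.normal(0.0, 1.5),
                ]
            )
            q = p + step
            # reflect off margins
            for k, hi in enumerate(
                (ext[0] - margin, ext[1] - margin, z_hi)
            ):
                lo = margin if k < 2 else z_lo
                if q[k] < lo:
                    q[k] = 2 * lo - q[k]
                    if k == 0:
                        heading = math.pi - heading
                    elif k == 1:
                        heading = -heading
                if q[k] > hi:
                    q[k] = 2 * hi - q[k]
                    if k == 0:
                        heading = math.pi - heading
                    elif k == 1:
                        heading = -heading
            q = np.clip(q, [margin, margin, z_lo], [ext[0] - margin, ext[1] - margin, z_hi])
            pts.append(q)
            p = q
        return VesselSegment(id=sid, points=np.asarray(pts), radius_um=radius,
                             vclass=vclass)

    for i in range(vp.n_sinusoids):
        r = float(np.clip(rng.normal(vp.sinusoid_radius_um,
                                     vp.sinusoid_radius_sd_um), 5.0, 14.0))
        segments.append(_walk(r, "sinusoid", f"sin{i:03d}"))
    for i in range(vp.n_arterioles):
        r = float(np.clip(rng.normal(vp.arteriole_radius_um,
                                     vp.arteriole_radius_sd_um), 3.0, 8.0))
        segments.append(_walk(r, "arteriole", f"art{i:03d}"))
    return VesselNetwork(segments)


def place_megakaryocytes(
    config: GeneratorConfig,
    network: VesselNetwork,
    rng: np.random.Generator,
    id_start: int = 0,
) -> pd.DataFrame:
    """Megakaryocytes placed perivascularly along random sinusoids."""
    sinusoids = network.of_class("sinusoid")
    rows = []
    vol = config.volume
    r_mk = mean_radius("MK")
    for i in range(config.n_megakaryocytes):
        for _ in range(200):
            seg = sinusoids[rng.integers(len(sinusoids))] if sinusoids else None
            if seg is None:
                p = rng.uniform([0, 0, 0], config.volume_extent_um)
                break
            walk = _PolylineWalk(seg)
            p = _surface_point(
                walk,
                rng.uniform(0, walk.length),
                rng.uniform(0, 2 * math.pi),
                r_mk,
                rng.uniform(0.0, 2.0),
            )
            if vol.contains(p)[0]:
                break
        else:
            raise PlacementError("could not place megakaryocyte inside volume")
        rows.append((id_start + i, "MK", p[0], p[1], p[2], r_mk, "none"))
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


def place_pool(
    config: GeneratorConfig, rng: np.random.Generator, id_start: int = 0
) -> pd.DataFrame:
    """Type-agnostic background pool: CSR over the slab."""
    n = config.pool_count
    pts = rng.uniform([0.0, 0.0, 0.0], config.volume_extent_um, size=(n, 3))
    return pd.DataFrame(
        {
            "id": np.arange(id_start, id_start + n),
            "cell_type": "hematopoietic",
            "x_um": pts[:, 0],
            "y_um": pts[:, 1],
            "z_um": pts[:, 2],
            "radius_um": mean_radius("hematopoietic"),
            "confetti": "none",
        }
    )


def _scatter_types(
    config: GeneratorConfig, rng: np.random.Generator, id_start: int
) -> pd.DataFrame:
    """Extra dispersed typed cells requested via per_type_frequency (CSR)."""
    rows = []
    i = id_start
    for cell_type, count in config.per_type_frequency.items():
        r = mean_radius(cell_type)
        pts = rng.uniform([0.0, 0.0, 0.0], config.volume_extent_um,
                          size=(int(count), 3))
        for p in pts:
            rows.append((i, cell_type, p[0], p[1], p[2], r, "none"))
            i += 1
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


def place_hspc(
    config: GeneratorConfig,
    scene: "SyntheticMarrow",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    id_start: int | None = None,
) -> pd.DataFrame:
    """Soft-core sequential placement of HSPCs with niche biases.

    Proposals are uniform over the slab; a proposal is rejected outright if
    its gap to any placed HSPC is below half the repulsion scale, thinned
    with probability exp(-w·Σ(1 − gap/scale)) for neighbours inside the
    scale (Strauss-like soft core), and finally thinned by bounded
    exponential factors that pull cells toward megakaryocytes and push them
    away from arterioles.  With scale and both bias weights at 0 this is
    exactly CSR over the slab.
    """
    hp = config.hspc
    rng = rng if rng is not None else np.random.default_rng(seed)
    vol = scene.volume
    ext = np.asarray(config.volume_extent_um)
    mks = scene.megakaryocytes
    mk_pos = mks[["x_um", "y_um", "z_um"]].to_numpy(float) if len(mks) else None
    mk_rad = mks["radius_um"].to_numpy(float) if len(mks) else None
    art = scene.vessels._stacked("arteriole") if len(scene.vessels) else None

    placed_pos: list[np.ndarray] = []
    placed_rad: list[float] = []
    rows = []
    next_id = id_start if id_start is not None else (
        int(scene.cells["id"].max()) + 1 if len(scene.cells) else 0
    )
    bias_total = hp.mk_weight + hp.arteriole_avoidance
    for cell_type in hp.counts:
        r_cell = mean_radius(cell_type)
        for _ in range(int(hp.counts[cell_type])):
            for _attempt in range(hp.max_tries_per_cell):
                p = rng.uniform([0.0, 0.0, 0.0], ext)
                if placed_pos and hp.repulsion_scale_um > 0:
                    gaps = (
                        np.linalg.norm(np.vstack(placed_pos) - p, axis=1)
                        - np.asarray(placed_rad)
                        - r_cell
                    )
                    if np.any(gaps < hp.repulsion_scale_um / 2.0):
                        continue
                    if hp.repulsion_weight > 0:
                        pen = np.clip(
                            1.0 - gaps / hp.repulsion_scale_um, 0.0, None
                        ).sum()
                        if rng.random() > math.exp(-hp.repulsion_weight * pen):
                            continue
                if bias_total > 0:
                    score = 0.0
                    if hp.mk_weight > 0 and mk_pos is not None:
                        g = float(
                            np.min(np.linalg.norm(mk_pos - p, axis=1) - mk_rad)
                            - r_cell
                        )
                        score += hp.mk_weight * math.exp(
                            -max(g, 0.0) / hp.bias_range_um
                        )
                    if hp.arteriole_avoidance > 0 and art is not None:
                        d, _ = _min_dist_to_capsules(p[None, :], art[0], art[1], art[2])
                        g = float(d[0]) - r_cell
                        score += hp.arteriole_avoidance * (
                            1.0 - math.exp(-max(g, 0.0) / hp.bias_range_um)
                        )
                    if rng.random() > math.exp(score - bias_total):
                        continue
                break
            else:
                raise PlacementError(
                    f"could not place {cell_type} after "
                    f"{hp.max_tries_per_cell} tries: repulsion scale "
                    f"{hp.repulsion_scale_um} µm incompatible with density"
                )
            placed_pos.append(p)
            placed_rad.append(r_cell)
            rows.append((next_id, cell_type, p[0], p[1], p[2], r_cell, "none"))
            next_id += 1
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


# -- production sites -------------------------------------------------------

def _dart_cluster(
    rng: np.random.Generator,
    centre: np.ndarray,
    n: int,
    cell_radius: float,
    ext: np.ndarray,
    max_anchor_dist: float | None = None,
    anchor: np.ndarray | None = None,
) -> np.ndarray:
    """Dart-throw n cell centres around `centre` with a soft minimum
    separation of 0.8 cell diameters, confined to the slab (and optionally
    to a ball around `anchor`).  The working radius grows if packing gets
    tight, so requested sizes always fit."""
    sep = 1.6 * cell_radius
    v_cell = (4.0 / 3.0) * math.pi * (sep / 2.0) ** 3
    radius = max(8.0, (n * v_cell / 0.15 / ((4.0 / 3.0) * math.pi)) ** (1.0 / 3.0))
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries % 4000 == 0:
            radius *= 1.15
        # uniform in ball
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        p = centre + u * radius * rng.random() ** (1.0 / 3.0)
        if not np.all((p >= 0.0) & (p <= ext)):
            continue
        if max_anchor_dist is not None and anchor is not None:
            if np.linalg.norm(p - anchor) > max_anchor_dist:
                continue
        if pts and _min_dist_to_points(p, pts) < sep:
            continue
        pts.append(p)
    return np.vstack(pts)


class _SiteBuilder:
    """Shared bookkeeping for lineage site placement within one scene."""

    def __init__(self, config: GeneratorConfig, scene: SyntheticMarrow):
        self.config = config
        self.scene = scene
        self.ext = np.asarray(config.volume_extent_um)
        self.used_vessels: set = set(
            s.get("anchor_segment") for s in scene.truth.get("sites", [])
        )
        self.footprints: list[np.ndarray] = [
            np.asarray(s["footprint"]) for s in scene.truth.get("sites", [])
            if "footprint" in s
        ]
        self.next_id = int(scene.cells["id"].max()) + 1 if len(scene.cells) else 0
        self.rows: list[tuple] = []
        self.sites: list[dict] = []

    def new_cell(self, cell_type: str, p: np.ndarray) -> int:
        cid = self.next_id
        self.rows.append(
            (cid, cell_type, p[0], p[1], p[2], mean_radius(cell_type), "none")
        )
        self.next_id += 1
        return cid

    def free_sinusoid(self, rng: np.random.Generator) -> VesselSegment:
        free = [
            s for s in self.scene.vessels.of_class("sinusoid")
            if s.id not in self.used_vessels
        ]
        if not free:
            raise PlacementError(
                "anchor exhaustion: no unoccupied sinusoid left for a new "
                "production site (each anchor vessel hosts at most one lineage)"
            )
        return free[rng.integers(len(free))]

    def far_enough(self, pts: np.ndarray, spacing: float) -> bool:
        if not self.footprints:
            return True
        other = np.vstack(self.footprints)
        d = np.linalg.norm(
            other[None, :, :] - np.atleast_2d(pts)[:, None, :], axis=2
        )
        return bool(d.min() >= spacing)


def _place_erythroid(builder: _SiteBuilder, rng: np.random.Generator) -> None:
    cfg = builder.config.erythroid
    ext = builder.ext
    r_cfue = mean_radius("CFU-E")
    sizes = cfg.string_size.sample(rng, cfg.n_sites)
    for site_i in range(cfg.n_sites):
        size = int(sizes[site_i])
        for _attempt in range(300):
            seg = builder.free_sinusoid(rng)
            walk = _PolylineWalk(seg)
            need = size * cfg.member_spacing_um
            if walk.length < need + 40.0:
                continue
            s0 = rng.uniform(20.0, walk.length - need - 20.0)
            azimuth = rng.uniform(0.0, 2.0 * math.pi)
            member_pts = []
            s = s0
            ok = True
            for _m in range(size):
                placed = False
                for _try in range(60):
                    az = azimuth + rng.normal(0.0, 0.2)
                    p = _surface_point(walk, s, az, r_cfue, rng.uniform(0.0, 0.3))
                    if not np.all((p >= 0.0) & (p <= ext)):
                        continue
                    # strings are contiguous: keep the surface gap between
                    # consecutive members well below the linkage distance
                    # even across polyline kinks
                    if member_pts and (
                        np.linalg.norm(p - member_pts[-1]) > 2 * r_cfue + 6.0
                    ):
                        continue
                    member_pts.append(p)
                    azimuth = az
                    placed = True
                    break
                if not placed:
                    ok = False
                    break
                s += cfg.member_spacing_um + rng.uniform(-1.0, 1.0)
            if not ok or len(member_pts) != size:
                continue
            member_arr = np.vstack(member_pts)
            if not builder.far_enough(member_arr, cfg.site_spacing_um):
                continue
            break
        else:
            raise PlacementError(
                "could not place erythroid string: not enough separated "
                "sinusoid arc available (site count too high for the network)"
            )
        builder.used_vessels.add(seg.id)
        member_ids = [builder.new_cell("CFU-E", p) for p in member_pts]

        members: dict[str, list[int]] = {"CFU-E": member_ids}
        clusters: dict[str, list[list[int]]] = {"early": [], "late": []}

        def _bud(cell_type: str, n: int) -> list[int]:
            """A cluster budding from a random string member, all cells
            within capture distance of that member."""
            anchor_idx = rng.integers(size)
            anchor = member_arr[anchor_idx]
            _, tangent = walk.at(s0 + anchor_idx * cfg.member_spacing_um)
            u, v = _perp_basis(tangent)
            az = rng.uniform(0, 2 * math.pi)
            centre = anchor + (math.cos(az) * u + math.sin(az) * v) * cfg.bud_offset_um
            centre = np.clip(centre, 2.0, ext - 2.0)
            pts = _dart_cluster(
                rng, centre, n, mean_radius(cell_type), ext,
                max_anchor_dist=55.0, anchor=anchor,
            )
            return [builder.new_cell(cell_type, p) for p in pts]

        n_early = rng.integers(cfg.early_clusters_per_site[0],
                               cfg.early_clusters_per_site[1] + 1)
        for _c in range(n_early):
            n = int(np.clip(np.rint(rng.normal(*cfg.early_cluster_size)), 2, 12))
            ids = _bud("early erythroblast", n)
            members.setdefault("early erythroblast", []).extend(ids)
            clusters["early"].append(ids)
        for _c in range(cfg.n_late_clusters):
            n = int(cfg.late_cluster_size.sample(rng, 1)[0])
            ids = _bud("late erythroblast", n)
            members.setdefault("late erythroblast", []).extend(ids)
            clusters["late"].append(ids)
        for cell_type, mean_n in (
            ("reticulocyte", cfg.n_reticulocytes_mean),
            ("RBC", cfg.n_rbc_mean),
        ):
            n = int(rng.poisson(mean_n))
            if n:
                ids = _bud(cell_type, n)
                members.setdefault(cell_type, []).extend(ids)

        builder.footprints.append(member_arr)
        builder.sites.append(
            {
                "site_id": f"ery{site_i:03d}",
                "lineage": "erythroid",
                "anchor_segment": seg.id,
                "members": members,
                "clusters": clusters,
                "footprint": member_arr.tolist(),
            }
        )


def _place_b_sites(builder: _SiteBuilder, rng: np.random.Generator) -> None:
    cfg = builder.config.b_site
    ext = builder.ext
    arterioles = builder.scene.vessels.of_class("arteriole")
    if not arterioles and cfg.n_sites > 0:
        raise PlacementError("no arterioles available to anchor CLPs")
    r_clp = mean_radius("CLP")
    # candidate CLP anchors along all arterioles, then a greedy max-min
    # selection at the required spacing (robust where sequential rejection
    # can stall on a spatially clustered arteriole network)
    candidates: list[np.ndarray] = []
    for _ in range(200 * max(1, cfg.n_sites)):
        seg = arterioles[rng.integers(len(arterioles))]
        walk = _PolylineWalk(seg)
        p = _surface_point(
            walk,
            rng.uniform(0.0, walk.length),
            rng.uniform(0.0, 2.0 * math.pi),
            r_clp,
            rng.uniform(0.5, 10.0),
        )
        if np.all((p >= 0.0) & (p <= ext)) and builder.far_enough(p[None, :], 100.0):
            candidates.append(p)
    clp_positions: list[np.ndarray] = []
    if candidates and cfg.n_sites > 0:
        cand = np.vstack(candidates)
        # farthest-point greedy with restarts: near-optimal max-min packing
        for _restart in range(8):
            start = int(rng.integers(len(cand)))
            chosen = [start]
            dmin = np.linalg.norm(cand - cand[start], axis=1)
            while len(chosen) < cfg.n_sites:
                nxt = int(np.argmax(dmin))
                if dmin[nxt] < cfg.clp_spacing_um:
                    break
                chosen.append(nxt)
                dmin = np.minimum(dmin, np.linalg.norm(cand - cand[nxt], axis=1))
            if len(chosen) == cfg.n_sites:
                clp_positions = [cand[i] for i in chosen]
                break
    if len(clp_positions) < cfg.n_sites:
        raise PlacementError(
            "anchor exhaustion: cannot place "
            f"{cfg.n_sites} CLPs at the required spacing "
            f"({cfg.clp_spacing_um} µm) near arterioles"
        )
    for site_i in range(cfg.n_sites):
        p = clp_positions[site_i]
        clp_id = builder.new_cell("CLP", p)
        members: dict[str, list[int]] = {"CLP": [clp_id]}
        for cell_type, (mu, sd) in (
            ("pre-pro B", cfg.pre_pro_b),
            ("pro B", cfg.pro_b),
            ("pre B", cfg.pre_b),
        ):
            n = int(max(0, round(rng.normal(mu, sd))))
            lo, hi = cfg.stage_bands_um[cell_type]
            ids = []
            for _k in range(n):
                for _try in range(500):
                    u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    q = p + u * rng.uniform(lo, hi)
                    if np.all((q >= 0.0) & (q <= ext)):
                        break
                else:
                    raise PlacementError("cannot fit B-stage cell inside volume")
                ids.append(builder.new_cell(cell_type, q))
            members[cell_type] = ids
        builder.footprints.append(p[None, :])
        builder.sites.append(
            {
                "site_id": f"b{site_i:03d}",
                "lineage": "B",
                "anchor_segment": seg.id,
                "members": members,
                "footprint": [p.tolist()],
            }
        )


def _place_myeloid(
    builder: _SiteBuilder, rng: np.random.Generator, lineage: str
) -> None:
    cfg = builder.config.myeloid
    ext = builder.ext
    if lineage == "neutrophil":
        n_sites, focal_type, prefix = cfg.n_neutrophil_sites, "GP", "neu"
        count_dist = cfg.pn_per_site
    else:
        n_sites, focal_type, prefix = cfg.n_monodc_sites, "MDP", "mdc"
        count_dist = cfg.progeny_per_site
    r_focal = mean_radius(focal_type)
    for site_i in range(n_sites):
        for _attempt in range(300):
            seg = builder.free_sinusoid(rng)
            walk = _PolylineWalk(seg)
            p = _surface_point(
                walk,
                rng.uniform(20.0, max(20.0, walk.length - 20.0)),
                rng.uniform(0.0, 2.0 * math.pi),
                r_focal,
                rng.uniform(0.0, 0.3),
            )
            if not np.all((p >= 0.0) & (p <= ext)):
                continue
            if not builder.far_enough(p[None, :], cfg.site_spacing_um):
                continue
            break
        else:
            raise PlacementError(
                f"anchor exhaustion: no separated sinusoid left for a "
                f"{lineage} site"
            )
        builder.used_vessels.add(seg.id)
        focal_id = builder.new_cell(focal_type, p)
        n = int(np.clip(np.rint(rng.normal(*count_dist)), 1, None))
        members: dict[str, list[int]] = {focal_type: [focal_id]}
        fate = {}
        for _k in range(n):
            for _try in range(500):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                q = p + u * rng.uniform(8.0, cfg.progeny_radius_um)
                if np.all((q >= 0.0) & (q <= ext)):
                    break
            else:
                raise PlacementError("cannot fit myeloid progeny inside volume")
            if lineage == "neutrophil":
                cell_type = "PN"
            else:
                cell_type = "cDC" if rng.random() < cfg.cdc_fraction else "monocyte"
            members.setdefault(cell_type, []).append(
                builder.new_cell(cell_type, q)
            )
        if lineage == "monoDC":
            n_cdc = len(members.get("cDC", []))
            n_mono = len(members.get("monocyte", []))
            fate = {"cdc_fraction": n_cdc / max(1, n_cdc + n_mono)}
        builder.footprints.append(p[None, :])
        builder.sites.append(
            {
                "site_id": f"{prefix}{site_i:03d}",
                "lineage": lineage,
                "anchor_segment": seg.id,
                "members": members,
                "fate": fate,
                "footprint": [p.tolist()],
            }
        )


def place_production_sites(
    lineage: str,
    config: GeneratorConfig,
    scene: SyntheticMarrow,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Plant production sites for one lineage; returns (new cells, truth).

    erythroid — contiguous CFU-E strings in surface contact with a single
    sinusoid, plus budding early-erythroblast clusters, one large late-
    erythroblast cluster, reticulocytes and RBC, all within the 50 µm
    capture distance of a string member; B — a CLP near an arteriole with
    pre-pro/pro/pre B at increasing distances within 150 µm; neutrophil and
    monoDC — a focal progenitor on an unoccupied sinusoid with immature
    progeny within 50 µm.  Anchor vessels are never shared across lineages.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    builder = _SiteBuilder(config, scene)
    if lineage == "erythroid":
        _place_erythroid(builder, rng)
    elif lineage == "B":
        _place_b_sites(builder, rng)
    elif lineage in ("neutrophil", "monoDC"):
        _place_myeloid(builder, rng, lineage)
    else:
        raise ConfigError(f"unknown lineage {lineage!r}")
    return pd.DataFrame(builder.rows, columns=CELL_COLUMNS), builder.sites


def place_pre_cfu_e(
    config: GeneratorConfig,
    scene: SyntheticMarrow,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[int, bool]]:
    """pre CFU-E with a configured probability of direct sinusoid contact.

    Contact cells sit on a sinusoid surface (gap ≤ 0.3 µm); the remainder
    are placed uniformly with at least `clearance_um` of vessel gap.
    """
    pc = config.pre_cfu_e
    ext = np.asarray(config.volume_extent_um)
    sinusoids = scene.vessels.of_class("sinusoid")
    stacked = scene.vessels._stacked(None)
    r_cell = mean_radius("pre CFU-E")
    next_id = int(scene.cells["id"].max()) + 1 if len(scene.cells) else 0
    rows, contact_truth = [], {}
    n_contact = int(round(pc.count * pc.contact_fraction))
    for i in range(pc.count):
        on_vessel = i < n_contact
        for _try in range(5000):
            if on_vessel:
                seg = sinusoids[rng.integers(len(sinusoids))]
                walk = _PolylineWalk(seg)
                p = _surface_point(
                    walk,
                    rng.uniform(0.0, walk.length),
                    rng.uniform(0.0, 2.0 * math.pi),
                    r_cell,
                    rng.uniform(0.0, 0.3),
                )
                if not np.all((p >= 0.0) & (p <= ext)):
                    continue
                # surface contact can be spoiled by a second vessel passing
                # through the same spot; accept as long as no vessel overlaps
                d, _ = _min_dist_to_capsules(p[None, :], *stacked[:3])
                if d[0] - r_cell < -0.5:
                    continue
                break
            else:
                p = rng.uniform([0.0, 0.0, 0.0], ext)
                d, _ = _min_dist_to_capsules(p[None, :], *stacked[:3])
                if d[0] - r_cell > pc.clearance_um:
                    break
        else:
            raise PlacementError("could not place pre CFU-E under contact rule")
        cid = next_id
        next_id += 1
        rows.append((cid, "pre CFU-E", p[0], p[1], p[2], r_cell, "none"))
        contact_truth[cid] = bool(on_vessel)
    return pd.DataFrame(rows, columns=CELL_COLUMNS), contact_truth


# -- Confetti ---------------------------------------------------------------

def assign_confetti(
    cells: pd.DataFrame,
    confetti: ConfettiParams,
    truth: dict,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Assign clone ids per structure and Confetti colours per clone.

    Clone policy: each erythroblast cluster inherits the single clone of its
    nearest CFU-E string member (monoclonal); CFU-E string members draw from
    a small per-string clone set (oligoclonal); B and myeloid progeny share
    their focal progenitor's clone with a configured probability; every
    other cell is its own clone.  Each clone is then labelled independently
    with the configured recombination fraction and given one of the four
    colours, which all its cells inherit.
    """
    if not (0.0 <= confetti.fraction <= 1.0):
        raise ConfigError("confetti fraction must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    cells = cells.copy()
    pos = cells.set_index("id")[["x_um", "y_um", "z_um"]]

    clone_of: dict[int, int] = {}
    next_clone = 0

    def new_clone() -> int:
        nonlocal next_clone
        next_clone += 1
        return next_clone - 1

    for site in truth.get("sites", []):
        members = site["members"]
        if site["lineage"] == "erythroid":
            string_ids = members.get("CFU-E", [])
            k = min(confetti.string_clone_count, max(1, len(string_ids)))
            string_clones = [new_clone() for _ in range(k)]
            for cid in string_ids:
                clone_of[cid] = string_clones[rng.integers(k)]
            string_pos = pos.loc[string_ids].to_numpy(float)
            clusters = site.get("clusters", {})
            for kind in ("early", "late"):
                for cluster in clusters.get(kind, []):
                    centre = pos.loc[cluster].to_numpy(float).mean(axis=0)
                    j = int(
                        np.argmin(np.linalg.norm(string_pos - centre, axis=1))
                    )
                    inherited = clone_of[string_ids[j]]
                    for cid in cluster:
                        clone_of[cid] = inherited
            for cell_type in ("reticulocyte", "RBC"):
                for cid in members.get(cell_type, []):
                    clone_of[cid] = new_clone()
        elif site["lineage"] == "B":
            focal = members["CLP"][0]
            focal_clone = new_clone()
            clone_of[focal] = focal_clone
            for cell_type in ("pre-pro B", "pro B", "pre B"):
                for cid in members.get(cell_type, []):
                    clone_of[cid] = (
                        focal_clone
                        if rng.random() < confetti.b_share_prob
                        else new_clone()
                    )
        else:  # neutrophil / monoDC
            focal_type = "GP" if site["lineage"] == "neutrophil" else "MDP"
            focal = members[focal_type][0]
            focal_clone = new_clone()
            clone_of[focal] = focal_clone
            for cell_type, ids in members.items():
                if cell_type == focal_type:
                    continue
                for cid in ids:
                    clone_of[cid] = (
                        focal_clone
                        if rng.random() < confetti.myeloid_share_prob
                        else new_clone()
                    )

    clone_arr = np.empty(len(cells), dtype=int)
    id_arr = cells["id"].to_numpy()
    singleton_mask = np.array([cid not in clone_of for cid in id_arr])
    n_single = int(singleton_mask.sum())
    clone_arr[singleton_mask] = np.arange(next_clone, next_clone + n_single)
    next_clone += n_single
    clone_arr[~singleton_mask] = [
        clone_of[cid] for cid in id_arr[~singleton_mask]
    ]

    # label clones
    colours = list(confetti.colour_weights)
    weights = np.asarray([confetti.colour_weights[c] for c in colours], float)
    weights = weights / weights.sum() if weights.sum() > 0 else None
    labelled = rng.random(next_clone) < confetti.fraction
    colour_idx = rng.choice(len(colours), size=next_clone, p=weights)
    clone_colour = np.where(
        labelled, np.asarray(colours, dtype=object)[colour_idx], "none"
    )
    cells["confetti"] = clone_colour[clone_arr]

    truth = dict(truth)
    truth["clone_of"] = {int(c): int(k) for c, k in zip(id_arr, clone_arr)}
    truth["labelled_clones"] = int(labelled.sum())
    return cells, truth


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def build_volume(config: GeneratorConfig, seed: int | None = None) -> SyntheticMarrow:
    """Generate a complete labelled scene; (config, seed) fully determine it."""
    config.validate()
    seed = config.seed if seed is None else seed
    streams = _seed_streams(seed)
    volume = config.volume

    vessels = place_vessel_network(config, rng=streams["vessels"])
    truth: dict = {"sites": [], "process_of": {}}
    scene = SyntheticMarrow(
        cells=pd.DataFrame(columns=CELL_COLUMNS),
        vessels=vessels, volume=volume, truth=truth, config=config,
    )

    frames = []
    mks = place_megakaryocytes(config, vessels, streams["mk"], id_start=0)
    frames.append(mks)
    scene.cells = pd.concat([f for f in frames if len(f)], ignore_index=True)

    pool = place_pool(config, streams["pool"], id_start=len(scene.cells))
    frames.append(pool)
    scene.cells = pd.concat([f for f in frames if len(f)], ignore_index=True)

    if config.per_type_frequency:
        scatter = _scatter_types(config, streams["scatter"],
                                 id_start=len(scene.cells))
        frames.append(scatter)
        scene.cells = pd.concat([f for f in frames if len(f)], ignore_index=True)

    hspcs = place_hspc(config, scene, rng=streams["hspc"])
    frames.append(hspcs)
    scene.cells = pd.concat([f for f in frames if len(f)], ignore_index=True)

    for lineage in ("erythroid", "B", "neutrophil", "monoDC"):
        new_cells, sites = place_production_sites(
            lineage, config, scene, rng=streams[lineage]
        )
        frames.append(new_cells)
        scene.cells = pd.concat([f for f in frames if len(f)], ignore_index=True)
        truth["sites"].extend(sites)

    pre_cfue, contact_truth = place_pre_cfu_e(config, scene, streams["pre_cfu_e"])
    frames.append(pre_cfue)
    scene.cells = pd.concat([f for f in frames if len(f)], ignore_index=True)
    truth["pre_cfu_e_contact"] = contact_truth

    # record the placement process per cell
    process_names = ["MK", "pool"]
    if config.per_type_frequency:
        process_names.append("scatter")
    process_names += ["hspc", "erythroid", "B", "neutrophil", "monoDC",
                      "pre_cfu_e"]
    for frame, name in zip(frames, process_names):
        for cid in frame["id"]:
            truth["process_of"][int(cid)] = name

    scene.cells, scene.truth = assign_confetti(
        scene.cells, config.confetti, truth, rng=streams["confetti"]
    )
    assert scene.volume.contains(
        scene.cells[["x_um", "y_um", "z_um"]].to_numpy(float)
    ).all(), "generated cell centre outside volume"
    return scene


# ---------------------------------------------------------------------------
# presets: anatomical endpoints of the stress models (site numbers and
# compositions only; no mechanistic simulation of stress signalling)
# ---------------------------------------------------------------------------

def _preset(**overrides) -> Callable[[], GeneratorConfig]:
    def make() -> GeneratorConfig:
        cfg = GeneratorConfig()
        for path, value in overrides.items():
            obj = cfg
            *parents, leaf = path.split(".")
            for p in parents:
                obj = getattr(obj, p)
            setattr(obj, leaf, value)
        return cfg
    return make


PRESETS: dict[str, Callable[[], GeneratorConfig]] = {
    # steady-state young sternum
    "steady_state": _preset(),
    # day-2 phlebotomy: erythroid sites up in number and output; B output down
    "phlebotomy_d2": _preset(**{
        "erythroid.n_sites": 18,
        "erythroid.late_cluster_size": SizeDistribution(19, 96, 55.0, 15.0),
        "b_site.pre_b": (10.0, 5.0),
    }),
    # G-CSF sternum: all production sites reduced in number and output
    "gcsf_sternum": _preset(**{
        "erythroid.n_sites": 4,
        "b_site.n_sites": 4,
        "myeloid.n_neutrophil_sites": 3,
        "myeloid.n_monodc_sites": 2,
        "myeloid.pn_per_site": (4.0, 2.0),
    }),
    # G-CSF tibia: granulopoiesis nearly doubled
    "gcsf_tibia": _preset(**{
        "myeloid.n_neutrophil_sites": 18,
        "erythroid.n_sites": 6,
        "b_site.n_sites": 6,
    }),
    # 20-month-old: site numbers maintained, outputs reduced; DC output up
    "aged": _preset(**{
        "erythroid.late_cluster_size": SizeDistribution(19, 96, 30.0, 12.0),
        "b_site.pre_b": (10.0, 5.0),
        "myeloid.pn_per_site": (5.0, 2.0),
        "myeloid.cdc_fraction": 0.5,
    }),
}
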