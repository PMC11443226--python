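"""Plant architecture and organ growth.

A daylily plant is modelled as a clump of shoots ("fans"); each shoot carries
13 phytomers (an opposite leaf pair per rank), optionally a scape (the
leafless flowering stem) with flower buds attached, plus a root compartment
that only consumes assimilate.  Organ expansion follows the determinate
sigmoid growth function of Yin and co-workers: the growth *rate* is

    dw/dt = c_m * ((t_e - t)/(t_e - t_m)) * (t/t_m)^(t_m/(t_e - t_m))

for organ age t in [0, t_e], with maximum rate c_m reached at t_m and growth
stopping at t_e.  Its exact integral (used for cumulative size) is

    w(t) = w_max * (1 + (t_e - t)/(t_e - t_m)) * (t/t_e)^(t_e/(t_e - t_m))

which guarantees w(t_e) = w_max; c_m is derived from (w_max, t_m, t_e).

Leaf area is tied to dry mass by the specific leaf area constant
SLA = 0.0023 m2 g-1; leaves are rendered as chains of parallelogram facets
arching from base to tip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SLA",
    "BetaGrowthParams",
    "Organ",
    "Phytomer",
    "Plant",
    "LeafGeometry",
    "LeafArchParams",
    "PhenologyEntry",
    "PhenologySchedule",
    "PlantLayout",
    "beta_growth_rate",
    "beta_growth_cumulative",
    "leaf_area_from_biomass",
    "build_leaf_geometry",
    "init_plant",
    "build_scene",
    "default_schedule",
]

#: Specific leaf area, m2 leaf per g leaf dry matter.
SLA = 0.0023

OrganKind = Literal["leaf", "scape", "bud", "root", "internode"]


@dataclass(frozen=True)
class BetaGrowthParams:
    """Determinate growth-curve parameters for one organ.

    Times are absolute simulation days; internally ages are measured from
    ``t_0``.  ``w_max`` is the final size (m) or mass (g); ``c_m`` (the
    maximum rate, at ``t_m``) is derived so the curve integrates to
    ``w_max`` exactly.
    """

    t_0: float
    t_m: float
    t_e: float
    w_max: float

    def __post_init__(self) -> None:
        if not (self.t_0 < self.t_m < self.t_e):
            raise ValueError(f"require t_0 < t_m < t_e, got {self.t_0}, {self.t_m}, {self.t_e}")
        if self.w_max <= 0:
            raise ValueError("w_max must be positive")

    @property
    def c_m(self) -> float:
        te = self.t_e - self.t_0
        tm = self.t_m - self.t_0
        return (
            self.w_max
            * (2.0 * te - tm)
            / (te * (te - tm))
            * (tm / te) ** (tm / (te - tm))
        )


def beta_growth_rate(t: float, p: BetaGrowthParams) -> float:
    """Potential growth rate dw/dt at absolute day ``t`` (0 outside [t_0, t_e])."""
    tau = t - p.t_0
    te = p.t_e - p.t_0
    tm = p.t_m - p.t_0
    if tau <= 0.0 or tau > te:
        return 0.0
    return p.c_m * ((te - tau) / (te - tm)) * (tau / tm) ** (tm / (te - tm))


def beta_growth_cumulative(t: float, p: BetaGrowthParams) -> float:
    """Cumulative size w(t); 0 at t_0, w_max at and beyond t_e."""
    tau = t - p.t_0
    te = p.t_e - p.t_0
    tm = p.t_m - p.t_0
    if tau <= 0.0:
        return 0.0
    if tau >= te:
        return p.w_max
    return p.w_max * (1.0 + (te - tau) / (te - tm)) * (tau / te) ** (te / (te - tm))


def leaf_area_from_biomass(biomass_dm: float) -> float:
    """Leaf area (m2) from leaf dry mass (g): area = SLA * biomass."""
    if biomass_dm < 0:
        raise ValueError("biomass must be >= 0")
    return SLA * biomass_dm


def beta_growth_cumulative_arrays(
    t: float, t_0: np.ndarray, t_m: np.ndarray, t_e: np.ndarray, w_max: np.ndarray
) -> np.ndarray:
    """Vectorized cumulative growth w(t) for arrays of curve parameters."""
    tau = np.clip(t - t_0, 0.0, t_e - t_0)
    te = t_e - t_0
    tm = t_m - t_0
    frac = np.clip(tau / te, 0.0, 1.0)
    with np.errstate(invalid="ignore"):
        w = w_max * (1.0 + (te - tau) / (te - tm)) * frac ** (te / (te - tm))
    return np.where(tau <= 0.0, 0.0, np.where(tau >= te, w_max, w))


# --- organs / plants ------------------------------------------------------


@dataclass
class Organ:
    """A structural unit carrying biomass, length and (for leaves) area."""

    kind: OrganKind
    rank: int
    shoot: int
    birth_day: float
    growth_len: Optional[BetaGrowthParams]  # length trajectory (m)
    growth_dm: Optional[BetaGrowthParams]  # dry-mass potential (g)
    biomass_dm: float = 0.0
    length: float = 0.0
    azimuth: float = 0.0  # radians
    absorbed_flux: float = 0.0  # W m-2 per unit leaf area (leaves)
    ppfd: float = 0.0  # umol m-2 s-1 (leaves)
    a_net: float = 0.0  # umol CO2 m-2 s-1 (leaves)
    t_leaf: float = float("nan")

    @property
    def area(self) -> float:
        """Leaf area (m2); zero for non-leaf organs."""
        return leaf_area_from_biomass(self.biomass_dm) if self.kind == "leaf" else 0.0

    def potential_increment(self, day: float, dt: float = 1.0) -> float:
        """Potential dry-mass gain over [day, day+dt] (g): the day's sink strength."""
        if self.growth_dm is None:
            return 0.0
        return beta_growth_cumulative(day + dt, self.growth_dm) - beta_growth_cumulative(
            day, self.growth_dm
        )

    def update_length(self, day: float) -> None:
        if self.growth_len is not None:
            self.length = beta_growth_cumulative(day, self.growth_len)


@dataclass
class Phytomer:
    """One node: an opposite leaf pair, optionally the shoot's scape + buds."""

    rank: int
    shoot: int
    leaf_pair: tuple[Organ, Organ]
    scape: Optional[Organ] = None
    buds: list[Organ] = field(default_factory=list)

    def __post_init__(self) -> None:
        a, b = self.leaf_pair
        if a.birth_day != b.birth_day:
            raise ValueError("leaves of an opposite pair must share birth_day")
        if self.buds and self.scape is None:
            raise ValueError("buds require a scape")


@dataclass
class Plant:
    """A planted position: a clump of ``shoots`` fans at ``position`` (x, y in m)."""

    position: tuple[float, float]
    shoots: int
    phytomers: list[Phytomer]
    interior: bool = True
    pool: float = 0.0  # shared assimilate pool (g glucose)
    shoot_bases: Optional[np.ndarray] = None  # (shoots, 2) offsets from position

    def __post_init__(self) -> None:
        if self.shoots < 1:
            raise ValueError("shoots >= 1")

    @property
    def has_scape(self) -> bool:
        return any(ph.scape is not None for ph in self.phytomers)

    @property
    def scapes(self) -> list[Organ]:
        return [ph.scape for ph in self.phytomers if ph.scape is not None]

    @property
    def leaves(self) -> list[Organ]:
        return [lf for ph in self.phytomers for lf in ph.leaf_pair]

    @property
    def buds(self) -> list[Organ]:
        return [b for ph in self.phytomers for b in ph.buds]

    def organs(self) -> list[Organ]:
        out: list[Organ] = []
        for ph in self.phytomers:
            out.extend(ph.leaf_pair)
            if ph.scape is not None:
                out.append(ph.scape)
            out.extend(ph.buds)
        return out

    @property
    def structural_dm(self) -> float:
        return sum(o.biomass_dm for o in self.organs())


# --- phenology schedule ---------------------------------------------------


@dataclass(frozen=True)
class PhenologyEntry:
    organ: OrganKind
    rank: int
    birth_doy: float
    t_m: float
    t_e: float
    w_max_len_m: float
    w_max_dm_g: float


@dataclass
class PhenologySchedule:
    """Per-organ birth days and growth-curve endpoints (the calibration table)."""

    entries: list[PhenologyEntry]

    def leaf_entries(self) -> list[PhenologyEntry]:
        return sorted((e for e in self.entries if e.organ == "leaf"), key=lambda e: e.rank)

    def entry(self, organ: str, rank: int = 0) -> PhenologyEntry:
        for e in self.entries:
            if e.organ == organ and e.rank == rank:
                return e
        raise KeyError(f"no schedule entry for {organ} rank {rank}")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [
                [e.organ, e.rank, e.birth_doy, e.t_m, e.t_e, e.w_max_len_m, e.w_max_dm_g]
                for e in self.entries
            ],
            columns=["organ", "rank", "birth_doy", "t_m", "t_e", "w_max_len_m", "w_max_dm_g"],
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PhenologySchedule":
        df = pd.read_csv(path)
        return cls(
            [
                PhenologyEntry(
                    organ=str(r.organ), rank=int(r.rank), birth_doy=float(r.birth_doy),
                    t_m=float(r.t_m), t_e=float(r.t_e),
                    w_max_len_m=float(r.w_max_len_m), w_max_dm_g=float(r.w_max_dm_g),
                )
                for r in df.itertuples()
            ]
        )


#: Dry-mass line density of leaves (g per m of leaf length) used by the
#: default calibration; with SLA it fixes the emergent leaf width.
LEAF_DM_PER_M = 1.0

#: Final bud calibration: 40 buds per scape at 0.128 m mean length; the
#: per-bud dry mass anchors the per-scape bud fresh weight of 171.42 g at
#: the default bud fresh:dry ratio of 12 (tender flower buds, ~92% water).
BUD_FRESH_PER_SCAPE = 171.42
BUD_FRESH_DRY_RATIO = 12.0
BUD_WMAX_LEN = 0.128
BUD_WMAX_DM = BUD_FRESH_PER_SCAPE / 40.0 / BUD_FRESH_DRY_RATIO


def default_schedule(n_ranks: int = 13, buds_per_scape: int = 40) -> PhenologySchedule:
    """Default calibration: 13 leaf ranks appearing every 6 days from day 65
    (spring regrowth of the perennial clump begins in March, so the lower
    ranks are already partly expanded when the simulated window opens),
    scape elongating from day 137 to 1.19 m, 40 buds per scape averaging
    0.128 m, staggered through the flowering window.
    """
    entries: list[PhenologyEntry] = []
    for r in range(1, n_ranks + 1):
        birth = 65.0 + 6.0 * (r - 1)
        length = 0.25 + 0.05 * r
        entries.append(
            PhenologyEntry(
                organ="leaf", rank=r, birth_doy=birth, t_m=birth + 22.0, t_e=birth + 50.0,
                w_max_len_m=length, w_max_dm_g=length * LEAF_DM_PER_M,
            )
        )
    entries.append(
        PhenologyEntry(
            organ="scape", rank=0, birth_doy=137.0, t_m=172.0, t_e=207.0,
            w_max_len_m=1.19, w_max_dm_g=3.0,
        )
    )
    for b in range(buds_per_scape):
        birth = 170.0 + 35.0 * b / max(1, buds_per_scape - 1)  # staggered flowering
        entries.append(
            PhenologyEntry(
                organ="bud", rank=b + 1, birth_doy=birth, t_m=birth + 18.0, t_e=birth + 30.0,
                w_max_len_m=BUD_WMAX_LEN, w_max_dm_g=BUD_WMAX_DM,
            )
        )
    return PhenologySchedule(entries)


# --- leaf geometry --------------------------------------------------------


@dataclass(frozen=True)
class LeafArchParams:
    """Arching habit of the strap-shaped leaf: inclination (deg above the
    horizontal) interpolated linearly from base to tip."""

    base_inclination: float = 58.0
    tip_inclination: float = -25.0


@dataclass
class LeafGeometry:
    """Chain of parallelogram facets: origin O, edge vectors U (along the
    leaf) and V (across), one row per facet."""

    origins: np.ndarray  # (n, 3)
    u_vecs: np.ndarray  # (n, 3)
    v_vecs: np.ndarray  # (n, 3)

    @property
    def areas(self) -> np.ndarray:
        return np.linalg.norm(np.cross(self.u_vecs, self.v_vecs), axis=1)

    @property
    def centroids(self) -> np.ndarray:
        return self.origins + 0.5 * (self.u_vecs + self.v_vecs)

    @property
    def normals(self) -> np.ndarray:
        n = np.cross(self.u_vecs, self.v_vecs)
        return n / np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-300)

    @property
    def vertices(self) -> np.ndarray:
        """(n, 4, 3) corner array, facet winding O, O+U, O+U+V, O+V."""
        o, u, v = self.origins, self.u_vecs, self.v_vecs
        return np.stack([o, o + u, o + u + v, o + v], axis=1)


def build_leaf_geometry(
    leaf: Organ,
    n_facets: int = 3,
    arch: LeafArchParams = LeafArchParams(),
    base: Sequence[float] = (0.0, 0.0, 0.0),
) -> LeafGeometry:
    """Facet chain for one leaf; facet areas sum to the leaf's area exactly.

    The leaf is a constant-width strap (width = area / length) following a
    polyline whose inclination falls linearly from base to tip; V is kept
    horizontal and perpendicular to the leaf azimuth so each facet is a true
    parallelogram of area (length / n) * width.
    """
    if n_facets < 1:
        raise ValueError("n_facets >= 1")
    if leaf.length <= 0 or leaf.area <= 0:
        raise ValueError("leaf must have positive length and area")
    width = leaf.area / leaf.length
    seg = leaf.length / n_facets
    az = leaf.azimuth
    incs = np.radians(
        np.linspace(arch.base_inclination, arch.tip_inclination, n_facets + 1)
    )
    incs = 0.5 * (incs[:-1] + incs[1:])  # per-segment midpoint inclination
    u = np.stack(
        [
            seg * np.cos(incs) * np.sin(az) * np.ones_like(incs),
            -seg * np.cos(incs) * np.cos(az) * np.ones_like(incs),
            seg * np.sin(incs),
        ],
        axis=1,
    )
    v = np.tile(np.array([math.cos(az), math.sin(az), 0.0]) * width, (n_facets, 1))
    pts = np.vstack([np.asarray(base, dtype=float), np.asarray(base) + np.cumsum(u, axis=0)])
    origins = pts[:-1] - 0.5 * v
    return LeafGeometry(origins, u, v)


# --- plant and scene construction ----------------------------------------

GOLDEN_ANGLE = math.radians(137.508)


def init_plant(
    position: tuple[float, float],
    shoots: int,
    schedule: PhenologySchedule,
    rng: np.random.Generator,
    emergence_rate: float = 0.5,
    buds_per_scape: int = 40,
    azimuth_jitter: float = 0.15,
) -> Plant:
    """Build one plant: per shoot, 13 opposite leaf pairs in rank order and
    (on the scape-bearing shoots) one scape with ``buds_per_scape`` buds.

    The number of scape-bearing shoots is round(emergence_rate * shoots),
    with the bearing shoots drawn from the seeded ``rng`` — the emergence
    rate is honoured exactly in expectation and variance is suppressed,
    which keeps small desk-scale plots representative.
    """
    leaf_entries = schedule.leaf_entries()
    if not leaf_entries:
        raise ValueError("schedule has no leaf entries")
    n_scapes = int(round(emergence_rate * shoots))
    bearing = set(rng.choice(shoots, size=n_scapes, replace=False)) if n_scapes else set()
    bud_entries = sorted(
        (e for e in schedule.entries if e.organ == "bud"), key=lambda e: e.rank
    )[:buds_per_scape]
    try:
        scape_entry: Optional[PhenologyEntry] = schedule.entry("scape")
    except KeyError:
        scape_entry = None

    phytomers: list[Phytomer] = []
    base_angle = rng.uniform(0.0, 2.0 * math.pi)
    shoot_bases = 0.04 * np.stack(
        [
            np.cos(base_angle + 2.0 * np.pi * np.arange(shoots) / shoots),
            np.sin(base_angle + 2.0 * np.pi * np.arange(shoots) / shoots),
        ],
        axis=1,
    )
    for s in range(shoots):
        shoot_az = rng.uniform(0.0, 2.0 * math.pi)
        for e in leaf_entries:
            az = shoot_az + e.rank * GOLDEN_ANGLE + rng.normal(0.0, azimuth_jitter)
            pair = tuple(
                Organ(
                    kind="leaf", rank=e.rank, shoot=s, birth_day=e.birth_doy,
                    growth_len=BetaGrowthParams(e.birth_doy, e.t_m, e.t_e, e.w_max_len_m),
                    growth_dm=BetaGrowthParams(e.birth_doy, e.t_m, e.t_e, e.w_max_dm_g),
                    azimuth=az + side * math.pi,
                )
                for side in (0, 1)
            )
            phytomers.append(Phytomer(rank=e.rank, shoot=s, leaf_pair=pair))  # type: ignore[arg-type]
        if s in bearing and scape_entry is not None:
            sc = scape_entry
            scape = Organ(
                kind="scape", rank=0, shoot=s, birth_day=sc.birth_doy,
                growth_len=BetaGrowthParams(sc.birth_doy, sc.t_m, sc.t_e, sc.w_max_len_m),
                growth_dm=BetaGrowthParams(sc.birth_doy, sc.t_m, sc.t_e, sc.w_max_dm_g),
            )
            buds = [
                Organ(
                    kind="bud", rank=e.rank, shoot=s, birth_day=e.birth_doy,
                    growth_len=BetaGrowthParams(e.birth_doy, e.t_m, e.t_e, e.w_max_len_m),
                    growth_dm=BetaGrowthParams(e.birth_doy, e.t_m, e.t_e, e.w_max_dm_g),
                )
                for e in bud_entries
            ]
            phytomers[-1].scape = scape
            phytomers[-1].buds = buds
    return Plant(
        position=position, shoots=shoots, phytomers=phytomers, shoot_bases=shoot_bases
    )


@dataclass
class PlantLayout:
    """Planting positions on a plot, with guard rows/columns flagged."""

    positions: np.ndarray  # (n, 2)
    interior: np.ndarray  # (n,) bool
    plot_x: float
    plot_y: float
    realized_density: float  # plants per hectare, from per-plant allotment

    @property
    def n_plants(self) -> int:
        return len(self.positions)


def _row_positions(pattern: str, wide: float, narrow: float, plot_x: float) -> list[float]:
    if pattern == "ER":
        if plot_x < wide:
            raise ValueError("plot smaller than one row period")
        n = int(round(plot_x / wide))
        return [wide * (i + 0.5) for i in range(n)]
    period = wide + narrow
    if plot_x < period:
        raise ValueError("plot smaller than one row period")
    n_per = int(round(plot_x / period))
    xs = []
    for k in range(n_per):
        x0 = k * period + 0.5 * wide
        xs.extend([x0, x0 + narrow])
    return xs


def build_scene(
    scenario,
    plot_x: float,
    plot_y: float,
    stagger_drbr: bool = True,
) -> PlantLayout:
    """Lay plants out for a planting scenario on a (plot_x x plot_y) plot.

    ER places rows every ``wide`` m; NWR and DRBR place row pairs ``narrow``
    m apart repeating every (wide + narrow) m; DRBR additionally staggers
    plants within each ridge pair by half the plant spacing.  The outermost
    rows and row-end plants are guard plants excluded from summaries.  The
    realized density comes from the per-plant allotment (exact, unrounded).
    """
    pattern = scenario.pattern
    wide, narrow, spacing = scenario.wide_row, scenario.narrow_row, scenario.plant_spacing
    if spacing <= 0 or wide <= 0 or (pattern != "ER" and narrow <= 0):
        raise ValueError("spacings must be > 0")
    xs = _row_positions(pattern, wide, narrow, plot_x)
    n_plants_row = int(round(plot_y / spacing))
    if n_plants_row < 1:
        raise ValueError("plot shorter than one plant spacing")
    positions = []
    interior = []
    n_rows = len(xs)
    for i, x in enumerate(xs):
        offset = 0.5 * spacing * (i % 2) if (pattern == "DRBR" and stagger_drbr) else 0.0
        for j in range(n_plants_row):
            y = (j + 0.5) * spacing + offset
            positions.append((x, y % (n_plants_row * spacing)))
            interior.append(0 < i < n_rows - 1 and 0 < j < n_plants_row - 1)
    if pattern == "ER":
        per_plant_area = wide * spacing
    else:
        per_plant_area = 0.5 * (wide + narrow) * spacing
    return PlantLayout(
        positions=np.array(positions),
        interior=np.array(interior, dtype=bool),
        plot_x=plot_x,
        plot_y=n_plants_row * spacing,
        realized_density=1e4 / per_plant_area,
    )


def build_leaf_geometry_batch(
    lengths: np.ndarray,
    areas: np.ndarray,
    azimuths: np.ndarray,
    bases: np.ndarray,
    n_facets: int = 3,
    arch: LeafArchParams = LeafArchParams(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Facet chains for many leaves at once.

    Returns flat (L*n, 3) origin/U/V arrays plus the facet -> leaf index,
    identical facet-for-facet to mapping :func:`build_leaf_geometry` over
    the leaves (same arch, no jitter beyond the supplied azimuths).
    """
    if n_facets < 1:
        raise ValueError("n_facets >= 1")
    lengths = np.asarray(lengths, dtype=float)
    areas = np.asarray(areas, dtype=float)
    az = np.asarray(azimuths, dtype=float)
    bases = np.asarray(bases, dtype=float)
    if bases.shape[1] == 2:  # ground-level bases
        bases = np.column_stack([bases, np.zeros(len(bases))])
    n_leaves = len(lengths)
    widths = areas / lengths
    seg = lengths / n_facets
    incs = np.radians(np.linspace(arch.base_inclination, arch.tip_inclination, n_facets + 1))
    incs = 0.5 * (incs[:-1] + incs[1:])  # (n,)
    cos_i, sin_i = np.cos(incs), np.sin(incs)
    sin_a, cos_a = np.sin(az), np.cos(az)
    u = np.empty((n_leaves, n_facets, 3))
    u[:, :, 0] = seg[:, None] * cos_i[None, :] * sin_a[:, None]
    u[:, :, 1] = -seg[:, None] * cos_i[None, :] * cos_a[:, None]
    u[:, :, 2] = seg[:, None] * sin_i[None, :]
    v = np.empty((n_leaves, n_facets, 3))
    v[:, :, 0] = (widths * cos_a)[:, None]
    v[:, :, 1] = (widths * sin_a)[:, None]
    v[:, :, 2] = 0.0
    starts = np.concatenate(
        [np.zeros((n_leaves, 1, 3)), np.cumsum(u, axis=1)[:, :-1, :]], axis=1
    )
    origins = starts + bases[:, None, :] - 0.5 * v
    leaf_index = np.repeat(np.arange(n_leaves), n_facets)
    return (
        origins.reshape(-1, 3),
        u.reshape(-1, 3),
        v.reshape(-1, 3),
        leaf_index,
    )


def export_obj(geometries: Iterable[LeafGeometry], path) -> None:
    """Write leaf facet quads as a Wavefront OBJ mesh (via trimesh)."""
    import trimesh

    verts = []
    faces = []
    off = 0
    for g in geometries:
        quads = g.vertices
        for q in quads:
            verts.extend(q.tolist())
            faces.append([off, off + 1, off + 2])
            faces.append([off, off + 2, off + 3])
            off += 4
    mesh = trimesh.Trimesh(vertices=np.array(verts), faces=np.array(faces), process=False)
    Path(path).write_text(trimesh.exchange.obj.export_obj(mesh))
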