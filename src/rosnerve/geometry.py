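"""Synthetic optic-nerve geometry.

Builds voxelized models of a bundle of parallel retinal-ganglion-cell axons:
axons are non-overlapping circles in the coronal (XY) plane, placed
stochastically with octant-dependent diameter distributions, rasterized onto
an anisotropic voxel grid with explicit one-voxel membranes, and decorated
with single-voxel mitochondria.  Along the nerve axis (Z) the model is zoned
into unmyelinated, internodal, paranodal and node-of-Ranvier slabs.

Conventions
-----------
* Physical units are micrometres; resolutions are pixels per micrometre.
* The coronal plane uses the image convention of a right optic nerve viewed
  from the front: X grows to the right, Y grows downward, so the temporal (T)
  octant is on the left, nasal (N) on the right, superior (S) on top and
  inferior (I) at the bottom.
* Grid arrays are indexed ``[ix, iy, iz]``.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "EXTRA_AXONAL", "AXON_INTERIOR", "AXON_MEMBRANE", "MYELIN", "NODE_GAP",
    "ZONE_UNMYELINATED", "ZONE_INTERNODAL", "ZONE_PARANODAL", "ZONE_NODE",
    "OCTANTS", "octant_of_point",
    "AxonSpec", "OctantLaw", "DiameterDistribution", "SegmentRef",
    "NerveModel", "Slab", "GeometryError", "PlacementWarning",
    "place_axons", "rasterize_model", "place_mitochondria",
    "build_longitudinal_model", "abridged_layout", "node_slice_layout",
    "reduced_model_radius", "FULL_NERVE_RADIUS_UM", "FULL_NERVE_AXON_COUNT",
]

# -- compartment labels (uint8 voxel classes) --------------------------------
EXTRA_AXONAL = 0
AXON_INTERIOR = 1
AXON_MEMBRANE = 2
MYELIN = 3          # membrane voxel wrapped in myelin (attenuated permeability)
NODE_GAP = 4        # bare membrane voxel at a node of Ranvier

COMPARTMENT_NAMES = {
    EXTRA_AXONAL: "extra_axonal",
    AXON_INTERIOR: "axon_interior",
    AXON_MEMBRANE: "axon_membrane",
    MYELIN: "myelin",
    NODE_GAP: "node_gap",
}

# -- axial zones (uint8 per z-slice) -----------------------------------------
ZONE_UNMYELINATED = 0
ZONE_INTERNODAL = 1
ZONE_PARANODAL = 2
ZONE_NODE = 3

ZONE_NAMES = {
    ZONE_UNMYELINATED: "unmyelinated",
    ZONE_INTERNODAL: "internodal",
    ZONE_PARANODAL: "paranodal",
    ZONE_NODE: "node",
}

#: Octant labels in the reporting order used for coronal sections:
#: temporal first, then clockwise around the disc.
OCTANTS = ("T", "ST", "S", "SN", "N", "IN", "I", "IT")

# Octant labels ordered by mathematical angle (counter-clockwise from +X with
# "up" = -Y, i.e. the nasal octant sits at angle 0).
_OCTANTS_BY_ANGLE = ("N", "SN", "S", "ST", "T", "IT", "I", "IN")

# Healthy young-adult optic nerve: about 1.2 million RGC axons in a disc of
# roughly 1.5 mm diameter.  An "x %" reduced model keeps the same diameter
# distributions in a disc of radius x/100 of the full nerve, so its axon
# count scales as (x/100)^2.
FULL_NERVE_RADIUS_UM = 750.0
FULL_NERVE_AXON_COUNT = 1_200_000


class GeometryError(ValueError):
    """Raised when a model cannot be built from the requested parameters."""


class PlacementWarning(UserWarning):
    """Axon placement could not reach the target density."""


def octant_of_point(x: float, y: float, cx: float = 0.0, cy: float = 0.0) -> str:
    """Octant label of a coronal point.

    Octants are half-open 45-degree wedges centred on the eight compass
    directions (T left, N right, S up, I down in image coordinates where Y
    grows downward).  A point exactly on a 22.5-degree wedge boundary is
    assigned to the counter-clockwise wedge.
    """
    theta = math.degrees(math.atan2(-(y - cy), x - cx)) % 360.0
    return _OCTANTS_BY_ANGLE[int(math.floor((theta + 22.5) / 45.0)) % 8]


@dataclass(frozen=True)
class AxonSpec:
    """One axon: a circle in the coronal plane.

    ``x``/``y`` are the centre in µm relative to the disc centre, ``radius``
    in µm; ``octant`` is derived from the centre angle.
    """

    id: int
    x: float
    y: float
    radius: float
    octant: str


@dataclass(frozen=True)
class OctantLaw:
    """Per-octant lognormal diameter law and areal density.

    ``median_um``/``sigma_log`` parameterize the lognormal of axon *diameter*
    in µm; ``density_per_um2`` is the target number of axon centres per µm²
    of octant area.
    """

    median_um: float
    sigma_log: float
    density_per_um2: float


@dataclass(frozen=True)
class DiameterDistribution:
    """Octant-resolved axon diameter distributions.

    The shipped default skews small diameters temporally: the temporal octant
    has the smallest median diameter and the highest areal density, emulating
    the histological observation that the temporal optic nerve carries large
    groups of small-diameter fibres.  Densities are normalized so that the
    full nerve (radius 750 µm) holds ~1.2 million axons at roughly equal
    area-fill per octant.
    """

    laws: dict[str, OctantLaw]
    min_diameter_um: float = 0.5
    max_diameter_um: float = 2.5

    def __post_init__(self):
        unknown = set(self.laws) - set(OCTANTS)
        if unknown:
            raise GeometryError(f"unknown octant labels: {sorted(unknown)}")
        if not (0 < self.min_diameter_um < self.max_diameter_um):
            raise GeometryError("need 0 < min_diameter_um < max_diameter_um")

    @classmethod
    def default(cls, density_scale: float = 1.0) -> "DiameterDistribution":
        medians = {"T": 0.65, "ST": 0.70, "IT": 0.70, "S": 0.80, "I": 0.80,
                   "SN": 0.90, "IN": 0.90, "N": 0.95}
        sigma = 0.35
        # density ∝ 1/E[diameter²], normalized so the 8 octant densities
        # average to FULL_NERVE_AXON_COUNT / (π · FULL_NERVE_RADIUS_UM²).
        mean_sq = {k: m * m * math.exp(2 * sigma * sigma) for k, m in medians.items()}
        inv = {k: 1.0 / (math.pi / 4.0 * s) for k, s in mean_sq.items()}
        target_mean = FULL_NERVE_AXON_COUNT / (math.pi * FULL_NERVE_RADIUS_UM**2)
        scale = density_scale * target_mean * 8.0 / sum(inv.values())
        laws = {k: OctantLaw(medians[k], sigma, inv[k] * scale) for k in medians}
        return cls(laws=laws)

    @classmethod
    def uniform(cls, median_um: float = 0.8, sigma_log: float = 0.35,
                density_per_um2: float = 0.6) -> "DiameterDistribution":
        law = OctantLaw(median_um, sigma_log, density_per_um2)
        return cls(laws={k: law for k in OCTANTS})


def reduced_model_radius(percent: float,
                         full_radius_um: float = FULL_NERVE_RADIUS_UM) -> float:
    """Disc radius of an "x %" reduced nerve model.

    A reduced model keeps the full nerve's diameter distributions and areal
    densities, so its axon count scales as (percent/100)² of the full count.
    """
    if percent <= 0:
        raise GeometryError("model percent must be positive")
    return full_radius_um * percent / 100.0


@dataclass(frozen=True)
class SegmentRef:
    """Half-open z-slab of voxels belonging to one axon."""

    axon_id: int
    z_lo: int
    z_hi: int


@dataclass(frozen=True)
class Slab:
    """One axial zone slab of a longitudinal layout."""

    zone: str            # "unmyelinated" | "myelinated" | "node"
    thickness_um: float


def abridged_layout() -> list[Slab]:
    """Abridged longitudinal nerve: 50 µm unmyelinated, 200 µm myelinated,
    a 5 µm node slab, then 155 µm myelinated (Z total 410 µm)."""
    return [Slab("unmyelinated", 50.0), Slab("myelinated", 200.0),
            Slab("node", 5.0), Slab("myelinated", 155.0)]


def node_slice_layout(thickness_um: float = 10.0, node_offset_um: float = 6.0,
                      node_length_um: float = 1.0) -> list[Slab]:
    """Thin myelinated coronal slice around a single node of Ranvier.

    Default: 10 µm thick with a 1 µm node placed 6 µm from the proximal side.
    """
    distal = thickness_um - node_offset_um - node_length_um
    if node_offset_um <= 0 or distal <= 0:
        raise GeometryError("node must lie strictly inside the slice")
    return [Slab("myelinated", node_offset_um), Slab("node", node_length_um),
            Slab("myelinated", distal)]


@dataclass
class NerveModel:
    """Voxelized nerve model.

    Arrays are indexed ``[ix, iy, iz]``.  ``labels`` holds compartment codes,
    ``axon_id`` maps every axon voxel (interior and membrane) to its axon
    index (−1 elsewhere), ``mito`` flags single-voxel mitochondria, and
    ``zone_z`` gives the axial zone of each z-slice.  The physical voxel is a
    cuboid of edge 1/res_xy in X and Y and 1/res_z in Z.
    """

    labels: np.ndarray          # uint8 (nx, ny, nz)
    axon_id: np.ndarray         # int32 (nx, ny, nz)
    mito: np.ndarray            # bool  (nx, ny, nz)
    zone_z: np.ndarray          # uint8 (nz,)
    res_xy: float               # px/µm
    res_z: float                # px/µm
    nerve_radius_um: float
    axons: list[AxonSpec] = field(default_factory=list)
    segments: list[SegmentRef] = field(default_factory=list)

    # -- basic derived quantities -------------------------------------------
    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_um3(self) -> float:
        """Physical volume of one voxel: (1/res_xy)² · (1/res_z) µm³."""
        return (1.0 / self.res_xy) ** 2 * (1.0 / self.res_z)

    @property
    def n_axons(self) -> int:
        return len(self.axons)

    def centers(self) -> np.ndarray:
        """(n_axons, 2) array of axon centres in µm."""
        return np.array([[a.x, a.y] for a in self.axons], dtype=float).reshape(-1, 2)

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.axons], dtype=float)

    def is_membrane_like(self) -> np.ndarray:
        """Boolean mask of membrane, myelin and node-gap voxels."""
        return (self.labels == AXON_MEMBRANE) | (self.labels == MYELIN) \
            | (self.labels == NODE_GAP)

    def digest(self) -> str:
        """Deterministic content hash used by reproducibility tests."""
        h = hashlib.sha256()
        for arr in (self.labels, self.axon_id, self.mito.astype(np.uint8),
                    self.zone_z):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(repr((self.res_xy, self.res_z, self.nerve_radius_um)).encode())
        h.update(repr([(int(a.id), round(float(a.x), 9), round(float(a.y), 9),
                        round(float(a.radius), 9), a.octant)
                       for a in self.axons]).encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# axon placement
# ---------------------------------------------------------------------------

def _sample_diameters(law: OctantLaw, n: int, lo: float, hi: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Sample n diameters from a truncated lognormal by resampling."""
    out = np.empty(n)
    have = 0
    mu = math.log(law.median_um)
    while have < n:
        d = rng.lognormal(mu, law.sigma_log, size=max(n - have, 16))
        d = d[(d >= lo) & (d <= hi)]
        take = min(d.size, n - have)
        out[have:have + take] = d[:take]
        have += take
    return out


class _CellGrid:
    """Uniform-grid spatial hash for non-overlap queries."""

    def __init__(self, cell: float, capacity: int):
        self.cell = cell
        self.cells: dict[tuple[int, int], list[int]] = {}
        self.xs = np.empty(capacity)
        self.ys = np.empty(capacity)
        self.rs = np.empty(capacity)
        self.n = 0

    def conflicts(self, x: float, y: float, r: float) -> bool:
        cx, cy = int(x // self.cell), int(y // self.cell)
        for ix in (cx - 1, cx, cx + 1):
            for iy in (cy - 1, cy, cy + 1):
                idx = self.cells.get((ix, iy))
                if not idx:
                    continue
                ii = np.asarray(idx)
                dx = self.xs[ii] - x
                dy = self.ys[ii] - y
                if np.any(dx * dx + dy * dy < (self.rs[ii] + r) ** 2):
                    return True
        return False

    def insert(self, x: float, y: float, r: float) -> None:
        i = self.n
        self.xs[i], self.ys[i], self.rs[i] = x, y, r
        self.cells.setdefault((int(x // self.cell), int(y // self.cell)),
                              []).append(i)
        self.n = i + 1


def place_axons(nerve_radius_um: float,
                distributions: DiameterDistribution,
                rng_seed: int | np.random.Generator = 0,
                max_attempts: int = 2000) -> list[AxonSpec]:
    """Stochastically place non-overlapping circular axons in a disc.

    Dart-throwing rejection sampling, largest-first: per octant, the target
    count is ``density · octant area``; diameters are drawn from the octant's
    truncated lognormal, then all axons are inserted in order of decreasing
    radius, sampling candidate centres uniformly within the octant wedge
    until a placement free of overlap (centre distance ≥ sum of radii) and
    fully inside the disc is found.

    Axons that cannot be placed within ``max_attempts`` candidates are
    dropped and a :class:`PlacementWarning` reports the achieved density.
    Identical seed and inputs give a byte-identical layout.
    """
    if nerve_radius_um <= 0:
        raise GeometryError("nerve_radius_um must be positive")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))

    area_oct = math.pi * nerve_radius_um**2 / 8.0
    pending: list[tuple[float, int]] = []  # (radius, octant_index_by_angle)
    for oct_idx, name in enumerate(_OCTANTS_BY_ANGLE):
        law = distributions.laws.get(name)
        if law is None or law.density_per_um2 <= 0:
            continue
        n_target = int(round(law.density_per_um2 * area_oct))
        if n_target == 0:
            continue
        diam = _sample_diameters(law, n_target, distributions.min_diameter_um,
                                 distributions.max_diameter_um, rng)
        pending.extend((float(d) / 2.0, oct_idx) for d in diam)

    if not pending:
        return []
    # Largest-first insertion makes high packing fractions reachable.
    pending.sort(key=lambda t: (-t[0], t[1]))

    grid = _CellGrid(cell=max(distributions.max_diameter_um,
                              2.0 * max(r for r, _ in pending)),
                     capacity=len(pending))
    axons: list[AxonSpec] = []
    n_failed = 0
    for radius, oct_idx in pending:
        r_max = nerve_radius_um - radius
        if r_max <= 0:
            n_failed += 1
            continue
        theta_lo = oct_idx * 45.0 - 22.5
        placed = False
        for _ in range(max_attempts):
            theta = math.radians(theta_lo + 45.0 * rng.random())
            rho = r_max * math.sqrt(rng.random())
            x = rho * math.cos(theta)
            y = -rho * math.sin(theta)   # image convention: Y grows downward
            if not grid.conflicts(x, y, radius):
                grid.insert(x, y, radius)
                axons.append(AxonSpec(id=len(axons), x=x, y=y, radius=radius,
                                      octant=_OCTANTS_BY_ANGLE[oct_idx]))
                placed = True
                break
        if not placed:
            n_failed += 1

    if n_failed:
        target = len(pending)
        achieved = len(axons) / (math.pi * nerve_radius_um**2)
        warnings.warn(
            f"placed {len(axons)}/{target} axons "
            f"(achieved density {achieved:.4f} axons/µm²); "
            f"increase max_attempts or lower densities",
            PlacementWarning, stacklevel=2)
    return axons


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

_EROSION_STRUCT = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _raster_disc(axon: AxonSpec, res_xy: float, half_px: int):
    """Pixel mask of one axon's disc plus its interior/membrane split.

    Returns (ix0, iy0, interior_mask, membrane_mask) in grid indices.
    Pixel (i, j) has its centre at ((i + 0.5)/res − half, ...) relative to
    the disc centre.
    """
    cx_px = axon.x * res_xy + half_px
    cy_px = axon.y * res_xy + half_px
    r_px = axon.radius * res_xy
    ix0 = int(math.floor(cx_px - r_px - 1))
    iy0 = int(math.floor(cy_px - r_px - 1))
    n = int(math.ceil(2 * r_px)) + 3
    ii = ix0 + np.arange(n)
    jj = iy0 + np.arange(n)
    dx = (ii + 0.5) - cx_px
    dy = (jj + 0.5) - cy_px
    mask = dx[:, None] ** 2 + dy[None, :] ** 2 <= r_px * r_px
    interior = ndimage.binary_erosion(mask, structure=_EROSION_STRUCT)
    if not interior.any():
        raise GeometryError(
            f"axon {axon.id} (radius {axon.radius:.3f} µm) is too small to "
            f"rasterize a distinct interior and membrane at res_xy="
            f"{res_xy} px/µm; increase the resolution or the minimum diameter")
    membrane = mask & ~interior
    return ix0, iy0, interior, membrane


def _zones_from_layout(layout: list[Slab] | None, nz: int, res_z: float,
                       paranodal_extent_um: float) -> np.ndarray:
    """Per-z-slice zone codes from an ordered slab layout.

    Myelinated slices within ``paranodal_extent_um`` of a node slab are
    labelled paranodal; the remaining myelinated slices are internodal.
    """
    if layout is None:
        return np.full(nz, ZONE_UNMYELINATED, dtype=np.uint8)
    dz = 1.0 / res_z
    total = sum(s.thickness_um for s in layout)
    if abs(total - nz * dz) > 0.5 * dz:
        raise GeometryError(
            f"layout thicknesses sum to {total} µm but the grid spans "
            f"{nz * dz} µm ({nz} slices of {dz} µm)")
    zone = np.empty(nz, dtype=np.uint8)
    is_myel = np.zeros(nz, dtype=bool)
    is_node = np.zeros(nz, dtype=bool)
    z = 0.0
    for slab in layout:
        k0 = int(round(z * res_z))
        k1 = int(round((z + slab.thickness_um) * res_z))
        k1 = min(max(k1, k0 + 1), nz)
        if slab.zone == "unmyelinated":
            zone[k0:k1] = ZONE_UNMYELINATED
        elif slab.zone == "node":
            zone[k0:k1] = ZONE_NODE
            is_node[k0:k1] = True
        elif slab.zone == "myelinated":
            zone[k0:k1] = ZONE_INTERNODAL
            is_myel[k0:k1] = True
        else:
            raise GeometryError(f"unknown zone {slab.zone!r}")
        z += slab.thickness_um
    if is_node.any() and is_myel.any():
        node_k = np.flatnonzero(is_node)
        myel_k = np.flatnonzero(is_myel)
        dist = np.min(np.abs(myel_k[:, None] - node_k[None, :]), axis=1) * dz
        zone[myel_k[dist <= paranodal_extent_um]] = ZONE_PARANODAL
    return zone


def rasterize_model(axons: list[AxonSpec], res_xy: float, res_z: float = 1.0,
                    nz: int = 1, nerve_radius_um: float | None = None,
                    layout: list[Slab] | None = None,
                    segment_um: float = 5.0,
                    paranodal_extent_um: float = 2.0) -> NerveModel:
    """Rasterize placed axons onto the voxel grid.

    Each axon becomes a rasterized disc (pixel centres within its radius)
    whose one-pixel-thick boundary layer is labelled as membrane; the
    remainder is interior.  In myelinated z-slabs the membrane voxels are
    labelled myelin, and at node slabs node-gap.  Axons too small to have a
    distinct interior at this resolution are rejected with a clear message.
    """
    if res_xy <= 0 or res_z <= 0:
        raise GeometryError("resolutions must be positive")
    if nz < 1:
        raise GeometryError("nz must be >= 1")
    if nerve_radius_um is None:
        if axons:
            nerve_radius_um = max(math.hypot(a.x, a.y) + a.radius for a in axons)
        else:
            nerve_radius_um = 1.0
    n_xy = int(math.ceil(2 * nerve_radius_um * res_xy))
    half_px = n_xy / 2.0

    labels = np.zeros((n_xy, n_xy, nz), dtype=np.uint8)
    axon_id = np.full((n_xy, n_xy, nz), -1, dtype=np.int32)
    zone_z = _zones_from_layout(layout, nz, res_z, paranodal_extent_um)

    # per-z membrane label resolved from the axial zone
    memb_label_z = np.where(
        zone_z == ZONE_NODE, NODE_GAP,
        np.where((zone_z == ZONE_INTERNODAL) | (zone_z == ZONE_PARANODAL),
                 MYELIN, AXON_MEMBRANE)).astype(np.uint8)

    plane_label = np.zeros((n_xy, n_xy), dtype=np.uint8)  # 0 extra, 1 int, 2 memb
    plane_axon = np.full((n_xy, n_xy), -1, dtype=np.int32)
    for axon in axons:
        ix0, iy0, interior, membrane = _raster_disc(axon, res_xy, n_xy / 2.0)
        ni, nj = interior.shape
        # clip the bounding-box margin; actual disc pixels always fit the grid
        ci0, cj0 = max(ix0, 0), max(iy0, 0)
        ci1, cj1 = min(ix0 + ni, n_xy), min(iy0 + nj, n_xy)
        cut = (slice(ci0 - ix0, ci1 - ix0), slice(cj0 - iy0, cj1 - iy0))
        clipped = (interior | membrane)
        clipped[cut] = False
        if clipped.any():
            raise GeometryError(f"axon {axon.id} extends beyond the grid")
        interior, membrane = interior[cut], membrane[cut]
        sl = (slice(ci0, ci1), slice(cj0, cj1))
        if np.any((plane_label[sl] != 0) & (interior | membrane)):
            raise GeometryError(f"axon {axon.id} overlaps a previous axon "
                                "after rasterization")
        plane_label[sl][interior] = 1
        plane_label[sl][membrane] = 2
        plane_axon[sl][interior | membrane] = axon.id

    interior2d = plane_label == 1
    membrane2d = plane_label == 2
    for k in range(nz):
        lab_k = labels[:, :, k]
        lab_k[interior2d] = AXON_INTERIOR
        lab_k[membrane2d] = memb_label_z[k]
        axon_id[:, :, k] = plane_axon

    # segments tile each axon's Z extent in slabs of ~segment_um
    seg_len = max(1, int(round(segment_um * res_z)))
    bounds = list(range(0, nz, seg_len)) + [nz]
    segments = [SegmentRef(a.id, z0, z1)
                for a in axons
                for z0, z1 in zip(bounds[:-1], bounds[1:])]

    return NerveModel(labels=labels, axon_id=axon_id,
                      mito=np.zeros_like(labels, dtype=bool), zone_z=zone_z,
                      res_xy=res_xy, res_z=res_z,
                      nerve_radius_um=nerve_radius_um,
                      axons=list(axons), segments=segments)


def place_mitochondria(model: NerveModel, mito_axon_pct: float,
                       mito_glia_pct: float,
                       rng_seed: int | np.random.Generator = 0) -> NerveModel:
    """Flag single-voxel mitochondria by independent Bernoulli draws.

    Every axon-interior voxel becomes a mitochondrion with probability
    ``mito_axon_pct/100`` and every extra-axonal voxel with probability
    ``mito_glia_pct/100`` (glial mitochondria, no cell boundaries).  Node
    z-slices never receive mitochondria: at nodes of Ranvier mitochondria sit
    next to, not at, the node.  Returns the model with ``mito`` replaced.
    """
    if not (0 <= mito_axon_pct <= 100 and 0 <= mito_glia_pct <= 100):
        raise GeometryError("mitochondrial percentages must be in [0, 100]")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    mito = np.zeros(model.grid_shape, dtype=bool)
    not_node = model.zone_z != ZONE_NODE
    if mito_axon_pct > 0:
        cand = (model.labels == AXON_INTERIOR) & not_node[None, None, :]
        mito[cand] = rng.random(int(cand.sum())) < mito_axon_pct / 100.0
    if mito_glia_pct > 0:
        cand = (model.labels == EXTRA_AXONAL) & not_node[None, None, :]
        mito[cand] = rng.random(int(cand.sum())) < mito_glia_pct / 100.0
    return replace(model, mito=mito)


def build_longitudinal_model(layout: list[Slab], axons: list[AxonSpec],
                             res_xy: float, res_z: float,
                             nerve_radius_um: float | None = None,
                             segment_um: float = 5.0,
                             paranodal_extent_um: float = 2.0) -> NerveModel:
    """Build a zoned longitudinal model from an ordered slab layout.

    The number of z-slices is derived from the layout's total thickness;
    slab thicknesses must tile the Z extent exactly (to voxel precision).
    """
    total = sum(s.thickness_um for s in layout)
    nz = int(round(total * res_z))
    if abs(nz / res_z - total) > 1e-9 + 1e-12 * total:
        raise GeometryError(
            f"layout total {total} µm is not a whole number of z-voxels at "
            f"res_z={res_z} px/µm")
    return rasterize_model(axons, res_xy=res_xy, res_z=res_z, nz=nz,
                           nerve_radius_um=nerve_radius_um, layout=layout,
                           segment_um=segment_um,
                           paranodal_extent_um=paranodal_extent_um)
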