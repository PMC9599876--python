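"""Spatial analysis of simulation outcomes.

Octant partitioning of the coronal cross-section, the decibel axonal-loss
metric, diameter-resolved survival histograms, a permutation statistic for
spatially clustered ("neighborhood") loss, zone/octant concentration
summaries and anatomical plane slices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import geometry as geo

__all__ = [
    "LOSS_FLOOR_DB", "octant_of", "octant_loss", "OctantReport",
    "octant_report", "survival_by_diameter", "ClusterStat",
    "neighborhood_statistic", "region_summary", "plane_slice",
]

#: Floor of the octant loss metric; below the dB value of a single surviving
#: axon in any realistic octant, and used in place of -inf at complete loss.
LOSS_FLOOR_DB = -101.0


def octant_of(center_xy, disc_center=(0.0, 0.0)) -> str:
    """Octant label of a coronal point (T left, N right, S up, I down).

    Wedges are half-open 45° sectors centred on the eight compass
    directions; a point exactly on a boundary (22.5° off an axis) belongs to
    the counter-clockwise wedge.
    """
    x, y = center_xy
    return geo.octant_of_point(x, y, disc_center[0], disc_center[1])


def octant_loss(n_alive: int, n_total: int) -> float:
    """Axonal loss of one octant in dB: max(10·log10(alive/total), −101).

    Full survival gives 0 dB; complete loss is floored at −101 dB.  An empty
    octant has no defined loss (raises; callers report it as not applicable).
    """
    if n_total < 1:
        raise ValueError("octant loss is undefined for an empty octant")
    if not 0 <= n_alive <= n_total:
        raise ValueError("need 0 <= n_alive <= n_total")
    if n_alive == 0:
        return LOSS_FLOOR_DB
    return max(10.0 * math.log10(n_alive / n_total), LOSS_FLOOR_DB)


@dataclass
class OctantReport:
    """Per-octant alive/total counts and dB loss, plus global survival."""

    table: pd.DataFrame          # index: octant; columns n_alive, n_total, loss_db
    survival_fraction: float

    def loss_db(self, octant: str) -> float:
        return float(self.table.loc[octant, "loss_db"])


def octant_report(axons: list[geo.AxonSpec],
                  dead_mask: np.ndarray) -> OctantReport:
    """Summarize survival per octant from axon specs and a dead flag array."""
    dead_mask = np.asarray(dead_mask, dtype=bool)
    if len(axons) != dead_mask.size:
        raise ValueError("dead_mask length must match axon count")
    rows = []
    for name in geo.OCTANTS:
        idx = [i for i, a in enumerate(axons) if a.octant == name]
        total = len(idx)
        alive = int(total - dead_mask[idx].sum()) if total else 0
        rows.append({"octant": name, "n_alive": alive, "n_total": total,
                     "loss_db": octant_loss(alive, total) if total
                     else float("nan")})
    table = pd.DataFrame(rows).set_index("octant")
    n = len(axons)
    surv = 1.0 - dead_mask.sum() / n if n else 1.0
    return OctantReport(table=table, survival_fraction=float(surv))


def survival_by_diameter(axons: list[geo.AxonSpec], dead_mask: np.ndarray,
                         bin_width_um: float = 0.1,
                         d_range: tuple[float, float] | None = None
                         ) -> pd.DataFrame:
    """Stacked alive/dead histogram over axon diameter.

    Returns one row per bin with columns ``d_lo``, ``d_hi``, ``alive``,
    ``dead``; alive + dead sums to the axon count over all bins.
    """
    diam = 2.0 * np.array([a.radius for a in axons])
    dead_mask = np.asarray(dead_mask, dtype=bool)
    if d_range is None:
        d_range = (0.0, float(diam.max()) + bin_width_um) if diam.size \
            else (0.0, bin_width_um)
    edges = np.arange(d_range[0], d_range[1] + bin_width_um, bin_width_um)
    alive, _ = np.histogram(diam[~dead_mask], bins=edges)
    dead, _ = np.histogram(diam[dead_mask], bins=edges)
    return pd.DataFrame({"d_lo": edges[:-1], "d_hi": edges[1:],
                         "alive": alive, "dead": dead})


@dataclass
class ClusterStat:
    """Nearest-neighbour dead-state concordance vs its permutation null."""

    observed: float
    null_mean: float
    null_sd: float
    z: float
    degenerate: bool = False


def neighborhood_statistic(axons: list[geo.AxonSpec], dead_mask: np.ndarray,
                           k_neighbors: int = 6, n_permutations: int = 999,
                           seed: int | np.random.Generator = 0) -> ClusterStat:
    """Quantify spatially clustered axonal loss.

    Observed score: the mean, over dead axons, of the fraction of their k
    nearest neighbours (by centre distance) that are also dead.  The null
    distribution permutes the dead labels across axon positions, preserving
    the alive/dead counts, so z = (obs − mean)/sd measures clustering beyond
    what the loss fraction alone implies.  Interspersed loss gives |z| ~ 1;
    contiguous dead patches give z >> 3.  All-dead or all-alive inputs are
    flagged degenerate with z = 0.
    """
    dead_mask = np.asarray(dead_mask, dtype=bool)
    n = len(axons)
    if n < 2:
        raise ValueError("need at least 2 axons")
    n_dead = int(dead_mask.sum())
    if n_dead == 0 or n_dead == n:
        return ClusterStat(float("nan"), float("nan"), float("nan"), 0.0,
                           degenerate=True)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    k = min(k_neighbors, n - 1)
    pts = np.array([[a.x, a.y] for a in axons])
    _, nbr = cKDTree(pts).query(pts, k=k + 1)
    nbr = nbr[:, 1:]                       # drop self

    def score(mask: np.ndarray) -> float:
        return float(mask[nbr[mask]].mean())

    observed = score(dead_mask)
    null = np.empty(n_permutations)
    labels = dead_mask.copy()
    for i in range(n_permutations):
        rng.shuffle(labels)
        null[i] = score(labels)
    mu, sd = float(null.mean()), float(null.std())
    z = (observed - mu) / sd if sd > 0 else 0.0
    return ClusterStat(observed=observed, null_mean=mu, null_sd=sd, z=z,
                       degenerate=sd == 0)


def region_summary(field, model: geo.NerveModel,
                   axon_interior_only: bool = False) -> pd.DataFrame:
    """Mean/min/max concentration per axial zone and per coronal octant.

    Rows are zones first (``kind == 'zone'``), then octants.  With
    ``axon_interior_only`` the statistics are restricted to axon-interior
    voxels (octant rows then summarize intra-axonal levels).
    """
    values = field.values if hasattr(field, "values") else np.asarray(field)
    nx, ny, nz = values.shape
    sel3d = np.ones(values.shape, dtype=bool)
    if axon_interior_only:
        sel3d &= model.labels == geo.AXON_INTERIOR
    rows = []
    for code, name in geo.ZONE_NAMES.items():
        mask = sel3d & (model.zone_z == code)[None, None, :]
        if mask.any():
            v = values[mask]
            rows.append({"kind": "zone", "name": name, "mean": v.mean(),
                         "min": v.min(), "max": v.max(), "n_voxels": v.size})
    # octant of every XY column (image convention, Y down)
    xs = (np.arange(nx) + 0.5) / model.res_xy - nx / (2.0 * model.res_xy)
    ys = (np.arange(ny) + 0.5) / model.res_xy - ny / (2.0 * model.res_xy)
    theta = np.degrees(np.arctan2(-ys[None, :], xs[:, None])) % 360.0
    oct_idx = np.floor((theta + 22.5) / 45.0).astype(int) % 8
    for i, name in enumerate(geo._OCTANTS_BY_ANGLE):
        mask = sel3d & (oct_idx == i)[:, :, None]
        if mask.any():
            v = values[mask]
            rows.append({"kind": "octant", "name": name, "mean": v.mean(),
                         "min": v.min(), "max": v.max(), "n_voxels": v.size})
    return pd.DataFrame(rows)


def plane_slice(field, plane: str, index: int) -> np.ndarray:
    """2D anatomical cut of the field, display-oriented as (rows, columns).

    * coronal: XY plane at z = index; rows are Y (superior at top), columns
      X (temporal left, nasal right),
    * transverse: XZ plane at y = index; rows are Z (proximal at top),
      columns X,
    * sagittal: YZ plane at x = index; rows are Y (superior top), columns Z
      (proximal left).
    """
    values = field.values if hasattr(field, "values") else np.asarray(field)
    nx, ny, nz = values.shape
    if plane == "coronal":
        if not 0 <= index < nz:
            raise IndexError("coronal index out of range")
        return values[:, :, index].T
    if plane == "transverse":
        if not 0 <= index < ny:
            raise IndexError("transverse index out of range")
        return values[:, index, :].T
    if plane == "sagittal":
        if not 0 <= index < nx:
            raise IndexError("sagittal index out of range")
        return values[index, :, :]
    raise ValueError("plane must be coronal, transverse or sagittal")
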