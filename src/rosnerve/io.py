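"""Serialization and figure export.

Models and fields are stored in HDF5 (one dataset per voxel array,
attributes for resolutions and metadata) with a human-readable JSON sidecar
listing the axon records.  Analysis tables go to TSV; concentration maps are
exported as 8-bit heatmap PNGs whose physical scale (vmin/vmax in nM) is
written to a JSON sidecar rather than silently rescaled per image.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from . import geometry as geo
from .dynamics import SimulationResult, UnitStates
from .solver import ConcentrationField

__all__ = [
    "save_model", "load_model", "save_field", "load_field",
    "save_checkpoint", "load_checkpoint", "write_events_tsv",
    "heatmap_png",
]


def _axon_records(axons: list[geo.AxonSpec]) -> list[dict]:
    return [{"id": a.id, "x": a.x, "y": a.y, "radius": a.radius,
             "octant": a.octant} for a in axons]


def save_model(model: geo.NerveModel, path: str | Path) -> Path:
    """Write a NerveModel to HDF5 plus a ``<stem>.axons.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=model.labels, compression="gzip")
        f.create_dataset("axon_id", data=model.axon_id, compression="gzip")
        f.create_dataset("mito", data=model.mito.astype(np.uint8),
                         compression="gzip")
        f.create_dataset("zone_z", data=model.zone_z)
        f.create_dataset(
            "segments",
            data=np.array([(s.axon_id, s.z_lo, s.z_hi)
                           for s in model.segments], dtype=np.int64
                          ).reshape(-1, 3))
        f.attrs["res_xy"] = model.res_xy
        f.attrs["res_z"] = model.res_z
        f.attrs["nerve_radius_um"] = model.nerve_radius_um
    sidecar = path.with_suffix(".axons.json")
    sidecar.write_text(json.dumps(_axon_records(model.axons), indent=1))
    return path


def load_model(path: str | Path) -> geo.NerveModel:
    path = Path(path)
    with h5py.File(path, "r") as f:
        labels = f["labels"][()]
        axon_id = f["axon_id"][()]
        mito = f["mito"][()].astype(bool)
        zone_z = f["zone_z"][()]
        segments = [geo.SegmentRef(int(a), int(lo), int(hi))
                    for a, lo, hi in f["segments"][()]]
        res_xy = float(f.attrs["res_xy"])
        res_z = float(f.attrs["res_z"])
        radius = float(f.attrs["nerve_radius_um"])
    axons = [geo.AxonSpec(id=r["id"], x=r["x"], y=r["y"], radius=r["radius"],
                          octant=r["octant"])
             for r in json.loads(path.with_suffix(".axons.json").read_text())]
    return geo.NerveModel(labels=labels, axon_id=axon_id, mito=mito,
                          zone_z=zone_z, res_xy=res_xy, res_z=res_z,
                          nerve_radius_um=radius, axons=axons,
                          segments=segments)


def save_field(field: ConcentrationField, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=field.values, compression="gzip")
        f.attrs["species"] = field.species
        f.attrs["t"] = field.t
    return path


def load_field(path: str | Path) -> ConcentrationField:
    with h5py.File(path, "r") as f:
        return ConcentrationField(f["values"][()],
                                  species=str(f.attrs["species"]),
                                  t=float(f.attrs["t"]))


def save_checkpoint(result: SimulationResult, path: str | Path) -> Path:
    """Field + unit states; together with the lockfile this restarts a run."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=result.field.values,
                         compression="gzip")
        f.create_dataset("status", data=result.states.status)
        f.create_dataset("clock", data=result.states.clock)
        f.attrs["species"] = result.field.species
        f.attrs["t"] = result.field.t
        f.attrs["converged"] = result.converged
    return path


def load_checkpoint(path: str | Path) -> tuple[ConcentrationField, UnitStates]:
    with h5py.File(path, "r") as f:
        field = ConcentrationField(f["values"][()],
                                   species=str(f.attrs["species"]),
                                   t=float(f.attrs["t"]))
        states = UnitStates(f["status"][()], f["clock"][()])
    return field, states


def write_events_tsv(result: SimulationResult, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    result.events_frame().to_csv(path, sep="\t", index=False)
    return path


def heatmap_png(array2d: np.ndarray, path: str | Path,
                vmin: float | None = None, vmax: float | None = None,
                cmap: str = "inferno") -> Path:
    """Export a 2D map as an 8-bit heatmap with an explicit scale sidecar.

    The colour scale is never auto-rescaled silently: the vmin/vmax actually
    used (in nM) are written to ``<name>.scale.json`` so that images from
    different runs can be compared on a shared scale.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    from matplotlib import colormaps, colors
    from matplotlib.image import imsave

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    a = np.asarray(array2d, dtype=float)
    lo = float(a.min()) if vmin is None else float(vmin)
    hi = float(a.max()) if vmax is None else float(vmax)
    if hi <= lo:
        hi = lo + 1e-12
    norm = colors.Normalize(vmin=lo, vmax=hi, clip=True)
    rgba = (colormaps[cmap](norm(a)) * 255).astype(np.uint8)
    imsave(path, rgba)
    path.with_suffix(".scale.json").write_text(
        json.dumps({"vmin_nM": lo, "vmax_nM": hi, "cmap": cmap}))
    return path
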