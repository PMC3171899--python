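"""File formats: HDF5 snapshot/state files, CSV+JSON grids, MRC volumes.

Snapshot files hold ``/snapshots/counts`` (N x p), optionally
``/snapshots/true_quaternions`` (N x 4), a ``/geometry`` group mirroring the
detector block of the run config, and ``/provenance`` (seed and config
echo).  Grids are exchanged either as HDF5
(``/orientations/quaternions``, K x 4) or as a ``k,w,x,y,z`` CSV with a JSON
sidecar carrying the sampling spec.  Volumes go to HDF5
(``/volume/intensity``) and to MRC maps through gemmi.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .detector import DetectorGeometry
from .geometry import OrientationGrid, SamplingSpec
from .simulate import SnapshotSet
from .volumes import IntensityVolume

__all__ = [
    "save_snapshots",
    "load_snapshots",
    "save_grid_h5",
    "load_grid_h5",
    "save_grid_csv",
    "load_grid_csv",
    "save_state",
    "save_volume_h5",
    "load_volume_h5",
    "save_volume_mrc",
]


def _write_geometry(f: h5py.File, geom: DetectorGeometry) -> None:
    g = f.require_group("geometry")
    for key, val in geom.to_dict().items():
        g.attrs[key] = val


def _read_geometry(f: h5py.File) -> DetectorGeometry:
    a = dict(f["geometry"].attrs)
    a["beam_center"] = tuple(float(v) for v in a["beam_center"])
    for k in ("n_fast", "n_slow"):
        a[k] = int(a[k])
    a["curvature_mode"] = str(a["curvature_mode"])
    return DetectorGeometry(**a)


def save_snapshots(path, data: SnapshotSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("snapshots/counts", data=data.counts)
        if data.true_orientations is not None:
            f.create_dataset("snapshots/true_quaternions", data=data.true_orientations)
        _write_geometry(f, data.geometry)
        prov = f.require_group("provenance")
        prov.attrs["config_echo"] = json.dumps(data.provenance, sort_keys=True)
        if data.mean_photons is not None:
            prov.attrs["mean_photons"] = data.mean_photons
        if data.intensity_scale is not None:
            prov.attrs["intensity_scale"] = data.intensity_scale


def load_snapshots(path) -> SnapshotSet:
    with h5py.File(path, "r") as f:
        counts = f["snapshots/counts"][...]
        quats = f["snapshots/true_quaternions"][...] if "snapshots/true_quaternions" in f else None
        geom = _read_geometry(f)
        prov = json.loads(f["provenance"].attrs.get("config_echo", "{}"))
        mp = f["provenance"].attrs.get("mean_photons")
        sc = f["provenance"].attrs.get("intensity_scale")
    return SnapshotSet(counts=counts, geometry=geom, true_orientations=quats,
                       mean_photons=None if mp is None else float(mp),
                       intensity_scale=None if sc is None else float(sc),
                       provenance=prov)


def _spec_dict(spec: SamplingSpec) -> dict:
    return {"object_diameter": spec.object_diameter, "resolution": spec.resolution,
            "symmetry_order": spec.symmetry_order, "dof": spec.dof}


def _spec_from_dict(d: dict) -> SamplingSpec:
    obj = object.__new__(SamplingSpec)
    obj.object_diameter = float(d["object_diameter"])
    obj.resolution = float(d["resolution"])
    obj.symmetry_order = int(d.get("symmetry_order", 1))
    obj.dof = int(d.get("dof", 3))
    return obj


def save_grid_h5(path, grid: OrientationGrid) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("orientations/quaternions", data=grid.nodes)
        for k, v in _spec_dict(grid.spec).items():
            f["orientations"].attrs[k] = v


def load_grid_h5(path) -> OrientationGrid:
    with h5py.File(path, "r") as f:
        nodes = f["orientations/quaternions"][...]
        spec = _spec_from_dict(dict(f["orientations"].attrs))
    return OrientationGrid(nodes=nodes, spec=spec)


def save_grid_csv(path, grid: OrientationGrid) -> None:
    path = Path(path)
    with open(path, "w") as f:
        f.write("k,w,x,y,z\n")
        for k, q in enumerate(grid.nodes):
            f.write(f"{k},{q[0]:.17g},{q[1]:.17g},{q[2]:.17g},{q[3]:.17g}\n")
    path.with_suffix(".json").write_text(json.dumps(_spec_dict(grid.spec), indent=2))


def load_grid_csv(path) -> OrientationGrid:
    path = Path(path)
    rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    spec = _spec_from_dict(json.loads(path.with_suffix(".json").read_text()))
    return OrientationGrid(nodes=rows[:, 1:5], spec=spec)


def save_state(path, model, config_echo: dict | None = None) -> None:
    """Persist a fitted orienter (EMC or GTM) to an HDF5 state file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("tomograms", data=model.tomograms_)
        f.create_dataset("responsibilities", data=model.responsibilities_)
        f.create_dataset("loglik_trace", data=np.asarray(model.log_likelihood_trace_))
        f.create_dataset("orientations/quaternions", data=model.grid_.nodes)
        for k, v in _spec_dict(model.grid_.spec).items():
            f["orientations"].attrs[k] = v
        vol = getattr(model, "volume_", None)
        if vol is not None:
            f.create_dataset("volume/intensity", data=vol.values)
            f["volume"].attrs["voxel_spacing"] = vol.voxel_spacing
        if hasattr(model, "op_count_"):
            f.attrs["opcounts"] = model.op_count_
        if hasattr(model, "weights_"):
            g = f.require_group("gtm")
            g.create_dataset("weights", data=model.weights_)
            g.create_dataset("phi", data=model.phi_)
            g.attrs["beta"] = model.beta_
            g.attrs["alpha"] = model.alpha
            g.attrs["sigma_phi"] = model.sigma_phi_
        f.attrs["n_iter"] = model.n_iter_
        f.attrs["converged"] = bool(model.converged_)
        if config_echo:
            f.attrs["config_echo"] = json.dumps(config_echo, sort_keys=True)


def save_volume_h5(path, vol: IntensityVolume) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("volume/intensity", data=vol.values)
        f["volume"].attrs["voxel_spacing"] = vol.voxel_spacing


def load_volume_h5(path) -> IntensityVolume:
    with h5py.File(path, "r") as f:
        return IntensityVolume(values=f["volume/intensity"][...],
                               voxel_spacing=float(f["volume"].attrs["voxel_spacing"]))


def save_volume_mrc(path, vol: IntensityVolume) -> None:
    """Write the volume as an MRC/CCP4 map (voxel size from the lattice)."""
    import gemmi

    grid = gemmi.FloatGrid(np.ascontiguousarray(vol.values, dtype=np.float32))
    # the MRC cell is the real-space period of the reciprocal lattice
    cell = vol.L * (1.0 / (vol.L * vol.voxel_spacing))
    grid.set_unit_cell(gemmi.UnitCell(cell, cell, cell, 90, 90, 90))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))
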