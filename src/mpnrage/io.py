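"""File formats: HDF5 k-space containers, NIfTI volumes, YAML configs,
and run manifests.

The k-space container layout:

    /kdata       complex64  (blocks, views, samples, coils)
    /traj        float32    (blocks, views, samples, d)
    /spoke_dirs  float32    (blocks, views, d)
    /dcf         float32    (blocks, views, samples)     [optional]
    /ti_index    int32      (views,)
    /view_order  int32      (blocks, views)              [optional]
    /maps        complex64  (coils, *grid)               [optional]
    /support     uint8      (*grid)                      [optional]
    attrs        the sequence parameters

Dictionaries/bases cache to HDF5 as /atoms, /grid, /V, /sv.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .operators import CoilMaps, ImageSeries, KSpaceData
from .sequence import SequenceParams, SignalDictionary, TemporalBasis
from .trajectory import RadialTrajectory, ViewOrder

__all__ = [
    "save_kspace", "load_kspace", "save_series_nifti", "load_series_nifti",
    "save_basis", "load_basis", "load_config", "save_config", "write_manifest",
    "content_hash",
]


def save_kspace(path, ksp: KSpaceData, seq: SequenceParams | None = None,
                maps: CoilMaps | None = None, order: ViewOrder | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kdata", data=ksp.samples.astype(np.complex64))
        f.create_dataset("traj", data=ksp.traj.coords.astype(np.float32))
        f.create_dataset("spoke_dirs", data=ksp.traj.spoke_dirs.astype(np.float32))
        f.create_dataset("ti_index", data=ksp.ti_index.astype(np.int32))
        if ksp.dcf is not None:
            f.create_dataset("dcf", data=ksp.dcf.astype(np.float32))
        if order is not None:
            f.create_dataset("view_order", data=order.assignment.astype(np.int32))
            f["view_order"].attrs["scheme"] = order.scheme
        if maps is not None:
            f.create_dataset("maps", data=maps.maps.astype(np.complex64))
            f.create_dataset("support", data=maps.support.astype(np.uint8))
        if ksp.noise_sigma is not None:
            f.attrs["noise_sigma"] = ksp.noise_sigma
        if seq is not None:
            f.attrs["sequence"] = json.dumps(seq.asdict())


def load_kspace(path) -> tuple[KSpaceData, SequenceParams | None, CoilMaps | None]:
    with h5py.File(path, "r") as f:
        traj = RadialTrajectory(coords=f["traj"][...].astype(float),
                                spoke_dirs=f["spoke_dirs"][...].astype(float))
        ksp = KSpaceData(
            samples=f["kdata"][...].astype(complex),
            traj=traj,
            ti_index=f["ti_index"][...],
            dcf=f["dcf"][...].astype(float) if "dcf" in f else None,
            noise_sigma=float(f.attrs["noise_sigma"]) if "noise_sigma" in f.attrs else None,
        )
        seq = None
        if "sequence" in f.attrs:
            d = json.loads(f.attrs["sequence"])
            d["flip_schedule_deg"] = np.asarray(d["flip_schedule_deg"])
            seq = SequenceParams(**d)
        maps = None
        if "maps" in f:
            maps = CoilMaps(maps=f["maps"][...].astype(complex),
                            support=f["support"][...].astype(bool))
    return ksp, seq, maps


def save_series_nifti(path, series: ImageSeries | np.ndarray,
                      voxel_size_mm: float = 1.0) -> None:
    """Write a contrast series (or parameter map) as NIfTI, contrast last."""
    vols = np.abs(getattr(series, "volumes", series))
    if vols.ndim >= 3 and hasattr(series, "volumes"):
        vols = np.moveaxis(vols, 0, -1)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(vols, dtype=np.float32), affine), str(path))


def load_series_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def save_basis(path, dictionary: SignalDictionary | None,
               basis: TemporalBasis) -> None:
    with h5py.File(path, "w") as f:
        if dictionary is not None:
            f.create_dataset("atoms", data=dictionary.atoms)
            f.create_dataset("grid", data=dictionary.grid)
        f.create_dataset("V", data=basis.v)
        f.create_dataset("sv", data=basis.singular_values)


def load_basis(path) -> tuple[SignalDictionary | None, TemporalBasis]:
    with h5py.File(path, "r") as f:
        dictionary = None
        if "atoms" in f:
            dictionary = SignalDictionary(atoms=f["atoms"][...], grid=f["grid"][...])
        basis = TemporalBasis(v=f["V"][...], singular_values=f["sv"][...])
    return dictionary, basis


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}


def save_config(path, config: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=True)


def content_hash(*arrays) -> str:
    """Deterministic content hash of a set of arrays (for manifests)."""
    h = hashlib.sha256()
    for a in arrays:
        a = np.ascontiguousarray(a)
        h.update(str(a.dtype).encode())
        h.update(str(a.shape).encode())
        h.update(a.tobytes())
    return h.hexdigest()[:16]


def write_manifest(path, config: dict, seed: int, input_hashes: dict | None = None,
                   outputs: dict | None = None) -> None:
    """Record everything needed to reproduce a run bit-for-bit."""
    manifest = {
        "seed": int(seed),
        "config": config,
        "input_hashes": input_hashes or {},
        "outputs": outputs or {},
    }
    save_config(path, manifest)
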