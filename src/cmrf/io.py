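"""Serialization: HDF5 for k-space/dictionary/model data, NIfTI for maps."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .epg import Dictionary, Subspace
from .fgn import FGNModel
from .nn import Dense
from .phantom import CoilMaps, TissuePhantom
from .sequence import (CardiacRhythm, CardiacSchedule, PrepEvent,
                       SequenceParams, build_schedule)
from .spiral import SpiralMRFData, SpiralTrajectory

__all__ = [
    "save_schedule_yaml", "load_schedule_yaml",
    "save_dictionary", "load_dictionary",
    "save_spiral_data", "load_spiral_data",
    "save_cartesian_data", "load_cartesian_data",
    "save_maps_nifti", "save_phantom_nifti",
    "save_fgn", "load_fgn",
]


# -- schedule ---------------------------------------------------------------

def save_schedule_yaml(schedule: CardiacSchedule, path):
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(schedule.to_dict(), fh, sort_keys=False)


def load_schedule_yaml(path) -> CardiacSchedule:
    import yaml

    with open(path) as fh:
        d = yaml.safe_load(fh)
    params = SequenceParams(**{**d["params"],
                               "t2prep_times_ms": tuple(d["params"]["t2prep_times_ms"])})
    rhythm = CardiacRhythm(tuple(d["rr_intervals_ms"]))
    return build_schedule(params, rhythm, flip_pattern=d["flip_deg"])


# -- dictionary / subspace --------------------------------------------------

def save_dictionary(path, D: Dictionary, S: Subspace | None = None):
    with h5py.File(path, "w") as f:
        f.create_dataset("entries", data=D.entries)
        f.create_dataset("D", data=D.D)
        f.attrs["schedule_hash"] = D.schedule_hash
        if S is not None:
            f.create_dataset("V_k", data=S.V_k)
            f.attrs["k"] = S.k
            f.attrs["energy_fraction"] = S.energy_fraction


def load_dictionary(path):
    with h5py.File(path, "r") as f:
        D = Dictionary(entries=f["entries"][()], D=f["D"][()],
                       schedule_hash=f.attrs["schedule_hash"])
        S = None
        if "V_k" in f:
            S = Subspace(V_k=f["V_k"][()], k=int(f.attrs["k"]),
                         energy_fraction=float(f.attrs["energy_fraction"]))
    return D, S


# -- raw spiral data --------------------------------------------------------

def save_spiral_data(path, data: SpiralMRFData):
    with h5py.File(path, "w") as f:
        f.create_dataset("y", data=data.y)
        f.create_dataset("ktraj", data=data.trajectory.coords)
        f.create_dataset("rr_ms", data=data.schedule.rhythm.as_array())
        f.attrs["matrix"] = data.trajectory.matrix
        f.attrs["fov_mm"] = data.trajectory.fov_mm
        f.attrs["n_interleaves"] = data.trajectory.n_interleaves
        f.attrs["rotation_per_tr_deg"] = data.trajectory.rotation_per_tr_deg
        f.attrs["noise_pct"] = data.noise_pct
        f.attrs["noise_sigma"] = data.noise_sigma
        f.attrs["seed"] = data.seed
        f.attrs["schedule_json"] = json.dumps(data.schedule.to_dict())


def load_spiral_data(path) -> SpiralMRFData:
    with h5py.File(path, "r") as f:
        sched_d = json.loads(f.attrs["schedule_json"])
        params = SequenceParams(**{**sched_d["params"],
                                   "t2prep_times_ms": tuple(sched_d["params"]["t2prep_times_ms"])})
        schedule = build_schedule(params,
                                  CardiacRhythm(tuple(sched_d["rr_intervals_ms"])),
                                  flip_pattern=sched_d["flip_deg"])
        traj = SpiralTrajectory(coords=f["ktraj"][()],
                                n_interleaves=int(f.attrs["n_interleaves"]),
                                rotation_per_tr_deg=float(f.attrs["rotation_per_tr_deg"]),
                                matrix=int(f.attrs["matrix"]),
                                fov_mm=float(f.attrs["fov_mm"]))
        return SpiralMRFData(y=f["y"][()], trajectory=traj, schedule=schedule,
                             noise_sigma=float(f.attrs["noise_sigma"]),
                             noise_pct=float(f.attrs["noise_pct"]),
                             seed=int(f.attrs["seed"]))


# -- GROG-gridded Cartesian data -------------------------------------------

def save_cartesian_data(path, cart):
    with h5py.File(path, "w") as f:
        f.create_dataset("y_cart", data=cart.y_cart)
        f.create_dataset("P", data=np.packbits(cart.P, axis=-1))
        f.attrs["P_shape"] = cart.P.shape
        f.create_dataset("W", data=cart.W)
        f.create_dataset("csm", data=cart.csm.S)
        f.attrs["schedule_json"] = json.dumps(cart.schedule.to_dict())


def load_cartesian_data(path):
    from .grog import CartesianMRFData

    with h5py.File(path, "r") as f:
        shape = tuple(f.attrs["P_shape"])
        P = np.unpackbits(f["P"][()], axis=-1,
                          count=shape[-1]).astype(bool).reshape(shape)
        sched_d = json.loads(f.attrs["schedule_json"])
        params = SequenceParams(**{**sched_d["params"],
                                   "t2prep_times_ms": tuple(sched_d["params"]["t2prep_times_ms"])})
        schedule = build_schedule(params,
                                  CardiacRhythm(tuple(sched_d["rr_intervals_ms"])),
                                  flip_pattern=sched_d["flip_deg"])
        return CartesianMRFData(y_cart=f["y_cart"][()], P=P, W=f["W"][()],
                                csm=CoilMaps(S=f["csm"][()]),
                                schedule=schedule)


# -- maps -------------------------------------------------------------------

def save_maps_nifti(prefix, maps):
    import nibabel as nib

    aff = np.eye(4)
    nib.save(nib.Nifti1Image(maps.t1_map.astype(np.float32), aff),
             f"{prefix}_t1.nii")
    nib.save(nib.Nifti1Image(maps.t2_map.astype(np.float32), aff),
             f"{prefix}_t2.nii")
    nib.save(nib.Nifti1Image(np.abs(maps.m0_map).astype(np.float32), aff),
             f"{prefix}_m0_mag.nii")
    nib.save(nib.Nifti1Image(np.angle(maps.m0_map).astype(np.float32), aff),
             f"{prefix}_m0_phase.nii")


def save_phantom_nifti(prefix, phantom: TissuePhantom):
    import nibabel as nib

    aff = np.eye(4)
    for name, arr in [("t1", phantom.t1_map), ("t2", phantom.t2_map),
                      ("m0_mag", np.abs(phantom.m0_map)),
                      ("labels", phantom.labels.astype(np.float32))]:
        nib.save(nib.Nifti1Image(arr.astype(np.float32), aff),
                 f"{prefix}_{name}.nii")
    with open(f"{prefix}_tissues.json", "w") as fh:
        json.dump({"seed": phantom.seed, "tissues": phantom.tissue_values}, fh,
                  indent=2)


# -- FGN checkpoint ---------------------------------------------------------

def save_fgn(path, model: FGNModel):
    with h5py.File(path, "w") as f:
        f.attrs["n_rr"] = model.n_rr
        f.attrs["t"] = model.t
        f.attrs["schedule_hash"] = model.schedule_hash
        f.attrs["validation_loss"] = model.validation_loss
        for i, p in enumerate(model.params()):
            f.create_dataset(f"p{i}", data=p.value)


def load_fgn(path) -> FGNModel:
    rng = np.random.default_rng(0)
    with h5py.File(path, "r") as f:
        hidden = f["p2"].shape[0]
        model = FGNModel(int(f.attrs["n_rr"]), int(f.attrs["t"]), hidden, rng)
        model.schedule_hash = str(f.attrs["schedule_hash"])
        model.validation_loss = float(f.attrs["validation_loss"])
        for i, p in enumerate(model.params()):
            p.value = f[f"p{i}"][()]
    return model
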