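"""Checkpoint and tabular I/O: HDF5 for weights/state caches, delimited text
for spikes and trajectories, JSON manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .arena import EnvironmentGeometry, Trajectory


def save_spikes_csv(path, spike_times: dict) -> None:
    """Write spikes as a `unit_id,t` table; unit keys are serialized as
    ``g<module>:<index>`` / ``p<index>``."""
    import pandas as pd

    rows = []
    for key, times in spike_times.items():
        uid = f"g{key[1]}:{key[2]}" if key[0] == "g" else f"p{key[1]}"
        for t in np.asarray(times):
            rows.append((uid, float(t)))
    pd.DataFrame(rows, columns=["unit_id", "t"]).to_csv(path, index=False)


def load_spikes_csv(path) -> dict:
    import pandas as pd

    df = pd.read_csv(path)
    out = {}
    for uid, grp in df.groupby("unit_id"):
        uid = str(uid)
        if uid.startswith("g"):
            mi, idx = uid[1:].split(":")
            key = ("g", int(mi), int(idx))
        elif uid.startswith("p"):
            key = ("p", int(uid[1:]))
        else:
            raise ValueError(f"bad unit_id {uid!r}")
        out[key] = np.sort(grp["t"].to_numpy(float))
    return out


def save_checkpoint(path, net, config_dict: dict | None = None) -> None:
    """Persist the familiarized network (weights, wiring, state cache)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["sheet_size"] = net.config.sheet_size
        f.attrs["n_modules"] = net.config.n_modules
        if config_dict is not None:
            f.attrs["config_json"] = json.dumps(config_dict)
        f.create_dataset("w_bg", data=net.familiar_w_bg
                         if net.familiar_w_bg is not None else net.w_bg)
        if net.place is not None:
            f.create_dataset("w_gp", data=net.familiar_w_gp
                             if net.familiar_w_gp is not None else net.place.w)
            f.create_dataset("place_afferents", data=net.place.afferents)
        if net.state_cache:
            keys = np.array(sorted(net.state_cache), dtype=np.int64)
            vals = np.stack([net.state_cache[tuple(k)] for k in keys])
            f.create_dataset("cache_keys", data=keys)
            f.create_dataset("cache_states", data=vals)
        if net.recorded_grid:
            f.create_dataset(
                "recorded_grid",
                data=np.array([(u[1], u[2]) for u in net.recorded_grid],
                              dtype=np.int64))


def load_checkpoint(path, net) -> None:
    """Restore familiarized weights/cache into a structurally matching net."""
    import h5py

    with h5py.File(path, "r") as f:
        if int(f.attrs["sheet_size"]) != net.config.sheet_size or \
                int(f.attrs["n_modules"]) != net.config.n_modules:
            raise ValueError("checkpoint structure does not match the network")
        net.w_bg = f["w_bg"][()]
        net.familiar_w_bg = net.w_bg.copy()
        if net.place is not None and "w_gp" in f:
            net.place.w = f["w_gp"][()]
            net.familiar_w_gp = net.place.w.copy()
            net.place.afferents = f["place_afferents"][()]
        net.state_cache = {}
        if "cache_keys" in f:
            keys = f["cache_keys"][()]
            vals = f["cache_states"][()]
            for k, v in zip(keys, vals):
                net.state_cache[(int(k[0]), int(k[1]))] = v
        if "recorded_grid" in f:
            net.recorded_grid = [("g", int(m), int(i))
                                 for m, i in f["recorded_grid"][()]]


def save_environment_yaml(path, env: EnvironmentGeometry) -> None:
    import yaml

    Path(path).write_text(yaml.safe_dump(env.to_dict(), sort_keys=False))


def load_environment_yaml(path) -> EnvironmentGeometry:
    import yaml

    return EnvironmentGeometry.from_dict(yaml.safe_load(Path(path).read_text()))


def write_manifest(path, config_dict: dict, seeds: dict, extra: dict | None = None) -> None:
    """Reproducibility manifest: config hash, seeds, package version."""
    from . import __version__

    payload = {
        "package_version": __version__,
        "config": config_dict,
        "seeds": seeds,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
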