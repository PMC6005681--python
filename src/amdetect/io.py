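"""On-disk formats: session CSV, unit HDF5, config YAML, manifest JSON.

The unit HDF5 schema stores one group per unit
(``/animals/<animal>/units/<unit>``) holding a concatenated spike-time
dataset plus per-trial offsets (ragged storage), the trial table columns,
and unit metadata as attributes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .synthetic import (
    ABRPreset, BehavioralSession, CohortConfig, EFRPreset, PsychPreset,
    TuningPreset, UnitRecording,
)

__all__ = [
    "save_session_csv", "load_session_csv",
    "save_units_hdf5", "load_units_hdf5",
    "save_manifest_json", "load_config_yaml", "save_config_yaml",
]


def save_session_csv(session: BehavioralSession, path) -> None:
    df = session.trials.copy()
    df.insert(0, "animal_id", session.animal_id)
    df.insert(1, "hearing_status", session.hearing_status)
    df.insert(2, "rate_hz", session.rate_hz)
    df.to_csv(path, index=False)


def load_session_csv(path) -> BehavioralSession:
    df = pd.read_csv(path)
    meta = df.iloc[0]
    trials = df.drop(columns=["animal_id", "hearing_status", "rate_hz"])
    return BehavioralSession(
        animal_id=str(meta["animal_id"]),
        hearing_status=str(meta["hearing_status"]),
        rate_hz=float(meta["rate_hz"]),
        trials=trials.reset_index(drop=True),
        level_db_spl=float(trials["level_db_spl"].mean()),
        seed=-1,
        session_id=f"{meta['animal_id']}-{int(meta['rate_hz'])}Hz",
    )


def save_units_hdf5(units, path) -> None:
    with h5py.File(path, "w") as f:
        for u in units:
            grp = f.create_group(f"animals/{u.animal_id}/units/{u.unit_id}")
            flat = np.concatenate([np.asarray(s, float) for s in u.spikes]) \
                if u.spikes else np.empty(0)
            offsets = np.cumsum([0] + [len(s) for s in u.spikes])
            grp.create_dataset("spike_times", data=flat)
            grp.create_dataset("trial_offsets", data=offsets)
            tr = grp.create_group("trials")
            for col in u.trials.columns:
                data = u.trials[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                tr.create_dataset(col, data=data)
            grp.attrs.update({
                "animal_id": u.animal_id, "hearing_status": u.hearing_status,
                "rate_hz": u.rate_hz, "isolation": u.isolation,
                "nose_poke_t": u.nose_poke_t, "am_duration_s": u.am_duration_s,
            })


def load_units_hdf5(path) -> list:
    units = []
    with h5py.File(path, "r") as f:
        for animal in f["animals"]:
            for unit_id, grp in f[f"animals/{animal}/units"].items():
                flat = grp["spike_times"][...]
                offs = grp["trial_offsets"][...]
                spikes = [flat[offs[i]:offs[i + 1]] for i in range(len(offs) - 1)]
                cols = {}
                for col, ds in grp["trials"].items():
                    data = ds[...]
                    if data.dtype.kind == "S":
                        data = data.astype(str)
                    cols[col] = data
                trials = pd.DataFrame(cols)
                units.append(UnitRecording(
                    unit_id=unit_id,
                    animal_id=grp.attrs["animal_id"],
                    hearing_status=grp.attrs["hearing_status"],
                    rate_hz=float(grp.attrs["rate_hz"]),
                    isolation=grp.attrs["isolation"],
                    spikes=spikes,
                    trials=trials,
                    nose_poke_t=float(grp.attrs["nose_poke_t"]),
                    am_duration_s=float(grp.attrs["am_duration_s"]),
                ))
    return units


def save_manifest_json(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def save_config_yaml(config: CohortConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(synthetic.config_to_dict(config)))


def load_config_yaml(path) -> CohortConfig:
    raw = yaml.safe_load(Path(path).read_text())
    psych = {}
    for key, v in raw.pop("psych", {}).items():
        group, rate = key.split(":")
        psych[(group, float(rate))] = PsychPreset(**v)
    def _tuning(v):
        v = dict(v)
        for key in ("spont_hz", "driven_base_hz", "kappa"):
            if key in v:
                v[key] = tuple(v[key])
        for key in ("depth_gain_hz", "kappa_hz"):
            v[key] = {float(r): tuple(x) for r, x in v.get(key, {}).items()}
        return TuningPreset(**v)

    tuning = {g: _tuning(v) for g, v in raw.pop("tuning", {}).items()}
    efr = EFRPreset(**raw.pop("efr", {}))
    abr = {g: ABRPreset(**v) for g, v in raw.pop("abr", {}).items()}
    fields = {f.name for f in dataclasses.fields(CohortConfig)}
    kwargs = {k: v for k, v in raw.items() if k in fields}
    for key in ("groups", "rates_hz", "unit_count_range"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return CohortConfig(psych=psych, tuning=tuning, efr=efr, abr=abr, **kwargs)
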