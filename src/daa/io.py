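"""Model container I/O: one HDF5 file per fitted model with a JSON
metadata block (config, seed, model type).  Round trips are exact."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from .datamodel import ViewKey
from .model import DAAModel, FitConfig

__all__ = ["save_model", "load_model"]


def save_model(model: DAAModel, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["model_type"] = model.model_type
        f.attrs["config"] = json.dumps(dataclasses.asdict(model.config))
        f.attrs["seed"] = -1 if model.seed is None else int(model.seed)
        f.create_dataset("loss_trace", data=np.asarray(model.loss_trace))
        if isinstance(model.C, dict):
            g = f.create_group("C_per_view")
            for k, v in model.C.items():
                g.create_dataset(k.label(), data=v)
        else:
            f.create_dataset("C", data=model.C)
        gS = f.create_group("S")
        for k, v in model.S.items():
            gS.create_dataset(k.label(), data=v)
        gA = f.create_group("archetypes")
        for k, v in model.archetypes.items():
            gA.create_dataset(k.label(), data=v)
        if model.condition_slices:
            g = f.create_group("condition_slices")
            for c, sl in model.condition_slices.items():
                g.create_dataset(str(c), data=np.array([sl.start, sl.stop]))


def load_model(path: str | Path) -> DAAModel:
    with h5py.File(path, "r") as f:
        cfg = FitConfig(**json.loads(f.attrs["config"]))
        # JSON turns tuples into lists; restore hashable types where needed
        seed = int(f.attrs["seed"])
        if isinstance(f.get("C"), h5py.Dataset):
            C = f["C"][()]
        else:
            C = {ViewKey.from_label(k): v[()] for k, v in f["C_per_view"].items()}
        S = {ViewKey.from_label(k): v[()] for k, v in f["S"].items()}
        arche = {ViewKey.from_label(k): v[()] for k, v in f["archetypes"].items()}
        slices = None
        if "condition_slices" in f:
            slices = {c: slice(int(v[0]), int(v[1]))
                      for c, v in f["condition_slices"].items()}
        return DAAModel(
            model_type=str(f.attrs["model_type"]),
            C=C, S=S, archetypes=arche,
            loss_trace=f["loss_trace"][()],
            config=cfg,
            seed=None if seed == -1 else seed,
            condition_slices=slices,
        )
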