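"""Serialization: models as JSON, volumes/spectra/patterns as HDF5, metrics as CSV."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .emission import AngularGrid, EmissionPattern
from .metrics import CreationMetrics
from .spectral import SpectralComponents
from .structure import FibrilEnsembleSpec, FibrilModel, VoxelVolume

__all__ = [
    "save_model_json",
    "load_model_json",
    "save_volume_h5",
    "load_volume_h5",
    "save_components_h5",
    "load_components_h5",
    "save_pattern_h5",
    "load_pattern_h5",
    "metrics_to_frame",
]


def save_model_json(model: FibrilModel, path) -> None:
    doc = {
        "box": list(model.box),
        "seed": model.seed,
        "spec": dataclasses.asdict(model.spec) if model.spec else None,
        "fibrils": model.fibrils.tolist(),
        "lattice_index": (
            model.lattice_index.tolist() if model.lattice_index is not None else None
        ),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model_json(path) -> FibrilModel:
    doc = json.loads(Path(path).read_text())
    spec = FibrilEnsembleSpec(**doc["spec"]) if doc.get("spec") else None
    li = doc.get("lattice_index")
    return FibrilModel(
        fibrils=np.asarray(doc["fibrils"], dtype=float).reshape(-1, 4),
        box=tuple(doc["box"]),
        spec=spec,
        seed=doc.get("seed"),
        lattice_index=None if li is None else np.asarray(li, dtype=int),
    )


def save_volume_h5(vol: VoxelVolume, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=vol.values, compression="gzip")
        f.attrs["box"] = vol.box
        f.attrs["windowed"] = vol.windowed
        if vol.window_a is not None:
            f.attrs["window_a"] = vol.window_a
        if vol.lambda_window is not None:
            f.attrs["lambda_window"] = vol.lambda_window


def load_volume_h5(path) -> VoxelVolume:
    with h5py.File(path, "r") as f:
        return VoxelVolume(
            values=f["values"][...],
            box=tuple(f.attrs["box"]),
            windowed=bool(f.attrs["windowed"]),
            window_a=float(f.attrs["window_a"]) if "window_a" in f.attrs else None,
            lambda_window=(
                float(f.attrs["lambda_window"])
                if "lambda_window" in f.attrs
                else None
            ),
        )


def save_components_h5(comps: SpectralComponents, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("G", data=comps.G, compression="gzip")
        f.attrs["starts"] = comps.starts
        f.attrs["box"] = comps.box
        if comps.lambda_window is not None:
            f.attrs["lambda_window"] = comps.lambda_window
        if comps.window_a is not None:
            f.attrs["window_a"] = comps.window_a


def load_components_h5(path) -> SpectralComponents:
    with h5py.File(path, "r") as f:
        starts = tuple(int(s) for s in f.attrs["starts"])
        return SpectralComponents(
            G=f["G"][...],
            m_start=starts[0],
            n_start=starts[1],
            l_start=starts[2],
            box=tuple(f.attrs["box"]),
            lambda_window=(
                float(f.attrs["lambda_window"])
                if "lambda_window" in f.attrs
                else None
            ),
            window_a=float(f.attrs["window_a"]) if "window_a" in f.attrs else None,
        )


def save_pattern_h5(pattern: EmissionPattern, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("field", data=pattern.field, compression="gzip")
        f.create_dataset("theta", data=pattern.grid.theta)
        f.create_dataset("phi", data=pattern.grid.phi)
        f.attrs["lambda_fund"] = pattern.lambda_fund
        f.attrs["prefactor"] = pattern.prefactor
        f.attrs["window_mode"] = pattern.window_mode


def load_pattern_h5(path) -> EmissionPattern:
    with h5py.File(path, "r") as f:
        field = f["field"][...]
        grid = AngularGrid(n_theta=field.shape[0], n_phi=field.shape[1])
        return EmissionPattern(
            field=field,
            grid=grid,
            lambda_fund=float(f.attrs["lambda_fund"]),
            prefactor=float(f.attrs["prefactor"]),
            window_mode=str(f.attrs["window_mode"]),
        )


def metrics_to_frame(rows: list[dict | CreationMetrics]) -> pd.DataFrame:
    """Flatten metrics (optionally annotated dicts) into a DataFrame."""
    recs = []
    for r in rows:
        recs.append(dataclasses.asdict(r) if isinstance(r, CreationMetrics) else r)
    return pd.DataFrame(recs)
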