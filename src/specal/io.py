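"""CSV / YAML / JSON serialization.

Spectra CSV layout: first column ``wavelength_nm`` (strictly increasing),
one column per sample (header = sample id), absorbance in AU written at 6
decimal places. Concentration CSV: ``run_id`` then one column per
component (ug/mL). Models serialize to a single JSON document with a
``schema_version`` field and provenance block.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ann import AnnModel, AnnScaler
from .design import CalibrationSplit, DesignTable, LevelMap
from .pls import PlsModel
from .preprocess import CenteringTransform
from .synthspec import ComponentSpec, NoiseModel, SpectrumSet, WavelengthGrid

SCHEMA_VERSION = 1


# ---------------------------------------------------------------- spectra CSV

def write_spectra_csv(path, s: SpectrumSet) -> None:
    df = pd.DataFrame(
        {"wavelength_nm": s.grid.values}
        | {sid: s.absorbance[i] for i, sid in enumerate(s.sample_ids)}
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_spectra_csv(path) -> SpectrumSet:
    # pandas mangles duplicate headers, so check ids on the raw header line
    raw_header = Path(path).read_text().splitlines()[0].split(",")[1:]
    if len(set(raw_header)) != len(raw_header):
        dupes = sorted({c for c in raw_header if raw_header.count(c) > 1})
        raise ValueError(f"duplicated sample ids: {dupes}")
    df = _read_strict_csv(path)
    if df.columns[0] != "wavelength_nm":
        raise ValueError("first column must be 'wavelength_nm'")
    sample_ids = tuple(df.columns[1:])
    lam = df["wavelength_nm"].to_numpy(dtype=float)
    if lam.size < 2 or np.any(np.diff(lam) <= 0):
        raise ValueError("wavelength column must be strictly increasing")
    step = np.diff(lam).mean()
    grid = WavelengthGrid(
        start_nm=float(lam[0]), stop_nm=float(lam[-1]), step_nm=float(step)
    )
    absorbance = df[list(sample_ids)].to_numpy(dtype=float).T
    return SpectrumSet(grid=grid, absorbance=absorbance, sample_ids=sample_ids)


def _read_strict_csv(path) -> pd.DataFrame:
    """CSV reader with explicit ragged-row and non-numeric diagnostics."""
    raw = Path(path).read_text().strip().splitlines()
    header = raw[0].split(",")
    for i, line in enumerate(raw[1:], start=2):
        cells = line.split(",")
        if len(cells) != len(header):
            raise ValueError(
                f"{path}: ragged row at line {i} "
                f"({len(cells)} cells, expected {len(header)})"
            )
    df = pd.read_csv(path)
    for col in df.columns[1:] if df.columns[0] == "run_id" else df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            raise ValueError(
                f"{path}: non-numeric cell(s) in column {col!r}, "
                f"row(s) {[int(b) + 2 for b in bad]}"
            )
    return df


# ----------------------------------------------------- concentrations / design

def write_conc_csv(path, conc: np.ndarray, component_names, run_ids=None) -> None:
    conc = np.atleast_2d(np.asarray(conc, dtype=float))
    if run_ids is None:
        run_ids = np.arange(1, conc.shape[0] + 1)
    df = pd.DataFrame(conc, columns=list(component_names))
    df.insert(0, "run_id", run_ids)
    df.to_csv(path, index=False, float_format="%.6f")


def read_conc_csv(path) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Returns (concentrations, component names, run ids)."""
    df = _read_strict_csv(path)
    if df.columns[0] != "run_id":
        raise ValueError("first column must be 'run_id'")
    names = list(df.columns[1:])
    return df[names].to_numpy(dtype=float), names, df["run_id"].to_numpy()


def write_design_csv(outdir, design: DesignTable, conc: np.ndarray,
                     split: CalibrationSplit | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design.to_frame().to_csv(outdir / "design_coded.csv", index=False)
    write_conc_csv(outdir / "design_conc.csv", conc, design.factor_names)
    if split is not None:
        split.to_frame().to_csv(outdir / "split.csv", index=False)


def read_split_csv(path) -> CalibrationSplit:
    df = pd.read_csv(path)
    cal = np.flatnonzero(df["role"] == "calibration")
    val = np.flatnonzero(df["role"] == "validation")
    return CalibrationSplit(calibration_indices=cal, validation_indices=val)


# ------------------------------------------------------------------- YAML cfg

def read_ranges_yaml(path) -> LevelMap:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return LevelMap(ranges={k: (float(v[0]), float(v[1])) for k, v in data.items()})


def read_library_yaml(path) -> list[ComponentSpec]:
    """Band library: mapping name -> list of [center, sigma, peak] triplets."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [
        ComponentSpec(name=name, bands=tuple(tuple(map(float, b)) for b in bands))
        for name, bands in data.items()
    ]


def write_library_yaml(path, library: list[ComponentSpec]) -> None:
    data = {
        spec.name: [[float(c), float(s), float(p)] for c, s, p in spec.bands]
        for spec in library
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_noise_yaml(path) -> NoiseModel:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return NoiseModel(**data)


# ------------------------------------------------------------------ model JSON

def _provenance(extra: dict | None = None) -> dict:
    prov = {"software": "specal", "version": __version__}
    prov.update(extra or {})
    return prov


def save_pls_model(path, model: PlsModel, provenance: dict | None = None) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "model_type": "pls",
        "provenance": _provenance(provenance),
        "x_mean": model.centering.x_mean.tolist(),
        "y_mean": model.centering.y_mean.tolist(),
        "W": model.W.tolist(),
        "P": model.P.tolist(),
        "Q": model.Q.tolist(),
        "B": model.B.tolist(),
        "n_lv": model.n_lv,
        "scores": model.scores.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_pls_model(path) -> PlsModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("model_type") != "pls":
        raise ValueError(f"{path}: not a PLS model document")
    centering = CenteringTransform(
        x_mean=np.array(doc["x_mean"]), y_mean=np.array(doc["y_mean"])
    )
    return PlsModel(
        centering=centering,
        W=np.array(doc["W"]),
        P=np.array(doc["P"]),
        Q=np.array(doc["Q"]),
        B=np.array(doc["B"]),
        n_lv=int(doc["n_lv"]),
        scores=np.array(doc["scores"]),
    )


def save_ann_model(path, model: AnnModel, provenance: dict | None = None) -> None:
    if model.scaler is None:
        raise ValueError("refusing to serialize an untrained ANN model")
    doc = {
        "schema_version": SCHEMA_VERSION,
        "model_type": "ann",
        "provenance": _provenance(provenance),
        "W1": model.W1.tolist(),
        "b1": model.b1.tolist(),
        "W2": model.W2.tolist(),
        "b2": model.b2.tolist(),
        "scaler": {
            "x_mean": model.scaler.x_mean.tolist(),
            "x_scale": model.scaler.x_scale,
            "y_min": model.scaler.y_min.tolist(),
            "y_max": model.scaler.y_max.tolist(),
        },
        "config": model.config,
    }
    Path(path).write_text(json.dumps(doc))


def load_ann_model(path) -> AnnModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("model_type") != "ann":
        raise ValueError(f"{path}: not an ANN model document")
    sc = doc["scaler"]
    scaler = AnnScaler(
        x_mean=np.array(sc["x_mean"]),
        x_scale=float(sc["x_scale"]),
        y_min=np.array(sc["y_min"]),
        y_max=np.array(sc["y_max"]),
    )
    return AnnModel(
        W1=np.array(doc["W1"]),
        b1=np.array(doc["b1"]),
        W2=np.array(doc["W2"]),
        b2=np.array(doc["b2"]),
        scaler=scaler,
        config=doc.get("config", {}),
    )
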