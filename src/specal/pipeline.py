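"""End-to-end pipeline: design -> simulate -> preprocess -> fit -> validate.

Reproduces the full study workflow on synthetic spectra: build the 25-run
five-level design, realize concentrations, simulate mixture spectra,
slice the informative window, split 15/10, calibrate PLS (with LOO-selected
latent variables) and/or the linear ANN, and score the validation set with
the full figures-of-merit layer. Every stochastic stage is seeded from the
config, so runs are reproducible end to end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, ann as ann_mod
from .design import (
    DEFAULT_RANGES,
    FACTOR_NAMES,
    LevelMap,
    generate_design,
    realize_concentrations,
    split_runs,
)
from .io import (
    save_ann_model,
    save_pls_model,
    write_design_csv,
    write_library_yaml,
    write_spectra_csv,
)
from .merit import MeritReport, build_merit_report
from .pls import fit_pls, loo_curve, predict_pls, select_n_lv
from .preprocess import select_window
from .synthspec import (
    NoiseModel,
    WavelengthGrid,
    default_library,
    simulate_mixtures,
)

log = logging.getLogger("specal")


@dataclass
class RunConfig:
    """Configuration of a full synthetic calibration study."""

    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    window: tuple[float, float] = (250.0, 300.0)
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    library_seed: int = 0
    noise: NoiseModel = field(default_factory=NoiseModel)
    split_seed: int = 0
    n_validation: int = 10
    models: tuple[str, ...] = ("pls", "ann")
    max_lv: int = 10
    n_lv: int | None = None  # fixed LV count; None selects via LOO
    lv_threshold_ratio: float = 0.02
    ann_preset: str = "legacy"
    ann_seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        if not self.ranges:
            raise ValueError("config: ranges must not be empty")
        for name, (lo, hi) in self.ranges.items():
            if lo <= 0 or hi <= lo:
                raise ValueError(f"config: invalid range for {name}: ({lo}, {hi})")
        lo, hi = self.window
        if not (self.grid.start_nm <= lo <= hi <= self.grid.stop_nm):
            raise ValueError(f"config: window {self.window} outside grid")
        for m in self.models:
            if m not in ("pls", "ann"):
                raise ValueError(f"config: unknown model type {m!r}")
        if self.ann_preset not in ann_mod.PRESETS:
            raise ValueError(f"config: unknown ANN preset {self.ann_preset!r}")
        missing = [n for n in FACTOR_NAMES if n not in self.ranges]
        if missing:
            raise ValueError(f"config: ranges missing components {missing}")


@dataclass(frozen=True)
class PipelineResult:
    conc: np.ndarray
    spectra_window: np.ndarray
    calibration_indices: np.ndarray
    validation_indices: np.ndarray
    pls_n_lv: int | None
    reports: dict[str, MeritReport]
    predictions: dict[str, np.ndarray]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full workflow; writes artifacts if config.outdir is set."""
    config.validate()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    prov = {
        "library_seed": config.library_seed,
        "noise_seed": config.noise.seed,
        "split_seed": config.split_seed,
        "window": list(config.window),
        "version": __version__,
    }

    design = generate_design(len(FACTOR_NAMES))
    level_map = LevelMap(ranges=config.ranges)
    conc = realize_concentrations(design, level_map)
    log.info("design: %d runs x %d factors", *conc.shape)

    library = default_library(config.library_seed)
    spectra = simulate_mixtures(conc, library, config.grid, config.noise)
    log.info("simulated spectra: %d samples x %d points", *spectra.absorbance.shape)

    windowed = select_window(spectra, *config.window)
    log.info("window %s-%s nm: %d points", *config.window, windowed.grid.n_points)

    split = split_runs(design, n_validation=config.n_validation, seed=config.split_seed)
    cal, val = split.calibration_indices, split.validation_indices
    X = windowed.absorbance
    X_cal, Y_cal = X[cal], conc[cal]
    X_val, Y_val = X[val], conc[val]
    log.info("split: %d calibration / %d validation runs", len(cal), len(val))

    if outdir:
        write_design_csv(outdir, design, conc, split)
        write_spectra_csv(outdir / "spectra.csv", spectra)
        write_library_yaml(outdir / "library.yaml", library)

    reports: dict[str, MeritReport] = {}
    predictions: dict[str, np.ndarray] = {}
    pls_n_lv = None
    if "pls" in config.models:
        if config.n_lv is not None:
            pls_n_lv = config.n_lv
        else:
            a_max = min(config.max_lv, len(cal) - 2)
            # noiseless or low-rank spectra cannot support every candidate A;
            # back off until every LOO fold is feasible
            while True:
                try:
                    curve = loo_curve(X_cal, Y_cal, a_max)
                    break
                except ValueError:
                    if a_max <= 1:
                        raise
                    a_max -= 1
                    log.info("PLS: reducing candidate latent variables to %d", a_max)
            pls_n_lv = select_n_lv(curve, config.lv_threshold_ratio)
        model = fit_pls(X_cal, Y_cal, pls_n_lv)
        pred = predict_pls(model, X_val)
        reports["pls"] = build_merit_report(pred, Y_val, design.factor_names)
        predictions["pls"] = pred
        log.info("PLS: selected %d latent variables", pls_n_lv)
        if outdir:
            save_pls_model(outdir / "model_pls.json", model, prov)
    if "ann" in config.models:
        model, trace = ann_mod.train_preset(
            X_cal, Y_cal, preset=config.ann_preset, seed=config.ann_seed
        )
        pred = ann_mod.predict_ann(model, X_val)
        reports["ann"] = build_merit_report(pred, Y_val, design.factor_names)
        predictions["ann"] = pred
        log.info("ANN (%s): final loss %.3e after %d epochs",
                 config.ann_preset, trace[-1], len(trace))
        if outdir:
            save_ann_model(outdir / "model_ann.json", model, prov)

    if outdir:
        report_doc = {
            "schema_version": 1,
            "provenance": prov,
            "pls_n_lv": pls_n_lv,
            "reports": {k: r.to_dict() for k, r in reports.items()},
        }
        (outdir / "report.json").write_text(json.dumps(report_doc, indent=2))

    return PipelineResult(
        conc=conc,
        spectra_window=X,
        calibration_indices=cal,
        validation_indices=val,
        pls_n_lv=pls_n_lv,
        reports=reports,
        predictions=predictions,
    )
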