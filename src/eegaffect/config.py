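"""Structured run configuration and the end-to-end pipeline.

A :class:`RunConfig` validates every stage's parameters (unknown keys
are rejected by name) and its content hash is stamped into every output
file, so downstream stages can warn when they are fed artifacts from a
different configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import pandas as pd
import pydantic
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .datamodel import (
    read_feature_matrix,
    read_recording,
    write_feature_matrix,
    write_recording,
)
from .errors import ConfigurationError
from .features import BandDefinition, extract_feature_matrix
from .gom import GOMReport, ModelSpec, run_gom
from .preprocessing import FilterSpec, epoch_recording, preprocess_recording
from .synthetic import SyntheticConfig, simulate_dataset
from .tables import anova_f_scores, apply_cap_and_minmax, fit_normalization

logger = logging.getLogger(__name__)

_DEFAULT_BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta": (14.0, 30.0),
    "gamma": (30.0, 40.0),
}


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FilterConfig(_StrictModel):
    low_hz: float = 0.16
    high_hz: float = 43.0
    order: int = 4
    zero_phase: bool = True
    dc_method: str = "iir_highpass"

    def to_spec(self) -> FilterSpec:
        return FilterSpec(self.low_hz, self.high_hz, self.order, self.zero_phase)


class EpochConfig(_StrictModel):
    window_s: float = 1.0
    overlap: float = 0.0


class SelectionConfig(_StrictModel):
    mode: str = "strict"
    percentiles: list[int] = list(range(5, 101, 5))


class ModelsConfig(_StrictModel):
    roster: list[str] = [
        "svm_linear", "svm_poly", "svm_rbf", "svm_sigmoid",
        "decision_tree", "random_forest", "knn", "mlp",
    ]
    mlp_budget: int = 20
    mlp_max_iter: int = 200


class SimulateConfig(_StrictModel):
    enabled: bool = True
    n_subjects: int = 10
    records_per_subject: int = 2048
    asymmetry_effect: float = 2.0
    subject_sd: float = 0.2
    noise_exponent: float = 1.0
    snr: float = 1.0
    plant_beta_asymmetry: bool = False


class RunConfig(_StrictModel):
    """Top-level pipeline configuration; defaults reproduce the study
    settings (0.16–43 Hz band-pass, 5 bands, percentiles 5–100 step 5,
    8 models, 10 subjects x 2,048 records)."""

    seed: int = 0
    filter: FilterConfig = FilterConfig()
    epoch: EpochConfig = EpochConfig()
    bands: dict[str, tuple[float, float]] = dict(_DEFAULT_BAND_EDGES)
    selection: SelectionConfig = SelectionConfig()
    models: ModelsConfig = ModelsConfig()
    simulate: SimulateConfig = SimulateConfig()

    def band_definitions(self) -> tuple[BandDefinition, ...]:
        return tuple(BandDefinition(name, lo, hi) for name, (lo, hi) in self.bands.items())

    def synthetic_config(self) -> SyntheticConfig:
        s = self.simulate
        return SyntheticConfig(
            n_subjects=s.n_subjects,
            records_per_subject=s.records_per_subject,
            window_seconds=self.epoch.window_s,
            asymmetry_effect=s.asymmetry_effect,
            subject_sd=s.subject_sd,
            noise_exponent=s.noise_exponent,
            snr=s.snr,
            seed=self.seed,
            plant_beta_asymmetry=s.plant_beta_asymmetry,
        )

    def roster(self) -> list[ModelSpec]:
        out = []
        for fam in self.models.roster:
            if fam == "mlp":
                out.append(ModelSpec(
                    family="mlp", search="budgeted_random",
                    budget=self.models.mlp_budget,
                    fixed={"max_iter": self.models.mlp_max_iter},
                ))
            else:
                out.append(ModelSpec(family=fam))
        return out


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config file, applying flat overrides last."""
    data: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data = _deep_merge(data, overrides)
    try:
        return RunConfig(**data)
    except pydantic.ValidationError as exc:
        bad = "; ".join(
            ".".join(str(p) for p in err["loc"]) + f": {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigurationError(f"invalid configuration: {bad}") from exc


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def config_hash(cfg: RunConfig) -> str:
    """Stable 12-hex-digit digest of the configuration content."""
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def provenance_line(cfg: RunConfig) -> str:
    return f"config_hash={config_hash(cfg)} version={__version__} seed={cfg.seed}"


def read_provenance(path) -> str | None:
    """The config hash recorded in a pipeline output, if any."""
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("#") and "config_hash=" in first:
        return first.split("config_hash=")[1].split()[0]
    return None


def check_provenance(path, cfg: RunConfig) -> None:
    found = read_provenance(path)
    if found is not None and found != config_hash(cfg):
        warnings.warn(
            f"{path} was produced under config hash {found}, current is "
            f"{config_hash(cfg)}; stages may be inconsistent",
            stacklevel=2,
        )


def simulate_stage(cfg: RunConfig, out_dir) -> pd.DataFrame:
    """Generate recordings, write one CSV per subject x label + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in simulate_dataset(cfg.synthetic_config()):
        path = out_dir / f"{rec.subject_id}_label{rec.condition_label}.csv"
        write_recording(rec, path, header_comment=provenance_line(cfg))
        rows.append({"subject": rec.subject_id, "label": rec.condition_label,
                     "path": path.name})
    manifest = pd.DataFrame(rows)
    with open(out_dir / "manifest.csv", "w", encoding="utf-8") as fh:
        fh.write(f"# {provenance_line(cfg)}\n")
        manifest.to_csv(fh, index=False, lineterminator="\n")
    return manifest


def extract_stage(cfg: RunConfig, data_dir, out_path) -> pd.DataFrame:
    """Read recordings via the manifest, clean, epoch and extract features."""
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv", comment="#")
    spec = cfg.filter.to_spec()
    epochs = []
    for row in manifest.itertuples():
        rec = read_recording(
            data_dir / row.path, subject_id=str(row.subject),
            condition_label=int(row.label),
        )
        rec = preprocess_recording(rec, spec, dc_method=cfg.filter.dc_method)
        epochs.extend(epoch_recording(rec, cfg.epoch.window_s, cfg.epoch.overlap))
    frame = extract_feature_matrix(epochs, bands=cfg.band_definitions(), spec=spec)
    if out_path is not None:
        write_feature_matrix(frame, out_path, header_comment=provenance_line(cfg))
    return frame


def optimize_stage(cfg: RunConfig, features: pd.DataFrame) -> GOMReport:
    return run_gom(
        features,
        roster=cfg.roster(),
        percentiles=tuple(cfg.selection.percentiles),
        mode=cfg.selection.mode,
        seed=cfg.seed,
    )


def _write_csv(frame: pd.DataFrame, path, cfg: RunConfig) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {provenance_line(cfg)}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def run_pipeline(cfg: RunConfig, out_dir) -> GOMReport:
    """simulate? -> extract -> optimize, writing every artifact to disk.

    Outputs under ``out_dir``: per-recording CSVs + ``manifest.csv``
    (when simulation is enabled), ``features.csv``, ``report.csv``,
    ``cells.csv`` (every (model, percentile) evaluation),
    ``fscores.csv`` (per-feature ANOVA F on the full normalized matrix)
    and ``va_scatter.csv`` (the eight asymmetry metrics per record, for
    arousal-valence scatter plots). Each carries the config hash.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    if cfg.simulate.enabled:
        simulate_stage(cfg, out_dir / "recordings")
        logger.info("simulate stage: %.1f s (seed=%d)", time.perf_counter() - t0, cfg.seed)
    t1 = time.perf_counter()
    features = extract_stage(cfg, out_dir / "recordings", out_dir / "features.csv")
    logger.info("extract stage: %.1f s, %d records", time.perf_counter() - t1, len(features))

    t2 = time.perf_counter()
    report = optimize_stage(cfg, features)
    logger.info(
        "optimize stage: %.1f s, %d cv evaluations, %d fits",
        time.perf_counter() - t2, report.n_cv_evaluations, report.n_fits,
    )
    _write_csv(report.to_frame(), out_dir / "report.csv", cfg)
    _write_csv(report.cells_frame(), out_dir / "cells.csv", cfg)

    feat_cols = [c for c in features.columns if c not in ("label", "group")]
    norm = fit_normalization(features[feat_cols])
    scaled = apply_cap_and_minmax(features[feat_cols], norm)
    scores = anova_f_scores(scaled, features["label"])
    _write_csv(
        pd.DataFrame({"feature": feat_cols, "f_score": scores}),
        out_dir / "fscores.csv", cfg,
    )
    va_cols = ["v1", "v2", "v3", "v4", "a1", "a2", "a3", "a4"]
    _write_csv(
        features[va_cols + ["label"]], out_dir / "va_scatter.csv", cfg,
    )
    return report
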