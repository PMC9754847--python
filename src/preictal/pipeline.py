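"""Run-level orchestration: config records, stage runners, provenance.

Every stage writes its effective configuration (plus a hash and the seed)
next to its outputs so a run can be reproduced bit for bit from the
artifacts alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import KernelSpec, build_predictor_matrix, NetworkPredictorMatrix
from .epoching import EpochSet, extract_epochs, label_states, load_epoch_set, save_epoch_set, StateIntervals
from .io import CHANNEL_PRESETS, read_annotations, read_edf, select_channels
from .prediction import cross_validate, fit_ensemble, edge_importance

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "run_extract", "run_features", "run_predict"]


@dataclass
class RunConfig:
    """All pipeline parameters in one auditable record."""

    #: list of {"path": ..., "start_time_sec": ...} recording entries
    recordings: list = field(default_factory=list)
    annotations: str | None = None
    output_dir: str = "preictal_out"
    montage_preset: str | None = None        # "chbmit21" | "fhpku19" | None
    channels: list = field(default_factory=list)  # explicit list overrides preset
    montage: str = "referential"
    epoch_seconds: int = 60
    preictal_minutes: float = 30.0
    postictal_hours: float = 2.0
    kernel_rule: str = "power_third"
    kernel_bandwidth: float = 1.0
    lam: float = 0.1
    feature_mode: str = "network"
    center: bool = True
    B: int = 100
    k_folds: int = 5
    lambda_rule: str = "cv_once"
    seed: int = 0

    def kernel_spec(self) -> KernelSpec:
        return KernelSpec(bandwidth=self.kernel_bandwidth,
                          bandwidth_rule=self.kernel_rule)

    def channel_list(self) -> list | None:
        if self.channels:
            return list(self.channels)
        if self.montage_preset:
            return list(CHANNEL_PRESETS[self.montage_preset])
        return None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML/JSON config file; keyword overrides win over the file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _write_provenance(out_dir: Path, cfg: RunConfig, stage: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "stage": stage, "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(), "seed": cfg.seed,
        "package_version": __version__,
    }
    with open(out_dir / f"{stage}_config.json", "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)


def _clip_intervals(intervals: StateIntervals, lo: float, hi: float) -> StateIntervals:
    def clip(pairs):
        out = []
        for a, b in pairs:
            a2, b2 = max(a, lo), min(b, hi)
            if b2 > a2:
                out.append((a2, b2))
        return out

    return StateIntervals(
        preictal=clip(intervals.preictal),
        interictal=clip(intervals.interictal),
        excluded=[(max(a, lo), min(b, hi), r) for a, b, r in intervals.excluded
                  if min(b, hi) > max(a, lo)],
        truncated_preictal=clip(intervals.truncated_preictal),
    )


def run_extract(cfg: RunConfig, patient_id: str = "patient") -> Path:
    """EDF recordings + annotation CSV -> labeled epoch directory.

    State labeling runs once on the patient's continuous timeline spanning
    all configured recordings, then each file contributes the epochs whose
    windows it covers.
    """
    if not cfg.recordings:
        raise ValueError("config lists no recordings")
    if cfg.annotations is None:
        raise ValueError("config lists no annotation file")
    ann = read_annotations(cfg.annotations)
    recs = []
    for entry in cfg.recordings:
        rec = read_edf(entry["path"], start_time_sec=float(entry.get("start_time_sec", 0.0)),
                       montage=cfg.montage)
        spec = cfg.channel_list()
        if spec is not None:
            rec = select_channels(rec, spec)
        recs.append(rec)

    t0 = min(r.start_time_sec for r in recs)
    t1 = max(r.end_time_sec for r in recs)
    intervals = label_states(ann, t0, t1, preictal_minutes=cfg.preictal_minutes,
                             postictal_hours=cfg.postictal_hours)

    all_epochs = []
    for rec in recs:
        local = _clip_intervals(intervals, rec.start_time_sec, rec.end_time_sec)
        eset = extract_epochs(rec, local, epoch_seconds=cfg.epoch_seconds,
                              patient_id=patient_id)
        all_epochs.extend(eset.epochs)
    for i, e in enumerate(all_epochs):
        e.epoch_index = i
    out = Path(cfg.output_dir) / "epochs"
    save_epoch_set(EpochSet(epochs=all_epochs), out)
    _write_provenance(Path(cfg.output_dir), cfg, "extract")
    logger.info("wrote %d epochs to %s", len(all_epochs), out)
    return out / "manifest.csv"


def run_features(cfg: RunConfig, epochs: EpochSet | None = None) -> Path:
    """Epoch directory -> predictor matrix CSV + JSON sidecar."""
    out_dir = Path(cfg.output_dir)
    if epochs is None:
        epochs = load_epoch_set(out_dir / "epochs")
    pm = build_predictor_matrix(
        epochs, mode=cfg.feature_mode, lam=cfg.lam, spec=cfg.kernel_spec(),
        center=cfg.center, channel_labels=cfg.channel_list(),
    )
    df = pd.DataFrame(pm.V)
    df.insert(0, "Z", pm.Z)
    path = out_dir / "features.csv"
    out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    sidecar = {
        "edge_names": pm.edge_names, "feature_mode": pm.feature_mode,
        "lam": cfg.lam, "kernel": {"rule": cfg.kernel_rule,
                                   "bandwidth": cfg.kernel_bandwidth},
        "center": cfg.center, "config_hash": cfg.config_hash(),
    }
    with open(out_dir / "features.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    _write_provenance(out_dir, cfg, "features")
    return path


def load_features(out_dir: str | Path) -> NetworkPredictorMatrix:
    out_dir = Path(out_dir)
    df = pd.read_csv(out_dir / "features.csv")
    with open(out_dir / "features.json") as fh:
        sidecar = json.load(fh)
    return NetworkPredictorMatrix(
        V=df.drop(columns="Z").to_numpy(float), Z=df["Z"].to_numpy(int),
        edge_names=sidecar["edge_names"], feature_mode=sidecar["feature_mode"],
    )


def run_predict(cfg: RunConfig, epochs: EpochSet | None = None) -> dict:
    """Cross-validated metrics JSON + ranked-edge CSV from epochs on disk."""
    out_dir = Path(cfg.output_dir)
    if epochs is None:
        epochs = load_epoch_set(out_dir / "epochs")
    counts = (epochs.n1, epochs.n2)
    if min(counts) < cfg.k_folds:
        raise ValueError(
            f"need >= k={cfg.k_folds} epochs per class, have n1={counts[0]}, n2={counts[1]}"
        )
    metrics, psi = cross_validate(
        epochs, mode=cfg.feature_mode, k=cfg.k_folds, B=cfg.B, lam=cfg.lam,
        spec=cfg.kernel_spec(), seed=cfg.seed, center=cfg.center,
        lambda_rule=cfg.lambda_rule, channel_labels=cfg.channel_list(),
    )
    payload = metrics.to_dict()
    payload["provenance"] = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                             "package_version": __version__}
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    psi.to_frame().to_csv(out_dir / "edges.csv", index=False)
    _write_provenance(out_dir, cfg, "predict")
    return payload
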