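"""End-to-end orchestration: simulate -> segment -> features -> decode /
entropy / cluster -> report.

Everything is driven by one YAML-serializable config dict; the config (and
every stage seed derived from the master seed) is echoed verbatim into the
report so identical configs give byte-identical reports.
"""

from __future__ import annotations

import json
from copy import deepcopy
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import features as feat
from .cluster import cluster_trials, correlation_matrix
from .decode import shuffle_null, train_decoder_array
from .entropy import entropy_series, equalized_entropy_comparison
from .errors import ConfigError, DataError
from .segmentation import SegmentationParams, annotate_session
from .session import (
    Session,
    SNBClass,
    read_annotations,
    read_session,
    write_annotations,
    write_session,
)
from .synth import SynthConfig, generate_session

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synth": {},          # SynthConfig field overrides
    "segmentation": {},   # SegmentationParams field overrides
    "features": {"count_bin_ms": 100.0},
    "decode": {
        "n_repeats": 50,
        "n_shuffles": 200,
        "train_frac": 0.7,
        "C": 1.0,
        "percentiles": [5.0, 95.0],
    },
    "entropy": {"n_resamples": 300, "band_percentiles": [0.5, 99.5]},
    "cluster": {"threshold": 0.5, "bins": [0, 1]},
}


def load_config(path) -> dict:
    cfg = deepcopy(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must hold a mapping")
        for key, value in user.items():
            if key not in cfg:
                raise ConfigError(f"unknown config section {key!r}")
            if isinstance(cfg[key], dict):
                cfg[key].update(value or {})
            else:
                cfg[key] = value
    return cfg


def _stage_seed(master: int, offset: int) -> int:
    return int((int(master) + offset) % (2**31))


def simulate_stage(config: dict, outdir: Path) -> tuple[Session, list]:
    synth_kwargs = dict(config.get("synth", {}))
    synth_kwargs.setdefault("seed", _stage_seed(config["seed"], 0))
    cfg = SynthConfig(**synth_kwargs)
    session, truth = generate_session(cfg)
    outdir.mkdir(parents=True, exist_ok=True)
    write_session(session, outdir / "spikes.csv", outdir / "session.json")
    write_annotations(truth, outdir / "ground_truth.csv")
    return session, truth


def _session_paths(session_dir: Path) -> tuple[Path, Path]:
    return session_dir / "spikes.csv", session_dir / "session.json"


def segment_stage(session: Session, config: dict) -> list:
    params = SegmentationParams(**config.get("segmentation", {}))
    return annotate_session(session, params)


def features_stage(session: Session, config: dict):
    """Count tensor (100 ms bins) and binary tensor (250 ms, 550 ms first
    bin) for all trials, plus baseline statistics."""
    bin_ms = config.get("features", {}).get("count_bin_ms", 100.0)
    X, count_edges = feat.count_tensor(session.trials, bin_ms=bin_ms)
    baseline = feat.intertrial_baseline(session)
    B, binary_edges = feat.binary_tensor(session.trials, baseline)
    return X, count_edges, B, binary_edges, baseline


def write_features_h5(path, X, count_edges, B, binary_edges, labels, trial_ids) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=X)
        f.create_dataset("count_bin_edges_ms", data=count_edges)
        f.create_dataset("binary", data=B)
        f.create_dataset("binary_bin_edges_ms", data=binary_edges)
        f.create_dataset("cue_labels", data=np.asarray(labels))
        f.create_dataset("trial_ids", data=np.asarray(trial_ids))


def read_features_h5(path):
    import h5py

    with h5py.File(path, "r") as f:
        return (
            f["counts"][()],
            f["count_bin_edges_ms"][()],
            f["binary"][()],
            f["binary_bin_edges_ms"][()],
            f["cue_labels"][()],
            f["trial_ids"][()],
        )


def _group_indices(annotations) -> dict[str, np.ndarray]:
    groups: dict[str, list[int]] = {}
    for pos, ann in enumerate(annotations):
        groups.setdefault(ann.snb_class.value, []).append(pos)
    return {k: np.asarray(v) for k, v in groups.items()}


def decode_stage(X, count_edges, labels, annotations, config: dict) -> dict:
    dc = config["decode"]
    seed = _stage_seed(config["seed"], 1)
    groups = _group_indices(annotations)
    control = groups.get(SNBClass.CONTROL.value, np.empty(0, int))
    if control.size < 4:
        raise DataError("too few control trials to train the decoder")
    Xc, yc = X[control], labels[control]
    array = train_decoder_array(
        Xc, yc, split=dc["train_frac"], repeats=dc["n_repeats"], C=dc["C"],
        seed=seed, bin_edges=count_edges,
    )
    null = shuffle_null(
        Xc, yc, n_shuffles=dc["n_shuffles"], percentiles=tuple(dc["percentiles"]),
        train_frac=dc["train_frac"], C=dc["C"], seed=_stage_seed(config["seed"], 2),
    )
    report = {"within": array.series.to_dict(), "null": null.to_dict(), "cross": {}}
    for name in ("snb_single", "snb_cue", "snb_delay", "snb_probe"):
        idx = groups.get(name, np.empty(0, int))
        if idx.size:
            mean, sem = array.score_trials(X[idx], labels[idx])
            report["cross"][name] = {
                "mean": mean.tolist(), "sem": sem.tolist(), "n_trials": int(idx.size)
            }
    return report


def entropy_stage(B, binary_edges, annotations, config: dict) -> dict:
    ec = config["entropy"]
    groups = _group_indices(annotations)
    control = groups.get(SNBClass.CONTROL.value, np.empty(0, int))
    snb = np.sort(
        np.concatenate(
            [groups.get(k, np.empty(0, int))
             for k in ("snb_single", "snb_cue", "snb_delay", "snb_probe")]
        )
    ).astype(int)
    report: dict = {}
    if control.size:
        report["control"] = entropy_series(B[control], bin_edges=binary_edges).to_dict()
    if snb.size:
        report["snb"] = entropy_series(B[snb], bin_edges=binary_edges).to_dict()
    if control.size and snb.size:
        cmp = equalized_entropy_comparison(
            B[control], B[snb], n_resamples=ec["n_resamples"],
            seed=_stage_seed(config["seed"], 3),
            band_percentiles=tuple(ec["band_percentiles"]), bin_edges=binary_edges,
        )
        report["equalized"] = cmp.to_dict()
    return report


def cluster_stage(B, labels, config: dict) -> dict:
    cc = config["cluster"]
    report = {}
    for b in cc["bins"]:
        if not 0 <= b < B.shape[1]:
            raise ConfigError(f"cluster bin {b} outside the binary grid")
        R, _ = correlation_matrix(B[:, b, :])
        rep = cluster_trials(R, threshold=cc["threshold"], stimulus_labels=labels)
        report[str(b)] = rep.to_dict()
    return report


def run_pipeline(config: dict, outdir) -> dict:
    """Run every stage, writing all artifacts plus ``report.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    session, truth = simulate_stage(config, outdir)
    annotations = segment_stage(session, config)
    write_annotations(annotations, outdir / "annotations.csv")
    X, count_edges, B, binary_edges, baseline = features_stage(session, config)
    labels = session.cue_labels()
    trial_ids = np.array([t.trial_id for t in session.trials])
    write_features_h5(outdir / "features.h5", X, count_edges, B, binary_edges,
                      labels, trial_ids)
    report = {
        "config": config,
        "n_trials": len(session),
        "segmentation": {
            "classes": {
                ann.trial_id: ann.snb_class.value for ann in annotations
            },
            "ground_truth_agreement": None,
        },
        "decode": decode_stage(X, count_edges, labels, annotations, config),
        "entropy": entropy_stage(B, binary_edges, annotations, config),
        "cluster": cluster_stage(B, labels, config),
        "baseline": {
            "mean_hz": baseline.mean_hz.tolist(),
            "sd_hz": baseline.sd_hz.tolist(),
            "n_windows": baseline.n_windows,
        },
    }
    from .segmentation import agreement

    report["segmentation"]["ground_truth_agreement"] = agreement(annotations, truth)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
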