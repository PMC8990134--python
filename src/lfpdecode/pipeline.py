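"""Run configuration, feature/result persistence and the full pipeline."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .cnn import CNNConfig
from .decode import CHANNEL_SUBSETS, crossvalidate
from .preprocess import FeatureTensorSeries, preprocess_session
from .session import Session, read_session, write_session
from .synth import CouplingSpec, GaitModel, NoiseSpec, SynthConfig, generate_session

__all__ = [
    "RunConfig",
    "load_config",
    "write_features",
    "read_features",
    "run_pipeline",
]

log = logging.getLogger("lfpdecode")


@dataclass
class RunConfig:
    """Validated top-level configuration of a pipeline run."""

    out_dir: str = "lfpdecode_run"
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # SynthConfig overrides
    decoders: list[str] = field(default_factory=lambda: ["cnn", "pls", "lasso"])
    subsets: list[str] = field(default_factory=lambda: ["all"])
    cnn: dict = field(default_factory=dict)  # CNNConfig overrides
    analyses: list[str] = field(default_factory=lambda: ["tfmap", "mi"])
    session_paths: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for d in self.decoders:
            if d not in ("cnn", "pls", "lasso"):
                raise ValueError(f"unknown decoder '{d}'")
        for s in self.subsets:
            if s not in CHANNEL_SUBSETS:
                raise ValueError(f"unknown channel subset '{s}'")
        for a in self.analyses:
            if a not in ("tfmap", "mi", "cadence"):
                raise ValueError(f"unknown analysis '{a}'")
        CNNConfig(**self.cnn)  # validate overrides eagerly


def load_config(path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig(**raw)


def build_synth_config(overrides: dict, seed: int) -> SynthConfig:
    ov = dict(overrides)
    gait = GaitModel(**ov.pop("gait", {}))
    coupling = CouplingSpec(**ov.pop("coupling", {}))
    noise = NoiseSpec(**ov.pop("noise", {}))
    ov.setdefault("seed", seed)
    return SynthConfig(gait=gait, coupling=coupling, noise=noise, **ov)


def write_features(features: FeatureTensorSeries, targets: np.ndarray, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features/tensors", data=features.tensors)
        f.create_dataset("features/times", data=features.times)
        f.create_dataset("targets", data=targets)
        f.attrs["feature_names"] = json.dumps(list(features.feature_names))


def read_features(path) -> tuple[FeatureTensorSeries, np.ndarray]:
    with h5py.File(path, "r") as f:
        feats = FeatureTensorSeries(
            tensors=f["features/tensors"][()],
            times=f["features/times"][()],
            feature_names=tuple(json.loads(f.attrs["feature_names"])),
        )
        targets = f["targets"][()]
    return feats, targets


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # label the failing stage
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            log.info("stage %s: done in %.1f s", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """simulate (optional) -> preprocess -> decode -> analyze.

    Writes all tables under ``config.out_dir`` and returns the run manifest
    (also written as ``manifest.json``), listing every output file with a
    checksum alongside seeds and the configuration hash.
    """
    from . import __version__
    from .analysis import cadence_analysis, cycle_average, mi_analysis, segment_gait_cycles, session_envelopes

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    @_stage("simulate")
    def do_simulate() -> list[Session]:
        sessions = []
        if config.session_paths:
            for p in config.session_paths:
                sessions.append(read_session(p))
        else:
            cfg = build_synth_config(config.simulate, config.seed)
            session = generate_session(cfg)
            path = out_dir / "session.h5"
            write_session(session, path)
            outputs.append(path)
            sessions.append(session)
        return sessions

    @_stage("preprocess")
    def do_preprocess(sessions):
        prepped = []
        for i, s in enumerate(sessions):
            features, targets = preprocess_session(s)
            path = out_dir / f"features_{i}.h5"
            write_features(features, targets, path)
            outputs.append(path)
            prepped.append((features, targets))
        return prepped

    @_stage("decode")
    def do_decode(prepped):
        import pandas as pd

        frames = []
        for i, (features, targets) in enumerate(prepped):
            for decoder in config.decoders:
                for subset in config.subsets:
                    res = crossvalidate(
                        features,
                        targets,
                        decoder=decoder,
                        seed=config.seed,
                        cnn_config=CNNConfig(**config.cnn),
                        subset=subset,
                    )
                    df = res.to_frame()
                    df.insert(0, "session", i)
                    frames.append(df)
        table = pd.concat(frames, ignore_index=True)
        path = out_dir / "decode_results.csv"
        table.to_csv(path, index=False)
        outputs.append(path)
        return table

    @_stage("analyze")
    def do_analyze(sessions):
        import pandas as pd

        summary = {}
        if "tfmap" in config.analyses:
            s = sessions[0]
            envs, _, _ = session_envelopes(s)
            cycles = segment_gait_cycles(session=s)
            tf = cycle_average(envs, cycles)
            rows = []
            for c in range(tf.percent_change.shape[0]):
                for b, name in enumerate(tf.band_names):
                    for k in range(tf.n_bins):
                        rows.append(
                            {
                                "channel": c + 1,
                                "band": name,
                                "bin": k,
                                "percent_change": tf.percent_change[c, b, k],
                            }
                        )
            path = out_dir / "tfmap.csv"
            pd.DataFrame(rows).to_csv(path, index=False)
            outputs.append(path)
            summary["tfmap"] = {"bins": tf.n_bins}
        if "mi" in config.analyses:
            _, avg = mi_analysis(sessions)
            rows = []
            for c in range(avg.values.shape[0]):
                for fi, fname in enumerate(avg.feature_names):
                    for j, jname in enumerate(avg.joint_names):
                        rows.append(
                            {
                                "channel": c + 1,
                                "feature": fname,
                                "joint": jname,
                                "mi_bits": avg.values[c, fi, j],
                            }
                        )
            path = out_dir / "mi.csv"
            pd.DataFrame(rows).to_csv(path, index=False)
            outputs.append(path)
            summary["mi"] = {
                "band_average": dict(
                    zip(avg.feature_names, avg.band_average().round(4).tolist())
                )
            }
        if "cadence" in config.analyses:
            cmp_ = cadence_analysis(sessions)
            path = out_dir / "cadence.csv"
            cmp_.table.to_csv(path, index=False)
            outputs.append(path)
            summary["cadence"] = {"significant_bands": cmp_.significant_bands}
        return summary

    sessions = do_simulate()
    prepped = do_preprocess(sessions)
    do_decode(prepped)
    summary = do_analyze(sessions)

    cfg_json = json.dumps(asdict(config), sort_keys=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "analysis_summary": summary,
        "outputs": {
            str(p.relative_to(out_dir)): _sha256(p) for p in outputs
        },
    }
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest
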