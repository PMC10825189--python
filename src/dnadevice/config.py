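"""Run configuration: one flat, sectioned key=value file driving the pipeline.

Defaults equal the study conditions wherever a printed value exists: 4 s
same-channel frame period, 5-frame minimum track length, 7 px
co-localization radius, d = 3 px photometry aperture with 2-sigma clipping,
Mahalanobis threshold 3, P0 = 70 nM, K_D = 100 nM, t_fold = 86 s,
v = 10 nt/s, bleaching time 90 s.
"""

from __future__ import annotations

import configparser
import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imgpipe import PipelineParams
from .simkit import SimConfig

__all__ = ["RunConfig", "load_config", "save_provenance"]


@dataclass
class RunConfig:
    """Top-level pipeline configuration."""

    stages: tuple[str, ...] = ("simulate", "acf")
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"
    n_traces: int = 50
    mode: str = "random"  # initiation statistics for simulated traces
    max_lag: float = 600.0  # s, ACF delay window upper edge
    pulse_threshold: float = 3.0
    sim: SimConfig = field(default_factory=lambda: SimConfig(
        gene_extension_length=1980.0, initiation_rate=0.01))
    pipeline: PipelineParams = field(default_factory=PipelineParams)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


_SECTIONS = {"run", "simulate", "pipeline"}


def load_config(path: str | Path) -> RunConfig:
    """Read a sectioned key=value file ([run], [simulate], [pipeline])."""
    parser = configparser.ConfigParser()
    read = parser.read(str(path))
    if not read:
        raise IOError(f"cannot read config file {path}")
    unknown = set(parser.sections()) - _SECTIONS
    if unknown:
        raise ValueError(f"unknown config sections {sorted(unknown)}")
    cfg = RunConfig()
    if parser.has_section("run"):
        r = parser["run"]
        cfg = cfg.replace(
            stages=tuple(s.strip() for s in r.get("stages", "simulate,acf").split(",")),
            seed=r.getint("seed", cfg.seed),
            out_dir=r.get("out_dir", cfg.out_dir),
            log_level=r.get("log_level", cfg.log_level),
            n_traces=r.getint("n_traces", cfg.n_traces),
            mode=r.get("mode", cfg.mode),
            max_lag=r.getfloat("max_lag", cfg.max_lag),
            pulse_threshold=r.getfloat("pulse_threshold", cfg.pulse_threshold),
        )
    if parser.has_section("simulate"):
        fields = {f.name: f for f in dataclasses.fields(SimConfig)}
        kwargs = {}
        for key, raw in parser["simulate"].items():
            if key not in fields:
                raise ValueError(f"unknown [simulate] key {key!r}")
            kwargs[key] = int(raw) if key == "seed" else float(raw)
        if "gene_extension_length" not in kwargs:
            kwargs["gene_extension_length"] = cfg.sim.gene_extension_length
        if "initiation_rate" not in kwargs:
            kwargs["initiation_rate"] = cfg.sim.initiation_rate
        cfg = cfg.replace(sim=SimConfig(**kwargs))
    if parser.has_section("pipeline"):
        fields = {f.name: f for f in dataclasses.fields(PipelineParams)}
        kwargs = {}
        for key, raw in parser["pipeline"].items():
            if key not in fields:
                raise ValueError(f"unknown [pipeline] key {key!r}")
            if key == "bead_seeds":
                kwargs[key] = np.array(json.loads(raw), dtype=float)
            elif key in ("box_radius", "patch_half", "memory", "min_frames",
                         "min_cluster_size"):
                kwargs[key] = int(raw)
            else:
                kwargs[key] = float(raw)
        cfg = cfg.replace(pipeline=PipelineParams(**kwargs))
    return cfg


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def save_provenance(config: RunConfig, out_dir: str | Path) -> Path:
    """Echo the full configuration, versions, and seed next to the outputs."""
    import numpy
    import pandas
    import scipy

    payload = {
        "config": _jsonable(config),
        "seed": config.seed,
        "python": sys.version.split()[0],
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
    }
    path = Path(out_dir) / "provenance.json"
    path.write_text(json.dumps(payload, indent=2))
    return path
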