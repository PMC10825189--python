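"""Top-level pipeline driver: simulation -> images -> traces -> reports."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import fluct, imgpipe, io, pulses, simkit
from .config import RunConfig, save_provenance

__all__ = ["run_pipeline"]

log = logging.getLogger("dnadevice")

_KNOWN_STAGES = ("simulate", "movie", "process", "acf", "pulses")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in order; deterministic under the seed.

    Stages
    ------
    simulate : ensemble of intensity traces -> traces.csv
    movie    : synthetic two-channel movie -> movie_ch0.tif / movie_ch1.tif
               (+ ground truth)
    process  : image chain on the movie -> tracks.csv, drift.csv,
               measured_traces.csv
    acf      : ensemble ACF + mono-exponential fit -> acf.csv, acf_fit.csv
    pulses   : (D, F_max) features, classification against the simulated
               ensemble itself as reference -> features.csv

    Later stages consume the artifacts of earlier ones and raise a
    ``RuntimeError`` naming any missing dependency.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(config.stages)
    for s in stages:
        if s not in _KNOWN_STAGES and s != "all":
            raise ValueError(f"unknown stage {s!r}")
    if "all" in stages:
        stages = _KNOWN_STAGES

    artifacts: dict = {}
    sim = config.sim.replace(seed=int(config.seed))

    if "simulate" in stages:
        traces = simkit.simulate_ensemble(sim, config.n_traces, mode=config.mode)
        traces = [simkit.IntensityTrace(tr.t, tr.intensity, f"sim_{i:04d}")
                  for i, tr in enumerate(traces)]
        io.write_traces(out / "traces.csv", traces)
        artifacts["traces"] = traces
        log.info("simulate: %d traces of %d frames", len(traces), len(traces[0]))

    if "movie" in stages:
        rng = np.random.default_rng(config.seed)
        trace, _ = simkit.simulate_trace(sim.replace(noise_sigma=0.0), mode=config.mode)
        n_frames = min(len(trace), 60)
        spec = simkit.MovieSpec(
            n_frames=n_frames,
            expression_positions=np.array([[24.0, 40.0]]),
            expression_traces=[simkit.IntensityTrace(
                trace.t[:n_frames], 80.0 * trace.intensity[:n_frames], "planted")],
            dna_positions=np.array([[24.0, 40.0]]),
            bead_positions=np.array([[12.0, 12.0], [50.0, 20.0], [40.0, 52.0]]),
            noise_sigma=2.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        stacks, truth = simkit.render_movie(spec)
        io.write_movie(out / "movie_ch0.tif", stacks[0])
        io.write_movie(out / "movie_ch1.tif", stacks[1])
        truth.to_csv(out / "movie_truth.csv", index=False)
        artifacts["movie"] = stacks
        artifacts["movie_spec"] = spec
        log.info("movie: rendered %d frames per channel", n_frames)

    if "process" in stages:
        if "movie" not in artifacts:
            raise RuntimeError("process stage requires the movie stage artifact 'movie'")
        params = config.pipeline
        if params.bead_seeds is None:
            params.bead_seeds = artifacts["movie_spec"].bead_positions
        result = imgpipe.process_movie(artifacts["movie"][0], artifacts["movie"][1], params)
        result["table"].to_csv(out / "tracks.csv", index=False)
        pd.DataFrame(result["drift"], columns=["d_row_px", "d_col_px"]).to_csv(
            out / "drift.csv", index_label="frame")
        measured = [tr for tr in result["traces"] if tr is not None]
        io.write_traces(out / "measured_traces.csv", measured)
        artifacts["processed"] = result
        log.info("process: %d expression tracks retained (%d co-localized)",
                 len(result["tracks"]),
                 sum(t.colocalized_with_dna for t in result["tracks"]))

    if "acf" in stages:
        traces = artifacts.get("traces")
        if traces is None:
            raise RuntimeError("acf stage requires the simulate stage artifact 'traces'")
        res = fluct.FluctuationModel(traces, max_lag=config.max_lag).fit()
        res.to_frame().to_csv(out / "acf.csv", index=False)
        pd.DataFrame([{"g0_inverse": res.g0_inverse, "tau_c_s": res.tau_c,
                       "n_spots": res.n_spots}]).to_csv(out / "acf_fit.csv", index=False)
        artifacts["acf"] = res
        log.info("acf: G(0)^-1=%.3g tau_C=%.3g s", res.g0_inverse, res.tau_c)

    if "pulses" in stages:
        traces = artifacts.get("traces")
        if traces is None:
            raise RuntimeError("pulses stage requires the simulate stage artifact 'traces'")
        clf = pulses.PulseClassifier(traces, threshold=config.pulse_threshold).fit()
        feats = clf.classify(traces)
        clf.to_frame(feats).to_csv(out / "features.csv", index=False)
        artifacts["pulses"] = feats
        log.info("pulses: %d/%d traces classified as pulses",
                 int(sum(f.is_pulse for f in feats)), len(feats))

    save_provenance(config, out)
    return artifacts
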