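"""End-to-end pipeline orchestration with manifests and structured logging.

``run_behavior_pipeline`` composes saccade detection and state
classification (events.csv, labels.csv, occupancy.csv, raster.png);
``run_neural_pipeline`` composes neural post-processing, encoding, ramp
classification, enrichment and relative-time decoding.  Every run writes a
manifest with the configuration hash, package version and stage counts, so
reported Ns are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

import sleepscope
from sleepscope import presets, synthio
from sleepscope.saccades import detect_and_score, events_to_dataframe
from sleepscope import states as st
from sleepscope import neuro_prep as nprep
from sleepscope import encoding as enc
from sleepscope import dynamics as dyn
from sleepscope import io as sio

log = logging.getLogger("sleepscope")


@dataclasses.dataclass
class RunConfig:
    out_dir: str
    behavior_csv: str | None = None      # None -> synthesize a demo
    neural_h5: str | None = None
    labels_csv: str | None = None
    variant: str = "multi"
    fs_hz: float = 50.0
    gmm_json: str | None = None          # frozen reference fit, optional
    seed: int = 0
    demo_duration_s: float = 7200.0

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_manifest(cfg: RunConfig, counts: dict, name: str) -> None:
    manifest = {
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.hash(),
        "version": sleepscope.__version__,
        "counts": counts,
    }
    Path(cfg.out_dir, f"{name}_manifest.json").write_text(
        json.dumps(manifest, indent=2)
    )


def _demo_behavior(cfg: RunConfig):
    targets = {
        "day": {"QEM1": 0.4, "QEM2": 0.05},
        "night": {"QNEM": 0.35, "QEM2": 0.12, "QEM3": 0.08},
    }
    sched = synthio.make_schedule(
        cfg.demo_duration_s, {"on_h": 9.0, "off_h": 23.0}, targets,
        seed=cfg.seed,
    )
    return synthio.synth_behavior(sched, fs_hz=cfg.fs_hz, seed=cfg.seed)


def run_behavior_pipeline(cfg: RunConfig) -> dict:
    """Saccades -> sleep periods -> bins -> GMM labels -> occupancy."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.behavior_csv is not None:
        if not Path(cfg.behavior_csv).exists():
            raise FileNotFoundError(f"missing input: {cfg.behavior_csv}")
        trace, speed, _ = sio.read_behavior_csv(cfg.behavior_csv)
    else:
        synth = _demo_behavior(cfg)
        sio.write_behavior_csv(out / "behavior.csv", synth)
        trace, speed = synth.trace, synth.speed
    events, _ = detect_and_score(trace, variant=cfg.variant)
    log.info("saccades: %d accepted events", len(events))
    periods = st.detect_sleep(speed)
    log.info("sleep: %d periods", len(periods))
    bins, feats = [], []
    for p in periods:
        for b in st.bin_period(p):
            bins.append(b)
            feats.append(st.featurize(b, events))
    if cfg.gmm_json:
        gmm = sio.read_gmm_json(cfg.gmm_json)
    else:
        gmm = st.fit_substate_gmm(feats, seed=cfg.seed, select_k=False)
        sio.write_gmm_json(out / "gmm.json", gmm)
    duration = trace.n / trace.fs_hz
    series = st.classify(bins, feats, gmm, duration)
    occupancy = st.compute_occupancy(series)
    events_to_dataframe(events).to_csv(out / "events.csv", index=False)
    series.to_dataframe().to_csv(out / "labels.csv", index=False)
    occupancy.to_csv(out / "occupancy.csv", index=False)
    _raster_figure(series, out / "raster.png")
    counts = {
        "events": len(events), "sleep_periods": len(periods),
        "bins": len(bins),
        "labeled_bins": sum(1 for b in series.bins if b.label != "Wake"),
    }
    _write_manifest(cfg, counts, "behavior")
    return {"series": series, "events": events, "occupancy": occupancy,
            "gmm": gmm, "counts": counts}


def _raster_figure(series: st.StateLabelSeries, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"Wake": "#dddddd", "QEM1": "#e76fa0", "QEM2": "#57a15a",
              "QEM3": "#808000", "QNEM": "#3b5ba5", "Unlabeled": "#ffffff"}
    fig, ax = plt.subplots(figsize=(10, 1.6))
    for b in series.bins:
        ax.axvspan(b.start_s / 3600, b.end_s / 3600,
                   color=colors.get(b.label, "k"), lw=0)
    ax.set_xlabel("time (h)")
    ax.set_yticks([])
    ax.set_xlim(0, series.total_s / 3600)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_neural_pipeline(cfg: RunConfig) -> dict:
    """Post-process -> encode -> ramps -> enrichment -> decode."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.neural_h5 is None or cfg.labels_csv is None:
        raise FileNotFoundError("neural pipeline needs neural_h5 and labels_csv")
    mat = sio.read_neural_h5(cfg.neural_h5)
    ldf = pd.read_csv(cfg.labels_csv)
    series = st.StateLabelSeries(
        [st.LabeledBin(r.start_s, r.end_s, r.label) for r in ldf.itertuples()]
    )
    if abs(series.total_s - mat.n_time / mat.fs_hz) > 120:
        raise ValueError(
            "label/neural time bases differ by more than 2 min; "
            "resample the labels to the neural clock"
        )
    mat = nprep.merge_duplicates(mat)
    mat = nprep.coverage_filter(mat)
    mat = nprep.debleach(mat)
    log.info("neurons surviving filters: %d", mat.n_neurons)
    F = nprep.interpolate_missing(mat)
    counts = {"neurons": mat.n_neurons}
    results: dict = {"matrix": mat}
    qem1 = [p for p in series.periods_of("QEM1") if p[1] - p[0] >= 180.0]
    if len(qem1) >= 2:
        ramp_rows = []
        for i in range(mat.n_neurons):
            rf = enc.fit_ramps(F[i], qem1, mat.fs_hz)
            ramp_rows.append({
                "neuron": i, "model": rf.model, "b": rf.b, "r2": rf.r2,
                "delta_r2": rf.delta_r2,
            })
        ramps = pd.DataFrame(ramp_rows)
        ramps.to_csv(out / "ramps.csv", index=False)
        results["ramps"] = ramps
        counts["ramp_fits"] = len(ramps)
        dec = dyn.decode_relative_time(F, series, "QEM1", mat.fs_hz,
                                       seed=cfg.seed)
        pd.DataFrame({"median_weight": dec.median_weights}).to_csv(
            out / "decoder_weights.csv", index=False
        )
        results["decoder"] = dec
        counts["decoder_r2"] = round(dec.r2, 4)
    if len(set(mat.regions)) > 1:
        positive = np.zeros(mat.n_neurons, dtype=bool)
        if "ramps" in results:
            positive = (results["ramps"].model == "decay").values
        enr = enc.enrichment(positive, mat.regions, seed=cfg.seed)
        enc.enrichment_to_dataframe(enr).to_csv(out / "enrichment.csv",
                                                index=False)
        results["enrichment"] = enr
    else:
        log.warning("region labels absent; enrichment skipped")
    _write_manifest(cfg, counts, "neural")
    results["counts"] = counts
    return results
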