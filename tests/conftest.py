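"""Shared fixtures: small synthetic recordings generated at test time."""

import numpy as np
import pytest

from sleepscope import synthio
from sleepscope.states import LabeledBin, StateLabelSeries


@pytest.fixture(scope="session")
def qem1_run():
    """20 min of QEM-1 behavior at 25 Hz with the standard preset."""
    sched = synthio.StateSchedule(
        segments=[(0.0, 1200.0, "QEM1")], lights={"constant": 0}
    )
    return synthio.synth_behavior(sched, fs_hz=25.0, noise_sd_rad=0.01, seed=11)


@pytest.fixture(scope="session")
def qem2_run():
    """40 min of QEM-2 behavior at 25 Hz."""
    sched = synthio.StateSchedule(
        segments=[(0.0, 2400.0, "QEM2")], lights={"constant": 0}
    )
    return synthio.synth_behavior(sched, fs_hz=25.0, noise_sd_rad=0.01, seed=12)


@pytest.fixture(scope="session")
def wake_qem1_series():
    """Alternating wake/QEM-1 label series (6 periods each, 300 s)."""
    segs = []
    t = 0.0
    for _ in range(6):
        segs.append((t, t + 300.0, "Wake"))
        t += 300.0
        segs.append((t, t + 300.0, "QEM1"))
        t += 300.0
    return StateLabelSeries([LabeledBin(a, b, s) for a, b, s in segs])


@pytest.fixture(scope="session")
def neural_run(wake_qem1_series):
    """Mixed neural population locked to the wake/QEM-1 schedule."""
    segs = [(b.start_s, b.end_s, b.label) for b in wake_qem1_series.bins]
    sched = synthio.StateSchedule(segments=segs, lights={"constant": 0})
    spec = synthio.SyntheticNeuralSpec(
        n_suppressed=20, n_ramp_down=25, n_ramp_up=25, n_event_cells=5,
        n_noise=30, noise_sd=0.03, missing_fraction=0.1, seed=5,
    )
    mat, log = synthio.synth_neural(spec, sched)
    return mat, log, sched


def behavior_events(synth, variant="multi"):
    """Run the full detection chain on a synthesized recording."""
    from sleepscope.saccades import detect_and_score

    dur = synth.trace.n / synth.trace.fs_hz
    events, filt = detect_and_score(synth.trace, variant=variant,
                                    period_end_s=dur)
    return events, filt


def match_rate(injected_onsets, detected_onsets, tol_s=0.5):
    inj = np.asarray(injected_onsets, dtype=float)
    det = np.asarray(detected_onsets, dtype=float)
    if det.size == 0 or inj.size == 0:
        return 0.0, 0.0
    recall = np.mean([np.min(np.abs(det - o)) < tol_s for o in inj])
    precision = np.mean([np.min(np.abs(inj - d)) < tol_s for d in det])
    return float(recall), float(precision)
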