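"""Kinematic presets and analysis constants.

The per-substate saccade kinematics below are the published population
values for light-cycled larval zebrafish (rate in saccades/min, fixation
duration in s, decay slope and peak speed in deg/s).  Peak speed is printed
only for QEM-1; the QEM-2/3 values and the amplitude prior are package
assumptions (saccade amplitudes are never printed) and are documented in
docs/methods.md; the plateau amplitudes are chosen so the post-saccadic
decay geometry implied by the printed slope and fixation values is
self-consistent (see the methods note).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

DEG = 57.29577951308232  # degrees per radian

#: sleep criterion: rolling speed threshold (mm/s) and minimum duration (s)
SLEEP_SPEED_MM_S = 0.5
SLEEP_MIN_S = 60.0
SPEED_WINDOW_S = 5.0

#: saccade detection thresholds (velocity product, rad^2/s^2)
VPROD_THRESHOLD_SINGLE = 0.32
VPROD_THRESHOLD_MULTI = 0.60
MIN_ISI_S = 1.5

#: saccade selection
CORR_WINDOW_S = 5.0
CORR_MIN = 0.5
RESID_WINDOW_S = 15.0
RESID_MAX_RAD = 0.45

#: preprocessing
MEAN_WINDOW_S = 200.0
MEDIAN_WINDOW_S = 1.5
FUSED_LASSO_LAMBDA = 0.25

#: kinematic scoring
FIXATION_DECAY_FRACTION = 0.33
ONSET_OFFSET_VFRAC = 0.10
BASELINE_WINDOW_S = 1.0

#: substate GMM
GMM_REG_COVAR = 2e-5

#: eye tracking DoG sigmas (mm)
DOG_SIGMAS_SINGLE_MM = (0.10, 0.06)
DOG_SIGMAS_MULTI_MM = (0.15, 0.07)
EYE_MASK_MM = 0.30

STATES = ("Wake", "QEM1", "QEM2", "QEM3", "QNEM")
SLEEP_STATES = ("QEM1", "QEM2", "QEM3", "QNEM")


@dataclass(frozen=True)
class SubstateKinematics:
    """Generative saccade kinematics of one quiescent substate.

    ``regularity`` interpolates inter-saccade timing between a Poisson
    process (0) and clock-like regular intervals (1).
    """

    rate_per_min: float
    fixation_s: tuple[float, float]        # (mean, sd)
    decay_slope_deg_s: tuple[float, float]
    peak_speed_deg_s: tuple[float, float]
    amplitude_deg: tuple[float, float]
    regularity: float

    def __post_init__(self) -> None:
        if self.rate_per_min < 0:
            raise ValueError("rate_per_min must be >= 0")
        if not 0.0 <= self.regularity <= 1.0:
            raise ValueError("regularity must lie in [0, 1]")
        for name in ("fixation_s", "decay_slope_deg_s", "peak_speed_deg_s",
                     "amplitude_deg"):
            if getattr(self, name)[0] < 0:
                raise ValueError(f"{name} mean must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "SubstateKinematics":
        d = json.loads(s)
        for name in ("fixation_s", "decay_slope_deg_s", "peak_speed_deg_s",
                     "amplitude_deg"):
            d[name] = tuple(d[name])
        return cls(**d)


# QEM-1: frequent, temporally regular saccades with short static fixations.
QEM1 = SubstateKinematics(
    rate_per_min=10.2,
    fixation_s=(4.9, 1.8),
    decay_slope_deg_s=(0.32, 0.21),
    peak_speed_deg_s=(849.1, 158.7),
    amplitude_deg=(12.0, 3.0),
    regularity=0.8,
)

# QEM-2: sparse irregular saccades with steep post-saccadic decay.
QEM2 = SubstateKinematics(
    rate_per_min=1.6,
    fixation_s=(7.3, 5.6),
    decay_slope_deg_s=(0.89, 0.68),
    peak_speed_deg_s=(500.0, 150.0),
    amplitude_deg=(12.0, 3.0),
    regularity=0.1,
)

# QEM-3: sparse irregular saccades with long static fixations.
QEM3 = SubstateKinematics(
    rate_per_min=1.8,
    fixation_s=(9.7, 14.9),
    decay_slope_deg_s=(0.03, 0.07),
    peak_speed_deg_s=(500.0, 150.0),
    amplitude_deg=(12.0, 3.0),
    regularity=0.1,
)

# QNEM: quiescence with no eye movements at all.
QNEM = SubstateKinematics(
    rate_per_min=0.0,
    fixation_s=(0.0, 0.0),
    decay_slope_deg_s=(0.0, 0.0),
    peak_speed_deg_s=(0.0, 0.0),
    amplitude_deg=(0.0, 0.0),
    regularity=0.0,
)

KINEMATICS = {"QEM1": QEM1, "QEM2": QEM2, "QEM3": QEM3, "QNEM": QNEM}
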