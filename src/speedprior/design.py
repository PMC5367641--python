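"""Method-of-constant-stimuli designs for the two speed-comparison experiments.

Two experimental designs are supported:

``AF``
    The Aubert-Fleischl experiment: a moving dot patch viewed with
    stationary fixation (condition A) is compared against a patch tracked
    with a smooth-pursuit eye movement (condition B).  The two stimuli are
    shown sequentially; the pursued stimulus is the 8 deg/s standard in the
    cross-condition (AB) trials.

``CONTRAST``
    The contrast experiment: a high-contrast grating (condition A, the
    2 deg/s standard in AB trials) is compared against a low-contrast
    grating (condition B).  The two stimuli are shown simultaneously.

Each design combines three trial types — AA and BB speed-discrimination
trials used to estimate per-condition thresholds, and AB trials that measure
the perceived-speed match between the conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Experiment",
    "TRIAL_TYPES",
    "ConditionSpec",
    "DesignSpec",
    "build_design",
    "enumerate_trials",
    "design_to_dict",
    "design_from_dict",
    "save_trials",
    "load_trials",
]


class Experiment(str, Enum):
    """Tag for the two supported experimental paradigms."""

    AF = "af"
    CONTRAST = "contrast"


#: The three 2AFC trial types: within-condition discrimination (AA, BB)
#: and the cross-condition comparison (AB).
TRIAL_TYPES: tuple[str, ...] = ("AA", "BB", "AB")

TRIAL_COLUMNS = [
    "observer_id",
    "trial_type",
    "test_speed",
    "standard_speed",
    "order",
    "direction",
    "duration_s",
    "response",
]


@dataclass(frozen=True)
class ConditionSpec:
    """One of the two stimulus conditions being compared."""

    label: str
    description: str

    def __post_init__(self) -> None:
        if self.label not in ("A", "B"):
            raise ValueError(f"condition label must be 'A' or 'B', got {self.label!r}")


@dataclass(frozen=True)
class DesignSpec:
    """Full specification of a method-of-constant-stimuli session.

    Parameters
    ----------
    experiment
        Which paradigm this design instantiates.
    standard_speed
        Speed of the standard stimulus in deg/s (fixed across trials).
    trial_types
        Subset of :data:`TRIAL_TYPES` included in the session.
    test_speeds_by_type
        Mapping trial type -> tuple of test speeds (deg/s).
    reps_per_speed
        Number of repetitions of every (trial type, test speed) pair.
    stimulus_duration_s
        ``(lo, hi)`` bounds of the uniformly jittered stimulus duration in
        seconds (recorded per trial; not used by the analysis).
    interstimulus_s
        Blank interval between the two stimuli (sequential designs only).
    presentation
        ``"sequential"`` or ``"simultaneous"``.
    ab_test_condition
        Which condition ('A' or 'B') plays the *test* role in AB trials;
        the other condition is the standard.
    conditions
        Human-readable description of the two conditions.
    """

    experiment: Experiment
    standard_speed: float
    trial_types: tuple[str, ...]
    test_speeds_by_type: Mapping[str, tuple[float, ...]]
    reps_per_speed: int
    stimulus_duration_s: tuple[float, float]
    interstimulus_s: float
    presentation: str
    ab_test_condition: str
    conditions: tuple[ConditionSpec, ConditionSpec] = field(
        default=(
            ConditionSpec("A", "condition A"),
            ConditionSpec("B", "condition B"),
        )
    )

    def __post_init__(self) -> None:
        if self.reps_per_speed <= 0:
            raise ValueError("reps_per_speed must be positive")
        if self.standard_speed < 0:
            raise ValueError("standard_speed must be nonnegative")
        if self.presentation not in ("sequential", "simultaneous"):
            raise ValueError(f"unknown presentation {self.presentation!r}")
        if self.ab_test_condition not in ("A", "B"):
            raise ValueError("ab_test_condition must be 'A' or 'B'")
        for tt in self.trial_types:
            if tt not in TRIAL_TYPES:
                raise ValueError(f"unknown trial type {tt!r}")
            speeds = self.test_speeds_by_type.get(tt, ())
            if len(speeds) == 0:
                raise ValueError(f"empty speed list for trial type {tt!r}")
            if any(s < 0 for s in speeds):
                raise ValueError("all test speeds must be nonnegative")
        lo, hi = self.stimulus_duration_s
        if lo < 0 or hi < lo:
            raise ValueError("stimulus_duration_s must satisfy 0 <= lo <= hi")

    @property
    def n_trials(self) -> int:
        """Total session length: sum over types of n_speeds x reps."""
        return sum(
            len(self.test_speeds_by_type[tt]) * self.reps_per_speed
            for tt in self.trial_types
        )

    def speeds(self, trial_type: str) -> np.ndarray:
        return np.asarray(self.test_speeds_by_type[trial_type], dtype=float)


def _af_defaults() -> dict[str, Any]:
    # 7 test speeds spaced 8/6 ~ 1.33 deg/s apart: 4-12 for discrimination
    # trials, 0-8 for the cross-condition trials; 8 deg/s pursued standard.
    discrim = tuple(np.linspace(4.0, 12.0, 7))
    ab = tuple(np.linspace(0.0, 8.0, 7))
    return dict(
        experiment=Experiment.AF,
        standard_speed=8.0,
        trial_types=TRIAL_TYPES,
        test_speeds_by_type={"AA": discrim, "BB": discrim, "AB": ab},
        reps_per_speed=10,
        stimulus_duration_s=(1.15, 1.35),
        interstimulus_s=0.5,
        presentation="sequential",
        ab_test_condition="A",
        conditions=(
            ConditionSpec("A", "dot patch viewed with stationary fixation"),
            ConditionSpec("B", "dot patch tracked with smooth pursuit"),
        ),
    )


def _contrast_defaults(n_speeds: int = 9) -> dict[str, Any]:
    # Test speeds span 1-4 deg/s around the 2 deg/s high-contrast standard.
    # The grid density is configurable; the default of 9 equally spaced
    # levels yields a 270-trial session (3 types x 9 speeds x 10 reps).
    speeds = tuple(np.linspace(1.0, 4.0, n_speeds))
    return dict(
        experiment=Experiment.CONTRAST,
        standard_speed=2.0,
        trial_types=TRIAL_TYPES,
        test_speeds_by_type={tt: speeds for tt in TRIAL_TYPES},
        reps_per_speed=10,
        stimulus_duration_s=(0.3, 0.3),
        interstimulus_s=0.0,
        presentation="simultaneous",
        ab_test_condition="B",
        conditions=(
            ConditionSpec("A", "high-contrast (64%) grating"),
            ConditionSpec("B", "low-contrast (8%) grating"),
        ),
    )


def build_design(experiment: Experiment | str, **overrides: Any) -> DesignSpec:
    """Build a session design, starting from the paradigm's defaults.

    Parameters
    ----------
    experiment
        ``Experiment.AF`` / ``"af"`` or ``Experiment.CONTRAST`` / ``"contrast"``.
    **overrides
        Any :class:`DesignSpec` field, plus ``n_speeds`` (CONTRAST only),
        which rebuilds the default speed grid with that many levels.

    Examples
    --------
    >>> build_design("af").n_trials
    210
    >>> build_design("af", reps_per_speed=1).n_trials
    21
    """
    try:
        experiment = Experiment(experiment)
    except ValueError as exc:
        raise ValueError(f"unknown experiment tag {experiment!r}") from exc

    n_speeds = overrides.pop("n_speeds", None)
    if experiment is Experiment.AF:
        if n_speeds is not None:
            raise TypeError("n_speeds is only configurable for the CONTRAST design")
        defaults = _af_defaults()
    else:
        defaults = _contrast_defaults(9 if n_speeds is None else int(n_speeds))

    unknown = set(overrides) - set(defaults)
    if unknown:
        raise TypeError(f"unknown design override(s): {sorted(unknown)}")
    defaults.update(overrides)
    # normalise container types so DesignSpec instances hash/compare sanely
    defaults["trial_types"] = tuple(defaults["trial_types"])
    defaults["test_speeds_by_type"] = {
        tt: tuple(float(s) for s in speeds)
        for tt, speeds in defaults["test_speeds_by_type"].items()
    }
    return DesignSpec(**defaults)


def enumerate_trials(
    design: DesignSpec,
    seed: int | np.random.Generator,
    observer_id: str = "obs",
) -> pd.DataFrame:
    """Generate the randomly interleaved trial list for one session.

    Every (trial type, test speed) pair appears exactly ``reps_per_speed``
    times; trial order, interval order (or side), motion direction and
    stimulus duration are drawn from the seeded generator.  The ``response``
    column is left empty (NA) until the session is simulated or observed.

    Returns a :class:`pandas.DataFrame` with columns
    ``observer_id, trial_type, test_speed, standard_speed, order,
    direction, duration_s, response``.
    """
    rng = np.random.default_rng(seed)
    types: list[str] = []
    speeds: list[float] = []
    for tt in design.trial_types:
        for s in design.test_speeds_by_type[tt]:
            types.extend([tt] * design.reps_per_speed)
            speeds.extend([float(s)] * design.reps_per_speed)

    n = len(types)
    perm = rng.permutation(n)
    if design.presentation == "sequential":
        order_levels = ("test_first", "standard_first")
        direction_levels = ("left", "right")
    else:
        order_levels = ("test_left", "test_right")
        direction_levels = ("up", "down")
    order = rng.choice(order_levels, size=n)
    direction = rng.choice(direction_levels, size=n)
    lo, hi = design.stimulus_duration_s
    duration = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, lo)

    frame = pd.DataFrame(
        {
            "observer_id": observer_id,
            "trial_type": np.asarray(types)[perm],
            "test_speed": np.asarray(speeds)[perm],
            "standard_speed": design.standard_speed,
            "order": order,
            "direction": direction,
            "duration_s": duration,
            "response": pd.array([pd.NA] * n, dtype="boolean"),
        }
    )
    return frame


def design_to_dict(design: DesignSpec) -> dict[str, Any]:
    """Plain-dict (YAML-serialisable) form of a design."""
    return {
        "experiment": design.experiment.value,
        "standard_speed": design.standard_speed,
        "trial_types": list(design.trial_types),
        "test_speeds_by_type": {
            tt: [float(s) for s in speeds]
            for tt, speeds in design.test_speeds_by_type.items()
        },
        "reps_per_speed": design.reps_per_speed,
        "stimulus_duration_s": list(design.stimulus_duration_s),
        "interstimulus_s": design.interstimulus_s,
        "presentation": design.presentation,
        "ab_test_condition": design.ab_test_condition,
        "conditions": [
            {"label": c.label, "description": c.description}
            for c in design.conditions
        ],
    }


def design_from_dict(payload: Mapping[str, Any]) -> DesignSpec:
    payload = dict(payload)
    payload["experiment"] = Experiment(payload["experiment"])
    payload["trial_types"] = tuple(payload["trial_types"])
    payload["test_speeds_by_type"] = {
        tt: tuple(speeds) for tt, speeds in payload["test_speeds_by_type"].items()
    }
    payload["stimulus_duration_s"] = tuple(payload["stimulus_duration_s"])
    payload["conditions"] = tuple(
        ConditionSpec(c["label"], c["description"]) for c in payload["conditions"]
    )
    return DesignSpec(**payload)


def save_trials(frame: pd.DataFrame, path) -> None:
    """Write a trial table as CSV with the canonical column order."""
    frame.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def load_trials(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    frame["response"] = frame["response"].astype("boolean")
    return frame
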