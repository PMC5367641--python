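"""Eye-speed, pursuit-gain and sample-loss analysis of 1000-Hz eye traces.

Eye position is low-pass filtered with a Gaussian kernel specified by its
*frequency-domain* SD (default 16 Hz; the equivalent temporal SD is
``1 / (2 pi f)``, roughly 10 ms), then differentiated by central
differences.  Speed is the Euclidean norm of the two velocity components.
Blinks and dropouts (invalid samples) and saccades (speed above a
threshold) are masked out, with a guard window around each masked run, and
mean speeds are pooled over the surviving samples of all epochs of a kind.
Pursuit gain is the mean pursuit speed divided by the target (standard)
speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "EyeSampleSeries",
    "OculomotorConfig",
    "VelocityResult",
    "MaskedSpeed",
    "OculomotorSummary",
    "velocity",
    "mask_artifacts",
    "summarize",
]


@dataclass
class EyeSampleSeries:
    """A uniformly sampled eye-position epoch.

    ``time`` in seconds (uniform steps), ``x``/``y`` in degrees, ``valid``
    flags tracker dropouts, ``label`` names the epoch kind (e.g.
    ``"pursuit"`` / ``"fixation"``).
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    label: str = "other"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.time)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("time, x, y, valid must have equal length")
        if n >= 2:
            steps = np.diff(self.time)
            if np.any(steps <= 0):
                raise ValueError("time must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("sampling must be uniform")

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"time_s": self.time, "x_deg": self.x, "y_deg": self.y,
             "valid": self.valid.astype(int), "epoch": self.label}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EyeSampleSeries":
        frame = pd.read_csv(path, sep="\t")
        label = str(frame["epoch"].iloc[0]) if "epoch" in frame else "other"
        return cls(
            time=frame["time_s"].to_numpy(),
            x=frame["x_deg"].to_numpy(),
            y=frame["y_deg"].to_numpy(),
            valid=frame["valid"].to_numpy().astype(bool),
            label=label,
        )


@dataclass(frozen=True)
class OculomotorConfig:
    """Analysis parameters.

    ``filter_sd_hz`` — frequency-domain SD of the Gaussian position filter;
    ``saccade_threshold_deg_s`` — speed above which samples count as
    saccadic; ``guard_ms`` — half-width of the guard window masked around
    every invalid/saccadic run; ``edge_sds`` — number of temporal filter
    SDs trimmed at each end of an epoch, where boundary padding makes the
    derivative unreliable.
    """

    filter_sd_hz: float = 16.0
    saccade_threshold_deg_s: float = 30.0
    guard_ms: float = 10.0
    edge_sds: float = 4.0

    def temporal_sd_s(self) -> float:
        """Equivalent time-domain SD of the position filter, in seconds."""
        return 1.0 / (2.0 * math.pi * self.filter_sd_hz)


@dataclass
class VelocityResult:
    """Velocity components, speed, and per-sample quality flags."""

    vx: np.ndarray
    vy: np.ndarray
    speed: np.ndarray
    valid: np.ndarray          # invalidity dilated through the filter support
    low_confidence: np.ndarray  # within edge_sds temporal SDs of either end
    rate_hz: float


@dataclass
class MaskedSpeed:
    """Speed series with artifact mask applied."""

    speed: np.ndarray
    keep: np.ndarray           # samples entering summary statistics
    fraction_masked: float     # masked / interior samples
    usable: bool


@dataclass
class OculomotorSummary:
    """Per-observer eye-movement metrics."""

    mean_fixation_speed: float
    mean_pursuit_speed: float
    pursuit_gain: float
    fraction_samples_lost: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_samples_lost <= 1.0):
            raise ValueError("fraction_samples_lost must lie in [0, 1]")


def _dilate(mask: np.ndarray, half_width: int) -> np.ndarray:
    """Binary dilation of a 1-D mask by +-half_width samples."""
    if half_width <= 0 or not mask.any():
        return mask.copy()
    kernel = np.ones(2 * half_width + 1)
    return np.convolve(mask.astype(float), kernel, mode="same") > 0


def velocity(series: EyeSampleSeries, config: OculomotorConfig | None = None) -> VelocityResult:
    """Smooth positions, differentiate, and return the speed series.

    Positions are filtered with a Gaussian kernel (reflection padding)
    whose temporal SD matches ``config.filter_sd_hz``; velocity is the
    central difference of the smoothed positions.  Invalid input samples
    propagate invalidity to every output sample whose filter support they
    touch.  Samples within ``edge_sds`` temporal SDs of either end are
    flagged low-confidence.
    """
    config = config or OculomotorConfig()
    rate = series.rate_hz
    sigma_samples = config.temporal_sd_s() * rate
    support = int(math.ceil(4.0 * sigma_samples))  # matches kernel truncation
    n = len(series.time)
    if n < 2 * support + 3:
        raise ValueError(
            f"series of {n} samples is shorter than the filter support "
            f"({2 * support + 3} samples needed)"
        )

    xs = gaussian_filter1d(series.x, sigma_samples, mode="reflect")
    ys = gaussian_filter1d(series.y, sigma_samples, mode="reflect")
    dt = 1.0 / rate
    vx = np.gradient(xs, dt)
    vy = np.gradient(ys, dt)
    speed = np.hypot(vx, vy)

    invalid = _dilate(~series.valid, support + 1)  # +1 for the derivative stencil
    edge = int(math.ceil(config.edge_sds * sigma_samples)) + 1
    low_conf = np.zeros(n, dtype=bool)
    low_conf[:edge] = True
    low_conf[-edge:] = True
    return VelocityResult(
        vx=vx, vy=vy, speed=speed,
        valid=~invalid, low_confidence=low_conf, rate_hz=rate,
    )


def mask_artifacts(vel: VelocityResult, config: OculomotorConfig | None = None) -> MaskedSpeed:
    """Mask invalid and saccadic samples, with a guard window around each.

    A sample is masked if it is invalid (blink/dropout, already dilated
    through the filter support), exceeds the saccade speed threshold, or
    lies within ``guard_ms`` of such a sample.  Low-confidence edge samples
    are excluded from both numerator and denominator of the reported mask
    fraction, since they carry no information about data quality.
    """
    config = config or OculomotorConfig()
    guard = int(round(config.guard_ms * 1e-3 * vel.rate_hz))
    bad = ~vel.valid | (vel.speed > config.saccade_threshold_deg_s)
    bad = _dilate(bad, guard)
    interior = ~vel.low_confidence
    keep = interior & ~bad
    n_interior = int(interior.sum())
    fraction = float((bad & interior).sum() / n_interior) if n_interior else 1.0
    return MaskedSpeed(
        speed=vel.speed, keep=keep,
        fraction_masked=fraction, usable=bool(keep.any()),
    )


def summarize(
    pursuit: Sequence[EyeSampleSeries],
    fixation: Sequence[EyeSampleSeries],
    standard_speed: float,
    config: OculomotorConfig | None = None,
) -> OculomotorSummary:
    """Pool mean eye speeds over epochs and derive pursuit gain.

    Mean pursuit and fixation speeds are computed over the surviving
    (masked, interior) samples of all epochs of each kind; gain is the mean
    pursuit speed divided by ``standard_speed``; the loss fraction is the
    masked+invalid share of interior samples pooled over *all* epochs.
    """
    if standard_speed <= 0:
        raise ValueError("standard_speed must be positive")
    config = config or OculomotorConfig()

    def pool(series_list: Sequence[EyeSampleSeries], kind: str):
        speeds = []
        lost = 0
        total = 0
        for series in series_list:
            vel = velocity(series, config)
            masked = mask_artifacts(vel, config)
            interior = ~vel.low_confidence
            total += int(interior.sum())
            lost += int((interior & ~masked.keep).sum())
            if masked.usable:
                speeds.append(masked.speed[masked.keep])
        if not speeds:
            raise ValueError(f"no usable {kind} epochs")
        return float(np.mean(np.concatenate(speeds))), lost, total

    mean_pursuit, lost_p, tot_p = pool(pursuit, "pursuit")
    mean_fix, lost_f, tot_f = pool(fixation, "fixation")
    total = tot_p + tot_f
    return OculomotorSummary(
        mean_fixation_speed=mean_fix,
        mean_pursuit_speed=mean_pursuit,
        pursuit_gain=mean_pursuit / standard_speed,
        fraction_samples_lost=(lost_p + lost_f) / total if total else 1.0,
    )
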