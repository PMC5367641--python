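"""Generative Bayesian observers for 2AFC speed-comparison sessions.

The observer model: on each stimulus interval the observer draws a noisy
internal measurement ``m ~ N(V, sigma_l^2)`` of the stimulus speed ``V`` and
combines it with a zero-mean Gaussian slow-speed prior of variance
``sigma_p^2``.  The percept is the posterior mean

    w * m,    w = sigma_p^2 / (sigma_p^2 + sigma_l^2),

i.e. the measurement shrunk toward zero by an amount that grows as the
sensory evidence becomes less reliable.  The observer reports whichever of
the two intervals produced the larger percept.

Individual differences enter through two channels: the per-condition
likelihood SDs ``sigma_lA, sigma_lB`` (sensitivity) and the prior variance,
which is modelled as ``k * Q`` — a single cohort-wide scaling factor ``k``
times the observer's autism-spectrum-quotient trait score ``Q``.

Because the same shrinkage weight applies to both intervals of a
within-condition (AA or BB) trial, the implied psychometric function for
those trials is a cumulative Gaussian in test speed with SD
``sqrt(2) * sigma_l``; the fitted discrimination threshold ``delta``
therefore satisfies ``sigma_l^2 = delta^2 / 2``, which is exactly the
likelihood-variance mapping the cohort-level model assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import DesignSpec, enumerate_trials
from .oculomotor import EyeSampleSeries

__all__ = [
    "ObserverParams",
    "CohortSpec",
    "make_cohort",
    "shrinkage_weight",
    "percept_sample",
    "response_probability",
    "simulate_trial",
    "simulate_session",
    "simulate_eye_trace",
]


@dataclass(frozen=True)
class ObserverParams:
    """Generative truth for one simulated observer.

    ``Q`` is the trait score (0-50, integer-valued in practice), ``k`` the
    cohort-wide prior scaling in (deg/s)^2 per trait unit, and ``sigma_lA``
    / ``sigma_lB`` the likelihood SDs (deg/s) for the two stimulus
    conditions.  The prior variance is the derived quantity ``k * Q``.
    """

    observer_id: str
    Q: float
    k: float
    sigma_lA: float
    sigma_lB: float

    def __post_init__(self) -> None:
        if self.Q < 0:
            raise ValueError("trait score Q must be nonnegative")
        if self.k < 0:
            raise ValueError("prior scaling k must be nonnegative")
        if self.sigma_lA <= 0 or self.sigma_lB <= 0:
            raise ValueError("likelihood SDs must be positive")

    @property
    def prior_variance(self) -> float:
        """sigma_p^2 = k * Q, in (deg/s)^2."""
        return self.k * self.Q

    def sigma_l(self, condition: str) -> float:
        if condition == "A":
            return self.sigma_lA
        if condition == "B":
            return self.sigma_lB
        raise ValueError(f"unknown condition {condition!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Sampling recipe for a cohort of simulated observers.

    Defaults emulate the study population: 31 observers with integer trait
    scores drawn from N(15.6, 7.7^2) truncated to [0, 50], a shared prior
    scaling, and per-condition likelihood SDs drawn uniformly from ranges in
    which condition B (pursued / low-contrast) is noisier than condition A
    on average.
    """

    n_observers: int = 31
    Q_mean: float = 15.6
    Q_sd: float = 7.7
    k_true: float = 0.08
    sigma_lA_range: tuple[float, float] = (0.5, 1.0)
    sigma_lB_range: tuple[float, float] = (0.9, 1.8)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_observers < 1:
            raise ValueError("n_observers must be at least 1")
        if self.Q_sd < 0:
            raise ValueError("Q_sd must be nonnegative")
        if self.k_true < 0:
            raise ValueError("k_true must be nonnegative")
        for lo, hi in (self.sigma_lA_range, self.sigma_lB_range):
            if not (0 < lo <= hi):
                raise ValueError("sigma ranges must be positive with lo <= hi")


def make_cohort(spec: CohortSpec, seed: int | np.random.Generator | None = None) -> list[ObserverParams]:
    """Draw a cohort of observer parameter sets.

    Trait scores are sampled from the truncated normal on [0, 50] and
    rounded to integers (the instrument is integer-scored); likelihood SDs
    are uniform on their ranges.  Reproducible given a seed (``seed``
    argument wins over ``spec.seed``).
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    if spec.Q_sd == 0:
        q = np.full(spec.n_observers, spec.Q_mean)
    else:
        a = (0.0 - spec.Q_mean) / spec.Q_sd
        b = (50.0 - spec.Q_mean) / spec.Q_sd
        q = sps.truncnorm.rvs(
            a, b, loc=spec.Q_mean, scale=spec.Q_sd,
            size=spec.n_observers, random_state=rng,
        )
    q = np.clip(np.rint(q), 0, 50)
    sA = rng.uniform(*spec.sigma_lA_range, size=spec.n_observers)
    sB = rng.uniform(*spec.sigma_lB_range, size=spec.n_observers)
    return [
        ObserverParams(
            observer_id=f"obs{i:03d}",
            Q=float(q[i]),
            k=spec.k_true,
            sigma_lA=float(sA[i]),
            sigma_lB=float(sB[i]),
        )
        for i in range(spec.n_observers)
    ]


def shrinkage_weight(sigma_l, sigma_p2):
    """Posterior-mean weight w = sigma_p^2 / (sigma_p^2 + sigma_l^2)."""
    sigma_l = np.asarray(sigma_l, dtype=float)
    sigma_p2 = np.asarray(sigma_p2, dtype=float)
    if np.any(sigma_l <= 0):
        raise ValueError("sigma_l must be positive")
    if np.any(sigma_p2 < 0):
        raise ValueError("sigma_p2 must be nonnegative")
    return sigma_p2 / (sigma_p2 + sigma_l**2)


def percept_sample(V, sigma_l, sigma_p2, rng: np.random.Generator):
    """Draw a perceived speed: posterior mean of a noisy measurement.

    ``m ~ N(V, sigma_l^2)`` and the returned percept is ``w * m``; its
    expectation is ``w * V`` and its SD is ``w * sigma_l``.  With
    ``sigma_p2 = 0`` (a prior collapsed onto rest) the percept is exactly 0.
    Broadcasts over array arguments.
    """
    V = np.asarray(V, dtype=float)
    w = shrinkage_weight(sigma_l, sigma_p2)
    m = rng.normal(V, np.asarray(sigma_l, dtype=float))
    return w * m


def _interval_sigmas(trial_type: str, ab_test_condition: str, params: ObserverParams):
    """Likelihood SDs of the (test, standard) intervals for a trial type."""
    if trial_type == "AA":
        return params.sigma_lA, params.sigma_lA
    if trial_type == "BB":
        return params.sigma_lB, params.sigma_lB
    if trial_type == "AB":
        test = params.sigma_l(ab_test_condition)
        std = params.sigma_l("B" if ab_test_condition == "A" else "A")
        return test, std
    raise ValueError(f"unmapped trial type {trial_type!r}")


def response_probability(
    test_speed,
    standard_speed,
    sigma_test,
    sigma_standard,
    sigma_p2,
):
    """Analytic P(test judged faster) for independent per-interval percepts.

    The decision variable ``w_t m_t - w_s m_s`` is Gaussian, so

        P = Phi((w_t V_t - w_s V_s) / sqrt(w_t^2 s_t^2 + w_s^2 s_s^2)).

    Degenerate case ``sigma_p2 = 0`` (both percepts identically 0) returns
    0.5: the tie is resolved by a fair coin.
    """
    wt = shrinkage_weight(sigma_test, sigma_p2)
    ws = shrinkage_weight(sigma_standard, sigma_p2)
    loc = wt * np.asarray(test_speed, float) - ws * np.asarray(standard_speed, float)
    scale = np.sqrt((wt * np.asarray(sigma_test, float)) ** 2 + (ws * np.asarray(sigma_standard, float)) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = sps.norm.cdf(np.where(scale > 0, loc / np.where(scale > 0, scale, 1.0), 0.0))
    return np.where(scale > 0, p, 0.5)


def simulate_trial(trial, params: ObserverParams, rng: np.random.Generator,
                   ab_test_condition: str = "A"):
    """Answer one 2AFC trial; returns the trial with ``response`` filled.

    ``trial`` is a mapping/Series with ``trial_type``, ``test_speed`` and
    ``standard_speed``.  The response is True when the test interval's
    percept exceeds the standard interval's percept (exact ties — possible
    only when the prior variance is 0 — are resolved by a fair coin).
    """
    s_test, s_std = _interval_sigmas(trial["trial_type"], ab_test_condition, params)
    sp2 = params.prior_variance
    p_test = percept_sample(trial["test_speed"], s_test, sp2, rng)
    p_std = percept_sample(trial["standard_speed"], s_std, sp2, rng)
    if p_test == p_std:
        response = bool(rng.integers(2))
    else:
        response = bool(p_test > p_std)
    out = dict(trial)
    out["response"] = response
    return out


def simulate_session(
    design: DesignSpec,
    params: ObserverParams,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Simulate a full session: enumerate trials and answer each one.

    Vectorised over trials but statistically identical to calling
    :func:`simulate_trial` on each row; deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    trials = enumerate_trials(design, rng, observer_id=params.observer_id)
    sp2 = params.prior_variance

    sigma_test = np.empty(len(trials))
    sigma_std = np.empty(len(trials))
    for tt in design.trial_types:
        mask = (trials["trial_type"] == tt).to_numpy()
        st, ss = _interval_sigmas(tt, design.ab_test_condition, params)
        sigma_test[mask] = st
        sigma_std[mask] = ss

    w_test = shrinkage_weight(sigma_test, sp2)
    w_std = shrinkage_weight(sigma_std, sp2)
    p_test = w_test * rng.normal(trials["test_speed"].to_numpy(), sigma_test)
    p_std = w_std * rng.normal(trials["standard_speed"].to_numpy(), sigma_std)
    response = p_test > p_std
    ties = p_test == p_std
    if ties.any():
        response = np.where(ties, rng.integers(2, size=len(trials)).astype(bool), response)
    trials["response"] = pd.array(response, dtype="boolean")
    return trials


def simulate_eye_trace(
    kind: str,
    target_speed: float,
    gain: float,
    jitter_sd: float,
    duration_s: float = 1.25,
    rate_hz: float = 1000.0,
    blink_prob: float = 0.0,
    saccade_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> EyeSampleSeries:
    """Simulate one epoch of eye-position samples.

    The eye velocity is ``gain * target_speed`` (horizontal) plus white
    Gaussian velocity jitter of SD ``jitter_sd`` deg/s on both axes;
    position is its time integral.  Artifacts are deliberately simple:

    * blinks — with probability ``blink_prob`` one run of 100-200 ms is
      marked invalid and the recorded position drops to zero (tracker
      dropout);
    * saccades — a Poisson number (rate ``saccade_rate`` per second) of
      triangular horizontal velocity pulses, 30 ms long with peak speed
      100-300 deg/s.

    The generative truth (kind, gain, target speed) is stored in ``meta``
    for recovery tests.
    """
    if duration_s <= 0 or rate_hz <= 0:
        raise ValueError("duration_s and rate_hz must be positive")
    if kind not in ("fixation", "pursuit"):
        raise ValueError(f"unknown epoch kind {kind!r}")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    dt = 1.0 / rate_hz
    t = np.arange(n) * dt

    base = gain * target_speed if kind == "pursuit" else 0.0
    vx = np.full(n, base)
    vy = np.zeros(n)
    if jitter_sd > 0:
        vx = vx + rng.normal(0.0, jitter_sd, size=n)
        vy = vy + rng.normal(0.0, jitter_sd, size=n)

    # saccades: triangular velocity pulses with random sign and onset
    n_sacc = rng.poisson(saccade_rate * duration_s)
    sacc_len = max(2, int(round(0.030 * rate_hz)))
    pulse = np.concatenate(
        [np.linspace(0, 1, sacc_len // 2, endpoint=False),
         np.linspace(1, 0, sacc_len - sacc_len // 2)]
    )
    for _ in range(n_sacc):
        start = int(rng.integers(0, max(1, n - sacc_len)))
        peak = rng.uniform(100.0, 300.0) * (1 if rng.integers(2) else -1)
        vx[start:start + sacc_len] += peak * pulse[: n - start]

    x = np.cumsum(vx) * dt
    y = np.cumsum(vy) * dt
    valid = np.ones(n, dtype=bool)

    if blink_prob > 0 and rng.uniform() < blink_prob:
        blink_len = int(round(rng.uniform(0.100, 0.200) * rate_hz))
        start = int(rng.integers(0, max(1, n - blink_len)))
        valid[start:start + blink_len] = False
        x[start:start + blink_len] = 0.0   # tracker reports garbage during blinks
        y[start:start + blink_len] = 0.0

    return EyeSampleSeries(
        time=t, x=x, y=y, valid=valid, label=kind,
        meta={"kind": kind, "gain": gain, "target_speed": target_speed,
              "jitter_sd": jitter_sd, "rate_hz": rate_hz},
    )
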