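"""Cumulative-Gaussian psychometric fitting and observer-level summaries.

Per-level binary 2AFC counts are fitted by maximum likelihood with a probit
link: the probability of judging the test stimulus faster at test speed x is

    p(x) = Phi((x - mu) / sigma),

where ``mu`` is the point of subjective equality (PSE) and ``sigma`` the
discrimination threshold — the speed difference between the 84.1% point and
the PSE.  No lapse/guess parameters are fitted.

The module also derives the per-observer motion-effect ratio V_A/V_B and
applies the cohort exclusion rules (flat cross-condition function, poor
fixation, poor pursuit, excessive tracker loss, and — for the contrast
experiment — extreme PSE outliers).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from .design import DesignSpec, Experiment
from .oculomotor import OculomotorSummary

__all__ = [
    "PsychometricData",
    "PsychometricFit",
    "ObserverSummary",
    "ExclusionConfig",
    "aggregate",
    "fit_cumulative_gaussian",
    "effect_ratio",
    "summarize_observer",
    "apply_exclusions",
    "summaries_to_frame",
]


@dataclass(frozen=True)
class PsychometricData:
    """Binomial counts of "test faster" responses per test-speed level."""

    levels: np.ndarray
    n_test_faster: np.ndarray
    n_total: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", np.asarray(self.levels, dtype=float))
        object.__setattr__(self, "n_test_faster", np.asarray(self.n_test_faster, dtype=int))
        object.__setattr__(self, "n_total", np.asarray(self.n_total, dtype=int))
        if not (len(self.levels) == len(self.n_test_faster) == len(self.n_total)):
            raise ValueError("levels and counts must have equal length")
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("levels must be strictly increasing")
        if np.any(self.n_test_faster < 0) or np.any(self.n_test_faster > self.n_total):
            raise ValueError("need 0 <= n_test_faster <= n_total at every level")

    @property
    def proportions(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.n_total > 0, self.n_test_faster / self.n_total, np.nan)


@dataclass(frozen=True)
class PsychometricFit:
    """A fitted cumulative Gaussian: PSE (mu) and threshold (sigma)."""

    mu: float
    sigma: float
    log_likelihood: float
    converged: bool
    se_mu: float = float("nan")
    se_sigma: float = float("nan")
    message: str = ""


@dataclass
class ObserverSummary:
    """One analysis row per observer: trait, thresholds, effect ratio, eye."""

    observer_id: str
    Q: float
    delta_A: float
    delta_B: float
    pse_ab: float
    ratio_measured: float
    ab_converged: bool
    eye: OculomotorSummary | None = None
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass(frozen=True)
class ExclusionConfig:
    """Thresholds for the cohort exclusion rules (documented defaults)."""

    max_fixation_speed: float = 2.0     # deg/s
    min_pursuit_gain: float = 0.6
    max_fraction_lost: float = 0.5
    outlier_sds: float = 15.0           # contrast experiment, PSE outliers
    # Cohort moments for the outlier rule exclude the candidate: with the
    # candidate included, a single outlier can shift the SD so much that no
    # point can ever sit 15 SDs out (the largest attainable z is
    # (n-1)/sqrt(n)), so the rule would be vacuous.
    leave_one_out: bool = True


def aggregate(trials: pd.DataFrame, trial_type: str) -> PsychometricData:
    """Tally responses of one trial type into per-level binomial counts."""
    subset = trials[trials["trial_type"] == trial_type]
    if subset.empty:
        raise ValueError(f"no trials of type {trial_type!r}")
    if subset["response"].isna().any():
        raise ValueError("trial table contains unanswered trials")
    grouped = subset.groupby("test_speed")["response"]
    levels = np.array(sorted(grouped.groups))
    n_faster = grouped.sum().reindex(levels).to_numpy(dtype=int)
    n_total = grouped.count().reindex(levels).to_numpy(dtype=int)
    return PsychometricData(levels, n_faster, n_total)


def _nll(params: np.ndarray, data: PsychometricData) -> float:
    mu, log_sigma = params
    sigma = np.exp(log_sigma)
    p = norm.cdf((data.levels - mu) / sigma)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -float(np.sum(data.n_test_faster * np.log(p)
                         + (data.n_total - data.n_test_faster) * np.log1p(-p)))


def _nll_grad(params: np.ndarray, data: PsychometricData) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and its gradient in (mu, log sigma)."""
    mu, log_sigma = params
    sigma = np.exp(log_sigma)
    z = (data.levels - mu) / sigma
    p = np.clip(norm.cdf(z), 1e-12, 1 - 1e-12)
    phi = norm.pdf(z)
    k = data.n_test_faster
    n = data.n_total
    nll = -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))
    dl_dp = k / p - (n - k) / (1.0 - p)
    g_mu = float(np.sum(dl_dp * phi / sigma))         # -d logL/d mu
    g_ls = float(np.sum(dl_dp * phi * z))             # -d logL/d log sigma
    return nll, np.array([g_mu, g_ls])


def _hessian_se(params: np.ndarray, data: PsychometricData) -> tuple[float, float]:
    """Approximate SEs of (mu, sigma) from a finite-difference Hessian."""
    eps = 1e-4
    h = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            pp = params.copy(); pp[i] += eps; pp[j] += eps
            pm = params.copy(); pm[i] += eps; pm[j] -= eps
            mp = params.copy(); mp[i] -= eps; mp[j] += eps
            mm = params.copy(); mm[i] -= eps; mm[j] -= eps
            h[i, j] = (_nll(pp, data) - _nll(pm, data) - _nll(mp, data) + _nll(mm, data)) / (4 * eps**2)
    try:
        cov = np.linalg.inv(h)
        if np.any(np.diag(cov) <= 0):
            return float("nan"), float("nan")
        se_mu = float(np.sqrt(cov[0, 0]))
        # delta method: sigma = exp(log_sigma)
        se_sigma = float(np.sqrt(cov[1, 1]) * np.exp(params[1]))
        return se_mu, se_sigma
    except np.linalg.LinAlgError:
        return float("nan"), float("nan")


def fit_cumulative_gaussian(data: PsychometricData) -> PsychometricFit:
    """Maximum-likelihood probit fit of the psychometric function.

    Degenerate data never raise: responses that are all "slower" or all
    "faster", or so flat that the threshold is unidentifiable (fitted sigma
    far beyond the tested range), yield a fit flagged ``converged=False``.

    Requires at least 3 levels with nonzero totals.
    """
    active = data.n_total > 0
    if active.sum() < 3:
        raise ValueError("need at least 3 levels with observations")

    span = float(data.levels[-1] - data.levels[0])
    sigma_cap = 20.0 * span
    props = data.proportions[active]
    if np.all(data.n_test_faster[active] == 0) or np.all(
        data.n_test_faster[active] == data.n_total[active]
    ):
        return PsychometricFit(
            mu=float("nan"), sigma=float("nan"), log_likelihood=0.0,
            converged=False, message="degenerate data: all responses identical",
        )

    # initialisation: linear regression on probit-transformed proportions
    adj = np.clip(props, 0.05, 0.95)
    z = norm.ppf(adj)
    x = data.levels[active]
    slope, intercept = np.polyfit(x, z, 1)
    if slope > 1e-8:
        mu0, sigma0 = -intercept / slope, 1.0 / slope
    else:
        mu0, sigma0 = float(np.mean(x)), span
    sigma0 = float(np.clip(sigma0, 1e-3 * span, sigma_cap))

    bounds = [(data.levels[0] - 10 * span, data.levels[-1] + 10 * span),
              (np.log(1e-4 * span), np.log(50.0 * span))]

    def _solve(start):
        start = [float(np.clip(start[0], *bounds[0])),
                 float(np.clip(start[1], *bounds[1]))]
        return optimize.minimize(_nll_grad, np.asarray(start, float), args=(data,),
                                 jac=True, method="L-BFGS-B", bounds=bounds,
                                 options={"ftol": 1e-14, "gtol": 1e-10,
                                          "maxiter": 500})

    best = _solve([mu0, np.log(sigma0)])
    grad_ok = float(np.max(np.abs(best.jac))) < 1e-5
    if not (best.success or grad_ok):
        # rare: retry from generic starts and polish derivative-free
        for start in ([float(np.mean(x)), np.log(0.5 * span)],
                      [float(np.median(x)), np.log(0.1 * span)]):
            res = _solve(start)
            if res.fun < best.fun:
                best = res
        polish = optimize.minimize(_nll, best.x, args=(data,), method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-12,
                                            "maxiter": 400})
        if polish.fun <= best.fun:
            best = polish

    mu = float(best.x[0])
    sigma = float(np.exp(best.x[1]))
    grad_norm = float(np.max(np.abs(_nll_grad(best.x, data)[1])))
    converged = (bool(best.success) or grad_norm < 1e-5) and sigma < sigma_cap and np.isfinite(mu)
    se_mu, se_sigma = _hessian_se(best.x, data) if converged else (float("nan"),) * 2
    return PsychometricFit(
        mu=mu, sigma=sigma, log_likelihood=-float(best.fun),
        converged=converged, se_mu=se_mu, se_sigma=se_sigma,
        message="" if converged else "threshold unidentifiable or optimizer failed",
    )


def effect_ratio(fit_ab: PsychometricFit, design: DesignSpec) -> float:
    """The motion-effect ratio V_A/V_B from the cross-condition fit.

    For the pursuit experiment the pursued stimulus is the standard, so the
    ratio is PSE / standard speed; for the contrast experiment the
    high-contrast stimulus is the standard, so the ratio is standard speed
    / PSE.  Under the respective slowing effects both are below 1.
    """
    if not fit_ab.converged:
        raise ValueError("cannot form an effect ratio from a non-converged fit")
    if not np.isfinite(fit_ab.mu) or fit_ab.mu <= 0:
        raise ValueError("PSE must be positive")
    if design.experiment is Experiment.AF:
        return fit_ab.mu / design.standard_speed
    return design.standard_speed / fit_ab.mu


def summarize_observer(
    trials: pd.DataFrame,
    design: DesignSpec,
    Q: float,
    eye: OculomotorSummary | None = None,
) -> ObserverSummary:
    """Fit all three trial types and assemble the observer's analysis row."""
    fit_aa = fit_cumulative_gaussian(aggregate(trials, "AA"))
    fit_bb = fit_cumulative_gaussian(aggregate(trials, "BB"))
    fit_ab = fit_cumulative_gaussian(aggregate(trials, "AB"))
    if fit_ab.converged and fit_ab.mu > 0:
        ratio = effect_ratio(fit_ab, design)
        pse = fit_ab.mu
        ab_ok = True
    else:
        ratio, pse, ab_ok = float("nan"), float("nan"), False
    observer_id = str(trials["observer_id"].iloc[0])
    return ObserverSummary(
        observer_id=observer_id, Q=Q,
        delta_A=fit_aa.sigma if fit_aa.converged else float("nan"),
        delta_B=fit_bb.sigma if fit_bb.converged else float("nan"),
        pse_ab=pse, ratio_measured=ratio, ab_converged=ab_ok, eye=eye,
    )


def apply_exclusions(
    summaries: Sequence[ObserverSummary],
    experiment: Experiment | str,
    config: ExclusionConfig | None = None,
    require_eye: bool | None = None,
) -> tuple[list[ObserverSummary], list[ObserverSummary]]:
    """Partition observers into (included, excluded) by the cohort rules.

    Rules are evaluated in a fixed order and only the first violated rule
    is reported:

    1. the cross-condition psychometric function never exceeds 50%
       (flat / non-converged AB fit);
    2. mean fixation eye speed above 2 deg/s;
    3. mean pursuit gain below 0.6;
    4. more than 50% of eye samples lost;
    5. (contrast experiment only) AB PSE more than 15 cohort SDs above the
       cohort mean.

    Eye-based rules require eye metrics; their absence is an error for the
    pursuit experiment (``require_eye`` defaults to True there) and they
    are skipped otherwise.
    """
    experiment = Experiment(experiment)
    config = config or ExclusionConfig()
    if require_eye is None:
        require_eye = experiment is Experiment.AF

    out = [replace_summary(s) for s in summaries]

    # rule 5 needs cohort PSE moments (contrast experiment only)
    pses = np.array([s.pse_ab for s in out], dtype=float)

    def pse_outlier(i: int) -> bool:
        if experiment is not Experiment.CONTRAST:
            return False
        if not np.isfinite(pses[i]):
            return False
        others = np.delete(pses, i) if config.leave_one_out else pses
        others = others[np.isfinite(others)]
        if len(others) < 2:
            return False
        mean, sd = float(np.mean(others)), float(np.std(others, ddof=1))
        if sd == 0:
            return False
        return pses[i] > mean + config.outlier_sds * sd

    included: list[ObserverSummary] = []
    excluded: list[ObserverSummary] = []
    for i, s in enumerate(out):
        reason = ""
        if not s.ab_converged:
            reason = "AB psychometric function never exceeds 50%"
        elif s.eye is None:
            if require_eye:
                raise ValueError(
                    f"observer {s.observer_id}: eye metrics required for the "
                    "pursuit experiment's exclusion rules"
                )
        elif s.eye.mean_fixation_speed > config.max_fixation_speed:
            reason = f"fixation eye speed > {config.max_fixation_speed:g} deg/s"
        elif s.eye.pursuit_gain < config.min_pursuit_gain:
            reason = f"pursuit gain < {config.min_pursuit_gain:g}"
        elif s.eye.fraction_samples_lost > config.max_fraction_lost:
            reason = f"> {100 * config.max_fraction_lost:g}% eye samples lost"
        if not reason and pse_outlier(i):
            reason = f"AB PSE > {config.outlier_sds:g} SDs above cohort mean"
        s.excluded = bool(reason)
        s.exclusion_reason = reason
        (excluded if reason else included).append(s)
    return included, excluded


def replace_summary(s: ObserverSummary) -> ObserverSummary:
    """Shallow copy so exclusion labelling never mutates caller data."""
    return ObserverSummary(**{k: getattr(s, k) for k in s.__dataclass_fields__})


def summaries_to_frame(summaries: Sequence[ObserverSummary]) -> pd.DataFrame:
    """Flatten summaries (eye metrics inline) into one row per observer."""
    rows = []
    for s in summaries:
        row = {
            "observer_id": s.observer_id, "Q": s.Q,
            "delta_A": s.delta_A, "delta_B": s.delta_B,
            "pse_ab": s.pse_ab, "ratio_measured": s.ratio_measured,
            "ab_converged": s.ab_converged,
            "excluded": s.excluded, "exclusion_reason": s.exclusion_reason,
        }
        if s.eye is not None:
            row.update(
                mean_fixation_speed=s.eye.mean_fixation_speed,
                mean_pursuit_speed=s.eye.mean_pursuit_speed,
                pursuit_gain=s.eye.pursuit_gain,
                fraction_samples_lost=s.eye.fraction_samples_lost,
            )
        rows.append(row)
    return pd.DataFrame(rows)
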