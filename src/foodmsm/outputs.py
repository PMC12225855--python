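"""Post-fit products: covariate-setting predictions, probability paths,
observed-vs-expected prevalence, and the piecewise time-inhomogeneous model.

Covariate settings follow the survey analysis: hazards are reported with
covariates at zero (baseline), at their sample means, or at the profiles
that push food-insecurity risk up (female-headed, head under 40, rural,
not employed, no assistance, income reduced) or down (the complement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ctmc import (
    N_STATES,
    STATES,
    IntensityMatrix,
    ProbabilityMatrix,
    transition_probability_matrix,
)
from .exceptions import ConvergenceError, ValidationError
from .inference import FitResult, ModelParameters, intensity_at
from .panel import COVARIATE_COLUMNS, PanelDataset
from .selection import TransitionCovariateStructure

#: covariate profile that increases food-insecurity risk, and its complement
RISK_INCREASING_PROFILE = {
    "sex_female": 1,
    "age_ge40": 0,
    "urban": 0,
    "employed": 0,
    "assisted": 0,
    "income_reduced": 1,
}
RISK_DECREASING_PROFILE = {k: 1 - v for k, v in RISK_INCREASING_PROFILE.items()}

SETTING_MODES = ("zero", "mean", "risk_increasing", "risk_decreasing", "explicit")


@dataclass(frozen=True)
class CovariateSetting:
    """How to resolve covariate values for a prediction."""

    mode: str = "zero"
    values: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in SETTING_MODES:
            raise ValidationError(f"mode must be one of {SETTING_MODES}, got {self.mode!r}")
        if self.mode == "explicit" and self.values is None:
            raise ValidationError("explicit setting requires covariate values")

    def resolve(
        self,
        covariate_names: Sequence[str],
        ds: PanelDataset | None = None,
    ) -> dict[str, float]:
        if self.mode == "zero":
            return {c: 0.0 for c in covariate_names}
        if self.mode == "mean":
            if ds is None:
                raise ValidationError("mean setting requires a dataset to average over")
            return {c: float(ds.frame[c].mean()) for c in covariate_names}
        if self.mode == "risk_increasing":
            return {c: float(RISK_INCREASING_PROFILE.get(c, 0)) for c in covariate_names}
        if self.mode == "risk_decreasing":
            return {c: float(RISK_DECREASING_PROFILE.get(c, 0)) for c in covariate_names}
        missing = [c for c in covariate_names if c not in self.values]
        if missing:
            raise ValidationError(f"explicit setting missing covariates: {missing}")
        return {c: float(self.values[c]) for c in covariate_names}


def predict_intensities(
    fit: FitResult,
    setting: CovariateSetting,
    ds: PanelDataset | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Transition hazards at a covariate setting, with delta-method CIs.

    The log hazard for transition (i, j) is log(lambda_ij) + beta_ij' z,
    a linear form in the parameters, so its standard error is a quadratic
    form in the fitted covariance and the interval is exponentiated.
    """
    if not fit.converged or fit.covariance is None:
        raise ConvergenceError("prediction requires a converged fit")
    names = fit.structure.covariate_names or tuple(COVARIATE_COLUMNS)
    z = setting.resolve(names, ds)
    zcrit = norm.ppf(0.5 + level / 2.0)
    rows = []
    for t in fit.structure.allowed_transitions:
        g = np.zeros(len(fit.theta))
        g[fit.baseline_index(t)] = 1.0
        log_h = fit.theta[fit.baseline_index(t)]
        for c in fit.structure.covariate_placements.get(t, ()):
            k = fit.beta_index(t, c)
            g[k] = z[c]
            log_h += fit.theta[k] * z[c]
        se = float(np.sqrt(max(g @ fit.covariance @ g, 0.0)))
        rows.append(
            {
                "transition": f"{t[0]}->{t[1]}",
                "hazard": np.exp(log_h),
                "lower": np.exp(log_h - zcrit * se),
                "upper": np.exp(min(log_h + zcrit * se, 700.0)),
            }
        )
    return pd.DataFrame(rows).set_index("transition")


def probability_paths(
    Q: IntensityMatrix,
    grid: Sequence[float],
    start_states: Sequence[int] = STATES,
) -> pd.DataFrame:
    """State-occupation probability curves from each start state.

    Tidy frame: one row per (time, start_state, state) with the
    probability P(t)[start, state]; suitable for plotting.
    """
    grid = [float(t) for t in grid]
    if any(t < 0 for t in grid):
        raise ValidationError("probability path grid must be non-negative")
    rows = []
    for t in grid:
        P = transition_probability_matrix(Q, t)
        for s in start_states:
            for j in STATES:
                rows.append(
                    {"time": t, "start_state": int(s), "state": j, "prob": P.prob(s, j)}
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PrevalenceTable:
    """Observed vs model-expected state prevalences over a time grid."""

    table: pd.DataFrame  # columns: time, state, observed_pct, expected_pct, n_at_risk

    def max_discrepancy(self) -> float:
        return float((self.table["observed_pct"] - self.table["expected_pct"]).abs().max())


def prevalence_fit(
    fit: FitResult,
    ds: PanelDataset,
    grid: Sequence[float],
) -> PrevalenceTable:
    """Observed vs expected percentage of subjects in each state over time.

    At each grid time t the risk set is the subjects whose follow-up
    covers t (first observation <= t <= last observation).  The observed
    state is the last observation carried forward; the expected
    distribution is P(t - t_first; z_subject)[x_first, .] averaged over
    the risk set.  Grid times with an empty risk set are omitted with a
    warning.
    """
    if not fit.converged:
        raise ConvergenceError("goodness of fit requires a converged fit")
    frame = ds.frame
    first = frame.groupby("id", sort=False).first()
    last_time = frame.groupby("id", sort=False)["time"].max()
    names = fit.structure.covariate_names
    rows = []
    for t in sorted(float(x) for x in grid):
        at_risk = first.index[(first["time"] <= t) & (last_time >= t)]
        if len(at_risk) == 0:
            warnings.warn(f"no subjects at risk at t={t}; grid time omitted", stacklevel=2)
            continue
        sub = frame[frame["id"].isin(at_risk)]
        locf = (
            sub[sub["time"] <= t]
            .sort_values(["id", "time"], kind="stable")
            .groupby("id", sort=False)["state"]
            .last()
        )
        observed = np.zeros(N_STATES)
        for s, n in locf.value_counts().items():
            observed[int(s) - 1] = n
        observed = observed / observed.sum() * 100.0

        expected = np.zeros(N_STATES)
        fsub = first.loc[at_risk]
        cache: dict[tuple, np.ndarray] = {}
        keys = ["time", "state", *names]
        for key, n in fsub.groupby(keys, sort=False).size().items():
            key = key if isinstance(key, tuple) else (key,)
            t_first, x_first, zvals = float(key[0]), int(key[1]), key[2:]
            z = {c: float(v) for c, v in zip(names, zvals)}
            ck = (round(t - t_first, 10), zvals)
            if ck not in cache:
                Q = intensity_at(fit.params, fit.structure, z)
                cache[ck] = transition_probability_matrix(Q, t - t_first).p
            expected += n * cache[ck][x_first - 1]
        expected = expected / len(at_risk) * 100.0

        for j in STATES:
            rows.append(
                {
                    "time": t,
                    "state": j,
                    "observed_pct": observed[j - 1],
                    "expected_pct": expected[j - 1],
                    "n_at_risk": len(at_risk),
                }
            )
    return PrevalenceTable(pd.DataFrame(rows))


@dataclass(frozen=True)
class EpochParameters:
    """Piecewise-constant time-inhomogeneous model.

    ``breakpoints`` split the time axis into epochs [0, b1), [b1, b2), ...
    with one parameter set per epoch (len(breakpoints) + 1 sets).  Within
    an epoch the chain is homogeneous; transition probabilities across
    epochs compose by the ordered matrix product.
    """

    breakpoints: tuple[float, ...]
    epoch_params: tuple[ModelParameters, ...]

    def __post_init__(self) -> None:
        bp = tuple(float(b) for b in self.breakpoints)
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValidationError("breakpoints must be strictly increasing")
        if len(self.epoch_params) != len(bp) + 1:
            raise ValidationError(
                f"need {len(bp) + 1} parameter sets for {len(bp)} breakpoints, "
                f"got {len(self.epoch_params)}"
            )
        object.__setattr__(self, "breakpoints", bp)

    def epoch_edges(self, t0: float, t1: float):
        edges = [t0] + [b for b in self.breakpoints if t0 < b < t1] + [t1]
        for lo, hi in zip(edges, edges[1:]):
            idx = int(np.searchsorted(self.breakpoints, lo, side="right"))
            yield lo, hi, self.epoch_params[idx]


def piecewise_probability(
    epochs: EpochParameters,
    structure: TransitionCovariateStructure,
    z: Mapping[str, float],
    t0: float,
    t1: float,
) -> ProbabilityMatrix:
    """Transition probabilities of the piecewise-homogeneous chain on [t0, t1].

    The result is the ordered product of expm(delta * Q_e(z)) over the
    epochs intersecting the interval.
    """
    if t1 < t0:
        raise ValidationError(f"interval reversed: t0={t0} > t1={t1}")
    P = np.eye(N_STATES)
    for lo, hi, params in epochs.epoch_edges(float(t0), float(t1)):
        Q = intensity_at(params, structure, z)
        P = P @ transition_probability_matrix(Q, hi - lo).p
    return ProbabilityMatrix(P, float(t1) - float(t0))
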