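"""Synthetic phone-survey panels with known multistate dynamics.

The generator emulates the study design the analysis assumes: a cohort of
households followed over five survey rounds at fixed times (months since
baseline), with monotone attrition calibrated to per-round completion
counts, time-constant binary covariates, and latent state trajectories
evolving as a continuous-time Markov chain whose intensities are
modulated by the covariates through proportional hazards.  Because the
true generator is known, every pipeline stage (scoring, descriptives,
likelihood, fitting, selection, prediction, goodness of fit) can be
tested end to end without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import ctmc, fies
from .exceptions import ValidationError
from .inference import (
    ModelParameters,
    fit_msm,
    intensity_at,
    pack_parameters,
    parameter_names,
)
from .panel import (
    COVARIATE_COLUMNS,
    DEFAULT_ROUND_TIMES,
    PanelDataset,
    drop_single_observation_subjects,
    panel_from_frame,
)
from .selection import TransitionCovariateStructure, predefined_structures

#: per-round completion probabilities of the emulated survey
DEFAULT_RETENTION = (3107 / 3300, 3058 / 3300, 2770 / 3300, 2704 / 3300, 1982 / 3300)

#: plausible household covariate prevalences for the emulated cohort
DEFAULT_COVARIATE_PREVALENCES = {
    "sex_female": 0.25,
    "age_ge40": 0.50,
    "urban": 0.45,
    "employed": 0.55,
    "assisted": 0.12,
    "income_reduced": 0.45,
}

#: initial state distribution (food secure, mild, moderate, severe); a
#: simulation default shaped like the observed first-visit margins
DEFAULT_INITIAL_DISTRIBUTION = (0.42, 0.25, 0.26, 0.07)

_BASELINE_RATES = {
    (1, 2): 0.273804,
    (1, 3): 0.001641,
    (1, 4): 0.000326,
    (2, 1): 0.440019,
    (2, 3): 0.322575,
    (2, 4): 0.000148,
    (3, 1): 0.020105,
    (3, 2): 0.394426,
    (3, 4): 0.116817,
    (4, 1): 0.002548,
    (4, 2): 0.002232,
    (4, 3): 0.766246,
}

_TRUE_HAZARD_RATIOS = {
    (1, 2): {
        "sex_female": 1.2345,
        "age_ge40": 1.0200,
        "urban": 0.6958,
        "employed": 0.8578,
        "assisted": 0.6236,
        "income_reduced": 1.1938,
    },
    (2, 3): {
        "sex_female": 1.1720,
        "age_ge40": 0.8656,
        "urban": 0.7223,
        "employed": 0.9502,
        "assisted": 0.7175,
        "income_reduced": 1.4959,
    },
    (3, 4): {
        "sex_female": 0.9981,
        "age_ge40": 0.8896,
        "urban": 0.8515,
        "employed": 0.8505,
        "assisted": 0.7285,
        "income_reduced": 0.9084,
    },
}


def default_true_parameters() -> tuple[ModelParameters, TransitionCovariateStructure]:
    """Reference generator for simulations: full 12-rate baseline with
    covariates acting on the three forward-adjacent transitions."""
    structure = predefined_structures(COVARIATE_COLUMNS)["forward_adjacent"]
    log_baseline = {t: float(np.log(r)) for t, r in _BASELINE_RATES.items()}
    betas = {
        (t, c): float(np.log(hr))
        for t, hrs in _TRUE_HAZARD_RATIOS.items()
        for c, hr in hrs.items()
    }
    return ModelParameters(log_baseline=log_baseline, betas=betas), structure


@dataclass(frozen=True)
class SimulationDesign:
    """Study design of a synthetic panel."""

    n_subjects: int = 3300
    round_times: tuple[float, ...] = DEFAULT_ROUND_TIMES
    retention: tuple[float, ...] = DEFAULT_RETENTION
    covariate_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCES)
    )
    true_params: ModelParameters | None = None
    true_structure: TransitionCovariateStructure | None = None
    initial_state_distribution: tuple[float, ...] = DEFAULT_INITIAL_DISTRIBUTION
    emit_fies_items: bool = False
    seed: int = 20200501

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        rt = tuple(float(t) for t in self.round_times)
        if any(b <= a for a, b in zip(rt, rt[1:])):
            raise ValidationError("round times must be strictly increasing")
        if len(self.retention) != len(rt):
            raise ValidationError("retention needs one probability per round")
        if any(not 0 < r <= 1 for r in self.retention):
            raise ValidationError("retention probabilities must lie in (0, 1]")
        if any(b > a + 1e-12 for a, b in zip(self.retention, self.retention[1:])):
            raise ValidationError(
                "monotone attrition requires non-increasing marginal retention"
            )
        if any(not 0 <= p <= 1 for p in self.covariate_prevalences.values()):
            raise ValidationError("covariate prevalences must lie in [0, 1]")
        dist = np.asarray(self.initial_state_distribution, dtype=float)
        if dist.shape != (4,) or abs(dist.sum() - 1.0) > 1e-8 or (dist < 0).any():
            raise ValidationError("initial state distribution must be 4 probabilities summing to 1")
        object.__setattr__(self, "round_times", rt)

    def resolved_parameters(self) -> tuple[ModelParameters, TransitionCovariateStructure]:
        if self.true_params is None or self.true_structure is None:
            return default_true_parameters()
        return self.true_params, self.true_structure

    def to_json(self) -> str:
        params, structure = self.resolved_parameters()
        return json.dumps(
            {
                "n_subjects": self.n_subjects,
                "round_times": list(self.round_times),
                "retention": list(self.retention),
                "covariate_prevalences": self.covariate_prevalences,
                "initial_state_distribution": list(self.initial_state_distribution),
                "emit_fies_items": self.emit_fies_items,
                "seed": self.seed,
                "structure": json.loads(structure.to_json()),
                "true_theta": [float(x) for x in pack_parameters(params, structure)],
                "param_names": parameter_names(structure),
            },
            indent=2,
        )


def sample_covariates(design: SimulationDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Independent Bernoulli covariates, fixed per subject over time."""
    cols = {}
    for c in COVARIATE_COLUMNS:
        p = design.covariate_prevalences.get(c, 0.0)
        cols[c] = (rng.random(design.n_subjects) < p).astype(int)
    out = pd.DataFrame(cols)
    out.insert(0, "id", np.arange(1, design.n_subjects + 1))
    return out


def _items_for_state(state: int, rng: np.random.Generator) -> tuple[int, ...]:
    """Random FIES item pattern whose raw score lies in the state's band."""
    lo, hi = fies.RAW_SCORE_BANDS[state]
    raw = int(rng.integers(lo, hi + 1))
    items = np.zeros(fies.N_ITEMS, dtype=int)
    items[rng.choice(fies.N_ITEMS, size=raw, replace=False)] = 1
    return tuple(items)


@dataclass(frozen=True)
class SimulatedPanel:
    """A synthetic panel plus the truth that generated it."""

    dataset: PanelDataset
    latent_paths: dict[int, list[tuple[float, int]]]
    initial_states: dict[int, int]
    design: SimulationDesign
    raw_frame: pd.DataFrame | None = None  # includes fi1..fi8 when emitted

    def truth_json(self) -> str:
        return self.design.to_json()


def simulate_panel(design: SimulationDesign) -> SimulatedPanel:
    """Draw a full synthetic panel under the design.

    Per subject: covariates are sampled once; the latent state path is an
    exact CTMC simulation under Q(z); observations are the latent state
    at each completed round.  Dropout is monotone: the subject completes
    a prefix of the rounds, with conditional continuation probabilities
    chosen so the marginal per-round completion rates match the design.
    Subjects can end with fewer than two observations; the standard
    drop-single-observation filter applies downstream.
    """
    rng = np.random.default_rng(design.seed)
    params, structure = design.resolved_parameters()
    covs = sample_covariates(design, rng)
    horizon = design.round_times[-1]

    # conditional continuation: P(complete round k | completed k-1)
    marg = np.asarray(design.retention)
    cond = marg / np.concatenate([[1.0], marg[:-1]])

    init_dist = np.asarray(design.initial_state_distribution)
    q_cache: dict[tuple[int, ...], ctmc.IntensityMatrix] = {}

    rows = []
    latent: dict[int, list[tuple[float, int]]] = {}
    initial: dict[int, int] = {}
    for rec in covs.itertuples(index=False):
        sid = rec.id
        z = {c: getattr(rec, c) for c in COVARIATE_COLUMNS}
        zkey = tuple(z[c] for c in COVARIATE_COLUMNS)
        if zkey not in q_cache:
            q_cache[zkey] = intensity_at(params, structure, z)
        start = int(rng.choice([1, 2, 3, 4], p=init_dist))
        path = ctmc.simulate_path(q_cache[zkey], horizon, start, rng)
        latent[sid] = path
        initial[sid] = start

        n_rounds = 0
        for ck in cond:
            if rng.random() < ck:
                n_rounds += 1
            else:
                break
        for r in range(n_rounds):
            t = design.round_times[r]
            state = ctmc.state_at(path, start, t)
            row = {"id": sid, "time": t, "state": state, **z}
            if design.emit_fies_items:
                items = _items_for_state(state, rng)
                row.update({col: v for col, v in zip(fies.ITEM_COLUMNS, items)})
            rows.append(row)

    raw = pd.DataFrame(rows)
    frame = raw
    if design.emit_fies_items and len(frame):
        frame = frame.drop(columns=["state"])
    if len(frame) == 0:
        frame = pd.DataFrame(
            columns=["id", "time", "state", *COVARIATE_COLUMNS]
        )
    dataset = panel_from_frame(frame)
    return SimulatedPanel(
        dataset=dataset,
        latent_paths=latent,
        initial_states=initial,
        design=design,
        raw_frame=raw if design.emit_fies_items else None,
    )


def recovery_experiment(
    design: SimulationDesign,
    n_replicates: int,
    rng: np.random.Generator | None = None,
    *,
    level: float = 0.95,
) -> pd.DataFrame:
    """Repeated simulate-then-fit: bias, RMSE, and Wald coverage per parameter.

    Each replicate simulates a panel from the design's true parameters,
    drops single-observation subjects, and refits the true structure.
    Returns one row per parameter with the truth, mean estimate, bias,
    RMSE, CI coverage of the truth, and the count of converged replicates.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    params, structure = design.resolved_parameters()
    truth = pack_parameters(params, structure)
    names = parameter_names(structure)
    zcrit = norm.ppf(0.5 + level / 2.0)

    estimates, covered = [], []
    n_converged = 0
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        rep = replace(design, seed=rep_seed)
        ds, _ = drop_single_observation_subjects(simulate_panel(rep).dataset)
        fit = fit_msm(ds, structure)
        if not fit.converged:
            continue
        n_converged += 1
        estimates.append(fit.theta)
        se = fit.se
        covered.append(np.abs(fit.theta - truth) <= zcrit * se)

    if n_converged == 0:
        raise ValidationError("no replicate converged; cannot summarize recovery")
    est = np.asarray(estimates)
    cov = np.asarray(covered, dtype=float)
    return pd.DataFrame(
        {
            "parameter": names,
            "truth": truth,
            "mean_estimate": est.mean(axis=0),
            "bias": est.mean(axis=0) - truth,
            "rmse": np.sqrt(((est - truth) ** 2).mean(axis=0)),
            "coverage": cov.mean(axis=0),
            "n_converged": n_converged,
            "n_replicates": n_replicates,
        }
    )
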