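"""Maximum-likelihood inference for the covariate-modulated multistate model.

Observation scheme: each household is seen only at its visit times (panel
data), so the contribution of a consecutive observation pair (state x0 at
t0, state x1 at t1) is the interval transition probability
``expm((t1 - t0) * Q(z))[x0, x1]`` with ``z`` the covariates recorded at
the interval's left endpoint.  Intensities follow the proportional form

    q_ij(z) = lambda_ij * exp(beta_ij' z)

so the working parameters are the log baseline rates and the raw
regression coefficients, both unconstrained.

The log-likelihood gradient is exact: intervals are grouped by
(covariate pattern, interval length), and for each group the derivative
of the summed log transition probabilities with respect to the generator
is obtained from the Frechet derivative of the matrix exponential in
adjoint form (one linear solve per group rather than one per parameter).
A spectral (eigendecomposition) fast path evaluates all groups in batch;
a scaling-and-squaring fallback handles ill-conditioned eigenbases.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import expm, expm_frechet
from scipy.optimize import minimize
from scipy.stats import norm

from .ctmc import N_STATES, IntensityMatrix
from .exceptions import ConvergenceError, ValidationError
from .panel import PanelDataset
from .selection import TransitionCovariateStructure, aic_value

logger = logging.getLogger(__name__)

_TINY_PROB = 1e-300
_EIG_COND_MAX = 1e8


def _safe_exp(x):
    """exp with the argument capped so weakly identified bounds stay finite."""
    return np.exp(np.minimum(x, 700.0))


@dataclass(frozen=True)
class ModelParameters:
    """Log baseline intensities and covariate coefficients.

    ``log_baseline`` maps each allowed transition (i, j) to log(lambda_ij)
    with covariates at zero; ``betas`` maps ((i, j), covariate_name) to
    the log hazard ratio for that covariate on that transition.
    """

    log_baseline: dict[tuple[int, int], float]
    betas: dict[tuple[tuple[int, int], str], float] = field(default_factory=dict)

    def beta(self, transition: tuple[int, int], covariate: str) -> float:
        return self.betas.get((transition, covariate), 0.0)


def _check_structure_params(
    params: ModelParameters, structure: TransitionCovariateStructure
) -> None:
    allowed = set(structure.allowed_transitions)
    extra = set(params.log_baseline) - allowed
    if extra:
        raise ValidationError(f"log_baseline for disallowed transitions: {sorted(extra)}")
    placed = {
        (t, c) for t, covs in structure.covariate_placements.items() for c in covs
    }
    extra = set(params.betas) - placed
    if extra:
        raise ValidationError(f"betas outside the structure's placements: {sorted(extra)}")


def parameter_names(structure: TransitionCovariateStructure) -> list[str]:
    """Flat parameter ordering used by the optimizer and covariance matrix."""
    names = [f"logq({i}->{j})" for i, j in structure.allowed_transitions]
    for t in structure.allowed_transitions:
        for c in structure.covariate_placements.get(t, ()):
            names.append(f"beta({t[0]}->{t[1]}):{c}")
    return names


def pack_parameters(
    params: ModelParameters, structure: TransitionCovariateStructure
) -> np.ndarray:
    _check_structure_params(params, structure)
    theta = [params.log_baseline[t] for t in structure.allowed_transitions]
    for t in structure.allowed_transitions:
        for c in structure.covariate_placements.get(t, ()):
            theta.append(params.beta(t, c))
    return np.asarray(theta, dtype=float)


def unpack_parameters(
    theta: np.ndarray, structure: TransitionCovariateStructure
) -> ModelParameters:
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (structure.n_parameters(),):
        raise ValidationError(
            f"parameter vector must have length {structure.n_parameters()}, got {theta.shape}"
        )
    n_trans = len(structure.allowed_transitions)
    log_baseline = dict(zip(structure.allowed_transitions, theta[:n_trans]))
    betas = {}
    k = n_trans
    for t in structure.allowed_transitions:
        for c in structure.covariate_placements.get(t, ()):
            betas[(t, c)] = float(theta[k])
            k += 1
    return ModelParameters(log_baseline=log_baseline, betas=betas)


def intensity_at(
    params: ModelParameters,
    structure: TransitionCovariateStructure,
    z: Mapping[str, float],
) -> IntensityMatrix:
    """Intensity matrix at covariate values z (fractional values allowed)."""
    _check_structure_params(params, structure)
    q = np.zeros((N_STATES, N_STATES))
    for (i, j) in structure.allowed_transitions:
        log_rate = params.log_baseline.get((i, j))
        if log_rate is None:
            raise ValidationError(f"missing log_baseline for transition ({i},{j})")
        for c in structure.covariate_placements.get((i, j), ()):
            if c not in z:
                raise ValidationError(f"covariate {c!r} required by the structure is absent")
            log_rate += params.beta((i, j), c) * float(z[c])
        q[i - 1, j - 1] = np.exp(log_rate)
    np.fill_diagonal(q, -q.sum(axis=1))
    return IntensityMatrix(q)


# --------------------------------------------------------------------------
# likelihood machinery
# --------------------------------------------------------------------------


class _PanelDesign:
    """Sufficient statistics of a dataset for one covariate structure.

    Intervals are grouped by (covariate pattern, length); within a group
    only the counts of (from, to) state pairs matter.
    """

    def __init__(self, ds: PanelDataset, structure: TransitionCovariateStructure):
        self.structure = structure
        iv = ds.intervals()
        if len(iv) == 0:
            raise ValidationError("dataset has no observation intervals")
        cov_names = structure.covariate_names
        if cov_names:
            zmat = iv[list(cov_names)].to_numpy(dtype=float)
            self.z_patterns, pat = np.unique(zmat, axis=0, return_inverse=True)
        else:
            self.z_patterns = np.zeros((1, 0))
            pat = np.zeros(len(iv), dtype=int)
        self.cov_names = cov_names

        cells = pd.DataFrame(
            {
                "pat": pat,
                "dt": iv["dt"].to_numpy(),
                "i": iv["from_state"].to_numpy() - 1,
                "j": iv["to_state"].to_numpy() - 1,
            }
        )
        if (cells["dt"] <= 0).any():
            raise ValidationError("observation times must be strictly increasing")
        cells = cells.groupby(["pat", "dt", "i", "j"], sort=True).size().reset_index(name="n")
        groups = cells[["pat", "dt"]].drop_duplicates().reset_index(drop=True)
        key = pd.MultiIndex.from_frame(groups)
        grp_of_cell = key.get_indexer(pd.MultiIndex.from_frame(cells[["pat", "dt"]]))

        self.grp_pat = groups["pat"].to_numpy(dtype=int)
        self.grp_dt = groups["dt"].to_numpy(dtype=float)
        self.cell_grp = grp_of_cell.astype(int)
        self.cell_i = cells["i"].to_numpy(dtype=int)
        self.cell_j = cells["j"].to_numpy(dtype=int)
        self.cell_n = cells["n"].to_numpy(dtype=float)

        self.n_subjects = ds.n_subjects
        self.n_intervals = int(self.cell_n.sum())
        self.n_transitions_observed = int(self.cell_n[self.cell_i != self.cell_j].sum())

        # index maps for the chain rule theta -> Q
        self.transitions = structure.allowed_transitions
        self.n_trans = len(self.transitions)
        self.beta_index: list[tuple[int, int, int]] = []  # (theta idx, trans idx, cov col)
        k = self.n_trans
        col = {c: ci for ci, c in enumerate(cov_names)}
        for ti, t in enumerate(self.transitions):
            for c in structure.covariate_placements.get(t, ()):
                self.beta_index.append((k, ti, col[c]))
                k += 1
        self.n_params = k

    def rates(self, theta: np.ndarray) -> np.ndarray:
        """Off-diagonal rates per covariate pattern: (n_patterns, n_trans)."""
        log_rates = np.tile(theta[: self.n_trans], (len(self.z_patterns), 1))
        for k, ti, ci in self.beta_index:
            log_rates[:, ti] += theta[k] * self.z_patterns[:, ci]
        return np.exp(log_rates)

    def generators(self, theta: np.ndarray) -> np.ndarray:
        """Intensity matrices per covariate pattern: (n_patterns, 4, 4)."""
        rates = self.rates(theta)
        Q = np.zeros((len(self.z_patterns), N_STATES, N_STATES))
        for ti, (a, b) in enumerate(self.transitions):
            Q[:, a - 1, b - 1] = rates[:, ti]
        diag = -Q.sum(axis=2)
        idx = np.arange(N_STATES)
        Q[:, idx, idx] = diag
        return Q


def _group_probabilities(design: _PanelDesign, Q: np.ndarray) -> tuple[np.ndarray, dict | None]:
    """Transition matrices per group and (optionally) spectral factors.

    Returns (P, spectral) where P has shape (n_groups, 4, 4).  ``spectral``
    carries the eigendecomposition reused by the gradient, or None when
    the eigenbasis is too ill-conditioned and the fallback path is used.
    """
    w, V = np.linalg.eig(Q)
    cond_ok = True
    try:
        Vinv = np.linalg.inv(V)
        cond = np.linalg.cond(V)
        cond_ok = bool(np.all(np.isfinite(cond)) and cond.max() < _EIG_COND_MAX)
    except np.linalg.LinAlgError:
        cond_ok = False
    if cond_ok:
        a = design.grp_dt[:, None] * w[design.grp_pat]          # (G, 4)
        with np.errstate(over="ignore", invalid="ignore"):
            E = np.exp(a)
        Vg = V[design.grp_pat]
        Vinvg = Vinv[design.grp_pat]
        P = np.einsum("gik,gk,gkj->gij", Vg, E, Vinvg).real
        return P, {"a": a, "E": E, "V": Vg, "Vinv": Vinvg}
    P = np.stack(
        [expm(dt * Q[p]) for p, dt in zip(design.grp_pat, design.grp_dt)]
    )
    return P, None


def _loglik_cells(design: _PanelDesign, P: np.ndarray) -> tuple[float, np.ndarray]:
    probs = P[design.cell_grp, design.cell_i, design.cell_j]
    if not np.all(np.isfinite(probs)):  # overflowed trial point
        return -np.inf, probs
    bad = probs <= _TINY_PROB
    if bad.any():
        k = int(np.flatnonzero(bad)[0])
        logger.warning(
            "zero transition probability for pair %d->%d over dt=%.4g; "
            "log-likelihood is -inf",
            design.cell_i[k] + 1,
            design.cell_j[k] + 1,
            design.grp_dt[design.cell_grp[k]],
        )
        return -np.inf, probs
    return float(design.cell_n @ np.log(probs)), probs


def _loglik_and_grad(theta: np.ndarray, design: _PanelDesign) -> tuple[float, np.ndarray]:
    # extreme trial points (huge rates) overflow harmlessly: they are
    # rejected below by the finiteness guards
    with np.errstate(over="ignore", invalid="ignore"):
        ll, grad = _loglik_and_grad_raw(theta, design)
    if not np.all(np.isfinite(grad)):
        return -np.inf, np.zeros_like(theta)
    return ll, grad


def _loglik_and_grad_raw(theta: np.ndarray, design: _PanelDesign) -> tuple[float, np.ndarray]:
    Q = design.generators(theta)
    P, spectral = _group_probabilities(design, Q)
    ll, probs = _loglik_cells(design, P)
    if not np.isfinite(ll):
        return ll, np.zeros_like(theta)

    # adjoint weights: dll/dP per group
    n_groups = len(design.grp_dt)
    W = np.zeros((n_groups, N_STATES, N_STATES))
    np.add.at(W, (design.cell_grp, design.cell_i, design.cell_j), design.cell_n / probs)

    # dll/dQ accumulated per covariate pattern
    G = np.zeros_like(Q)
    if spectral is not None:
        a, E, V, Vinv = spectral["a"], spectral["E"], spectral["V"], spectral["Vinv"]
        diff = a[:, :, None] - a[:, None, :]
        near = np.abs(diff) < 1e-10 * np.maximum(1.0, np.abs(a[:, :, None]))
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (E[:, :, None] - E[:, None, :]) / diff
        F = np.where(near, np.exp(0.5 * (a[:, :, None] + a[:, None, :])), F)
        # dll/dA with A = dt*Q:  L(A^T, W) = (V (F o (V^-1 W^T V)) V^-1)^T
        M = np.einsum("gik,gkl,glj->gij", Vinv, np.transpose(W, (0, 2, 1)).astype(complex), V)
        dA = np.transpose(
            np.einsum("gik,gkl,glj->gij", V, F * M, Vinv), (0, 2, 1)
        ).real
        np.add.at(G, design.grp_pat, design.grp_dt[:, None, None] * dA)
    else:
        for g in range(n_groups):
            A = design.grp_dt[g] * Q[design.grp_pat[g]]
            dA = expm_frechet(A.T, W[g], compute_expm=False)
            G[design.grp_pat[g]] += design.grp_dt[g] * dA.T

    # chain rule to theta: q_ab = exp(logq + beta.z); diagonal compensates
    rates = design.rates(theta)
    grad = np.zeros(design.n_params)
    idx = np.arange(len(Q))
    base_sens = np.empty((len(Q), design.n_trans))
    for ti, (a_s, b_s) in enumerate(design.transitions):
        base_sens[:, ti] = rates[:, ti] * (G[:, a_s - 1, b_s - 1] - G[idx, a_s - 1, a_s - 1])
    grad[: design.n_trans] = base_sens.sum(axis=0)
    for k, ti, ci in design.beta_index:
        grad[k] = base_sens[:, ti] @ design.z_patterns[:, ci]
    return ll, grad


def panel_log_likelihood(
    params: ModelParameters,
    structure: TransitionCovariateStructure,
    ds: PanelDataset,
) -> float:
    """Interval-censored panel log-likelihood of the dataset."""
    design = _PanelDesign(ds, structure)
    theta = pack_parameters(params, structure)
    Q = design.generators(theta)
    P, _ = _group_probabilities(design, Q)
    ll, _ = _loglik_cells(design, P)
    return ll


def crude_initial_parameters(
    ds: PanelDataset, structure: TransitionCovariateStructure, floor: float = 1e-4
) -> ModelParameters:
    """Crude-rate initialization: observed i->j pairs / time observed in i.

    Treats consecutive-pair counts as if transitions were directly
    observed; floors each rate at ``floor`` so every log is finite.
    Covariate coefficients start at zero.
    """
    iv = ds.intervals()
    time_in = iv.groupby("from_state")["dt"].sum()
    counts = iv.groupby(["from_state", "to_state"]).size()
    log_baseline = {}
    for (i, j) in structure.allowed_transitions:
        denom = float(time_in.get(i, 0.0))
        num = float(counts.get((i, j), 0.0))
        rate = num / denom if denom > 0 else 0.0
        log_baseline[(i, j)] = float(np.log(max(rate, floor)))
    return ModelParameters(log_baseline=log_baseline)


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one covariate structure."""

    params: ModelParameters
    structure: TransitionCovariateStructure
    loglik: float
    df: int
    aic: float
    covariance: np.ndarray | None
    converged: bool
    n_subjects: int
    n_transitions_observed: int
    theta: np.ndarray
    param_names: tuple[str, ...]

    @property
    def se(self) -> np.ndarray:
        if self.covariance is None:
            raise ConvergenceError("no covariance available (fit did not converge)")
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    def param_index(self, name: str) -> int:
        try:
            return self.param_names.index(name)
        except ValueError:
            raise ValidationError(f"unknown parameter {name!r}") from None

    def baseline_index(self, transition: tuple[int, int]) -> int:
        return self.param_index(f"logq({transition[0]}->{transition[1]})")

    def beta_index(self, transition: tuple[int, int], covariate: str) -> int:
        return self.param_index(f"beta({transition[0]}->{transition[1]}):{covariate}")

    def baseline_intensities(self) -> IntensityMatrix:
        return intensity_at(self.params, self.structure, {c: 0.0 for c in self.structure.covariate_names})

    def to_json(self) -> str:
        se = None
        if self.covariance is not None:
            se = [float(s) for s in self.se]
        return json.dumps(
            {
                "structure": json.loads(self.structure.to_json()),
                "loglik": self.loglik,
                "df": self.df,
                "aic": self.aic,
                "converged": self.converged,
                "n_subjects": self.n_subjects,
                "n_transitions_observed": self.n_transitions_observed,
                "param_names": list(self.param_names),
                "theta": [float(t) for t in self.theta],
                "se": se,
            },
            indent=2,
        )


def _observed_information(theta: np.ndarray, design: _PanelDesign) -> np.ndarray:
    """Negative Hessian of the log-likelihood by central differences of the
    exact gradient."""
    n = len(theta)
    H = np.zeros((n, n))
    h = 1e-5 * np.maximum(1.0, np.abs(theta))
    for k in range(n):
        up = theta.copy()
        up[k] += h[k]
        dn = theta.copy()
        dn[k] -= h[k]
        _, g_up = _loglik_and_grad(up, design)
        _, g_dn = _loglik_and_grad(dn, design)
        H[:, k] = (g_up - g_dn) / (2 * h[k])
    H = 0.5 * (H + H.T)
    return -H


def fit_msm(
    ds: PanelDataset,
    structure: TransitionCovariateStructure,
    init: ModelParameters | str = "crude",
    *,
    maxiter: int = 1000,
    compute_covariance: bool = True,
) -> FitResult:
    """Fit the multistate model by quasi-Newton maximization.

    Optimizes the panel log-likelihood over unconstrained log baseline
    rates and covariate coefficients (L-BFGS-B with the exact adjoint
    gradient).  The covariance of the estimates is the inverse of the
    observed information, differenced numerically at the maximum.
    """
    design = _PanelDesign(ds, structure)
    if isinstance(init, str):
        if init != "crude":
            raise ValidationError(f"unknown init scheme {init!r}")
        init_params = crude_initial_parameters(ds, structure)
    else:
        init_params = init
    theta0 = pack_parameters(init_params, structure)

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        ll, grad = _loglik_and_grad(theta, design)
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(theta)
        return -ll, -grad

    # generous box: rates between exp(-40) and exp(8) per month, |beta| <= 40
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(-40.0, 8.0)] * len(theta0),
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-6},
    )
    theta = res.x
    ll = -float(res.fun)
    converged = bool(res.success)
    if not converged:
        logger.warning("optimizer did not report convergence: %s", res.message)

    covariance = None
    if compute_covariance:
        # Eigenvalue-floored inverse of the observed information: directions
        # with (numerically) zero curvature -- e.g. a rare transition with no
        # supporting events -- get an honestly enormous variance instead of
        # poisoning the whole matrix with differencing noise.
        info = _observed_information(theta, design)
        evals, evecs = np.linalg.eigh(info)
        scale = max(float(evals.max()), 1e-12)
        if evals.min() < -1e-6 * scale:
            logger.warning("observed information indefinite at the optimum")
            converged = False
        else:
            floored = np.maximum(evals, 1e-10 * scale)
            covariance = (evecs / floored) @ evecs.T
            covariance = 0.5 * (covariance + covariance.T)

    df = structure.n_parameters()
    return FitResult(
        params=unpack_parameters(theta, structure),
        structure=structure,
        loglik=ll,
        df=df,
        aic=aic_value(ll, df),
        covariance=covariance,
        converged=converged,
        n_subjects=design.n_subjects,
        n_transitions_observed=design.n_transitions_observed,
        theta=theta,
        param_names=tuple(parameter_names(structure)),
    )


def _require_converged(fit: FitResult) -> None:
    if not fit.converged or fit.covariance is None:
        raise ConvergenceError("operation requires a converged fit with a covariance")


def baseline_intensity_cis(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Wald intervals for the baseline intensities (log scale, then exp).

    The intervals are multiplicatively symmetric about the estimate:
    exp(log lambda +- z * se(log lambda)).
    """
    _require_converged(fit)
    zcrit = norm.ppf(0.5 + level / 2.0)
    se = fit.se
    rows = []
    for t in fit.structure.allowed_transitions:
        k = fit.baseline_index(t)
        est = np.exp(fit.theta[k])
        rows.append(
            {
                "transition": f"{t[0]}->{t[1]}",
                "estimate": est,
                "lower": est * _safe_exp(-zcrit * se[k]),
                "upper": est * _safe_exp(zcrit * se[k]),
            }
        )
    return pd.DataFrame(rows).set_index("transition")


def hazard_ratios(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Hazard ratios exp(beta) with Wald intervals per (transition, covariate)."""
    _require_converged(fit)
    if not fit.structure.covariate_placements:
        raise ValidationError("fit has no covariates; no hazard ratios to report")
    zcrit = norm.ppf(0.5 + level / 2.0)
    se = fit.se
    rows = []
    for t in fit.structure.allowed_transitions:
        for c in fit.structure.covariate_placements.get(t, ()):
            k = fit.beta_index(t, c)
            hr = np.exp(fit.theta[k])
            lo = hr * np.exp(-zcrit * se[k])
            hi = hr * np.exp(zcrit * se[k])
            rows.append(
                {
                    "transition": f"{t[0]}->{t[1]}",
                    "covariate": c,
                    "hr": hr,
                    "lower": lo,
                    "upper": hi,
                    "significant": bool(lo > 1.0 or hi < 1.0),
                }
            )
    return pd.DataFrame(rows)
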