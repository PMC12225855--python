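"""Candidate covariate-placement structures and AIC-based model selection.

A structure says which of the 12 off-diagonal transitions carry baseline
rates (all of them, in this application: every direct jump between the
four severity states is allowed) and which covariates act on which
transitions through proportional intensities.  Five named candidates are
provided: a null model and four placements of the full covariate set on
forward and/or backward transitions; the winner is the fit with smallest
AIC.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ValidationError
from .panel import COVARIATE_COLUMNS

logger = logging.getLogger(__name__)

#: all 12 ordered state pairs (direct jumps between any two states allowed)
ALL_TRANSITIONS = tuple((i, j) for i in range(1, 5) for j in range(1, 5) if i != j)

FORWARD_ADJACENT = ((1, 2), (2, 3), (3, 4))
BACKWARD_ADJACENT = ((2, 1), (3, 2), (4, 3))
ALL_FORWARD = ((1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4))


@dataclass(frozen=True)
class TransitionCovariateStructure:
    """Which transitions have baseline rates and which carry covariates."""

    allowed_transitions: tuple[tuple[int, int], ...] = ALL_TRANSITIONS
    covariate_placements: dict[tuple[int, int], tuple[str, ...]] = field(default_factory=dict)
    label: str = "custom"

    def __post_init__(self) -> None:
        allowed = set(self.allowed_transitions)
        for trans, covs in self.covariate_placements.items():
            if trans not in allowed:
                raise ValidationError(
                    f"covariate placement on disallowed transition {trans}"
                )
            if len(set(covs)) != len(covs):
                raise ValidationError(f"duplicate covariate on transition {trans}")

    @property
    def covariate_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for covs in self.covariate_placements.values():
            for c in covs:
                if c not in seen:
                    seen.append(c)
        return tuple(seen)

    def n_parameters(self) -> int:
        return len(self.allowed_transitions) + sum(
            len(v) for v in self.covariate_placements.values()
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "label": self.label,
                "baseline": [list(t) for t in self.allowed_transitions],
                "placements": {
                    f"{i}->{j}": list(covs)
                    for (i, j), covs in sorted(self.covariate_placements.items())
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TransitionCovariateStructure":
        spec = json.loads(text)
        placements = {}
        for key, covs in spec.get("placements", {}).items():
            i, j = key.split("->")
            placements[(int(i), int(j))] = tuple(covs)
        return cls(
            allowed_transitions=tuple(tuple(t) for t in spec["baseline"]),
            covariate_placements=placements,
            label=spec.get("label", "custom"),
        )


def predefined_structures(
    covariate_names: tuple[str, ...] = COVARIATE_COLUMNS,
) -> dict[str, TransitionCovariateStructure]:
    """The five candidate models, all with the full 12-transition baseline.

    - ``null``: no covariates.
    - ``all_forward``: covariates on every forward transition.
    - ``forward_adjacent``: covariates on 1->2, 2->3, 3->4.
    - ``backward_adjacent``: covariates on 2->1, 3->2, 4->3 (recovery).
    - ``forward_backward_adjacent``: covariates on all six adjacent moves.
    """
    covs = tuple(covariate_names)

    def _structure(label: str, transitions: tuple[tuple[int, int], ...]):
        return TransitionCovariateStructure(
            allowed_transitions=ALL_TRANSITIONS,
            covariate_placements={t: covs for t in transitions},
            label=label,
        )

    return {
        "null": TransitionCovariateStructure(label="null"),
        "all_forward": _structure("all_forward", ALL_FORWARD),
        "forward_adjacent": _structure("forward_adjacent", FORWARD_ADJACENT),
        "backward_adjacent": _structure("backward_adjacent", BACKWARD_ADJACENT),
        "forward_backward_adjacent": _structure(
            "forward_backward_adjacent", FORWARD_ADJACENT + BACKWARD_ADJACENT
        ),
    }


def count_parameters(structure: TransitionCovariateStructure) -> int:
    """Degrees of freedom: baseline rates plus covariate coefficients."""
    return structure.n_parameters()


def aic_value(loglik: float, df: int) -> float:
    """Akaike information criterion: -2*loglik + 2*df."""
    if df < 0:
        raise ValidationError(f"df must be >= 0, got {df}")
    return -2.0 * loglik + 2.0 * df


def select_model(fits: dict[str, "FitResult"]) -> tuple[str, pd.DataFrame]:
    """Pick the converged fit with smallest AIC.

    Returns the winning label and a comparison table (label, loglik, df,
    aic, converged) sorted by AIC.  Ties break lexicographically by label.
    """
    rows = [
        {
            "label": label,
            "loglik": fit.loglik,
            "df": fit.df,
            "aic": fit.aic,
            "converged": fit.converged,
        }
        for label, fit in fits.items()
    ]
    if not any(r["converged"] for r in rows):
        raise ValidationError("no converged fits to select among")
    table = pd.DataFrame(rows).sort_values(["aic", "label"], kind="stable").reset_index(drop=True)
    candidates = table[table["converged"]]
    best = candidates.iloc[0]
    ties = candidates[candidates["aic"] == best["aic"]]
    if len(ties) > 1:
        logger.info(
            "AIC tie among %s; selecting %r by label order",
            list(ties["label"]),
            best["label"],
        )
    return str(best["label"]), table
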