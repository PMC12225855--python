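"""Long-format interval-censored panel data: model, validation, I/O, descriptives.

A panel dataset is one row per household-visit: subject id, observation
time in months since baseline, the observed food-insecurity state (1-4),
and six binary household covariates.  Subjects are observed only at their
visit times; the state path between visits is unobserved (panel /
interval-censored observation scheme).  If a file carries the raw FIES
item columns fi1..fi8 instead of a state column, states are derived via
the scoring cut-offs and rows with incomplete items are excluded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import fies
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

#: canonical covariate columns; 0 is always the reference category
#: (male head, head aged <40, rural, not employed, no assistance,
#: income not reduced)
COVARIATE_COLUMNS = (
    "sex_female",
    "age_ge40",
    "urban",
    "employed",
    "assisted",
    "income_reduced",
)

#: default visit grid of the emulated phone survey (months since baseline)
DEFAULT_ROUND_TIMES = (0.0, 0.7667, 3.4667, 4.3667, 11.3667)

_BASE_COLUMNS = ("id", "time", "state")


@dataclass(frozen=True)
class PanelDataset:
    """Validated long-format panel: one row per (subject, visit).

    The underlying frame is sorted by (id, time) with columns
    id, time, state, and the six covariates.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        object.__setattr__(self, "frame", _validate_frame(self.frame))

    @property
    def n_subjects(self) -> int:
        return self.frame["id"].nunique()

    @property
    def n_observations(self) -> int:
        return len(self.frame)

    def subjects(self) -> Sequence:
        return self.frame["id"].unique()

    def intervals(self) -> pd.DataFrame:
        """One row per consecutive observation pair within a subject.

        Columns: id, from_state, to_state, dt, plus the covariates
        recorded at the interval's left endpoint (the convention used by
        the likelihood).
        """
        g = self.frame
        nxt = g.groupby("id", sort=False).shift(-1)
        keep = nxt["time"].notna()
        out = pd.DataFrame(
            {
                "id": g.loc[keep, "id"],
                "from_state": g.loc[keep, "state"].astype(int),
                "to_state": nxt.loc[keep, "state"].astype(int),
                "dt": (nxt.loc[keep, "time"] - g.loc[keep, "time"]).astype(float),
            }
        )
        for c in COVARIATE_COLUMNS:
            out[c] = g.loc[keep, c].astype(int)
        return out.reset_index(drop=True)

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    missing = [c for c in (*_BASE_COLUMNS, *COVARIATE_COLUMNS) if c not in frame.columns]
    if missing:
        raise ValidationError(f"panel frame missing columns: {missing}")
    frame = frame[list(_BASE_COLUMNS) + list(COVARIATE_COLUMNS)]

    times = pd.to_numeric(frame["time"], errors="coerce")
    bad = frame.index[times.isna()]
    if len(bad):
        raise ValidationError(f"non-numeric observation time at row {bad[0]}")
    if (times < 0).any():
        raise ValidationError(
            f"negative observation time at row {frame.index[(times < 0)][0]}"
        )
    frame["time"] = times.astype(float)

    states = pd.to_numeric(frame["state"], errors="coerce")
    bad = frame.index[states.isna() | ~states.isin([1, 2, 3, 4])]
    if len(bad):
        raise ValidationError(
            f"state outside 1-4 at row {bad[0]} (value {frame.loc[bad[0], 'state']!r})"
        )
    frame["state"] = states.astype(int)

    for c in COVARIATE_COLUMNS:
        vals = pd.to_numeric(frame[c], errors="coerce")
        bad = frame.index[vals.isna() | ~vals.isin([0, 1])]
        if len(bad):
            raise ValidationError(
                f"non-binary covariate {c!r} at row {bad[0]} (value {frame.loc[bad[0], c]!r})"
            )
        frame[c] = vals.astype(int)

    dup = frame.duplicated(subset=["id", "time"])
    if dup.any():
        row = frame.index[dup][0]
        raise ValidationError(
            f"duplicate (id, time) pair at row {row}: "
            f"({frame.loc[row, 'id']!r}, {frame.loc[row, 'time']})"
        )
    return frame.sort_values(["id", "time"], kind="stable").reset_index(drop=True)


def read_panel(path) -> PanelDataset:
    """Read and validate a long-format panel CSV.

    The file must have id, time, the six covariate columns, and either a
    ``state`` column or the eight FIES item columns fi1..fi8 (from which
    states are derived; rows with incomplete items are dropped with a
    warning).
    """
    frame = pd.read_csv(path)
    return panel_from_frame(frame)


def panel_from_frame(frame: pd.DataFrame) -> PanelDataset:
    """Build a validated dataset from an in-memory long-format frame."""
    if "state" not in frame.columns:
        if not set(fies.ITEM_COLUMNS) <= set(frame.columns):
            raise ValidationError(
                "panel frame needs either a 'state' column or fi1..fi8 item columns"
            )
        state = fies.states_from_items(frame)
        n_bad = int(state.isna().sum())
        if n_bad:
            warnings.warn(
                f"dropping {n_bad} row(s) with incomplete FIES item responses",
                stacklevel=2,
            )
        frame = frame.loc[state.notna()].copy()
        frame["state"] = state.loc[state.notna()].astype(int)
    return PanelDataset(frame)


def write_panel(ds: PanelDataset, path) -> None:
    ds.write_csv(path)


def drop_single_observation_subjects(ds: PanelDataset) -> tuple[PanelDataset, int]:
    """Remove subjects observed fewer than twice.

    Panel-likelihood inference needs at least one observation interval per
    subject.  Returns the filtered dataset and the number of dropped rows.
    """
    counts = ds.frame.groupby("id", sort=False)["id"].transform("size")
    keep = counts >= 2
    n_dropped = int((~keep).sum())
    if keep.sum() == 0 and n_dropped:
        logger.warning("all %d subjects have a single observation; dataset is empty", n_dropped)
        return PanelDataset(ds.frame.iloc[0:0]), n_dropped
    return PanelDataset(ds.frame.loc[keep]), n_dropped


def consecutive_pair_table(ds: PanelDataset) -> pd.DataFrame:
    """Cross-tabulate consecutive observed state pairs.

    Cell (i, j) counts the occasions a subject was observed in state i at
    one visit and state j at the next.  Returns a frame with count
    columns per destination state, row percentages, and the row totals
    ("households initially" margin).
    """
    states = list(range(1, 5))
    counts = pd.DataFrame(0, index=states, columns=states, dtype=int)
    if ds.n_observations:
        pairs = ds.intervals()
        tab = pd.crosstab(pairs["from_state"], pairs["to_state"])
        counts.loc[tab.index, tab.columns] = tab
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = counts.div(totals.replace(0, np.nan), axis=0) * 100.0
    out = counts.copy()
    out.columns = [f"to_{j}" for j in states]
    for j in states:
        out[f"pct_{j}"] = pct[j]
    out["total"] = totals
    out.index.name = "from_state"
    return out


def observation_time_summary(ds: PanelDataset) -> dict[str, float]:
    """Mean and median of all observation times in the dataset (months)."""
    if ds.n_observations == 0:
        raise ValidationError("cannot summarize observation times of an empty dataset")
    times = ds.frame["time"]
    return {"mean": float(times.mean()), "median": float(times.median())}
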