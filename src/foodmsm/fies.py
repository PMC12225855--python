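"""Food Insecurity Experience Scale (FIES) scoring.

The FIES instrument asks eight yes/no questions about a household's food
access over the recall period (worry about food, skipping meals, going a
whole day without eating, ...).  The raw score is the number of affirmative
answers, 0-8.  Severity states are assigned by discrete raw-score cut-offs:

====  =========  =====================
code  raw score  label
====  =========  =====================
1     0          food secure
2     1-3        mild food insecure
3     4-7        moderate food insecure
4     8          severe food insecure
====  =========  =====================
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

N_ITEMS = 8

ITEM_COLUMNS = tuple(f"fi{i}" for i in range(1, N_ITEMS + 1))

#: state code -> inclusive (low, high) band of raw scores
RAW_SCORE_BANDS = {1: (0, 0), 2: (1, 3), 3: (4, 7), 4: (8, 8)}

STATE_LABELS = {
    1: "food secure",
    2: "mild food insecure",
    3: "moderate food insecure",
    4: "severe food insecure",
}


def score_fies(items: Sequence[int]) -> int:
    """Sum the eight binary FIES item responses into a raw score.

    Parameters
    ----------
    items : sequence of 8 ints
        1 if the household experienced the item, 0 otherwise.

    Returns
    -------
    int
        Raw score in 0..8.

    Raises
    ------
    ValidationError
        If there are not exactly 8 items or any item is not 0/1.
    """
    items = list(items)
    if len(items) != N_ITEMS:
        raise ValidationError(f"expected {N_ITEMS} FIES items, got {len(items)}")
    for k, v in enumerate(items, start=1):
        if v not in (0, 1):
            raise ValidationError(f"FIES item fi{k} must be 0 or 1, got {v!r}")
    return int(sum(items))


def classify_state(raw: int) -> int:
    """Map a raw FIES score to the four-level severity state (1-4)."""
    if not isinstance(raw, (int, np.integer)) or isinstance(raw, bool):
        raise ValidationError(f"raw score must be an integer, got {raw!r}")
    for state, (lo, hi) in RAW_SCORE_BANDS.items():
        if lo <= raw <= hi:
            return state
    raise ValidationError(f"raw score must be in 0..{N_ITEMS}, got {raw}")


def classify_items(items: Sequence[int]) -> int:
    """Score then classify in one step."""
    return classify_state(score_fies(items))


def states_from_items(frame: pd.DataFrame) -> pd.Series:
    """Derive the severity-state column from fi1..fi8 item columns.

    Rows with any missing or non-binary item yield no state (NaN); the
    caller decides whether to drop them.  Returns a float Series aligned
    with ``frame`` (NaN marks excluded rows).
    """
    missing = [c for c in ITEM_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing FIES item columns: {missing}")
    items = frame[list(ITEM_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    valid = items.notna().all(axis=1) & items.isin([0, 1]).all(axis=1)
    raw = items.sum(axis=1)
    state = pd.Series(np.nan, index=frame.index, dtype=float)
    bins = raw[valid].astype(int)
    state.loc[valid] = bins.map(classify_state).astype(float)
    return state


def enumerate_patterns() -> Iterable[tuple[tuple[int, ...], int, int]]:
    """Yield every 8-item response pattern with its raw score and state.

    Convenience for exhaustive audits of the cut-off mapping (256 patterns).
    """
    for code in range(2**N_ITEMS):
        items = tuple((code >> k) & 1 for k in range(N_ITEMS))
        raw = score_fies(items)
        yield items, raw, classify_state(raw)
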