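"""Scoring of raw questionnaire items into analysis variables.

Two instruments are scored here:

* A ten-item previous-day diet questionnaire. Each item asks how often a
  food was consumed yesterday and is coded 0 ("not at all"), 1 ("once"),
  2 ("twice") or 3 ("more than twice"). Treating each instance of intake
  as one serving, items are summed into three daily serving scores:
  fruit and vegetables (3 items, 0-9 serves), discretionary foods
  (4 items, 0-12 serves) and sugar-sweetened beverages (2 items,
  0-6 serves).

* The PedsQL 4.0 teen physical-functioning scale: eight items coded
  0 ("never") .. 4 ("almost always"), where higher raw responses indicate
  more difficulty. The scale score is the reverse-scored mean of the
  non-missing items mapped onto 0-100 (higher = better functioning),
  ``25 * (4 - mean)``. The score is set missing when five or more items
  are missing.

All scorers are vectorised over a pandas DataFrame; missing responses are
NaN. A missing diet item makes the whole food-group score missing (the
record is then excluded from the analytic sample downstream).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: item columns per food group, in questionnaire order
DIET_ITEM_COLUMNS: dict[str, list[str]] = {
    "fruit_veg": ["fruit_veg_1", "fruit_veg_2", "fruit_veg_3"],
    "discretionary": [
        "discretionary_1",
        "discretionary_2",
        "discretionary_3",
        "discretionary_4",
    ],
    "ssb": ["ssb_1", "ssb_2"],
}

#: inclusive serving-score bounds per food group
DIET_SCORE_BOUNDS: dict[str, tuple[float, float]] = {
    "fruit_veg": (0, 9),
    "discretionary": (0, 12),
    "ssb": (0, 6),
}

DIET_SCORE_COLUMNS = list(DIET_ITEM_COLUMNS)

PEDSQL_ITEM_COLUMNS = [f"pedsql_{i}" for i in range(1, 9)]

#: PedsQL rule: score is missing when this many or more items are missing
PEDSQL_MAX_MISSING = 5


def _check_item_range(items: pd.DataFrame, low: int, high: int) -> None:
    """Raise ValueError naming the first offending cell outside {low..high, NaN}."""
    values = items.to_numpy(dtype=float)
    ok = np.isnan(values) | (
        (values >= low) & (values <= high) & (values == np.round(values))
    )
    if not ok.all():
        r, c = np.argwhere(~ok)[0]
        raise ValueError(
            f"invalid item response {values[r, c]!r} at row {items.index[r]}, "
            f"column {items.columns[c]!r}; expected integer in {low}..{high} or missing"
        )


def score_diet(items: pd.DataFrame) -> pd.DataFrame:
    """Sum diet item responses into the three daily serving scores.

    Parameters
    ----------
    items
        DataFrame containing the ten columns of :data:`DIET_ITEM_COLUMNS`
        (extra columns are ignored). Values must be integers 0-3 or NaN.

    Returns
    -------
    DataFrame with columns ``fruit_veg``, ``discretionary``, ``ssb``.
    A score is NaN whenever any of its component items is missing.
    """
    scores = {}
    for group, cols in DIET_ITEM_COLUMNS.items():
        missing = [c for c in cols if c not in items.columns]
        if missing:
            raise KeyError(f"missing diet item columns: {missing}")
        block = items[cols]
        _check_item_range(block, 0, 3)
        # skipna=False: any missing item voids the food-group score
        scores[group] = block.sum(axis=1, skipna=False)
    return pd.DataFrame(scores, index=items.index)


def score_pedsql(items: pd.DataFrame) -> pd.Series:
    """Score the 8-item physical-functioning scale onto 0-100.

    The mean of the non-missing items is reverse-mapped linearly,
    ``25 * (4 - mean)``, so all-0 responses give 100 (no difficulty) and
    all-4 responses give 0. With :data:`PEDSQL_MAX_MISSING` (five) or more
    items missing the score is NaN.
    """
    missing = [c for c in PEDSQL_ITEM_COLUMNS if c not in items.columns]
    if missing:
        raise KeyError(f"missing PedsQL item columns: {missing}")
    block = items[PEDSQL_ITEM_COLUMNS]
    _check_item_range(block, 0, 4)
    n_missing = block.isna().sum(axis=1)
    score = 25.0 * (4.0 - block.mean(axis=1, skipna=True))
    score[n_missing >= PEDSQL_MAX_MISSING] = np.nan
    return score.rename("pf_score")


def score_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Attach serving scores and the physical-functioning score to a cohort.

    Returns a copy of ``df`` with four new columns: ``fruit_veg``,
    ``discretionary``, ``ssb`` and ``pf_score``.
    """
    out = df.copy()
    diet = score_diet(df)
    for col in diet.columns:
        out[col] = diet[col]
    out["pf_score"] = score_pedsql(df)
    return out
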