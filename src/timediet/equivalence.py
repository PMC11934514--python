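"""Enumeration of equivalent time-use and diet behaviour-change options.

Starting from a reference "average day" (time-use compositional mean
rounded to the 10-min grid, diet serves rounded to integers), the engine
enumerates every feasible joint change:

* time: all zero-sum reallocation vectors with each behaviour shifted by
  a multiple of 10 min within +/-30 min (total time is conserved — the
  grid is the lattice of isotemporal substitutions inside a Chebyshev
  radius);
* diet: all combinations of -1.5..+1.5 serve changes in 0.5-serve steps
  that keep each serving score within its feasible range (for a
  reference of 1 SSB serve/day this leaves -1 as the largest decrease).

For each combination the fitted model predicts the difference in
physical functioning relative to the reference, on the back-transformed
0-100 scale, with covariates fixed at their sample mean/mode. Options
are then binned into equivalence bands around target differences
(+/-0.5, 1, ..., 2.5 points): every option in a band is an "equivalent"
behaviour change. Band membership can be summarised per behaviour
(stacked-bar style percentages) and explored interactively by fixing
one behaviour change at a time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compositional import ReferenceProfile, ilr_transform
from .model import FittedModel
from .scoring import DIET_SCORE_BOUNDS, DIET_SCORE_COLUMNS

DEFAULT_TARGETS = (0.5, 1.0, 1.5, 2.0, 2.5)
DEFAULT_TOLERANCE = 0.25

def _delta_columns(reference: ReferenceProfile) -> tuple[list[str], list[str]]:
    time_cols = [f"{p}_delta" for p in reference.part_names]
    diet_cols = [f"{d}_delta" for d in reference.diet_names]
    return time_cols, diet_cols


# ---------------------------------------------------------------------------
# grids


def make_time_grid(
    reference: ReferenceProfile | np.ndarray,
    step: float = 10.0,
    radius: float = 30.0,
) -> np.ndarray:
    """All zero-sum time reallocations on the step grid within ``radius``.

    Returns an ``(n, 7)`` integer-valued array in deterministic
    lexicographic order. Every row sums to zero (total time conserved),
    every entry lies in ``[-radius, +radius]``, and the perturbed
    reference stays strictly positive in every part.
    """
    ref = reference.time if isinstance(reference, ReferenceProfile) else np.asarray(reference, dtype=float)
    if radius < 0 or step <= 0:
        raise ValueError("step must be positive and radius non-negative")
    if abs(radius / step - round(radius / step)) > 1e-9:
        raise ValueError("radius must be a multiple of step")
    d = ref.size
    k = int(round(radius / step))
    levels = np.arange(-k, k + 1)
    if d == 1:
        grid = np.zeros((1, 1))
        return grid * step
    # enumerate the first d-1 coordinates; the last is forced by the
    # zero-sum constraint
    head = np.array(list(itertools.product(levels, repeat=d - 1)), dtype=np.int64)
    tail = -head.sum(axis=1)
    keep = np.abs(tail) <= k
    deltas = np.column_stack([head[keep], tail[keep]]).astype(float) * step
    keep_pos = np.all(ref[None, :] + deltas > 0, axis=1)
    return deltas[keep_pos]


def make_diet_grid(
    reference: ReferenceProfile | np.ndarray,
    lo: float = -1.5,
    hi: float = 1.5,
    step: float = 0.5,
) -> np.ndarray:
    """All diet serve-change triples keeping each score within range.

    The candidate deltas ``lo..hi`` in ``step`` increments are filtered
    per score so that ``reference + delta`` stays within the score's
    bounds (0-9, 0-12, 0-6 serves); the Cartesian product of the
    surviving levels is returned in lexicographic order.
    """
    if isinstance(reference, ReferenceProfile):
        ref = reference.diet
        names = reference.diet_names
    else:
        ref = np.asarray(reference, dtype=float)
        names = DIET_SCORE_COLUMNS
    candidates = np.arange(round(lo / step), round(hi / step) + 1) * step
    levels = []
    for r, name in zip(ref, names):
        lo_b, hi_b = DIET_SCORE_BOUNDS[name]
        levels.append([d for d in candidates if lo_b <= r + d <= hi_b])
    return np.array(list(itertools.product(*levels)), dtype=float)


# ---------------------------------------------------------------------------
# prediction


def predict_difference(
    model: FittedModel,
    reference: ReferenceProfile,
    time_delta,
    diet_delta,
    covariates: dict | None = None,
) -> float:
    """Predicted physical-functioning difference for one joint change.

    Both the perturbed and the reference profile are pushed through the
    model and back-transformed; the difference is reported on the
    original 0-100 scale (the model is additive on the transformed
    scale, not on the score scale).
    """
    time_delta = np.asarray(time_delta, dtype=float)
    diet_delta = np.asarray(diet_delta, dtype=float)
    perturbed = reference.time + time_delta
    if np.any(perturbed <= 0):
        raise ValueError("perturbed composition has a non-positive part")
    t_ref = model.predict_transformed(reference.time, reference.diet, covariates)
    t_new = model.predict_transformed(perturbed, reference.diet + diet_delta, covariates)
    return float(model.invert(t_new) - model.invert(t_ref))


def _band_codes(diff: np.ndarray, targets, tolerance: float, include_negative: bool) -> np.ndarray:
    """Integer band codes: diff within ``tolerance`` of ``k * spacing`` -> k."""
    targets = np.sort(np.asarray(targets, dtype=float))
    spacing = targets[0] if targets.size == 1 else float(np.min(np.diff(np.concatenate([[0.0], targets]))))
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if tolerance > spacing / 2 + 1e-12:
        raise ValueError(
            f"tolerance {tolerance} exceeds half the target spacing {spacing}: bands would overlap"
        )
    k = np.rint(diff / spacing).astype(np.int16)
    kmax = int(round(targets[-1] / spacing))
    valid = (np.abs(diff - k * spacing) < tolerance) & (k != 0) & (np.abs(k) <= kmax)
    # keep only codes matching an actual target
    target_ks = {int(round(t / spacing)) for t in targets}
    in_targets = np.isin(np.abs(k), list(target_ks))
    valid &= in_targets
    if not include_negative:
        valid &= k > 0
    codes = np.where(valid, k, 0).astype(np.int16)
    return codes


@dataclass
class OptionTable:
    """Every enumerated (time reallocation, diet change) combination.

    Stored compactly as the two grids plus a dense matrix of predicted
    differences (rows: time vectors, columns: diet triples) and a
    matching matrix of band codes (0 = no band, k = band at
    ``k * spacing`` points). Row order is lexicographic in (time grid,
    diet grid), so exports are byte-stable.
    """

    reference: ReferenceProfile
    time_deltas: np.ndarray
    diet_deltas: np.ndarray
    diff: np.ndarray
    codes: np.ndarray
    targets: tuple[float, ...]
    tolerance: float
    spacing: float = 0.5

    @property
    def n_rows(self) -> int:
        return self.time_deltas.shape[0] * self.diet_deltas.shape[0]

    def band_values(self) -> list[float]:
        """All band labels present in the table definition (signed)."""
        out = [-t for t in sorted(self.targets, reverse=True)]
        out += list(sorted(self.targets))
        return out

    def band_counts(self) -> dict[float, int]:
        counts = {}
        for b in self.band_values():
            k = int(round(b / self.spacing))
            counts[b] = int(np.count_nonzero(self.codes == k))
        counts["none"] = self.n_rows - sum(counts.values())
        return counts

    def band_frame(self, band: float) -> pd.DataFrame:
        """Rows of one equivalence band as a tidy DataFrame."""
        k = int(round(band / self.spacing))
        if abs(k * self.spacing - band) > 1e-9 or k == 0:
            raise ValueError(f"{band} is not a valid band label")
        ti, dj = np.nonzero(self.codes == k)
        time_cols, diet_cols = _delta_columns(self.reference)
        out = pd.DataFrame(self.time_deltas[ti], columns=time_cols)
        for j, c in enumerate(diet_cols):
            out[c] = self.diet_deltas[dj, j]
        out["predicted_difference"] = self.diff[ti, dj]
        out["band"] = band
        return out

    def to_frame(self, bands=None) -> pd.DataFrame:
        """Concatenate banded rows (all bands by default) into one frame."""
        bands = self.band_values() if bands is None else list(bands)
        frames = [self.band_frame(b) for b in bands]
        frames = [f for f in frames if len(f)]
        if not frames:
            time_cols, diet_cols = _delta_columns(self.reference)
            return pd.DataFrame(
                columns=time_cols + diet_cols + ["predicted_difference", "band"]
            )
        return pd.concat(frames, ignore_index=True)

    def write_csv(self, path, bands=None) -> None:
        self.to_frame(bands).to_csv(path, index=False, float_format="%.6f")


def enumerate_options(
    model: FittedModel,
    reference: ReferenceProfile,
    step: float = 10.0,
    radius: float = 30.0,
    targets=DEFAULT_TARGETS,
    tolerance: float = DEFAULT_TOLERANCE,
    include_negative: bool = True,
    covariates: dict | None = None,
) -> OptionTable:
    """Score every joint time-use/diet change and band it by target.

    The model is linear on the transformed scale, so the prediction for
    a combined change decomposes into a time contribution plus a diet
    contribution; the full (time x diet) matrix is then back-transformed
    in one vectorised pass.
    """
    tg = make_time_grid(reference, step, radius)
    dg = make_diet_grid(reference)
    if tg.size == 0 or dg.size == 0:
        raise ValueError("empty reallocation grid")

    beta_z = model.params[[f"z{i}" for i in range(1, 7)]].to_numpy()
    beta_d = model.params[DIET_SCORE_COLUMNS].to_numpy()
    t_ref = model.predict_transformed(reference.time, reference.diet, covariates)
    y_ref = model.invert(t_ref)

    z_ref = ilr_transform(reference.time, model.sbp)
    z_pert = ilr_transform(reference.time[None, :] + tg, model.sbp)
    ct = (z_pert - z_ref) @ beta_z  # time contribution, transformed scale
    cd = dg @ beta_d  # diet contribution, transformed scale

    t_mat = t_ref + ct[:, None] + cd[None, :]
    diff = model.invert(t_mat) - y_ref
    codes = _band_codes(diff, targets, tolerance, include_negative)
    spacing = float(np.min(np.diff(np.sort(np.concatenate([[0.0], np.asarray(targets, float)])))))
    return OptionTable(
        reference=reference,
        time_deltas=tg,
        diet_deltas=dg,
        diff=diff,
        codes=codes,
        targets=tuple(sorted(targets)),
        tolerance=tolerance,
        spacing=spacing,
    )


# ---------------------------------------------------------------------------
# summaries


def summarize_options(table: OptionTable, band: float) -> pd.DataFrame:
    """Per-behaviour distribution of delta levels within one band.

    For each of the ten behaviours (seven time-use, three diet) the
    percentage of the band's rows at each delta level; percentages sum
    to 100 per behaviour. An empty band yields an empty frame.
    """
    rows = table.band_frame(band)
    time_cols, diet_cols = _delta_columns(table.reference)
    records = []
    if len(rows):
        for col in time_cols + diet_cols:
            counts = rows[col].value_counts().sort_index()
            for delta, count in counts.items():
                records.append(
                    {
                        "band": band,
                        "behaviour": col.removesuffix("_delta"),
                        "delta": float(delta),
                        "count": int(count),
                        "percent": 100.0 * count / len(rows),
                    }
                )
    return pd.DataFrame(
        records, columns=["band", "behaviour", "delta", "count", "percent"]
    )


def plot_band_summary(summary: pd.DataFrame, path=None, ax=None):
    """Stacked-bar chart of delta-level percentages per behaviour."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    if len(summary) == 0:
        ax.set_title("empty band")
    else:
        pivot = summary.pivot_table(
            index="behaviour", columns="delta", values="percent", fill_value=0.0
        )
        bottom = np.zeros(len(pivot))
        cmap = matplotlib.colormaps["RdYlBu"]
        deltas = list(pivot.columns)
        for i, d in enumerate(deltas):
            ax.bar(
                pivot.index,
                pivot[d],
                bottom=bottom,
                label=f"{d:+g}",
                color=cmap(i / max(len(deltas) - 1, 1)),
            )
            bottom += pivot[d].to_numpy()
        ax.set_ylabel("% of options in band")
        ax.legend(fontsize=6, ncol=2, title="delta")
        ax.tick_params(axis="x", rotation=45)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=120)
        plt.close(ax.figure)
    return ax


# ---------------------------------------------------------------------------
# sequential interactive filtering


@dataclass(frozen=True)
class SelectionState:
    """State of a sequential behaviour-change exploration.

    Mirrors the decision flow of an interactive options app: the user
    fixes a target band, then repeatedly picks a behaviour and one of
    the delta values still available; each pick restricts the remaining
    option set. Selections are conjunctive, so the final subset does not
    depend on the order of the picks.
    """

    options: pd.DataFrame
    selections: tuple[tuple[str, float], ...] = ()

    @property
    def behaviours(self) -> list[str]:
        return [
            c.removesuffix("_delta")
            for c in self.options.columns
            if c.endswith("_delta")
        ]

    @property
    def remaining(self) -> pd.DataFrame:
        return self.options


def start_selection(table: OptionTable, band: float) -> SelectionState:
    rows = table.band_frame(band)
    if len(rows) == 0:
        raise ValueError(f"band {band:+g} contains no options")
    return SelectionState(options=rows.reset_index(drop=True))


def available_deltas(state: SelectionState) -> dict[str, list[float]]:
    """Deltas still offered for each behaviour not yet selected."""
    chosen = {b for b, _ in state.selections}
    out = {}
    for b in state.behaviours:
        if b in chosen:
            continue
        out[b] = sorted(state.options[f"{b}_delta"].unique().tolist())
    return out


def select_option(state: SelectionState, behaviour: str, delta: float) -> SelectionState:
    """Fix one behaviour's delta, narrowing the remaining options."""
    col = f"{behaviour}_delta"
    if col not in state.options.columns:
        raise KeyError(f"unknown behaviour {behaviour!r}")
    if behaviour in {b for b, _ in state.selections}:
        raise ValueError(f"{behaviour!r} already selected")
    avail = sorted(state.options[col].unique().tolist())
    if delta not in avail:
        raise ValueError(
            f"delta {delta:+g} not available for {behaviour!r}; choose from {avail}"
        )
    remaining = state.options[state.options[col] == delta].reset_index(drop=True)
    return SelectionState(
        options=remaining, selections=state.selections + ((behaviour, float(delta)),)
    )
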