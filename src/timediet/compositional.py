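"""Compositional geometry for 24-h time-use data.

The seven daily behaviours (sleep, self-care, screen time, quiet time,
physical activity, school-related, domestic/social) are treated as a
composition closed to 1440 min/day: only relative information is
meaningful, and the parts are perfectly collinear by construction. The
tools here implement the standard Aitchison-geometry workflow:

* replacement of zero durations by small positive values (diary zeros are
  taken as below-detection rather than structural absence), via an
  EM-style log-ratio imputation bounded by a configurable cap;
* isometric log-ratio (ilr) coordinates from a sequential binary
  partition, so the composition can enter a linear model as 6
  unconstrained columns;
* the closed geometric mean ("compositional mean") and its rounding to a
  10-min reference grid used as the starting point for reallocation
  modelling.

All public functions accept plain arrays ordered as :data:`TIME_USE_PARTS`
(or any explicitly supplied part list).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

#: canonical part order for the 7-part day
TIME_USE_PARTS: tuple[str, ...] = (
    "sleep",
    "self_care",
    "screen",
    "quiet",
    "physical_activity",
    "school",
    "domestic_social",
)

#: behaviours in which a diary zero is not allowed (everyone sleeps and
#: performs some self-care on any recorded day)
ZERO_FREE_PARTS: tuple[str, ...] = ("sleep", "self_care")

TOTAL_MINUTES: float = 1440.0

_CLOSURE_TOL = 1e-6


def closure(x: np.ndarray, total: float = TOTAL_MINUTES) -> np.ndarray:
    """Rescale rows of ``x`` to sum to ``total``."""
    x = np.asarray(x, dtype=float)
    s = x.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("cannot close a composition with non-positive total")
    return x * (total / s)


def _as_matrix(x) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    return x, False


def _check_closed(x: np.ndarray, total: float) -> None:
    bad = np.abs(x.sum(axis=1) - total) > _CLOSURE_TOL * max(total, 1.0)
    if bad.any():
        raise ValueError(
            f"row {int(np.flatnonzero(bad)[0])} does not sum to {total}"
        )


# ---------------------------------------------------------------------------
# ilr basis and transform


def make_sbp(parts=TIME_USE_PARTS) -> np.ndarray:
    """Orthonormal ilr contrast matrix for a pivot-balance partition.

    Row ``i`` contrasts part ``i`` against all later parts. For ``D``
    parts the result is a ``(D-1, D)`` matrix ``V`` with ``V @ V.T = I``
    and zero row sums; ilr coordinates are ``z = V @ ln(x)``.
    """
    parts = tuple(parts)
    if len(set(parts)) != len(parts):
        raise ValueError(f"duplicate part names in {parts}")
    d = len(parts)
    if d < 2:
        raise ValueError("need at least two parts")
    V = np.zeros((d - 1, d))
    for i in range(d - 1):
        r = d - i - 1  # number of parts in the denominator group
        V[i, i] = np.sqrt(r / (r + 1.0))
        V[i, i + 1 :] = -1.0 / np.sqrt(r * (r + 1.0))
    return V


def ilr_transform(x, sbp: np.ndarray | None = None) -> np.ndarray:
    """Map strictly positive compositions to ilr coordinates ``V @ ln x``."""
    xm, squeeze = _as_matrix(x)
    if sbp is None:
        sbp = make_sbp(TIME_USE_PARTS[: xm.shape[1]])
    if np.any(xm <= 0):
        raise ValueError(
            "composition has a non-positive part; run replace_zeros first"
        )
    z = np.log(xm) @ sbp.T
    return z[0] if squeeze else z


def ilr_inverse(z, sbp: np.ndarray | None = None, total: float = TOTAL_MINUTES) -> np.ndarray:
    """Invert ilr coordinates to a positive composition closed to ``total``."""
    zm, squeeze = _as_matrix(z)
    if sbp is None:
        sbp = make_sbp(TIME_USE_PARTS[: zm.shape[1] + 1])
    if not np.all(np.isfinite(zm)):
        raise ValueError("non-finite ilr coordinates")
    x = closure(np.exp(zm @ sbp), total)
    return x[0] if squeeze else x


def clr_transform(x) -> np.ndarray:
    """Centred log-ratio: ``ln x`` centred within each row."""
    xm, squeeze = _as_matrix(x)
    if np.any(xm <= 0):
        raise ValueError("composition has a non-positive part")
    lx = np.log(xm)
    out = lx - lx.mean(axis=1, keepdims=True)
    return out[0] if squeeze else out


def aitchison_distance(x, y) -> float:
    """Euclidean distance between the clr images of two compositions."""
    return float(np.linalg.norm(clr_transform(x) - clr_transform(y)))


def geometric_mean_composition(x, total: float = TOTAL_MINUTES) -> np.ndarray:
    """Closed geometric mean (the compositional mean) of the rows of ``x``."""
    xm, _ = _as_matrix(x)
    if xm.shape[0] == 0:
        raise ValueError("empty sample")
    if np.any(xm <= 0):
        raise ValueError("compositional mean requires strictly positive parts")
    return closure(np.exp(np.log(xm).mean(axis=0)), total)


# ---------------------------------------------------------------------------
# zero replacement


def multiplicative_replacement(
    x, delta: float = 6.5, total: float = TOTAL_MINUTES
) -> np.ndarray:
    """Simple multiplicative zero replacement.

    Every zero becomes ``delta`` and the remaining parts of the row are
    scaled down by a common factor so the row still sums to ``total``.
    Kept deliberately simple as an independent check on
    :func:`replace_zeros`.
    """
    xm, squeeze = _as_matrix(x)
    _check_closed(xm, total)
    out = xm.copy()
    zero = out == 0
    for i in np.flatnonzero(zero.any(axis=1)):
        z = zero[i]
        imputed = delta * z.sum()
        if imputed >= total:
            raise ValueError(f"row {i}: imputed mass exceeds the total")
        out[i, z] = delta
        out[i, ~z] *= (total - imputed) / xm[i, ~z].sum()
    return out[0] if squeeze else out


def replace_zeros(
    x,
    cap: float = 10.0,
    *,
    total: float = TOTAL_MINUTES,
    zero_free: tuple[int, ...] | None = None,
    parts: tuple[str, ...] = TIME_USE_PARTS,
    max_iter: int = 50,
    tol: float = 1e-6,
    init_frac: float = 0.65,
) -> np.ndarray:
    """Replace zero durations with small positive values, EM-style.

    Zeros are treated as censored small values. Starting from
    ``init_frac * cap``, each iteration (i) estimates the mean and
    covariance of the additive log-ratio coordinates of the whole sample,
    (ii) replaces each censored coordinate by its Gaussian conditional
    expectation given the row's observed coordinates, and (iii) maps back
    to minutes, capping every imputed value at ``cap`` and rescaling the
    observed parts of the row by a common factor so the row still closes
    to ``total`` (ratios between originally non-zero parts are therefore
    preserved). Iteration stops when the largest relative change of any
    imputed value falls below ``tol``.

    Parameters
    ----------
    x
        Matrix of raw durations, one row per person, rows summing to
        ``total``. Rows without zeros are returned unchanged.
    cap
        Upper bound (minutes) for any imputed value.
    zero_free
        Indices of parts in which zeros are invalid input. Defaults to
        the positions of :data:`ZERO_FREE_PARTS` within ``parts``.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    xm, squeeze = _as_matrix(x)
    if np.any(xm < 0):
        raise ValueError("negative duration")
    if np.any((xm > 0).sum(axis=1) == 0):
        raise ValueError("a row is entirely zero")
    _check_closed(xm, total)

    if zero_free is None:
        zero_free = tuple(
            parts.index(p) for p in ZERO_FREE_PARTS if p in parts
        )
    zero = xm == 0
    for j in zero_free:
        if zero[:, j].any():
            raise ValueError(
                f"zero duration in zero-free part {parts[j]!r} "
                f"(row {int(np.flatnonzero(zero[:, j])[0])})"
            )
    if not zero.any():
        return (xm[0] if squeeze else xm).copy()

    d = xm.shape[1]
    # reference part for the alr coordinates: first part with no zeros
    ref_candidates = np.flatnonzero(~zero.any(axis=0))
    if ref_candidates.size == 0:
        raise ValueError("no zero-free part available as alr reference")
    ref = int(ref_candidates[0])
    others = [j for j in range(d) if j != ref]

    w = xm.copy()
    w[zero] = init_frac * cap
    rows_z = np.flatnonzero(zero.any(axis=1))
    for i in rows_z:
        obs = ~zero[i]
        w[i, obs] *= (total - w[i, zero[i]].sum()) / xm[i, obs].sum()

    if xm.shape[0] < 3:
        # too few rows to estimate a log-ratio covariance: keep the
        # capped initial values (multiplicative-style replacement)
        return w[0] if squeeze else w

    # censoring patterns over alr coordinates, grouped for vectorisation
    col_of = {j: k for k, j in enumerate(others)}
    patterns: dict[tuple[int, ...], list[int]] = {}
    for i in rows_z:
        key = tuple(col_of[j] for j in np.flatnonzero(zero[i]))
        patterns.setdefault(key, []).append(i)

    prev = w[zero].copy()
    for _ in range(max_iter):
        a = np.log(w[:, others] / w[:, [ref]])
        mu = a.mean(axis=0)
        sigma = np.cov(a, rowvar=False)
        sigma = np.atleast_2d(sigma) + 1e-10 * np.eye(d - 1)
        for cen, rows in patterns.items():
            cen = list(cen)
            obs = [k for k in range(d - 1) if k not in cen]
            rows = np.asarray(rows)
            if obs:
                b = np.linalg.solve(sigma[np.ix_(obs, obs)], sigma[np.ix_(obs, cen)])
                cond = mu[cen] + (a[np.ix_(rows, obs)] - mu[obs]) @ b
                cvar = np.diag(sigma)[cen] - np.einsum(
                    "ij,ij->j", sigma[np.ix_(obs, cen)], b
                )
            else:
                cond = np.broadcast_to(mu[cen], (rows.size, len(cen))).copy()
                cvar = np.diag(sigma)[cen]
            csd = np.sqrt(np.maximum(cvar, 1e-12))
            # the cap acts as a detection limit: impute the conditional
            # expectation truncated to log-ratios below log(cap / ref)
            limit = np.log(cap / w[rows, ref])[:, None]
            alpha = (limit - cond) / csd
            cond = cond - csd * np.exp(norm.logpdf(alpha) - norm.logcdf(alpha))
            zcols = np.array([others[k] for k in cen])
            vals = np.minimum(w[rows, ref][:, None] * np.exp(cond), cap)
            w[np.ix_(rows, zcols)] = vals
        for i in rows_z:
            obs = ~zero[i]
            w[i, obs] *= (total - w[i, zero[i]].sum()) / w[i, obs].sum()
        cur = w[zero]
        if np.max(np.abs(cur - prev) / prev) < tol:
            break
        prev = cur.copy()

    return w[0] if squeeze else w


# ---------------------------------------------------------------------------
# reference profile


def round_composition(
    x, step: float = 10.0, total: float = TOTAL_MINUTES
) -> np.ndarray:
    """Round a composition to the ``step`` grid, preserving the total.

    Each part is first rounded to the nearest multiple of ``step``
    (halves away from zero). If the rounded parts no longer sum to
    ``total``, a largest-remainder adjustment moves one ``step`` at a
    time: the part whose rounding error is most in the direction of the
    surplus is adjusted, ties broken toward the part with the larger raw
    duration (perturbing a long behaviour changes relative time use
    least).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("round_composition expects a single composition")
    target = total / step
    if abs(target - round(target)) > 1e-9:
        raise ValueError("total is not a multiple of step")
    target = int(round(target))
    units = np.floor(x / step + 0.5)  # halves away from zero for positive data
    err = units - x / step
    while int(units.sum()) > target:
        i = np.lexsort((x, err))[-1]  # max error, tie -> larger raw value
        units[i] -= 1
        err[i] -= 1
    while int(units.sum()) < target:
        i = np.lexsort((x, -err))[-1]  # min error, tie -> larger raw value
        units[i] += 1
        err[i] += 1
    return units * step


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class ReferenceProfile:
    """The "average day" every simulated reallocation starts from.

    ``time`` holds 7 durations on the 10-min grid summing to exactly
    1440; ``diet`` holds integer reference serves for fruit/vegetables,
    discretionary foods and sugar-sweetened beverages.
    """

    time: np.ndarray
    diet: np.ndarray
    part_names: tuple[str, ...] = TIME_USE_PARTS
    diet_names: tuple[str, ...] = ("fruit_veg", "discretionary", "ssb")
    step: float = 10.0

    def __post_init__(self):
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "diet", np.asarray(self.diet, dtype=float))
        if abs(self.time.sum() - TOTAL_MINUTES) > 1e-9:
            raise ValueError("reference durations must sum to 1440")
        if np.any(np.abs(self.time / self.step - np.round(self.time / self.step)) > 1e-9):
            raise ValueError(f"reference durations must be multiples of {self.step}")

    def as_dict(self) -> dict:
        return {
            "time": dict(zip(self.part_names, self.time.tolist())),
            "diet": dict(zip(self.diet_names, self.diet.tolist())),
            "step": self.step,
        }


def reference_profile(
    time_matrix, diet_scores, step: float = 10.0, total: float = TOTAL_MINUTES
) -> ReferenceProfile:
    """Build the reallocation reference from a preprocessed sample.

    The time reference is the compositional (closed geometric) mean of
    the zero-replaced durations rounded to the nearest ``step`` with a
    total-preserving largest-remainder adjustment; the diet reference is
    the arithmetic mean of each serving score rounded to the nearest
    integer (halves away from zero).
    """
    tm, _ = _as_matrix(time_matrix)
    if tm.shape[0] == 0:
        raise ValueError("empty sample")
    if tm.shape[0] == 1:
        # a pre-computed mean: keep its reported precision, the grid
        # rounding below enforces the 1440 total
        mean = tm[0]
        if np.any(mean <= 0):
            raise ValueError("compositional mean requires strictly positive parts")
    else:
        mean = geometric_mean_composition(tm, total)
    time_ref = round_composition(mean, step, total)
    diet = np.asarray(diet_scores, dtype=float)
    if diet.ndim == 1:
        diet = diet[None, :]
    if diet.shape[0] == 0:
        raise ValueError("empty sample")
    diet_ref = _round_half_away(diet.mean(axis=0))
    return ReferenceProfile(time=time_ref, diet=diet_ref, step=step)
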