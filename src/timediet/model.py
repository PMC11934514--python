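"""Box-Cox linear model of physical functioning on time use and diet.

The analysis model is ordinary least squares of the Box-Cox-transformed
physical-functioning score on the six ilr coordinates of the 24-h
time-use composition, the three diet serving scores, and the covariates
age, sex and socioeconomic position:

    bc(y + shift; lambda) = b0 + bz' z + bd' diet + bc' cov + e

The composition enters as a block: its overall association is judged by
the partial F test comparing the full model with the model omitting all
six coordinates (the test is invariant to the particular ilr basis,
because different bases span the same column space). Diet associations
are reported as standardized betas, b * sd(x) / sd(transformed y).

lambda is estimated by profile likelihood on a bounded interval; a unit
shift is applied before transforming whenever the score attains 0 (the
scale floor), and recorded in the fitted model so predictions can be
mapped back to the 0-100 scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

from .compositional import TIME_USE_PARTS, ilr_transform, make_sbp
from .scoring import DIET_SCORE_COLUMNS

COVARIATE_COLUMNS = ["age", "sex", "sep"]
ILR_COLUMNS = [f"z{i}" for i in range(1, 7)]

BOXCOX_BOUNDS = (-5.0, 5.0)


# ---------------------------------------------------------------------------
# Box-Cox transform


def boxcox_apply(y, lam: float):
    """Box-Cox transform: ``(y**lam - 1)/lam`` (``log y`` at ``lam = 0``)."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if lam == 0.0:
        return np.log(y)
    return (np.power(y, lam) - 1.0) / lam


def boxcox_invert(t, lam: float):
    """Exact inverse of :func:`boxcox_apply`."""
    t = np.asarray(t, dtype=float)
    if lam == 0.0:
        return np.exp(t)
    base = lam * t + 1.0
    if np.any(base <= 0):
        raise ValueError("value outside the range of the Box-Cox transform")
    return np.power(base, 1.0 / lam)


def boxcox_loglik(lam: float, y, X: np.ndarray | None = None) -> float:
    """Profile log-likelihood of the Box-Cox parameter.

    With ``X`` given, profiles the Gaussian regression likelihood
    (lambda chosen to normalise the residuals); otherwise the marginal
    likelihood (intercept-only model).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    t = boxcox_apply(y, lam)
    if X is None:
        rss = float(np.sum((t - t.mean()) ** 2))
    else:
        resid = t - X @ np.linalg.lstsq(X, t, rcond=None)[0]
        rss = float(resid @ resid)
    if rss <= 0:
        raise ValueError("degenerate (zero-variance) response")
    return -0.5 * n * np.log(rss / n) + (lam - 1.0) * float(np.sum(np.log(y)))


def boxcox_fit(
    y, X: np.ndarray | None = None, bounds: tuple[float, float] = BOXCOX_BOUNDS
) -> float:
    """Estimate lambda by maximising the profile log-likelihood on ``bounds``.

    A coarse grid scan locates the basin; a bounded Brent refinement
    finds the maximum. Deterministic and derivative-free.
    """
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant response: Box-Cox lambda is undefined")
    grid = np.linspace(bounds[0], bounds[1], 41)
    ll = np.array([boxcox_loglik(l, y, X) for l in grid])
    k = int(np.argmax(ll))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda l: -boxcox_loglik(l, y, X), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# model fit


@dataclass
class FittedModel:
    """OLS fit of Box-Cox(physical functioning) on ilr + diet + covariates.

    Carries everything the equivalence engine needs to predict without
    refitting: the transform (``lam``, ``shift``), the coefficient
    vector, the ilr basis (``sbp``) and the covariate values at which
    predictions are fixed (sample mean for age and SEP, mode for sex).
    """

    lam: float
    shift: float
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    sigma2: float
    n: int
    df_resid: int
    sbp: np.ndarray
    part_order: tuple[str, ...]
    x_sd: pd.Series
    t_sd: float
    covariate_fix: dict[str, float]
    saturated: bool = False
    _results: object = field(default=None, repr=False, compare=False)
    _design: pd.DataFrame = field(default=None, repr=False, compare=False)
    _t: np.ndarray = field(default=None, repr=False, compare=False)

    def predict_transformed(self, composition, diet, covariates=None) -> float:
        """Linear predictor on the transformed scale for one profile."""
        z = ilr_transform(np.asarray(composition, dtype=float), self.sbp)
        cov = self.covariate_fix if covariates is None else covariates
        val = self.params["const"] + float(z @ self.params[ILR_COLUMNS].to_numpy())
        val += float(
            np.asarray(diet, dtype=float) @ self.params[DIET_SCORE_COLUMNS].to_numpy()
        )
        for c in COVARIATE_COLUMNS:
            val += self.params[c] * cov[c]
        return val

    def invert(self, t):
        """Back-transform a linear predictor to the 0-100 score scale."""
        return boxcox_invert(t, self.lam) - self.shift

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "lam": self.lam,
            "shift": self.shift,
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "sigma2": self.sigma2,
            "n": self.n,
            "df_resid": self.df_resid,
            "sbp": self.sbp.tolist(),
            "part_order": list(self.part_order),
            "x_sd": self.x_sd.to_dict(),
            "t_sd": self.t_sd,
            "covariate_fix": self.covariate_fix,
            "saturated": self.saturated,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            lam=d["lam"],
            shift=d["shift"],
            params=pd.Series(d["params"]),
            bse=pd.Series(d["bse"]),
            pvalues=pd.Series(d["pvalues"]),
            sigma2=d["sigma2"],
            n=d["n"],
            df_resid=d["df_resid"],
            sbp=np.asarray(d["sbp"], dtype=float),
            part_order=tuple(d["part_order"]),
            x_sd=pd.Series(d["x_sd"]),
            t_sd=d["t_sd"],
            covariate_fix=d["covariate_fix"],
            saturated=d.get("saturated", False),
        )

    @classmethod
    def load(cls, path) -> "FittedModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_design(df: pd.DataFrame, sbp: np.ndarray) -> pd.DataFrame:
    """Design matrix: intercept, z1..z6, diet scores, covariates."""
    comp = df[list(TIME_USE_PARTS)].to_numpy(dtype=float)
    z = ilr_transform(comp, sbp)
    X = pd.DataFrame(z, columns=ILR_COLUMNS[: z.shape[1]], index=df.index)
    for c in DIET_SCORE_COLUMNS + COVARIATE_COLUMNS:
        X[c] = df[c].to_numpy(dtype=float)
    return sm.add_constant(X, has_constant="add")


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        culprits = [
            col
            for col in X.columns
            if np.linalg.matrix_rank(X.drop(columns=col).to_numpy(dtype=float)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {culprits}")


def fit_model(
    df: pd.DataFrame,
    sbp: np.ndarray | None = None,
    lam: float | None = None,
    shift: float | None = None,
) -> FittedModel:
    """Fit the physical-functioning model on a complete-case cohort.

    ``df`` must carry the seven (strictly positive, zero-replaced)
    duration columns, the three diet scores, ``age``/``sex``/``sep`` and
    ``pf_score``, with no missing values. ``lam`` and ``shift`` may be
    fixed (e.g. for simulation studies with known ground truth);
    by default ``shift`` is 1 when the score attains 0 and ``lam`` is
    estimated by regression profile likelihood.
    """
    required = (
        list(TIME_USE_PARTS) + DIET_SCORE_COLUMNS + COVARIATE_COLUMNS + ["pf_score"]
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KeyError(f"missing columns: {missing}")
    if df[required].isna().any().any():
        raise ValueError("missing values present: filter to complete cases first")
    n = len(df)
    if n < 13:
        raise ValueError(f"need at least 13 observations, got {n}")

    if sbp is None:
        sbp = make_sbp(TIME_USE_PARTS)
    X = build_design(df, sbp)
    _check_rank(X)

    y = df["pf_score"].to_numpy(dtype=float)
    if shift is None:
        shift = 1.0 if y.min() <= 0 else 0.0
    if np.any(y + shift <= 0):
        raise ValueError("non-positive response after shift")
    if lam is None:
        lam = boxcox_fit(y + shift, X.to_numpy(dtype=float))
    t = boxcox_apply(y + shift, lam)

    res = sm.OLS(t, X).fit()
    df_resid = int(res.df_resid)
    sigma2 = float(res.ssr / df_resid) if df_resid > 0 else 0.0

    sex = df["sex"].to_numpy(dtype=float)
    mode_sex = 1.0 if np.mean(sex) > 0.5 else 0.0  # ties -> 0 (female)
    return FittedModel(
        lam=float(lam),
        shift=float(shift),
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        sigma2=sigma2,
        n=n,
        df_resid=df_resid,
        sbp=sbp,
        part_order=TIME_USE_PARTS,
        x_sd=X.drop(columns="const").std(ddof=1),
        t_sd=float(np.std(t, ddof=1)),
        covariate_fix={
            "age": float(df["age"].mean()),
            "sex": mode_sex,
            "sep": float(df["sep"].mean()),
        },
        saturated=df_resid == 0,
        _results=res,
        _design=X,
        _t=t,
    )


# ---------------------------------------------------------------------------
# inference


@dataclass(frozen=True)
class BlockTestResult:
    F: float
    df1: int
    df2: int
    p: float


def _require_results(model: FittedModel):
    if model._results is None:
        raise ValueError(
            "model was deserialized without data; refit to run tests"
        )
    return model._results


def composition_block_test(model: FittedModel) -> BlockTestResult:
    """Partial F test of the six ilr coordinates as a block.

    Compares the full fit with the nested model omitting every ilr
    coordinate; answers whether the overall time-use composition is
    associated with the outcome, independently of the basis chosen.
    """
    res = _require_results(model)
    X = model._design
    reduced = sm.OLS(model._t, X.drop(columns=ILR_COLUMNS)).fit()
    f, p, df_num = res.compare_f_test(reduced)
    return BlockTestResult(F=float(f), df1=int(df_num), df2=model.df_resid, p=float(p))


def standardized_betas(
    model: FittedModel, variables: tuple[str, ...] = tuple(DIET_SCORE_COLUMNS)
) -> pd.DataFrame:
    """Standardized coefficients ``b * sd(x) / sd(t)`` with their p-values."""
    rows = []
    for v in variables:
        sd_x = model.x_sd[v]
        if sd_x == 0 or model.t_sd == 0:
            raise ValueError(f"zero-variance variable {v!r}")
        rows.append(
            {
                "variable": v,
                "std_beta": model.params[v] * sd_x / model.t_sd,
                "p": model.pvalues[v],
            }
        )
    return pd.DataFrame(rows)


def sex_interaction_screen(model: FittedModel) -> pd.DataFrame:
    """Joint partial-F screen of sex-by-behaviour interactions.

    For the composition, the six sex * z terms are added jointly; each
    diet score contributes a single sex * score term. Returns one row
    per behavioural block with the partial F and its p-value. Raises if
    the sample contains a single sex (interactions inestimable).
    """
    res = _require_results(model)
    X = model._design
    sex = X["sex"].to_numpy()
    if np.unique(sex).size < 2:
        raise ValueError("single-sex sample: sex interactions are inestimable")
    blocks = {"composition": ILR_COLUMNS, **{v: [v] for v in DIET_SCORE_COLUMNS}}
    rows = []
    for name, cols in blocks.items():
        Xi = X.copy()
        for c in cols:
            Xi[f"sex_x_{c}"] = Xi[c] * sex
        full = sm.OLS(model._t, Xi).fit()
        f, p, df_num = full.compare_f_test(res)
        rows.append(
            {"block": name, "F": float(f), "df1": int(df_num),
             "df2": int(full.df_resid), "p": float(p)}
        )
    return pd.DataFrame(rows)
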