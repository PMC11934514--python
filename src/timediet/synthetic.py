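"""Synthetic adolescent cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes
for a population-based adolescent sample: a 7-part 24-h time-use
composition with a logistic-normal law centred on a realistic
compositional mean (sleep approx 741 min/day, physical activity approx
50 min/day, ...), occasional diary zeros in the five behaviours that can
plausibly be skipped on a single day, item-level diet questionnaire
responses calibrated so the serving scores average about 3.7 / 2.0 /
0.6 serves/day, covariates (age approx N(14.4, 0.5), sex approx
Bernoulli(0.5), SEP z-score approx N(0, 1)), and a physical-functioning
outcome generated from a known linear model on the ilr coordinates,
diet scores and covariates on a Box-Cox-transformed scale.

Everything downstream (scoring, zero replacement, model fit, the
equivalence engine) can therefore be tested against known parameters.
The generated outcome uses the same preprocessing chain as the analysis
(zero replacement, then ilr in the configured basis), so the fitted
model is correctly specified up to the item quantisation of the
PedsQL scale and the clamping of the score to [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import scoring
from .compositional import (
    TIME_USE_PARTS,
    TOTAL_MINUTES,
    closure,
    ilr_transform,
    make_sbp,
    replace_zeros,
)
from .model import ILR_COLUMNS, boxcox_apply, boxcox_invert

DIET_ITEM_ALL = [c for cols in scoring.DIET_ITEM_COLUMNS.values() for c in cols]


def _clr_to_ilr_beta(clr_beta: np.ndarray, sbp: np.ndarray) -> np.ndarray:
    """Map a sum-zero coefficient vector on log-parts to ilr coefficients."""
    return sbp @ clr_beta


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters of the synthetic cohort.

    Defaults are calibrated to a mid-adolescent population: the
    compositional mean and diet/covariate moments mirror a large
    Australian cohort's descriptives, per-part log-scale spreads are
    set so arithmetic SDs of the generated durations land near the
    reported ones, and the outcome model produces a physical-functioning
    scale averaging about 89 points with behaviour effects of a few
    scale points across a feasible behaviour-change range.
    """

    n: int = 2000
    # time use -------------------------------------------------------------
    mean_composition: tuple[float, ...] = (741.0, 125.0, 163.0, 175.0, 50.0, 129.0, 58.0)
    log_sd: tuple[float, ...] = (0.147, 0.459, 1.03, 0.714, 1.227, 1.273, 1.195)
    zero_rates: tuple[float, ...] = (0.0, 0.0, 0.002, 0.002, 0.008, 0.003, 0.006)
    zero_cap: float = 10.0
    # diet: P(item response = 0..3) per food group --------------------------
    fruit_veg_probs: tuple[float, ...] = (0.30, 0.33, 0.20, 0.17)
    discretionary_probs: tuple[float, ...] = (0.62, 0.28, 0.08, 0.02)
    ssb_probs: tuple[float, ...] = (0.78, 0.15, 0.06, 0.01)
    # covariates ------------------------------------------------------------
    age_mean: float = 14.4
    age_sd: float = 0.5
    sex_p: float = 0.5
    sep_mean: float = 0.0
    sep_sd: float = 1.0
    # outcome model on the Box-Cox transformed scale ------------------------
    true_clr_beta: tuple[float, ...] = (190.0, -110.0, -110.0, -90.0, 170.0, 20.0, -70.0)
    true_diet_beta: tuple[float, ...] = (30.0, -25.0, -45.0)
    true_covariate_beta: tuple[float, ...] = (-20.0, 40.0, 25.0)  # age, sex, sep
    sex_interaction_clr: tuple[float, ...] = (0.0,) * 7
    true_lambda: float = 2.0
    true_shift: float = 0.0
    sigma: float = 268.0
    target_mean_pf: float = 89.3
    # missingness -----------------------------------------------------------
    missing_pedsql_rate: float = 0.01
    missing_pedsql_scale_rate: float = 0.004  # person skips the whole scale
    missing_diet_rate: float = 0.005

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if abs(sum(self.true_clr_beta)) > 1e-9:
            raise ValueError("true_clr_beta must sum to zero (log-contrast)")
        if abs(sum(self.sex_interaction_clr)) > 1e-9:
            raise ValueError("sex_interaction_clr must sum to zero")
        for name in ("fruit_veg_probs", "discretionary_probs", "ssb_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.size != 4 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be 4 probabilities summing to 1")
        for name in ("log_sd", "zero_rates"):
            v = getattr(self, name)
            if len(v) != 7:
                raise ValueError(f"{name} must have 7 entries")
        if any(r > 0 for r in self.zero_rates[:2]):
            raise ValueError("sleep and self-care are zero-free behaviours")

    # ---- derived quantities ----------------------------------------------

    @property
    def sbp(self) -> np.ndarray:
        return make_sbp(TIME_USE_PARTS)

    @property
    def ilr_covariance(self) -> np.ndarray:
        """ilr covariance implied by independent log-part spreads.

        With ``ln x ~ N(mu, diag(s^2))`` before closure, the clr
        covariance is ``G diag(s^2) G`` with ``G = I - J/7``, and the
        ilr covariance is its projection through the basis.
        """
        s2 = np.diag(np.asarray(self.log_sd, dtype=float) ** 2)
        d = len(self.log_sd)
        g = np.eye(d) - np.ones((d, d)) / d
        V = self.sbp
        cov = V @ g @ s2 @ g @ V.T
        # guard: must be positive definite
        np.linalg.cholesky(cov)
        return cov

    @property
    def diet_item_probs(self) -> dict[str, tuple[float, ...]]:
        return {
            "fruit_veg": self.fruit_veg_probs,
            "discretionary": self.discretionary_probs,
            "ssb": self.ssb_probs,
        }

    def expected_diet_means(self) -> np.ndarray:
        """Expected serving-score means implied by the item probabilities."""
        out = []
        for group, cols in scoring.DIET_ITEM_COLUMNS.items():
            p = np.asarray(self.diet_item_probs[group], dtype=float)
            out.append(len(cols) * float(p @ np.arange(4)))
        return np.array(out)

    def true_params(self) -> pd.Series:
        """Ground-truth coefficients in the fitted model's parameterization."""
        beta_z = _clr_to_ilr_beta(np.asarray(self.true_clr_beta), self.sbp)
        mean = closure(np.asarray(self.mean_composition, dtype=float), TOTAL_MINUTES)
        t_target = float(boxcox_apply(self.target_mean_pf + self.true_shift, self.true_lambda))
        lin = float(ilr_transform(mean, self.sbp) @ beta_z)
        lin += float(self.expected_diet_means() @ np.asarray(self.true_diet_beta))
        ba, bs, bp = self.true_covariate_beta
        lin += ba * self.age_mean + bs * self.sex_p + bp * self.sep_mean
        values = np.concatenate(
            [[t_target - lin], beta_z, self.true_diet_beta, self.true_covariate_beta]
        )
        names = ["const"] + ILR_COLUMNS + scoring.DIET_SCORE_COLUMNS + ["age", "sex", "sep"]
        return pd.Series(values, index=names)


# ---------------------------------------------------------------------------
# generation


def _round_rows_to_total(x: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rounding of each row to integers summing to total."""
    base = np.floor(x)
    need = (total - base.sum(axis=1)).astype(int)
    frac = x - base
    # rank fractional parts descending within each row
    order = np.argsort(-frac, axis=1, kind="stable")
    rank = np.empty_like(order)
    rows = np.arange(x.shape[0])[:, None]
    rank[rows, order] = np.arange(x.shape[1])[None, :]
    return base + (rank < need[:, None])


def gen_timeuse(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw integer-minute daily compositions, with diary zeros injected.

    ilr coordinates are drawn from a multivariate normal centred on the
    configured compositional mean, inverted to minutes, rounded to whole
    minutes preserving the 1440 total, and then, with the configured
    per-behaviour probability, a behaviour's whole duration is
    redistributed pro-rata over the remaining parts (a day on which the
    behaviour was simply not done; pro-rata donation preserves the
    ratios among the remaining behaviours, so the cohort's compositional
    mean stays centred on the configured one).
    """
    mean = closure(np.asarray(config.mean_composition, dtype=float), TOTAL_MINUTES)
    z0 = ilr_transform(mean, config.sbp)
    cov = config.ilr_covariance
    z = rng.multivariate_normal(z0, cov, size=config.n, method="cholesky")
    x = closure(np.exp(z @ config.sbp), TOTAL_MINUTES)
    x = _round_rows_to_total(x, int(TOTAL_MINUTES))
    for b, rate in enumerate(config.zero_rates):
        if rate <= 0:
            continue
        hit = np.flatnonzero(rng.random(config.n) < rate)
        for i in hit:
            if x[i, b] == 0:
                continue
            keep = np.ones(x.shape[1], dtype=bool)
            keep[b] = False
            scaled = x[i, keep] * (TOTAL_MINUTES / x[i, keep].sum())
            x[i, keep] = _round_rows_to_total(scaled[None, :], int(TOTAL_MINUTES))[0]
            x[i, b] = 0
    return x


def gen_diet(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Independent categorical draws for the ten diet items (0..3)."""
    out = {}
    for group, cols in scoring.DIET_ITEM_COLUMNS.items():
        p = np.asarray(config.diet_item_probs[group], dtype=float)
        for c in cols:
            out[c] = rng.choice(4, size=config.n, p=p).astype(float)
    return pd.DataFrame(out)


def gen_covariates(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": rng.normal(config.age_mean, config.age_sd, config.n),
            "sex": (rng.random(config.n) < config.sex_p).astype(float),
            "sep": rng.normal(config.sep_mean, config.sep_sd, config.n),
        }
    )


def _score_to_items(score: np.ndarray) -> np.ndarray:
    """Deterministically convert 0-100 scores to 8 PedsQL item responses.

    The item sum is the nearest integer to ``32 - 0.32 * score``; the sum
    is spread as evenly as possible over the items, so the re-scored mean
    reproduces the score to within half the item-grid resolution
    (25/8 points).
    """
    s = np.clip(np.rint(32.0 - 0.32 * np.asarray(score, dtype=float)), 0, 32).astype(int)
    q, r = np.divmod(s, 8)
    items = np.tile(q[:, None], (1, 8))
    items[np.arange(8)[None, :] < r[:, None]] += 1
    return items.astype(float)


def gen_outcome(
    config: GeneratorConfig,
    durations: np.ndarray,
    diet_items: pd.DataFrame,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Generate PedsQL item responses from the true linear model.

    The latent transformed score is built from the true preprocessing
    chain (zero replacement, then ilr in the configured basis), the true
    coefficients and Gaussian noise; it is back-transformed, clamped to
    [0, 100] and quantised onto the 8-item response grid.
    """
    if config.sigma < 0:
        raise ValueError("sigma must be non-negative")
    positive = replace_zeros(
        np.asarray(durations, dtype=float), cap=config.zero_cap
    )
    z = ilr_transform(positive, config.sbp)
    scores = scoring.score_diet(diet_items).to_numpy(dtype=float)
    beta = config.true_params()
    t = (
        beta["const"]
        + z @ beta[ILR_COLUMNS].to_numpy()
        + scores @ beta[scoring.DIET_SCORE_COLUMNS].to_numpy()
        + covariates[["age", "sex", "sep"]].to_numpy() @ beta[["age", "sex", "sep"]].to_numpy()
    )
    if any(v != 0 for v in config.sex_interaction_clr):
        a_int = config.sbp @ np.asarray(config.sex_interaction_clr)
        t = t + covariates["sex"].to_numpy() * (z @ a_int)
    t = t + rng.normal(0.0, config.sigma, config.n)
    y = np.clip(boxcox_invert(t, config.true_lambda) - config.true_shift, 0.0, 100.0)
    items = _score_to_items(y)
    return pd.DataFrame(items, columns=scoring.PEDSQL_ITEM_COLUMNS)


def generate_cohort(
    config: GeneratorConfig | None = None, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, dict]:
    """Generate a full person-level cohort and its ground truth.

    Returns the cohort DataFrame (raw durations with zeros, diet and
    PedsQL item responses with missingness injected, covariates) and a
    dictionary with the true parameters in the fitted model's
    parameterization.
    """
    config = config or GeneratorConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    durations = gen_timeuse(config, rng)
    diet = gen_diet(config, rng)
    covs = gen_covariates(config, rng)
    peds = gen_outcome(config, durations, diet, covs, rng)

    # missingness injected after outcome generation (missing at random)
    if config.missing_diet_rate > 0:
        mask = rng.random(diet.shape) < config.missing_diet_rate
        diet = diet.mask(mask)
    if config.missing_pedsql_rate > 0:
        mask = rng.random(peds.shape) < config.missing_pedsql_rate
        peds = peds.mask(mask)
    if config.missing_pedsql_scale_rate > 0:
        whole = rng.random(len(peds)) < config.missing_pedsql_scale_rate
        peds = peds.mask(np.broadcast_to(whole[:, None], peds.shape))

    df = pd.concat(
        [
            pd.DataFrame(durations.astype(float), columns=list(TIME_USE_PARTS)),
            diet,
            peds,
            covs,
        ],
        axis=1,
    )
    truth = {
        "params": config.true_params(),
        "lam": config.true_lambda,
        "shift": config.true_shift,
        "sigma": config.sigma,
        "config": config,
    }
    return df, truth
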